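"""End-to-end workflow: filter -> prioritize -> intersect -> enrich.

Mirrors the two-arm study design: the discovery arm extracts variants
with the recessive inheritance pattern and filters them on MAF and
predicted deleteriousness; the hypothesis arm propagates seed-gene mass
over the interaction network and keeps genes with significant
permutation p-values.  The report intersects the filtered-variant genes
with the union of seed genes and network-significant genes, lists
per-sample genotype occurrences, tracks parental-carrier variants
separately, and records the full configuration in a manifest so runs
are reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .enrichment import hypergeometric_enrichment, read_gmt
from .genemodel import read_bed12
from .network import load_network, permutation_pvalues, prioritize
from .pedigree import read_ped
from .variants import (
    annotate_regions,
    deleteriousness_filter,
    inheritance_filter,
    maf_filter,
    read_vcf,
    summarize_counts,
    variants_to_frame,
)

logger = logging.getLogger(__name__)


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    vcf: str
    ped: str
    gene_model: str
    network: str
    seeds: str
    out_dir: str
    categories: str | None = None
    max_maf: float = 0.0
    keep_unknown_maf: bool = False
    apply_deleteriousness: bool = True
    score_threshold: float = 0.0
    method: str = "random_walk_restart"
    params: dict = field(default_factory=dict)
    n_perm: int = 10_000
    alpha: float = 0.005
    rng_seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)


def read_seed_list(path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def _occurrences(variant, pedigree) -> tuple[str, str]:
    """Comma-joined sample labels carrying the alternate allele."""
    children = [s.sample_id for s in pedigree.affected()]
    parents: dict[str, None] = {}
    for c in children:
        for p in pedigree.parents_of(c):
            parents.setdefault(p.sample_id)
    in_patients = [
        c for c in children if variant.genotypes[c].carries(variant.alt_index)
    ]
    in_parents = [
        p for p in parents if variant.genotypes[p].is_het_for(variant.alt_index)
    ]
    return ", ".join(in_patients), ", ".join(in_parents)


def run_pipeline(config: PipelineConfig) -> dict[str, str]:
    """Run every stage; return a name -> path map of the report bundle."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}
    timings: dict[str, float] = {}

    def stage(name: str, fn):
        t0 = time.perf_counter()
        try:
            result = fn()
        except Exception as exc:
            logger.error("stage %s failed: %s", name, exc)
            raise PipelineStageError(name, exc) from exc
        timings[name] = round(time.perf_counter() - t0, 4)
        logger.info("stage %s finished in %.2fs", name, timings[name])
        return result

    def load_inputs():
        return (
            read_vcf(config.vcf),
            read_ped(config.ped),
            read_bed12(config.gene_model),
            read_seed_list(config.seeds),
        )

    variants, pedigree, model, seeds = stage("load_inputs", load_inputs)

    def filter_variants():
        classified = annotate_regions(variants, model)
        qualifying = inheritance_filter(classified, pedigree)
        counts = summarize_counts(qualifying)
        filtered = maf_filter(
            qualifying, config.max_maf, keep_unknown=config.keep_unknown_maf
        )
        if config.apply_deleteriousness:
            filtered = deleteriousness_filter(filtered)
        return classified, qualifying, filtered, counts

    classified, qualifying, filtered, counts = stage("filter", filter_variants)
    frame = variants_to_frame(filtered)
    frame.to_csv(out_dir / "filtered_variants.tsv", sep="\t", index=False)
    counts.rename_axis("region_class").reset_index().to_csv(
        out_dir / "region_counts.tsv", sep="\t", index=False
    )
    outputs["filtered_variants"] = str(out_dir / "filtered_variants.tsv")
    outputs["region_counts"] = str(out_dir / "region_counts.tsv")

    def prioritization():
        network = load_network(config.network, config.score_threshold)
        results = permutation_pvalues(
            network,
            seeds,
            method=config.method,
            params=config.params,
            n_perm=config.n_perm,
            rng_seed=config.rng_seed,
        )
        if config.alpha > 0:
            significant = prioritize(results, config.alpha)
        else:  # alpha = 0: nothing can satisfy p < 0
            significant = results.iloc[0:0]
        return results, significant

    results, significant = stage("prioritize", prioritization)
    results.to_csv(out_dir / "prioritization.tsv", sep="\t", index=False)
    outputs["prioritization"] = str(out_dir / "prioritization.tsv")

    def intersect():
        candidate_genes = set(seeds) | set(significant["gene"])
        pmap = dict(zip(results["gene"], results["p_value"]))
        rows, carrier_rows = [], []
        pool = maf_filter(
            classified, config.max_maf, keep_unknown=config.keep_unknown_maf
        )
        if config.apply_deleteriousness:
            pool = deleteriousness_filter(pool)
        qual_keys = {v.key for v in filtered}
        children = [s.sample_id for s in pedigree.affected()]
        for v in pool:
            if v.gene is None or v.gene not in candidate_genes:
                continue
            in_patients, in_parents = _occurrences(v, pedigree)
            row = {
                "gene": v.gene,
                "nw_p_value": pmap.get(v.gene, "seed"),
                "variant": v.key,
                "region_class": v.region_class,
                "deleteriousness": v.deleteriousness,
                "maf": v.maf,
                "occurrence_in_patients": in_patients,
                "occurrence_in_parents": in_parents,
            }
            if v.key in qual_keys:
                rows.append(row)
            elif not any(
                v.genotypes[c].is_hom_alt(v.alt_index) for c in children
            ) and in_parents:
                carrier_rows.append(row)
        cols = list(
            rows[0] if rows else {
                "gene": 0, "nw_p_value": 0, "variant": 0, "region_class": 0,
                "deleteriousness": 0, "maf": 0, "occurrence_in_patients": 0,
                "occurrence_in_parents": 0,
            }
        )
        return (
            pd.DataFrame(rows, columns=cols),
            pd.DataFrame(carrier_rows, columns=cols),
        )

    intersection, carriers = stage("intersect", intersect)
    intersection.to_csv(out_dir / "intersection.tsv", sep="\t", index=False)
    carriers.to_csv(out_dir / "parental_carriers.tsv", sep="\t", index=False)
    outputs["intersection"] = str(out_dir / "intersection.tsv")
    outputs["parental_carriers"] = str(out_dir / "parental_carriers.tsv")

    if config.categories is not None:
        def enrich():
            cats = read_gmt(config.categories)
            query = sorted({v.gene for v in filtered if v.gene is not None})
            return hypergeometric_enrichment(query, cats)

        enrichment = stage("enrich", enrich)
        enrichment.to_csv(out_dir / "enrichment.tsv", sep="\t", index=False)
        outputs["enrichment"] = str(out_dir / "enrichment.tsv")

    manifest = {
        "config": dataclasses.asdict(config),
        "rng_seed": config.rng_seed,
        "varprior_version": __version__,
        "stage_timings_s": timings,
        "outputs": outputs,
        "n_variants": len(variants),
        "n_qualifying": len(qualifying),
        "n_filtered": len(filtered),
        "n_significant": int(len(significant)),
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    outputs["manifest"] = str(out_dir / "manifest.json")
    return outputs
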