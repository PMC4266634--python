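"""Synthetic cohorts with known planted structure.

Every downstream stage is exercised against data whose ground truth is
known exactly: nuclear families with a planted recessive genotype
pattern (homozygous-alternate in all affected children, heterozygous in
all parents), a gene model with exon/UTR/intron structure, INFO-field
MAF and deleteriousness annotations, and a scale-free interaction
network carrying a densely connected planted module around the seed
genes.

Non-qualifying variants are actively corrupted — at least one required
sample's genotype is forced off the qualifying pattern — so planted
counts are exact rather than expected, and filter tests are
deterministic.  All generation is reproducible from the spec's RNG
seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .genemodel import GeneModel, Transcript
from .network import GeneNetwork
from .pedigree import Pedigree, Sample
from .variants import REGION_CLASSES, _classify_against_transcript

_BASES = ("A", "C", "G", "T")

DEFAULT_REGION_MIX = {
    "exonic": 0.10,
    "utr5": 0.05,
    "utr3": 0.05,
    "intronic": 0.40,
    "intergenic": 0.40,
}


class PlacementError(ValueError):
    """The gene model cannot host the requested region mix."""


@dataclass(frozen=True)
class PlantSpec:
    """What to plant in a synthetic variant set."""

    n_variants_total: int = 200
    n_qualifying: int = 12
    n_rare: int = 60  # MAF exactly 0
    region_mix: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_REGION_MIX)
    )
    deleterious_fraction: float = 0.6
    rng_seed: int = 0

    def __post_init__(self):
        if min(self.n_variants_total, self.n_qualifying, self.n_rare) < 0:
            raise ValueError("counts must be nonnegative")
        if self.n_qualifying > self.n_variants_total:
            raise ValueError("n_qualifying exceeds n_variants_total")
        if self.n_rare > self.n_variants_total:
            raise ValueError("n_rare exceeds n_variants_total")
        if set(self.region_mix) != set(REGION_CLASSES):
            raise ValueError(f"region_mix must cover {REGION_CLASSES}")
        if abs(sum(self.region_mix.values()) - 1.0) > 1e-9:
            raise ValueError("region_mix must sum to 1")
        if not 0.0 <= self.deleterious_fraction <= 1.0:
            raise ValueError("deleterious_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class NetworkPlantSpec:
    """A scale-free background graph with a dense planted module."""

    n_nodes: int = 500
    attachment_parameter: int = 3
    module_genes: tuple[str, ...] = tuple(f"MOD{i:02d}" for i in range(1, 11))
    module_edge_weight: float = 0.99
    background_genes: tuple[str, ...] = ()
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_nodes <= len(self.module_genes):
            raise ValueError("n_nodes must exceed the module size")
        if not 0.0 <= self.module_edge_weight <= 1.0:
            raise ValueError("module_edge_weight must lie in [0, 1]")
        if self.attachment_parameter < 1:
            raise ValueError("attachment_parameter must be >= 1")


def generate_pedigree(n_families: int, children_per_family: int) -> Pedigree:
    """Nuclear families: two unaffected parents, affected children.

    Sample naming follows the fF/fM (father/mother) and fC1, fC2, ...
    (children) convention with f the 1-based family index.
    """
    if n_families < 1 or children_per_family < 1:
        raise ValueError("need at least one family with at least one child")
    samples: list[Sample] = []
    for f in range(1, n_families + 1):
        fam = str(f)
        father, mother = f"{f}F", f"{f}M"
        samples.append(Sample(father, fam, None, None, 1, affected=False))
        samples.append(Sample(mother, fam, None, None, 2, affected=False))
        for c in range(1, children_per_family + 1):
            samples.append(
                Sample(f"{f}C{c}", fam, father, mother, (c % 2) + 1, affected=True)
            )
    return Pedigree(samples)


def generate_gene_model(n_genes: int = 30, chrom: str = "chr1") -> GeneModel:
    """Deterministic three-exon genes on one chromosome.

    Each gene spans 1300 bp in a 10 kb slot: exons at offsets
    [0, 300), [500, 800), [1000, 1300) with CDS [150, 1150), leaving
    150 bp of UTR at each end and two introns.  Strands alternate so
    both UTR orientations are exercised.
    """
    transcripts = []
    for i in range(n_genes):
        o = 1000 + i * 10_000
        transcripts.append(
            Transcript(
                gene=f"G{i + 1:03d}",
                chrom=chrom,
                strand="+" if i % 2 == 0 else "-",
                exons=((o, o + 300), (o + 500, o + 800), (o + 1000, o + 1300)),
                cds_start=o + 150,
                cds_end=o + 1150,
            )
        )
    return GeneModel(transcripts)


def _position_pools(
    model: GeneModel, chrom_length: int
) -> tuple[dict[str, list[tuple[str, int]]], list[tuple[str, int, int]]]:
    """Per-class genic position pools plus intergenic gap intervals."""
    pools: dict[str, list[tuple[str, int]]] = {c: [] for c in REGION_CLASSES}
    spans: dict[str, list[tuple[int, int]]] = {}
    for t in model.transcripts:
        for pos0 in range(t.start, t.end):
            pools[_classify_against_transcript(pos0, t)].append((t.chrom, pos0))
        spans.setdefault(t.chrom, []).append((t.start, t.end))
    gaps: list[tuple[str, int, int]] = []
    for chrom, ivals in spans.items():
        ivals.sort()
        cursor = 0
        for s, e in ivals:
            if s > cursor:
                gaps.append((chrom, cursor, s))
            cursor = max(cursor, e)
        if chrom_length > cursor:
            gaps.append((chrom, cursor, chrom_length))
    return pools, gaps


def _vcf_header(samples: list[str], contigs: dict[str, int]) -> str:
    lines = ["##fileformat=VCFv4.2"]
    for chrom, length in contigs.items():
        lines.append(f"##contig=<ID={chrom},length={length}>")
    lines.append(
        '##INFO=<ID=MAF,Number=1,Type=Float,Description="Minor allele frequency">'
    )
    lines.append(
        '##INFO=<ID=DEL_CLASS,Number=1,Type=String,'
        'Description="Predicted deleteriousness class">'
    )
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples)
    )
    return "\n".join(lines)


def generate_variant_set(
    pedigree: Pedigree,
    gene_model: GeneModel,
    spec: PlantSpec,
    vcf_path,
    chrom_length: int | None = None,
) -> pd.DataFrame:
    """Write a multi-sample VCF with planted structure; return its truth table.

    Exactly ``spec.n_qualifying`` variants carry the recessive pattern
    (children 1/1, parents 0/1); every other variant is corrupted in at
    least one required sample.  The truth table has one row per VCF
    record with columns chrom, pos, ref, alt, region_class, gene, maf,
    del_class, qualifying.
    """
    if len(gene_model) == 0:
        raise ValueError("gene model is empty")
    rng = np.random.default_rng(spec.rng_seed)
    if chrom_length is None:
        chrom_length = max(t.end for t in gene_model.transcripts) + 10_000
    pools, gaps = _position_pools(gene_model, chrom_length)

    classes = list(REGION_CLASSES)
    probs = np.array([spec.region_mix[c] for c in classes])
    counts = rng.multinomial(spec.n_variants_total, probs)

    positions: list[tuple[str, int, str]] = []  # (chrom, pos0, class)
    for cls, need in zip(classes, counts):
        if need == 0:
            continue
        if cls == "intergenic":
            lengths = np.array([e - s for _, s, e in gaps], dtype=float)
            if lengths.sum() < need:
                raise PlacementError("not enough intergenic space")
            chosen: set[tuple[str, int]] = set()
            while len(chosen) < need:
                gi = rng.choice(len(gaps), p=lengths / lengths.sum())
                chrom, s, e = gaps[gi]
                chosen.add((chrom, int(rng.integers(s, e))))
            positions += [(c, p, cls) for c, p in sorted(chosen)]
        else:
            pool = pools[cls]
            if len(pool) < need:
                raise PlacementError(
                    f"gene model offers {len(pool)} {cls} positions, need {need}"
                )
            idx = rng.choice(len(pool), size=need, replace=False)
            positions += [(pool[i][0], pool[i][1], cls) for i in sorted(idx)]

    n = len(positions)
    qualifying = np.zeros(n, dtype=bool)
    qualifying[rng.choice(n, size=spec.n_qualifying, replace=False)] = True
    # rare (MAF = 0) variants preferentially cover the planted recessive
    # set: causal recessive candidates are the population-unobserved ones
    rare = np.zeros(n, dtype=bool)
    qual_idx = np.flatnonzero(qualifying)
    rare[qual_idx[: spec.n_rare]] = True
    remaining = spec.n_rare - int(rare.sum())
    if remaining > 0:
        others = np.flatnonzero(~qualifying)
        rare[rng.choice(others, size=remaining, replace=False)] = True

    children = [s.sample_id for s in pedigree.affected()]
    parents: dict[str, None] = {}
    for c in children:
        for p in pedigree.parents_of(c):
            parents.setdefault(p.sample_id)
    parents = list(parents)
    sample_order = pedigree.sample_ids

    records = []
    for i, (chrom, pos0, cls) in enumerate(positions):
        ref = _BASES[rng.integers(4)]
        alt = _BASES[(rng.integers(1, 4) + _BASES.index(ref)) % 4]
        maf = 0.0 if rare[i] else float(np.round(rng.uniform(0.0005, 0.5), 4))
        if cls == "exonic":
            if rng.random() < spec.deleterious_fraction:
                del_class = (
                    "probably_damaging" if rng.random() < 0.5 else "possibly_damaging"
                )
            else:
                del_class = "benign"
        else:
            del_class = None
        gts = _plant_genotypes(rng, sample_order, children, parents, qualifying[i])
        records.append((chrom, pos0, ref, alt, maf, del_class, cls, gts))

    order = sorted(range(n), key=lambda i: (records[i][0], records[i][1]))
    contigs = {}
    for t in gene_model.transcripts:
        contigs.setdefault(t.chrom, chrom_length)
    lines = [_vcf_header(sample_order, contigs)]
    truth_rows = []
    for rank, i in enumerate(order):
        chrom, pos0, ref, alt, maf, del_class, cls, gts = records[i]
        info = f"MAF={maf:g}"
        if del_class is not None:
            info += f";DEL_CLASS={del_class}"
        vid = f"v{rank + 1:05d}"
        lines.append(
            f"{chrom}\t{pos0 + 1}\t{vid}\t{ref}\t{alt}\t.\tPASS\t{info}\tGT\t"
            + "\t".join(gts[s] for s in sample_order)
        )
        gene = _gene_at(gene_model, chrom, pos0) if cls != "intergenic" else None
        truth_rows.append(
            {
                "id": vid,
                "chrom": chrom,
                "pos": pos0 + 1,
                "ref": ref,
                "alt": alt,
                "region_class": cls,
                "gene": gene,
                "maf": maf,
                "del_class": del_class,
                "qualifying": bool(qualifying[i]),
            }
        )
    with open(vcf_path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    return pd.DataFrame(truth_rows)


def _gene_at(model: GeneModel, chrom: str, pos0: int) -> str | None:
    for t in model.overlapping(chrom, pos0):
        return t.gene
    return None


def _plant_genotypes(
    rng: np.random.Generator,
    sample_order: list[str],
    children: list[str],
    parents: list[str],
    qualifying: bool,
) -> dict[str, str]:
    required = set(children) | set(parents)
    if qualifying:
        gts = {s: ("1/1" if s in children else "0/1") for s in sample_order}
        for s in sample_order:
            if s not in required:
                gts[s] = ["0/0", "0/1", "1/1"][rng.integers(3)]
        return gts
    gts = {s: ["0/0", "0/1", "1/1"][rng.integers(3)] for s in sample_order}
    matches = all(gts[c] == "1/1" for c in children) and all(
        gts[p] == "0/1" for p in parents
    )
    if matches:  # corrupt one required sample so the pattern is broken
        victim = [*children, *parents][rng.integers(len(children) + len(parents))]
        gts[victim] = "0/1" if victim in children else "1/1"
    return gts


def generate_network(spec: NetworkPlantSpec) -> tuple[GeneNetwork, list[str]]:
    """Scale-free background with a planted near-clique module.

    Background topology is preferential attachment; background edge
    scores are drawn uniformly from 150-850 (STRING scale), while every
    pair of module genes is connected at ``module_edge_weight``.  The
    module genes replace the latest-attached (peripheral) nodes so the
    module is not confounded with background hubs.  Returns the network
    and the seed list: the lexicographically first half of the module
    genes (the held-out half is the recovery target).
    """
    rng = np.random.default_rng(spec.rng_seed)
    g = nx.barabasi_albert_graph(
        spec.n_nodes, spec.attachment_parameter, seed=int(spec.rng_seed)
    )
    n_mod = len(spec.module_genes)
    names: dict[int, str] = {}
    bg_iter = iter(spec.background_genes)
    bg_count = 0
    for node in range(spec.n_nodes):
        if node >= spec.n_nodes - n_mod:
            names[node] = spec.module_genes[node - (spec.n_nodes - n_mod)]
        else:
            nxt = next(bg_iter, None)
            bg_count += 1
            names[node] = nxt if nxt is not None else f"BG{bg_count:04d}"
    edges: dict[tuple[str, str], float] = {}
    for u, v in g.edges():
        a, b = sorted((names[u], names[v]))
        edges[(a, b)] = rng.integers(150, 851) / 1000.0
    module = sorted(spec.module_genes)
    for i, u in enumerate(module):
        for v in module[i + 1:]:
            edges[(u, v)] = spec.module_edge_weight
    network = GeneNetwork(
        sorted(names.values()), [(u, v, w) for (u, v), w in edges.items()]
    )
    seeds = module[: n_mod // 2]
    return network, seeds
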