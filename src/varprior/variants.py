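"""Variant annotation and filtering.

Implements the discovery arm of the workflow: read a multi-sample VCF,
assign each variant a genomic region class against a gene model, extract
the recessive inheritance pattern (homozygous-alternate in every
affected child, heterozygous in every parent of an affected child), and
apply minor-allele-frequency and predicted-deleteriousness filters.

All filters are pure functions returning subsets; they commute and are
idempotent, so composition order never changes the final set.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import pandas as pd
from cyvcf2 import VCF

from .genemodel import GeneModel, Transcript
from .pedigree import Pedigree

REGION_CLASSES = ("exonic", "utr5", "utr3", "intronic", "intergenic")
# most-severe-first precedence across overlapping isoforms
_SEVERITY = {"exonic": 0, "utr5": 1, "utr3": 2, "intronic": 3, "intergenic": 4}

DAMAGING_CLASSES = frozenset({"possibly_damaging", "probably_damaging"})
DELETERIOUSNESS_CLASSES = frozenset({"benign"}) | DAMAGING_CLASSES


class VcfError(ValueError):
    pass


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class Genotype:
    """One sample's diploid call; ``missing`` calls carry no alleles."""

    allele_a: int | None
    allele_b: int | None
    missing: bool = False

    def is_hom_alt(self, alt_index: int) -> bool:
        return (
            not self.missing
            and self.allele_a == alt_index
            and self.allele_b == alt_index
        )

    def is_het_for(self, alt_index: int) -> bool:
        """Exactly one copy of the given alternate allele; phase ignored."""
        if self.missing:
            return False
        return (self.allele_a == alt_index) != (self.allele_b == alt_index)

    def carries(self, alt_index: int) -> bool:
        return not self.missing and alt_index in (self.allele_a, self.allele_b)


MISSING_GT = Genotype(None, None, missing=True)


@dataclass(frozen=True)
class AnnotatedVariant:
    chrom: str
    pos: int  # 1-based, VCF convention
    ref: str
    alt: str
    alt_index: int  # allele index of ``alt`` in the original record
    genotypes: dict[str, Genotype]
    maf: float | None = None  # None = unknown
    deleteriousness: str | None = None  # None = unknown
    region_class: str | None = None
    gene: str | None = None

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


def read_vcf(path) -> list[AnnotatedVariant]:
    """Read a VCF into annotated variants (region class unset).

    Multi-allelic records are split into one variant per alternate
    allele; genotype allele indices keep the record's original
    numbering, with ``alt_index`` naming the allele each split variant
    describes.  ``MAF`` (float) and ``DEL_CLASS`` (string) INFO keys are
    consumed when present, otherwise left unknown.
    """
    try:
        vcf = VCF(str(path), gts012=False)
    except Exception as exc:  # htslib raises bare OSError/Exception
        raise VcfError(f"cannot open VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    out: list[AnnotatedVariant] = []
    record_index = 0
    try:
        for record in vcf:
            record_index += 1
            gts = {}
            for sample, call in zip(samples, record.genotypes):
                a, b = call[0], call[1]
                if a < 0 or b < 0:
                    gts[sample] = MISSING_GT
                else:
                    gts[sample] = Genotype(int(a), int(b))
            maf = record.INFO.get("MAF")
            del_class = record.INFO.get("DEL_CLASS")
            for j, alt in enumerate(record.ALT):
                out.append(
                    AnnotatedVariant(
                        chrom=record.CHROM,
                        pos=record.POS,
                        ref=record.REF,
                        alt=alt,
                        alt_index=j + 1,
                        genotypes=gts,
                        maf=float(maf) if maf is not None else None,
                        deleteriousness=str(del_class) if del_class is not None else None,
                    )
                )
    except Exception as exc:
        raise VcfError(
            f"malformed VCF {path} at record {record_index + 1}: {exc}"
        ) from exc
    return out


def _classify_against_transcript(pos0: int, t: Transcript) -> str:
    in_exon = any(s <= pos0 < e for s, e in t.exons)
    if not in_exon:
        return "intronic"
    if t.cds_start <= pos0 < t.cds_end:
        return "exonic"
    if pos0 < t.cds_start:
        return "utr5" if t.strand == "+" else "utr3"
    return "utr3" if t.strand == "+" else "utr5"


def classify_region(
    variant: AnnotatedVariant, model: GeneModel
) -> AnnotatedVariant:
    """Assign a region class by most-severe precedence across isoforms.

    Precedence: coding exon > 5'UTR > 3'UTR > intron > intergenic; the
    UTR side is resolved by transcript strand.  The gene symbol of the
    winning transcript is attached; intergenic variants carry no gene.
    """
    pos0 = variant.pos - 1  # sole VCF -> BED conversion point
    best: tuple[int, str, str | None] = (_SEVERITY["intergenic"], "intergenic", None)
    for t in model.overlapping(variant.chrom, pos0):
        cls = _classify_against_transcript(pos0, t)
        cand = (_SEVERITY[cls], cls, t.gene)
        if cand[0] < best[0]:
            best = cand
    return dataclasses.replace(variant, region_class=best[1], gene=best[2])


def annotate_regions(
    variants: list[AnnotatedVariant], model: GeneModel
) -> list[AnnotatedVariant]:
    return [classify_region(v, model) for v in variants]


def inheritance_filter(
    variants: list[AnnotatedVariant], pedigree: Pedigree
) -> list[AnnotatedVariant]:
    """Keep variants homozygous-alternate in every affected child and
    heterozygous in every parent of an affected child.

    A missing genotype among the required samples disqualifies the
    variant.  Samples in the pedigree but absent from the VCF columns
    raise a configuration error.
    """
    children = [s.sample_id for s in pedigree.affected()]
    parents: dict[str, None] = {}
    for child in children:
        for p in pedigree.parents_of(child):
            parents.setdefault(p.sample_id)
    required = children + list(parents)
    kept = []
    for v in variants:
        for sid in required:
            if sid not in v.genotypes:
                raise ConfigurationError(
                    f"pedigree sample {sid!r} has no genotype column in the VCF"
                )
        if not children:
            continue
        if all(v.genotypes[c].is_hom_alt(v.alt_index) for c in children) and all(
            v.genotypes[p].is_het_for(v.alt_index) for p in parents
        ):
            kept.append(v)
    return kept


def maf_filter(
    variants: list[AnnotatedVariant],
    max_maf: float,
    keep_unknown: bool = False,
) -> list[AnnotatedVariant]:
    """Keep variants with MAF <= ``max_maf``; unknown MAF is excluded
    unless ``keep_unknown`` (strict reading of "rare = MAF 0")."""
    if not 0.0 <= max_maf <= 1.0:
        raise ValueError("max_maf must lie in [0, 1]")
    out = []
    for v in variants:
        if v.maf is None:
            if keep_unknown:
                out.append(v)
        elif v.maf <= max_maf:
            out.append(v)
    return out


def deleteriousness_filter(
    variants: list[AnnotatedVariant],
    damaging: frozenset[str] = DAMAGING_CLASSES,
) -> list[AnnotatedVariant]:
    """Drop exonic variants not predicted damaging; pass everything else.

    The deleteriousness label only applies to coding variants, so
    non-exonic variants (and variants with no region class yet) are
    retained unchanged; an exonic variant with an unknown label is
    excluded.
    """
    out = []
    for v in variants:
        if v.region_class == "exonic":
            if v.deleteriousness in damaging:
                out.append(v)
        else:
            out.append(v)
    return out


def summarize_counts(variants: list[AnnotatedVariant]) -> pd.Series:
    """Per-region-class counts (all five classes present; total = input size)."""
    counts = dict.fromkeys(REGION_CLASSES, 0)
    for v in variants:
        if v.region_class is None:
            raise ValueError(f"unclassified variant {v.key}")
        counts[v.region_class] += 1
    return pd.Series(counts, name="count")


def variants_to_frame(variants: list[AnnotatedVariant]) -> pd.DataFrame:
    """Flat table view (one row per variant) used by reports."""
    rows = []
    for v in variants:
        rows.append(
            {
                "chrom": v.chrom,
                "pos": v.pos,
                "ref": v.ref,
                "alt": v.alt,
                "maf": v.maf,
                "deleteriousness": v.deleteriousness,
                "region_class": v.region_class,
                "gene": v.gene,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "pos", "ref", "alt", "maf",
            "deleteriousness", "region_class", "gene",
        ],
    )
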