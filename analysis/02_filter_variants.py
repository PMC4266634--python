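#!/usr/bin/env python
"""Discovery arm: classify every variant against the gene model,
extract the recessive pattern (homozygous-alternate in all affected
children, heterozygous in all parents), then apply the MAF = 0 and
exonic-deleteriousness filters.  Verifies the recovered set against the
generator truth table and writes the filtered table plus region counts.
"""

import argparse
from pathlib import Path

import pandas as pd

from varprior.genemodel import read_bed12
from varprior.pedigree import read_ped
from varprior.variants import (
    annotate_regions,
    deleteriousness_filter,
    inheritance_filter,
    maf_filter,
    read_vcf,
    summarize_counts,
    variants_to_frame,
)

ROOT = Path(__file__).resolve().parents[1]


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--sim", type=Path, default=ROOT / "results" / "sim")
    parser.add_argument("--out", type=Path, default=ROOT / "results")
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    pedigree = read_ped(args.sim / "families.ped")
    model = read_bed12(args.sim / "genes.bed")
    variants = annotate_regions(read_vcf(args.sim / "cohort.vcf"), model)
    truth = pd.read_csv(args.sim / "truth.tsv", sep="\t")

    qualifying = inheritance_filter(variants, pedigree)
    counts = summarize_counts(qualifying)
    rare = maf_filter(qualifying, 0.0)
    final = deleteriousness_filter(rare)

    planted = set(truth.loc[truth["qualifying"], "pos"])
    recovered = {v.pos for v in qualifying}
    assert recovered == planted, "inheritance filter missed planted truth"

    variants_to_frame(final).to_csv(
        args.out / "filtered_variants.tsv", sep="\t", index=False
    )
    counts.rename_axis("region_class").reset_index().to_csv(
        args.out / "region_counts.tsv", sep="\t", index=False
    )

    print(f"{len(variants)} variants read; {len(qualifying)} match the "
          "recessive pattern (exactly the planted set)")
    print("region breakdown of pattern-matching variants:")
    for cls, n in counts.items():
        print(f"  {cls:<11} {n}")
    print(f"{len(rare)} remain at MAF = 0; {len(final)} after the exonic "
          "deleteriousness filter")
    print(f"tables written to {args.out}")


if __name__ == "__main__":
    main()
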