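#!/usr/bin/env python
"""Category enrichment of the filtered candidate genes: upper-tail
hypergeometric p-values with BH correction plus one-sided enrichment
Bayes factors, against the synthetic category map.  The planted-module
category should dominate.
"""

import argparse
from pathlib import Path

import pandas as pd

from varprior.enrichment import hypergeometric_enrichment, read_gmt
from varprior.genemodel import read_bed12

ROOT = Path(__file__).resolve().parents[1]


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--sim", type=Path, default=ROOT / "results" / "sim")
    parser.add_argument("--out", type=Path, default=ROOT / "results")
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    filtered = pd.read_csv(args.out / "filtered_variants.tsv", sep="\t")
    query = sorted(set(filtered["gene"].dropna()))
    background = read_bed12(args.sim / "genes.bed").genes()
    categories = read_gmt(args.sim / "categories.gmt",
                          background=set(background))

    result = hypergeometric_enrichment(query, categories)
    result.to_csv(args.out / "enrichment.tsv", sep="\t", index=False)

    print(f"query: {len(query)} genes with surviving variants "
          f"({', '.join(query)})")
    print(result.to_string(index=False,
                           float_format=lambda x: f"{x:.4g}"))
    top = result.iloc[0]
    print(f"most enriched category: {top['category']} "
          f"(overlap {top['overlap']}/{top['size']}, "
          f"adjusted p = {top['adjusted_p']:.3g}, "
          f"BF = {top['bayes_factor']:.3g})")


if __name__ == "__main__":
    main()
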