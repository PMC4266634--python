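#!/usr/bin/env python
"""Simulate the study cohort: two consanguineous-style nuclear families
(two affected children each), a 30-gene model, a 200-variant VCF with a
planted recessive pattern, and a 150-node interaction network carrying
a dense module around the genes that received planted variants.

Writes everything downstream steps read to results/sim/.
"""

import argparse
import json
from pathlib import Path

from varprior.genemodel import write_bed12
from varprior.network import write_edge_list
from varprior.pedigree import write_ped
from varprior.synthetic import (
    NetworkPlantSpec,
    PlantSpec,
    generate_gene_model,
    generate_network,
    generate_pedigree,
    generate_variant_set,
)

ROOT = Path(__file__).resolve().parents[1]


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=29)
    parser.add_argument("--out", type=Path, default=ROOT / "results" / "sim")
    args = parser.parse_args()
    out = args.out
    out.mkdir(parents=True, exist_ok=True)

    pedigree = generate_pedigree(n_families=2, children_per_family=2)
    model = generate_gene_model(30)
    write_ped(pedigree, out / "families.ped")
    write_bed12(model, out / "genes.bed")

    truth = generate_variant_set(
        pedigree, model, PlantSpec(rng_seed=args.seed), out / "cohort.vcf"
    )
    truth.to_csv(out / "truth.tsv", sep="\t", index=False)

    planted_genes = sorted(
        set(truth.loc[truth["qualifying"] & truth["gene"].notna(), "gene"])
    )
    module = list(planted_genes)
    for g in model.genes():
        if len(module) >= 10:
            break
        if g not in module:
            module.append(g)
    module = sorted(module)
    background = [g for g in model.genes() if g not in module]
    network, seeds = generate_network(
        NetworkPlantSpec(
            n_nodes=150, module_genes=tuple(module),
            background_genes=tuple(background), rng_seed=args.seed,
        )
    )
    write_edge_list(network, out / "network.txt")
    (out / "seeds.txt").write_text("\n".join(seeds) + "\n")
    (out / "categories.gmt").write_text(
        "planted_module\tsynthetic\t" + "\t".join(module) + "\n"
        "background_slice\tsynthetic\t" + "\t".join(background[:12]) + "\n"
    )
    (out / "sim_manifest.json").write_text(json.dumps({
        "seed": args.seed,
        "n_samples": len(pedigree),
        "n_variants": len(truth),
        "n_qualifying": int(truth["qualifying"].sum()),
        "planted_genes": planted_genes,
        "module": module,
        "seeds": seeds,
    }, indent=2))

    print(f"cohort: {len(pedigree)} samples "
          f"({len(pedigree.affected())} affected), {len(truth)} variants, "
          f"{truth['qualifying'].sum()} with the planted recessive pattern")
    print(f"planted variant genes: {', '.join(planted_genes)}")
    print(f"network: {len(network)} genes; module {', '.join(module)}; "
          f"seeds {', '.join(seeds)}")
    print(f"wrote inputs to {out}")


if __name__ == "__main__":
    main()
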