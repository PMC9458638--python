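"""Simulate the paired study cohorts.

Generates the synthetic stand-ins for the two population cohorts: a
2504-individual primary cohort and a 20000-individual secondary cohort
over 5000 missense variants, 5% of them planted recessive lethals
(homozygous carriers re-drawn as heterozygous).  Writes the cohort
tables (VCF + TSV) and the ground-truth table to scratch/data/ and a
small genotype-structure summary to results/.

Run: python analysis/01_simulate_cohorts.py [--seed 1]
"""

import argparse
from pathlib import Path

import pandas as pd

from hetscreen import CohortSpec, simulate_cohort_pair
from hetscreen.cohort import write_tsv
from hetscreen.synthetic import write_vcf

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()

    spec = CohortSpec(
        n_individuals=2504, n_individuals_b=20000, n_variants=5000,
        lethal_fraction=0.05, maf_range=(0.02, 0.5), cross_cohort_noise=0.02,
        seed=args.seed,
    )
    a, b, truth = simulate_cohort_pair(spec)

    data_dir = ROOT / "scratch" / "data"
    data_dir.mkdir(parents=True, exist_ok=True)
    write_vcf(a, data_dir / "cohort_a.vcf", cohort="A")
    write_tsv(a, data_dir / "cohort_a.tsv", cohort="A")
    write_tsv(b, data_dir / "cohort_b.tsv", cohort="B")
    truth.to_csv(data_dir / "truth.tsv", sep="\t", index=False)

    lethal = truth["is_lethal_recessive"]
    hom_a = pd.Series([r.counts["A"].hom_alt for r in a])
    het_a = pd.Series([r.counts["A"].het for r in a])
    summary = pd.DataFrame([
        {"group": "lethal", "n": int(lethal.sum()),
         "mean_het_A": het_a[lethal.values].mean(),
         "mean_hom_A": hom_a[lethal.values].mean(),
         "max_hom_A": int(hom_a[lethal.values].max())},
        {"group": "non_lethal", "n": int((~lethal).sum()),
         "mean_het_A": het_a[~lethal.values].mean(),
         "mean_hom_A": hom_a[~lethal.values].mean(),
         "max_hom_A": int(hom_a[~lethal.values].max())},
    ])
    (ROOT / "results").mkdir(exist_ok=True)
    summary.to_csv(ROOT / "results" / "01_cohort_summary.tsv", sep="\t", index=False)

    print(f"wrote {len(a)} variants per cohort to {data_dir}")
    print(summary.to_string(index=False))
    print("planted lethals have zero homozygotes by construction; "
          "non-lethal variants carry the Hardy-Weinberg homozygote load.")


if __name__ == "__main__":
    main()
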