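"""Harmonize the cohorts and run the exclusive-heterozygosity screen.

Reads the simulated cohort tables written by 01_simulate_cohorts.py,
keeps variants with concordant minor allele frequencies (|ΔMAF| ≤ 10
percentage points), and applies the filter cascade: ≥41 heterozygotes
and 0 homozygotes in the primary cohort, ≤5 homozygotes in the
secondary.  Reports sensitivity against the planted truth and the
candidate counts as the secondary homozygote cap is lowered 5 → 0.

Run: python analysis/02_screen_variants.py
"""

import sys
from pathlib import Path

import pandas as pd

from hetscreen import ScreenConfig, apply_screen, harmonize_cohorts, hom_cap_sweep, read_variants

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    data_dir = ROOT / "scratch" / "data"
    if not (data_dir / "cohort_a.vcf").exists():
        sys.exit("cohort tables not found; run analysis/01_simulate_cohorts.py first")

    a = read_variants(data_dir / "cohort_a.vcf", format="vcf", cohort="A")
    b = read_variants(data_dir / "cohort_b.tsv", format="tsv", cohort="B")
    truth = pd.read_csv(data_dir / "truth.tsv", sep="\t")

    merged = harmonize_cohorts(a, b)
    cfg = ScreenConfig()
    results = apply_screen(merged, cfg)

    df = pd.DataFrame([
        {"variant_id": r.variant_id, "gene": r.gene, "p_value": r.p_value,
         "passes_het_floor": r.passes_het_floor,
         "passes_hom_caps": r.passes_hom_caps, "candidate": r.candidate}
        for r in results
    ]).merge(truth[["variant_id", "is_lethal_recessive"]], on="variant_id")
    df.to_csv(data_dir / "screen_full.tsv", sep="\t", index=False)
    candidates = df[df["candidate"]]
    candidates.to_csv(ROOT / "results" / "02_candidates.tsv", sep="\t", index=False)

    lethal_ids = set(truth.loc[truth["is_lethal_recessive"], "variant_id"])
    eligible = [m for m in merged
                if m.variant_id in lethal_ids and m.counts["A"].het >= cfg.min_het]
    flags = {r.variant_id: r.candidate for r in results}
    sens = sum(flags[m.variant_id] for m in eligible) / len(eligible)

    sweep = hom_cap_sweep(merged, [5, 4, 3, 2, 1, 0], cfg)
    sweep_df = pd.DataFrame(
        {"hom_cap_secondary": list(sweep), "n_candidates": list(sweep.values())}
    )
    sweep_df.to_csv(ROOT / "results" / "02_hom_cap_sweep.tsv", sep="\t", index=False)

    print(f"{len(merged)} of {len(a)} variants survive MAF harmonization")
    print(f"{len(candidates)} candidates "
          f"({int(candidates['is_lethal_recessive'].sum())} planted lethals, "
          f"{int((~candidates['is_lethal_recessive']).sum())} false)")
    print(f"sensitivity among {len(eligible)} eligible planted lethals: {sens:.3f}")
    print("candidate count as the secondary hom cap drops:")
    print(sweep_df.to_string(index=False))


if __name__ == "__main__":
    main()
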