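"""Canonical synthetic study scenarios.

These functions fix the study conditions under which the pipeline is
exercised end to end — a 1000-Genomes-scale primary cohort (2504
individuals) paired with a larger secondary cohort, 5% planted
recessive-lethal variants at frequencies common enough to clear the
41-heterozygote floor, the 100-cycle genotype shuffle, and a labelled
benchmark for score calibration.  The analysis drivers, the test suite
and the acceptance script all run the same scenarios so their numbers
agree.
"""

from __future__ import annotations

import math
from typing import Mapping

import numpy as np
from sklearn.metrics import roc_auc_score

from .cohort import harmonize_cohorts
from .integrate import enrichment_curves, integrate_table, roc_calibrate, select_threshold
from .screen import ScreenConfig, apply_screen, hom_cap_sweep
from .shuffle import ShuffleConfig, shuffle_variant
from .synthetic import (
    CohortSpec,
    simulate_benchmark,
    simulate_cohort_features,
    simulate_cohort_pair,
    simulate_residue_features,
)
from .features import train_zone_table

#: per-channel benchmark effect sizes (standard deviations of shift)
BENCHMARK_EFFECTS: Mapping[str, float] = {
    "ortho": 1.5, "homo": 1.2, "blosum": 1.0,
    "sec": 0.6, "acc": 0.8, "bur": 0.8, "phi_psi": 0.5,
}


def shuffle_convergence(seed: int, freq: float = 0.19,
                        n_individuals: int = 2504, n_cycles: int = 100) -> dict:
    """Shuffle one variant at the worked-example frequency of 19%.

    Returns the cycle-averaged hom/het fractions alongside the
    Hardy-Weinberg expectations f² and 2f(1-f) and their standard
    errors over the pooled draws.
    """
    cfg = ShuffleConfig(n_individuals=n_individuals, n_cycles=n_cycles, seed=seed)
    s = shuffle_variant(freq, cfg)
    p_hom, p_het = freq**2, 2 * freq * (1 - freq)
    n_draws = n_individuals * n_cycles
    return {
        "mean_hom_frac": s.mean_hom / n_individuals,
        "mean_het_frac": s.mean_het / n_individuals,
        "expected_hom_frac": p_hom,
        "expected_het_frac": p_het,
        "se_hom": math.sqrt(p_hom * (1 - p_hom) / n_draws),
        "se_het": math.sqrt(p_het * (1 - p_het) / n_draws),
        "n_draws": n_draws,
    }


def planted_lethal_screen(seed: int, n_variants: int = 5000) -> dict:
    """Two-cohort screen recovery of planted recessive lethals.

    2504 + 20000 individuals, 5% planted lethals, MAFs >= 0.02 (so the
    expected heterozygote count exceeds 60 and the 41-het floor is
    reachable).  Reports the screen's sensitivity among planted lethals
    that pass the het floor after harmonization, the false-candidate
    rate among non-lethal variants, and the secondary-cohort hom-cap
    sweep.
    """
    spec = CohortSpec(
        n_individuals=2504, n_individuals_b=20000, n_variants=n_variants,
        lethal_fraction=0.05, maf_range=(0.02, 0.5), cross_cohort_noise=0.02,
        seed=seed,
    )
    a, b, truth = simulate_cohort_pair(spec)
    merged = harmonize_cohorts(a, b)
    cfg = ScreenConfig()
    results = {r.variant_id: r for r in apply_screen(merged, cfg)}
    lethal_ids = set(truth.loc[truth["is_lethal_recessive"], "variant_id"])

    eligible = [m.variant_id for m in merged
                if m.variant_id in lethal_ids and m.counts["A"].het >= cfg.min_het]
    sensitivity = (
        sum(results[v].candidate for v in eligible) / len(eligible)
        if eligible else float("nan")
    )
    nonlethal = [m.variant_id for m in merged if m.variant_id not in lethal_ids]
    false_rate = (
        sum(results[v].candidate for v in nonlethal) / len(nonlethal)
        if nonlethal else float("nan")
    )
    caps = [5, 4, 3, 2, 1, 0]
    return {
        "spec": spec,
        "truth": truth,
        "merged": merged,
        "n_merged": len(merged),
        "n_lethal_eligible": len(eligible),
        "sensitivity": sensitivity,
        "false_candidate_rate": false_rate,
        "cap_sweep": hom_cap_sweep(merged, caps, cfg),
    }


def zone_recovery(seed: int, n_residues: int = 50000) -> dict:
    """Zone-table training on biased vs amino-acid-independent residues."""
    biased = train_zone_table(
        simulate_residue_features(n_residues, seed=seed), "acc")
    null = train_zone_table(
        simulate_residue_features(n_residues, seed=seed + 1, burial_bias=0.0),
        "acc")
    return {
        "ile_low_acc": float(biased.log_odds.loc["I", "low"]),
        "lys_low_acc": float(biased.log_odds.loc["K", "low"]),
        "null_max_abs": float(np.abs(null.log_odds.values).max()),
    }


def impact_enrichment(seed: int, n_variants: int = 3000,
                      n_pos: int = 2000, n_neg: int = 2000) -> dict:
    """Calibrated impact scoring of a planted-lethal cohort.

    A labelled benchmark calibrates the channels; the cohort's planted
    lethals draw channel values with the same effect sizes, so high
    impact scores co-occur with hom-depletion.  The impact threshold is
    chosen on the benchmark at FDR < 1% and FPR < 5%, and the
    enrichment curves report the high-impact fraction vs het count
    (among hom = 0 variants) and vs hom count.
    """
    spec = CohortSpec(
        n_individuals=2504, n_variants=n_variants, lethal_fraction=0.08,
        maf_range=(0.005, 0.5), maf_beta=(0.8, 6.0), seed=seed,
    )
    a, _, truth = simulate_cohort_pair(spec)

    bench = simulate_benchmark(n_pos, n_neg, BENCHMARK_EFFECTS, seed=seed + 1)
    labels = bench["label"].to_numpy()
    calib = roc_calibrate(bench[list(BENCHMARK_EFFECTS)], labels)
    bench_scored = integrate_table(bench, calib)
    bench_auc = float(roc_auc_score(labels, bench_scored["impact_score"]))
    sel = select_threshold(bench_scored["impact_score"], labels,
                           max_fdr=0.01, max_fpr=0.05)

    feats = simulate_cohort_features(truth, BENCHMARK_EFFECTS, seed=seed + 2)
    scored = integrate_table(feats, calib)
    scored["het"] = [r.counts["A"].het for r in a]
    scored["hom"] = [r.counts["A"].hom_alt for r in a]
    by_het, by_hom = enrichment_curves(scored, impact_threshold=sel.threshold)
    return {
        "benchmark_auc": bench_auc,
        "threshold": sel,
        "scored": scored,
        "by_het": by_het,
        "by_hom": by_hom,
        "truth": truth,
    }
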