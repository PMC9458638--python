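"""Genotype shuffling null model.

Re-draws cohort genotypes from each variant's observed allele frequency
to show what hom/het count structure is expected when genotypes are
random: for every individual two uniform deviates are drawn, each
allele is mutated iff its deviate is <= the allele frequency, and the
two alleles form the simulated genotype.  Averaging heterozygous and
homozygous counts over simulation cycles yields, per variant, the
expected scatter against which the observed excess of exclusively
heterozygous variants is judged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import VariantRecord


@dataclass(frozen=True)
class ShuffleConfig:
    n_individuals: int = 2504
    n_cycles: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")


@dataclass(frozen=True)
class ShuffleSummary:
    variant_id: str
    mean_het: float
    mean_hom: float
    het_cycles: np.ndarray | None = None
    hom_cycles: np.ndarray | None = None


def genotype_counts_from_uniforms(
    u: np.ndarray, allele_freq: float
) -> tuple[np.ndarray, np.ndarray]:
    """Het and hom counts from uniform deviates of shape (..., n, 2).

    An allele is mutated iff its deviate is smaller than or equal to the
    allele frequency (a draw exactly equal to the frequency counts as
    mutated).  Reduces over the last two axes.
    """
    mutated = u <= allele_freq
    n_alt = mutated.sum(axis=-1)
    return (n_alt == 1).sum(axis=-1), (n_alt == 2).sum(axis=-1)


def shuffle_variant(
    allele_freq: float,
    config: ShuffleConfig = ShuffleConfig(),
    rng: np.random.Generator | None = None,
    variant_id: str = "",
    keep_cycles: bool = False,
) -> ShuffleSummary:
    """Simulate one variant's genotypes over ``n_cycles`` cohort draws."""
    if not np.isfinite(allele_freq) or not 0.0 <= allele_freq <= 1.0:
        raise ValueError(f"allele frequency {allele_freq} outside [0, 1]")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    u = rng.random((config.n_cycles, config.n_individuals, 2))
    het, hom = genotype_counts_from_uniforms(u, allele_freq)
    return ShuffleSummary(
        variant_id=variant_id,
        mean_het=float(het.mean()),
        mean_hom=float(hom.mean()),
        het_cycles=het if keep_cycles else None,
        hom_cycles=hom if keep_cycles else None,
    )


def shuffle_cohort(
    variants: Sequence[VariantRecord] | Sequence[tuple[str, float]],
    config: ShuffleConfig = ShuffleConfig(),
    cohort: str = "A",
    keep_cycles: bool = False,
) -> tuple[list[ShuffleSummary], pd.DataFrame]:
    """Shuffle every variant; emit summaries plus a plot-ready table.

    ``variants`` is either harmonized :class:`VariantRecord` objects (the
    raw alternate-allele frequency of ``cohort`` is used, matching the
    observed-frequency resampling) or explicit ``(variant_id, freq)``
    pairs.  Returns the per-variant summaries and a tidy
    ``(variant_id, mean_het, mean_hom)`` scatter table for hom-vs-het
    plots.  Each variant gets its own deterministic random substream
    derived from the config seed.
    """
    pairs: list[tuple[str, float]] = []
    for v in variants:
        if isinstance(v, VariantRecord):
            pairs.append((v.variant_id, v.counts[cohort].alt_frequency))
        else:
            pairs.append((v[0], float(v[1])))

    streams = np.random.SeedSequence(config.seed).spawn(len(pairs))
    summaries = [
        shuffle_variant(
            freq, config, rng=np.random.default_rng(ss),
            variant_id=vid, keep_cycles=keep_cycles,
        )
        for (vid, freq), ss in zip(pairs, streams)
    ]
    table = pd.DataFrame(
        {
            "variant_id": [s.variant_id for s in summaries],
            "mean_het": [s.mean_het for s in summaries],
            "mean_hom": [s.mean_hom for s in summaries],
        }
    )
    return summaries, table
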