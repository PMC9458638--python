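"""Exclusive-heterozygosity screen.

The screen asks, for each variant, whether the complete absence (or near
absence) of homozygous-alternate carriers is surprising given how many
heterozygous carriers exist.  Under Mendelian segregation the chance
that the offspring of variant-carrying parents is homozygous for the
variant is obtained by enumerating parental genotype pairings
("G0 constellations"):

* if homozygous carriers are viable and reproduce, the six pairings
  AA x AA, Aa x Aa, AA x aa, aa x aa, Aa x AA, Aa x aa give an
  unweighted mean homozygous-offspring probability of 7/24 (~0.29);
* if homozygotes are non-viable, only Aa x Aa, aa x aa and Aa x aa
  remain, and the mean drops to 1/12 (~0.083).

Each variant with ``het`` heterozygous and ``hom`` homozygous carriers
is then tested with a lower binomial tail: how likely is it to see at
most ``hom`` homozygotes among ``het + hom`` carriers when each carrier
is homozygous with probability p_hom?  A small p-value flags a variant
whose homozygotes are unexpectedly missing — the signature of a
recessive-lethal (or recessive-disease) allele.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Sequence

from scipy.stats import binom

from .cohort import VariantRecord

logger = logging.getLogger(__name__)

# Parental genotype pairings; "A" denotes the variant allele.
VIABLE_CONSTELLATIONS: tuple[tuple[str, str], ...] = (
    ("AA", "AA"), ("Aa", "Aa"), ("AA", "aa"),
    ("aa", "aa"), ("Aa", "AA"), ("Aa", "aa"),
)
NONVIABLE_CONSTELLATIONS: tuple[tuple[str, str], ...] = (
    ("Aa", "Aa"), ("aa", "aa"), ("Aa", "aa"),
)


def _p_hom_offspring(parents: tuple[str, str]) -> Fraction:
    """Mendelian P(offspring is AA) for one parental pairing."""
    p = Fraction(0)
    for g1 in parents[0]:
        for g2 in parents[1]:
            if g1 == "A" and g2 == "A":
                p += Fraction(1, len(parents[0]) * len(parents[1]))
    return p


def constellation_hom_prob(viability: str = "hom_nonviable") -> Fraction:
    """Homozygous-offspring probability under a viability assumption.

    Enumerates the parental constellations compatible with the
    assumption and returns the unweighted mean of their Mendelian
    homozygous-offspring probabilities, as an exact rational:
    ``hom_viable`` -> 7/24 (~0.29); ``hom_nonviable`` -> 1/12 (~0.083).
    """
    if viability == "hom_viable":
        pairings = VIABLE_CONSTELLATIONS
    elif viability == "hom_nonviable":
        pairings = NONVIABLE_CONSTELLATIONS
    else:
        raise ValueError(
            f"unknown viability assumption {viability!r}; "
            "expected 'hom_viable' or 'hom_nonviable'"
        )
    probs = [_p_hom_offspring(p) for p in pairings]
    return sum(probs, Fraction(0)) / len(probs)


def exclusive_het_test(het: int, hom: int, p_hom: float) -> float:
    """Lower binomial tail P(X <= hom), X ~ Binomial(het + hom, p_hom).

    The probability of observing so few homozygotes among the variant's
    carriers.  With no carriers at all the test is uninformative and
    returns 1.
    """
    if het < 0 or hom < 0:
        raise ValueError("counts must be non-negative")
    if not 0.0 < p_hom < 1.0:
        raise ValueError(f"p_hom must lie in (0, 1), got {p_hom}")
    n = het + hom
    if n == 0:
        return 1.0
    return float(binom.cdf(hom, n, p_hom))


def min_het_for_alpha(alpha: float, p_hom: float) -> int:
    """Smallest carrier count n with (1 - p_hom)^n <= alpha.

    The heterozygote floor implied by a significance level: with n
    all-heterozygous carriers the exclusivity p-value is (1-p_hom)^n.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    return math.ceil(math.log(alpha) / math.log(1.0 - p_hom))


@dataclass(frozen=True)
class ScreenConfig:
    """Thresholds for the candidate filter cascade (all inclusive)."""

    min_het: int = 41
    max_hom_primary: int = 0
    max_hom_secondary: int = 5
    viability: str = "hom_nonviable"
    alpha: float = 0.05
    blacklist: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if min(self.min_het, self.max_hom_primary, self.max_hom_secondary) < 0:
            raise ValueError("thresholds must be non-negative")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        object.__setattr__(
            self, "blacklist", frozenset(g.upper() for g in self.blacklist)
        )

    @property
    def p_hom(self) -> float:
        return float(constellation_hom_prob(self.viability))


@dataclass(frozen=True)
class ScreenResult:
    variant_id: str
    gene: str
    p_value: float
    passes_het_floor: bool
    passes_hom_caps: bool
    blacklisted: bool

    @property
    def candidate(self) -> bool:
        return self.passes_het_floor and self.passes_hom_caps and not self.blacklisted


def apply_screen(
    records: Sequence[VariantRecord],
    config: ScreenConfig = ScreenConfig(),
    cohort_a: str = "A",
    cohort_b: str = "B",
) -> list[ScreenResult]:
    """Run the filter cascade over harmonized two-cohort records.

    A candidate must have at least ``min_het`` heterozygotes in the
    primary cohort, at most ``max_hom_primary`` homozygotes there, at
    most ``max_hom_secondary`` homozygotes in the secondary cohort, and
    a gene outside the blacklist.  The exclusivity p-value is attached
    for reporting; the pass/fail flags implement the published fixed
    thresholds.  Records missing either cohort's counts are skipped
    with a warning.
    """
    p_hom = config.p_hom
    results: list[ScreenResult] = []
    for r in records:
        ca = r.counts.get(cohort_a)
        cb = r.counts.get(cohort_b)
        if ca is None or cb is None:
            logger.warning(
                "variant %s missing counts for cohort %s; skipped",
                r.variant_id, cohort_a if ca is None else cohort_b,
            )
            continue
        results.append(
            ScreenResult(
                variant_id=r.variant_id,
                gene=r.gene,
                p_value=exclusive_het_test(ca.het, ca.hom_alt, p_hom),
                passes_het_floor=ca.het >= config.min_het,
                passes_hom_caps=(
                    ca.hom_alt <= config.max_hom_primary
                    and cb.hom_alt <= config.max_hom_secondary
                ),
                blacklisted=r.gene.upper() in config.blacklist,
            )
        )
    return results


def hom_cap_sweep(
    records: Sequence[VariantRecord],
    caps: Iterable[int],
    config: ScreenConfig = ScreenConfig(),
    cohort_a: str = "A",
    cohort_b: str = "B",
) -> dict[int, int]:
    """Candidate counts as the secondary-cohort homozygote cap varies.

    Re-runs the screen once per cap value (replacing
    ``max_hom_secondary``) and returns ``{cap: n_candidates}``.  Counts
    are monotone non-increasing as the cap drops since the filters nest.
    """
    from dataclasses import replace

    out: dict[int, int] = {}
    for cap in caps:
        cfg = replace(config, max_hom_secondary=cap)
        out[cap] = sum(
            s.candidate for s in apply_screen(records, cfg, cohort_a, cohort_b)
        )
    return out
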