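"""Synthetic input generators.

Everything the pipeline consumes can be generated here with the
statistical structure the analysis assumes, so every stage is testable
offline:

* two-cohort diploid genotype-count tables at Hardy-Weinberg
  equilibrium, with a planted subset of recessive-lethal variants whose
  homozygous-alternate carriers are re-drawn as heterozygous;
* protein multiple alignments with position-specific conservation;
* per-residue structural feature tables with an amino-acid-dependent
  burial bias (hydrophobic residues less accessible on average);
* labelled benchmark feature vectors with per-channel effect sizes.

Genotype sampling is per individual — two uniform allele draws, shared
machinery with the genotype shuffler — rather than a single multinomial
over the cohort, and every generator derives all randomness from one
explicit seed (per-variant substreams), so identical seeds give
byte-identical outputs.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .constants import AMINO_ACIDS, BACKGROUND_VECTOR, HYDROPHOBIC, MAX_ASA_GXG
from .cohort import GenotypeCounts, VariantRecord
from .shuffle import genotype_counts_from_uniforms

SEC_CLASSES = np.array(list("HGEBCTS"))
SEC_PROBS = np.array([0.30, 0.04, 0.18, 0.02, 0.26, 0.12, 0.08])

DEFAULT_CHANNELS = (
    "ortho", "homo", "blosum", "sec", "acc", "bur", "phi_psi",
    "fda", "omim", "haplotype", "uniprot_function",
)


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a simulated two-cohort screen.

    The defaults emulate a 1000-Genomes-scale primary cohort (2504
    individuals) paired with a larger secondary cohort, with minor
    allele frequencies drawn from a rare-skewed beta distribution and a
    small fraction of variants planted as recessive-lethal.
    """

    n_individuals: int = 2504
    n_variants: int = 2000
    maf_beta: tuple[float, float] = (1.5, 8.0)
    maf_range: tuple[float, float] = (0.02, 0.5)
    lethal_fraction: float = 0.05
    cross_cohort_noise: float = 0.02
    seed: int = 0
    n_individuals_b: int | None = None

    def __post_init__(self) -> None:
        vals = [
            self.n_individuals, self.n_variants, *self.maf_beta,
            *self.maf_range, self.lethal_fraction, self.cross_cohort_noise,
        ]
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("cohort spec parameters must be finite")
        if self.n_individuals < 1 or self.n_variants < 1:
            raise ValueError("cohort and variant counts must be >= 1")
        if not 0.0 <= self.lethal_fraction <= 1.0:
            raise ValueError("lethal_fraction must lie in [0, 1]")
        if min(self.maf_beta) <= 0 or self.cross_cohort_noise < 0:
            raise ValueError("beta shapes must be positive and noise >= 0")
        lo, hi = self.maf_range
        if not 0.0 <= lo <= hi <= 0.5:
            raise ValueError("maf_range must satisfy 0 <= lo <= hi <= 0.5")

    @property
    def n_b(self) -> int:
        return self.n_individuals_b or self.n_individuals


def _sample_counts(
    rng: np.random.Generator, f: float, n: int, lethal: bool
) -> GenotypeCounts:
    """Per-individual Hardy-Weinberg draw; lethal homs re-drawn as het."""
    het, hom = genotype_counts_from_uniforms(rng.random((1, n, 2)), f)
    het, hom = int(het[0]), int(hom[0])
    if lethal:
        # homozygous carriers are non-viable: they survive only as
        # heterozygotes, so carriers are preserved and hom drops to 0
        het, hom = het + hom, 0
    return GenotypeCounts(het, hom, n)


def simulate_cohort_pair(
    spec: CohortSpec,
) -> tuple[list[VariantRecord], list[VariantRecord], pd.DataFrame]:
    """Generate paired cohort tables plus the ground-truth table.

    Cohort A variants get MAFs from the spec's beta sampler; cohort B
    MAFs are cohort A's plus truncated Gaussian noise.  For each
    variant every individual's genotype is two independent allele draws
    at the cohort's true MAF; for planted lethals any
    homozygous-alternate individual is re-drawn as heterozygous in both
    cohorts.  Returns (records A, records B, truth) where truth maps
    ``variant_id`` to ``is_lethal_recessive`` and ``true_maf``.
    """
    root = np.random.SeedSequence(spec.seed)
    meta_ss, var_root = root.spawn(2)
    meta = np.random.default_rng(meta_ss)

    a, b = spec.maf_beta
    lo, hi = spec.maf_range
    maf_a = lo + (hi - lo) * meta.beta(a, b, size=spec.n_variants)
    noise = meta.normal(0.0, spec.cross_cohort_noise, size=spec.n_variants) \
        if spec.cross_cohort_noise > 0 else np.zeros(spec.n_variants)
    maf_b = np.clip(maf_a + noise, lo, hi)
    is_lethal = meta.random(spec.n_variants) < spec.lethal_fraction

    aas = np.array(AMINO_ACIDS)
    ref_idx = meta.integers(0, 20, size=spec.n_variants)
    alt_off = meta.integers(1, 20, size=spec.n_variants)
    alt_idx = (ref_idx + alt_off) % 20

    rec_a: list[VariantRecord] = []
    rec_b: list[VariantRecord] = []
    truth_rows = []
    for i, ss in enumerate(var_root.spawn(spec.n_variants)):
        rng = np.random.default_rng(ss)
        vid = f"var{i:06d}"
        gene = f"GENE{i // 5:05d}"
        common = dict(
            variant_id=vid, gene=gene, aa_pos=(i % 400) + 1,
            aa_ref=str(aas[ref_idx[i]]), aa_alt=str(aas[alt_idx[i]]),
        )
        rec_a.append(VariantRecord(
            **common,
            counts={"A": _sample_counts(rng, maf_a[i], spec.n_individuals,
                                        bool(is_lethal[i]))},
        ))
        rec_b.append(VariantRecord(
            **common,
            counts={"B": _sample_counts(rng, maf_b[i], spec.n_b,
                                        bool(is_lethal[i]))},
        ))
        truth_rows.append({
            "variant_id": vid, "is_lethal_recessive": bool(is_lethal[i]),
            "true_maf": float(maf_a[i]), "true_maf_b": float(maf_b[i]),
        })
    return rec_a, rec_b, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# alignments


def simulate_alignment(
    n_sequences: int,
    length: int,
    conserved_positions: Iterable[int] = (),
    conservation_strength: float = 0.9,
    seed: int = 0,
) -> MultipleSeqAlignment:
    """Aligned homolog set with position-specific conservation.

    At each conserved (1-based) position one residue type — chosen per
    position — appears with probability ``conservation_strength`` in
    every row; all other cells draw from the background composition.
    The first row, ``ref``, is the profile reference and always carries
    the dominant residue at conserved positions.
    """
    if length < 1:
        raise ValueError("alignment length must be >= 1")
    if n_sequences < 1:
        raise ValueError("need at least one sequence")
    conserved = set(conserved_positions)
    if conserved and (min(conserved) < 1 or max(conserved) > length):
        raise ValueError("conserved positions must lie within 1..length")
    if not 0.0 <= conservation_strength <= 1.0:
        raise ValueError("conservation_strength must lie in [0, 1]")

    rng = np.random.default_rng(seed)
    aas = np.array(AMINO_ACIDS)
    cols = rng.choice(aas, size=(n_sequences, length), p=BACKGROUND_VECTOR)
    for pos in sorted(conserved):
        dominant = rng.choice(aas, p=BACKGROUND_VECTOR)
        keep = rng.random(n_sequences) < conservation_strength
        cols[keep, pos - 1] = dominant
        cols[0, pos - 1] = dominant
    records = [
        SeqRecord(Seq("".join(row)), id=("ref" if i == 0 else f"seq{i}"),
                  description="")
        for i, row in enumerate(cols)
    ]
    return MultipleSeqAlignment(records)


# ---------------------------------------------------------------------------
# residue features


def _wrap_angle(a: np.ndarray) -> np.ndarray:
    return np.where(a >= 180.0, a - 360.0, a)


def simulate_residue_features(
    n_residues: int,
    seed: int = 0,
    protein_id: str = "SYNPROT",
    burial_bias: float = 1.0,
) -> pd.DataFrame:
    """Residue feature table with a planted hydrophobic-burial bias.

    Hydrophobic residues draw accessibility from a lower-mean gamma
    distribution than polar ones (interpolated by ``burial_bias``;
    0 gives amino-acid-independent features — the independence null for
    zone training).  Angles are uniform on [-180, 180); accessibility
    is capped at the residue's Gly-X-Gly maximum.
    """
    if n_residues < 1:
        raise ValueError("n_residues must be >= 1")
    if not 0.0 <= burial_bias <= 1.0:
        raise ValueError("burial_bias must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    aas = rng.choice(np.array(AMINO_ACIDS), size=n_residues, p=BACKGROUND_VECTOR)
    hydro = np.array([aa in HYDROPHOBIC for aa in aas])
    mean_acc = np.where(hydro, 70.0 - 50.0 * burial_bias, 70.0)
    acc = rng.gamma(shape=2.0, scale=mean_acc / 2.0)
    max_asa = np.array([MAX_ASA_GXG[aa] for aa in aas])
    acc = np.minimum(acc, max_asa)
    return pd.DataFrame(
        {
            "protein_id": protein_id,
            "pos": np.arange(1, n_residues + 1),
            "aa": aas,
            "sec": rng.choice(SEC_CLASSES, size=n_residues, p=SEC_PROBS),
            "acc": np.round(acc, 1),
            # rounding can land exactly on +180, which wraps to -180
            "phi": _wrap_angle(np.round(rng.uniform(-180.0, 180.0, n_residues), 1)),
            "psi": _wrap_angle(np.round(rng.uniform(-180.0, 180.0, n_residues), 1)),
        }
    )


# ---------------------------------------------------------------------------
# labelled benchmark


def simulate_benchmark(
    n_pos: int,
    n_neg: int,
    channel_effect_sizes: Mapping[str, float] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Labelled feature vectors for score calibration.

    Negatives draw every channel from N(0, 1); positives are shifted
    down by the channel's effect size (damaging variants score lower on
    delta-type channels; calibration auto-detects direction, so only
    the magnitude matters).  Returns a tidy frame with a boolean
    ``label`` column (True = damaging) and one column per channel.
    """
    if n_pos < 1 or n_neg < 1:
        raise ValueError("both classes need at least one example")
    effects = dict(channel_effect_sizes or {c: 1.0 for c in DEFAULT_CHANNELS})
    rng = np.random.default_rng(seed)
    n = n_pos + n_neg
    label = np.repeat([True, False], [n_pos, n_neg])
    data: dict[str, np.ndarray] = {"label": label}
    for channel, effect in effects.items():
        x = rng.normal(0.0, 1.0, size=n)
        x[label] -= effect
        data[channel] = x
    df = pd.DataFrame(data)
    df.insert(0, "variant_id", [f"bench{i:06d}" for i in range(n)])
    return df


def simulate_cohort_features(
    truth: pd.DataFrame,
    channel_effect_sizes: Mapping[str, float] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Feature vectors for simulated cohort variants.

    Planted recessive-lethal variants draw their channels like
    benchmark positives (shifted by the per-channel effect size);
    non-lethal variants draw like negatives.  Use together with a
    benchmark from :func:`simulate_benchmark` (same effect sizes) so
    calibrated scores separate the planted lethals.
    """
    effects = dict(channel_effect_sizes or {c: 1.0 for c in DEFAULT_CHANNELS})
    rng = np.random.default_rng(seed)
    lethal = truth["is_lethal_recessive"].to_numpy(dtype=bool)
    data: dict = {"variant_id": truth["variant_id"].to_numpy()}
    for channel, effect in effects.items():
        x = rng.normal(0.0, 1.0, size=len(truth))
        x[lethal] -= effect
        data[channel] = x
    return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# writers


def write_vcf(
    records: Sequence[VariantRecord], path: str | os.PathLike, cohort: str = "A"
) -> None:
    """Write records as a minimal VCF with aggregate-count INFO fields."""
    header = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=AC,Number=A,Type=Integer,Description="Alternate allele count">',
        '##INFO=<ID=AN,Number=1,Type=Integer,Description="Allele number">',
        '##INFO=<ID=nhomalt,Number=A,Type=Integer,Description="Homozygous-alternate individuals">',
        '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">',
        '##INFO=<ID=AAPOS,Number=1,Type=Integer,Description="1-based protein position">',
        '##INFO=<ID=AAREF,Number=1,Type=String,Description="Reference amino acid">',
        '##INFO=<ID=AAALT,Number=1,Type=String,Description="Alternate amino acid">',
        '##INFO=<ID=CSQCLASS,Number=1,Type=String,Description="Consequence class">',
        "##contig=<ID=1>",
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    lines = list(header)
    for i, r in enumerate(records):
        c = r.counts[cohort]
        info = ";".join([
            f"AC={c.alt_allele_count}", f"AN={c.allele_number}",
            f"nhomalt={c.hom_alt}", f"GENE={r.gene}", f"AAPOS={r.aa_pos}",
            f"AAREF={r.aa_ref}", f"AAALT={r.aa_alt}", f"CSQCLASS={r.consequence}",
        ])
        lines.append(f"1\t{1000 + 3 * i}\t{r.variant_id}\tA\tT\t.\tPASS\t{info}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
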