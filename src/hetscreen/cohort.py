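"""Cohort ingestion and harmonization.

Reads per-variant genotype-count tables from VCF (gnomAD-style aggregate
INFO fields) or a TSV dialect, computes folded minor allele frequencies,
and intersects two cohorts keeping only variants whose MAFs agree within
a tolerance.  The pipeline never needs per-sample genotypes: everything
downstream runs on (het, hom-alt, n) counts.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

CONSEQUENCE_CLASSES = {
    "missense", "synonymous", "frameshift", "inframe_indel",
    "stop_gain", "utr", "splice", "intronic", "noncoding",
}

#: default INFO keys for VCF ingestion (gnomAD conventions)
DEFAULT_INFO_KEYS: dict[str, str] = {
    "ac": "AC",
    "an": "AN",
    "nhomalt": "nhomalt",
    "gene": "GENE",
    "aa_pos": "AAPOS",
    "aa_ref": "AAREF",
    "aa_alt": "AAALT",
    "consequence": "CSQCLASS",
}

TSV_COLUMNS = [
    "variant_id", "gene", "aa_pos", "aa_ref", "aa_alt",
    "het_count", "hom_alt_count", "n_individuals",
]


class UndefinedFrequencyError(ValueError):
    """Raised when a MAF is requested for a zero allele number."""


@dataclass(frozen=True)
class GenotypeCounts:
    """Aggregate genotype counts for one variant in one cohort."""

    het: int
    hom_alt: int
    n_individuals: int

    def __post_init__(self) -> None:
        if min(self.het, self.hom_alt, self.n_individuals) < 0:
            raise ValueError("genotype counts must be non-negative")
        if self.het + self.hom_alt > self.n_individuals:
            raise ValueError(
                f"carriers ({self.het} het + {self.hom_alt} hom) exceed "
                f"cohort size {self.n_individuals}"
            )

    @property
    def allele_number(self) -> int:
        return 2 * self.n_individuals

    @property
    def alt_allele_count(self) -> int:
        return self.het + 2 * self.hom_alt

    @property
    def alt_frequency(self) -> float:
        """Raw (unfolded) alternate-allele frequency."""
        if self.n_individuals == 0:
            raise UndefinedFrequencyError("allele number is zero")
        return self.alt_allele_count / self.allele_number


@dataclass(frozen=True)
class VariantRecord:
    """One alternate allele with per-cohort genotype counts.

    ``counts`` maps a cohort label (conventionally ``"A"`` for the
    primary cohort, ``"B"`` for the secondary) to :class:`GenotypeCounts`.
    """

    variant_id: str
    gene: str
    aa_pos: int
    aa_ref: str
    aa_alt: str
    consequence: str = "missense"
    counts: Mapping[str, GenotypeCounts] = field(default_factory=dict)

    def __post_init__(self) -> None:
        # "X" is the placeholder when protein annotation is absent
        if (self.consequence == "missense" and self.aa_ref != "X"
                and self.aa_ref == self.aa_alt):
            raise ValueError(
                f"{self.variant_id}: missense variant with aa_ref == aa_alt"
            )

    def maf(self, cohort: str) -> float:
        return minor_allele_frequency(self.counts[cohort])


def fold_maf(f: float) -> float:
    """Fold an allele frequency onto [0, 0.5] (invert when > 50%)."""
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"allele frequency {f} outside [0, 1]")
    return f if f <= 0.5 else 1.0 - f


def minor_allele_frequency(counts: GenotypeCounts) -> float:
    """Folded minor allele frequency from aggregate genotype counts.

    The raw alternate-allele frequency ``(het + 2*hom_alt) / (2*n)`` is
    folded so the returned value always lies in [0, 0.5].
    """
    return fold_maf(counts.alt_frequency)


# ---------------------------------------------------------------------------
# readers / writers


def _require(info: Mapping, key: str, where: str):
    value = info.get(key)
    if value is None:
        raise ValueError(f"missing required INFO field '{key}' at {where}")
    return value


def _per_alt(value, i: int, n_alt: int):
    """Extract the i-th entry of a Number=A INFO value."""
    if isinstance(value, (tuple, list)):
        return value[i]
    if n_alt == 1:
        return value
    # cyvcf2 may hand back a comma-joined string for unusual headers
    return type(value)(str(value).split(",")[i]) if isinstance(value, str) else value


def read_variants(
    path: str | os.PathLike,
    format: str = "tsv",
    cohort: str = "A",
    info_keys: Mapping[str, str] | None = None,
) -> list[VariantRecord]:
    """Read one cohort's variant table.

    Parameters
    ----------
    path:
        VCF (plain or bgzipped) or TSV file.
    format:
        ``"vcf"`` or ``"tsv"``.
    cohort:
        Label under which the counts are stored on each record.
    info_keys:
        Override the VCF INFO keys (defaults to gnomAD-style
        ``AC``/``AN``/``nhomalt`` plus annotation keys).
    """
    if format == "tsv":
        return _read_tsv(path, cohort)
    if format == "vcf":
        return _read_vcf(path, cohort, info_keys or DEFAULT_INFO_KEYS)
    raise ValueError(f"unknown format {format!r}; expected 'vcf' or 'tsv'")


def _read_vcf(path, cohort: str, keys: Mapping[str, str]) -> list[VariantRecord]:
    from cyvcf2 import VCF

    records: list[VariantRecord] = []
    for v in VCF(str(path)):
        n_alt = len(v.ALT)
        where = f"{v.CHROM}:{v.POS}"
        info = v.INFO
        an = int(_require(info, keys["an"], where))
        ac_all = _require(info, keys["ac"], where)
        nhom_all = _require(info, keys["nhomalt"], where)
        for i, alt in enumerate(v.ALT):
            ac = int(_per_alt(ac_all, i, n_alt))
            nhom = int(_per_alt(nhom_all, i, n_alt))
            het = ac - 2 * nhom
            if het < 0:
                raise ValueError(
                    f"inconsistent counts at {where} (AC={ac} < 2*nhomalt={nhom})"
                )
            vid = v.ID if v.ID and n_alt == 1 else (
                f"{v.ID or where}_{alt}" if n_alt > 1 else (v.ID or where)
            )
            records.append(
                VariantRecord(
                    variant_id=vid,
                    gene=str(info.get(keys["gene"]) or ""),
                    aa_pos=int(info.get(keys["aa_pos"]) or 0),
                    aa_ref=str(info.get(keys["aa_ref"]) or "X"),
                    aa_alt=str(info.get(keys["aa_alt"]) or "X"),
                    consequence=str(info.get(keys["consequence"]) or "missense"),
                    counts={cohort: GenotypeCounts(het, nhom, an // 2)},
                )
            )
    return records


def _read_tsv(path, cohort: str) -> list[VariantRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"variant_id": str, "gene": str})
    missing = [c for c in TSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    records = []
    for idx, row in enumerate(df.itertuples(index=False), start=2):
        try:
            counts = GenotypeCounts(
                int(row.het_count), int(row.hom_alt_count), int(row.n_individuals)
            )
            records.append(
                VariantRecord(
                    variant_id=str(row.variant_id),
                    gene=str(row.gene),
                    aa_pos=int(row.aa_pos),
                    aa_ref=str(row.aa_ref),
                    aa_alt=str(row.aa_alt),
                    consequence=str(getattr(row, "consequence", "missense")),
                    counts={cohort: counts},
                )
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}, line {idx}: {exc}") from exc
    return records


def write_tsv(records: Sequence[VariantRecord], path, cohort: str = "A") -> None:
    """Write one cohort's counts in the TSV dialect read by ``read_variants``."""
    rows = []
    for r in records:
        c = r.counts[cohort]
        rows.append(
            {
                "variant_id": r.variant_id,
                "gene": r.gene,
                "aa_pos": r.aa_pos,
                "aa_ref": r.aa_ref,
                "aa_alt": r.aa_alt,
                "het_count": c.het,
                "hom_alt_count": c.hom_alt,
                "n_individuals": c.n_individuals,
                "consequence": r.consequence,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# harmonization


def _check_unique(records: Iterable[VariantRecord], label: str) -> dict[str, VariantRecord]:
    out: dict[str, VariantRecord] = {}
    for r in records:
        if r.variant_id in out:
            raise ValueError(f"duplicate variant_id {r.variant_id!r} in cohort {label}")
        out[r.variant_id] = r
    return out


def harmonize_cohorts(
    a: Sequence[VariantRecord],
    b: Sequence[VariantRecord],
    max_maf_diff: float = 0.10,
    cohort_a: str = "A",
    cohort_b: str = "B",
) -> list[VariantRecord]:
    """Intersect two cohorts, keeping variants with concordant MAFs.

    A variant is retained iff it is present in both cohorts and the
    absolute difference of its folded MAFs is ``<= max_maf_diff``
    (boundary inclusive).  Retained records carry both cohorts' counts.
    """
    ia = _check_unique(a, cohort_a)
    ib = _check_unique(b, cohort_b)
    merged: list[VariantRecord] = []
    for vid, ra in ia.items():
        rb = ib.get(vid)
        if rb is None:
            continue
        maf_a = minor_allele_frequency(ra.counts[cohort_a])
        maf_b = minor_allele_frequency(rb.counts[cohort_b])
        if abs(maf_a - maf_b) <= max_maf_diff:
            merged.append(
                replace(ra, counts={cohort_a: ra.counts[cohort_a],
                                    cohort_b: rb.counts[cohort_b]})
            )
    return merged


def records_to_frame(records: Sequence[VariantRecord]) -> pd.DataFrame:
    """Flatten records (any cohorts present) into a tidy DataFrame."""
    rows = []
    for r in records:
        row: dict = {
            "variant_id": r.variant_id, "gene": r.gene, "aa_pos": r.aa_pos,
            "aa_ref": r.aa_ref, "aa_alt": r.aa_alt, "consequence": r.consequence,
        }
        for label, c in r.counts.items():
            row[f"het_{label}"] = c.het
            row[f"hom_{label}"] = c.hom_alt
            row[f"n_{label}"] = c.n_individuals
            row[f"maf_{label}"] = minor_allele_frequency(c) if c.n_individuals else float("nan")
        rows.append(row)
    return pd.DataFrame(rows)
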