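"""Per-variant feature channels.

Conservation channels come from alignment-column log-odds profiles
(``ortho`` from ortholog alignments, ``homo`` from all-homolog
alignments); the substitution channel is the BLOSUM62 entry; the
structural channels (``sec``, ``acc``, ``bur``, ``phi_psi``) score the
mutant against amino-acid x structural-environment-zone log-odds tables
trained on representative residue data; the annotation channels
(``fda``, ``omim``, ``haplotype``, ``uniprot_function``) come from gene
and position lookup tables.  Every delta-type channel is the mutant's
score minus the wild-type's, so negative values mean the mutant fits
its position worse.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment, substitution_matrices

from .constants import AMINO_ACIDS, BACKGROUND_FREQS, MAX_ASA_GXG

_BLOSUM62 = substitution_matrices.load("BLOSUM62")

COMMODITIES = ("sec", "acc", "bur", "phi_psi")

SEC_ZONES = ("helix", "strand", "coil")
ACC_ZONES = ("low", "medium", "high")
BUR_ZONES = ("low", "medium", "high")
PHI_PSI_ZONES = tuple(f"pp_{i}_{j}" for i in range(12) for j in range(12))


@dataclass(frozen=True)
class ProteinVariant:
    protein_id: str
    aa_pos: int
    aa_ref: str
    aa_alt: str


@dataclass(frozen=True)
class PositionProfile:
    """Log2-odds (vs background) of each amino acid at one reference position."""

    position: int
    ref_aa: str
    scores: Mapping[str, float]


def _check_aa(*aas: str) -> None:
    for aa in aas:
        if aa not in BACKGROUND_FREQS:
            raise ValueError(f"nonstandard amino acid {aa!r}")


# ---------------------------------------------------------------------------
# alignment profiles


def build_profile(
    alignment: MultipleSeqAlignment | str | os.PathLike,
    reference_id: str = "ref",
    pseudocount_weight: float = 1.0,
) -> dict[int, PositionProfile]:
    """Position-specific log-odds profiles from an alignment.

    For each ungapped position of the reference row, column amino-acid
    frequencies are smoothed with ``pseudocount_weight`` effective
    observations of the background composition and converted to
    log2-odds against background.  Columns where the reference is
    gapped are skipped; profile positions are 1-based reference
    coordinates.
    """
    if isinstance(alignment, (str, Path, os.PathLike)):
        alignment = AlignIO.read(str(alignment), "fasta")
    if len(alignment) == 0:
        raise ValueError("empty alignment")
    if pseudocount_weight <= 0:
        raise ValueError("pseudocount_weight must be positive")
    ref_row = next((r for r in alignment if r.id == reference_id), None)
    if ref_row is None:
        raise ValueError(f"reference row {reference_id!r} not in alignment")

    profiles: dict[int, PositionProfile] = {}
    ref_pos = 0
    for col_idx, ref_char in enumerate(str(ref_row.seq)):
        if ref_char == "-":
            continue
        ref_pos += 1
        column = [str(r.seq[col_idx]) for r in alignment]
        counts = {aa: 0.0 for aa in AMINO_ACIDS}
        n_obs = 0
        for c in column:
            if c in counts:
                counts[c] += 1.0
                n_obs += 1
        denom = n_obs + pseudocount_weight
        scores = {
            aa: float(np.log2(
                ((counts[aa] + pseudocount_weight * BACKGROUND_FREQS[aa]) / denom)
                / BACKGROUND_FREQS[aa]
            ))
            for aa in AMINO_ACIDS
        }
        profiles[ref_pos] = PositionProfile(ref_pos, ref_char, scores)
    return profiles


def profile_delta(profile: PositionProfile, aa_ref: str, aa_alt: str) -> float:
    """Mutant minus wild-type profile score; negative = mutant disfavoured."""
    _check_aa(aa_ref, aa_alt)
    if profile.ref_aa in BACKGROUND_FREQS and profile.ref_aa != aa_ref:
        raise ValueError(
            f"variant reference {aa_ref} does not match alignment residue "
            f"{profile.ref_aa} at position {profile.position}"
        )
    return profile.scores[aa_alt] - profile.scores[aa_ref]


def blosum_score(aa_ref: str, aa_alt: str) -> int:
    """BLOSUM62 substitution score for the residue pair."""
    _check_aa(aa_ref, aa_alt)
    return int(_BLOSUM62[aa_ref, aa_alt])


# ---------------------------------------------------------------------------
# structural zones


def burial(amino_acid: str, acc_value: float) -> float:
    """Gly-X-Gly maximal accessibility minus observed, floored at 0 (Å²)."""
    _check_aa(amino_acid)
    if acc_value < 0:
        raise ValueError("accessibility must be non-negative")
    return max(0.0, MAX_ASA_GXG[amino_acid] - acc_value)


def assign_zone(commodity: str, value) -> str:
    """Map a raw structural measurement to its environment zone.

    * ``sec``: DSSP character — H, G -> helix; E, B -> strand; else coil.
    * ``acc``: accessibility in Å² — [0, 16) low, [16, 60) medium, >=60 high.
    * ``bur``: burial in Å² — [0, 115) low, [115, 165) medium, >=165 high.
    * ``phi_psi``: an (phi, psi) pair in degrees — 12 x 12 grid of
      half-open 30° bins over [-180, 180), +180 wrapped to -180.
    """
    if commodity == "sec":
        c = str(value).upper()
        if c in ("H", "G"):
            return "helix"
        if c in ("E", "B"):
            return "strand"
        return "coil"
    if commodity in ("acc", "bur"):
        v = float(value)
        if v < 0:
            raise ValueError(f"{commodity} value must be non-negative")
        lo, hi = (16.0, 60.0) if commodity == "acc" else (115.0, 165.0)
        return "low" if v < lo else ("medium" if v < hi else "high")
    if commodity == "phi_psi":
        phi, psi = (float(value[0]), float(value[1]))
        cells = []
        for angle in (phi, psi):
            if angle == 180.0:
                angle = -180.0
            if not -180.0 <= angle < 180.0:
                raise ValueError(f"dihedral angle {angle} outside [-180, 180)")
            cells.append(int((angle + 180.0) // 30.0))
        return f"pp_{cells[0]}_{cells[1]}"
    raise ValueError(f"unknown commodity {commodity!r}")


def zones_for(commodity: str) -> tuple[str, ...]:
    return {
        "sec": SEC_ZONES, "acc": ACC_ZONES,
        "bur": BUR_ZONES, "phi_psi": PHI_PSI_ZONES,
    }[commodity]


@dataclass(frozen=True)
class ZoneTable:
    """Log2-odds of observed vs expected amino-acid counts per zone."""

    commodity: str
    log_odds: pd.DataFrame  # index: amino acid, columns: zones

    def delta(self, zone: str, aa_ref: str, aa_alt: str) -> float:
        return zone_delta(self, zone, aa_ref, aa_alt)


def _row_zones(rows: pd.DataFrame, commodity: str) -> pd.Series:
    if commodity == "sec":
        return rows["sec"].map(lambda c: assign_zone("sec", c))
    if commodity == "acc":
        return rows["acc"].map(lambda v: assign_zone("acc", v))
    if commodity == "bur":
        bur = [burial(aa, acc) for aa, acc in zip(rows["aa"], rows["acc"])]
        return pd.Series([assign_zone("bur", b) for b in bur], index=rows.index)
    if commodity == "phi_psi":
        return pd.Series(
            [assign_zone("phi_psi", (phi, psi))
             for phi, psi in zip(rows["phi"], rows["psi"])],
            index=rows.index,
        )
    raise ValueError(f"unknown commodity {commodity!r}")


def train_zone_table(
    rows: pd.DataFrame, commodity: str, pseudocount: float = 0.5
) -> ZoneTable:
    """Train amino-acid x zone log-odds from a residue feature table.

    ``log_odds(aa, zone) = log2[(obs(aa, zone) + pc) / (exp(aa, zone) + pc)]``
    with ``exp(aa, zone) = total(zone) * freq(aa)`` — the counts expected
    if residue identity and structural environment were independent.
    On amino-acid-independent data all entries shrink toward 0.
    """
    if len(rows) == 0:
        raise ValueError("empty residue table")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    zone = _row_zones(rows, commodity)
    obs = (
        pd.crosstab(rows["aa"], zone)
        .reindex(index=list(AMINO_ACIDS), columns=list(zones_for(commodity)),
                 fill_value=0)
        .astype(float)
    )
    total = obs.values.sum()
    aa_freq = obs.sum(axis=1) / total
    zone_total = obs.sum(axis=0)
    expected = np.outer(aa_freq, zone_total)  # sums to total(zone) per zone
    log_odds = np.log2((obs.values + pseudocount) / (expected + pseudocount))
    return ZoneTable(
        commodity,
        pd.DataFrame(log_odds, index=obs.index, columns=obs.columns),
    )


def zone_delta(table: ZoneTable, zone: str, aa_ref: str, aa_alt: str) -> float:
    """Mutant minus wild-type zone log-odds, within the wild-type's zone."""
    _check_aa(aa_ref, aa_alt)
    if zone not in table.log_odds.columns:
        raise ValueError(f"zone {zone!r} not in {table.commodity} table")
    col = table.log_odds[zone]
    return float(col[aa_alt] - col[aa_ref])


def structural_deltas(
    tables: Mapping[str, ZoneTable],
    residue_row: Mapping,
    aa_alt: str,
) -> dict[str, float]:
    """All structural channel deltas for one variant.

    ``residue_row`` is the wild-type residue's feature row (``aa``,
    ``sec``, ``acc``, ``phi``, ``psi``); the mutant is scored inside the
    wild-type's zone for every commodity.
    """
    aa_ref = residue_row["aa"]
    out: dict[str, float] = {}
    for commodity, table in tables.items():
        if commodity == "sec":
            zone = assign_zone("sec", residue_row["sec"])
        elif commodity == "acc":
            zone = assign_zone("acc", residue_row["acc"])
        elif commodity == "bur":
            zone = assign_zone("bur", burial(aa_ref, residue_row["acc"]))
        else:
            zone = assign_zone("phi_psi", (residue_row["phi"], residue_row["psi"]))
        out[commodity if commodity != "phi_psi" else "phi_psi"] = zone_delta(
            table, zone, aa_ref, aa_alt
        )
    return out


# ---------------------------------------------------------------------------
# annotations

HAPLOTYPE_SCORES: dict[str, float] = {
    "autosomal_recessive": 1.0,
    "sufficient_evidence": 0.75,
    "some_evidence": 0.5,
    "minimal_evidence": 0.25,
    "no_evidence": 0.0,
    "unlikely": 0.0,
}


@dataclass(frozen=True)
class AnnotationTables:
    """Gene- and position-level annotation lookups.

    ``fda_genes``/``omim_genes``: gene symbols with approved drugs /
    OMIM disease association.  ``haplotype``: gene -> ClinGen-style
    dosage-sensitivity category.  ``uniprot_features``: intervals
    (gene, start, end) of annotated functional features (PTM sites,
    active centres, known variants).
    """

    fda_genes: frozenset[str] = frozenset()
    omim_genes: frozenset[str] = frozenset()
    haplotype: Mapping[str, str] = field(default_factory=dict)
    uniprot_features: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["gene", "start", "end"])
    )

    def __post_init__(self) -> None:
        object.__setattr__(self, "fda_genes",
                           frozenset(g.upper() for g in self.fda_genes))
        object.__setattr__(self, "omim_genes",
                           frozenset(g.upper() for g in self.omim_genes))
        object.__setattr__(self, "haplotype",
                           {g.upper(): c for g, c in self.haplotype.items()})


def load_gene_list(path) -> frozenset[str]:
    """One gene symbol per line; ``#`` comments and blanks ignored."""
    genes = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                genes.add(line.upper())
    return frozenset(genes)


def annotation_scores(
    gene: str,
    aa_pos: int,
    tables: AnnotationTables,
    uniprot_window: int = 0,
) -> dict[str, float]:
    """FDA/OMIM/haplotype/uniprot-function channels for one variant.

    FDA and OMIM are 1 iff the gene is listed; the haplotype channel
    maps the gene's dosage-sensitivity category onto
    {1, 0.75, 0.5, 0.25, 0} (autosomal-recessive evidence scoring
    highest, absent or unlikely scoring 0); ``uniprot_function`` is 1
    iff the variant position falls within ``uniprot_window`` residues of
    an annotated functional feature of the gene.
    """
    g = gene.upper()
    category = tables.haplotype.get(g)
    if category is None:
        haplo = 0.0
    else:
        key = category.strip().lower().replace(" ", "_")
        if key not in HAPLOTYPE_SCORES:
            raise ValueError(
                f"unknown haplotype category {category!r} for gene {gene}; "
                f"expected one of {sorted(HAPLOTYPE_SCORES)}"
            )
        haplo = HAPLOTYPE_SCORES[key]

    feats = tables.uniprot_features
    hit = False
    if len(feats):
        sub = feats[feats["gene"].str.upper() == g]
        hit = bool(
            ((sub["start"] - uniprot_window <= aa_pos)
             & (aa_pos <= sub["end"] + uniprot_window)).any()
        )
    return {
        "fda": 1.0 if g in tables.fda_genes else 0.0,
        "omim": 1.0 if g in tables.omim_genes else 0.0,
        "haplotype": haplo,
        "uniprot_function": 1.0 if hit else 0.0,
    }
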