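"""Feature channels: profiles, BLOSUM62, structural zones, annotations."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from hetscreen import (
    AnnotationTables,
    annotation_scores,
    assign_zone,
    blosum_score,
    build_profile,
    burial,
    profile_delta,
    simulate_alignment,
    simulate_residue_features,
    train_zone_table,
    zone_delta,
)
from hetscreen.constants import AMINO_ACIDS, BACKGROUND_FREQS, MAX_ASA_GXG
from hetscreen.features import load_gene_list, structural_deltas

aa_strategy = st.sampled_from(AMINO_ACIDS)


def brute_force_profile(alignment, pos, pc=1.0):
    """Oracle: direct column counting for small alignments."""
    ref = str(alignment[0].seq)
    ungapped = [i for i, c in enumerate(ref) if c != "-"]
    col_idx = ungapped[pos - 1]
    column = [str(r.seq[col_idx]) for r in alignment]
    counts = {aa: column.count(aa) for aa in AMINO_ACIDS}
    n = sum(counts.values())
    return {
        aa: math.log2(((counts[aa] + pc * BACKGROUND_FREQS[aa]) / (n + pc))
                      / BACKGROUND_FREQS[aa])
        for aa in AMINO_ACIDS
    }


class TestProfiles:
    def test_agrees_with_column_count_oracle(self):
        aln = simulate_alignment(10, 8, conserved_positions={3},
                                 conservation_strength=0.8, seed=31)
        profiles = build_profile(aln)
        for pos in (1, 3, 8):
            oracle = brute_force_profile(aln, pos)
            for aa in AMINO_ACIDS:
                assert profiles[pos].scores[aa] == pytest.approx(oracle[aa])

    def test_conserved_column_favours_wild_type(self):
        """A fully conserved column scores its residue well above any mutant."""
        aln = simulate_alignment(10, 6, conserved_positions={4},
                                 conservation_strength=1.0, seed=32)
        profiles = build_profile(aln)
        wt = profiles[4].ref_aa
        assert all(
            profiles[4].scores[wt] > profiles[4].scores[aa] + 1.0
            for aa in AMINO_ACIDS if aa != wt
        )
        assert profile_delta(profiles[4], wt, "L" if wt != "L" else "K") < 0

    def test_large_pseudocount_flattens_scores(self):
        aln = simulate_alignment(1, 10, seed=33)
        profiles = build_profile(aln, pseudocount_weight=1e6)
        assert all(
            abs(s) < 0.01 for p in profiles.values() for s in p.scores.values()
        )

    def test_delta_identity_and_antisymmetry(self):
        aln = simulate_alignment(8, 5, seed=34)
        profiles = build_profile(aln)
        p = profiles[2]
        ref = p.ref_aa
        alt = "W" if ref != "W" else "Y"
        assert profile_delta(p, ref, ref) == 0.0
        fwd = p.scores[alt] - p.scores[ref]
        assert profile_delta(p, ref, alt) == pytest.approx(fwd)

    def test_reference_mismatch_and_missing_reference(self):
        aln = simulate_alignment(5, 5, seed=35)
        with pytest.raises(ValueError, match="reference row"):
            build_profile(aln, reference_id="nope")
        profiles = build_profile(aln)
        p = profiles[1]
        wrong = "A" if p.ref_aa != "A" else "C"
        with pytest.raises(ValueError, match="does not match"):
            profile_delta(p, wrong, "G")


class TestBlosum:
    def test_known_entries(self):
        assert blosum_score("I", "F") == 0
        assert blosum_score("Q", "Q") == 5

    @given(aa_strategy, aa_strategy)
    def test_symmetry(self, a, b):
        assert blosum_score(a, b) == blosum_score(b, a)

    def test_nonstandard_rejected(self):
        with pytest.raises(ValueError):
            blosum_score("B", "A")


class TestZoneAssignment:
    @pytest.mark.parametrize("char,zone", [
        ("H", "helix"), ("G", "helix"), ("E", "strand"), ("B", "strand"),
        ("C", "coil"), ("T", "coil"), ("S", "coil"), ("I", "coil"),
    ])
    def test_secondary_structure(self, char, zone):
        assert assign_zone("sec", char) == zone

    @pytest.mark.parametrize("v,zone", [
        (0, "low"), (15, "low"), (16, "medium"), (59, "medium"), (60, "high"),
    ])
    def test_accessibility_bands(self, v, zone):
        assert assign_zone("acc", v) == zone

    @pytest.mark.parametrize("v,zone", [
        (0, "low"), (114, "low"), (115, "medium"), (164, "medium"), (165, "high"),
    ])
    def test_burial_bands(self, v, zone):
        assert assign_zone("bur", v) == zone

    def test_phi_psi_grid_boundaries(self):
        assert assign_zone("phi_psi", (-180.0, -180.0)) == "pp_0_0"
        assert assign_zone("phi_psi", (179.9, -180.0)) == "pp_11_0"
        assert assign_zone("phi_psi", (180.0, 180.0)) == "pp_0_0"  # wrapped
        assert assign_zone("phi_psi", (-150.0, -121.0)) == "pp_1_1"
        with pytest.raises(ValueError):
            assign_zone("phi_psi", (200.0, 0.0))

    @given(aa_strategy,
           st.floats(min_value=0, max_value=300, allow_nan=False),
           st.floats(min_value=-180, max_value=179.999),
           st.floats(min_value=-180, max_value=179.999),
           st.sampled_from("HGEBCTSI"))
    def test_assignment_is_total(self, aa, acc, phi, psi, sec):
        assert assign_zone("sec", sec) in ("helix", "strand", "coil")
        assert assign_zone("acc", acc) in ("low", "medium", "high")
        assert assign_zone("bur", burial(aa, acc)) in ("low", "medium", "high")
        assert assign_zone("phi_psi", (phi, psi)).startswith("pp_")


class TestBurial:
    def test_fully_exposed_and_fully_buried(self):
        assert burial("K", MAX_ASA_GXG["K"]) == 0.0
        assert burial("K", 0.0) == MAX_ASA_GXG["K"]

    def test_glycine_has_smallest_reference(self):
        assert MAX_ASA_GXG["G"] == min(MAX_ASA_GXG.values())
        assert burial("G", 10.0) <= MAX_ASA_GXG["G"]

    def test_floored_at_zero(self):
        assert burial("G", 500.0) == 0.0


class TestZoneTraining:
    def test_independence_null_near_zero_and_shrinking(self):
        maxima = {}
        for n in (2000, 80000):
            rows = simulate_residue_features(n, seed=41, burial_bias=0.0)
            table = train_zone_table(rows, "acc")
            maxima[n] = float(np.abs(table.log_odds.values).max())
        assert maxima[80000] < 0.3
        assert maxima[80000] < maxima[2000]

    def test_planted_ile_burial_bias_recovered(self):
        rows = simulate_residue_features(20000, seed=42)
        table = train_zone_table(rows, "acc")
        assert table.log_odds.loc["I", "low"] > 0.2
        assert table.log_odds.loc["K", "low"] < 0.0

    def test_expected_counts_conserve_zone_totals(self):
        rows = simulate_residue_features(3000, seed=43)
        zone = rows["acc"].map(lambda v: assign_zone("acc", v))
        obs = pd.crosstab(rows["aa"], zone).astype(float)
        aa_freq = obs.sum(axis=1) / obs.values.sum()
        expected = np.outer(aa_freq, obs.sum(axis=0))
        np.testing.assert_allclose(expected.sum(axis=0), obs.sum(axis=0).values)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            train_zone_table(pd.DataFrame(columns=["aa", "acc"]), "acc")

    def test_delta_identity_antisymmetry_and_direction(self):
        rows = simulate_residue_features(20000, seed=44)
        table = train_zone_table(rows, "acc")
        assert zone_delta(table, "low", "I", "I") == 0.0
        assert zone_delta(table, "low", "I", "K") == pytest.approx(
            -zone_delta(table, "low", "K", "I"))
        # hydrophobic -> charged in the buried zone is penalised; the
        # hydrophobic -> hydrophobic swap is near neutral
        assert zone_delta(table, "low", "I", "K") < zone_delta(table, "low", "I", "F")
        assert zone_delta(table, "low", "I", "K") < -0.3

    def test_structural_deltas_cover_all_commodities(self):
        rows = simulate_residue_features(5000, seed=45)
        tables = {c: train_zone_table(rows, c) for c in ("sec", "acc", "bur", "phi_psi")}
        row = rows.iloc[0]
        deltas = structural_deltas(tables, row, "W" if row["aa"] != "W" else "Y")
        assert set(deltas) == {"sec", "acc", "bur", "phi_psi"}
        same = structural_deltas(tables, row, row["aa"])
        assert all(v == 0.0 for v in same.values())


class TestAnnotations:
    def _tables(self):
        return AnnotationTables(
            fda_genes=frozenset({"ADRB1"}),
            omim_genes=frozenset({"PANK2", "ADRB1"}),
            haplotype={"NLRP12": "autosomal_recessive", "GLIS2": "some_evidence"},
            uniprot_features=pd.DataFrame(
                {"gene": ["CCDC8"], "start": [197], "end": [202]}
            ),
        )

    def test_listed_gene_scores_one(self):
        s = annotation_scores("ADRB1", 270, self._tables())
        assert s == {"fda": 1.0, "omim": 1.0, "haplotype": 0.0, "uniprot_function": 0.0}

    def test_haplotype_five_level_mapping(self):
        t = self._tables()
        assert annotation_scores("NLRP12", 394, t)["haplotype"] == 1.0
        assert annotation_scores("GLIS2", 420, t)["haplotype"] == 0.5

    def test_position_overlap_and_window(self):
        t = self._tables()
        assert annotation_scores("CCDC8", 200, t)["uniprot_function"] == 1.0
        assert annotation_scores("CCDC8", 250, t)["uniprot_function"] == 0.0
        assert annotation_scores("CCDC8", 205, t, uniprot_window=5)["uniprot_function"] == 1.0

    def test_unannotated_gene_all_zero(self):
        s = annotation_scores("ZAN", 871, self._tables())
        assert set(s.values()) == {0.0}

    def test_unknown_haplotype_category_named_in_error(self):
        t = AnnotationTables(haplotype={"G1": "mystery_level"})
        with pytest.raises(ValueError, match="mystery_level"):
            annotation_scores("G1", 1, t)

    def test_gene_list_loader(self, tmp_path):
        p = tmp_path / "genes.txt"
        p.write_text("# blacklist\nMUC16\n\nfLg\n")
        assert load_gene_list(p) == frozenset({"MUC16", "FLG"})
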