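"""Epitope scanning, variant discovery and cluster-weighted count matrices."""

import numpy as np
import pandas as pd
import pytest

from gliascan.catalogue import THIRTY_THREE_MER, load_packaged_presence
from gliascan.cluster import dedup_clusters
from gliascan.quantify import (
    count_matrix,
    discover_variants,
    intact_33mer,
    occurrence_counts,
    presence_matrix,
    scan_sequence,
)


def oracle_hits(protein, records, max_mismatch):
    """Naive triple loop over (length, window, record); test-local oracle."""
    recs = [r for r in records if "*" not in r.peptide]
    hits = []
    for length in sorted({len(r.peptide) for r in recs}):
        group = [r for r in recs if len(r.peptide) == length]
        for start in range(len(protein) - length + 1):
            window = protein[start : start + length]
            best_mm, best_name = max_mismatch + 1, None
            for rec in group:
                mm = sum(a != b for a, b in zip(window, rec.peptide))
                if mm < best_mm:
                    best_mm, best_name = mm, rec.name
            if best_name is not None and best_mm <= max_mismatch:
                hits.append((best_name, start, length, best_mm))
    return sorted(hits, key=lambda h: (h[2], h[1]))


def clusters_of(line, protein_counts, min_members=1):
    return {line: dedup_clusters(protein_counts, min_members, line)}


class TestScanner:
    def test_33mer_exact_scan_six_overlapping_hits(self, catalogue):
        canon = [r for r in catalogue if r.name in
                 ("DQ2.5-glia-α1a", "DQ2.5-glia-α1b", "DQ2.5-glia-α2")]
        hits = scan_sequence(THIRTY_THREE_MER, canon, 0)
        assert len(hits) == 6
        assert {(h.epitope, h.start) for h in hits} == {
            ("DQ2.5-glia-α1a", 4),
            ("DQ2.5-glia-α2", 6),
            ("DQ2.5-glia-α1b", 11),
            ("DQ2.5-glia-α2", 13),
            ("DQ2.5-glia-α1b", 18),
            ("DQ2.5-glia-α2", 20),
        }

    def test_full_catalogue_still_attributes_33mer_to_canonicals(self, catalogue):
        counts = occurrence_counts(THIRTY_THREE_MER, catalogue, 1)
        assert counts["DQ2.5-glia-α1a"] == 1
        assert counts["DQ2.5-glia-α1b"] == 2
        assert counts["DQ2.5-glia-α2"] == 3

    def test_empty_protein_no_hits(self, catalogue):
        assert scan_sequence("", catalogue, 1) == []

    @pytest.mark.parametrize("max_mismatch", [0, 1, 2])
    def test_matches_naive_oracle_on_fuzzed_sequences(self, catalogue, max_mismatch):
        rng = np.random.default_rng(11)
        alphabet = np.array(list("PQLFYSRHKAGT"))
        for _ in range(40):
            protein = "".join(rng.choice(alphabet, size=120))
            got = [(h.epitope, h.start, h.length, h.mismatches)
                   for h in scan_sequence(protein, catalogue, max_mismatch)]
            assert got == oracle_hits(protein, catalogue, max_mismatch)

    def test_mismatch_monotonicity(self, catalogue):
        rng = np.random.default_rng(13)
        alphabet = np.array(list("PQLFYS"))
        for _ in range(10):
            protein = "".join(rng.choice(alphabet, size=80))
            c0 = occurrence_counts(protein, catalogue, 0)
            c1 = occurrence_counts(protein, catalogue, 1)
            c2 = occurrence_counts(protein, catalogue, 2)
            assert sum(c0.values()) <= sum(c1.values()) <= sum(c2.values())

    def test_invalid_mismatch_rejected(self, catalogue):
        with pytest.raises(ValueError):
            scan_sequence("PQPQLPYPQ", catalogue, 3)


class TestDiscoverVariants:
    def test_finds_unlisted_one_mismatch_variant(self, catalogue):
        reduced = [r for r in catalogue if r.name != "DQ2.5-glia-α2 (var15)"]
        protein = "AGDE" + "LQPQLPYPQ" + "VNTE"
        novel = discover_variants(protein, reduced, 1)
        assert len(novel) == 1
        assert novel[0].peptide == "LQPQLPYPQ"
        assert novel[0].nearest_canonical == "DQ2.5-glia-α2"
        assert novel[0].distance == 1

    def test_catalogued_windows_are_not_novel(self, catalogue):
        protein = "PFPQPQLPY" + "PQPQLPYPQ"
        assert discover_variants(protein, catalogue, 1) == []

    def test_equals_set_difference_oracle(self, catalogue):
        rng = np.random.default_rng(3)
        alphabet = np.array(list("PQLFYS"))
        canonicals = [r for r in catalogue if r.canonical and len(r.peptide) == 9]
        known = {r.peptide for r in catalogue if "*" not in r.peptide}
        for _ in range(30):
            protein = "".join(rng.choice(alphabet, size=100))
            expected = set()
            for start in range(len(protein) - 8):
                w = protein[start : start + 9]
                d = min(sum(a != b for a, b in zip(w, r.peptide)) for r in canonicals)
                if d <= 1 and w not in known:
                    expected.add(w)
            assert {v.peptide for v in discover_variants(protein, catalogue, 1)} == expected


class TestCountMatrix:
    def test_cluster_weighted_arithmetic(self, catalogue):
        protein = "PQPQLPYPQ" + "AGDEVNTAG" + "PQPQLPYPQ"  # 2 occurrences
        cm = count_matrix(clusters_of("L1", {protein: 50}), catalogue, 0)
        assert cm.raw.loc["DQ2.5-glia-α2", "L1"] == 100

    def test_summed_over_clusters(self, catalogue):
        a = "PQPQLPYPQ" + "AGDEVNTAG"          # 1 occurrence × 30
        b = ("PQPQLPYPQ" + "AGDEVNT") * 3      # 3 occurrences × 20
        cm = count_matrix(clusters_of("L1", {a: 30, b: 20}), catalogue, 0)
        assert cm.raw.loc["DQ2.5-glia-α2", "L1"] == 90

    def test_normalization_and_log2(self, catalogue):
        protein = "PQPQLPYPQ" + "AGDEVNTAG"
        cm = count_matrix(clusters_of("L1", {protein: 40}), catalogue, 0)
        assert cm.depths["L1"] == 40
        norm = cm.normalized.loc["DQ2.5-glia-α2", "L1"]
        assert norm == pytest.approx(40 * 1e6 / 40)
        assert cm.log2.loc["DQ2.5-glia-α2", "L1"] == pytest.approx(np.log2(norm + 1))

    def test_depth_doubling_leaves_normalized_unchanged(self, catalogue):
        counts = {"PQPQLPYPQAGDEVNTAG": 25, "PFPQPQLPYAGDEVNTAG": 30}
        cm1 = count_matrix(clusters_of("L1", counts), catalogue, 0)
        cm2 = count_matrix(
            clusters_of("L1", {k: 2 * v for k, v in counts.items()}), catalogue, 0
        )
        pd.testing.assert_frame_equal(cm1.normalized, cm2.normalized)

    def test_all_rows_flag_keeps_zero_rows(self, catalogue):
        cm = count_matrix(clusters_of("L1", {"AGDEVNTAG": 30}), catalogue, 0, all_rows=True)
        assert len(cm.raw) == len(catalogue)
        assert cm.raw["L1"].sum() == 0


class TestPresenceMatrix:
    def test_packaged_fixture_reproduces_reference_totals(self):
        presence = load_packaged_presence()
        _, totals = presence_matrix(presence)
        assert totals.tolist() == [42, 39, 42, 44, 39, 41, 43, 48]
        assert totals["L8"] == 48

    def test_zero_column_total_zero(self):
        raw = pd.DataFrame({"a": [0, 0], "b": [3, 0]}, index=["e1", "e2"])
        presence, totals = presence_matrix(raw)
        assert totals["a"] == 0 and totals["b"] == 1

    def test_totals_equal_independent_recount(self, rng):
        raw = pd.DataFrame(
            rng.integers(0, 5, size=(10, 4)),
            index=[f"e{i}" for i in range(10)],
            columns=list("ABCD"),
        )
        presence, totals = presence_matrix(raw)
        for col in raw.columns:
            assert totals[col] == sum(1 for v in raw[col] if v > 0)
        assert ((presence == 1) == (raw > 0)).all().all()


class TestIntact33mer:
    def test_containing_cluster_counts_members(self, catalogue):
        protein = "AGDE" + THIRTY_THREE_MER + "VNTE"
        counts = intact_33mer(clusters_of("L5", {protein: 28}))
        assert counts["L5"] == 28

    def test_absent_means_zero(self):
        assert intact_33mer(clusters_of("L1", {"AGDEVNTAG": 30}))["L1"] == 0

    def test_single_substitution_breaks_exactness(self):
        broken = THIRTY_THREE_MER[:16] + "A" + THIRTY_THREE_MER[17:]
        assert intact_33mer(clusters_of("L1", {("AG" + broken + "DE"): 50}))["L1"] == 0

    def test_33mer_implies_six_canonical_hits(self, catalogue):
        protein = "AGDE" + THIRTY_THREE_MER + "VNTE"
        counts = occurrence_counts(protein, catalogue, 0)
        total = sum(
            counts.get(n, 0)
            for n in ("DQ2.5-glia-α1a", "DQ2.5-glia-α1b", "DQ2.5-glia-α2")
        )
        assert total >= 6
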