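"""Synthetic amplicon generator: template truth, read emission, determinism."""

import numpy as np
import pytest

from gliascan.catalogue import THIRTY_THREE_MER, scannable
from gliascan.layout import (
    BARCODE_LENGTH,
    CORE_OFFSET,
    FORWARD_PRIMER,
    REV_TAIL_LENGTH,
    iupac_mismatches,
    reverse_complement,
)
from gliascan.simulate import (
    DEFAULT_BARCODES,
    ImpossiblePlanError,
    SimConfig,
    back_translate,
    build_template,
    emit_reads,
    margin_safe_records,
    naive_scan,
    sample_epitope_plan,
    simulate_run,
    truth_table,
)


def oracle_scan(protein, records, max_mismatch):
    """Test-local brute-force scan, written independently of the package."""
    recs = [r for r in records if "*" not in r.peptide]
    counts = {}
    for length in sorted({len(r.peptide) for r in recs}):
        group = [r for r in recs if len(r.peptide) == length]
        for start in range(len(protein) - length + 1):
            window = protein[start : start + length]
            scored = [
                (sum(a != b for a, b in zip(window, r.peptide)), i)
                for i, r in enumerate(group)
            ]
            mm, idx = min(scored)
            if mm <= max_mismatch:
                name = group[idx].name
                counts[name] = counts.get(name, 0) + 1
    return counts


class TestBuildTemplate:
    def test_33mer_plan_realizes_six_overlapping_epitopes(self, catalogue, rng):
        tpl = build_template("line1", DEFAULT_BARCODES[0], [("33mer", 1)], rng, catalogue)
        assert tpl.truth_epitopes["DQ2.5-glia-α1a"] == 1
        assert tpl.truth_epitopes["DQ2.5-glia-α1b"] == 2
        assert tpl.truth_epitopes["DQ2.5-glia-α2"] == 3
        assert THIRTY_THREE_MER in tpl.protein_core

    def test_empty_plan_has_empty_truth(self, catalogue, rng):
        tpl = build_template("line1", DEFAULT_BARCODES[0], [], rng, catalogue)
        assert tpl.truth_epitopes == {}

    def test_truth_matches_independent_oracle(self, catalogue, rng):
        tpl = build_template(
            "line1", DEFAULT_BARCODES[0], [("DQ2.5-glia-α3", 2)], rng, catalogue
        )
        assert tpl.truth_epitopes == oracle_scan(tpl.protein_core, catalogue, 1)
        assert tpl.truth_epitopes["DQ2.5-glia-α3"] == 2

    def test_layout_round_trip(self, catalogue, rng):
        tpl = build_template("line1", DEFAULT_BARCODES[0], [("33mer", 1)], rng, catalogue)
        assert tpl.cds.startswith(tpl.barcode)
        assert iupac_mismatches(FORWARD_PRIMER, tpl.cds[BARCODE_LENGTH : BARCODE_LENGTH + len(FORWARD_PRIMER)]) == 0
        assert back_translate(tpl.protein_core) == tpl.core_cds
        assert 192 <= len(tpl.core_cds) <= 432

    def test_pseudogene_carries_internal_stop(self, catalogue, rng):
        tpl = build_template(
            "line1", DEFAULT_BARCODES[0], [("DQ2.5-glia-α2", 1)], rng, catalogue, is_pseudogene=True
        )
        assert tpl.is_pseudogene
        assert "*" in tpl.protein_core
        assert "TAA" in tpl.core_cds

    def test_impossible_plan_names_culprits(self, catalogue, rng):
        with pytest.raises(ImpossiblePlanError, match="33mer"):
            build_template("line1", DEFAULT_BARCODES[0], [("33mer", 5)], rng, catalogue)

    def test_unknown_epitope_rejected(self, catalogue, rng):
        with pytest.raises(KeyError):
            build_template("line1", DEFAULT_BARCODES[0], [("nonsense", 1)], rng, catalogue)


class TestNaiveScanOracle:
    def test_agrees_with_independent_oracle_on_fuzzed_sequences(self, catalogue):
        rng = np.random.default_rng(7)
        alphabet = np.array(list("PQLFYSRHAK"))
        for _ in range(25):
            protein = "".join(rng.choice(alphabet, size=60))
            for mm in (0, 1):
                assert naive_scan(protein, catalogue, mm) == oracle_scan(protein, catalogue, mm)


class TestEmitReads:
    def test_zero_error_reads_are_template_copies(self, catalogue, rng, tmp_path):
        tpl = build_template(
            "line1", DEFAULT_BARCODES[0], [("33mer", 1)], rng, catalogue, abundance=30
        )
        cfg = SimConfig(error_rate=0.0, seed=5)
        n = emit_reads([tpl], cfg, tmp_path / "r1.fastq", tmp_path / "r2.fastq")
        assert n == 30
        r1 = (tmp_path / "r1.fastq").read_text().splitlines()
        seqs = {r1[i] for i in range(1, len(r1), 4)}
        assert seqs == {tpl.cds[:250]}
        r2 = (tmp_path / "r2.fastq").read_text().splitlines()
        assert {r2[i] for i in range(1, len(r2), 4)} == {reverse_complement(tpl.cds)[:250]}

    def test_deterministic_under_seed(self, catalogue, tmp_path):
        cfg = SimConfig(n_lines=2, templates_per_line=3, seed=9, error_rate=0.01)
        out_a = simulate_run(cfg, catalogue, tmp_path / "a")
        out_b = simulate_run(cfg, catalogue, tmp_path / "b")
        assert out_a.r1_path.read_bytes() == out_b.r1_path.read_bytes()
        assert out_a.r2_path.read_bytes() == out_b.r2_path.read_bytes()
        assert out_a.truth_path.read_text() == out_b.truth_path.read_text()

    def test_error_rate_within_binomial_bounds(self, catalogue, rng, tmp_path):
        tpl = build_template(
            "line1", DEFAULT_BARCODES[0], [("33mer", 1)], rng, catalogue, abundance=40
        )
        rate = 0.01
        cfg = SimConfig(error_rate=rate, seed=3)
        emit_reads([tpl], cfg, tmp_path / "r1.fastq", tmp_path / "r2.fastq")
        lines = (tmp_path / "r1.fastq").read_text().splitlines()
        ref = tpl.cds[:250]
        mismatches = sum(
            sum(a != b for a, b in zip(lines[i], ref)) for i in range(1, len(lines), 4)
        )
        n_bases = 40 * 250
        sd = (n_bases * rate * (1 - rate)) ** 0.5
        assert abs(mismatches - n_bases * rate) <= 3 * sd

    def test_total_pairs_equals_abundance_sum(self, small_sim):
        assert small_sim.n_pairs == sum(t.abundance for t in small_sim.templates)

    def test_read_length_shorter_than_prefix_rejected(self):
        with pytest.raises(ValueError, match="read_length"):
            SimConfig(read_length=20)


class TestTruthTable:
    def test_pseudogenes_excluded_from_truth(self, catalogue, rng):
        good = build_template(
            "line1", DEFAULT_BARCODES[0], [("DQ2.5-glia-α2", 1)], rng, catalogue, abundance=10
        )
        pseudo = build_template(
            "line1", DEFAULT_BARCODES[0], [("DQ2.5-glia-α2", 1)], rng, catalogue,
            abundance=99, is_pseudogene=True,
        )
        df = truth_table([good, pseudo])
        assert set(df["depth"]) == {10}
        assert df.loc[df.epitope == "DQ2.5-glia-α2", "count"].sum() == 10

    def test_normalized_is_per_million(self, catalogue, rng):
        tpl = build_template(
            "line1", DEFAULT_BARCODES[0], [("DQ2.5-glia-α2", 1)], rng, catalogue, abundance=50
        )
        df = truth_table([tpl])
        row = df[df.epitope == "DQ2.5-glia-α2"].iloc[0]
        assert row["normalized"] == pytest.approx(row["count"] * 1e6 / row["depth"])


def test_default_barcodes_well_separated():
    from gliascan.layout import hamming

    for i, a in enumerate(DEFAULT_BARCODES):
        for b in DEFAULT_BARCODES[i + 1 :]:
            assert hamming(a, b) >= 3


def test_margin_safe_records_excludes_boundary_composites(catalogue):
    safe = {r.name for r in margin_safe_records(catalogue)}
    assert "P31-43 (var7)" not in safe  # implies a 1-mismatch window of another entry
    assert "DQ2.5-glia-α2" in safe
    assert "P31-43 (var6)" in safe  # its implied sub-occurrences are exact


def test_sample_plans_fit_capacity(catalogue, rng):
    for _ in range(50):
        plan = sample_epitope_plan(rng, catalogue)
        tpl = build_template("x", DEFAULT_BARCODES[0], plan, rng, catalogue)
        assert len(tpl.protein_core) <= 112
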