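"""Semi-log ROC construction and logAUC/aLogAUC metrics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from screeneval.enrichment import (
    DEFAULT_LAMBDA,
    InvalidParameterError,
    InvalidScreenError,
    ROCCurve,
    ScoreRecord,
    ScreenTable,
    alogauc,
    build_roc,
    classify_enrichment,
    logauc,
    random_logauc,
    read_screens,
    screen_alogauc,
    write_screens,
)

from conftest import logauc_quadrature, random_small_table, roc_threshold_sweep


def make_table(ligand_scores, decoy_scores, undocked_ligands=0, undocked_decoys=0):
    records = []
    for i, s in enumerate(ligand_scores):
        records.append(ScoreRecord(f"l{i}", True, s, True, "m"))
    for i in range(undocked_ligands):
        records.append(ScoreRecord(f"ul{i}", True, math.nan, False, "m"))
    for i, s in enumerate(decoy_scores):
        records.append(ScoreRecord(f"d{i}", False, s, True, "m"))
    for i in range(undocked_decoys):
        records.append(ScoreRecord(f"ud{i}", False, math.nan, False, "m"))
    return ScreenTable(records=records, model_id="m")


class TestBuildRoc:
    def test_perfect_separation(self):
        curve = build_roc(make_table([-10.0], [-5.0]))
        assert np.allclose(curve.points, [(0, 0), (0, 1), (1, 1)])

    def test_tie_is_single_diagonal_step(self):
        curve = build_roc(make_table([-7.0], [-7.0]))
        assert np.allclose(curve.points, [(0, 0), (1, 1)])

    def test_matches_threshold_sweep_oracle(self):
        # 2 ligands at ranks 1 and 3 among 8 decoys, all scores distinct
        table = make_table([-10.0, -8.0], [-9.0, -7.5, -7.0, -6.0, -5.0, -4.0, -3.0, -2.0])
        curve = build_roc(table)
        assert np.allclose(curve.points, roc_threshold_sweep(table))

    @pytest.mark.parametrize("seed", range(20))
    def test_random_tables_match_threshold_sweep(self, seed):
        table = random_small_table(np.random.default_rng(seed))
        assert np.allclose(build_roc(table).points, roc_threshold_sweep(table))

    def test_undocked_form_final_block(self):
        table = make_table([-10.0], [-5.0], undocked_ligands=1, undocked_decoys=2)
        curve = build_roc(table)
        assert np.allclose(curve.points[-2:], [(1 / 3, 1 / 2), (1, 1)])

    def test_empty_class_rejected(self):
        with pytest.raises(InvalidScreenError):
            ScreenTable(records=[ScoreRecord("a", True, -1.0, True, "m")])

    def test_nonfinite_docked_score_rejected(self):
        with pytest.raises(InvalidScreenError):
            make_table([math.inf], [-5.0])


class TestLogAuc:
    def test_random_diagonal_closed_form(self):
        diag = ROCCurve(np.array([[0.0, 0.0], [1.0, 1.0]]))
        lam = 0.001
        expected = 100 * (1 - lam) / math.log(1 / lam)  # 14.47
        assert logauc(diag, lam) == pytest.approx(expected, abs=1e-12)
        assert logauc(diag, lam) == pytest.approx(14.47, abs=0.01)

    @pytest.mark.parametrize("lam", [0.001, 0.01, 0.2])
    def test_perfect_screen_is_100(self, lam):
        perfect = ROCCurve(np.array([[0.0, 0.0], [0.0, 1.0], [1.0, 1.0]]))
        assert logauc(perfect, lam) == pytest.approx(100.0, abs=1e-12)

    def test_ten_compound_curve_matches_quadrature(self):
        table = make_table([-9.0, -8.0, -4.0], [-8.5, -8.0, -7.0, -6.0, -5.0, -3.0, -2.0])
        curve = build_roc(table)
        assert logauc(curve, DEFAULT_LAMBDA) == pytest.approx(
            logauc_quadrature(curve, DEFAULT_LAMBDA), abs=1e-6
        )

    def test_lambda_domain_checked(self):
        diag = ROCCurve(np.array([[0.0, 0.0], [1.0, 1.0]]))
        for bad in (0.0, 1.0, -0.1, 2.0):
            with pytest.raises(InvalidParameterError):
                logauc(diag, bad)


class TestALogAuc:
    def test_diagonal_is_zero_for_every_lambda(self):
        diag = ROCCurve(np.array([[0.0, 0.0], [1.0, 1.0]]))
        for lam in (1e-4, 0.001, 0.05, 0.5, 0.9):
            assert alogauc(diag, lam).alogauc == pytest.approx(0.0, abs=1e-12)

    def test_doubling_curve_is_about_ten(self):
        # retrieving twice the random ligand fraction everywhere ~ aLogAUC 10
        curve = ROCCurve(np.array([[0.0, 0.0], [0.5, 1.0], [1.0, 1.0]]))
        assert alogauc(curve, 0.001).alogauc == pytest.approx(10.0, abs=0.5)

    def test_perfect_screen_complement(self):
        perfect = ROCCurve(np.array([[0.0, 0.0], [0.0, 1.0], [1.0, 1.0]]))
        res = alogauc(perfect, 0.001)
        assert res.alogauc == pytest.approx(100.0 - random_logauc(0.001), abs=1e-9)
        assert res.alogauc == pytest.approx(85.53, abs=0.01)

    def test_bounds(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            res = screen_alogauc(random_small_table(rng))
            assert 0.0 <= res.logauc <= 100.0
            assert -random_logauc(DEFAULT_LAMBDA) - 1e-9 <= res.alogauc
            assert res.alogauc <= 100.0 - random_logauc(DEFAULT_LAMBDA) + 1e-9


class TestCategories:
    @pytest.mark.parametrize(
        "value,expected",
        [
            (26.6, "excellent"),
            (9.0, "poor"),
            (18.1, "good"),
            (10.0, "fair"),  # boundary: upper edges inclusive
            (15.0, "fair"),
            (20.0, "good"),
            (25.0, "very good"),
            (-5.3, "poor"),
            (9.999, "poor"),
            (25.001, "excellent"),
        ],
    )
    def test_band_lookup(self, value, expected):
        assert classify_enrichment(value) == expected


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_permutation_invariance(seed):
    """Shuffling record order changes neither the curve nor the metrics."""
    rng = np.random.default_rng(seed)
    table = random_small_table(rng)
    shuffled = list(table.records)
    rng.shuffle(shuffled)
    table2 = ScreenTable(records=shuffled, model_id="rand")
    assert np.array_equal(build_roc(table).points, build_roc(table2).points)
    assert screen_alogauc(table).alogauc == screen_alogauc(table2).alogauc


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_improving_a_ligand_rank_never_hurts(seed):
    """Lowering one ligand's score (better rank) never decreases aLogAUC."""
    rng = np.random.default_rng(seed)
    table = random_small_table(rng)
    ligs = [i for i, r in enumerate(table.records) if r.is_ligand and r.docked]
    if not ligs:
        return
    idx = int(rng.choice(ligs))
    before = screen_alogauc(table).alogauc
    rec = table.records[idx]
    improved = list(table.records)
    improved[idx] = ScoreRecord(rec.compound_id, True, rec.score - 5.0, True, "m")
    after = screen_alogauc(ScreenTable(records=improved, model_id="rand")).alogauc
    assert after >= before - 1e-9


def test_csv_round_trip(tmp_path):
    rng = np.random.default_rng(5)
    tables = []
    for i in range(2):
        base = random_small_table(rng)
        records = [
            ScoreRecord(r.compound_id, r.is_ligand, r.score, r.docked, f"m{i}")
            for r in base.records
        ]
        tables.append(ScreenTable(records=records, model_id=f"m{i}"))
    path = tmp_path / "screens.csv"
    write_screens(tables, path)
    back = read_screens(path)
    assert set(back) == {"m0", "m1"}
    for i, t in enumerate(tables):
        orig = screen_alogauc(t).alogauc
        assert screen_alogauc(back[f"m{i}"]).alogauc == pytest.approx(orig)
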