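"""Designability statistics: bimodality, consensus, cross-talk, counting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from regazyme import (
    BC_UNIFORM_THRESHOLD,
    bimodality_coefficient,
    circuit_count,
    consensus,
    crosstalk_matrix,
    orthogonality_report,
    sample_scores,
)


def bc_brute_force(x):
    """Independent moment computation from first principles."""
    x = np.asarray(x, dtype=float)
    n = x.size
    mu = x.sum() / n
    m2 = ((x - mu) ** 2).sum() / n
    m3 = ((x - mu) ** 3).sum() / n
    m4 = ((x - mu) ** 4).sum() / n
    g1 = m3 / m2**1.5
    g2 = m4 / m2**2 - 3.0
    return (g1**2 + 1.0) / (g2 + 3.0 * (n - 1) ** 2 / ((n - 2) * (n - 3)))


class TestBimodalityCoefficient:
    def test_matches_brute_force_moments(self, rng):
        for _ in range(20):
            x = rng.gamma(2.0, size=rng.integers(10, 500))
            assert bimodality_coefficient(x) == pytest.approx(bc_brute_force(x))

    def test_scale_and_location_invariance(self, rng):
        x = rng.normal(size=200)
        ref = bimodality_coefficient(x)
        for a, b in [(2.0, 0.0), (-3.0, 7.0), (0.001, -5.0)]:
            assert bimodality_coefficient(a * x + b) == pytest.approx(ref, rel=1e-9)

    def test_uniform_benchmark_is_five_ninths(self):
        rng = np.random.default_rng(0)
        bc = bimodality_coefficient(rng.uniform(size=1_000_000))
        assert bc == pytest.approx(BC_UNIFORM_THRESHOLD, abs=0.005)

    def test_small_sample_guards(self):
        with pytest.raises(ValueError):
            bimodality_coefficient([1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            bimodality_coefficient([2.0, 2.0, 2.0, 2.0])


class TestSampleScores:
    def test_row_count_and_bounds(self, layout, toy_engine):
        table = sample_scores(layout, 100, toy_engine, rng=1)
        assert len(table) == 100
        assert (table["d_apt"] <= layout.aptamer.length).all()
        assert (table["d_seed_pre"] <= layout.seed_length).all()
        assert (table["d_seed_post"] <= layout.seed_length).all()
        assert (table["total"] >= 0).all()

    def test_empty_sample(self, layout, toy_engine):
        table = sample_scores(layout, 0, toy_engine, rng=1)
        assert len(table) == 0
        assert list(table.columns)[:4] == ["transducer", "d_apt", "d_seed_pre", "d_seed_post"]

    def test_seeded_reproducibility(self, layout, toy_engine):
        a = sample_scores(layout, 30, toy_engine, rng=7)
        b = sample_scores(layout, 30, toy_engine, rng=7)
        pd.testing.assert_frame_equal(a, b)

    def test_zero_score_is_rare_but_present_in_toy_space(self, layout, toy_engine):
        """8 of 64 candidates are perfect; a large sample finds some."""
        table = sample_scores(layout, 500, toy_engine, rng=3)
        frac = (table["total"] == 0).mean()
        assert 0.02 < frac < 0.35


class TestConsensus:
    def test_anchor_registered_consensus(self):
        res = consensus(["ACCCA", "ACUCA"], "CYC")
        a0, a1 = res.anchor_span
        assert res.consensus[a0:a1] == "CYC"
        assert res.consensus == "ACYCA"

    def test_single_and_identical_sequences(self):
        assert consensus(["GGGAA"], "GGG").consensus == "GGGAA"
        assert consensus(["GCUA", "GCUA"], "GC").consensus == "GCUA"

    def test_order_invariance(self):
        seqs = ["ACCCA", "ACUCA", "GCCCU"]
        assert consensus(seqs, "CYC").consensus == consensus(seqs[::-1], "CYC").consensus

    def test_iupac_two_base_column(self):
        res = consensus(["AGG", "CGG"], "GG")
        assert res.consensus[0] == "M"  # {A,C}

    def test_missing_anchor_warned_and_excluded(self):
        with pytest.warns(UserWarning, match="lacks anchor"):
            res = consensus(["ACCCA", "AAAAA"], "CYC")
        assert res.excluded == ["AAAAA"]
        assert res.used == ["ACCCA"]
        with pytest.raises(ValueError):
            consensus(["AAAA"], "CYC")

    def test_variable_length_alignment(self):
        """Sequences of different lengths register on the anchor columns."""
        res = consensus(["UUCUCAA", "CUCA"], "CYC")
        a0, a1 = res.anchor_span
        assert res.consensus[a0:a1] == "CUC"
        assert res.conservation[a0] == 1.0


class TestCrosstalk:
    def test_matrix_shape_and_cognate_signal(self, toy_engine):
        meds = ["GGGAAA", "ACACAC"]
        tgts = ["UUUCCC", "GUGUGU"]
        m = crosstalk_matrix(meds, tgts, toy_engine)
        assert m.shape == (2, 2)
        assert (m.to_numpy() <= 0).all()
        # cognate pairs bind more strongly than swapped ones
        assert m.iat[0, 0] < m.iat[0, 1]
        assert m.iat[1, 1] < m.iat[1, 0]

    def test_empty_matrix(self, toy_engine):
        assert crosstalk_matrix([], [], toy_engine).shape == (0, 0)

    def test_orthogonality_report_flags_near_cognate(self):
        m = pd.DataFrame(
            [[-8.0, -7.5], [-1.0, -9.0]],
            index=["m0", "m1"], columns=["t0", "t1"],
        )
        rep = orthogonality_report(m, margin=2.0)
        assert len(rep) == 1
        assert rep.iloc[0]["mediator"] == "m0" and rep.iloc[0]["target"] == "t1"


class TestCircuitCount:
    @pytest.mark.parametrize("n,m,p,expected", [(1, 1, 1, 1), (3, 3, 1, 9), (3, 3, 2, 81)])
    def test_examples(self, n, m, p, expected):
        assert circuit_count(n, m, p) == expected

    def test_exact_big_integers(self):
        assert circuit_count(10, 10, 10) == 10**20

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            circuit_count(-1, 2, 2)


@given(
    st.lists(st.floats(-100, 100), min_size=5, max_size=60).filter(
        lambda xs: np.ptp(xs) > 1e-6
    )
)
@settings(deadline=None, max_examples=50, derandomize=True)
def test_bc_in_unit_interval(xs):
    """Sarle's BC lies in (0, 1] for any non-constant sample."""
    bc = bimodality_coefficient(xs)
    assert 0 < bc <= 1.0 + 1e-9
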