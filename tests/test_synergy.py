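"""Fractional activity, Bliss expectation, EoB scoring and panel ranking."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import blisscreen as bs
from blisscreen.errors import DomainError
from conftest import make_matrix_from_fa

unit = st.floats(0.0, 1.0, allow_nan=False)


@pytest.mark.parametrize("viability, fa", [
    (0.40, 0.60),   # the Fa convention: 40% viability is Fa 0.6
    (1.0, 0.0),
    (0.0, 1.0),
    (1.15, 0.0),    # growth above control clamps to zero activity
])
def test_viability_to_fa(viability, fa):
    assert bs.viability_to_fa(viability) == pytest.approx(fa, abs=1e-15)


def test_negative_viability_rejected():
    with pytest.raises(DomainError):
        bs.viability_to_fa(-0.1)


@pytest.mark.parametrize("fa_a, fa_b, expected", [
    (0.0, 0.0, 0.0),
    (1.0, 0.3, 1.0),   # a fully active drug absorbs the expectation
    (0.6, 0.2, 0.68),
])
def test_bliss_expected_values(fa_a, fa_b, expected):
    assert bs.bliss_expected(fa_a, fa_b) == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize("fa_a, fa_b, fa_c, expected", [
    (0.5, 0.5, 0.75, 0.0),    # exact Bliss independence
    (0.6, 0.2, 0.9, 22.0),
    (1.0, 0.0, 1.0, 0.0),
])
def test_excess_over_bliss_values(fa_a, fa_b, fa_c, expected):
    assert bs.excess_over_bliss(fa_a, fa_b, fa_c) == pytest.approx(expected, abs=1e-12)


def test_out_of_domain_rejected():
    with pytest.raises(DomainError):
        bs.bliss_expected(1.2, 0.5)
    with pytest.raises(DomainError):
        bs.excess_over_bliss(0.5, 0.5, -0.1)


@given(unit, unit, unit)
def test_eob_symmetric_and_bounded(a, b, c):
    e1 = bs.excess_over_bliss(a, b, c)
    e2 = bs.excess_over_bliss(b, a, c)
    assert e1 == pytest.approx(e2, abs=1e-12)
    assert -100.0 <= e1 <= 100.0


@given(unit, unit)
def test_bliss_dominates_better_monotherapy(a, b):
    assert bs.bliss_expected(a, b) >= max(a, b) - 1e-12


@given(unit, unit, unit, unit)
def test_eob_strictly_increasing_in_combo_activity(a, b, c1, c2):
    lo, hi = sorted((c1, c2))
    if hi - lo > 1e-9:
        assert bs.excess_over_bliss(a, b, hi) > bs.excess_over_bliss(a, b, lo)


class TestScoreMatrix:
    def test_matches_well_by_well_hand_computation(self):
        """score_matrix equals an independent per-well evaluation of
        (Fa12 - [(Fa1 + Fa2) - Fa1*Fa2]) * 100."""
        rng = np.random.default_rng(42)
        fa_a, fa_b = rng.uniform(0, 1, 8), rng.uniform(0, 1, 8)
        fa_c = rng.uniform(0, 1, 8)
        matrix = make_matrix_from_fa(fa_a, fa_b, fa_c)
        result = bs.score_matrix(matrix)
        hand = [
            (c - ((a + b) - a * b)) * 100.0
            for a, b, c in zip(fa_a, fa_b, fa_c)
        ]
        got = result.points.sort_values("conc_a", ascending=False)
        np.testing.assert_allclose(got["excess_over_bliss"], hand, atol=1e-12)
        assert result.max_excess == pytest.approx(max(hand), abs=1e-12)

    def test_bliss_null_construction_scores_zero(self):
        fa_a = np.array([0.2, 0.5, 0.8])
        fa_b = np.array([0.1, 0.4, 0.7])
        fa_c = fa_a + fa_b - fa_a * fa_b
        result = bs.score_matrix(make_matrix_from_fa(fa_a, fa_b, fa_c))
        np.testing.assert_allclose(result.points["excess_over_bliss"], 0.0, atol=1e-9)
        assert result.max_excess == pytest.approx(0.0, abs=1e-9)

    def test_single_boosted_well_sets_max(self):
        fa_a = np.array([0.2, 0.5, 0.8])
        fa_b = np.array([0.1, 0.4, 0.7])
        fa_c = fa_a + fa_b - fa_a * fa_b
        fa_c[1] += 0.25
        result = bs.score_matrix(make_matrix_from_fa(fa_a, fa_b, fa_c))
        assert result.max_excess == pytest.approx(25.0, abs=1e-9)

    def test_replicates_averaged_on_viability_scale(self):
        # two replicates 0.3/0.5 average to 0.4 -> Fa 0.6 before the formula
        m = make_matrix_from_fa([0.5], [0.5], [0.5], n_rep=2)
        m.wells.loc[m.wells["conc_a"] * m.wells["conc_b"] > 0, "viability"] = [0.3, 0.5]
        result = bs.score_matrix(m)
        assert result.points["fa_combo"].iloc[0] == pytest.approx(0.6)

    def test_full_matrix_uniform_delta_noise_free(self):
        pair = bs.default_pair(n_doses=7, synergy=bs.SynergySpec("uniform_delta", 10.0))
        screen, _ = bs.simulate_combination_panel(
            [pair], n_lines=1, n_rep=1, design="full", seed=0
        )
        result = bs.score_panel(screen)[0]
        assert len(result.points) == 36
        # wells where the combination Fa hit the [0,1] clamp cannot carry
        # the full injected delta; all unclamped wells must
        unclamped = result.points["fa_combo"] < 1.0 - 1e-12
        assert unclamped.sum() > 20
        np.testing.assert_allclose(
            result.points.loc[unclamped, "excess_over_bliss"], 10.0, atol=1e-9
        )

    def test_empty_matrix_errors(self, tiny_screen_df):
        mono = tiny_screen_df[tiny_screen_df["conc_b"] == 0]
        from blisscreen.io import DoseMatrix
        matrix = DoseMatrix("L1", "A", "B", mono)
        with pytest.raises(Exception):
            bs.score_matrix(matrix)


class TestMaxAndRanking:
    def test_max_matches_brute_force(self):
        rng = np.random.default_rng(7)
        fa = rng.uniform(0, 1, (3, 10))
        result = bs.score_matrix(make_matrix_from_fa(*fa))
        brute = max(
            (c - (a + b - a * b)) * 100.0 for a, b, c in zip(*fa)
        )
        assert bs.max_excess_per_line(result) == pytest.approx(brute, abs=1e-12)

    def test_argmax_tie_breaks_to_lowest_concentration(self):
        fa_a = np.array([0.2, 0.2, 0.2])
        fa_b = np.array([0.2, 0.2, 0.2])
        fa_c = fa_a + fa_b - fa_a * fa_b + 0.1  # same EoB everywhere
        result = bs.score_matrix(make_matrix_from_fa(fa_a, fa_b, fa_c))
        pts = result.points
        lowest = (pts["conc_a"] + pts["conc_b"]).min()
        assert sum(result.argmax_conc) == pytest.approx(lowest)

    def test_rank_means_and_order(self):
        def res(line, pair, maxima):
            pts = pd.DataFrame({
                "conc_a": [1.0], "conc_b": [1.0], "fa_a": [0.1], "fa_b": [0.1],
                "fa_combo": [0.5], "bliss_expected": [0.19],
                "excess_over_bliss": [maxima],
            })
            return bs.SynergyResult(line, pair[0], pair[1], pts)

        results = [
            res("L1", ("X1", "X2"), 30.0), res("L2", ("X1", "X2"), 20.0),
            res("L1", ("Y1", "Y2"), 10.0), res("L2", ("Y1", "Y2"), 10.0),
        ]
        ranking = bs.rank_combinations(results)
        top = ranking.entries.iloc[0]
        assert (top["drug_a"], top["rank"]) == ("X1", 1)
        assert top["mean_of_maxima"] == pytest.approx(25.0)
        # permuting input order must not change the ranking
        ranking2 = bs.rank_combinations(results[::-1])
        pd.testing.assert_frame_equal(ranking.entries, ranking2.entries)

    def test_partial_coverage_flagged(self):
        screen, _ = bs.simulate_combination_panel(
            [bs.default_pair("A", "B"), bs.default_pair("C", "D")],
            n_lines=2, seed=1,
        )
        results = bs.score_panel(screen)
        partial = [r for r in results if not (r.drug_a == "C" and r.cell_line == "line02")]
        ranking = bs.rank_combinations(partial)
        cd = ranking.entries.set_index("drug_a").loc["C"]
        assert not cd["full_coverage"] and cd["n_lines"] == 1

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            bs.rank_combinations([])
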