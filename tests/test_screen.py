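"""Screen statistic: GLM fits, z-scores, Stouffer combination, GFP scores."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from memoryflow.screen import (
    TransitionFit,
    combine_windows_stouffer,
    filter_abundant_strains,
    fit_transition_glm,
    gfp_score,
    memory_z,
    sign_change_filter,
)
from conftest import make_transition_counts
from oracles import irls_binomial_logit, sign_changes_bruteforce, transition_design


def _fit(strain, wt, **kw):
    return fit_transition_glm(strain, wt, ("TPa", "TPb"), **kw)


class TestTransitionGLM:
    def test_no_change_gives_zero_beta(self):
        rows = [(tp, r, 50) for tp in ("TPa", "TPb") for r in (1, 2)]
        cols = ["timepoint", "replicate", "count"]
        s = pd.DataFrame(rows, columns=cols)
        w = pd.DataFrame([(tp, r, 200) for tp in ("TPa", "TPb")
                          for r in (1, 2)], columns=cols)
        fit = _fit(s, w)
        assert fit.beta == pytest.approx(0.0, abs=1e-10)

    def test_single_replicate_closed_form_log_odds_ratio(self):
        cols = ["timepoint", "replicate", "count"]
        s = pd.DataFrame([("TPa", 1, 10), ("TPb", 1, 40)], columns=cols)
        w = pd.DataFrame([("TPa", 1, 100), ("TPb", 1, 100)], columns=cols)
        fit = _fit(s, w)
        assert fit.beta == pytest.approx(np.log(4.0), abs=1e-12)
        assert fit.df_resid == 0
        assert fit.dispersion == 1.0

    def test_matches_irls_oracle_on_random_tables(self):
        rng = np.random.default_rng(77)
        for _ in range(30):
            n_reps = int(rng.integers(2, 4))
            s, w = make_transition_counts(rng, n_reps=n_reps)
            fit = _fit(s, w)
            X = transition_design(n_reps)
            succ = s.sort_values(["replicate", "timepoint"])["count"].to_numpy(float)
            fail = w.sort_values(["replicate", "timepoint"])["count"].to_numpy(float)
            beta, se, disp, df = irls_binomial_logit(X, succ, fail)
            assert fit.beta == pytest.approx(beta[-1], abs=1e-6)
            expected_se = se[-1] * np.sqrt(max(disp, 1.0))
            assert fit.se == pytest.approx(expected_se, abs=1e-6)
            assert fit.dispersion == pytest.approx(disp, rel=1e-4, abs=1e-6)

    def test_zero_cell_replicate_dropped_with_warning(self):
        cols = ["timepoint", "replicate", "count"]
        s = pd.DataFrame([("TPa", 1, 10), ("TPb", 1, 40),
                          ("TPa", 2, 0), ("TPb", 2, 30)], columns=cols)
        w = pd.DataFrame([("TPa", 1, 100), ("TPb", 1, 100),
                          ("TPa", 2, 0), ("TPb", 2, 90)], columns=cols)
        with pytest.warns(UserWarning, match="zero strain"):
            fit = _fit(s, w)
        # only replicate 1 survives -> closed form
        assert fit.beta == pytest.approx(np.log(4.0), abs=1e-12)

    def test_complete_separation_capped_and_flagged(self):
        cols = ["timepoint", "replicate", "count"]
        s = pd.DataFrame([("TPa", 1, 0), ("TPb", 1, 40)], columns=cols)
        w = pd.DataFrame([("TPa", 1, 100), ("TPb", 1, 100)], columns=cols)
        fit = _fit(s, w)
        assert not fit.converged
        assert abs(fit.beta) <= 15.0


class TestMemoryZ:
    def test_equal_betas_give_zero(self):
        f = TransitionFit(beta=1.0, se=0.2, dispersion=1.0, df_resid=1)
        assert memory_z(f, f) == 0.0

    def test_printed_formula_value(self):
        f1 = TransitionFit(beta=1.3863, se=0.25, dispersion=1.0, df_resid=1)
        f2 = TransitionFit(beta=2.0, se=0.25, dispersion=1.0, df_resid=1)
        assert memory_z(f1, f2) == pytest.approx(-0.6137 / np.sqrt(0.5),
                                                 abs=1e-4)

    def test_quadrature_option(self):
        f1 = TransitionFit(beta=1.0, se=0.3, dispersion=1.0, df_resid=1)
        f2 = TransitionFit(beta=0.0, se=0.4, dispersion=1.0, df_resid=1)
        assert memory_z(f1, f2, se_combine="quadrature") == pytest.approx(
            1.0 / np.sqrt(0.09 + 0.16)
        )

    def test_antisymmetry_under_swap(self):
        f1 = TransitionFit(beta=0.7, se=0.2, dispersion=1.0, df_resid=1)
        f2 = TransitionFit(beta=-0.1, se=0.3, dispersion=1.0, df_resid=1)
        assert memory_z(f1, f2) == pytest.approx(-memory_z(f2, f1))

    def test_nonpositive_se_rejected(self):
        f1 = TransitionFit(beta=1.0, se=0.0, dispersion=1.0, df_resid=1)
        with pytest.raises(ValueError):
            memory_z(f1, f1)


class TestStoufferCombination:
    def test_single_window_returns_absolute_z(self):
        assert combine_windows_stouffer({"R5": -2.3}, {"R5": 42.0}) == \
            pytest.approx(2.3)

    def test_weighted_example(self):
        z = {"R5": 2.0, "R6": -1.0, "R7": 1.0}
        w = {"R5": 100.0, "R6": 100.0, "R7": 200.0}
        assert combine_windows_stouffer(z, w) == pytest.approx(
            500.0 / np.sqrt(60000.0)
        )

    def test_equal_weights_symmetric_case(self):
        z = {w: 1.0 for w in ("R5", "R6", "R7")}
        wt = {w: 5.0 for w in ("R5", "R6", "R7")}
        assert combine_windows_stouffer(z, wt) == pytest.approx(np.sqrt(3.0))

    @given(st.floats(0.1, 100.0))
    @settings(max_examples=20, deadline=None)
    def test_invariant_to_weight_rescaling(self, c):
        z = {"R5": 0.5, "R6": -1.5, "R7": 2.0, "R8": 0.1}
        w = {"R5": 10.0, "R6": 30.0, "R7": 5.0, "R8": 55.0}
        base = combine_windows_stouffer(z, w)
        scaled = combine_windows_stouffer(z, {k: c * v for k, v in w.items()})
        assert scaled == pytest.approx(base, rel=1e-9)

    def test_monotone_in_each_abs_z(self):
        w = {"R5": 10.0, "R6": 30.0, "R7": 5.0}
        z_lo = {"R5": 0.5, "R6": 1.0, "R7": 2.0}
        z_hi = {"R5": 0.5, "R6": 1.8, "R7": 2.0}
        assert combine_windows_stouffer(z_hi, w) > \
            combine_windows_stouffer(z_lo, w)

    def test_all_zero_weights_error(self):
        with pytest.raises(ValueError):
            combine_windows_stouffer({"R5": 1.0}, {"R5": 0.0})


class TestSignChangeFilter:
    @pytest.mark.parametrize(
        "z, expected",
        [
            ([1, 1, -1, -1], True),
            ([1, -1, 1, -1], False),
            ([1, 0, 1, 1], True),
            ([0, 0, 0, 0], True),
            ([-1, -1, -1, -1], True),
            ([1, -1, -1, 1], False),
        ],
    )
    def test_examples(self, z, expected):
        assert sign_change_filter(z) is expected

    def test_matches_bruteforce_on_all_sign_vectors(self):
        # exhaustive over all 3^4 sign vectors
        from itertools import product

        for signs in product((-1, 0, 1), repeat=4):
            expected = sign_changes_bruteforce(signs) <= 1
            assert sign_change_filter(list(signs)) is expected, signs


class TestAbundanceFilter:
    def _table(self, counts_by_strain):
        rows = []
        for strain, c in counts_by_strain.items():
            for tp in ("TP0", "TP1"):
                for w in ("R5", "R6"):
                    rows.append((strain, tp, w, 1, c))
        return pd.DataFrame(
            rows, columns=["strain", "timepoint", "window", "replicate",
                           "count"]
        )

    def test_exactly_five_removed_strict(self):
        t = self._table({"a": 5, "b": 6})
        kept = filter_abundant_strains(t)["strain"].unique()
        assert list(kept) == ["b"]

    def test_mean_above_threshold_kept(self):
        t = self._table({"a": 5.1})
        assert filter_abundant_strains(t)["strain"].nunique() == 1

    def test_all_zero_strain_removed(self):
        t = self._table({"a": 0, "b": 50})
        assert list(filter_abundant_strains(t)["strain"].unique()) == ["b"]


class TestGfpScore:
    def _inputs(self, masses):
        rows = [("s", "TP0", w, 1, m) for w, m in
                zip(("R5", "R6", "R7", "R8"), masses)]
        counts = pd.DataFrame(
            rows, columns=["strain", "timepoint", "window", "replicate",
                           "count"]
        )
        facs = pd.DataFrame(
            [("TP0", w, 100.0) for w in ("R5", "R6", "R7", "R8")],
            columns=["timepoint", "window", "events"],
        )
        return counts, facs

    @pytest.mark.parametrize(
        "masses, expected",
        [
            ((10, 0, 0, 0), 1.0),
            ((0, 0, 0, 10), 4.0),
            ((5, 5, 5, 5), 2.5),
            ((5, 5, 0, 0), 1.5),
        ],
    )
    def test_boundary_and_symmetric_cases(self, masses, expected):
        counts, facs = self._inputs(masses)
        score = gfp_score(counts, facs)
        assert score.loc["s", "TP0"] == pytest.approx(expected)

    def test_score_in_unit_range_and_monotone_under_mass_shift(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            masses = rng.integers(1, 50, size=4).astype(float)
            counts, facs = self._inputs(masses)
            s0 = gfp_score(counts, facs).loc["s", "TP0"]
            assert 1.0 <= s0 <= 4.0
            # move mass from R5 to R8: score must not decrease
            shifted = masses.copy()
            shifted[0] -= 1
            shifted[3] += 1
            counts2, _ = self._inputs(shifted)
            s1 = gfp_score(counts2, facs).loc["s", "TP0"]
            assert s1 >= s0 - 1e-12

    def test_zero_mass_gives_na(self):
        counts, facs = self._inputs((0, 0, 0, 0))
        assert np.isnan(gfp_score(counts, facs).loc["s", "TP0"])
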