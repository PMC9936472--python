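"""Memory classification rules, TM_score, normalization and overlap test."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from memoryflow.expression import (
    TIMEPOINTS,
    benjamini_hochberg,
    classify_base,
    classify_memory,
    eight_category_label,
    estimate_lfc,
    hypergeometric_overlap,
    mutant_effect,
    normalize_by_coding_sum,
    tm_score,
)
from oracles import bh_stepup_reference, hypergeom_upper_tail

LOG2_15 = float(np.log2(1.5))


def lfc_table(lfc_by_tp, padj=1e-5):
    rows = [
        {"gene": "g", "timepoint": tp, "lfc": v, "pvalue": padj, "padj": padj}
        for tp, v in lfc_by_tp.items()
    ]
    return pd.DataFrame(rows)


def full_traj(t30=0.0, t60=0.0, t180=0.0, t0p=0.0, t15p=0.0, t30p=0.0,
              t60p=0.0):
    return {"t30": t30, "t60": t60, "t180": t180, "t0'": t0p, "t15'": t15p,
            "t30'": t30p, "t60'": t60p}


class TestNormalization:
    def test_size_factor_ratio_follows_coding_sums(self):
        counts = pd.DataFrame(
            {"s1": [5e5, 5e5], "s2": [1e6, 1e6]},
            index=["g1", "g2"],
        )
        _, sf = normalize_by_coding_sum(counts, pd.Series(True, index=counts.index))
        assert sf["s2"] / sf["s1"] == pytest.approx(2.0)

    def test_identical_samples_give_unit_factors(self):
        counts = pd.DataFrame({"a": [10, 20], "b": [10, 20]}, index=["g", "h"])
        _, sf = normalize_by_coding_sum(counts, pd.Series(True, index=counts.index))
        assert np.allclose(sf, 1.0)

    def test_normalized_coding_sums_equal(self):
        rng = np.random.default_rng(1)
        counts = pd.DataFrame(rng.integers(1, 500, size=(50, 4)).astype(float),
                              index=[f"g{i}" for i in range(50)],
                              columns=list("abcd"))
        coding = pd.Series([i % 2 == 0 for i in range(50)], index=counts.index)
        norm, _ = normalize_by_coding_sum(counts, coding)
        sums = norm.loc[coding].sum(axis=0)
        assert np.allclose(sums, sums.iloc[0])

    def test_zero_coding_sum_names_sample(self):
        counts = pd.DataFrame({"ok": [10.0], "bad": [0.0]}, index=["g"])
        with pytest.raises(ValueError, match="bad"):
            normalize_by_coding_sum(counts, pd.Series(True, index=["g"]))


class TestEstimateLfc:
    def _run(self, mean_a, mean_b, n=3):
        counts = pd.DataFrame(
            {**{f"r{i}": [mean_b] * 2 for i in range(n)},
             **{f"t{i}": [mean_a] * 2 for i in range(n)}},
            index=["g1", "g2"], dtype=float,
        )
        info = pd.DataFrame(
            {"sample": [f"r{i}" for i in range(n)] + [f"t{i}" for i in range(n)],
             "strain": "w",
             "timepoint": ["t0"] * n + ["t30"] * n,
             "replicate": list(range(n)) * 2}
        )
        return estimate_lfc(counts, info, "t30")

    def test_identical_means_give_zero_lfc(self):
        out = self._run(100, 100)
        assert np.allclose(out["lfc"], 0.0)

    def test_pseudocount_formula(self):
        out = self._run(400, 100)
        assert out["lfc"].iloc[0] == pytest.approx(np.log2(400.5 / 100.5))

    def test_single_replicate_gives_nan_p(self):
        counts = pd.DataFrame({"a": [10.0], "b": [30.0]}, index=["g"])
        info = pd.DataFrame(
            {"sample": ["a", "b"], "strain": "w",
             "timepoint": ["t0", "t30"], "replicate": [1, 1]}
        )
        out = estimate_lfc(counts, info, "t30")
        assert np.isnan(out["pvalue"].iloc[0])
        assert np.isfinite(out["lfc"].iloc[0])

    def test_type_one_error_calibrated_on_nb_null(self):
        rng = np.random.default_rng(321)
        alpha_true, mu = 0.05, 100.0
        lam = rng.gamma(1 / alpha_true, mu * alpha_true, size=(2000, 6))
        counts = pd.DataFrame(
            rng.poisson(lam).astype(float),
            index=[f"g{i}" for i in range(2000)],
            columns=[f"s{i}" for i in range(6)],
        )
        info = pd.DataFrame(
            {"sample": [f"s{i}" for i in range(6)], "strain": "w",
             "timepoint": ["t0"] * 3 + ["t30"] * 3, "replicate": [1, 2, 3] * 2}
        )
        out = estimate_lfc(counts, info, "t30")
        rate = float((out["pvalue"] < 0.05).mean())
        assert 0.03 <= rate <= 0.08


class TestClassificationRules:
    def test_induced_example(self):
        t = lfc_table(full_traj(t30=0.5, t60=1.0, t180=2.0, t15p=1.2,
                                t30p=1.4, t60p=1.6))
        assert classify_base(t).iloc[0] == "induced"

    def test_all_zero_is_no_change(self):
        t = lfc_table(full_traj(), padj=1.0)
        assert classify_base(t).iloc[0] == "no-change"

    def test_repressed_example(self):
        t = lfc_table(full_traj(t30=-0.5, t60=-1.0, t180=-2.0, t15p=-1.2,
                                t30p=-1.4, t60p=-1.7))
        assert classify_base(t).iloc[0] == "repressed"

    def test_padj_filter_blocks_call(self):
        t = lfc_table(full_traj(t30=0.5, t60=1.0, t180=2.0, t15p=1.2,
                                t30p=1.4, t60p=1.6), padj=0.01)
        assert classify_base(t, alpha=0.001).iloc[0] == "no-change"

    @pytest.mark.parametrize("diff, expected", [
        (0.7, True),            # above log2(1.5) = 0.585
        (LOG2_15, False),       # exactly at threshold: strict inequality
        (LOG2_15 + 1e-9, True),
        (LOG2_15 - 1e-9, False),
        (0.0, False),
    ])
    def test_memory_threshold_strictness_induced(self, diff, expected):
        t = lfc_table(full_traj(t30=1.0, t60=1.5, t180=2.0, t15p=1.0,
                                t30p=1.0 + diff, t60p=1.5))
        base = classify_base(t)
        flag = classify_memory(t, base).iloc[0]
        assert bool(flag) is expected

    def test_repression_memory_mirrored(self):
        t = lfc_table(full_traj(t30=-1.0, t60=-1.5, t180=-2.0, t15p=-1.0,
                                t30p=-1.8, t60p=-1.5))
        base = classify_base(t)
        assert base.iloc[0] == "repressed"
        assert bool(classify_memory(t, base).iloc[0]) is True

    def test_memory_na_for_no_change(self):
        t = lfc_table(full_traj(), padj=1.0)
        flag = classify_memory(t, classify_base(t)).iloc[0]
        assert flag is pd.NA

    def test_ratio_monotonicity_never_adds_memory_genes(self):
        rng = np.random.default_rng(9)
        tables = []
        for i in range(50):
            vals = rng.normal(0, 1.5, size=7)
            tables.append(lfc_table(dict(zip(
                ["t30", "t60", "t180", "t0'", "t15'", "t30'", "t60'"], vals))))
        for t in tables:
            base = classify_base(t)
            lo = classify_memory(t, base, ratio=1.5).iloc[0]
            hi = classify_memory(t, base, ratio=2.5).iloc[0]
            if hi is not pd.NA and bool(hi):
                assert bool(lo)


class TestTmScoreAndMutantEffect:
    @pytest.mark.parametrize("t15p, t180, expected", [
        (0.5, 2.5, -2.0),
        (1.3, 1.3, 0.0),
        (-2.0, -3.0, 1.0),
    ])
    def test_tm_score_values(self, t15p, t180, expected):
        t = lfc_table(full_traj(t180=t180, t15p=t15p))
        assert tm_score(t).iloc[0] == pytest.approx(expected)

    @pytest.mark.parametrize("base, dtm, expected", [
        ("induced", 0.8, "enhanced"),
        ("induced", 0.58, "unchanged"),       # boundary, strict >
        ("induced", -0.8, "attenuated"),
        ("repressed", -0.7, "enhanced"),
        ("repressed", 0.7, "attenuated"),
        ("repressed", 0.58, "unchanged"),
        ("induced", 0.58 + 1e-9, "enhanced"),
        ("induced", 0.58 - 1e-9, "unchanged"),
    ])
    def test_effect_rules_and_boundaries(self, base, dtm, expected):
        assert mutant_effect(0.0, dtm, base) == expected

    def test_no_change_rejected(self):
        with pytest.raises(ValueError):
            mutant_effect(0.0, 1.0, "no-change")

    def test_delta_monotonicity(self):
        rng = np.random.default_rng(4)
        dtms = rng.normal(0, 1, size=100)
        lo = mutant_effect(pd.Series(np.zeros(100)), pd.Series(dtms),
                           pd.Series(["induced"] * 100), delta=0.58)
        hi = mutant_effect(pd.Series(np.zeros(100)), pd.Series(dtms),
                           pd.Series(["induced"] * 100), delta=1.5)
        assert ((hi != "unchanged") <= (lo != "unchanged")).all()


class TestEightCategories:
    def test_memory_gene_labels(self):
        assert eight_category_label("induced", True, "enhanced") == \
            "induction memory enhanced in mutant"
        assert eight_category_label("repressed", True, "unchanged") == \
            "repression memory unchanged in mutant"

    def test_no_memory_and_no_change(self):
        assert eight_category_label("repressed", False, None) == \
            "repressed no memory"
        assert eight_category_label("no-change", pd.NA, None) == "no-change"

    def test_inconsistent_inputs_rejected(self):
        with pytest.raises(ValueError):
            eight_category_label("induced", True, None)
        with pytest.raises(ValueError):
            eight_category_label("induced", pd.NA, "enhanced")


class TestBenjaminiHochberg:
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=40))
    @settings(max_examples=50, deadline=None)
    def test_matches_reference_stepup(self, pvals):
        ours = benjamini_hochberg(np.array(pvals))
        ref = bh_stepup_reference(pvals)
        assert np.allclose(ours, ref)


class TestHypergeometricOverlap:
    def test_exact_example(self):
        universe = set(range(10))
        a, b = set(range(5)), {0, 1, 2, 3}
        assert hypergeometric_overlap(a, b, universe) == pytest.approx(
            5 / 210, abs=1e-12
        )

    def test_zero_overlap_gives_one(self):
        assert hypergeometric_overlap({1}, {2}, {1, 2, 3}) == pytest.approx(1.0)

    def test_b_equals_universe_degenerate(self):
        u = set(range(6))
        assert hypergeometric_overlap({0, 1}, u, u) == pytest.approx(1.0)

    def test_not_subset_rejected(self):
        with pytest.raises(ValueError):
            hypergeometric_overlap({99}, {1}, {1, 2})

    def test_matches_enumeration_small_universes(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            N = int(rng.integers(4, 20))
            universe = set(range(N))
            a = set(rng.choice(N, size=rng.integers(1, N), replace=False).tolist())
            b = set(rng.choice(N, size=rng.integers(1, N), replace=False).tolist())
            ours = hypergeometric_overlap(a, b, universe)
            ref = hypergeom_upper_tail(N, len(a), len(b), len(a & b))
            assert ours == pytest.approx(ref, abs=1e-12)
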