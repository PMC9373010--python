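"""ICC, group tests, ROC/Youden, DeLong and the logistic screen against
independent oracles (exhaustive enumeration, pingouin, sklearn, R's pROC)."""

import itertools
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from splquant.diagnostic_stats import (
    compare_groups,
    delong_test,
    icc_category,
    icc_two_reader,
    logistic_screen,
    roc_analysis,
)

rng0 = np.random.default_rng  # shorthand


# ---------------------------------------------------------------------------
# ICC
# ---------------------------------------------------------------------------

class TestICC:
    def test_duplicated_readers_give_exactly_one(self):
        x = np.array([1.0, 2.5, 3.1, 4.0, 0.2])
        res = icc_two_reader(x, x)
        assert res.icc == pytest.approx(1.0, abs=1e-12)
        assert res.category == "excellent"

    def test_systematic_offset_is_penalised_by_absolute_agreement(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = icc_two_reader(x, x + 10.0)
        assert res.icc < 1.0
        # consistency form ignores the offset entirely
        res_c = icc_two_reader(x, x + 10.0, model="consistency")
        assert res_c.icc == pytest.approx(1.0, abs=1e-12)

    def test_shared_constant_shift_leaves_icc_unchanged(self):
        rng = rng0(5)
        x, y = rng.normal(0, 1, 30), rng.normal(0, 1, 30)
        a = icc_two_reader(x, y).icc
        b = icc_two_reader(x + 7.3, y + 7.3).icc
        assert a == pytest.approx(b, abs=1e-12)

    def test_matches_pingouin_icc2_on_random_data(self):
        pingouin = pytest.importorskip("pingouin")
        rng = rng0(17)
        subj = rng.normal(0, 1, 40)
        x = subj + rng.normal(0, 0.3, 40)
        y = subj + 0.2 + rng.normal(0, 0.3, 40)
        mine = icc_two_reader(x, y).icc
        long = pd.DataFrame(
            {
                "subject": np.tile(np.arange(40), 2),
                "rater": np.repeat(["r1", "r2"], 40),
                "score": np.concatenate([x, y]),
            }
        )
        ref = pingouin.intraclass_corr(
            long, targets="subject", raters="rater", ratings="score"
        )
        # pingouin names two-way random absolute-agreement single as ICC(A,1)
        mask = ref["Type"].isin(["ICC2", "ICC(A,1)"])
        icc2 = float(ref.loc[mask, "ICC"].iloc[0])
        assert mine == pytest.approx(icc2, abs=1e-10)

    def test_dominant_reader_noise_lands_in_poor(self):
        rng = rng0(23)
        subj = rng.normal(0, 0.1, 200)  # between-subject SD << reader SD
        x = subj + rng.normal(0, 1.0, 200)
        y = subj + rng.normal(0, 1.0, 200)
        assert icc_two_reader(x, y).category == "poor"

    @pytest.mark.parametrize(
        "icc, cat",
        [(0.75, "excellent"), (0.749, "good"), (0.60, "good"),
         (0.599, "fair"), (0.40, "fair"), (0.399, "poor"), (-0.2, "poor")],
    )
    def test_category_thresholds(self, icc, cat):
        assert icc_category(icc) == cat

    def test_too_few_pairs_or_zero_variance_raise(self):
        with pytest.raises(ValueError):
            icc_two_reader([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            icc_two_reader([3.0, 3.0, 3.0], [3.0, 3.0, 3.0])


# ---------------------------------------------------------------------------
# Group comparison
# ---------------------------------------------------------------------------

def exact_mwu_two_sided(a, b):
    """Oracle: enumerate all label assignments of the pooled sample and get
    the exact two-sided Mann-Whitney p (no ties assumed)."""
    pooled = np.concatenate([a, b])
    n_a = len(a)

    def u_stat(idx_a):
        xa = pooled[list(idx_a)]
        xb = np.delete(pooled, list(idx_a))
        return sum((x > y) + 0.5 * (x == y) for x in xa for y in xb)

    u_obs = u_stat(range(n_a))
    us = [u_stat(c) for c in itertools.combinations(range(len(pooled)), n_a)]
    us = np.array(us)
    p_low = np.mean(us <= u_obs)
    p_high = np.mean(us >= u_obs)
    return min(1.0, 2.0 * min(p_low, p_high))


class TestCompareGroups:
    def test_forced_u_branch_small_sample_exact(self):
        """A=(1,2) vs B=(3,4): 2 of the 6 equally likely rank splits are as
        extreme, so the exact two-sided p is 1/3."""
        res = compare_groups(
            [1, 2, 3, 4], ["A", "A", "B", "B"], force_test="mann_whitney_u"
        )
        assert res.test_used == "mann_whitney_u"
        assert res.p_two_sided == pytest.approx(1 / 3, rel=1e-12)

    def test_mwu_p_matches_exhaustive_enumeration(self):
        rng = rng0(31)
        for _ in range(8):
            n_a, n_b = rng.integers(3, 8, 2)
            pooled = rng.permutation(np.arange(1.0, n_a + n_b + 1))  # distinct
            a, b = pooled[:n_a], pooled[n_a:]
            res = compare_groups(
                np.concatenate([a, b]),
                ["A"] * n_a + ["B"] * n_b,
                force_test="mann_whitney_u",
            )
            assert res.p_two_sided == pytest.approx(exact_mwu_two_sided(a, b), rel=1e-9)

    def test_identical_groups_give_p_one(self):
        vals = [1.0, 2.0, 3.0, 4.0, 5.0] * 2
        labels = ["A"] * 5 + ["B"] * 5
        res = compare_groups(vals, labels)
        assert res.p_two_sided == pytest.approx(1.0, abs=1e-9)

    def test_separated_gaussians_reject(self):
        rng = rng0(2)
        vals = np.concatenate([rng.normal(0, 1, 50), rng.normal(5, 1, 50)])
        res = compare_groups(vals, ["A"] * 50 + ["B"] * 50)
        assert res.p_two_sided < 1e-3

    def test_normality_gate_routes_skewed_data_to_u(self):
        rng = rng0(8)
        a = rng.lognormal(0, 1.5, 60)  # clearly non-normal
        b = rng.lognormal(0.5, 1.5, 60)
        res = compare_groups(np.concatenate([a, b]), ["A"] * 60 + ["B"] * 60)
        assert res.test_used == "mann_whitney_u"
        normal = np.concatenate([rng.normal(0, 1, 60), rng.normal(0.2, 1, 60)])
        res2 = compare_groups(normal, ["A"] * 60 + ["B"] * 60)
        assert res2.test_used == "student_t"

    def test_errors(self):
        with pytest.raises(ValueError):
            compare_groups([1, 2, 3], ["A", "A", "A"])
        with pytest.raises(ValueError):
            compare_groups([1.0, 1.0, 1.0, 1.0], ["A", "A", "B", "B"])


# ---------------------------------------------------------------------------
# ROC / Youden
# ---------------------------------------------------------------------------

def auc_pair_counting(scores, y):
    """Oracle: explicit concordant-pair counting with ties worth 1/2."""
    pos = [s for s, l in zip(scores, y) if l == 1]
    neg = [s for s, l in zip(scores, y) if l == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestROC:
    def test_small_example(self):
        res = roc_analysis([1, 3, 2, 4], [0, 0, 1, 1])
        assert res.auc == pytest.approx(0.75)

    def test_perfect_separation(self):
        res = roc_analysis([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert res.auc == 1.0
        assert res.youden == pytest.approx(1.0)
        assert res.sensitivity == 1.0 and res.specificity == 1.0

    def test_auc_equals_exhaustive_pair_counting(self):
        rng = rng0(77)
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        for trial in range(30):
            n = int(rng.integers(4, 13))
            scores = np.round(rng.normal(0, 1, n), 1)  # rounding induces ties
            y = rng.integers(0, 2, n)
            if y.min() == y.max():
                y[0] = 1 - y[0]
            res = roc_analysis(scores, y)
            oracle = auc_pair_counting(scores, y)
            oriented = max(oracle, 1 - oracle)
            assert res.auc == pytest.approx(oriented, abs=1e-12)
            # second independent route for the unoriented value
            skl = sklearn_metrics.roc_auc_score(y, scores)
            assert oracle == pytest.approx(skl, abs=1e-12)

    def test_direction_flip_symmetry(self):
        rng = rng0(4)
        s = rng.normal(0, 1, 60)
        y = (rng.random(60) < 0.4).astype(int)
        d = delong_test(s, -s, y)
        assert d.auc_a == pytest.approx(1.0 - d.auc_b, abs=1e-12)
        a, b = roc_analysis(s, y), roc_analysis(-s, y)
        assert a.auc == pytest.approx(b.auc, abs=1e-12)
        assert a.direction != b.direction

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_youden_and_auc_invariant_under_monotone_transform(self, seed):
        rng = rng0(seed)
        s = rng.normal(0, 1, 40)
        y = np.r_[np.ones(15, int), np.zeros(25, int)]
        a = roc_analysis(s, y)
        b = roc_analysis(np.exp(s), y)  # strictly increasing transform
        assert a.auc == pytest.approx(b.auc, abs=1e-12)
        assert a.youden == pytest.approx(b.youden, abs=1e-12)
        assert b.cutoff == pytest.approx(np.exp(a.cutoff), rel=1e-12)

    def test_youden_identity_holds_at_reported_cutoff(self):
        rng = rng0(6)
        s = rng.normal(0, 1, 200) + np.r_[np.zeros(120), np.ones(80)]
        y = np.r_[np.zeros(120, int), np.ones(80, int)]
        res = roc_analysis(s, y)
        assert res.youden == pytest.approx(res.sensitivity + res.specificity - 1.0)

    def test_youden_tie_broken_toward_higher_specificity(self):
        # cutoffs 2 and 4 both give Youden 0.5; spec 0.5 vs 1.0
        res = roc_analysis([1, 2, 3, 4], [0, 1, 0, 1])
        assert res.cutoff == 4.0
        assert res.specificity == 1.0 and res.sensitivity == 0.5

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            roc_analysis([1, 2, 3], [1, 1, 1])


# ---------------------------------------------------------------------------
# DeLong
# ---------------------------------------------------------------------------

class TestDeLong:
    def test_identical_markers_degenerate_p_one(self):
        rng = rng0(12)
        s = rng.normal(0, 1, 50)
        y = np.r_[np.ones(20, int), np.zeros(30, int)]
        d = delong_test(s, s, y)
        assert d.p == 1.0 and d.degenerate
        assert d.auc_diff == 0.0

    def test_monotone_transform_gives_zero_difference(self):
        rng = rng0(13)
        s = rng.normal(0, 1, 50)
        y = np.r_[np.ones(25, int), np.zeros(25, int)]
        d = delong_test(s, 2.0 * s + 5.0, y)
        assert d.auc_diff == pytest.approx(0.0, abs=1e-12)

    def test_informative_vs_noise_marker_detected(self):
        rng = rng0(14)
        y = np.r_[np.ones(250, int), np.zeros(250, int)]
        informative = y + rng.normal(0, 0.7, 500)
        noise = rng.normal(0, 1, 500)
        d = delong_test(informative, noise, y)
        assert d.p < 0.01

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not available")
    def test_matches_pROC_delong(self, tmp_path):
        """Independent oracle: pROC's paired DeLong test on the same data."""
        rng = rng0(15)
        y = np.r_[np.ones(20, int), np.zeros(20, int)]
        a = y + rng.normal(0, 1.0, 40)
        b = 0.5 * y + rng.normal(0, 1.0, 40)
        csv = tmp_path / "d.csv"
        pd.DataFrame({"y": y, "a": a, "b": b}).to_csv(csv, index=False)
        script = (
            "suppressMessages(library(pROC));"
            f"d <- read.csv('{csv}');"
            "ra <- roc(d$y, d$a, direction='<', quiet=TRUE);"
            "rb <- roc(d$y, d$b, direction='<', quiet=TRUE);"
            "t <- roc.test(ra, rb, method='delong', paired=TRUE);"
            "cat(format(t$p.value, digits=15), format(as.numeric(auc(ra)), digits=15),"
            "    format(as.numeric(auc(rb)), digits=15), sep='\\n')"
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, timeout=120
        )
        assert out.returncode == 0, out.stderr
        p_ref, auc_a_ref, auc_b_ref = (float(x) for x in out.stdout.split())
        d = delong_test(a, b, y)
        assert d.auc_a == pytest.approx(auc_a_ref, abs=1e-10)
        assert d.auc_b == pytest.approx(auc_b_ref, abs=1e-10)
        assert d.p == pytest.approx(p_ref, rel=1e-6)


# ---------------------------------------------------------------------------
# Logistic screen
# ---------------------------------------------------------------------------

def simulate_logit(rng, n, beta0=-1.0, beta1=2.0):
    x = rng.normal(0, 1, n)
    p = 1.0 / (1.0 + np.exp(-(beta0 + beta1 * x)))
    y = (rng.random(n) < p).astype(int)
    return pd.DataFrame({"x": x, "y": y})


class TestLogisticScreen:
    def test_null_covariate_or_near_one(self):
        rng = rng0(21)
        df = pd.DataFrame(
            {"x": rng.normal(0, 1, 10_000), "y": rng.integers(0, 2, 10_000)}
        )
        res = logistic_screen(df, "y", ["x"])
        row = res.univariate.loc["x"]
        assert row["or"] == pytest.approx(1.0, abs=0.1)
        assert row["ci_low"] <= 1.0 <= row["ci_high"]

    def test_parameter_recovery(self):
        """Data simulated from logit(p) = -1 + 2x: the fitted slope is within
        5% of beta = 2 at n = 10^4."""
        df = simulate_logit(rng0(22), 10_000)
        res = logistic_screen(df, "y", ["x"])
        assert res.selected == ["x"]
        assert np.log(res.multivariate.loc["x", "or"]) == pytest.approx(2.0, rel=0.05)
        # single selected candidate: multivariate == univariate
        assert res.multivariate.loc["x", "or"] == pytest.approx(
            res.univariate.loc["x", "or"], rel=1e-8
        )
        assert res.combined_score is not None
        assert np.all((res.combined_score >= 0) & (res.combined_score <= 1))

    def test_perfect_separation_flagged_and_excluded(self):
        x = np.r_[np.zeros(20), np.ones(20)]
        y = x.astype(int)
        rng = rng0(25)
        df = pd.DataFrame({"sep": x, "noise": rng.normal(0, 1, 40), "y": y})
        res = logistic_screen(df, "y", ["sep", "noise"])
        assert "sep" in res.separation_flags
        assert "sep" not in res.selected

    def test_wald_ci_coverage_near_nominal(self):
        """95% Wald CI for the slope covers the truth in [0.93, 0.97] of 500
        simulations at n = 500."""
        rng = rng0(26)
        hits = 0
        for _ in range(500):
            df = simulate_logit(rng, 500)
            res = logistic_screen(df, "y", ["x"])
            row = res.univariate.loc["x"]
            if row["ci_low"] <= np.exp(2.0) <= row["ci_high"]:
                hits += 1
        assert 0.93 <= hits / 500 <= 0.97

    def test_missing_column_raises(self):
        with pytest.raises(ValueError):
            logistic_screen(pd.DataFrame({"y": [0, 1]}), "y", ["absent"])
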