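"""Correlation primitives against independent brute-force oracles."""

import itertools
import math
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import special, stats

from rbclink import (
    InsufficientDataError,
    ZeroVarianceError,
    detect_outliers,
    pearson,
    shapiro_wilk,
    spearman,
    two_way_anova,
)

# ---------------------------------------------------------------- oracles


def pearson_oracle(x, y):
    """Direct covariance-formula r and incomplete-beta p (independent path)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    r = sxy / math.sqrt(sxx * syy)
    df = n - 2
    if abs(r) >= 1:
        return r, 0.0
    # P(|T| > t) for T ~ t_df expressed through the regularized beta function
    p = special.betainc(df / 2.0, 0.5, df / (df + df * r * r / (1 - r * r)))
    return r, p


def ranks_oracle(x):
    """Average ranks by explicit sorting (ties -> mean rank)."""
    x = list(x)
    order = sorted(range(len(x)), key=lambda i: x[i])
    ranks = [0.0] * len(x)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and x[order[j + 1]] == x[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def spearman_exact_oracle(x, y):
    """rho and exact p by literal enumeration with itertools (n <= 7)."""
    rx, ry = ranks_oracle(x), ranks_oracle(y)
    r_obs, _ = pearson_oracle(rx, ry)
    count = total = 0
    for perm in itertools.permutations(ry):
        r_perm, _ = pearson_oracle(rx, perm)
        total += 1
        if abs(r_perm) >= abs(r_obs) - 1e-12:
            count += 1
    return r_obs, count / total


# ---------------------------------------------------------------- pearson


class TestPearson:
    @pytest.mark.parametrize(
        "x,y,expected_r",
        [
            ([1, 2, 3, 4, 5], [2, 4, 6, 8, 10], 1.0),
            ([1, 2, 3], [3, 2, 1], -1.0),
            ([1, 2, 3, 4], [1, 3, 2, 4], 0.8),
        ],
    )
    def test_hand_examples(self, x, y, expected_r):
        r, p, n = pearson(x, y)
        assert r == pytest.approx(expected_r, abs=1e-12)
        assert n == len(x)

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(200):
            n = int(rng.integers(4, 13))
            x = rng.standard_normal(n)
            y = rng.standard_normal(n)
            r, p, _ = pearson(x, y)
            r0, p0 = pearson_oracle(x, y)
            assert r == pytest.approx(r0, abs=1e-12)
            assert p == pytest.approx(p0, abs=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(ZeroVarianceError, match="undefined correlation"):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_too_few_points_rejected(self):
        with pytest.raises(InsufficientDataError):
            pearson([1.0, 2.0], [2.0, 1.0])


# ---------------------------------------------------------------- spearman


class TestSpearman:
    def test_monotone_transform_gives_unit_rho(self):
        x = [0.3, 1.2, -0.5, 2.2, 0.9]
        y = [math.exp(v) for v in x]
        r, p, _ = spearman(x, y)
        assert r == pytest.approx(1.0)

    def test_ties_use_average_ranks(self):
        # ranks of x are (1, 2.5, 2.5, 4)
        x, y = [1, 2, 2, 3], [1, 2, 3, 4]
        r, _, _ = spearman(x, y)
        r0, _ = pearson_oracle([1, 2.5, 2.5, 4], [1, 2, 3, 4])
        assert r == pytest.approx(r0, abs=1e-12)

    def test_exact_p_perfect_concordance_n6(self):
        """Only 2 of the 720 rank permutations reach |rho| = 1."""
        _, p, _ = spearman(range(6), range(6))
        assert p == pytest.approx(2 / 720, abs=0)

    def test_exact_p_matches_enumeration_with_ties(self, rng):
        for _ in range(10):
            n = int(rng.integers(4, 7))
            x = rng.integers(0, 4, n).astype(float)
            y = rng.integers(0, 4, n).astype(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            r, p, _ = spearman(x, y)
            r0, p0 = spearman_exact_oracle(x, y)
            assert r == pytest.approx(r0, abs=1e-12)
            assert p == pytest.approx(p0, abs=1e-12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        data=st.lists(
            st.integers(min_value=-500, max_value=500), min_size=5, max_size=20,
            unique=True,
        ),
        scale=st.floats(min_value=0.1, max_value=5.0),
    )
    def test_invariant_under_strictly_monotone_transform(self, data, scale):
        x = np.asarray(data) / 10.0
        y = np.sin(x / 100.0) + x  # strictly increasing on the domain
        r1, p1, _ = spearman(x, y)
        r2, p2, _ = spearman(np.exp(scale * x / 50.0), y)
        assert r1 == pytest.approx(r2, abs=1e-9)
        assert p1 == pytest.approx(p2, abs=1e-9)


# ---------------------------------------------------------------- outliers


class TestDetectOutliers:
    def test_single_extreme_point_flagged(self):
        values = [0.0] * 9 + [1.0]
        # mean = .1, sd = sqrt(.9*.01+.81*.1... ) -- oracle arithmetic:
        mean = sum(values) / 10
        sd = math.sqrt(sum((v - mean) ** 2 for v in values) / 9)
        assert abs(1.0 - mean) > 2 * sd
        assert detect_outliers(values) == [9]

    def test_constant_series_has_no_outliers(self):
        assert detect_outliers([5.0, 5.0, 5.0, 5.0]) == []

    def test_values_within_one_sd_never_flagged(self, rng):
        x = rng.uniform(-1, 1, 30)
        x = (x - x.mean()) / x.std(ddof=1)  # all within ~1 sd after clipping
        x = np.clip(x, -1, 1)
        assert detect_outliers(x) == []


# ---------------------------------------------------------------- shapiro


class TestShapiroWilk:
    def test_normal_quantiles_look_normal(self):
        q = stats.norm.ppf((np.arange(1, 11) - 0.5) / 10)
        res = shapiro_wilk(q)
        assert res.W > 0.95
        assert res.p > 0.05

    def test_spike_fails_normality(self):
        assert shapiro_wilk([1, 1, 1, 1, 10]).p < 0.05

    def test_constant_rejected(self):
        with pytest.raises(ZeroVarianceError, match="zero variance"):
            shapiro_wilk([2.0, 2.0, 2.0])

    def test_too_small_rejected(self):
        with pytest.raises(InsufficientDataError):
            shapiro_wilk([1.0, 2.0])

    def test_agrees_with_r_reference(self, tmp_path):
        """Cross-language oracle: R's shapiro.test on a fixed series."""
        if shutil.which("Rscript") is None:
            pytest.fail("Rscript not available for the reference check")
        x = [0.12, 1.4, -0.8, 2.1, 0.33, -1.7, 0.9, -0.25, 0.6, -1.1, 0.05, 1.9]
        script = tmp_path / "shap.R"
        script.write_text(
            "x <- c(%s)\ns <- shapiro.test(x)\n"
            'cat(sprintf("%%.8f %%.8f", s$statistic, s$p.value))\n'
            % ", ".join(map(str, x))
        )
        out = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, check=True
        ).stdout.split()
        w_ref, p_ref = float(out[0]), float(out[1])
        res = shapiro_wilk(x)
        assert res.W == pytest.approx(w_ref, abs=1e-6)
        assert res.p == pytest.approx(p_ref, abs=1e-6)


# ---------------------------------------------------------------- anova


def _balanced_frame(rng, effect=0.0):
    rows = []
    for g in ("deficient", "sufficient"):
        for t in ("D7", "D14", "D21"):
            for _ in range(4):
                mu = effect if g == "deficient" else 0.0
                rows.append({"group": g, "timepoint": t,
                             "value": mu + rng.standard_normal()})
    return pd.DataFrame(rows)


class TestTwoWayAnova:
    def test_ss_decomposition_exact_on_balanced_data(self, rng):
        for _ in range(5):
            row = two_way_anova(_balanced_frame(rng), "v")
            total = row.ss_group + row.ss_time + row.ss_interaction + row.ss_error
            assert total == pytest.approx(row.ss_total, rel=1e-9)

    def test_matches_statsmodels_type_i_on_balanced_data(self, rng):
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        df = _balanced_frame(rng, effect=0.8)
        row = two_way_anova(df, "v")
        fit = smf.ols("value ~ C(group)*C(timepoint)", data=df).fit()
        tab = anova_lm(fit, typ=1)
        assert row.F_group == pytest.approx(tab.loc["C(group)", "F"], rel=1e-9)
        assert row.F_time == pytest.approx(tab.loc["C(timepoint)", "F"], rel=1e-9)
        assert row.F_interaction == pytest.approx(
            tab.loc["C(group):C(timepoint)", "F"], rel=1e-9
        )
        assert row.p_group == pytest.approx(tab.loc["C(group)", "PR(>F)"], rel=1e-9)

    def test_planted_group_offset_detected(self, rng):
        row = two_way_anova(_balanced_frame(rng, effect=5.0), "v")
        assert row.p_group < 0.01
        assert row.sig_group

    def test_null_f_behaves_like_f_distribution(self):
        rng = np.random.default_rng(99)
        ps = [two_way_anova(_balanced_frame(rng), "v").p_group for _ in range(300)]
        frac = np.mean([p < 0.05 for p in ps])
        assert 0.01 <= frac <= 0.12  # ~binomial(300, .05)

    def test_unbalanced_cells_use_cell_mean_weighting(self, rng):
        df = _balanced_frame(rng).drop(index=[0, 1]).reset_index(drop=True)
        row = two_way_anova(df, "v")
        assert not row.balanced
        assert 0 < row.p_group <= 1 and np.isfinite(row.F_group)

    def test_empty_cell_named_in_error(self, rng):
        df = _balanced_frame(rng)
        df = df[~((df["group"] == "deficient") & (df["timepoint"] == "D14"))]
        with pytest.raises(ValueError, match="deficient.*D14"):
            two_way_anova(df, "v")

    def test_single_level_factor_rejected(self, rng):
        df = _balanced_frame(rng)
        with pytest.raises(ValueError, match="2 levels"):
            two_way_anova(df[df["group"] == "deficient"], "v")
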