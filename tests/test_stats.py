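"""Mixed ANOVA, Greenhouse-Geisser correction, Duncan test, KS screen."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from neurosw.errors import IncompleteDesignError, InvalidSpecError
from neurosw.stats import (
    duncan_multiple_range,
    duncan_posthoc,
    greenhouse_geisser_epsilon,
    ks_normality,
    mixed_anova,
    report,
)


def make_sw(Y, groups, band_names=None):
    """Wide (subjects x bands) matrix -> tidy SW table."""
    n, k = Y.shape
    band_names = band_names or [f"b{i}" for i in range(k)]
    rows = []
    for s in range(n):
        for b in range(k):
            rows.append(
                {
                    "subject": f"s{s:02d}",
                    "group": groups[s],
                    "band": band_names[b],
                    "SW": Y[s, b],
                }
            )
    return pd.DataFrame(rows)


def random_design(rng, n_per_group=13, k=7, effect=0.0):
    n = 2 * n_per_group
    Y = rng.standard_normal((n, k)) + rng.standard_normal((n, 1))  # subject effect
    Y[:n_per_group, 1] += effect
    groups = ["PD"] * n_per_group + ["Nold"] * n_per_group
    return Y, groups


def anova_projection_oracle(Y, groups):
    """Brute-force sums of squares via nested least-squares model fits."""
    n, k = Y.shape
    y = Y.ravel()
    subj = np.repeat(np.arange(n), k)
    band = np.tile(np.arange(k), n)
    grp = np.repeat([0 if g == groups[0] else 1 for g in groups], k)

    def dummies(idx, levels):
        return np.eye(levels)[idx]

    blocks = {
        "mu": np.ones((len(y), 1)),
        "G": dummies(grp, 2),
        "S": dummies(subj, n),
        "B": dummies(band, k),
        "GB": dummies(grp * k + band, 2 * k),
    }

    def rss(names):
        X = np.hstack([blocks[nm] for nm in names])
        res = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
        return res @ res

    seq = [["mu"], ["mu", "G"], ["mu", "G", "S"], ["mu", "G", "S", "B"],
           ["mu", "G", "S", "B", "GB"]]
    rsss = [rss(s) for s in seq]
    ss = {
        "Group": rsss[0] - rsss[1],
        "Subj": rsss[1] - rsss[2],
        "Band": rsss[2] - rsss[3],
        "GxB": rsss[3] - rsss[4],
        "Resid": rsss[4],
    }
    F_group = (ss["Group"] / 1) / (ss["Subj"] / (n - 2))
    F_band = (ss["Band"] / (k - 1)) / (ss["Resid"] / ((n - 2) * (k - 1)))
    F_gxb = (ss["GxB"] / (k - 1)) / (ss["Resid"] / ((n - 2) * (k - 1)))
    return ss, F_group, F_band, F_gxb


class TestMixedAnova:
    def test_study_scale_degrees_of_freedom(self, rng):
        Y, groups = random_design(rng)
        res = mixed_anova(make_sw(Y, groups))
        assert (res["Group"].df_num, res["Group"].df_den) == (1, 24)
        assert (res["Band"].df_num, res["Band"].df_den) == (6, 144)
        assert (res["Group x Band"].df_num, res["Group x Band"].df_den) == (6, 144)

    def test_matches_projection_oracle_on_toy_designs(self, rng):
        for _ in range(20):
            Y = rng.standard_normal((4, 3))
            groups = ["A", "A", "B", "B"]
            res = mixed_anova(make_sw(Y, groups))
            _, F_g, F_b, F_gxb = anova_projection_oracle(Y, groups)
            assert res["Group"].F == pytest.approx(F_g, abs=1e-9)
            assert res["Band"].F == pytest.approx(F_b, abs=1e-9)
            assert res["Group x Band"].F == pytest.approx(F_gxb, abs=1e-9)

    def test_unequal_group_sizes_supported(self, rng):
        Y = rng.standard_normal((7, 4))
        groups = ["A"] * 3 + ["B"] * 4
        res = mixed_anova(make_sw(Y, groups))
        ss, F_g, F_b, F_gxb = anova_projection_oracle(Y, groups)
        assert res["Group x Band"].F == pytest.approx(F_gxb, abs=1e-9)

    def test_agrees_with_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        Y, groups = random_design(rng, n_per_group=8, effect=0.5)
        sw = make_sw(Y, groups)
        res = mixed_anova(sw)
        ref = pg.mixed_anova(
            data=sw, dv="SW", within="band", subject="subject", between="group",
            correction=True,
        ).set_index("Source")
        assert res["Group"].F == pytest.approx(ref.loc["group", "F"], rel=1e-9)
        assert res["Group x Band"].F == pytest.approx(
            ref.loc["Interaction", "F"], rel=1e-9
        )
        assert res["Band"].p_uncorrected == pytest.approx(
            ref.loc["band", "p_unc"], rel=1e-9
        )

    def test_missing_cell_raises(self, rng):
        Y, groups = random_design(rng, n_per_group=3, k=4)
        sw = make_sw(Y, groups).iloc[:-1]
        with pytest.raises(IncompleteDesignError):
            mixed_anova(sw)

    def test_single_subject_per_group_rejected(self, rng):
        Y = rng.standard_normal((2, 3))
        with pytest.raises(IncompleteDesignError):
            mixed_anova(make_sw(Y, ["A", "B"]))

    def test_constant_data_flagged_not_crashed(self):
        Y = np.ones((6, 3))
        with pytest.warns(UserWarning, match="zero error mean square"):
            res = mixed_anova(make_sw(Y, ["A"] * 3 + ["B"] * 3))
        assert np.isnan(res["Group x Band"].F)


class TestGreenhouseGeisser:
    def test_compound_symmetry_drives_epsilon_to_one(self, rng):
        # exchangeable covariance satisfies sphericity -> epsilon = 1
        n, k = 200, 7
        subj = rng.standard_normal((n, 1))
        Y = subj + rng.standard_normal((n, k))
        groups = np.array(["A"] * 100 + ["B"] * 100)
        eps = greenhouse_geisser_epsilon(Y, groups)
        assert eps == pytest.approx(1.0, abs=0.05)

    def test_rank_one_covariance_hits_the_floor(self, rng):
        n, k = 40, 7
        shared = rng.standard_normal((n, 1))
        Y = shared * np.linspace(1, 2, k)  # rank-1 band covariance
        eps = greenhouse_geisser_epsilon(Y, np.array(["A"] * 20 + ["B"] * 20))
        assert eps == pytest.approx(1.0 / 6.0, abs=1e-9)

    def test_agrees_with_pingouin_epsilon(self, rng):
        pg = pytest.importorskip("pingouin")
        Y = rng.standard_normal((30, 5)) @ rng.standard_normal((5, 5))
        groups = np.array(["A"] * 30)
        eps = greenhouse_geisser_epsilon(Y, groups)
        ref = pg.epsilon(pd.DataFrame(Y), correction="gg")
        assert eps == pytest.approx(ref, abs=1e-9)

    def test_epsilon_one_means_no_correction(self, rng):
        Y, groups = random_design(rng, n_per_group=6, k=4)
        res = mixed_anova(make_sw(Y, groups))
        rep = res["Group x Band"]
        expected = sps.f.sf(rep.F, res.gg_epsilon * rep.df_num,
                            res.gg_epsilon * rep.df_den)
        assert rep.p_gg == pytest.approx(expected, rel=1e-12)
        if res.gg_epsilon == 1.0:
            assert rep.p_gg == pytest.approx(rep.p_uncorrected, rel=1e-12)


class TestDuncan:
    def test_identical_group_means_not_significant(self, rng):
        half = rng.standard_normal((6, 7))
        Y = np.vstack([half, half])  # group B mirrors group A exactly
        groups = ["PD"] * 6 + ["Nold"] * 6
        sw = make_sw(Y, groups)
        d = duncan_posthoc(sw, mixed_anova(sw))
        assert (d["difference"] == 0).all()
        assert not d["significant"].any()

    def test_two_group_duncan_equals_pooled_t_decision(self, rng):
        # with p = 2 the critical range is sqrt(2) t_{1-alpha/2} sqrt(MS/n):
        # decisions must coincide with an unpaired t-test using the same MS
        n, df, alpha = 9, 32.0, 0.05
        t_crit = sps.t.ppf(1 - alpha / 2, df)
        for _ in range(1000):
            m = rng.standard_normal(2)
            ms = rng.random() * 0.4 + 0.05
            sig = duncan_multiple_range(
                m, np.array([n, n]), ms, df, alpha=alpha
            )[0, 1]
            t_stat = abs(m[0] - m[1]) / np.sqrt(2 * ms / n)
            assert sig == (t_stat > t_crit)

    def test_three_group_protection_logic(self):
        # far-apart outer means, inner pair equal: outer comparisons fire,
        # the inner pair does not
        means = np.array([0.0, 0.01, 3.0])
        sig = duncan_multiple_range(means, np.array([10, 10, 10]), 0.1, 27.0)
        assert sig[0, 2] and sig[1, 2]
        assert not sig[0, 1]

    def test_posthoc_table_layout(self, rng):
        Y, groups = random_design(rng, effect=2.0)
        sw = make_sw(Y, groups, band_names=list("abcdefg"))
        res = mixed_anova(sw)
        d = duncan_posthoc(sw, res)
        assert len(d) == 7
        assert {"mean_PD", "mean_Nold", "difference", "critical_range",
                "p", "significant"} <= set(d.columns)
        # the planted effect sits in the second band
        assert bool(d.loc[d["band"] == "b", "significant"].iloc[0])

    def test_error_stratum_option(self, rng):
        Y, groups = random_design(rng)
        sw = make_sw(Y, groups)
        res = mixed_anova(sw)
        d_int = duncan_posthoc(sw, res, error_stratum="interaction")
        d_pb = duncan_posthoc(sw, res, error_stratum="per_band")
        assert not d_int["critical_range"].equals(d_pb["critical_range"])
        with pytest.raises(InvalidSpecError):
            duncan_posthoc(sw, res, error_stratum="nope")

    def test_group_label_swap_flips_difference_sign(self, rng):
        Y, groups = random_design(rng, effect=1.0)
        sw = make_sw(Y, groups)
        res = mixed_anova(sw)
        d = duncan_posthoc(sw, res)
        swapped = sw.assign(
            group=sw["group"].map({"PD": "Nold", "Nold": "PD"})
        )
        d_sw = duncan_posthoc(swapped, mixed_anova(swapped))
        np.testing.assert_allclose(
            d_sw["difference"].to_numpy(), -d["difference"].to_numpy(), atol=1e-12
        )


class TestNormalityScreen:
    def test_gaussian_cells_mostly_pass(self, rng):
        # Monte-Carlo size of the Lilliefors screen at the study's cell size
        passes = 0
        cells = 0
        for _ in range(100):
            Y, groups = random_design(rng)
            table, _ = ks_normality(make_sw(Y, groups))
            passes += (~table["reject"]).sum()
            cells += len(table)
        assert passes / cells >= 0.90

    def test_constant_cell_flagged_degenerate(self, rng):
        Y, groups = random_design(rng, n_per_group=4, k=3)
        Y[:4, 0] = 2.5
        table, _ = ks_normality(make_sw(Y, groups))
        row = table[(table.group == "PD") & (table.band == "b0")].iloc[0]
        assert bool(row["degenerate"])

    def test_heavy_tails_detected(self, rng):
        x = sps.t.rvs(1, size=(200, 1), random_state=np.random.RandomState(0))
        rejections = 0
        for seed in range(20):
            x = sps.t.rvs(1, size=200, random_state=np.random.RandomState(seed))
            sw = pd.DataFrame(
                {"subject": range(200), "group": "A", "band": "b0", "SW": x}
            )
            table, _ = ks_normality(sw)
            rejections += int(table["reject"].iloc[0])
        assert rejections / 20 > 0.5

    def test_tiny_cell_rejected(self):
        sw = pd.DataFrame(
            {"subject": ["a", "b"], "group": "A", "band": "b0", "SW": [1.0, 2.0]}
        )
        with pytest.raises(IncompleteDesignError):
            ks_normality(sw)


class TestReport:
    def test_summary_means_match_table_means(self, rng):
        Y, groups = random_design(rng, n_per_group=5)
        sw = make_sw(Y, groups, band_names=list("abcdefg"))
        res = mixed_anova(sw)
        d = duncan_posthoc(sw, res)
        summary, fig = report(sw, res, d)
        for band in "abcdefg":
            expected = sw[(sw.group == "PD") & (sw.band == band)]["SW"].mean()
            assert summary.loc[("PD", "mean"), band] == pytest.approx(
                expected, abs=1e-12
            )
        import matplotlib.pyplot as plt

        plt.close(fig)

    def test_single_subject_group_blank_se(self, rng):
        Y = rng.standard_normal((3, 7))
        sw = make_sw(Y, ["PD", "Nold", "Nold"])
        from neurosw.graph import group_band_summary

        with pytest.warns(UserWarning, match="SE undefined"):
            summary = group_band_summary(sw)
        assert summary.loc[("PD", "SE")].isna().all()
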