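"""Group x Band statistics on the small-world table.

The design is a split-plot (mixed) ANOVA: Group (2 levels, between
subjects) crossed with Band (7 levels, within subjects).  The
between-subject stratum tests Group against subjects-within-group; the
within-subject stratum tests Band and Group x Band against the
Band x subjects-within-group residual.  For 13+13 subjects and 7 bands
the interaction has (6, 144) degrees of freedom.  Within-subject
p-values are additionally corrected by the Greenhouse-Geisser sphericity
factor estimated from the pooled within-group band covariance.

The per-band group comparison uses Duncan's multiple range test: means
are ordered and a span of p means is declared different when it exceeds
``q(1 - alpha_p, p, df_err) * sqrt(MS_err / n_h)`` with protection level
``alpha_p = 1 - (1 - alpha)^(p-1)`` and harmonic mean group size
``n_h``.  With two groups this reduces to a protected LSD, but the
general stepwise machinery is implemented so the module extends to more
groups.  By default the error term is a per-band independent-samples
pooled variance; the within-subject interaction residual is available
as a sensitivity option (see ``duncan_posthoc`` for why it is not the
default).

Normality screening per Group x Band cell uses the Kolmogorov-Smirnov
test in its Lilliefors form (parameters estimated from the data; the
plain KS null would be anti-conservative).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors

from .bands import BAND_NAMES
from .errors import IncompleteDesignError, InvalidSpecError

__all__ = [
    "AnovaReport",
    "MixedAnovaResult",
    "ks_normality",
    "mixed_anova",
    "greenhouse_geisser_epsilon",
    "duncan_posthoc",
    "duncan_multiple_range",
    "report",
]

_SS_DECOMP_TOL = 1e-9


@dataclass(frozen=True)
class AnovaReport:
    """One effect line of the mixed ANOVA."""

    effect: str
    F: float
    df_num: float
    df_den: float
    p_uncorrected: float
    ms_error: float
    gg_epsilon: float | None = None
    p_gg: float | None = None

    def to_dict(self) -> dict:
        return {
            "effect": self.effect,
            "F": self.F,
            "df_num": self.df_num,
            "df_den": self.df_den,
            "p_uncorrected": self.p_uncorrected,
            "ms_error": self.ms_error,
            "gg_epsilon": self.gg_epsilon,
            "p_gg": self.p_gg,
        }


@dataclass
class MixedAnovaResult:
    """All three effects plus the error strata needed by post-hoc tests."""

    reports: dict[str, AnovaReport]
    gg_epsilon: float
    ms_error_within: float
    df_error_within: float
    ms_error_between: float
    df_error_between: float
    group_sizes: dict[str, int] = field(default_factory=dict)

    def __getitem__(self, effect: str) -> AnovaReport:
        return self.reports[effect]


def _pivot(
    sw: pd.DataFrame, dv: str
) -> tuple[np.ndarray, np.ndarray, list[str], list[str]]:
    """Wide subjects x bands matrix, group labels, group order, band order."""
    piv = sw.pivot_table(index=["group", "subject"], columns="band", values=dv)
    bands = [b for b in BAND_NAMES if b in piv.columns]
    bands += [b for b in piv.columns if b not in BAND_NAMES]
    piv = piv[bands]
    if piv.isna().any().any():
        missing = piv[piv.isna().any(axis=1)].index.get_level_values("subject")
        raise IncompleteDesignError(
            f"missing cells for subject(s) {sorted(set(missing))}; "
            "the repeated-measures design must be complete"
        )
    groups = piv.index.get_level_values("group").to_numpy()
    order = list(dict.fromkeys(groups))
    return piv.to_numpy(dtype=float), groups, order, bands


def greenhouse_geisser_epsilon(Y: np.ndarray, groups: np.ndarray) -> float:
    """Greenhouse-Geisser sphericity factor from pooled within-group covariance.

    ``eps = tr(S*)^2 / ((k-1) tr(S*^2))`` with ``S*`` the double-centered
    pooled covariance; lies in ``[1/(k-1), 1]``, reaching 1 under
    sphericity and the floor for a rank-one band covariance.
    """
    k = Y.shape[1]
    labels = np.unique(groups)
    pooled = np.zeros((k, k))
    dof = 0
    for g in labels:
        Yg = Y[groups == g]
        if len(Yg) >= 2:
            pooled += (len(Yg) - 1) * np.cov(Yg, rowvar=False)
            dof += len(Yg) - 1
    if dof < 1:
        raise InvalidSpecError("need n >= 2 in at least one group to estimate epsilon")
    pooled /= dof
    H = np.eye(k) - np.full((k, k), 1.0 / k)
    S = H @ pooled @ H
    tr2 = np.trace(S) ** 2
    denom = (k - 1) * np.trace(S @ S)
    if denom <= 0 or not np.isfinite(tr2 / denom):
        warnings.warn(
            "singular band covariance; flooring epsilon at 1/(k-1)", stacklevel=2
        )
        return 1.0 / (k - 1)
    eps = tr2 / denom
    return float(min(1.0, max(eps, 1.0 / (k - 1))))


def mixed_anova(sw: pd.DataFrame, dv: str = "SW") -> MixedAnovaResult:
    """Split-plot ANOVA of ``dv`` with Group between and Band within.

    The sum-of-squares decomposition
    ``SS_total = SS_Group + SS_subj(Group) + SS_Band + SS_GxB + SS_resid``
    is verified to 1e-9 (relative) on every call.  Degenerate inputs
    (zero error mean square) yield NaN F with a warning rather than a
    crash.
    """
    Y, groups, order, _bands = _pivot(sw, dv)
    N, k = Y.shape
    labels = order
    G = len(labels)
    if G < 2:
        raise InvalidSpecError("mixed ANOVA needs at least two groups")
    if N < G + 1:
        raise IncompleteDesignError("need at least 2 subjects in some group")

    grand = Y.mean()
    subj_means = Y.mean(axis=1)
    band_means = Y.mean(axis=0)
    n_g = np.array([(groups == g).sum() for g in labels], dtype=float)
    group_means = np.array([subj_means[groups == g].mean() for g in labels])
    cell_means = np.vstack([Y[groups == g].mean(axis=0) for g in labels])

    ss_total = ((Y - grand) ** 2).sum()
    ss_between_subj = k * ((subj_means - grand) ** 2).sum()
    ss_group = k * (n_g * (group_means - grand) ** 2).sum()
    ss_subj = ss_between_subj - ss_group
    ss_band = N * ((band_means - grand) ** 2).sum()
    ss_gxb = (
        n_g[:, None]
        * (cell_means - group_means[:, None] - band_means[None, :] + grand) ** 2
    ).sum()
    ss_within_subj = ((Y - subj_means[:, None]) ** 2).sum()
    ss_resid = ss_within_subj - ss_band - ss_gxb

    decomp = ss_group + ss_subj + ss_band + ss_gxb + ss_resid
    if abs(decomp - ss_total) > _SS_DECOMP_TOL * max(1.0, ss_total):
        raise AssertionError(
            f"sum-of-squares decomposition violated: {decomp} vs {ss_total}"
        )

    df_group, df_subj = G - 1.0, N - G
    df_band = k - 1.0
    df_gxb = (G - 1.0) * (k - 1.0)
    df_resid = (N - G) * (k - 1.0)

    ms_subj = ss_subj / df_subj
    ms_resid = ss_resid / df_resid

    def f_and_p(ss, df_num, ms_err, df_den):
        if ms_err <= 0:
            warnings.warn("zero error mean square; F undefined", stacklevel=3)
            return float("nan"), float("nan")
        F = (ss / df_num) / ms_err
        return F, float(sps.f.sf(F, df_num, df_den))

    eps = greenhouse_geisser_epsilon(Y, groups)

    F_g, p_g = f_and_p(ss_group, df_group, ms_subj, df_subj)
    F_b, p_b = f_and_p(ss_band, df_band, ms_resid, df_resid)
    F_i, p_i = f_and_p(ss_gxb, df_gxb, ms_resid, df_resid)

    def gg_p(F, df_num, df_den):
        if not np.isfinite(F):
            return float("nan")
        return float(sps.f.sf(F, eps * df_num, eps * df_den))

    reports = {
        "Group": AnovaReport("Group", F_g, df_group, df_subj, p_g, ms_subj),
        "Band": AnovaReport(
            "Band", F_b, df_band, df_resid, p_b, ms_resid, eps, gg_p(F_b, df_band, df_resid)
        ),
        "Group x Band": AnovaReport(
            "Group x Band",
            F_i,
            df_gxb,
            df_resid,
            p_i,
            ms_resid,
            eps,
            gg_p(F_i, df_gxb, df_resid),
        ),
    }
    return MixedAnovaResult(
        reports=reports,
        gg_epsilon=eps,
        ms_error_within=ms_resid,
        df_error_within=df_resid,
        ms_error_between=ms_subj,
        df_error_between=df_subj,
        group_sizes={g: int((groups == g).sum()) for g in labels},
    )


@lru_cache(maxsize=512)
def _q_crit(alpha_p: float, p: int, df: float) -> float:
    return float(sps.studentized_range.ppf(1.0 - alpha_p, p, df))


def _q_sf(q: float, p: int, df: float) -> float:
    """Studentized-range survival function; exact two-mean shortcut.

    For p = 2 the range of two means satisfies
    ``P(Q > q) = 2 P(t_df > q / sqrt(2))``, which avoids the numerical
    integration of the general distribution.
    """
    if p == 2:
        return float(2.0 * sps.t.sf(q / np.sqrt(2.0), df))
    return float(sps.studentized_range.sf(q, p, df))


def duncan_multiple_range(
    means: np.ndarray,
    n_per_group: np.ndarray,
    ms_error: float,
    df_error: float,
    alpha: float = 0.05,
) -> np.ndarray:
    """Duncan's stepwise multiple range test on a set of means.

    Returns a boolean matrix ``sig[i, j]`` of pairwise decisions.  A
    span of ``p`` ordered means is significant when its range exceeds
    ``q(1-alpha_p, p, df) * sqrt(MS / n_h)``; once a span is declared
    non-significant, all sub-spans inside it are protected (declared
    non-significant without testing).
    """
    means = np.asarray(means, dtype=float)
    n_per_group = np.asarray(n_per_group, dtype=float)
    m = len(means)
    if df_error < 1:
        raise InvalidSpecError("error degrees of freedom must be >= 1")
    order = np.argsort(means)
    sig = np.zeros((m, m), dtype=bool)
    blocked = np.zeros((m, m), dtype=bool)  # protected spans (in sorted coords)
    for span in range(m, 1, -1):
        alpha_p = 1.0 - (1.0 - alpha) ** (span - 1)
        for start in range(0, m - span + 1):
            end = start + span - 1
            if blocked[start, end]:
                continue
            idx = order[start : end + 1]
            n_h = len(idx) / (1.0 / n_per_group[idx]).sum()
            crit = _q_crit(round(alpha_p, 10), span, round(float(df_error), 6)) * np.sqrt(
                ms_error / n_h
            )
            lo_i, hi_i = order[start], order[end]
            if means[hi_i] - means[lo_i] > crit:
                sig[lo_i, hi_i] = sig[hi_i, lo_i] = True
            else:
                # protect every sub-span
                for a in range(start, end + 1):
                    for b in range(a, end + 1):
                        blocked[a, b] = True
    return sig


def duncan_posthoc(
    sw: pd.DataFrame,
    anova: MixedAnovaResult,
    alpha: float = 0.05,
    dv: str = "SW",
    error_stratum: str = "per_band",
) -> pd.DataFrame:
    """Per-band Duncan comparison of the two group means.

    ``error_stratum="per_band"`` (default) pools an independent-samples
    variance within each band; ``"interaction"`` uses the ANOVA's
    within-subject residual mean square.  The per-band stratum is the
    calibrated default: the cross-band normalization induces negative
    correlation between a subject's band values, which makes the
    interaction residual overstate the variance of a per-band group
    contrast (empirically a conservative test).
    """
    if error_stratum not in ("interaction", "per_band"):
        raise InvalidSpecError(f"unknown error_stratum {error_stratum!r}")
    Y, groups, order, piv_bands = _pivot(sw, dv)
    # report PD first when the canonical group labels are present
    order = [g for g in ("PD", "Nold") if g in order] + [
        g for g in order if g not in ("PD", "Nold")
    ]
    if len(order) != 2:
        raise InvalidSpecError(
            "the tabular report compares exactly two groups; "
            "use duncan_multiple_range directly for more"
        )
    rows = []
    for bi, band in enumerate(piv_bands):
        cells = [Y[groups == g, bi] for g in order]
        means = np.array([c.mean() for c in cells])
        ns = np.array([len(c) for c in cells], dtype=float)
        if error_stratum == "interaction":
            ms, df = anova.ms_error_within, anova.df_error_within
        else:
            sse = sum(((c - c.mean()) ** 2).sum() for c in cells)
            df = sum(len(c) - 1 for c in cells)
            ms = sse / df if df > 0 else float("nan")
        sig = duncan_multiple_range(means, ns, ms, df, alpha)
        n_h = len(ns) / (1.0 / ns).sum()
        crit = _q_crit(round(alpha, 10), 2, round(float(df), 6)) * np.sqrt(ms / n_h)
        q_obs = abs(means[0] - means[1]) / np.sqrt(ms / n_h)
        rows.append(
            {
                "band": band,
                f"mean_{order[0]}": means[0],
                f"mean_{order[1]}": means[1],
                "difference": means[0] - means[1],
                "critical_range": crit,
                "p": _q_sf(q_obs, 2, df),
                "significant": bool(sig[0, 1]),
            }
        )
    return pd.DataFrame(rows)


def ks_normality(
    sw: pd.DataFrame, dv: str = "SW", alpha: float = 0.05
) -> tuple[pd.DataFrame, bool]:
    """Lilliefors-corrected KS normality screen per Group x Band cell.

    Degenerate (zero-variance) cells are flagged rather than crashed.
    Returns the per-cell table and an overall pass flag (no
    non-degenerate cell rejected at ``alpha``).
    """
    rows = []
    for (group, band), cell in sw.groupby(["group", "band"]):
        x = cell[dv].to_numpy(dtype=float)
        if len(x) < 4:
            raise IncompleteDesignError(
                f"cell ({group}, {band}) has {len(x)} < 4 observations; "
                "the normality screen needs at least 4 per cell"
            )
        if np.std(x) < 1e-12 * max(1.0, abs(np.mean(x))):
            rows.append(
                {"group": group, "band": band, "ks_stat": np.nan, "p": np.nan,
                 "degenerate": True, "reject": False}
            )
            continue
        stat, p = lilliefors(x, dist="norm", pvalmethod="table")
        rows.append(
            {"group": group, "band": band, "ks_stat": float(stat), "p": float(p),
             "degenerate": False, "reject": bool(p < alpha)}
        )
    table = pd.DataFrame(rows)
    overall_pass = not table["reject"].any()
    return table, overall_pass


def report(
    sw: pd.DataFrame,
    anova: MixedAnovaResult,
    duncan: pd.DataFrame,
    out_dir: str | Path | None = None,
    dv: str = "SW",
):
    """Summary table (group x band means/SEs with significance flags)
    and a band-profile figure of group means ± SE.

    Returns ``(table, figure)``; when ``out_dir`` is given, also writes
    ``table1.csv`` and ``figure_sw.png``.
    """
    from .graph import group_band_summary

    summary = group_band_summary(sw, value=dv)
    flags = duncan.set_index("band")["significant"]
    flag_row = pd.DataFrame(
        [[bool(flags.get(b, False)) for b in summary.columns]],
        index=pd.MultiIndex.from_tuples([("", "significant")], names=summary.index.names),
        columns=summary.columns,
        dtype=object,
    )
    summary = pd.concat([summary, flag_row])

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    bands = [b for b in BAND_NAMES if b in summary.columns]
    xs = np.arange(len(bands))
    for group in sorted({g for g, s in summary.index if g}):
        mean = summary.loc[(group, "mean"), bands].astype(float)
        se = summary.loc[(group, "SE"), bands].astype(float)
        ax.errorbar(xs, mean, yerr=se, marker="o", capsize=3, label=group)
    for i, b in enumerate(bands):
        if flags.get(b, False):
            ax.annotate("*", (i, ax.get_ylim()[1]), ha="center", fontsize=14)
    ax.set_xticks(xs, bands)
    ax.set_ylabel(dv)
    ax.set_xlabel("band")
    ax.legend()
    fig.tight_layout()

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        summary.to_csv(out_dir / "table1.csv")
        fig.savefig(out_dir / "figure_sw.png", dpi=120)
    return summary, fig
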