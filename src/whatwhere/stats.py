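"""Inferential layer: ANOVAs with partial eta squared, Holm post-hocs,
Pearson correlations and covariate residualization.

The two ANOVA engines are sums-of-squares decompositions specialised to the
task's balanced 2 x 2 within-subject design (set size x delay), optionally
crossed with a between-subject group factor.  Both report partial eta
squared, ``SS_effect / (SS_effect + SS_error)``, per effect.  All within
effects have a single numerator degree of freedom, so no sphericity
correction is needed.

Conventions: t-tests are pooled-variance (Student) two-sided by default with
Welch available via a flag; correlation p-values are two-sided; Holm
correction is applied per measure across the pairwise group contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AnovaResult",
    "TTestResult",
    "CorrelationResult",
    "ResidualizedVolume",
    "rm_anova_2x2",
    "mixed_anova",
    "holm_adjust",
    "pearson_corr",
    "independent_ttest",
    "pairwise_group_ttests",
    "residualize_volume",
    "anova_table",
]


@dataclass(frozen=True)
class AnovaResult:
    effect: str
    F: float
    df_num: int
    df_den: int
    p: float
    partial_eta_sq: float
    ss_effect: float
    ss_error: float

    def __post_init__(self) -> None:
        if self.F < 0 or not 0.0 <= self.partial_eta_sq <= 1.0:
            raise ValueError("invalid ANOVA result")


@dataclass(frozen=True)
class TTestResult:
    comparison: str
    t: float
    df: float
    p_raw: float
    p_holm: Optional[float] = None

    def __post_init__(self) -> None:
        if self.p_holm is not None and self.p_holm < self.p_raw - 1e-12:
            raise ValueError("Holm-adjusted p cannot be below the raw p")


@dataclass(frozen=True)
class CorrelationResult:
    pair: str
    r: float
    df: int
    p: float
    n: int

    def __post_init__(self) -> None:
        if abs(self.r) > 1 + 1e-12:
            raise ValueError("|r| must be <= 1")
        if self.df != self.n - 2:
            raise ValueError("df must equal n - 2")


@dataclass(frozen=True)
class ResidualizedVolume:
    """Regional volume with age and TIV regressed out (grand mean added back)."""

    region: str
    raw: np.ndarray
    corrected: np.ndarray


def _ratio(ss_eff: float, df_eff: int, ss_err: float, df_err: int) -> tuple[float, float, float]:
    """(F, p, partial eta squared) with the zero-variance edge cases pinned."""
    if ss_eff <= 0.0:
        return 0.0, 1.0, 0.0
    if ss_err <= 0.0:
        return float("inf"), 0.0, 1.0
    f = (ss_eff / df_eff) / (ss_err / df_err)
    p = float(sps.f.sf(f, df_eff, df_err))
    return float(f), p, float(ss_eff / (ss_eff + ss_err))


def _pivot_within(
    data: pd.DataFrame, dv: str, subject: str, within: tuple[str, str]
) -> tuple[np.ndarray, pd.Index]:
    """(N, a, b) cell array for the balanced 2 x 2 within design."""
    a_name, b_name = within
    for col in (dv, subject, a_name, b_name):
        if col not in data.columns:
            raise ValueError(f"column {col!r} missing from the data")
    wide = data.pivot_table(
        index=subject, columns=[a_name, b_name], values=dv, aggfunc="mean",
        observed=True,
    )
    if wide.isna().any().any():
        bad = wide.index[wide.isna().any(axis=1)].tolist()
        raise ValueError(f"missing within-subject cells for participants: {bad}")
    a_levels = sorted({lv for lv, _ in wide.columns})
    b_levels = sorted({lv for _, lv in wide.columns})
    if len(a_levels) != 2 or len(b_levels) != 2:
        raise ValueError("the within design must have 2 x 2 cells")
    y = np.empty((len(wide), 2, 2))
    for i, al in enumerate(a_levels):
        for j, bl in enumerate(b_levels):
            y[:, i, j] = wide[(al, bl)].to_numpy(dtype=float)
    return y, wide.index


def rm_anova_2x2(
    data: pd.DataFrame,
    dv: str,
    subject: str = "participant_id",
    within: tuple[str, str] = ("set_size", "delay_s"),
) -> list[AnovaResult]:
    """Repeated-measures ANOVA for one group on the 2 x 2 within design.

    Each effect (both main effects and their interaction) is tested against
    its own effect-by-subject error term with degrees of freedom (1, N - 1).
    Requires a complete cell for every participant.
    """
    y, index = _pivot_within(data, dv, subject, within)
    n = y.shape[0]
    if n < 3:
        raise ValueError("need at least 3 participants")
    gm = y.mean()
    s_mean = y.mean(axis=(1, 2))          # per-subject
    a_mean = y.mean(axis=(0, 2))          # factor A level means
    b_mean = y.mean(axis=(0, 1))
    sa = y.mean(axis=2)                   # (N, 2)
    sb = y.mean(axis=1)
    cell = y.mean(axis=0)                 # (2, 2)

    ss_a = 2 * n * ((a_mean - gm) ** 2).sum()
    ss_axs = 2 * ((sa - s_mean[:, None] - a_mean[None, :] + gm) ** 2).sum()
    ss_b = 2 * n * ((b_mean - gm) ** 2).sum()
    ss_bxs = 2 * ((sb - s_mean[:, None] - b_mean[None, :] + gm) ** 2).sum()
    ss_ab = n * ((cell - a_mean[:, None] - b_mean[None, :] + gm) ** 2).sum()
    resid = (
        y
        - sa[:, :, None] - sb[:, None, :] - cell[None, :, :]
        + s_mean[:, None, None] + a_mean[None, :, None] + b_mean[None, None, :]
        - gm
    )
    ss_abxs = (resid**2).sum()

    out = []
    for name, ss_eff, ss_err in (
        (within[0], ss_a, ss_axs),
        (within[1], ss_b, ss_bxs),
        (f"{within[0]}*{within[1]}", ss_ab, ss_abxs),
    ):
        f, p, eta = _ratio(ss_eff, 1, ss_err, n - 1)
        out.append(AnovaResult(name, f, 1, n - 1, p, eta, ss_eff, ss_err))
    return out


def mixed_anova(
    data: pd.DataFrame,
    dv: str,
    subject: str = "participant_id",
    between: str = "group",
    within: tuple[str, str] = ("set_size", "delay_s"),
) -> list[AnovaResult]:
    """Mixed ANOVA: k groups x (2 x 2 within design).

    The group effect is tested against subjects-within-groups with degrees of
    freedom (k - 1, N - k); each within effect (and its interaction with
    group) against the corresponding effect-by-subjects-within-groups term
    with denominator df N - k.
    """
    y, index = _pivot_within(data, dv, subject, within)
    groups = (
        data.drop_duplicates(subject).set_index(subject)[between].reindex(index)
    )
    if groups.isna().any():
        raise ValueError("every participant needs a group label")
    labels = sorted(groups.unique())
    k = len(labels)
    if k < 2:
        raise ValueError("need at least 2 groups")
    n = y.shape[0]
    if n <= k:
        raise ValueError("need more participants than groups")
    gidx = np.array([labels.index(g) for g in groups])
    n_g = np.bincount(gidx, minlength=k).astype(float)

    gm = y.mean(axis=(1, 2)).mean()       # unweighted over subjects
    s_mean = y.mean(axis=(1, 2))
    sa = y.mean(axis=2)
    sb = y.mean(axis=1)

    def by_group(arr: np.ndarray) -> np.ndarray:
        """Group means of a per-subject array (subjects on axis 0)."""
        sums = np.zeros((k,) + arr.shape[1:])
        np.add.at(sums, gidx, arr)
        return sums / n_g.reshape((k,) + (1,) * (arr.ndim - 1))

    g_mean = by_group(s_mean)             # (k,)
    ga = by_group(sa)                     # (k, 2)
    gb = by_group(sb)
    gab = by_group(y)                     # (k, 2, 2)
    a_mean = y.mean(axis=(0, 2))
    b_mean = y.mean(axis=(0, 1))
    ab = y.mean(axis=0)

    c = 4  # cells per subject
    ss_group = c * (n_g * (g_mean - gm) ** 2).sum()
    ss_sub = c * ((s_mean - g_mean[gidx]) ** 2).sum()

    ss_a = 2 * n * ((a_mean - gm) ** 2).sum()
    ss_axg = 2 * (
        n_g[:, None] * (ga - g_mean[:, None] - a_mean[None, :] + gm) ** 2
    ).sum()
    ss_axs = 2 * ((sa - s_mean[:, None] - ga[gidx] + g_mean[gidx, None]) ** 2).sum()

    ss_b = 2 * n * ((b_mean - gm) ** 2).sum()
    ss_bxg = 2 * (
        n_g[:, None] * (gb - g_mean[:, None] - b_mean[None, :] + gm) ** 2
    ).sum()
    ss_bxs = 2 * ((sb - s_mean[:, None] - gb[gidx] + g_mean[gidx, None]) ** 2).sum()

    ss_ab = n * ((ab - a_mean[:, None] - b_mean[None, :] + gm) ** 2).sum()
    ss_abxg = (
        n_g[:, None, None]
        * (
            gab
            - ga[:, :, None] - gb[:, None, :] - ab[None, :, :]
            + g_mean[:, None, None] + a_mean[None, :, None] + b_mean[None, None, :]
            - gm
        ) ** 2
    ).sum()
    resid = (
        y
        - sa[:, :, None] - sb[:, None, :] - gab[gidx]
        + s_mean[:, None, None] + ga[gidx, :, None] + gb[gidx, None, :]
        - g_mean[gidx, None, None]
    )
    ss_abxs = (resid**2).sum()

    a_name, b_name = within
    df_err = n - k
    out = []
    for name, ss_eff, df_num, ss_err in (
        (between, ss_group, k - 1, ss_sub),
        (a_name, ss_a, 1, ss_axs),
        (f"{a_name}*{between}", ss_axg, k - 1, ss_axs),
        (b_name, ss_b, 1, ss_bxs),
        (f"{b_name}*{between}", ss_bxg, k - 1, ss_bxs),
        (f"{a_name}*{b_name}", ss_ab, 1, ss_abxs),
        (f"{a_name}*{b_name}*{between}", ss_abxg, k - 1, ss_abxs),
    ):
        f, p, eta = _ratio(ss_eff, df_num, ss_err, df_err)
        out.append(AnovaResult(name, f, df_num, df_err, p, eta, ss_eff, ss_err))
    return out


def holm_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Holm step-down adjusted p-values, in the input order.

    Sort ascending, multiply the i-th smallest by (m - i + 1), enforce a
    monotone non-decreasing sequence and cap at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


def pearson_corr(
    x: Sequence[float], y: Sequence[float], pair: str = ""
) -> CorrelationResult:
    """Pearson correlation with a two-sided p from the t distribution."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and of equal length")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("x and y must be finite")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    r, p = sps.pearsonr(x, y)
    return CorrelationResult(pair=pair, r=float(r), df=n - 2, p=float(p), n=n)


def independent_ttest(
    group_a: Sequence[float],
    group_b: Sequence[float],
    comparison: str = "",
    welch: bool = False,
) -> TTestResult:
    """Two-sided independent-samples t-test (pooled variance by default)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if not welch and a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        raise ValueError("zero pooled variance: t undefined")
    res = sps.ttest_ind(a, b, equal_var=not welch)
    df = float(res.df) if welch else float(a.size + b.size - 2)
    return TTestResult(comparison=comparison, t=float(res.statistic), df=df,
                       p_raw=float(res.pvalue))


def pairwise_group_ttests(
    values_by_group: dict[str, Sequence[float]],
    measure: str = "",
    welch: bool = False,
) -> list[TTestResult]:
    """All pairwise group contrasts with Holm correction across the family.

    The family is the set of pairwise contrasts for this one measure (three
    contrasts for three groups).
    """
    labels = list(values_by_group)
    results = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            name = f"{measure + ': ' if measure else ''}{labels[i]} vs {labels[j]}"
            results.append(
                independent_ttest(values_by_group[labels[i]],
                                  values_by_group[labels[j]],
                                  comparison=name, welch=welch)
            )
    adj = holm_adjust([r.p_raw for r in results])
    return [
        TTestResult(r.comparison, r.t, r.df, r.p_raw, p_holm=float(ph))
        for r, ph in zip(results, adj)
    ]


def residualize_volume(
    volume: Sequence[float],
    age: Sequence[float],
    tiv: Sequence[float],
    region: str = "",
) -> ResidualizedVolume:
    """Regress a regional volume on age and TIV; return residual + grand mean.

    Constant covariates are dropped (with both constant, the data are
    returned unchanged); genuinely collinear covariates raise.
    """
    v = np.asarray(volume, dtype=float)
    a = np.asarray(age, dtype=float)
    t = np.asarray(tiv, dtype=float)
    if not (v.shape == a.shape == t.shape) or v.ndim != 1:
        raise ValueError("volume, age and tiv must be 1-D and aligned")
    if v.size < 4:
        raise ValueError("need at least 4 observations")
    if not (np.isfinite(v).all() and np.isfinite(a).all() and np.isfinite(t).all()):
        raise ValueError("inputs must be finite")

    covs = [c for c in (a, t) if np.ptp(c) > 0]
    if not covs:
        return ResidualizedVolume(region=region, raw=v, corrected=v.copy())
    x = np.column_stack([np.ones_like(v)] + covs)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("age and TIV are collinear: residualization undefined")
    beta, *_ = np.linalg.lstsq(x, v, rcond=None)
    resid = v - x @ beta
    return ResidualizedVolume(region=region, raw=v, corrected=resid + v.mean())


def anova_table(results: Sequence[AnovaResult]) -> pd.DataFrame:
    """Tidy DataFrame view of a list of ANOVA effects."""
    return pd.DataFrame(
        [
            {
                "effect": r.effect,
                "F": r.F,
                "df_num": r.df_num,
                "df_den": r.df_den,
                "p": r.p,
                "partial_eta_sq": r.partial_eta_sq,
            }
            for r in results
        ]
    )
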