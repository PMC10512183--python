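"""Univariate group statistics for the ratio panel.

One-way ANOVA with Tukey HSD post-hoc comparisons (Tukey-Kramer for unequal
group sizes), plus the two diagnostics conventionally reported alongside:
Shapiro-Wilk normality per group and the Brown-Forsythe homoscedasticity test
(ANOVA on absolute deviations from group medians).  Diagnostics are reported,
never used to gate the ANOVA.  Significance annotation follows the usual
star convention with strict thresholds: * p < 0.05, ** p < 0.01,
*** p < 0.001.

Sums of squares and q statistics are computed here; tail probabilities come
from scipy's F, studentized-range, and Shapiro-Wilk (Royston AS R94)
implementations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .bands import RatioPanelResult
from .spectra import SpectraError

__all__ = [
    "AnovaResult",
    "PairwiseComparison",
    "AnovaTukeyResult",
    "DiagnosticsResult",
    "one_way_anova",
    "tukey_hsd",
    "brown_forsythe",
    "shapiro_wilk",
    "annotate_significance",
    "ratio_panel_stats",
    "ratio_panel_diagnostics",
]


class AnovaResult(NamedTuple):
    F: float
    df_between: int
    df_within: int
    p: float


class PairwiseComparison(NamedTuple):
    group_a: str
    group_b: str
    mean_difference: float  # mean_b - mean_a
    q: float
    p_adjusted: float
    stars: str


@dataclass
class AnovaTukeyResult:
    name: str
    anova: AnovaResult
    pairwise: list[PairwiseComparison]
    stars: str  # annotation of the omnibus ANOVA p


@dataclass
class DiagnosticsResult:
    name: str
    shapiro: dict[str, tuple[float, float]]  # group -> (W, p)
    brown_forsythe: tuple[float, float]


def _check_groups(groups: Sequence[np.ndarray]) -> list[np.ndarray]:
    gs = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(gs) < 2:
        raise SpectraError("need >= 2 groups")
    for g in gs:
        if g.size < 2:
            raise SpectraError("every group needs n >= 2")
        if not np.all(np.isfinite(g)):
            raise SpectraError("group values must be finite")
    return gs


def one_way_anova(groups: Sequence[np.ndarray]) -> AnovaResult:
    """Classical one-way ANOVA from the between/within decomposition."""
    gs = _check_groups(groups)
    n_total = sum(g.size for g in gs)
    grand = sum(g.sum() for g in gs) / n_total
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in gs)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in gs)
    df_b = len(gs) - 1
    df_w = n_total - len(gs)
    if ss_within == 0.0 and ss_between == 0.0:
        raise SpectraError("F undefined: zero between- and within-group variance")
    if ss_within == 0.0:
        return AnovaResult(float("inf"), df_b, df_w, 0.0)
    F = (ss_between / df_b) / (ss_within / df_w)
    p = float(sps.f.sf(F, df_b, df_w))
    return AnovaResult(float(F), df_b, df_w, p)


def tukey_hsd(
    groups: Sequence[np.ndarray], group_names: Sequence[str] | None = None
) -> list[PairwiseComparison]:
    """All-pairs Tukey HSD (Tukey-Kramer for unequal n).

    q_ij = |mean_i - mean_j| / sqrt(MSW * (1/n_i + 1/n_j) / 2); the adjusted
    p is the studentized-range survival function with k groups and the
    within-group degrees of freedom.
    """
    gs = _check_groups(groups)
    names = list(group_names) if group_names is not None else [
        f"g{i + 1}" for i in range(len(gs))
    ]
    k = len(gs)
    df_w = sum(g.size for g in gs) - k
    msw = sum(((g - g.mean()) ** 2).sum() for g in gs) / df_w
    if msw == 0.0:
        raise SpectraError("Tukey HSD undefined: zero within-group variance")
    out = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = gs[j].mean() - gs[i].mean()
            se = np.sqrt(msw * (1.0 / gs[i].size + 1.0 / gs[j].size) / 2.0)
            q = abs(diff) / se
            p = float(np.clip(sps.studentized_range.sf(q, k, df_w), 0.0, 1.0))
            out.append(
                PairwiseComparison(names[i], names[j], float(diff), float(q), p,
                                   annotate_significance(p))
            )
    return out


def brown_forsythe(groups: Sequence[np.ndarray]) -> tuple[float, float]:
    """Brown-Forsythe homoscedasticity test: one-way ANOVA applied to
    z_ij = |x_ij - median(group i)|.  Returns (statistic, p)."""
    gs = _check_groups(groups)
    zs = [np.abs(g - np.median(g)) for g in gs]
    try:
        res = one_way_anova(zs)
    except SpectraError:
        # all deviations identical in every group: spreads are exactly equal
        return 0.0, 1.0
    return res.F, res.p


def shapiro_wilk(sample: np.ndarray) -> tuple[float, float]:
    """Shapiro-Wilk normality test (Royston AS R94), 3 <= n <= 5000."""
    x = np.asarray(sample, dtype=float).ravel()
    if not 3 <= x.size <= 5000:
        raise SpectraError(f"Shapiro-Wilk needs 3 <= n <= 5000, got {x.size}")
    if np.ptp(x) == 0.0:
        raise SpectraError("Shapiro-Wilk undefined for a constant sample")
    w, p = sps.shapiro(x)
    return float(w), float(p)


def annotate_significance(p: float) -> str:
    """Star annotation with strict thresholds (p = 0.05 exactly is 'ns')."""
    if not 0.0 <= p <= 1.0:
        raise SpectraError(f"p must be in [0, 1], got {p}")
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


# ---------------------------------------------------------------------------
# panel-level drivers


def _split(values: pd.Series, groups: pd.Series) -> tuple[list[str], list[np.ndarray]]:
    names = sorted(groups.unique())
    return names, [values[groups == g].to_numpy(dtype=float) for g in names]


def ratio_panel_stats(
    panel: RatioPanelResult, bh_adjust: bool = False
) -> tuple[list[AnovaTukeyResult], pd.DataFrame]:
    """ANOVA + Tukey for every ratio of a panel.

    Per-ratio testing without multiplicity correction is the default
    (mirroring per-ratio reporting conventions); ``bh_adjust=True``
    additionally applies Benjamini-Hochberg across the panel's ANOVA p values
    (column ``p_anova_bh``).
    """
    results = []
    rows = []
    for name in panel.values.columns:
        col = panel.values[name].dropna()
        names, gs = _split(col, panel.groups.loc[col.index])
        anova = one_way_anova(gs)
        pw = tukey_hsd(gs, names)
        res = AnovaTukeyResult(name, anova, pw, annotate_significance(anova.p))
        results.append(res)
        row = {
            "ratio": name,
            "F": anova.F,
            "df_between": anova.df_between,
            "df_within": anova.df_within,
            "p_anova": anova.p,
            "stars": res.stars,
        }
        for c in pw:
            key = f"{c.group_a} vs {c.group_b}"
            row[f"p [{key}]"] = c.p_adjusted
            row[f"diff [{key}]"] = c.mean_difference
            row[f"stars [{key}]"] = c.stars
        rows.append(row)
    table = pd.DataFrame(rows).set_index("ratio")
    if bh_adjust:
        from statsmodels.stats.multitest import multipletests

        table["p_anova_bh"] = multipletests(table["p_anova"], method="fdr_bh")[1]
    return results, table


def ratio_panel_diagnostics(panel: RatioPanelResult) -> tuple[list[DiagnosticsResult], pd.DataFrame]:
    """Shapiro-Wilk per group and Brown-Forsythe for every ratio."""
    results = []
    rows = []
    for name in panel.values.columns:
        col = panel.values[name].dropna()
        names, gs = _split(col, panel.groups.loc[col.index])
        shapiro = {g: shapiro_wilk(x) for g, x in zip(names, gs)}
        bf = brown_forsythe(gs)
        results.append(DiagnosticsResult(name, shapiro, bf))
        row = {"ratio": name, "bf_stat": bf[0], "bf_p": bf[1]}
        for g in names:
            row[f"shapiro_W [{g}]"] = shapiro[g][0]
            row[f"shapiro_p [{g}]"] = shapiro[g][1]
        rows.append(row)
    return results, pd.DataFrame(rows).set_index("ratio")
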