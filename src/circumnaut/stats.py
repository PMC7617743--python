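"""Nonparametric group comparison of the kinematic measures.

The analysis layer mirrors standard practice for non-normal kinematic
variables: a Shapiro–Wilk normality screen, robust descriptives (median,
IQR, range, quartiles), the Kruskal–Wallis rank test across genotypes
for each dependent measure, and post-hoc pairwise comparisons.  The
Kruskal–Wallis statistic is computed from midranks with the usual tie
correction,

    H = [ 12 / (N (N+1)) * sum_g R_g^2 / n_g  -  3 (N+1) ]
        / [ 1 - sum_t (t^3 - t) / (N^3 - N) ],

and referred to a chi-square distribution with (number of groups - 1)
degrees of freedom.  Two post-hoc procedures are available: Dunn's
z-tests on midranks with Holm adjustment (default), and Tukey's HSD
applied to rank-transformed data (offered because pairing a Tukey post
hoc with a Kruskal–Wallis omnibus is common in the applied literature,
if nonstandard).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InvalidArgumentError

__all__ = [
    "GroupTestResult",
    "Descriptives",
    "shapiro_wilk",
    "kruskal_wallis",
    "kruskal_wallis_exact_p",
    "posthoc_pairwise",
    "describe",
    "run_group_analysis",
    "GroupAnalysisReport",
]

DEFAULT_MEASURES = (
    "duration_min",
    "mean_vel_mm_min",
    "max_acc_mm_min2",
    "dist_origin_mm",
    "dist_support_mm",
)


@dataclass(frozen=True)
class GroupTestResult:
    H: float
    df: int
    p: float
    tie_corrected: bool
    n_per_group: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.H < -1e-12:
            raise InvalidArgumentError("H must be >= 0")
        if not (0.0 <= self.p <= 1.0):
            raise InvalidArgumentError("p must lie in [0, 1]")

    def to_dict(self) -> dict:
        return {
            "statistic_H": self.H,
            "df": self.df,
            "p": self.p,
            "tie_corrected": self.tie_corrected,
            "n_per_group": list(self.n_per_group),
        }


@dataclass(frozen=True)
class Descriptives:
    median: float
    iqr: float
    range: tuple[float, float]
    p25: float
    p50: float
    p75: float
    n: int

    def to_dict(self) -> dict:
        return {
            "median": self.median,
            "IQR": self.iqr,
            "min": self.range[0],
            "max": self.range[1],
            "p25": self.p25,
            "p50": self.p50,
            "p75": self.p75,
            "n": self.n,
        }


def shapiro_wilk(sample) -> tuple[float, float]:
    """Shapiro–Wilk normality test (W, p) via the Royston approximation."""
    x = np.asarray(sample, dtype=float)
    if x.ndim != 1 or len(x) < 3 or len(x) > 5000:
        raise InvalidArgumentError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise InvalidArgumentError("Shapiro-Wilk is undefined for a constant sample")
    res = sps.shapiro(x)
    return float(res.statistic), float(res.pvalue)


def _validate_groups(groups) -> list[np.ndarray]:
    gs = [np.asarray(g, dtype=float).ravel() for g in groups]
    gs = [g for g in gs if g.size > 0]
    if len(gs) < 2:
        raise InvalidArgumentError("need >= 2 non-empty groups")
    if sum(g.size for g in gs) < 3:
        raise InvalidArgumentError("need >= 3 observations in total")
    return gs


def _h_statistic(gs: list[np.ndarray]) -> tuple[float, bool]:
    pooled = np.concatenate(gs)
    N = pooled.size
    ranks = sps.rankdata(pooled)  # midranks
    h = 0.0
    start = 0
    for g in gs:
        r = ranks[start : start + g.size]
        h += r.sum() ** 2 / g.size
        start += g.size
    h = 12.0 / (N * (N + 1)) * h - 3.0 * (N + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie_sum = float(np.sum(counts**3 - counts))
    has_ties = tie_sum > 0
    correction = 1.0 - tie_sum / (N**3 - N)
    if correction <= 0.0:  # all observations identical
        return 0.0, True
    return h / correction, has_ties


def kruskal_wallis(groups) -> GroupTestResult:
    """Kruskal–Wallis rank test across groups, with tie correction.

    The p-value comes from the chi-square approximation with
    ``len(groups) - 1`` degrees of freedom; an all-tied input returns
    H = 0 with p = 1.
    """
    gs = _validate_groups(groups)
    H, tie_corrected = _h_statistic(gs)
    H = max(H, 0.0)
    df = len(gs) - 1
    p = float(sps.chi2.sf(H, df)) if H > 0 else 1.0
    return GroupTestResult(
        H=float(H),
        df=df,
        p=min(p, 1.0),
        tie_corrected=tie_corrected,
        n_per_group=tuple(g.size for g in gs),
    )


def kruskal_wallis_exact_p(groups, max_total: int = 10) -> float:
    """Exact permutation p-value P(H >= H_obs) by exhaustive enumeration.

    Feasible only for tiny samples (total n <= ``max_total``); serves as
    an independent oracle for the chi-square approximation.
    """
    from itertools import combinations

    gs = _validate_groups(groups)
    sizes = [g.size for g in gs]
    N = sum(sizes)
    if N > max_total:
        raise InvalidArgumentError(f"exhaustive enumeration limited to n <= {max_total}")
    pooled = np.concatenate(gs)
    h_obs, _ = _h_statistic(gs)

    def assignments(indices: tuple[int, ...], remaining_sizes: list[int]):
        if len(remaining_sizes) == 1:
            yield (indices,)
            return
        for chosen in combinations(indices, remaining_sizes[0]):
            rest = tuple(i for i in indices if i not in set(chosen))
            for tail in assignments(rest, remaining_sizes[1:]):
                yield (chosen,) + tail

    count = 0
    total = 0
    for parts in assignments(tuple(range(N)), sizes):
        arranged = [pooled[list(idx)] for idx in parts]
        h, _ = _h_statistic(arranged)
        total += 1
        if h >= h_obs - 1e-12:
            count += 1
    return count / total


def holm_adjust(p_raw: np.ndarray) -> np.ndarray:
    """Holm step-down adjustment with enforced monotonicity."""
    p = np.asarray(p_raw, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


def posthoc_pairwise(
    groups,
    method: str = "dunn_holm",
    labels: list[str] | None = None,
) -> pd.DataFrame:
    """Pairwise group comparisons after a Kruskal–Wallis omnibus.

    ``dunn_holm``: Dunn z-statistics on midranks (tie-corrected pooled
    variance) with Holm-adjusted two-sided p-values.  ``tukey_on_ranks``:
    Tukey's HSD on rank-transformed observations.
    """
    gs = _validate_groups(groups)
    k = len(gs)
    if labels is None:
        labels = [f"group{i}" for i in range(k)]
    if len(labels) != k:
        raise InvalidArgumentError("labels length must match number of groups")

    pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]
    if method == "dunn_holm":
        pooled = np.concatenate(gs)
        N = pooled.size
        ranks = sps.rankdata(pooled)
        mean_ranks = []
        start = 0
        for g in gs:
            mean_ranks.append(ranks[start : start + g.size].mean())
            start += g.size
        _, counts = np.unique(pooled, return_counts=True)
        tie_term = float(np.sum(counts**3 - counts)) / (12.0 * (N - 1))
        var_base = N * (N + 1) / 12.0 - tie_term
        stats_z, p_raw = [], []
        for i, j in pairs:
            se = np.sqrt(var_base * (1.0 / gs[i].size + 1.0 / gs[j].size))
            z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
            stats_z.append(z)
            p_raw.append(2.0 * sps.norm.sf(abs(z)) if se > 0 else 1.0)
        p_adj = holm_adjust(np.array(p_raw))
        rows = [
            {
                "group1": labels[i],
                "group2": labels[j],
                "statistic": stats_z[m],
                "p_raw": p_raw[m],
                "p_adj": float(p_adj[m]),
            }
            for m, (i, j) in enumerate(pairs)
        ]
    elif method == "tukey_on_ranks":
        pooled = np.concatenate(gs)
        ranks = sps.rankdata(pooled)
        rank_groups = []
        start = 0
        for g in gs:
            rank_groups.append(ranks[start : start + g.size])
            start += g.size
        res = sps.tukey_hsd(*rank_groups)
        rows = [
            {
                "group1": labels[i],
                "group2": labels[j],
                "statistic": float(res.statistic[i, j]),
                "p_raw": float(res.pvalue[i, j]),
                "p_adj": float(res.pvalue[i, j]),  # Tukey is family-wise already
            }
            for i, j in pairs
        ]
    else:
        raise InvalidArgumentError(
            f"unknown post-hoc method {method!r}; use 'dunn_holm' or 'tukey_on_ranks'"
        )
    out = pd.DataFrame(rows)
    out["method"] = method
    return out


def describe(sample) -> Descriptives:
    """Median, IQR, range and quartiles (linear-interpolation percentiles)."""
    x = np.asarray(sample, dtype=float)
    if x.size < 1:
        raise InvalidArgumentError("describe requires a non-empty sample")
    p25, p50, p75 = np.percentile(x, [25, 50, 75], method="linear")
    return Descriptives(
        median=float(p50),
        iqr=float(p75 - p25),
        range=(float(x.min()), float(x.max())),
        p25=float(p25),
        p50=float(p50),
        p75=float(p75),
        n=int(x.size),
    )


# ---------------------------------------------------------------------------
# whole-table analysis


@dataclass
class GroupAnalysisReport:
    unit: str
    group_labels: list[str]
    posthoc_method: str
    measures: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {
            "unit": self.unit,
            "groups": self.group_labels,
            "posthoc_method": self.posthoc_method,
            "measures": {},
        }
        for m, entry in self.measures.items():
            out["measures"][m] = {
                "shapiro_wilk": entry["shapiro_wilk"],
                "descriptives": {
                    g: d.to_dict() for g, d in entry["descriptives"].items()
                },
                "kruskal_wallis": entry["kruskal_wallis"].to_dict(),
                "posthoc": entry["posthoc"].drop(columns="method").to_dict("records"),
            }
        return out

    def render_text(self) -> str:
        """Plain-text 'statistic, df, p' rendering of the omnibus tests."""
        lines = [f"Observational unit: {self.unit}"]
        for m, entry in self.measures.items():
            kw = entry["kruskal_wallis"]
            lines.append(
                f"{m}: H({kw.df}) = {kw.H:.3f}, p = {kw.p:.4g} "
                f"(n = {list(kw.n_per_group)})"
            )
        return "\n".join(lines)


def run_group_analysis(
    summaries: pd.DataFrame,
    measures=DEFAULT_MEASURES,
    unit: str = "per_cycle",
    group_col: str = "genotype",
    posthoc: str = "dunn_holm",
) -> GroupAnalysisReport:
    """Full statistical report for a tidy per-observation table.

    ``summaries`` must carry one row per observation at the declared
    ``unit`` (plants or circumnutation cycles), a ``group_col`` label
    column and all requested measure columns.  Per measure the report
    holds the Shapiro–Wilk screen per group, descriptives per group, the
    Kruskal–Wallis omnibus and the post-hoc pairwise table.
    """
    if unit not in ("per_plant", "per_cycle"):
        raise InvalidArgumentError("unit must be 'per_plant' or 'per_cycle'")
    if group_col not in summaries.columns:
        raise InvalidArgumentError(f"missing group column {group_col!r}")
    missing = [m for m in measures if m not in summaries.columns]
    if missing:
        raise InvalidArgumentError(f"missing measure columns: {missing}")
    labels = sorted(summaries[group_col].unique())
    report = GroupAnalysisReport(
        unit=unit, group_labels=list(labels), posthoc_method=posthoc
    )
    for m in measures:
        groups = [
            summaries.loc[summaries[group_col] == g, m].to_numpy(dtype=float)
            for g in labels
        ]
        sw = {}
        for g, vals in zip(labels, groups):
            try:
                w, p = shapiro_wilk(vals)
                sw[g] = {"W": w, "p": p}
            except InvalidArgumentError as exc:
                sw[g] = {"W": None, "p": None, "note": str(exc)}
        report.measures[m] = {
            "shapiro_wilk": sw,
            "descriptives": {g: describe(v) for g, v in zip(labels, groups)},
            "kruskal_wallis": kruskal_wallis(groups),
            "posthoc": posthoc_pairwise(groups, method=posthoc, labels=list(labels)),
        }
    return report
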