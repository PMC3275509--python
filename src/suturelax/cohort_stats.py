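"""Tissue-level aggregation, nonparametric comparisons and correlations.

Per-suture phase metrics and fit results are aggregated into one row per
tissue (mean ± sample SD), compared across tissues with the Kruskal–Wallis
test — pairwise Mann–Whitney tests are run only when the omnibus test is
significant at 0.05, and no multiple-testing correction is applied (a
deliberate mirror of common practice in small-animal biomechanics reports;
interpret pairwise p-values accordingly) — and related to collagen/protein
content through Pearson correlations.

Censored half-tension times (traces that never fell to half their peak
within the record) are excluded from means and rendered as a "> record
length" lower bound, never imputed.

Small-sample exactness: for pooled n <= 10 (Kruskal–Wallis) / combined
n <= 12 (Mann–Whitney) p-values come from exact enumeration over group
assignments of the pooled values (tie-safe); larger samples use the
chi-square reference (Kruskal–Wallis, tie-corrected H) and the normal
approximation with tie and continuity correction (Mann–Whitney).
"""
from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .trace_io import TISSUES

__all__ = [
    "CollagenMeasurement",
    "TestResult",
    "CorrelationRecord",
    "CohortSummary",
    "kruskal_wallis",
    "mann_whitney",
    "pearson_correlation",
    "collagen_correlations",
    "summarize_by_tissue",
    "ZeroVarianceError",
]

#: Pooled-sample sizes up to which exact enumeration replaces asymptotics.
KRUSKAL_EXACT_N = 10
MANN_WHITNEY_EXACT_N = 12

#: Metric columns aggregated and tested per tissue.
METRIC_COLUMNS = (
    "p0", "p1", "pplat", "rcp_loss_pct", "decline_pct_per_min",
    "plateau_ratio_pct", "collagen",
)


class ZeroVarianceError(ValueError):
    """A correlation was requested on a constant sample."""


@dataclass(frozen=True)
class CollagenMeasurement:
    """Collagen per total protein for one suture site, µg/mg."""

    suture_id: str
    tissue: str
    content: float

    def __post_init__(self) -> None:
        if self.content < 0:
            raise ValueError("collagen content must be >= 0")


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str


@dataclass(frozen=True)
class CorrelationRecord:
    x_name: str
    y_name: str
    r: float
    p_value: float
    n: int
    level: str = "sutures"  # "sutures" (pooled) or "tissue_means"
    valid: bool = True


def _rank_h_statistic(values: np.ndarray, labels: np.ndarray) -> float:
    """Tie-corrected Kruskal–Wallis H from pooled values and group labels."""
    n = len(values)
    ranks = sps.rankdata(values)
    total = 0.0
    for g in np.unique(labels):
        r = ranks[labels == g]
        total += r.sum() ** 2 / len(r)
    h = 12.0 / (n * (n + 1)) * total - 3.0 * (n + 1)
    _, counts = np.unique(values, return_counts=True)
    tie_term = np.sum(counts**3 - counts)
    correction = 1.0 - tie_term / (n**3 - n)
    if correction == 0:
        return 0.0  # every observation identical
    return h / correction


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> TestResult:
    """Kruskal–Wallis rank test across ``groups``.

    H is the tie-corrected rank statistic.  The p-value is exact (permutation
    enumeration over group assignments of the pooled values) when the pooled
    sample size is at most :data:`KRUSKAL_EXACT_N`, and chi-square with
    ``k - 1`` degrees of freedom otherwise.
    """
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    values = np.concatenate(arrays)
    labels = np.concatenate([np.full(len(g), i) for i, g in enumerate(arrays)])
    if np.all(values == values[0]):
        return TestResult(0.0, 1.0, "degenerate")
    h_obs = _rank_h_statistic(values, labels)
    n = len(values)
    if n <= KRUSKAL_EXACT_N:
        # Ranks and the tie correction are invariant under relabelling, so H
        # reduces to an affine function of the per-group rank-sum squares.
        ranks = sps.rankdata(values)
        _, counts = np.unique(values, return_counts=True)
        correction = 1.0 - np.sum(counts**3 - counts) / (n**3 - n)
        scale = 12.0 / (n * (n + 1))
        shift = 3.0 * (n + 1)
        sizes = [len(g) for g in arrays]
        count = 0
        total = 0
        for assignment in _group_assignments(list(range(n)), sizes):
            total_sq = sum(
                ranks[list(members)].sum() ** 2 / len(members)
                for members in assignment
            )
            h_perm = scale * total_sq - shift
            h_perm = h_perm / correction if correction != 0 else 0.0
            if h_perm >= h_obs - 1e-12:
                count += 1
            total += 1
        return TestResult(float(h_obs), count / total, "exact_permutation")
    p = float(sps.chi2.sf(h_obs, df=len(arrays) - 1))
    return TestResult(float(h_obs), p, "chi2")


def _group_assignments(indices: List[int], sizes: List[int]):
    """Yield all partitions of ``indices`` into ordered groups of ``sizes``."""
    if len(sizes) == 1:
        yield (tuple(indices),)
        return
    first, rest = sizes[0], sizes[1:]
    for combo in itertools.combinations(indices, first):
        remaining = [i for i in indices if i not in combo]
        for tail in _group_assignments(remaining, rest):
            yield (combo,) + tail


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U = number of (x, y) pairs with x > y, counting ties as 1/2."""
    greater = (x[:, None] > y[None, :]).sum()
    ties = (x[:, None] == y[None, :]).sum()
    return float(greater) + 0.5 * float(ties)


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided Mann–Whitney U test.

    Convention: ``U`` counts pairs with ``x > y`` (ties as 1/2), so
    ``U = 0`` when every x is below every y and ``U = n_x * n_y`` in the
    opposite extreme; swapping the samples maps ``U`` to ``n_x*n_y - U``.
    Exact p by enumeration (two-sided via ``|U - n_x n_y / 2|``) for
    combined n <= :data:`MANN_WHITNEY_EXACT_N`; otherwise the normal
    approximation with tie and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    nx, ny = len(x), len(y)
    u_obs = _u_statistic(x, y)
    mu = nx * ny / 2.0
    if nx + ny <= MANN_WHITNEY_EXACT_N:
        pooled = np.concatenate([x, y])
        dev_obs = abs(u_obs - mu)
        count = 0
        total = 0
        for combo in itertools.combinations(range(nx + ny), nx):
            mask = np.zeros(nx + ny, dtype=bool)
            mask[list(combo)] = True
            u_perm = _u_statistic(pooled[mask], pooled[~mask])
            if abs(u_perm - mu) >= dev_obs - 1e-12:
                count += 1
            total += 1
        return TestResult(u_obs, count / total, "exact_enumeration")
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return TestResult(u_obs, float(res.pvalue), "normal_approx")


def pearson_correlation(
    x: Sequence[float], y: Sequence[float]
) -> Tuple[float, float, int]:
    """Product-moment correlation with a two-sided t-test p-value (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("samples must have equal length")
    if len(x) < 3:
        raise ValueError("need n >= 3 for a correlation p-value")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ZeroVarianceError("correlation undefined for a constant sample")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue), len(x)


def collagen_correlations(
    metrics: Sequence,
    collagen: Sequence[CollagenMeasurement],
) -> List[CorrelationRecord]:
    """Correlate collagen content with RCP loss and plateau ratio.

    Computed on pooled per-suture records (the primary result), plus
    secondary records at the tissue-means level (n = number of tissues).
    A constant sample yields a flagged, invalid record rather than r = 0.
    """
    by_id = {m.suture_id: m for m in metrics}
    collagen_ids = {c.suture_id for c in collagen}
    orphans = sorted(collagen_ids.symmetric_difference(by_id))
    if orphans:
        raise ValueError(f"unmatched suture_ids between inputs: {orphans}")
    ordered = sorted(collagen, key=lambda c: c.suture_id)
    content = np.array([c.content for c in ordered])
    rows = pd.DataFrame(
        {
            "tissue": [by_id[c.suture_id].tissue for c in ordered],
            "collagen": content,
            "rcp_loss_pct": [by_id[c.suture_id].rcp_loss_pct for c in ordered],
            "plateau_ratio_pct": [
                by_id[c.suture_id].plateau_ratio_pct for c in ordered
            ],
        }
    )
    records: List[CorrelationRecord] = []
    for metric in ("rcp_loss_pct", "plateau_ratio_pct"):
        sub = rows.dropna(subset=[metric, "collagen"])
        records.append(
            _correlation_record("collagen", metric, sub["collagen"], sub[metric],
                                level="sutures")
        )
        means = sub.groupby("tissue", sort=False)[["collagen", metric]].mean()
        if len(means) >= 3:
            records.append(
                _correlation_record("collagen", metric, means["collagen"],
                                    means[metric], level="tissue_means")
            )
    return records


def _correlation_record(x_name, y_name, x, y, level) -> CorrelationRecord:
    try:
        r, p, n = pearson_correlation(np.asarray(x), np.asarray(y))
    except (ZeroVarianceError, ValueError):
        return CorrelationRecord(x_name, y_name, float("nan"), float("nan"),
                                 len(x), level=level, valid=False)
    return CorrelationRecord(x_name, y_name, r, p, n, level=level)


@dataclass
class CohortSummary:
    """Tissue-level report: the per-tissue table, tests and correlations."""

    table: pd.DataFrame
    per_suture: pd.DataFrame
    omnibus: Dict[str, TestResult] = field(default_factory=dict)
    pairwise: Dict[str, Dict[Tuple[str, str], TestResult]] = field(
        default_factory=dict
    )
    correlations: List[CorrelationRecord] = field(default_factory=list)
    record_min: float = 60.0
    flags: Tuple[str, ...] = ()

    def to_dict(self) -> dict:
        table = {
            tissue: {k: _jsonable(v) for k, v in row.items()}
            for tissue, row in self.table.to_dict(orient="index").items()
        }
        return {
            "tissues": table,
            "omnibus": {
                m: {"statistic": t.statistic, "p_value": t.p_value,
                    "method": t.method}
                for m, t in self.omnibus.items()
            },
            "pairwise": {
                m: {
                    f"{a}_vs_{b}": {"statistic": t.statistic,
                                    "p_value": t.p_value, "method": t.method}
                    for (a, b), t in pairs.items()
                }
                for m, pairs in self.pairwise.items()
            },
            "correlations": [
                {
                    "x": c.x_name, "y": c.y_name, "r": _jsonable(c.r),
                    "p_value": _jsonable(c.p_value), "n": c.n,
                    "level": c.level, "valid": c.valid,
                }
                for c in self.correlations
            ],
            "record_min": self.record_min,
            "flags": list(self.flags),
        }

    def to_markdown(self) -> str:
        """Render the per-tissue table in the style of a tension-summary table."""
        tissues = list(self.table.index)
        pretty = {
            "p0": "P0 in N",
            "p1": "P1 in N",
            "pplat": "Pplat in N",
            "rcp_loss_pct": "Decrease of tension in the RCP in %",
            "decline_pct_per_min":
                "Estimated decrease of tension in the CDP per minute in %",
            "plateau_ratio_pct": "Relation of Pplat to P0 in %",
            "collagen": "Collagen/Protein content in µg/mg",
        }
        lines = ["| Metric | " + " | ".join(tissues) + " |",
                 "|" + "---|" * (len(tissues) + 1)]
        for metric, label in pretty.items():
            if f"{metric}_mean" not in self.table.columns:
                continue
            cells = []
            for tissue in tissues:
                mean = self.table.loc[tissue, f"{metric}_mean"]
                sd = self.table.loc[tissue, f"{metric}_sd"]
                if pd.isna(mean):
                    cells.append("–")
                elif pd.isna(sd):
                    cells.append(f"{mean:.1f}")
                else:
                    cells.append(f"{mean:.1f} ± {sd:.1f}")
            lines.append(f"| {label} | " + " | ".join(cells) + " |")
        cells = []
        for tissue in tissues:
            n_cens = int(self.table.loc[tissue, "half_time_censored_n"])
            n_tot = int(self.table.loc[tissue, "n"])
            mean = self.table.loc[tissue, "half_time_mean"]
            sd = self.table.loc[tissue, "half_time_sd"]
            if n_cens == n_tot:
                cells.append(f"> {self.record_min:g}")
            else:
                cell = f"{mean:.1f}" if pd.isna(sd) else f"{mean:.1f} ± {sd:.1f}"
                if n_cens:
                    cell += f" ({n_cens} censored)"
                cells.append(cell)
        lines.append(
            "| Time after half of the tension is reached in min | "
            + " | ".join(cells) + " |"
        )
        return "\n".join(lines)


def _jsonable(v):
    if isinstance(v, (np.floating, np.integer)):
        v = v.item()
    if isinstance(v, float) and math.isnan(v):
        return None
    return v


def _per_suture_frame(metrics, fits, collagen) -> pd.DataFrame:
    from .relaxation_fit import decline_per_minute  # local: avoid cycle

    rows = []
    for m in metrics:
        rows.append(
            {
                "suture_id": m.suture_id,
                "tissue": m.tissue,
                "p0": m.p0,
                "p1": m.p1,
                "pplat": m.pplat,
                "rcp_loss_pct": m.rcp_loss_pct,
                "plateau_ratio_pct": m.plateau_ratio_pct,
                "half_time_min": m.half_time_min,
                "half_time_censored": m.half_time_censored,
            }
        )
    frame = pd.DataFrame(rows).set_index("suture_id")
    if fits:
        decline = {}
        for f in fits:
            try:
                decline[f.suture_id] = decline_per_minute(f)
            except ValueError:
                decline[f.suture_id] = float("nan")
        frame["decline_pct_per_min"] = pd.Series(decline)
    else:
        frame["decline_pct_per_min"] = float("nan")
    if collagen:
        frame["collagen"] = pd.Series({c.suture_id: c.content for c in collagen})
    else:
        frame["collagen"] = float("nan")
    return frame


def summarize_by_tissue(
    metrics: Sequence,
    fits: Sequence = (),
    collagen: Sequence[CollagenMeasurement] = (),
    record_min: float = 60.0,
    alpha: float = 0.05,
) -> CohortSummary:
    """Aggregate per-suture results into the tissue-level summary report.

    Means use the sample SD (n-1 denominator); a tissue with a single suture
    gets a missing SD, not zero, and suppresses all hypothesis tests.
    Censored half-times are excluded from the half-time mean and counted
    separately.  Pairwise Mann–Whitney tests run per metric only when that
    metric's Kruskal–Wallis omnibus test is significant at ``alpha``.
    """
    if not metrics:
        raise ValueError("no metrics to summarize")
    frame = _per_suture_frame(metrics, fits, collagen)
    tissues = [t for t in TISSUES if t in set(frame["tissue"])]
    flags: List[str] = []

    rows = {}
    for tissue in tissues:
        sub = frame[frame["tissue"] == tissue]
        row = {"n": len(sub)}
        for col in METRIC_COLUMNS:
            vals = sub[col].dropna()
            row[f"{col}_mean"] = vals.mean() if len(vals) else float("nan")
            row[f"{col}_sd"] = vals.std(ddof=1) if len(vals) >= 2 else float("nan")
        uncensored = sub.loc[~sub["half_time_censored"], "half_time_min"]
        row["half_time_mean"] = (
            uncensored.mean() if len(uncensored) else float("nan")
        )
        row["half_time_sd"] = (
            uncensored.std(ddof=1) if len(uncensored) >= 2 else float("nan")
        )
        row["half_time_censored_n"] = int(sub["half_time_censored"].sum())
        rows[tissue] = row
    table = pd.DataFrame.from_dict(rows, orient="index").loc[tissues]

    omnibus: Dict[str, TestResult] = {}
    pairwise: Dict[str, Dict[Tuple[str, str], TestResult]] = {}
    min_group = int(table["n"].min()) if len(table) else 0
    if len(tissues) >= 2 and min_group >= 2:
        for col in METRIC_COLUMNS:
            groups = [
                frame.loc[frame["tissue"] == t, col].dropna().to_numpy()
                for t in tissues
            ]
            if any(len(g) < 2 for g in groups):
                continue
            omnibus[col] = kruskal_wallis(groups)
            if omnibus[col].p_value < alpha:
                pairs = {}
                for a, b in itertools.combinations(tissues, 2):
                    xa = frame.loc[frame["tissue"] == a, col].dropna()
                    xb = frame.loc[frame["tissue"] == b, col].dropna()
                    pairs[(a, b)] = mann_whitney(xa, xb)
                pairwise[col] = pairs
    else:
        flags.append("tests_skipped_insufficient_n")
        warnings.warn(
            "fewer than 2 sutures in some tissue: hypothesis tests skipped",
            stacklevel=2,
        )

    correlations: List[CorrelationRecord] = []
    if len(collagen) and len(metrics) >= 3:
        correlations = collagen_correlations(metrics, collagen)

    return CohortSummary(
        table=table,
        per_suture=frame,
        omnibus=omnibus,
        pairwise=pairwise,
        correlations=correlations,
        record_min=record_min,
        flags=tuple(flags),
    )
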