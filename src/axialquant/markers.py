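"""Per-cell marker quantification: three-level classification and gating.

Marker intensity per nucleus (immunofluorescence or HCR) is classified into
three categories — not expressed, low and high — either with manual
thresholds or by fitting a 3-component Gaussian mixture to log-transformed
intensities. Cells are then gated into co-expression classes (e.g. SOX2
alone, TBXT alone, double positive) and colony composition is summarised
with standard Tukey box-plot statistics (median, quartile hinges, whiskers
at the most extreme values within 1.5× the interquartile range of the
nearer hinge).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "LEVELS",
    "TrinarizeResult",
    "Gate",
    "GateSet",
    "GateConflictError",
    "default_gates",
    "trinarize",
    "gate_cells",
    "boxplot_stats",
    "composition_summary",
]

LEVELS = ("absent", "low", "high")
_LEVEL_RANK = {lvl: i for i, lvl in enumerate(LEVELS)}


@dataclass
class TrinarizeResult:
    levels: np.ndarray  # array of LEVELS strings
    thresholds: Tuple[float, float]  # (t1, t2) on the raw intensity scale
    method: str


class GateConflictError(ValueError):
    """Two gates matched the same cell: the gate set is not exclusive."""


@dataclass
class Gate:
    """A named predicate: all listed markers must be at an allowed level."""

    name: str
    rules: Dict[str, Set[str]]

    def matches(self, levels: Dict[str, str]) -> bool:
        return all(levels.get(m) in allowed for m, allowed in self.rules.items())


@dataclass
class GateSet:
    """Ordered gates plus an implicit exhaustive 'other' class."""

    gates: List[Gate]
    other_name: str = "other"

    def class_names(self) -> List[str]:
        return [g.name for g in self.gates] + [self.other_name]


def default_gates() -> GateSet:
    """Co-expression classes of the micropattern analysis."""
    return GateSet(
        gates=[
            Gate("SOX2_only", {"SOX2": {"low", "high"}, "TBXT": {"absent"}}),
            Gate("TBXT_only", {"TBXT": {"low", "high"}, "SOX2": {"absent"}}),
            Gate("double_positive", {"SOX2": {"low", "high"}, "TBXT": {"low", "high"}}),
        ]
    )


def _apply_thresholds(values: np.ndarray, t1: float, t2: float) -> np.ndarray:
    levels = np.full(len(values), "absent", dtype=object)
    levels[values >= t1] = "low"
    levels[values >= t2] = "high"
    return levels


def _gmm_thresholds(log_values: np.ndarray, random_state: int) -> Optional[Tuple[float, float]]:
    from sklearn.mixture import GaussianMixture

    gm = GaussianMixture(n_components=3, random_state=random_state, n_init=3)
    gm.fit(log_values.reshape(-1, 1))
    order = np.argsort(gm.means_.ravel())
    grid = np.linspace(log_values.min(), log_values.max(), 4096)
    resp = gm.predict_proba(grid.reshape(-1, 1))[:, order]
    assign = resp.argmax(axis=1)
    cuts = []
    for comp in (0, 1):
        above = np.nonzero(assign > comp)[0]
        below = np.nonzero(assign <= comp)[0]
        if len(above) == 0 or len(below) == 0:
            return None
        # first grid point where the classification moves past this component
        idx = above[0]
        if idx == 0:
            return None
        cuts.append(0.5 * (grid[idx - 1] + grid[idx]))
    if not cuts[0] < cuts[1]:
        return None
    return cuts[0], cuts[1]


def trinarize(
    values: Sequence[float],
    method: str = "gmm",
    manual_thresholds: Optional[Tuple[float, float]] = None,
    quantiles: Tuple[float, float] = (0.5, 0.9),
    background: float = 0.0,
    random_state: int = 0,
) -> TrinarizeResult:
    """Classify one marker's per-cell intensities into absent/low/high.

    With ``manual_thresholds`` (t1, t2): absent below t1, low in [t1, t2),
    high at or above t2. Otherwise thresholds are fit on log(value + 1): by a
    3-component Gaussian mixture with cuts at the posterior-equality
    crossings (``method='gmm'``), or at the given quantiles
    (``method='quantile'``); the mixture falls back to quantiles when its
    components do not separate. Fitted thresholds are reported on the raw
    intensity scale.
    """
    v = np.asarray(values, dtype=float)
    if len(v) == 0:
        raise ValueError("need at least one cell")
    if manual_thresholds is not None:
        t1, t2 = manual_thresholds
        if not t1 < t2:
            raise ValueError("manual thresholds must satisfy t1 < t2")
        return TrinarizeResult(_apply_thresholds(v, t1, t2), (float(t1), float(t2)), "manual")

    if np.all(v == v[0]):
        if v[0] <= background:
            return TrinarizeResult(
                np.full(len(v), "absent", dtype=object), (np.inf, np.inf), "degenerate"
            )
        raise ValueError(
            "all intensities identical and above background; "
            "automatic thresholding is undefined — supply manual thresholds"
        )

    logv = np.log(v + 1.0)
    cuts = None
    used = method
    if method == "gmm":
        cuts = _gmm_thresholds(logv, random_state)
        if cuts is None:
            used = "quantile-fallback"
    elif method != "quantile":
        raise ValueError(f"unknown trinarize method {method!r}")
    if cuts is None:
        q1, q2 = np.quantile(logv, quantiles)
        if not q1 < q2:
            q2 = q1 + 1e-9
        cuts = (q1, q2)
    t1, t2 = (float(np.exp(c) - 1.0) for c in cuts)
    return TrinarizeResult(_apply_thresholds(v, t1, t2), (t1, t2), used)


def gate_cells(records: pd.DataFrame, gates: GateSet) -> Tuple[pd.DataFrame, pd.Series]:
    """Assign each cell to exactly one co-expression class.

    ``records`` must hold ``level_<marker>`` columns for every marker a gate
    references. Returns the table with a ``cell_class`` column plus per-class
    counts. Raises :class:`GateConflictError` if two gates match one cell.
    """
    markers = sorted({m for g in gates.gates for m in g.rules})
    missing = [m for m in markers if f"level_{m}" not in records.columns]
    if missing:
        raise ValueError(f"records lack trinarized levels for markers: {missing}")
    out = records.copy()
    classes = []
    for _, row in out.iterrows():
        levels = {m: row[f"level_{m}"] for m in markers}
        hits = [g.name for g in gates.gates if g.matches(levels)]
        if len(hits) > 1:
            raise GateConflictError(
                f"gates {hits} overlap on levels {levels}; gate set must be exclusive"
            )
        classes.append(hits[0] if hits else gates.other_name)
    out["cell_class"] = classes
    counts = out["cell_class"].value_counts().reindex(gates.class_names(), fill_value=0)
    return out, counts


def boxplot_stats(values: Sequence[float]) -> Dict[str, float]:
    """Tukey box-plot statistics with linear-interpolation quartiles.

    Hinges are the first and third quartiles; whiskers extend to the most
    extreme data point within 1.5×IQR of the nearer hinge; points beyond are
    reported as outliers.
    """
    v = np.sort(np.asarray(values, dtype=float))
    if len(v) == 0:
        raise ValueError("empty vector")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    lo_lim, hi_lim = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = v[(v >= lo_lim) & (v <= hi_lim)]
    return {
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "whisker_low": float(inside.min()),
        "whisker_high": float(inside.max()),
        "n": int(len(v)),
        "outliers": [float(x) for x in v[(v < lo_lim) | (v > hi_lim)]],
    }


def composition_summary(
    records: pd.DataFrame,
    class_names: Optional[Sequence[str]] = None,
    colony_col: str = "colony_id",
    class_col: str = "cell_class",
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Per-colony class proportions and across-colony box-plot statistics.

    Returns ``(per_colony, summary)``: the first has one row per colony and
    one column per class (proportions summing to 1), the second one row per
    class with mean proportion and box-plot statistics across colonies.
    Colonies with zero cells are excluded with a warning.
    """
    if class_names is None:
        class_names = sorted(records[class_col].unique())
    rows = []
    for colony, grp in records.groupby(colony_col):
        n = len(grp)
        if n == 0:  # pragma: no cover - groupby drops empties
            warnings.warn(f"colony {colony} has no cells; excluded")
            continue
        counts = grp[class_col].value_counts()
        rows.append(
            {colony_col: colony, "n_cells": n}
            | {c: counts.get(c, 0) / n for c in class_names}
        )
    if not rows:
        raise ValueError("no non-empty colonies")
    per_colony = pd.DataFrame(rows).set_index(colony_col)
    summary_rows = []
    for c in class_names:
        stats = boxplot_stats(per_colony[c].to_numpy())
        outliers = stats.pop("outliers")
        summary_rows.append(
            {"cell_class": c, "mean": float(per_colony[c].mean()), "n_outliers": len(outliers)}
            | stats
        )
    return per_colony, pd.DataFrame(summary_rows).set_index("cell_class")
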