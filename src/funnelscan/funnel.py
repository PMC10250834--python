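"""Narrow-funnel statistics over interaction-energy distributions.

A pair with one dominant binding orientation shows a narrow funnel-like
joint (energy, iRMS) distribution: the low-energy decoys concentrate near
the strongest-interacting pose. The narrow-funnel fraction counts the
decoys that are simultaneously strong (energy <= e_max) and close
(iRMS <= irms_max); a pair is called a specific interaction when that
fraction meets the distribution criterion (>=, inclusive). The three
thresholds are chosen by maximizing the true-positive minus false-positive
rate over a grid, mirroring how the criteria were screened against labeled
positive and random pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin

from .scores import MetricsTable


@dataclass(frozen=True)
class FunnelCriteria:
    """The three classification thresholds."""

    e_max: float          # interaction-energy criterion, kcal/mol
    irms_max: float       # iRMS criterion, A
    fraction_min: float   # distribution criterion, percent of decoys

    def __post_init__(self) -> None:
        if self.irms_max <= 0:
            raise ValueError("irms_max must be positive")
        if not 0 < self.fraction_min <= 100:
            raise ValueError("fraction_min must be in (0, 100]")


@dataclass(frozen=True)
class FunnelVerdict:
    fraction: float
    is_narrow_funnel: bool
    criteria: FunnelCriteria


def narrow_funnel_fraction(metrics: MetricsTable, e_max: float, irms_max: float) -> float:
    """Percent of decoys with energy <= e_max and iRMS <= irms_max (inclusive)."""
    df = metrics.df
    if len(df) == 0:
        raise ValueError("empty metrics table")
    inside = (df["energy_kcal_mol"] <= e_max) & (df["irms_A"] <= irms_max)
    return 100.0 * float(inside.sum()) / len(df)


def classify_funnel(metrics: MetricsTable, criteria: FunnelCriteria) -> FunnelVerdict:
    fraction = narrow_funnel_fraction(metrics, criteria.e_max, criteria.irms_max)
    return FunnelVerdict(fraction, fraction >= criteria.fraction_min, criteria)


# ---------------------------------------------------------------------------
# Criteria grid search
# ---------------------------------------------------------------------------

#: Distribution-criterion default grid (percent of decoys).
DEFAULT_FRACTION_GRID = (0.1, 0.2, 0.5, 1.0, 2.0, 5.0, 10.0)


def default_energy_grid(pooled_energies: np.ndarray, n_steps: int = 20) -> np.ndarray:
    """Energy axis from the pooled 1st percentile up to 0 kcal/mol."""
    low = float(np.percentile(np.asarray(pooled_energies, dtype=float), 1))
    if low >= 0:
        low = float(np.min(pooled_energies))
    return np.linspace(low, 0.0, n_steps)


def default_irms_grid() -> np.ndarray:
    """iRMS axis: 1 to 30 A in 1 A steps."""
    return np.arange(1.0, 31.0, 1.0)


@dataclass
class CriteriaGridResult:
    """TP/FP rates over the (fraction, energy, iRMS) criteria grid.

    Arrays are indexed ``[fraction, energy, irms]``; rates are percentages.
    """

    energy_grid: np.ndarray
    irms_grid: np.ndarray
    fraction_grid: np.ndarray
    tp_rate: np.ndarray
    fp_rate: np.ndarray

    @property
    def diff(self) -> np.ndarray:
        return self.tp_rate - self.fp_rate

    @property
    def best(self) -> tuple[FunnelCriteria, float]:
        """Criteria maximizing TP-FP; ties resolve to the lexicographically
        first (fraction, energy, irms) grid cell."""
        diff = self.diff
        idx = np.unravel_index(int(np.argmax(diff)), diff.shape)  # first max, C order
        criteria = FunnelCriteria(
            e_max=float(self.energy_grid[idx[1]]),
            irms_max=float(self.irms_grid[idx[2]]),
            fraction_min=float(self.fraction_grid[idx[0]]),
        )
        return criteria, float(diff[idx])

    def to_frame(self) -> pd.DataFrame:
        f, e, i = np.meshgrid(
            self.fraction_grid, self.energy_grid, self.irms_grid, indexing="ij"
        )
        return pd.DataFrame(
            {
                "fraction_min_percent": f.ravel(),
                "e_max_kcal_mol": e.ravel(),
                "irms_max_A": i.ravel(),
                "tp_rate_percent": self.tp_rate.ravel(),
                "fp_rate_percent": self.fp_rate.ravel(),
                "diff_percent": self.diff.ravel(),
            }
        )


def _fraction_surface(
    metrics: MetricsTable, energy_grid: np.ndarray, irms_grid: np.ndarray
) -> np.ndarray:
    """Narrow-funnel fraction (%) of one table at every (energy, irms) cell."""
    df = metrics.df
    e = df["energy_kcal_mol"].to_numpy()[:, None, None]
    r = df["irms_A"].to_numpy()[:, None, None]
    inside = (e <= energy_grid[None, :, None]) & (r <= irms_grid[None, None, :])
    return 100.0 * inside.mean(axis=0)


def criteria_grid_search(
    positives: Sequence[MetricsTable],
    negatives: Sequence[MetricsTable],
    energy_grid: np.ndarray | None = None,
    irms_grid: np.ndarray | None = None,
    fraction_grid: Sequence[float] = DEFAULT_FRACTION_GRID,
) -> CriteriaGridResult:
    """TP-FP landscape over the three-criteria grid.

    ``tp_rate[f,e,i]`` is the percentage of positive pairs classified as
    narrow funnel at that criteria triple; ``fp_rate`` likewise for the
    negative (random) pairs.
    """
    if not positives or not negatives:
        raise ValueError("need at least one positive and one negative ensemble")
    if energy_grid is None:
        pooled = np.concatenate(
            [t.df["energy_kcal_mol"].to_numpy() for t in [*positives, *negatives]]
        )
        energy_grid = default_energy_grid(pooled)
    energy_grid = np.asarray(energy_grid, dtype=float)
    irms_grid = np.asarray(irms_grid if irms_grid is not None else default_irms_grid(), dtype=float)
    fraction_grid = np.asarray(list(fraction_grid), dtype=float)
    for name, axis in (("energy", energy_grid), ("irms", irms_grid), ("fraction", fraction_grid)):
        if axis.size == 0:
            raise ValueError(f"empty {name} grid axis")

    def rate(tables: Sequence[MetricsTable]) -> np.ndarray:
        surfaces = np.stack([_fraction_surface(t, energy_grid, irms_grid) for t in tables])
        passing = surfaces[:, None, :, :] >= fraction_grid[None, :, None, None]
        return 100.0 * passing.mean(axis=0)

    return CriteriaGridResult(
        energy_grid=energy_grid,
        irms_grid=irms_grid,
        fraction_grid=fraction_grid,
        tp_rate=rate(positives),
        fp_rate=rate(negatives),
    )


def reduce_max_per_fraction(grid: CriteriaGridResult) -> pd.DataFrame:
    """Per distribution-criterion value, the maximum TP-FP over the
    energy x iRMS plane, with the maximizing thresholds."""
    rows = []
    diff = grid.diff
    for k, frac in enumerate(grid.fraction_grid):
        plane = diff[k]
        e_idx, i_idx = np.unravel_index(int(np.argmax(plane)), plane.shape)
        rows.append(
            {
                "fraction_min_percent": float(frac),
                "max_diff_percent": float(plane[e_idx, i_idx]),
                "e_max_kcal_mol": float(grid.energy_grid[e_idx]),
                "irms_max_A": float(grid.irms_grid[i_idx]),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Ensemble summaries and group comparison
# ---------------------------------------------------------------------------

_SUMMARY_COLUMNS = {
    "energy": "energy_kcal_mol",
    "irms": "irms_A",
    "rtm": "rtm",
    "itm_complex": "itm_complex",
    "ritm": "ritm",
}


@dataclass(frozen=True)
class EnsembleSummary:
    """Mean and median of each metric over one ensemble's decoys."""

    n_decoys: int
    mean: dict[str, float]
    median: dict[str, float]

    def metric_mean(self, metric: str) -> float:
        return self.mean[metric]


def summarize(metrics: MetricsTable) -> EnsembleSummary:
    df = metrics.df
    if len(df) == 0:
        raise ValueError("empty metrics table")
    mean, median = {}, {}
    for name, col in _SUMMARY_COLUMNS.items():
        if col in df.columns:
            mean[name] = float(df[col].mean())
            median[name] = float(df[col].median())
    return EnsembleSummary(n_decoys=len(df), mean=mean, median=median)


def significance_stars(p: float) -> str:
    """Asterisk convention: * 95%, ** 99%, *** 99.95% confidence."""
    if p < 0.0005:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass(frozen=True)
class GroupComparison:
    metric: str
    t_statistic: float
    p_value: float
    stars: str
    mean_a: float
    mean_b: float


def compare_groups(
    a: Sequence[EnsembleSummary], b: Sequence[EnsembleSummary], metric: str = "irms"
) -> GroupComparison:
    """Two-sample Student's t test (pooled variance) on per-ensemble means."""
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 ensembles")
    xa = np.array([s.metric_mean(metric) for s in a], dtype=float)
    xb = np.array([s.metric_mean(metric) for s in b], dtype=float)
    if np.var(xa, ddof=1) == 0 and np.var(xb, ddof=1) == 0 and xa.mean() == xb.mean():
        return GroupComparison(metric, 0.0, 1.0, "", float(xa.mean()), float(xb.mean()))
    t, p = stats.ttest_ind(xa, xb, equal_var=True)
    return GroupComparison(
        metric, float(t), float(p), significance_stars(float(p)),
        float(xa.mean()), float(xb.mean()),
    )


# ---------------------------------------------------------------------------
# Estimator wrapper
# ---------------------------------------------------------------------------

class NarrowFunnelScreen(BaseEstimator, ClassifierMixin):
    """Criteria-search classifier over labeled metrics tables.

    ``fit`` runs the TP-FP grid search over labeled ensembles and freezes
    the best criteria triple; ``predict`` classifies new metrics tables as
    narrow funnel (1) or not (0).

    Parameters
    ----------
    energy_grid, irms_grid, fraction_grid
        Criteria axes; ``None`` uses the data-driven defaults
        (energy: pooled 1st percentile to 0 in 20 steps; iRMS: 1-30 A;
        fraction: {0.1, 0.2, 0.5, 1, 2, 5, 10} %).
    """

    def __init__(self, energy_grid=None, irms_grid=None, fraction_grid=DEFAULT_FRACTION_GRID):
        self.energy_grid = energy_grid
        self.irms_grid = irms_grid
        self.fraction_grid = fraction_grid

    def fit(self, X: Sequence[MetricsTable], y: Sequence):
        y = np.asarray(y)
        labels = np.unique(y)
        if len(labels) != 2:
            raise ValueError("need exactly two classes (positive/negative)")
        positive = _positive_label(labels)
        positives = [t for t, lab in zip(X, y) if lab == positive]
        negatives = [t for t, lab in zip(X, y) if lab != positive]
        self.classes_ = np.array(sorted(labels, key=lambda v: v != positive))
        self.grid_result_ = criteria_grid_search(
            positives, negatives, self.energy_grid, self.irms_grid, self.fraction_grid
        )
        self.criteria_, self.best_diff_ = self.grid_result_.best
        self.positive_label_ = positive
        return self

    def predict(self, X: Sequence[MetricsTable]) -> np.ndarray:
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "criteria_")
        verdicts = [classify_funnel(t, self.criteria_).is_narrow_funnel for t in X]
        negative = next(lab for lab in self.classes_ if lab != self.positive_label_)
        return np.array([self.positive_label_ if v else negative for v in verdicts])


def _positive_label(labels: np.ndarray):
    for candidate in ("positive", "interacting", 1, True):
        if candidate in labels:
            return candidate
    return labels[-1]
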