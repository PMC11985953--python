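"""Uncertainty propagation and validation statistics.

Two Monte Carlo analyses: (1) intensity uncertainty — each threat's
intensity is redrawn uniformly between its min and max bound (one scalar
per threat per draw) and the cumulative surface recomputed, giving
per-pixel mean and SD; (2) land-cover classification error — each pixel's
class is redrawn from the confusion-matrix row of its predicted class,
independently per pixel (spatially unstructured error), and a downstream
summary recomputed per realization.

Validation against reference plots uses weighted RMSE; temporal change is
summarized as linear mean annual percent change relative to the start
year plus the changed-area fraction (Delta H above a threshold).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .core import increasive_mean, modification_from_footprint
from .grid import CategoricalLayer, Layer, check_aligned
from .registry import ThreatRegistry


@dataclass
class ReferencePlotSet:
    """Point samples with independently observed modification values."""

    x: np.ndarray
    y: np.ndarray
    observed: np.ndarray
    weight: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.float64)
        self.observed = np.asarray(self.observed, dtype=np.float64)
        if self.weight is None:
            self.weight = np.ones_like(self.observed)
        self.weight = np.asarray(self.weight, dtype=np.float64)
        n = len(self.x)
        if not (len(self.y) == len(self.observed) == len(self.weight) == n):
            raise ValueError("plot arrays must have equal length")
        if n and (self.observed.min() < 0 or self.observed.max() > 1):
            raise ValueError("observed values must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.x)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"x": self.x, "y": self.y,
                             "observed": self.observed, "weight": self.weight})

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ReferencePlotSet":
        return cls(df["x"].to_numpy(), df["y"].to_numpy(),
                   df["observed"].to_numpy(),
                   df["weight"].to_numpy() if "weight" in df else None)


@dataclass
class ConfusionMatrix:
    """Class-by-class table; rows = predicted class, columns = true class."""

    classes: list[int]
    table: np.ndarray  # counts or probabilities

    def __post_init__(self) -> None:
        self.table = np.asarray(self.table, dtype=np.float64)
        k = len(self.classes)
        if self.table.shape != (k, k):
            raise ValueError("confusion matrix must be square over the classes")
        if (self.table < 0).any():
            raise ValueError("confusion-matrix entries must be >= 0")

    def row_probabilities(self) -> np.ndarray:
        sums = self.table.sum(axis=1, keepdims=True)
        if (sums == 0).any():
            raise ValueError("every predicted class needs at least one count")
        return self.table / sums

    @classmethod
    def identity(cls, classes: Sequence[int]) -> "ConfusionMatrix":
        return cls(list(classes), np.eye(len(classes)))


def intensity_monte_carlo(footprints: dict[str, Layer],
                          registry: ThreatRegistry, n: int = 100,
                          seed: int | None = None,
                          subtypes: dict[str, str] | None = None,
                          ) -> tuple[Layer, Layer]:
    """Per-pixel mean and SD of cumulative H under intensity uncertainty.

    ``footprints`` maps threat codes to footprint layers; each draw samples
    every threat's intensity from Uniform(min, max) (one scalar per threat)
    and recombines with the fuzzy sum.  Degenerate min == max ranges give
    SD 0.  Deterministic under ``seed``.
    """
    if n < 2:
        raise ValueError("need at least 2 draws")
    rng = np.random.default_rng(seed)
    codes = list(footprints)
    check_aligned(*[footprints[c].grid for c in codes])
    specs = [registry.intensity(c, (subtypes or {}).get(c)) for c in codes]
    grid = footprints[codes[0]].grid
    # accumulate around the first draw (exact SD = 0 for degenerate ranges)
    shift = None
    total_d = np.zeros(grid.shape)
    total_d2 = np.zeros(grid.shape)
    for _ in range(n):
        draws = [rng.uniform(s.min, s.max) for s in specs]
        hs = [modification_from_footprint(footprints[c], d)
              for c, d in zip(codes, draws)]
        H = increasive_mean(hs).values
        if shift is None:
            shift = H.copy()
        d = H - shift
        total_d += d
        total_d2 += d ** 2
    mean = shift + total_d / n
    var = np.maximum(total_d2 / n - (total_d / n) ** 2, 0.0)
    return (Layer(grid, mean, kind="H", scope="cumulative"),
            Layer(grid, np.sqrt(var), kind="raw"))


def confusion_resample(landcover: CategoricalLayer, cm: ConfusionMatrix,
                       summarizer: Callable[[CategoricalLayer], pd.DataFrame],
                       n: int = 100, seed: int | None = None) -> pd.DataFrame:
    """Zone summaries under per-pixel class resampling from a confusion matrix.

    Each realization redraws every pixel's class from the row distribution
    of its predicted class (independent per pixel), re-runs ``summarizer``
    (which must return a table with 'zone' and 'mean' columns), and the
    realizations are reduced to per-zone mean and SD.
    """
    observed = set(landcover.classes().tolist())
    if not observed <= set(cm.classes):
        raise ValueError("confusion matrix does not cover all observed classes")
    rng = np.random.default_rng(seed)
    probs = cm.row_probabilities()
    class_arr = np.asarray(cm.classes)
    index = {c: i for i, c in enumerate(cm.classes)}
    vals = landcover.values
    valid = vals != landcover.nodata
    rows_idx = np.vectorize(index.get)(vals[valid]) if valid.any() else np.array([], int)
    results = []
    for _ in range(n):
        new = vals.copy()
        if valid.any():
            u = rng.random(rows_idx.size)
            cum = probs[rows_idx].cumsum(axis=1)
            choice = (u[:, None] > cum).sum(axis=1)
            new[valid] = class_arr[choice]
        realization = CategoricalLayer(landcover.grid, new,
                                       nodata=landcover.nodata,
                                       labels=dict(landcover.labels))
        results.append(summarizer(realization).set_index("zone")["mean"])
    frame = pd.DataFrame(results)
    return pd.DataFrame({
        "zone": frame.columns,
        "mean": frame.mean(axis=0).to_numpy(),
        "sd": frame.std(axis=0, ddof=0).to_numpy(),
    }).reset_index(drop=True)


def rmse_validation(H: Layer, plots: ReferencePlotSet) -> float:
    """Weighted root-mean-square error of H against reference plots."""
    if not len(plots):
        raise ValueError("need at least one reference plot")
    pred = np.empty(len(plots))
    for i, (x, y) in enumerate(zip(plots.x, plots.y)):
        if not H.grid.contains(x, y):
            raise ValueError(f"plot {i} at ({x}, {y}) falls outside the grid")
        r, c = H.grid.index_of(x, y)
        pred[i] = H.values[r, c]
    ok = np.isfinite(pred)
    w = plots.weight[ok]
    err = (pred[ok] - plots.observed[ok]) ** 2
    return float(np.sqrt(np.sum(w * err) / np.sum(w)))


def temporal_change_stats(series: Sequence[Layer],
                          zones: CategoricalLayer | None = None,
                          delta_threshold: float = 0.01) -> pd.DataFrame:
    """Per-zone change summary between the first and last year of a series.

    Annual rate (percent) is linear relative to the start mean:
    ``100 * ((mean_end - mean_start) / mean_start) / n_years``; the changed
    fraction is the share of valid pixels with H_end - H_start above the
    threshold.  A zero start mean leaves the rate undefined (NaN).
    """
    if len(series) < 2:
        raise ValueError("need at least two years")
    check_aligned(*[l.grid for l in series])
    first, last = series[0], series[-1]
    try:
        n_years = int(last.year) - int(first.year)
    except (TypeError, ValueError):
        n_years = len(series) - 1
    if n_years <= 0:
        raise ValueError("series years must increase")
    if zones is None:
        zvals = np.zeros(first.grid.shape, dtype=np.int64)
        zones = CategoricalLayer(first.grid, zvals, nodata=-1)
    rows = []
    for z in zones.classes():
        sel = (zones.values == z) & np.isfinite(first.values) \
            & np.isfinite(last.values)
        m0 = float(first.values[sel].mean()) if sel.any() else np.nan
        m1 = float(last.values[sel].mean()) if sel.any() else np.nan
        delta = m1 - m0
        rate = 100.0 * (delta / m0) / n_years if m0 and np.isfinite(m0) else np.nan
        changed = float(np.mean((last.values[sel] - first.values[sel])
                                > delta_threshold)) if sel.any() else np.nan
        rows.append({
            "zone": int(z),
            "start_year": first.year,
            "end_year": last.year,
            "mean_start": m0,
            "mean_end": m1,
            "delta": delta,
            "annual_rate_pct": rate,
            "changed_fraction": changed,
        })
    return pd.DataFrame(rows)


def annual_rate_pct(mean_start: float, mean_end: float, n_years: int) -> float:
    """Linear mean annual percent change relative to the start mean."""
    if mean_start == 0:
        return float("nan")
    return 100.0 * ((mean_end - mean_start) / mean_start) / n_years
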