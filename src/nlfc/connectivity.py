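"""Linear and non-linear functional-connectivity measures.

Three pairwise dependence measures between region time series:

* ``pearson_corr`` — the linear measure, rho = cov(X, Y) / (sigma_X sigma_Y);
* ``mic`` — the maximal information coefficient: the maximum over grid shapes
  (p, q) with p*q bounded by the resolution budget B = n^0.6 of the grid
  mutual information normalised by log2 min(p, q);
* ``emic`` — the non-linear residual MIC - rho^2, isolating dependence the
  linear term does not explain.  It is deliberately not clamped: small
  negative values arise at finite n when rho^2 exceeds the MIC estimate.

``fc_matrix`` assembles a symmetric region-by-region matrix of any of the
three measures for one subject.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd

from ._mine import char_matrix_search
from .cohort import RoiTimeSeries

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.6
DEFAULT_CMAX = 5

_DIAGONAL = {"pcc": 1.0, "mic": 1.0, "emic": 0.0}


class DegenerateSeriesError(ValueError):
    """Raised when a measure is undefined because a series has zero variance."""


def _validate_pair(x, y, min_n: int) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("series lengths differ")
    if x.size < min_n:
        raise ValueError(f"need at least {min_n} samples, got {x.size}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("series contain non-finite values")
    return x, y


def pearson_corr(x, y) -> float:
    """Pearson's correlation coefficient between two equal-length series."""
    x, y = _validate_pair(x, y, 2)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateSeriesError("zero-variance series in Pearson correlation")
    r = float(np.corrcoef(x, y)[0, 1])
    return float(np.clip(r, -1.0, 1.0))


def grid_mutual_information(counts) -> float:
    """Mutual information (bits) of a grid occupancy table.

    I = H(row margins) + H(column margins) - H(joint), with 0*log 0 = 0.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2:
        raise ValueError("counts must be a 2-D table")
    if np.any(counts < 0):
        raise ValueError("negative count in occupancy table")
    n = counts.sum()
    if n < 1:
        raise ValueError("occupancy table is empty")
    p = counts / n

    def _h(v: np.ndarray) -> float:
        v = v[v > 0]
        return float(-(v * np.log2(v)).sum())

    return max(0.0, _h(p.sum(axis=1)) + _h(p.sum(axis=0)) - _h(p.ravel()))


def grid_budget(n: int, alpha: float = DEFAULT_ALPHA) -> int:
    """Resolution budget B(n): floor(n^alpha), floored at 4 so a 2x2 grid
    is always admissible."""
    return max(int(math.floor(n**alpha)), 4)


@dataclasses.dataclass
class CharacteristicMatrix:
    """Normalised maximal grid mutual information per grid shape.

    ``values[p, q]`` holds m_{p x q} for admissible shapes (2 <= p, q and
    p*q <= B); inadmissible or unvisited shapes are NaN.
    """

    values: np.ndarray
    b: int
    n: int

    def max(self) -> float:
        if np.all(np.isnan(self.values)):
            return 0.0
        return float(np.nanmax(self.values))


def characteristic_matrix(
    x, y, alpha: float = DEFAULT_ALPHA, cmax: int = DEFAULT_CMAX
) -> CharacteristicMatrix:
    """Heuristic characteristic matrix of two series.

    Requires n >= 8.  Degenerate (constant) input is legal here and simply
    yields zero entries, since no grid carries information.
    """
    x, y = _validate_pair(x, y, 8)
    b = grid_budget(x.size, alpha)
    m = char_matrix_search(x, y, b, int(cmax))
    vals = np.where(m < 0, np.nan, np.clip(m, 0.0, 1.0))
    return CharacteristicMatrix(values=vals, b=b, n=x.size)


def mic(x, y, alpha: float = DEFAULT_ALPHA, cmax: int = DEFAULT_CMAX) -> float:
    """Maximal information coefficient of two series, in [0, 1]."""
    return characteristic_matrix(x, y, alpha, cmax).max()


def brute_force_mic(x, y, alpha: float = DEFAULT_ALPHA) -> float:
    """Exact MIC by exhaustive enumeration of every admissible grid.

    Only feasible for n <= 12; this is the independent oracle that bounds
    the heuristic search from above.
    """
    x, y = _validate_pair(x, y, 8)
    n = x.size
    if n > 12:
        raise ValueError("brute-force enumeration refused for n > 12")
    b = grid_budget(n, alpha)

    def _cuts(v: np.ndarray) -> np.ndarray:
        u = np.unique(v)
        return (u[:-1] + u[1:]) / 2.0  # legal cut positions, between values

    cx, cy = _cuts(x), _cuts(y)
    best = 0.0
    for p in range(2, b // 2 + 1):
        for q in range(2, b // p + 1):
            if p - 1 > cx.size or q - 1 > cy.size:
                continue
            denom = math.log2(min(p, q))
            for xc in itertools.combinations(cx, p - 1):
                xi = np.searchsorted(np.array(xc), x)
                for yc in itertools.combinations(cy, q - 1):
                    yi = np.searchsorted(np.array(yc), y)
                    counts = np.zeros((p, q))
                    np.add.at(counts, (xi, yi), 1.0)
                    best = max(best, grid_mutual_information(counts) / denom)
    return best


def emic(x, y, alpha: float = DEFAULT_ALPHA, cmax: int = DEFAULT_CMAX) -> float:
    """Non-linear dependence: MIC minus squared Pearson correlation."""
    return mic(x, y, alpha, cmax) - pearson_corr(x, y) ** 2


@dataclasses.dataclass
class ConnectivityMatrix:
    """Symmetric region-by-region functional-connectivity matrix."""

    method: str  # "pcc" | "mic" | "emic"
    values: np.ndarray  # (R, R)
    region_labels: list[str]

    def to_csv(self, path: str | Path, **meta) -> None:
        path = Path(path)
        df = pd.DataFrame(
            self.values,
            index=pd.Index(self.region_labels, name="region"),
            columns=self.region_labels,
        )
        df.to_csv(path)
        sidecar = {"method": self.method, **meta}
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(sidecar, indent=2, sort_keys=True)
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "ConnectivityMatrix":
        path = Path(path)
        df = pd.read_csv(path, index_col=0, float_precision="round_trip")
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        return cls(meta["method"], df.to_numpy(), [str(c) for c in df.index])


def fc_matrix(
    ts: RoiTimeSeries,
    method: str,
    alpha: float = DEFAULT_ALPHA,
    cmax: int = DEFAULT_CMAX,
) -> ConnectivityMatrix:
    """Per-subject connectivity matrix under one measure.

    Each unordered pair is computed once and mirrored.  A zero-variance
    region cannot abort a cohort run: its Pearson term is substituted by 0
    with a logged warning (MIC of a constant series is 0 by construction).
    """
    if method not in _DIAGONAL:
        raise ValueError(f"unknown method {method!r}; expected pcc, mic or emic")
    r = ts.n_regions
    flat = np.ptp(ts.values, axis=1) == 0
    for idx in np.flatnonzero(flat):
        logger.warning(
            "subject %s: region %s has zero variance; Pearson term set to 0",
            ts.subject_id,
            ts.region_labels[idx],
        )
    out = np.full((r, r), _DIAGONAL[method])
    for i in range(r):
        for j in range(i + 1, r):
            xi, xj = ts.values[i], ts.values[j]
            degenerate = flat[i] or flat[j]
            if method == "pcc":
                v = 0.0 if degenerate else pearson_corr(xi, xj)
            elif method == "mic":
                v = mic(xi, xj, alpha, cmax)
            else:
                rho = 0.0 if degenerate else pearson_corr(xi, xj)
                v = mic(xi, xj, alpha, cmax) - rho**2
            out[i, j] = out[j, i] = v
    return ConnectivityMatrix(method, out, list(ts.region_labels))
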