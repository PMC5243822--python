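"""Between-group feature discrepancy ranking and selection.

Connectivity features are the R(R-1)/2 upper-triangle entries of a
subject's connectivity matrix.  For a two-group contrast, each feature is
scored with the cross-group Kendall statistic

    tau = (n_c - n_d) / (m * n)

where the m*n pairs are one subject from each group, a pair is concordant
when the feature value ordering matches the group-code ordering (codes run
CN=1 < MCI=2 < dementia=3, so positive tau means the feature increases with
impairment), and ties count as neither.  Features are ranked by |tau| and
the top fraction (default 1%, ceiling rounding: 6,670 features -> 67)
becomes the classifier's selection budget.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from .connectivity import ConnectivityMatrix


def n_features(r: int) -> int:
    """Number of non-redundant region pairs at R regions."""
    return r * (r - 1) // 2


def feature_index(i: int, j: int, r: int) -> int:
    """Row-major upper-triangle index of pair (i, j), i < j, 0-based."""
    if not 0 <= i < j < r:
        raise ValueError(f"need 0 <= i < j < R, got ({i}, {j}) at R={r}")
    return i * r - i * (i + 1) // 2 + (j - i - 1)


def feature_pairs(r: int) -> np.ndarray:
    """(N, 2) array of region index pairs in feature order."""
    iu = np.triu_indices(r, k=1)
    return np.column_stack(iu)


def features_from_matrix(conn: ConnectivityMatrix) -> np.ndarray:
    """Vectorise a connectivity matrix into its feature vector."""
    r = conn.values.shape[0]
    iu = np.triu_indices(r, k=1)
    return conn.values[iu]


def between_group_tau(values_a, values_b) -> float:
    """Cross-group Kendall statistic for one feature.

    ``values_a`` comes from the group with the smaller code.  Over all
    m*n cross pairs: concordant when the group-B value is larger (feature
    ordering matches group ordering), discordant when smaller, ties neither.
    """
    a = np.asarray(values_a, dtype=float).ravel()
    b = np.asarray(values_b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    s = np.sign(b[None, :] - a[:, None])
    return float(s.sum() / (a.size * b.size))


@dataclasses.dataclass
class DiscrepancyTable:
    """Per-feature tau for one contrast, with |tau| ranking and selection."""

    contrast: tuple[int, int]  # group codes, lower first
    tau: np.ndarray
    ranking: np.ndarray  # feature indices, |tau| descending, ties by index
    selected: np.ndarray  # prefix of ranking

    def to_frame(self, region_labels: list[str] | None = None) -> pd.DataFrame:
        n = self.tau.size
        r = int(round((1 + np.sqrt(1 + 8 * n)) / 2))
        pairs = feature_pairs(r)
        rank_of = np.empty(n, dtype=int)
        rank_of[self.ranking] = np.arange(1, n + 1)
        sel = np.zeros(n, dtype=bool)
        sel[self.selected] = True
        lab = region_labels or [f"R{k:03d}" for k in range(r)]
        return pd.DataFrame(
            {
                "feature": np.arange(n),
                "region_i": [lab[i] for i in pairs[:, 0]],
                "region_j": [lab[j] for j in pairs[:, 1]],
                "tau": self.tau,
                "abs_tau_rank": rank_of,
                "selected": sel,
            }
        )

    def to_csv(self, path: str | Path, region_labels: list[str] | None = None) -> None:
        self.to_frame(region_labels).to_csv(Path(path), index=False)


def rank_features(
    features: np.ndarray, group_codes, contrast: tuple[int, int] | None = None
) -> DiscrepancyTable:
    """Score and rank every feature for one two-group contrast.

    ``features`` is subjects x N; ``group_codes`` the per-subject codes.
    Ranking is by |tau| descending with ties broken by ascending feature
    index (stable sort on the negated magnitude).
    """
    features = np.asarray(features, dtype=float)
    codes = np.asarray(group_codes, dtype=int)
    if features.ndim != 2 or features.shape[0] != codes.size:
        raise ValueError("features must be subjects x N, aligned with group_codes")
    present = np.unique(codes)
    if contrast is None:
        if present.size != 2:
            raise ValueError("group_codes must contain exactly two groups")
        contrast = (int(present[0]), int(present[1]))
    lo, hi = contrast
    if lo >= hi:
        raise ValueError("contrast must be ordered (lower code first)")
    mask_a, mask_b = codes == lo, codes == hi
    if mask_a.sum() < 2 or mask_b.sum() < 2:
        raise ValueError("need at least 2 subjects in each group")
    fa, fb = features[mask_a], features[mask_b]  # (m, N), (n, N)
    s = np.sign(fb[None, :, :] - fa[:, None, :])  # (m, n, N)
    tau = s.sum(axis=(0, 1)) / (fa.shape[0] * fb.shape[0])
    ranking = np.argsort(-np.abs(tau), kind="stable")
    return DiscrepancyTable(contrast, tau, ranking, ranking[:0].copy())


def select_top_fraction(table: DiscrepancyTable, fraction: float = 0.01) -> np.ndarray:
    """Select the ceil(fraction * N) top-ranked features."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    k = int(np.ceil(fraction * table.tau.size))
    table.selected = table.ranking[:k].copy()
    return table.selected


def significant_rois(
    selected,
    r: int,
    region_labels: list[str] | None = None,
    top_k: int = 4,
) -> tuple[list[str], pd.DataFrame]:
    """Regions of highest degree in the selected-edge graph.

    Returns the ``top_k`` region names (degree descending, ties by
    ascending region index) together with the full edge list.
    """
    selected = np.asarray(selected, dtype=int)
    if selected.size == 0:
        raise ValueError("empty selection")
    pairs = feature_pairs(r)[selected]
    degree = np.zeros(r, dtype=int)
    np.add.at(degree, pairs[:, 0], 1)
    np.add.at(degree, pairs[:, 1], 1)
    lab = region_labels or [f"R{k:03d}" for k in range(r)]
    order = np.argsort(-degree, kind="stable")
    top = [lab[i] for i in order[:top_k]]
    edges = pd.DataFrame(
        {
            "region_i": [lab[i] for i in pairs[:, 0]],
            "region_j": [lab[j] for j in pairs[:, 1]],
        }
    )
    return top, edges
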