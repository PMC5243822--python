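"""Core cohort containers and their delimited-text serialisation.

A subject is an ROI-by-time matrix (region-averaged BOLD-like signal); a
cohort bundles subjects with cognitive group, MMSE, age and sex.  Cognitive
groups follow the MMSE screening convention: 28-30 cognitively normal (CN,
code 1), 23-27 mild cognitive impairment (MCI, code 2), below 23 dementia
(code 3).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

GROUP_NAMES = {1: "CN", 2: "MCI", 3: "dementia"}
GROUP_CODES = {v: k for k, v in GROUP_NAMES.items()}


def classify_mmse(score: int) -> int:
    """Map an MMSE score (0-30) to a cognitive group code.

    28-30 -> 1 (CN), 23-27 -> 2 (MCI), < 23 -> 3 (dementia).
    """
    if not 0 <= score <= 30:
        raise ValueError(f"MMSE score must lie in 0..30, got {score}")
    if score >= 28:
        return 1
    if score >= 23:
        return 2
    return 3


@dataclasses.dataclass
class RoiTimeSeries:
    """One subject's region-by-time signal matrix."""

    subject_id: str
    values: np.ndarray  # shape (R, T)
    region_labels: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D region-by-time matrix")
        r, t = self.values.shape
        if r < 2 or t < 8:
            raise ValueError(f"need R >= 2 regions and T >= 8 time points, got {r}x{t}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"non-finite values in subject {self.subject_id}")
        if len(self.region_labels) != r:
            raise ValueError("region_labels length must equal the number of rows")

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]


@dataclasses.dataclass
class Subject:
    series: RoiTimeSeries
    group_code: int
    mmse: int
    age: float
    sex: str  # "F" | "M"


@dataclasses.dataclass
class CohortSample:
    """An ordered collection of subjects sharing a parcellation."""

    subjects: list[Subject]

    def __post_init__(self) -> None:
        if not self.subjects:
            raise ValueError("cohort is empty")
        labels = self.subjects[0].series.region_labels
        for s in self.subjects:
            if s.series.region_labels != labels:
                raise ValueError(
                    f"subject {s.series.subject_id} has mismatching region labels"
                )

    @property
    def region_labels(self) -> list[str]:
        return self.subjects[0].series.region_labels

    @property
    def n_regions(self) -> int:
        return self.subjects[0].series.n_regions

    def group_codes(self) -> np.ndarray:
        return np.array([s.group_code for s in self.subjects], dtype=int)

    def mmse_scores(self) -> np.ndarray:
        return np.array([s.mmse for s in self.subjects], dtype=int)

    def subset(self, codes: Sequence[int]) -> "CohortSample":
        keep = [s for s in self.subjects if s.group_code in set(codes)]
        return CohortSample(keep)

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": [s.series.subject_id for s in self.subjects],
                "group": [GROUP_NAMES[s.group_code] for s in self.subjects],
                "mmse": [s.mmse for s in self.subjects],
                "age": [s.age for s in self.subjects],
                "sex": [s.sex for s in self.subjects],
            }
        )


def write_cohort(cohort: CohortSample, out_dir: str | Path) -> Path:
    """Write one TSV matrix per subject plus a cohort table CSV.

    Each matrix is regions x time with a header row of time indices and the
    region labels in the first column.  Returns the cohort-table path.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in cohort.subjects:
        path = out / f"{s.series.subject_id}.tsv"
        df = pd.DataFrame(
            s.series.values,
            index=pd.Index(s.series.region_labels, name="region"),
            columns=[f"t{t}" for t in range(s.series.n_timepoints)],
        )
        df.to_csv(path, sep="\t")
        rows.append(
            {
                "subject_id": s.series.subject_id,
                "group": GROUP_NAMES[s.group_code],
                "mmse": s.mmse,
                "age": s.age,
                "sex": s.sex,
                "path": path.name,
            }
        )
    table_path = out / "cohort.csv"
    pd.DataFrame(rows).to_csv(table_path, index=False)
    return table_path


def read_cohort(table_path: str | Path) -> CohortSample:
    """Load a cohort written by :func:`write_cohort` (or hand-assembled).

    The ``group`` column may be absent, in which case codes are derived from
    MMSE via :func:`classify_mmse`.
    """
    table_path = Path(table_path)
    base = table_path.parent
    df = pd.read_csv(table_path)
    subjects: list[Subject] = []
    shared_r: int | None = None
    for rec in df.to_dict("records"):
        sid = str(rec["subject_id"])
        path = base / str(rec["path"])
        if not path.exists():
            raise FileNotFoundError(f"matrix file for subject {sid} not found: {path}")
        mat = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
        series = RoiTimeSeries(sid, mat.to_numpy(), [str(x) for x in mat.index])
        if shared_r is None:
            shared_r = series.n_regions
        elif series.n_regions != shared_r:
            raise ValueError(
                f"subject {sid} has {series.n_regions} regions, expected {shared_r}"
            )
        mmse = int(rec["mmse"])
        if "group" in rec and not pd.isna(rec["group"]):
            g = rec["group"]
            code = GROUP_CODES[g] if isinstance(g, str) else int(g)
        else:
            code = classify_mmse(mmse)
        subjects.append(
            Subject(series, code, mmse, float(rec.get("age", np.nan)), str(rec.get("sex", "")))
        )
    return CohortSample(subjects)
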