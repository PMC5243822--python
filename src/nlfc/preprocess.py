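"""Resting-state preprocessing steps kept in scope: volume discard and
parcellation averaging.  Registration, slice timing and smoothing are
assumed done upstream."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .cohort import RoiTimeSeries


def discard_initial_volumes(series: np.ndarray, n_discard: int, time_axis: int = -1) -> np.ndarray:
    """Drop the first ``n_discard`` volumes along ``time_axis``.

    The opening volumes of a resting-state run are conventionally discarded
    to let the signal reach steady state (240 acquired -> 230 retained with
    the usual 10-volume discard).
    """
    series = np.asarray(series)
    length = series.shape[time_axis]
    if n_discard < 0:
        raise ValueError("n_discard must be non-negative")
    if n_discard >= length:
        raise ValueError(f"discarding {n_discard} of {length} volumes leaves nothing")
    index = [slice(None)] * series.ndim
    index[time_axis] = slice(n_discard, None)
    return series[tuple(index)]


def parcellation_average(
    volume_series: np.ndarray,
    labels: np.ndarray,
    region_ids,
    subject_id: str = "subject",
) -> RoiTimeSeries:
    """Average a 4-D (x, y, z, t) intensity array over an integer label
    volume, one row per requested region id."""
    volume_series = np.asarray(volume_series, dtype=float)
    labels = np.asarray(labels)
    if volume_series.ndim != 4:
        raise ValueError("volume_series must be 4-D (x, y, z, t)")
    if labels.shape != volume_series.shape[:3]:
        raise ValueError("label volume shape must match a single volume's spatial shape")
    t = volume_series.shape[3]
    flat = volume_series.reshape(-1, t)
    flat_labels = labels.ravel()
    rows = np.empty((len(region_ids), t))
    for r, rid in enumerate(region_ids):
        mask = flat_labels == rid
        if not mask.any():
            raise ValueError(f"region id {rid} absent from the label volume")
        rows[r] = flat[mask].mean(axis=0)
    return RoiTimeSeries(subject_id, rows, [str(r) for r in region_ids])


def load_nifti_pair(volume_path: str | Path, labels_path: str | Path):
    """Read a 4-D NIfTI series and a 3-D integer label volume."""
    import nibabel as nib

    vol = np.asarray(nib.load(str(volume_path)).dataobj, dtype=float)
    lab = np.asarray(nib.load(str(labels_path)).dataobj)
    return vol, np.rint(lab).astype(int)
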