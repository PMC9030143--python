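"""ROI time series, framewise-displacement QC, and functional-connectivity matrices.

A subject's resting-state scan, after standard upstream preprocessing
(slice timing, realignment, normalisation, detrending, filtering, nuisance
regression — all assumed done), is reduced to a T x R matrix of ROI-averaged
signals. Whole-brain functional connectivity is the R x R matrix of pairwise
Pearson correlations between ROI signals:

    rho(X, Y) = Cov(X, Y) / (sigma_X sigma_Y) = E[(X - mu_X)(Y - mu_Y)] / (sigma_X sigma_Y)

Population (divide-by-T) moments are used throughout; the ratio rho is
unaffected by the convention, but intermediate covariances are documented this
way for anyone comparing them. The diagonal is set to the constant 1 rather
than computed, and entries are clamped to [-1, 1] after floating-point
rounding, so every emitted matrix satisfies the FCMatrix invariants exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

TIMEPOINTS = ("BL", "12m", "24m")

__all__ = [
    "TIMEPOINTS",
    "ROITimeSeries",
    "FCMatrix",
    "FDTrace",
    "AtlasVolume",
    "FDDecision",
    "extract_roi_timeseries",
    "pearson_fc",
    "fd_exclude",
    "load_image4d",
    "load_atlas",
    "read_series_tsv",
    "write_series_tsv",
    "read_fc_tsv",
    "write_fc_tsv",
    "read_fd_trace",
]


@dataclass
class ROITimeSeries:
    """ROI-averaged signal, T frames x R regions.

    ``values[t, r]`` is the mean signal of region ``r+1`` at frame ``t``.
    """

    values: np.ndarray
    frame_period: float = 3.0
    subject_id: str = ""
    timepoint: str = "BL"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("ROI time series must be a 2D (frames x regions) array")
        t, r = self.values.shape
        if t < 3:
            raise ValueError(f"need at least 3 frames for a nondegenerate correlation, got {t}")
        if r < 2:
            raise ValueError(f"need at least 2 regions, got {r}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("ROI time series contains non-finite values")
        if self.timepoint not in TIMEPOINTS:
            raise ValueError(f"timepoint must be one of {TIMEPOINTS}, got {self.timepoint!r}")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_rois(self) -> int:
        return self.values.shape[1]


@dataclass
class FCMatrix:
    """Symmetric unit-diagonal correlation matrix over R regions."""

    values: np.ndarray
    subject_id: str = ""
    timepoint: str = "BL"
    provenance: str = "real"  # "real" or "synthetic"; tracked to keep CV folds leak-free

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.validate()

    def validate(self) -> None:
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("FC matrix must be square")
        if v.shape[0] < 2:
            raise ValueError("FC matrix needs at least 2 regions")
        if not np.all(np.isfinite(v)):
            raise ValueError("FC matrix contains non-finite values")
        if np.abs(v - v.T).max() > 1e-12:
            raise ValueError("FC matrix is not symmetric to within 1e-12")
        if np.any(np.diag(v) != 1.0):
            raise ValueError("FC matrix diagonal must be exactly 1")
        if v.min() < -1.0 or v.max() > 1.0:
            raise ValueError("FC matrix entries must lie in [-1, 1]")

    @property
    def roi_count(self) -> int:
        return self.values.shape[0]

    def upper_triangle(self) -> np.ndarray:
        """Strict upper triangle, row-major — the classifier's feature vector."""
        r = self.roi_count
        return self.values[np.triu_indices(r, k=1)]


@dataclass
class FDTrace:
    """Per-frame framewise displacement magnitudes in mm."""

    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64).ravel()
        if self.values.size == 0:
            raise ValueError("FD trace is empty")
        if not np.all(np.isfinite(self.values)) or self.values.min() < 0:
            raise ValueError("FD values must be finite and non-negative")


@dataclass
class AtlasVolume:
    """Integer label volume; region ids 1..R, 0 = background."""

    labels: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            if not np.all(self.labels == np.round(self.labels)):
                raise ValueError("atlas labels must be integers")
            self.labels = self.labels.astype(np.int64)
        if self.labels.min() < 0:
            raise ValueError("atlas labels must be non-negative")
        r = int(self.labels.max())
        if r < 2:
            raise ValueError("atlas must define at least 2 regions")
        present = np.unique(self.labels)
        missing = sorted(set(range(1, r + 1)) - set(present.tolist()))
        if missing:
            raise ValueError(f"atlas regions with zero voxels: {missing}")

    @property
    def n_regions(self) -> int:
        return int(self.labels.max())


@dataclass(frozen=True)
class FDDecision:
    exclude: bool
    bad_frames: int


def extract_roi_timeseries(image4d: np.ndarray, atlas: AtlasVolume,
                           drop_leading: int = 10, *, frame_period: float = 3.0,
                           subject_id: str = "", timepoint: str = "BL") -> ROITimeSeries:
    """Average voxels within each atlas region, after dropping leading frames.

    ``image4d`` is (T, X, Y, Z); the first ``drop_leading`` frames (scanner
    stabilisation) are discarded before averaging.
    """
    image4d = np.asarray(image4d, dtype=np.float64)
    if image4d.ndim != 4:
        raise ValueError("image must be 4D (frames, x, y, z)")
    if image4d.shape[1:] != atlas.labels.shape:
        raise ValueError(
            f"image spatial grid {image4d.shape[1:]} does not match atlas grid {atlas.labels.shape}")
    if drop_leading < 0:
        raise ValueError("drop_leading must be non-negative")
    t_total = image4d.shape[0]
    if drop_leading >= t_total:
        raise ValueError(f"drop_leading={drop_leading} >= number of frames {t_total}")
    frames = image4d[drop_leading:].reshape(t_total - drop_leading, -1)
    flat_labels = atlas.labels.ravel()
    r = atlas.n_regions
    # labelled mean per frame via one bincount-style matmul
    series = np.empty((frames.shape[0], r))
    for region in range(1, r + 1):
        mask = flat_labels == region
        series[:, region - 1] = frames[:, mask].mean(axis=1)
    return ROITimeSeries(series, frame_period=frame_period,
                         subject_id=subject_id, timepoint=timepoint)


def pearson_fc(series: ROITimeSeries) -> FCMatrix:
    """Pairwise Pearson correlation between ROI signals.

    Zero-variance columns cannot be correlated; their off-diagonal entries are
    set to 0 with a warning rather than propagating a division by zero.
    """
    x = series.values
    t, r = x.shape
    centered = x - x.mean(axis=0)
    cov = centered.T @ centered / t  # population convention
    sd = np.sqrt(np.diag(cov))
    degenerate = sd == 0.0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} zero-variance ROI column(s); their correlations are set to 0",
            stacklevel=2)
    safe_sd = np.where(degenerate, 1.0, sd)
    corr = cov / np.outer(safe_sd, safe_sd)
    corr[degenerate, :] = 0.0
    corr[:, degenerate] = 0.0
    corr = (corr + corr.T) / 2.0
    np.clip(corr, -1.0, 1.0, out=corr)
    np.fill_diagonal(corr, 1.0)
    return FCMatrix(corr, subject_id=series.subject_id, timepoint=series.timepoint)


def fd_exclude(trace: FDTrace, fd_threshold: float = 0.5,
               max_bad_frames: int = 50) -> FDDecision:
    """Motion QC: exclude a scan when more than ``max_bad_frames`` frames have
    FD strictly above ``fd_threshold`` (default 0.5 mm over 50 frames = 2.5 min
    at a 3 s frame period)."""
    bad = int(np.sum(trace.values > fd_threshold))
    return FDDecision(exclude=bad > max_bad_frames, bad_frames=bad)


# ---------------------------------------------------------------------------
# IO


def load_image4d(path: str | Path) -> np.ndarray:
    """Read a 4D NIfTI, returning (T, X, Y, Z)."""
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4D image, got shape {data.shape}")
    return np.moveaxis(data, -1, 0)  # NIfTI stores time last


def load_atlas(path: str | Path) -> AtlasVolume:
    import nibabel as nib

    img = nib.load(str(path))
    return AtlasVolume(np.asarray(img.dataobj))


def _roi_columns(r: int) -> list[str]:
    return [f"ROI_{i + 1}" for i in range(r)]


def write_series_tsv(series: ROITimeSeries, path: str | Path) -> None:
    df = pd.DataFrame(series.values, columns=_roi_columns(series.n_rois))
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_series_tsv(path: str | Path, *, frame_period: float = 3.0,
                    subject_id: str = "", timepoint: str = "BL") -> ROITimeSeries:
    df = pd.read_csv(path, sep="\t")
    return ROITimeSeries(df.to_numpy(dtype=np.float64), frame_period=frame_period,
                         subject_id=subject_id, timepoint=timepoint)


def write_fc_tsv(fc: FCMatrix, path: str | Path) -> None:
    cols = _roi_columns(fc.roi_count)
    pd.DataFrame(fc.values, columns=cols).to_csv(path, sep="\t", index=False,
                                                 float_format="%.17g")


def read_fc_tsv(path: str | Path, *, subject_id: str = "",
                timepoint: str = "BL") -> FCMatrix:
    df = pd.read_csv(path, sep="\t")
    return FCMatrix(df.to_numpy(dtype=np.float64), subject_id=subject_id,
                    timepoint=timepoint)


def read_fd_trace(path: str | Path) -> FDTrace:
    vals = np.loadtxt(path, ndmin=1)
    return FDTrace(vals)
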