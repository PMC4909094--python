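"""Functional connectome construction from regional BOLD time series.

Pipeline: ordinary-least-squares nuisance regression (6 motion parameters,
CSF, WM and — by default — the global mean signal), then an undecimated
wavelet decomposition per region keeping the scale-2 detail coefficients,
then Pearson correlation between regional coefficient series. For TR = 3.6 s
scale 2 isolates fluctuations in roughly the 0.03–0.07 Hz band
([1/(2^3 TR), 1/(2^2 TR)] = [0.035, 0.069] Hz).

Motion quality control follows the Power convention: framewise displacement
FD_t = sum of absolute translation deltas (mm) + 50 mm * sum of absolute
rotation deltas (radians); DVARS_t = RMS over regions of the frame-to-frame
signal change.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt

from .io import ConnectivityMatrix

WAVELET = "sym4"  # Daubechies least-asymmetric, filter length 8 (LA8)
HEAD_RADIUS_MM = 50.0

__all__ = ["RegionalTimeSeries", "MotionQC", "regress_nuisance", "wavelet_fc", "motion_qc",
           "scale2_band_hz"]


@dataclass
class RegionalTimeSeries:
    """T x N regional BOLD series with repetition time and T x K confounds."""

    data: np.ndarray
    tr: float
    confounds: np.ndarray = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be T x N")
        if self.data.shape[0] <= 32:
            raise ValueError(f"need T > 32 samples, got {self.data.shape[0]}")
        if np.isnan(self.data).any():
            raise ValueError("time series contains NaNs")
        if self.confounds is not None:
            self.confounds = np.asarray(self.confounds, dtype=float)
            if self.confounds.shape[0] != self.data.shape[0]:
                raise ValueError("confounds and data length mismatch")


@dataclass
class MotionQC:
    fd: np.ndarray
    dvars: np.ndarray
    mean_fd: float
    mean_dvars: float


def scale2_band_hz(tr: float) -> tuple:
    """Nominal frequency band of wavelet scale 2: [1/(8 TR), 1/(4 TR)] Hz."""
    return (1.0 / (8.0 * tr), 1.0 / (4.0 * tr))


def regress_nuisance(ts: RegionalTimeSeries, include_global: bool = True) -> RegionalTimeSeries:
    """OLS residuals of each region on [intercept | confounds].

    Residuals are orthogonal to every confound column. Idempotent: regressing
    the residuals again returns them unchanged.
    """
    conf = ts.confounds if ts.confounds is not None else np.empty((ts.data.shape[0], 0))
    if not include_global and conf.shape[1] >= 9:
        conf = conf[:, :-1]  # global mean is the last channel by convention
    design = np.column_stack([np.ones(conf.shape[0]), conf])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify columns whose removal restores full rank
        bad = [k for k in range(conf.shape[1])
               if np.linalg.matrix_rank(np.delete(design, k + 1, axis=1)) == rank]
        raise ValueError(f"rank-deficient confounds; collinear columns: {bad}")
    beta, *_ = np.linalg.lstsq(design, ts.data, rcond=None)
    resid = ts.data - design @ beta
    return RegionalTimeSeries(resid, ts.tr, ts.confounds)


def wavelet_scale2(data: np.ndarray) -> np.ndarray:
    """Scale-2 detail coefficients of the undecimated wavelet transform.

    The series is trimmed to a multiple of 4 samples (periodic boundary
    handling; boundary coefficients retained).
    """
    T = data.shape[0]
    if T < 64:
        raise ValueError(f"need T >= 64 for a 2-level decomposition, got {T}")
    T4 = (T // 4) * 4
    x = data[:T4]
    coeffs = pywt.swt(x, WAVELET, level=2, axis=0, norm=True, trim_approx=True)
    return coeffs[1]  # [cA2, cD2, cD1]


def wavelet_fc(ts: RegionalTimeSeries) -> ConnectivityMatrix:
    """Pearson correlation between regional scale-2 wavelet coefficient series."""
    if ts.tr <= 0:
        raise ValueError("tr must be positive")
    d2 = wavelet_scale2(ts.data)
    fc = np.corrcoef(d2.T)
    fc = np.clip((fc + fc.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(fc, 1.0)
    return ConnectivityMatrix(fc, kind="correlation")


def motion_qc(motion_params: np.ndarray, data: np.ndarray) -> MotionQC:
    """FD (Power convention) and DVARS; frame 0 of each is defined as 0."""
    mp = np.asarray(motion_params, dtype=float)
    if mp.ndim != 2 or mp.shape[1] != 6:
        raise ValueError(f"motion parameters must be T x 6, got {mp.shape}")
    d = np.abs(np.diff(mp, axis=0))
    fd = np.concatenate([[0.0], d[:, :3].sum(axis=1) + HEAD_RADIUS_MM * d[:, 3:].sum(axis=1)])
    dd = np.diff(np.asarray(data, dtype=float), axis=0)
    dvars = np.concatenate([[0.0], np.sqrt(np.mean(dd ** 2, axis=1))])
    return MotionQC(fd, dvars, float(fd.mean()), float(dvars.mean()))
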