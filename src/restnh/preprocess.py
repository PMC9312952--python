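"""Temporal preprocessing of a BOLD series.

Chain (in run order): discard leading volumes -> nuisance regression
(intercept, linear trend, Friston-24 motion expansion, WM, CSF) -> two
branches:

* NH branch: ideal band-pass + motion scrubbing, **no** series smoothing —
  network homogeneity is computed on unsmoothed series (the map gets its own
  4 mm mask-renormalized smoothing later); smoothing a series whose regions
  are comparable in size to the kernel saturates within-region correlations
  and destroys sensitivity to coupling differences.
* fALFF branch: spatial Gaussian smoothing + scrubbing, no band-pass — the
  band/total amplitude ratio is undefined on data already restricted to the
  band.

Because the nuisance design is identical at every voxel, per-voxel OLS
regression, band-pass filtering, volume deletion and spatial smoothing are
linear operators acting on disjoint axes: smoothing before or after
regression gives identical output, so the branch order above is exact, not an
approximation.

Framewise displacement is the Power convention: sum of absolute translation
deltas plus the arc length of absolute rotation deltas on a 50 mm sphere; the
first retained volume is defined as 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .io import BoldSeries, MotionParams, NetworkMask

__all__ = [
    "PreprocessConfig",
    "FdSeries",
    "compute_fd",
    "friston24",
    "regress_nuisance",
    "bandpass",
    "smooth_volume",
    "scrub",
    "run_preprocess",
    "PreprocessResult",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class PreprocessConfig:
    n_discard: int = 10
    band_hz: tuple[float, float] = (0.01, 0.08)
    smooth_fwhm_mm: float = 8.0
    fd_threshold_mm: float = 0.2
    fd_sphere_radius_mm: float = 50.0
    use_friston24: bool = True
    scrub_mode: str = "delete"  # or "censor-in-regression"
    smooth_nh_input: bool = False  # literal-listing mode: smooth the NH series too

    def __post_init__(self) -> None:
        if self.n_discard < 0:
            raise ValueError("n_discard must be nonnegative")
        lo, hi = self.band_hz
        if not 0 < lo < hi:
            raise ValueError(f"invalid band: {self.band_hz}")
        if self.fd_threshold_mm <= 0 or self.fd_sphere_radius_mm <= 0:
            raise ValueError("FD threshold and sphere radius must be positive")
        if self.scrub_mode not in ("delete", "censor-in-regression"):
            raise ValueError(f"unknown scrub_mode: {self.scrub_mode!r}")


@dataclass
class FdSeries:
    """Per-volume framewise displacement with scrub bookkeeping."""

    fd_mm: np.ndarray
    censored_indices: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.fd_mm = np.asarray(self.fd_mm, dtype=float)
        if np.any(self.fd_mm < 0):
            raise ValueError("FD values must be nonnegative")
        bad = [i for i in self.censored_indices if not 0 <= i < self.fd_mm.size]
        if bad:
            raise ValueError(f"censored indices out of range: {bad}")

    @property
    def mean_fd_mm(self) -> float:
        return float(self.fd_mm.mean())


def compute_fd(motion: MotionParams, sphere_radius_mm: float = 50.0) -> FdSeries:
    """Power-style framewise displacement.

    FD_t = sum_i |d trans_i| + r * sum_i |d rot_i| with rotations in radians
    converted to arc length on a sphere of radius r (default 50 mm); FD of the
    first volume is 0.
    """
    if motion.n_volumes < 2:
        raise ValueError("need at least 2 volumes to compute FD")
    dt = np.abs(np.diff(motion.translations_mm, axis=0)).sum(axis=1)
    dr = np.abs(np.diff(motion.rotations_rad, axis=0)).sum(axis=1)
    fd = np.concatenate([[0.0], dt + sphere_radius_mm * dr])
    return FdSeries(fd_mm=fd)


def friston24(motion: MotionParams) -> np.ndarray:
    """Friston 24-parameter expansion: the 6 rigid-body parameters, their
    one-volume lags (first row zero-padded), and the squares of both."""
    p6 = np.hstack([motion.translations_mm, motion.rotations_rad])
    lag = np.vstack([np.zeros((1, 6)), p6[:-1]])
    return np.hstack([p6, lag, p6**2, lag**2])


def _design_matrix(
    n_vols: int,
    motion: MotionParams | None,
    wm: np.ndarray | None,
    csf: np.ndarray | None,
    config: PreprocessConfig,
    spike_indices: Sequence[int] = (),
) -> tuple[np.ndarray, list[str]]:
    cols: list[np.ndarray] = [np.ones(n_vols)]
    names: list[str] = ["intercept"]
    trend = np.linspace(-1.0, 1.0, n_vols)
    cols.append(trend)
    names.append("trend")
    if motion is not None:
        if motion.n_volumes != n_vols:
            raise ValueError(
                f"motion rows ({motion.n_volumes}) != retained volumes ({n_vols})"
            )
        if config.use_friston24:
            mot = friston24(motion)
            mot_names = (
                [f"mot{i + 1}" for i in range(6)]
                + [f"mot{i + 1}_lag" for i in range(6)]
                + [f"mot{i + 1}_sq" for i in range(6)]
                + [f"mot{i + 1}_lag_sq" for i in range(6)]
            )
        else:
            mot = np.hstack([motion.translations_mm, motion.rotations_rad])
            mot_names = [f"mot{i + 1}" for i in range(6)]
        cols.extend(mot.T)
        names.extend(mot_names)
    for sig, name in ((wm, "wm"), (csf, "csf")):
        if sig is not None:
            sig = np.asarray(sig, dtype=float).ravel()
            if sig.size != n_vols:
                raise ValueError(f"{name} regressor length {sig.size} != {n_vols}")
            cols.append(sig)
            names.append(name)
    for idx in sorted(spike_indices):
        spike = np.zeros(n_vols)
        spike[idx] = 1.0
        cols.append(spike)
        names.append(f"spike{idx}")
    X = np.column_stack(cols)
    return X, names


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # locate near-dependent columns via the QR diagonal
        _, R = np.linalg.qr(X / np.linalg.norm(X, axis=0))
        diag = np.abs(np.diag(R))
        bad = [names[i] for i in np.where(diag < 1e-8)[0]]
        raise ValueError(f"rank-deficient nuisance design; collinear columns: {bad}")


def regress_nuisance(
    bold: BoldSeries,
    motion: MotionParams | None,
    wm_signal: np.ndarray | None,
    csf_signal: np.ndarray | None,
    config: PreprocessConfig | None = None,
    spike_indices: Sequence[int] = (),
) -> BoldSeries:
    """Per-voxel OLS residuals against [intercept, linear trend, Friston-24
    motion expansion, WM, CSF] (plus one-hot spike regressors in
    censor-in-regression scrub mode)."""
    config = config or PreprocessConfig()
    T = bold.n_volumes
    X, names = _design_matrix(T, motion, wm_signal, csf_signal, config, spike_indices)
    # all-zero regressors (e.g. a motionless run) carry no information; drop
    # them rather than failing the rank check
    nonzero = np.linalg.norm(X, axis=0) > 0
    X = X[:, nonzero]
    names = [n for n, keep in zip(names, nonzero) if keep]
    _check_rank(X, names)
    Y = bold.voxel_data.reshape(-1, T).T  # T x V
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    return bold.with_data(resid.T.reshape(bold.shape))


def bandpass(bold: BoldSeries, band_hz: tuple[float, float]) -> BoldSeries:
    """Ideal (hard) frequency-domain band-pass: DFT coefficients with frequency
    outside [low, high] are zeroed (DC always removed).  Linear and idempotent."""
    lo, hi = band_hz
    nyquist = 1.0 / (2.0 * bold.tr_seconds)
    if not 0 < lo < hi:
        raise ValueError(f"invalid band: {band_hz}")
    if hi > nyquist + 1e-12:
        raise ValueError(f"band upper edge {hi} Hz above Nyquist {nyquist} Hz")
    T = bold.n_volumes
    freqs = np.fft.rfftfreq(T, d=bold.tr_seconds)
    keep = (freqs >= lo - 1e-12) & (freqs <= hi + 1e-12)
    keep[0] = False
    spec = np.fft.rfft(bold.voxel_data, axis=3)
    spec[..., ~keep] = 0.0
    return bold.with_data(np.fft.irfft(spec, n=T, axis=3))


def smooth_volume(
    data: np.ndarray,
    fwhm_mm: float,
    voxel_size_mm: float | Sequence[float],
    mask: NetworkMask | None = None,
) -> np.ndarray:
    """Gaussian smoothing with sigma = FWHM / (2 sqrt(2 ln 2)) per axis in mm.

    Accepts a 3D map or a 4D series (no smoothing along time).  With a mask,
    smoothing is mask-renormalized — convolve data*mask and mask and divide —
    so no signal bleeds across the mask boundary; outside voxels are returned
    unchanged.
    """
    data = np.asarray(data, dtype=float)
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be nonnegative")
    if fwhm_mm == 0:
        return data.copy()
    vox = np.broadcast_to(np.asarray(voxel_size_mm, dtype=float).ravel(), (3,))
    sigma_vox = fwhm_mm * FWHM_TO_SIGMA / vox
    sigma = tuple(sigma_vox) + ((0.0,) if data.ndim == 4 else ())
    if mask is None:
        return ndimage.gaussian_filter(data, sigma=sigma)
    m = mask.binary.astype(float)
    if data.ndim == 4:
        m = m[..., None]
    filled = np.where(np.isfinite(data), data, 0.0) * m
    num = ndimage.gaussian_filter(filled, sigma=sigma)
    den = ndimage.gaussian_filter(np.broadcast_to(m, data.shape).copy(), sigma=sigma)
    out = data.copy()
    inside = np.broadcast_to(mask.binary[..., None] if data.ndim == 4 else mask.binary, data.shape)
    out[inside] = num[inside] / den[inside]
    return out


def scrub(bold: BoldSeries, fd: FdSeries, config: PreprocessConfig) -> tuple[BoldSeries, FdSeries, bool]:
    """Delete volumes with FD above threshold.

    Returns (scrubbed bold, FdSeries with censored indices recorded, flag) —
    the flag marks subjects retaining fewer than half their volumes.
    """
    if fd.fd_mm.size != bold.n_volumes:
        raise ValueError("FD series not aligned with BOLD volumes")
    censored = np.where(fd.fd_mm > config.fd_threshold_mm)[0]
    keep = np.setdiff1d(np.arange(bold.n_volumes), censored)
    if keep.size == 0:
        raise ValueError("all volumes censored by FD scrubbing")
    out_fd = FdSeries(fd_mm=fd.fd_mm, censored_indices=frozenset(int(i) for i in censored))
    flagged = keep.size < 0.5 * bold.n_volumes
    return bold.with_data(bold.voxel_data[..., keep]), out_fd, flagged


@dataclass
class PreprocessResult:
    """Outputs of the full temporal chain for one subject."""

    nh_bold: BoldSeries       # band-passed branch, input to network homogeneity
    falff_bold: BoldSeries    # full-spectrum branch, input to fALFF
    fd: FdSeries
    flagged_for_exclusion: bool
    n_retained: int


def run_preprocess(
    bold: BoldSeries,
    motion: MotionParams | None,
    wm_signal: np.ndarray | None,
    csf_signal: np.ndarray | None,
    config: PreprocessConfig | None = None,
    mask: NetworkMask | None = None,
) -> PreprocessResult:
    """Run discard -> smooth -> regress -> {band-pass + scrub, scrub} on one
    subject.  ``mask`` restricts (mask-renormalized) smoothing when given."""
    config = config or PreprocessConfig()
    if config.n_discard >= bold.n_volumes:
        raise ValueError(
            f"n_discard ({config.n_discard}) >= total volumes ({bold.n_volumes})"
        )
    nyquist = 1.0 / (2.0 * bold.tr_seconds)
    if config.band_hz[1] > nyquist + 1e-12:
        raise ValueError(f"band {config.band_hz} invalid for TR {bold.tr_seconds}")

    d = config.n_discard
    data = bold.voxel_data[..., d:]
    motion_r = motion[d:] if motion is not None else None
    wm_r = None if wm_signal is None else np.asarray(wm_signal).ravel()[d:]
    csf_r = None if csf_signal is None else np.asarray(csf_signal).ravel()[d:]
    work = bold.with_data(data)

    if motion_r is not None:
        fd = compute_fd(motion_r, config.fd_sphere_radius_mm)
    else:
        fd = FdSeries(fd_mm=np.zeros(work.n_volumes))

    spikes: tuple[int, ...] = ()
    if config.scrub_mode == "censor-in-regression":
        spikes = tuple(int(i) for i in np.where(fd.fd_mm > config.fd_threshold_mm)[0])
    work = regress_nuisance(work, motion_r, wm_r, csf_r, config, spike_indices=spikes)

    nh = bandpass(work, config.band_hz)
    if config.smooth_nh_input and config.smooth_fwhm_mm > 0:
        nh = nh.with_data(smooth_volume(nh.voxel_data, config.smooth_fwhm_mm, _voxel_size(bold), mask))
    falff = work
    if config.smooth_fwhm_mm > 0:
        falff = falff.with_data(
            smooth_volume(falff.voxel_data, config.smooth_fwhm_mm, _voxel_size(bold), mask)
        )
    if config.scrub_mode == "delete":
        nh, fd, flagged = scrub(nh, fd, config)
        falff, _, _ = scrub(falff, fd, config)
    else:
        flagged = False
        fd = FdSeries(fd_mm=fd.fd_mm, censored_indices=frozenset(spikes))
    return PreprocessResult(
        nh_bold=nh,
        falff_bold=falff,
        fd=fd,
        flagged_for_exclusion=flagged,
        n_retained=nh.n_volumes,
    )


def _voxel_size(bold: BoldSeries) -> np.ndarray:
    return np.sqrt((bold.affine[:3, :3] ** 2).sum(axis=0))
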