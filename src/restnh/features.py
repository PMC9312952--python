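"""Per-subject feature maps: fALFF and network homogeneity (NH).

fALFF — per voxel, the spectral amplitude (square root of the periodogram
power) summed over 0.01-0.08 Hz, divided by the amplitude summed over the
whole positive DFT frequency grid up to Nyquist.  The zero-frequency term is
excluded from both sums so the ratio does not depend on the series mean.

NH — per voxel inside the network mask, the mean Pearson correlation of its
time series with every *other* mask voxel (self-correlation excluded).
"""

from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np

from .io import BoldSeries, FeatureMap, NetworkMask, check_same_grid
from .preprocess import smooth_volume

__all__ = [
    "compute_falff",
    "compute_nh",
    "smooth_nh",
    "standardize_map",
]

logger = logging.getLogger(__name__)


def _mask_series(bold: BoldSeries, mask: NetworkMask) -> np.ndarray:
    check_same_grid(bold.shape, bold.affine, mask.label_data.shape, mask.affine, "bold vs mask")
    return bold.voxel_data[mask.binary]  # V x T, C-order voxel enumeration


def _empty_map(mask: NetworkMask) -> np.ndarray:
    out = np.full(mask.label_data.shape, np.nan)
    return out


def compute_falff(
    bold: BoldSeries,
    mask: NetworkMask,
    band_hz: tuple[float, float] = (0.01, 0.08),
    full_range_hz: tuple[float, float] | None = None,
) -> FeatureMap:
    """Fractional amplitude of low-frequency fluctuations per mask voxel.

    ``full_range_hz`` optionally fixes the denominator range (e.g. 0-0.25 Hz);
    by default the denominator is the whole positive DFT grid up to Nyquist.
    Zero-variance voxels get fALFF 0 (counted in a warning).
    """
    series = _mask_series(bold, mask)
    T = bold.n_volumes
    if T < 64:
        raise ValueError("fALFF needs at least 64 volumes for spectral resolution")
    freqs = np.fft.rfftfreq(T, d=bold.tr_seconds)
    amp = np.abs(np.fft.rfft(series, axis=1))
    lo, hi = band_hz
    in_band = (freqs >= lo - 1e-12) & (freqs <= hi + 1e-12)
    in_band[0] = False
    if full_range_hz is None:
        in_total = np.ones_like(in_band)
    else:
        flo, fhi = full_range_hz
        in_total = (freqs >= flo - 1e-12) & (freqs <= fhi + 1e-12)
    in_total[0] = False

    band_sum = amp[:, in_band].sum(axis=1)
    total_sum = amp[:, in_total].sum(axis=1)
    degenerate = total_sum <= 0
    n_deg = int(degenerate.sum())
    if n_deg:
        logger.warning("%d zero-variance voxels: fALFF set to 0", n_deg)
    values = np.zeros(series.shape[0])
    ok = ~degenerate
    values[ok] = band_sum[ok] / total_sum[ok]
    out = _empty_map(mask)
    out[mask.binary] = values
    return FeatureMap(values=out, kind="falff", subject_id=bold.subject_id)


def compute_nh(bold: BoldSeries, mask: NetworkMask, chunk_size: int = 2048) -> FeatureMap:
    """Network homogeneity: per mask voxel, mean Pearson r against all other
    mask voxels.

    Computed with standardized matrix products in chunks of ``chunk_size``
    voxels; numerically identical (to ~1e-10) to the O(V^2) pairwise loop.
    Zero-variance voxels have all their correlations defined as 0.
    """
    series = _mask_series(bold, mask)
    V, T = series.shape
    if T < 3:
        raise ValueError("NH needs at least 3 volumes")
    if V < 2:
        raise ValueError("NH needs at least 2 mask voxels")
    centered = series - series.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered**2).sum(axis=1))
    valid = norms > 0
    n_deg = int((~valid).sum())
    if n_deg:
        logger.warning("%d zero-variance voxels: NH correlations set to 0", n_deg)
    Z = np.zeros_like(centered)
    Z[valid] = centered[valid] / norms[valid, None]
    # row sums of the correlation matrix R = Z Z^T, without forming R
    col = Z.sum(axis=0)  # length T
    row_sums = np.empty(V)
    for start in range(0, V, chunk_size):
        stop = min(start + chunk_size, V)
        row_sums[start:stop] = Z[start:stop] @ col
    self_corr = valid.astype(float)  # r(v, v) = 1 for valid voxels, 0 degenerate
    nh = (row_sums - self_corr) / (V - 1)
    out = _empty_map(mask)
    out[mask.binary] = nh
    return FeatureMap(values=out, kind="nh", subject_id=bold.subject_id)


def smooth_nh(
    nh_map: FeatureMap,
    mask: NetworkMask,
    fwhm_mm: float = 4.0,
    n_passes: int = 1,
) -> FeatureMap:
    """Mask-renormalized Gaussian smoothing of an NH map, ``n_passes`` times."""
    if nh_map.kind != "nh":
        raise ValueError("smooth_nh expects an NH map")
    if n_passes < 0:
        raise ValueError("n_passes must be nonnegative")
    values = nh_map.values
    for _ in range(n_passes):
        values = smooth_volume(values, fwhm_mm, mask.voxel_size_mm, mask=mask)
    return replace(nh_map, values=values)


def standardize_map(fmap: FeatureMap, mask: NetworkMask) -> FeatureMap:
    """Within-mask z-transform: z(v) = (x(v) - mask mean) / mask SD."""
    vals = fmap.masked(mask)
    mean = vals.mean()
    sd = vals.std()
    if sd <= 0:
        raise ValueError("cannot standardize a map with zero within-mask variance")
    out = _empty_map(mask)
    out[mask.binary] = (vals - mean) / sd
    return replace(fmap, values=out, standardized=True)
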