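"""Pulsation/modulation ratios, outlier rejection, smoothing and labeling.

The pulsation ratio of one detector/wavelength channel is AC/DC; the
modulation ratio (ratio of ratios) of a detector is the 740 nm pulsation
ratio divided by the 850 nm pulsation ratio.  Modulation ratios outside
[0.01, 100] are outliers (pulsation ratios at the two wavelengths more
than two orders of magnitude apart indicate a corrupted measurement) and
are discarded before a 1.5-min moving-average smoother; output is one
sample per second.  Hypoxemia labels come from linear interpolation of the
sparse ABG draws against the 30 % saturation threshold (strict: exactly
30 % is normoxemic).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .acdc import AcDcSeries
from .bll import PHI_VALID_RANGE
from .simulate import HYPOXEMIA_THRESHOLD

__all__ = [
    "pulsation_ratio",
    "modulation_ratio",
    "reject_and_smooth",
    "windowed_mean",
    "label_samples",
    "assemble_samples",
    "compute_features",
    "SMOOTHING_HALF_WINDOW",
    "MIN_WINDOW_COUNT",
]

#: Half-width of the centered smoothing window (the 1.5-min average).
SMOOTHING_HALF_WINDOW = 45.0  # s
#: Minimum number of non-outlier points a window needs to produce a value.
MIN_WINDOW_COUNT = 10


def pulsation_ratio(acdc: AcDcSeries) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise AC/DC with a validity mask (invalid where DC <= 0)."""
    valid = (acdc.dc > 0) & np.isfinite(acdc.ac) & np.isfinite(acdc.dc)
    pr = np.full(acdc.ac.shape, np.nan)
    pr[valid] = acdc.ac[valid] / acdc.dc[valid]
    return pr, valid


def modulation_ratio(
    pr740: np.ndarray, pr850: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise ratio-of-ratios Phi = pr740/pr850 with validity mask."""
    pr740 = np.asarray(pr740, dtype=float)
    pr850 = np.asarray(pr850, dtype=float)
    if pr740.shape != pr850.shape:
        raise ValueError("pulsation-ratio series must be aligned")
    valid = np.isfinite(pr740) & np.isfinite(pr850) & (pr850 != 0)
    phi = np.full(pr740.shape, np.nan)
    phi[valid] = pr740[valid] / pr850[valid]
    return phi, valid


def _window_stats(
    t: np.ndarray,
    values: np.ndarray,
    mask: np.ndarray,
    t_out: np.ndarray,
    half_window: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean of masked values in centered windows around each output time."""
    vals = np.where(mask, values, 0.0)
    cs = np.concatenate([[0.0], np.cumsum(vals)])
    cn = np.concatenate([[0], np.cumsum(mask.astype(np.int64))])
    lo = np.searchsorted(t, t_out - half_window, side="left")
    hi = np.searchsorted(t, t_out + half_window, side="right")
    count = cn[hi] - cn[lo]
    with np.errstate(invalid="ignore"):
        mean = np.where(count > 0, (cs[hi] - cs[lo]) / np.maximum(count, 1), np.nan)
    return mean, count


def reject_and_smooth(
    t: np.ndarray,
    phi: np.ndarray,
    valid: np.ndarray | None = None,
    *,
    half_window: float = SMOOTHING_HALF_WINDOW,
    min_count: int = MIN_WINDOW_COUNT,
    phi_range: tuple[float, float] = PHI_VALID_RANGE,
    t_out: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Outlier rejection and 1.5-min moving average, at 1 sample/s.

    Points with Phi outside ``phi_range`` are outliers and excluded; each
    output sample is the mean of the remaining points in the centered
    window, invalid when fewer than ``min_count`` contribute.

    Returns ``(t_out, phi_smooth, out_valid)``.
    """
    t = np.asarray(t, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if np.any(np.diff(t) < 0):
        raise ValueError("timestamps must be monotone")
    if valid is None:
        valid = np.isfinite(phi)
    lo, hi = phi_range
    keep = valid & np.isfinite(phi) & (phi >= lo) & (phi <= hi)
    if t_out is None:
        t_out = np.arange(np.ceil(t[0]), np.floor(t[-1]) + 1.0)
    mean, count = _window_stats(t, phi, keep, t_out, half_window)
    out_valid = count >= min_count
    return t_out, mean, out_valid


def windowed_mean(
    t: np.ndarray,
    values: np.ndarray,
    valid: np.ndarray,
    t_out: np.ndarray,
    *,
    half_window: float = SMOOTHING_HALF_WINDOW,
    min_count: int = MIN_WINDOW_COUNT,
) -> tuple[np.ndarray, np.ndarray]:
    """Centered moving average of valid points (used for pulsation ratios)."""
    mean, count = _window_stats(
        np.asarray(t, float), np.asarray(values, float), valid, t_out, half_window
    )
    return mean, count >= min_count


def label_samples(
    abg: pd.DataFrame,
    t_grid: np.ndarray,
    threshold: float = HYPOXEMIA_THRESHOLD,
) -> tuple[np.ndarray, np.ndarray]:
    """Hypoxemia labels on a time grid from sparse ABG draws.

    Linear interpolation between draws; a sample is hypoxemic iff the
    interpolated saturation is strictly below ``threshold``.  Samples
    outside the draw span are invalid.  Requires at least two draws.
    """
    t_abg = np.asarray(abg["t"], dtype=float)
    v_abg = np.asarray(abg["fsao2"], dtype=float)
    if t_abg.size < 2:
        raise ValueError("at least two ABG draws are required for interpolation")
    if np.any(np.diff(t_abg) <= 0):
        raise ValueError("ABG draw times must be strictly increasing")
    t_grid = np.asarray(t_grid, dtype=float)
    interp = np.interp(t_grid, t_abg, v_abg)
    labels = interp < threshold
    valid = (t_grid >= t_abg[0]) & (t_grid <= t_abg[-1])
    return labels, valid


def assemble_samples(
    t_out: np.ndarray,
    pulsation: dict[tuple[int, int], tuple[np.ndarray, np.ndarray]],
    modulation: dict[int, tuple[np.ndarray, np.ndarray]],
    labels: np.ndarray,
    label_valid: np.ndarray,
    round_id: int,
    *,
    half_window: float = SMOOTHING_HALF_WINDOW,
) -> pd.DataFrame:
    """One feature row per second: 10 pulsation + 5 modulation ratios + label.

    ``pulsation`` maps ``(detector, wavelength) -> (values, valid)`` and
    ``modulation`` maps ``detector -> (values, valid)``, all on ``t_out``.
    A row is valid iff all 15 features and the label are valid.  Each row
    records the raw-data window ``[t - half_window, t + half_window]`` its
    smoothed features were computed from (used by cross-validation overlap
    exclusion).  Invalid rows are retained with ``valid = False``.
    """
    df = pd.DataFrame({"t": t_out})
    df["round_id"] = round_id
    all_valid = np.asarray(label_valid, dtype=bool).copy()
    detectors = sorted(modulation.keys())
    for (d, lam), (vals, val_mask) in sorted(pulsation.items()):
        df[f"pr_d{d + 1}_{lam}"] = vals
        all_valid &= np.asarray(val_mask, dtype=bool)
    for d in detectors:
        vals, val_mask = modulation[d]
        df[f"phi_d{d + 1}"] = vals
        all_valid &= np.asarray(val_mask, dtype=bool)
    df["label"] = np.asarray(labels, dtype=bool)
    df["valid"] = all_valid
    df["win_start"] = df["t"] - half_window
    df["win_end"] = df["t"] + half_window
    return df


def compute_features(
    acdc: dict[tuple[int, int], AcDcSeries],
    abg: pd.DataFrame,
    round_id: int = 0,
    *,
    wavelengths: tuple[int, int] = (740, 850),
    threshold: float = HYPOXEMIA_THRESHOLD,
    half_window: float = SMOOTHING_HALF_WINDOW,
    min_count: int = MIN_WINDOW_COUNT,
) -> pd.DataFrame:
    """Feature table for one round from per-channel AC/DC series.

    ``acdc`` maps ``(detector, wavelength)`` to the channel's
    :class:`~tfo.acdc.AcDcSeries`.  Pulsation ratios are averaged over the
    same centered window used to smooth the modulation ratios, so the 10
    pulsation features and 5 modulation features of a row describe the same
    stretch of raw data.
    """
    detectors = sorted({d for d, _ in acdc.keys()})
    w1, w2 = wavelengths
    first = acdc[(detectors[0], w1)]
    t = first.time()
    t_out = np.arange(np.ceil(t[0]), np.floor(t[-1]) + 1.0)

    pr_point: dict[tuple[int, int], tuple[np.ndarray, np.ndarray]] = {}
    for key, series in acdc.items():
        pr_point[key] = pulsation_ratio(series)

    pulsation_1hz: dict[tuple[int, int], tuple[np.ndarray, np.ndarray]] = {}
    modulation_1hz: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for d in detectors:
        pr1, v1 = pr_point[(d, w1)]
        pr2, v2 = pr_point[(d, w2)]
        for lam, (pr, v) in ((w1, (pr1, v1)), (w2, (pr2, v2))):
            pulsation_1hz[(d, lam)] = windowed_mean(
                t, pr, v, t_out, half_window=half_window, min_count=min_count
            )
        phi, phi_valid = modulation_ratio(pr1, pr2)
        _, phi_s, phi_ok = reject_and_smooth(
            t,
            phi,
            phi_valid & v1 & v2,
            half_window=half_window,
            min_count=min_count,
            t_out=t_out,
        )
        modulation_1hz[d] = (phi_s, phi_ok)

    labels, label_valid = label_samples(abg, t_out, threshold=threshold)
    return assemble_samples(
        t_out,
        pulsation_1hz,
        modulation_1hz,
        labels,
        label_valid,
        round_id,
        half_window=half_window,
    )
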