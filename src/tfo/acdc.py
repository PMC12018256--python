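"""AC/DC decomposition of wavelength-specific mixed-PPG signals.

The DC component is the lower envelope of the mixed PPG: local minima (after
a 3-sample median prefilter) interpolated linearly onto the full sampling
grid.  The AC component is the magnitude of the fetal-cardiac signal,
extracted by quadrature lock-in detection against a variable-frequency
reference synthesized from the fetal heart-rate (FHR) trace: the PPG is
mixed with sin(phi(t)) and cos(phi(t)), phi(t) = 2*pi*Int fhr(tau) dtau,
low-pass filtered, and converted to polar magnitude.  Because only the
magnitude is kept, the result is invariant to the phase of the fetal
pulsation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.integrate import cumulative_trapezoid

__all__ = [
    "FhrTrace",
    "AcDcSeries",
    "extract_dc",
    "build_reference",
    "lockin_ac",
    "extract_acdc",
]

#: Lock-in low-pass: must reject the maternal cardiac line (the nearest
#: interferer, >= 0.6 Hz from the FHR in the observed rounds) while
#: following the slow drift of the fetal pulsation amplitude.
LOCKIN_LPF_CUTOFF = 0.15  # Hz
LOCKIN_LPF_ORDER = 4

#: Minimum spacing between detected minima, as a fraction of the maternal
#: cardiac period, to skip noise dimples between true envelope minima.
MIN_SPACING_FRACTION = 0.25
DEFAULT_MATERNAL_FREQ = 1.3  # Hz, centre of the observed 75-84 bpm range

#: High-pass applied before the FHR lock-in.  The quasi-static baseline is
#: orders of magnitude larger than the fetal pulsation; without removal it
#: leaks into the AC estimate through the spectral wings of the
#: frequency-wandering reference.  0.5 Hz removes baseline and respiratory
#: harmonics (<= 0.75 Hz) while leaving the cardiac band (> 1.2 Hz) intact.
BASELINE_HPF_CUTOFF = 0.5  # Hz
BASELINE_HPF_ORDER = 4


@dataclass
class FhrTrace:
    """Fetal heart-rate reference trace (from hemodynamic monitoring)."""

    t: np.ndarray  # s
    fhr_hz: np.ndarray  # instantaneous FHR in Hz
    source: str = "reference"

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.fhr_hz = np.asarray(self.fhr_hz, dtype=float)
        if self.t.shape != self.fhr_hz.shape:
            raise ValueError("t and fhr_hz must have the same shape")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if np.any(self.fhr_hz <= 0.5) or np.any(self.fhr_hz >= 5.0):
            raise ValueError("FHR outside the physiological band (0.5, 5) Hz")

    def check_gaps(self, max_gap: float) -> None:
        gaps = np.diff(self.t)
        bad = np.flatnonzero(gaps > max_gap)
        if bad.size:
            i = bad[0]
            raise ValueError(
                f"FHR trace gap of {gaps[i]:.1f} s at t = {self.t[i]:.1f} s "
                f"exceeds the {max_gap:.1f} s limit"
            )

    @classmethod
    def from_csv(cls, path: str | Path) -> "FhrTrace":
        df = pd.read_csv(path)
        return cls(t=df["t"].to_numpy(float), fhr_hz=df["fhr_hz"].to_numpy(float))

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"t": self.t, "fhr_hz": self.fhr_hz}).to_csv(path, index=False)


@dataclass
class AcDcSeries:
    """Paired AC-magnitude and DC-envelope series for one detector/wavelength."""

    ac: np.ndarray
    dc: np.ndarray
    fs: float
    t0: float = 0.0
    dc_fallback: bool = False  # True when too few minima were found

    def time(self) -> np.ndarray:
        return self.t0 + np.arange(self.ac.size) / self.fs


def extract_dc(
    ppg: np.ndarray,
    fs: float,
    *,
    maternal_freq: float = DEFAULT_MATERNAL_FREQ,
) -> tuple[np.ndarray, bool]:
    """Lower envelope of the mixed PPG via local minima + linear interpolation.

    A 3-sample median prefilter suppresses single-sample noise dimples; the
    minimum spacing between accepted minima is a quarter of the maternal
    cardiac period (the fastest strong oscillation in the mixed signal).
    Endpoints are extended with the nearest minimum's value.  If fewer than
    two minima exist (e.g. monotone input) the global minimum is used as a
    constant envelope and the fallback flag is set.
    """
    ppg = np.asarray(ppg, dtype=float)
    filt = sps.medfilt(ppg, kernel_size=3)
    distance = max(1, int(round(MIN_SPACING_FRACTION / maternal_freq * fs)))
    minima, _ = sps.find_peaks(-filt, distance=distance)
    if minima.size < 2:
        return np.full(ppg.shape, float(np.min(ppg))), True
    grid = np.arange(ppg.size)
    dc = np.interp(grid, minima, filt[minima])
    return dc, False


def build_reference(
    fhr_trace: FhrTrace,
    t_grid: np.ndarray,
    *,
    max_gap: float = 10.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Unit-amplitude quadrature reference pair at the instantaneous FHR.

    The FHR trace is linearly interpolated onto ``t_grid`` and integrated
    (trapezoid) into the phase phi(t) = 2*pi*Int_0^t fhr; returns
    ``(sin(phi), cos(phi))``.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid[0] < fhr_trace.t[0] - 1e-9 or t_grid[-1] > fhr_trace.t[-1] + 1e-9:
        raise ValueError(
            f"FHR trace [{fhr_trace.t[0]}, {fhr_trace.t[-1]}] s does not cover "
            f"the requested grid [{t_grid[0]}, {t_grid[-1]}] s"
        )
    fhr_trace.check_gaps(max_gap)
    fhr = np.interp(t_grid, fhr_trace.t, fhr_trace.fhr_hz)
    phase = 2.0 * np.pi * cumulative_trapezoid(fhr, t_grid, initial=0.0)
    return np.sin(phase), np.cos(phase)


def lockin_ac(
    ppg: np.ndarray,
    reference: tuple[np.ndarray, np.ndarray],
    fs: float,
    *,
    cutoff: float = LOCKIN_LPF_CUTOFF,
    order: int = LOCKIN_LPF_ORDER,
) -> np.ndarray:
    """Quadrature lock-in magnitude of the PPG at the reference frequency.

    I = LPF(ppg * sin(phi)), Q = LPF(ppg * cos(phi)); the output
    ``2 * sqrt(I^2 + Q^2)`` restores the amplitude of a sinusoidal
    component at the reference frequency, independent of its phase.  The
    low-pass is a zero-phase (forward-backward) Butterworth.
    """
    ref_sin, ref_cos = reference
    ppg = np.asarray(ppg, dtype=float)
    if ppg.shape != ref_sin.shape or ppg.shape != ref_cos.shape:
        raise ValueError(
            f"signal length {ppg.shape} does not match reference length {ref_sin.shape}"
        )
    sos = sps.butter(order, cutoff, fs=fs, output="sos")
    i_comp = sps.sosfiltfilt(sos, ppg * ref_sin)
    q_comp = sps.sosfiltfilt(sos, ppg * ref_cos)
    return 2.0 * np.hypot(i_comp, q_comp)


def extract_acdc(
    ppg: np.ndarray,
    fs: float,
    fhr_trace: FhrTrace,
    t0: float = 0.0,
    *,
    cutoff: float = LOCKIN_LPF_CUTOFF,
    maternal_freq: float = DEFAULT_MATERNAL_FREQ,
) -> AcDcSeries:
    """AC and DC series for one detector/wavelength channel."""
    ppg = np.asarray(ppg, dtype=float)
    t_grid = t0 + np.arange(ppg.size) / fs
    dc, fallback = extract_dc(ppg, fs, maternal_freq=maternal_freq)
    reference = build_reference(fhr_trace, t_grid)
    sos = sps.butter(BASELINE_HPF_ORDER, BASELINE_HPF_CUTOFF, btype="highpass", fs=fs, output="sos")
    pulsatile = sps.sosfiltfilt(sos, ppg)
    ac = lockin_ac(pulsatile, reference, fs, cutoff=cutoff)
    return AcDcSeries(ac=ac, dc=dc, fs=fs, t0=t0, dc_fallback=fallback)
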