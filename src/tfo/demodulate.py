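"""Demodulation of raw multiplexed detector outputs into per-wavelength PPG.

Each detector channel carries both LEDs' optical power, square-wave
multiplexed (50 % duty, on/off) at 690 Hz for the 740 nm LED and 940 Hz
for the 850 nm LED.  Recovery is by quadrature lock-in against the
fundamental of each carrier: the unipolar square wave's fundamental has
amplitude 2/pi, so the quadrature magnitude of the mixed-down signal is
envelope/pi regardless of carrier phase; the factor is removed
analytically.  The recovered 8 kHz envelopes are decimated to 80 Hz and
divided by detector gain and LED drive current to give source-normalized
received optical power, comparable across subjects and device settings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
from scipy import signal as sps

from .simulate import RawRecording, WAVELENGTHS

__all__ = [
    "WavelengthPPG",
    "demodulate",
    "downsample",
    "source_normalize",
    "process_recording",
    "DECIMATION_FACTOR",
]

#: 8 kHz -> 80 Hz
DECIMATION_FACTOR = 100

#: Lock-in low-pass for carrier demodulation: passes the full mixed-PPG
#: band (maternal + fetal + harmonics, < 5 Hz) while rejecting carrier
#: intermodulation products and aliased square-wave harmonics.  The nearest
#: such line sits 30 Hz from a carrier (the 13th harmonic of 690 Hz folds
#: to 970 Hz at 8 ksps), so the cutoff must be well below 30 Hz to keep
#: cross-talk under 0.5 %.
CARRIER_LPF_CUTOFF = 10.0  # Hz
CARRIER_LPF_ORDER = 4


@dataclass
class WavelengthPPG:
    """Per-detector, per-wavelength source-normalized power at 80 Hz."""

    power: np.ndarray  # (n_detectors, n_wavelengths, n_samples)
    fs: float
    wavelengths: tuple[int, ...] = WAVELENGTHS
    t0: float = 0.0

    def get(self, detector: int, wavelength: int) -> np.ndarray:
        return self.power[detector, self.wavelengths.index(wavelength)]

    @property
    def n_detectors(self) -> int:
        return self.power.shape[0]

    def time(self) -> np.ndarray:
        return self.t0 + np.arange(self.power.shape[2]) / self.fs

    def to_hdf5(self, path: str | Path) -> None:
        with h5py.File(path, "w") as f:
            g = f.create_group("ppg")
            g.attrs["fs"] = self.fs
            g.attrs["t0"] = self.t0
            for d in range(self.n_detectors):
                for i, lam in enumerate(self.wavelengths):
                    g.create_dataset(f"det{d + 1}/wl{lam}", data=self.power[d, i])

    @classmethod
    def from_hdf5(cls, path: str | Path) -> "WavelengthPPG":
        with h5py.File(path, "r") as f:
            g = f["ppg"]
            det_names = sorted(g.keys(), key=lambda k: int(k[3:]))
            wavelengths = tuple(
                sorted(int(k[2:]) for k in g[det_names[0]].keys())
            )
            power = np.stack(
                [
                    np.stack([g[f"{dn}/wl{lam}"][:] for lam in wavelengths])
                    for dn in det_names
                ]
            )
            return cls(
                power=power,
                fs=float(g.attrs["fs"]),
                wavelengths=wavelengths,
                t0=float(g.attrs["t0"]),
            )


def demodulate(raw: RawRecording) -> dict[int, np.ndarray]:
    """Lock-in demodulation of each wavelength's envelope, still at 8 kHz.

    Returns ``{wavelength: array (n_detectors, n_samples)}`` of recovered
    pre-modulation optical power envelopes (carrier scale factor removed).
    A warning is issued if the lock-in low-pass band could reach the beat
    frequency between the two carriers (envelope cross-talk risk).
    """
    freqs = sorted(raw.mod_freqs.values())
    beat = min(np.diff(freqs)) if len(freqs) > 1 else np.inf
    if CARRIER_LPF_CUTOFF > beat / 2:
        warnings.warn(
            f"lock-in low-pass cutoff {CARRIER_LPF_CUTOFF} Hz reaches the "
            f"carrier beat frequency {beat} Hz: envelopes may cross-talk"
        )
    t = raw.time()
    sos = sps.butter(
        CARRIER_LPF_ORDER, CARRIER_LPF_CUTOFF, fs=raw.fs_raw, output="sos"
    )
    out: dict[int, np.ndarray] = {}
    for lam, f_m in raw.mod_freqs.items():
        ref_sin = np.sin(2.0 * np.pi * f_m * t)
        ref_cos = np.cos(2.0 * np.pi * f_m * t)
        env = np.empty_like(raw.signals)
        for d in range(raw.n_detectors):
            i_comp = sps.sosfiltfilt(sos, raw.signals[d] * ref_sin)
            q_comp = sps.sosfiltfilt(sos, raw.signals[d] * ref_cos)
            # unipolar square-wave fundamental amplitude is 2/pi, and the
            # quadrature magnitude halves it again: envelope = pi * |I + jQ|
            env[d] = np.pi * np.hypot(i_comp, q_comp)
        out[lam] = env
    return out


def downsample(series: np.ndarray, factor: int = DECIMATION_FACTOR) -> np.ndarray:
    """Anti-aliased decimation (8 kHz -> 80 Hz for the default factor).

    Two cascaded zero-phase FIR decimation stages (windowed-sinc, as used
    by ``scipy.signal.decimate`` with ``ftype='fir'``).  The FIR passband is
    flat to well under 0.1 dB below 10 Hz, covering the fetal band
    (<= 2.9 Hz) and its first harmonics, and the stopband suppresses
    out-of-band tones by > 50 dB before they can alias.
    """
    series = np.asarray(series)
    if series.shape[-1] < factor:
        raise ValueError(
            f"input length {series.shape[-1]} shorter than one decimation block ({factor})"
        )
    stages: list[int] = []
    remaining = factor
    while remaining > 13:
        stages.append(10)
        if remaining % 10:
            raise ValueError(f"decimation factor {factor} not decomposable into stages of 10")
        remaining //= 10
    if remaining > 1:
        stages.append(remaining)
    out = series
    for q in stages:
        out = sps.decimate(out, q, ftype="fir", zero_phase=True)
    return out


def source_normalize(
    ppg: np.ndarray, gain: float, led_current: float, device_constant: float = 1.0
) -> np.ndarray:
    """Convert a demodulated envelope to source-normalized optical power.

    Divides out detector gain, LED drive current and the (configurable)
    radiometric device constant, so recordings of the same scene taken at
    different device settings become directly comparable.
    """
    if gain <= 0 or led_current <= 0 or device_constant <= 0:
        raise ValueError("gain, led_current and device_constant must be positive")
    return np.asarray(ppg) / (gain * led_current * device_constant)


def process_recording(
    raw: RawRecording, device_constant: float = 1.0
) -> WavelengthPPG:
    """Full front-end: demodulate, decimate to 80 Hz, source-normalize."""
    envelopes = demodulate(raw)
    wavelengths = tuple(sorted(raw.mod_freqs.keys()))
    n_out = int(np.ceil(raw.signals.shape[1] / DECIMATION_FACTOR))
    power = np.empty((raw.n_detectors, len(wavelengths), n_out))
    for i, lam in enumerate(wavelengths):
        low = downsample(envelopes[lam])
        for d in range(raw.n_detectors):
            power[d, i] = source_normalize(
                low[d], raw.gains[d], raw.led_currents[lam], device_constant
            )
    return WavelengthPPG(
        power=power,
        fs=raw.fs_raw / DECIMATION_FACTOR,
        wavelengths=wavelengths,
        t0=raw.t0,
    )
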