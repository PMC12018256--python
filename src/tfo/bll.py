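"""Modified Beer-Lambert law (mBLL) relations for two-wavelength oximetry.

The pulsatile change in optical absorbance at wavelength :math:`\\lambda` is

.. math::

    \\Delta A^{\\lambda} = (\\Delta C_{O_2Hb}\\,\\varepsilon_{O_2Hb}^{\\lambda}
        + \\Delta C_{RHb}\\,\\varepsilon_{RHb}^{\\lambda})\\,\\langle L \\rangle

with :math:`\\Delta C_{O_2Hb} = S\\,\\Delta C_{THb}` and
:math:`\\Delta C_{RHb} = (1-S)\\,\\Delta C_{THb}`, where *S* is the arterial
oxygen saturation, :math:`\\Delta C_{THb}` the pulsatile change in total
hemoglobin concentration (mM) and :math:`\\langle L \\rangle` the mean photon
path length (cm).

Taking the ratio of the absorbance changes at two wavelengths (the
"modulation ratio" or ratio-of-ratios, :math:`\\Phi`) cancels both
:math:`\\Delta C_{THb}` and :math:`\\langle L \\rangle` (assuming equal mean
path at both wavelengths), leaving a closed-form, calibration-free relation
between :math:`\\Phi` and *S* that this module implements in both directions.

These relations are used forward by the synthetic mixed-PPG generator (to
give the fetal pulsation physically consistent two-wavelength amplitudes)
and inverse by verification code (to recover saturation from measured
modulation ratios).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "ExtinctionTable",
    "ChromophoreState",
    "ModulationRatio",
    "default_extinction_table",
    "delta_absorbance",
    "phi_from_state",
    "saturation_from_phi",
]

#: Modulation ratios outside this range are treated as measurement outliers
#: (pulsation ratios at the two wavelengths more than two orders of
#: magnitude apart indicate a corrupted signal, not physiology).
PHI_VALID_RANGE = (0.01, 100.0)


@dataclass(frozen=True)
class ExtinctionTable:
    """Molar extinction coefficients of oxy- and deoxyhemoglobin.

    Parameters
    ----------
    wavelengths : tuple of float
        The two wavelengths in nm, e.g. ``(740.0, 850.0)``.  Order matters:
        the modulation ratio is defined as
        ``delta_A[wavelengths[0]] / delta_A[wavelengths[1]]``.
    eps_o2hb, eps_rhb : dict
        Extinction coefficients in M^-1 cm^-1 keyed by wavelength.
    """

    wavelengths: tuple[float, float]
    eps_o2hb: dict[float, float] = field(default_factory=dict)
    eps_rhb: dict[float, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        w1, w2 = self.wavelengths
        if w1 == w2:
            raise ValueError("the two wavelengths must be distinct")
        for lam in self.wavelengths:
            if lam not in self.eps_o2hb or lam not in self.eps_rhb:
                raise ValueError(f"missing extinction coefficients for {lam} nm")
            if self.eps_o2hb[lam] <= 0 or self.eps_rhb[lam] <= 0:
                raise ValueError(f"extinction coefficients at {lam} nm must be positive")
        if abs(np.linalg.det(self.matrix())) < 1e-12 * self._scale() ** 2:
            raise ValueError("extinction matrix is singular: wavelengths carry no independent information")

    def _scale(self) -> float:
        return max(max(self.eps_o2hb.values()), max(self.eps_rhb.values()))

    def matrix(self) -> np.ndarray:
        """2x2 matrix [[eps_o2hb^l1, eps_rhb^l1], [eps_o2hb^l2, eps_rhb^l2]]."""
        w1, w2 = self.wavelengths
        return np.array(
            [
                [self.eps_o2hb[w1], self.eps_rhb[w1]],
                [self.eps_o2hb[w2], self.eps_rhb[w2]],
            ]
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "ExtinctionTable":
        """Load a table from CSV with columns wavelength_nm, eps_o2hb, eps_rhb."""
        import pandas as pd

        df = pd.read_csv(path, comment="#")
        wavelengths = tuple(float(w) for w in df["wavelength_nm"])
        if len(wavelengths) != 2:
            raise ValueError(f"expected exactly 2 wavelengths, got {len(wavelengths)}")
        return cls(
            wavelengths=wavelengths,  # type: ignore[arg-type]
            eps_o2hb=dict(zip(wavelengths, df["eps_o2hb"].astype(float))),
            eps_rhb=dict(zip(wavelengths, df["eps_rhb"].astype(float))),
        )

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame(
            {
                "wavelength_nm": list(self.wavelengths),
                "eps_o2hb": [self.eps_o2hb[w] for w in self.wavelengths],
                "eps_rhb": [self.eps_rhb[w] for w in self.wavelengths],
            }
        ).to_csv(path, index=False)


@dataclass(frozen=True)
class ChromophoreState:
    """Pulsatile chromophore state of the (fetal) arterial compartment.

    saturation
        Fraction of total hemoglobin bound to oxygen, in [0, 1].
    delta_c_thb
        Pulsatile change in total hemoglobin concentration, mM (> 0).
    mean_path
        Mean photon path length in cm, assumed equal at both wavelengths.
    """

    saturation: float
    delta_c_thb: float
    mean_path: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.saturation <= 1.0:
            raise ValueError(f"saturation must be in [0, 1], got {self.saturation}")
        if self.delta_c_thb < 0:
            raise ValueError("delta_c_thb must be non-negative")
        if self.mean_path <= 0:
            raise ValueError("mean_path must be positive")


@dataclass(frozen=True)
class ModulationRatio:
    """A single ratio-of-ratios sample, with its outlier flag."""

    phi: float
    timestamp: float
    detector_id: int
    outlier: bool = False

    def __post_init__(self) -> None:
        lo, hi = PHI_VALID_RANGE
        if not self.outlier and not (lo <= self.phi <= hi):
            raise ValueError(
                f"non-outlier modulation ratio {self.phi} outside [{lo}, {hi}]"
            )


def default_extinction_table() -> ExtinctionTable:
    """The packaged 740/850 nm hemoglobin extinction table.

    Values are drawn from the standard compiled hemoglobin absorption
    spectra distributed with this package (see data/extinction_740_850.csv
    for provenance).  Any table with a non-singular extinction matrix
    satisfies the algebra; all operations also accept a user table.
    """
    ref = importlib.resources.files("tfo.data") / "extinction_740_850.csv"
    with importlib.resources.as_file(ref) as path:
        return ExtinctionTable.from_csv(path)


def delta_absorbance(
    state: ChromophoreState, eps: ExtinctionTable, wavelength: float
) -> float:
    """Pulsatile absorbance change dA at one wavelength (dimensionless).

    dA = (S * eps_o2hb + (1 - S) * eps_rhb) * dC_THb * <L>, with dC_THb in
    mM converted to M so that the M^-1 cm^-1 extinction units cancel.
    """
    if wavelength not in eps.eps_o2hb:
        raise ValueError(
            f"unknown wavelength {wavelength} nm; table has {eps.wavelengths}"
        )
    s = state.saturation
    eff_eps = s * eps.eps_o2hb[wavelength] + (1.0 - s) * eps.eps_rhb[wavelength]
    return eff_eps * (state.delta_c_thb * 1e-3) * state.mean_path


def phi_from_state(state: ChromophoreState, eps: ExtinctionTable) -> float:
    """Modulation ratio Phi = dA^l1 / dA^l2 for a chromophore state.

    dC_THb and <L> cancel, so Phi depends only on the saturation and the
    extinction table.  Raises if the denominator absorbance is degenerate.
    """
    w1, w2 = eps.wavelengths
    # Evaluate with a unit pulsation so Phi is defined even for dC_THb == 0.
    probe = ChromophoreState(
        saturation=state.saturation, delta_c_thb=1.0, mean_path=state.mean_path
    )
    num = delta_absorbance(probe, eps, w1)
    den = delta_absorbance(probe, eps, w2)
    if den == 0.0:
        raise ZeroDivisionError(f"absorbance change at {w2} nm is zero")
    return num / den


def saturation_from_phi(
    phi: float | np.ndarray,
    eps: ExtinctionTable,
    *,
    denominator_tol: float = 1e-12,
) -> float | np.ndarray:
    """Invert the ratio-of-ratios relation: saturation S from Phi.

    S = (Phi * eps_rhb^l2 - eps_rhb^l1)
        / (eps_o2hb^l1 - eps_rhb^l1 - Phi * (eps_o2hb^l2 - eps_rhb^l2))

    The raw algebraic value is returned without clamping; values outside
    [0, 1] indicate the measured Phi is inconsistent with a pure
    two-chromophore pulsation and should be flagged by the caller.

    Raises
    ------
    ZeroDivisionError
        If the denominator is within ``denominator_tol`` (relative to the
        extinction scale) of zero — Phi at the pole of the mapping.
    """
    w1, w2 = eps.wavelengths
    phi = np.asarray(phi, dtype=float)
    num = phi * eps.eps_rhb[w2] - eps.eps_rhb[w1]
    den = (
        eps.eps_o2hb[w1]
        - eps.eps_rhb[w1]
        - phi * (eps.eps_o2hb[w2] - eps.eps_rhb[w2])
    )
    scale = eps._scale()
    if np.any(np.abs(den) < denominator_tol * scale):
        raise ZeroDivisionError(
            "saturation_from_phi: denominator within tolerance of zero (Phi at the pole)"
        )
    out = num / den
    return float(out) if out.ndim == 0 else out
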