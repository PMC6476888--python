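"""UV-Vis analytics for ligand / CT-DNA binding studies.

Hypochromism (intensity loss at the free-compound band maximum) together
with a red shift of the maximum is the classic spectroscopic signature of
intercalation.  The module reproduces the quantities of the binding table:
percent hypochromism, the molar absorptivity change delta-epsilon, and the
wavelength shift between the free and DNA-bound band maxima, plus DNA
concentration (Beer-Lambert with epsilon(260 nm) = 6600 M^-1 cm^-1) and
the A260/A280 protein-purity check.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

EPSILON_DNA_260 = 6600.0  # M^-1 cm^-1, per-nucleotide extinction at 260 nm
PURITY_RATIO_MIN = 1.8  # A260/A280 must exceed this (strict) to pass
DEFAULT_WINDOW = (330.0, 450.0)  # long-wavelength band searched for lambda-max


@dataclass(frozen=True)
class Spectrum:
    """Absorbance spectrum on a strictly increasing wavelength grid [nm]."""

    wavelengths: np.ndarray
    absorbance: np.ndarray
    pathlength_cm: float = 1.0
    concentration_m: float | None = None

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        ab = np.asarray(self.absorbance, dtype=float)
        if wl.shape != ab.shape or wl.ndim != 1:
            raise ValueError("wavelengths and absorbance must be equal-length 1-D arrays")
        if not np.all(np.diff(wl) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(ab)):
            raise ValueError("absorbance must be finite")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "absorbance", ab)

    def at(self, wavelength: float) -> float:
        """Linear interpolation of the absorbance."""
        return float(np.interp(wavelength, self.wavelengths, self.absorbance))

    @classmethod
    def from_csv(cls, path: str | Path, **kwargs) -> "Spectrum":
        df = pd.read_csv(path)
        return cls(df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy(), **kwargs)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"nm": self.wavelengths, "au": self.absorbance}).to_csv(path, index=False)


def dna_concentration(a260: float, pathlength_cm: float = 1.0) -> float:
    """Molar (per-nucleotide) CT-DNA concentration from A260."""
    if a260 < 0:
        raise ValueError("absorbance must be non-negative")
    return a260 / (EPSILON_DNA_260 * pathlength_cm)


class PurityResult(NamedTuple):
    passed: bool
    ratio: float


def purity_check(a260: float, a280: float) -> PurityResult:
    """DNA purity: pass iff A260/A280 strictly exceeds 1.8."""
    if a280 <= 0:
        raise ValueError("A280 must be positive")
    ratio = a260 / a280
    return PurityResult(ratio > PURITY_RATIO_MIN, ratio)


def _lambda_max(spec: Spectrum, window: tuple[float, float]) -> float:
    lo, hi = window
    mask = (spec.wavelengths >= lo) & (spec.wavelengths <= hi)
    if mask.sum() < 3:
        raise ValueError(f"window {window} covers fewer than 3 grid points")
    wl, ab = spec.wavelengths[mask], spec.absorbance[mask]
    i = int(np.argmax(ab))
    interior = 0 < i < len(ab) - 1
    if not interior or ab[i] <= ab.min() + 1e-15:
        raise ValueError(
            f"no interior absorption maximum in window {window}; adjust the search window"
        )
    return float(wl[i])


def binding_metrics(
    free: Spectrum,
    bound: Spectrum,
    window: tuple[float, float] = DEFAULT_WINDOW,
) -> dict:
    """Hypochromism %, delta-epsilon, and band shift between two spectra.

    Each spectrum is evaluated at its own band maximum — the usual
    convention for reported hypochromism values, where the maxima of the
    free and the DNA-bound compound are read separately:

    H%      = 100 (A_free(lmax_free) - A_bound(lmax_bound)) / A_free(lmax_free)
    deps    = (A_free - A_bound) / (c l) at the same pair of maxima
              (requires the free spectrum's compound concentration)
    shift   = lambda_max(bound) - lambda_max(free); positive = red shift
    """
    lam_free = _lambda_max(free, window)
    lam_bound = _lambda_max(bound, window)
    a_free = free.at(lam_free)
    a_bound = bound.at(lam_bound)
    hypochromism = 100.0 * (a_free - a_bound) / a_free
    delta_eps = np.nan
    if free.concentration_m:
        delta_eps = (a_free - a_bound) / (free.concentration_m * free.pathlength_cm)
    return {
        "lambda_max_free_nm": lam_free,
        "lambda_max_bound_nm": lam_bound,
        "hypochromism_pct": float(hypochromism),
        "delta_epsilon": float(delta_eps),
        "red_shift_nm": float(lam_bound - lam_free),
    }


def batch_report(pairs: dict[str, tuple[Spectrum, Spectrum]], **kwargs) -> pd.DataFrame:
    """Binding-table-style report (one row per compound) from spectrum pairs."""
    return pd.DataFrame(
        {cid: binding_metrics(free, bound, **kwargs) for cid, (free, bound) in pairs.items()}
    ).T
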