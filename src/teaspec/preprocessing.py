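"""Spectral trimming and the compared preprocessing treatments.

Four row-wise treatments are compared ahead of calibration: raw (identity),
smoothing (centered moving average), normalize (divide by the spectrum
maximum) and SNV (standard normal variate, per-spectrum standardisation).
SNV removes any per-spectrum affine distortion a + b*x exactly, which is why
it corrects the multiplicative scatter and baseline offsets the generator
injects. Trimming removes noisy band edges by position: the study deletes
the first 500 and last 400 acquired points before any analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset import SpectrumSet

__all__ = [
    "PreprocessMethod",
    "METHOD_NAMES",
    "trim",
    "smooth",
    "normalize",
    "snv",
    "apply_method",
]

METHOD_NAMES = ("raw", "smoothing", "normalize", "snv")


@dataclass
class PreprocessMethod:
    """A named treatment plus its method-specific settings."""

    name: str
    window: int = 9  # smoothing only; must be odd and >= 3
    variant: str = "max"  # normalize only: "max" or "unit"

    def __post_init__(self) -> None:
        if self.name not in METHOD_NAMES:
            raise ValueError(
                f"unknown preprocessing method {self.name!r}; "
                f"expected one of {METHOD_NAMES}"
            )
        if self.name == "smoothing" and (self.window < 3 or self.window % 2 == 0):
            raise ValueError(f"smoothing window must be odd and >= 3, got {self.window}")
        if self.name == "normalize" and self.variant not in ("max", "unit"):
            raise ValueError(f"unknown normalize variant {self.variant!r}")


def trim(data: SpectrumSet, n_front: int, n_back: int) -> SpectrumSet:
    """Drop the first ``n_front`` and last ``n_back`` grid points."""
    if n_front < 0 or n_back < 0:
        raise ValueError("trim counts must be >= 0")
    p = data.n_variables
    if n_front + n_back >= p:
        raise ValueError(
            f"cannot trim {n_front} + {n_back} points from a {p}-point grid"
        )
    idx = np.arange(n_front, p - n_back)
    return data.take_variables(idx)


def smooth(spectrum: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average; the window shrinks symmetrically at edges."""
    x = np.asarray(spectrum, dtype=float)
    if window % 2 == 0:
        raise ValueError(f"smoothing window must be odd, got {window}")
    if not 3 <= window <= x.size:
        raise ValueError(
            f"smoothing window must be in [3, {x.size}], got {window}"
        )
    half = window // 2
    n = x.size
    out = np.empty_like(x)
    csum = np.concatenate([[0.0], np.cumsum(x)])
    for i in range(n):
        h = min(half, i, n - 1 - i)
        out[i] = (csum[i + h + 1] - csum[i - h]) / (2 * h + 1)
    return out


def normalize(spectrum: np.ndarray, variant: str = "max") -> np.ndarray:
    """Scale a spectrum to its maximum ("max") or to unit length ("unit")."""
    x = np.asarray(spectrum, dtype=float)
    if not np.any(x != 0):
        raise ValueError("cannot normalize an all-zero spectrum")
    if variant == "max":
        peak = x.max()
        if peak <= 0:
            raise ValueError("max-normalization requires a positive maximum")
        return x / peak
    if variant == "unit":
        return x / np.linalg.norm(x)
    raise ValueError(f"unknown normalize variant {variant!r}")


def snv(spectrum: np.ndarray) -> np.ndarray:
    """Standard normal variate: (x - mean) / sample sd (ddof = 1)."""
    x = np.asarray(spectrum, dtype=float)
    if x.size < 2:
        raise ValueError("SNV needs at least 2 points")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("SNV undefined for a spectrum with zero spread")
    return (x - x.mean()) / sd


def apply_method(data: SpectrumSet, method: PreprocessMethod) -> SpectrumSet:
    """Apply one treatment row-wise; doses and split labels are untouched."""
    if method.name == "raw":
        return data.copy()
    out = np.empty_like(data.absorbance)
    for i in range(data.n_samples):
        try:
            if method.name == "smoothing":
                out[i] = smooth(data.absorbance[i], method.window)
            elif method.name == "normalize":
                out[i] = normalize(data.absorbance[i], method.variant)
            else:
                out[i] = snv(data.absorbance[i])
        except ValueError as exc:
            raise ValueError(f"{method.name} failed on sample {i}: {exc}") from exc
    return SpectrumSet(
        data.wavenumbers.copy(), out, data.dose.copy(), data.subset.copy()
    )
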