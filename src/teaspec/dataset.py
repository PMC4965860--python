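"""Spectral dataset container and the CSV matrix format shared by all stages.

A :class:`SpectrumSet` holds a common wavenumber grid, one absorbance row per
sample, the talc dose label (mg adulterant per g tea) and the set assignment
(calibration or prediction). The on-disk form is a plain CSV matrix:
``dose,set,<wavenumber_1>,...,<wavenumber_p>`` with one row per sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CALIBRATION = "calibration"
PREDICTION = "prediction"
_SET_LABELS = (CALIBRATION, PREDICTION)


@dataclass
class SpectrumSet:
    """Samples x wavenumbers absorbance matrix with dose and split labels.

    Parameters
    ----------
    wavenumbers:
        Strictly increasing grid in cm^-1, shape ``(p,)``.
    absorbance:
        Absorbance in AU, shape ``(n, p)``.
    dose:
        Talc dose per sample in mg/g, shape ``(n,)``.
    subset:
        Per-sample split label, ``"calibration"`` or ``"prediction"``.
    """

    wavenumbers: np.ndarray
    absorbance: np.ndarray
    dose: np.ndarray
    subset: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.absorbance = np.atleast_2d(np.asarray(self.absorbance, dtype=float))
        self.dose = np.asarray(self.dose, dtype=float)
        if self.subset is None:
            self.subset = np.full(self.absorbance.shape[0], CALIBRATION, dtype=object)
        self.subset = np.asarray(self.subset, dtype=object)
        n, p = self.absorbance.shape
        if self.wavenumbers.shape != (p,):
            raise ValueError(
                f"grid length {self.wavenumbers.shape} does not match "
                f"{p} absorbance columns"
            )
        if self.dose.shape != (n,) or self.subset.shape != (n,):
            raise ValueError("dose/subset length does not match sample count")
        if p > 1 and not np.all(np.diff(self.wavenumbers) > 0):
            raise ValueError("wavenumber grid must be strictly increasing")
        bad = set(self.subset) - set(_SET_LABELS)
        if bad:
            raise ValueError(f"unknown set labels: {sorted(bad)}")

    @property
    def n_samples(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n_variables(self) -> int:
        return self.absorbance.shape[1]

    def take_samples(self, index: np.ndarray) -> "SpectrumSet":
        index = np.asarray(index)
        return SpectrumSet(
            self.wavenumbers.copy(),
            self.absorbance[index].copy(),
            self.dose[index].copy(),
            self.subset[index].copy(),
        )

    def take_variables(self, index: np.ndarray) -> "SpectrumSet":
        index = np.asarray(index)
        return SpectrumSet(
            self.wavenumbers[index].copy(),
            self.absorbance[:, index].copy(),
            self.dose.copy(),
            self.subset.copy(),
        )

    def calibration(self) -> "SpectrumSet":
        return self.take_samples(np.flatnonzero(self.subset == CALIBRATION))

    def prediction(self) -> "SpectrumSet":
        return self.take_samples(np.flatnonzero(self.subset == PREDICTION))

    def copy(self) -> "SpectrumSet":
        return self.take_samples(np.arange(self.n_samples))

    def equals(self, other: "SpectrumSet") -> bool:
        """Bitwise equality of grid, matrix, doses and split labels."""
        return (
            np.array_equal(self.wavenumbers, other.wavenumbers)
            and np.array_equal(self.absorbance, other.absorbance)
            and np.array_equal(self.dose, other.dose)
            and np.array_equal(self.subset, other.subset)
        )


def write_csv(data: SpectrumSet, path) -> None:
    """Write the ``dose,set,<w1>,...,<wp>`` CSV matrix."""
    frame = pd.DataFrame(
        data.absorbance, columns=[str(float(w)) for w in data.wavenumbers]
    )
    frame.insert(0, "set", data.subset)
    frame.insert(0, "dose", data.dose)
    frame.to_csv(path, index=False, float_format="%.17g")


def read_csv(path) -> SpectrumSet:
    """Read a CSV matrix written by :func:`write_csv`."""
    frame = pd.read_csv(path, float_precision="round_trip")
    if list(frame.columns[:2]) != ["dose", "set"]:
        raise ValueError("CSV matrix must start with 'dose,set' columns")
    wavenumbers = np.array([float(c) for c in frame.columns[2:]])
    return SpectrumSet(
        wavenumbers,
        frame.iloc[:, 2:].to_numpy(dtype=float),
        frame["dose"].to_numpy(dtype=float),
        frame["set"].to_numpy(dtype=object),
    )
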