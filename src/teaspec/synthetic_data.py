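"""Synthetic FT-IR spectra of talc-adulterated tea powder.

The study design this generator emulates: tea powder spiked with talcum
powder at 13 dose levels between 0 and 1.5 mg adulterant per g tea, scanned
in transmission over 400-4000 cm^-1, with seven levels reserved for
calibration and six for prediction. A sample at dose ``c`` follows a
Beer-Lambert mixture

    A(w) = gain * (A_tea(w) + c * kappa * A_talc(w)) + baseline(w) + noise

where ``A_tea`` and ``A_talc`` are pure-component spectra built from peak
libraries (talc's diagnostic Si-O-Si band near 1016 cm^-1 dominates),
``kappa`` scales the talc contribution per mg/g, ``gain`` is a per-spectrum
multiplicative scatter term, ``baseline`` a per-spectrum affine drift and
``noise`` i.i.d. additive noise. Gain and offset distortions are exactly the
artefacts standard-normal-variate (SNV) preprocessing removes, which is what
makes the preprocessing comparison downstream meaningful.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml
from scipy import signal

from .dataset import CALIBRATION, PREDICTION, SpectrumSet

__all__ = [
    "PeakSpec",
    "BroadBackground",
    "ComponentSpectrum",
    "DoseDesign",
    "NoiseModel",
    "SyntheticConfig",
    "mass_to_dose",
    "evaluate_component",
    "simulate_dataset",
    "split_by_level",
    "default_config",
    "config_to_dict",
    "config_from_dict",
    "save_config",
    "load_config",
    "DOSE_LEVELS",
    "CALIBRATION_LEVELS",
    "PREDICTION_LEVELS",
]

# The study's printed dose levels (mg/g). The printed list pairs 0.50 mg in
# 4.00 g with 0.15 mg/g even though 0.50/4.00 = 0.125; the printed level is
# kept verbatim and the arithmetic is not second-guessed here.
DOSE_LEVELS = (0.00, 0.15, 0.25, 0.35, 0.50, 0.65, 0.75, 0.85,
               1.00, 1.10, 1.25, 1.40, 1.50)
CALIBRATION_LEVELS = (0.00, 0.25, 0.50, 0.75, 1.00, 1.25, 1.50)
PREDICTION_LEVELS = (0.15, 0.35, 0.65, 0.85, 1.10, 1.40)


def mass_to_dose(adulterant_mass: float, matrix_mass: float) -> float:
    """Dose in mg/g from adulterant mass (mg) and tea matrix mass (g)."""
    if matrix_mass <= 0:
        raise ValueError(f"matrix mass must be positive, got {matrix_mass}")
    if adulterant_mass < 0:
        raise ValueError(f"adulterant mass must be >= 0, got {adulterant_mass}")
    return adulterant_mass / matrix_mass


@dataclass
class PeakSpec:
    """One absorbance band: center (cm^-1), height (AU), FWHM (cm^-1)."""

    center: float
    height: float
    width: float
    shape: str = "gaussian"

    def __post_init__(self) -> None:
        if self.height < 0:
            raise ValueError(f"peak height must be >= 0, got {self.height}")
        if self.width <= 0:
            raise ValueError(f"peak width must be > 0, got {self.width}")
        if self.shape not in ("gaussian", "lorentzian"):
            raise ValueError(f"unknown peak shape {self.shape!r}")

    def evaluate(self, grid: np.ndarray) -> np.ndarray:
        d = grid - self.center
        if self.shape == "gaussian":
            # FWHM parametrisation: value at center +- width/2 is height/2
            return self.height * np.exp(-4.0 * np.log(2.0) * d**2 / self.width**2)
        hw = self.width / 2.0
        return self.height * hw**2 / (d**2 + hw**2)


@dataclass
class BroadBackground:
    """Slowly decaying nonnegative background: amp * exp(-(w - ref)/scale)."""

    amplitude: float = 0.0
    length_scale: float = 1500.0
    reference: float = 400.0

    def evaluate(self, grid: np.ndarray) -> np.ndarray:
        if self.amplitude == 0.0:
            return np.zeros_like(grid)
        return self.amplitude * np.exp(-(grid - self.reference) / self.length_scale)


@dataclass
class ComponentSpectrum:
    """Pure-component spectrum: a peak library plus a broad background."""

    name: str
    peaks: list
    broad_background: BroadBackground = field(default_factory=BroadBackground)


def evaluate_component(component: ComponentSpectrum, grid: np.ndarray) -> np.ndarray:
    """Pointwise sum of all peak shapes plus the broad background."""
    grid = np.asarray(grid, dtype=float)
    if grid.size > 1 and not np.all(np.diff(grid) > 0):
        raise ValueError("grid must be strictly increasing")
    out = component.broad_background.evaluate(grid)
    lo, hi = grid[0], grid[-1]
    for peak in component.peaks:
        if not lo <= peak.center <= hi:
            warnings.warn(
                f"peak center {peak.center} cm^-1 outside grid span "
                f"[{lo}, {hi}]; tails are still evaluated",
                stacklevel=2,
            )
        out = out + peak.evaluate(grid)
    return out


@dataclass
class DoseDesign:
    """Dose levels, replicates per level, and the level-wise split."""

    levels: tuple
    replicates_per_level: tuple
    calibration_levels: tuple
    prediction_levels: tuple

    def __post_init__(self) -> None:
        self.levels = tuple(float(v) for v in self.levels)
        self.replicates_per_level = tuple(int(v) for v in self.replicates_per_level)
        self.calibration_levels = tuple(float(v) for v in self.calibration_levels)
        self.prediction_levels = tuple(float(v) for v in self.prediction_levels)
        if len(self.levels) != len(self.replicates_per_level):
            raise ValueError("one replicate count per level is required")
        if any(v < 0 for v in self.levels):
            raise ValueError("dose levels must be >= 0")
        if any(r <= 0 for r in self.replicates_per_level):
            raise ValueError("replicate counts must be positive")
        cal, pred = set(self.calibration_levels), set(self.prediction_levels)
        if cal & pred:
            raise ValueError(f"levels in both splits: {sorted(cal & pred)}")
        if cal | pred != set(self.levels):
            raise ValueError("calibration and prediction levels must partition levels")

    @property
    def n_samples(self) -> int:
        return sum(self.replicates_per_level)


@dataclass
class NoiseModel:
    """Per-spectrum gain jitter, affine baseline drift and additive noise.

    ``resolution_fwhm`` smooths the additive noise with a Gaussian line
    shape of that FWHM (cm^-1), preserving the per-channel standard
    deviation: a spectrometer sampling finer than its optical resolution
    produces noise that is correlated across neighbouring channels, not
    white. Zero means white noise.

    ``matrix_jitter_sd`` is the relative sd of per-sample, per-band height
    fluctuations of the tea matrix (each tea peak and its background get an
    independent multiplier 1 + N(0, sd) per sample). Distinct tea samples
    differ in composition; without this term the dose would be perfectly
    confounded with overall spectrum scale and every channel would act as a
    clean dose sensor, which no real matrix allows.
    """

    additive_sd: float = 0.0
    multiplicative_scale_sd: float = 0.0
    baseline_offset_sd: float = 0.0
    baseline_slope_sd: float = 0.0
    resolution_fwhm: float = 0.0
    matrix_jitter_sd: float = 0.0

    def __post_init__(self) -> None:
        for name in ("additive_sd", "multiplicative_scale_sd",
                     "baseline_offset_sd", "baseline_slope_sd",
                     "resolution_fwhm", "matrix_jitter_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class SyntheticConfig:
    """Everything that defines one simulated dataset, including the seed."""

    raw_grid: tuple  # (start cm^-1, stop cm^-1, n_points)
    tea: ComponentSpectrum
    talc: ComponentSpectrum
    kappa: float  # AU per (mg/g): scale of the talc contribution
    design: DoseDesign
    noise: NoiseModel
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kappa <= 0:
            raise ValueError(f"kappa must be > 0, got {self.kappa}")
        start, stop, n = self.raw_grid
        if not (stop > start and int(n) >= 2):
            raise ValueError(f"invalid raw grid {self.raw_grid}")
        self.raw_grid = (float(start), float(stop), int(n))

    def grid(self) -> np.ndarray:
        start, stop, n = self.raw_grid
        return np.linspace(start, stop, n)


def _default_tea() -> ComponentSpectrum:
    # Broad organic bands: polyphenol/caffeine ring modes near 1401 and
    # 1617, C-H stretch near 2920, O-H/C-H envelope near 3117 cm^-1.
    return ComponentSpectrum(
        name="tea",
        peaks=[
            PeakSpec(1050.0, 0.35, 130.0),
            PeakSpec(1401.0, 0.55, 95.0),
            PeakSpec(1617.0, 0.60, 85.0),
            PeakSpec(2920.0, 0.45, 110.0),
            PeakSpec(3117.0, 0.50, 260.0),
        ],
        broad_background=BroadBackground(amplitude=0.25, length_scale=1800.0),
    )


def _default_talc() -> ComponentSpectrum:
    # Si-O-Si stretches dominate near 990-1055 with the apex at 1016;
    # secondary carbonate/hydroxyl/Si-H bands per the band assignments.
    return ComponentSpectrum(
        name="talc",
        peaks=[
            PeakSpec(1016.0, 1.00, 14.0),
            PeakSpec(995.0, 0.55, 11.0),
            PeakSpec(1050.0, 0.50, 13.0),
            PeakSpec(1182.0, 0.30, 15.0),
            PeakSpec(1249.0, 0.30, 15.0),
            PeakSpec(1340.0, 0.25, 13.0),
            PeakSpec(1444.0, 0.35, 18.0),
            PeakSpec(1631.0, 0.20, 16.0),
            PeakSpec(2296.0, 0.15, 20.0),
        ],
        broad_background=BroadBackground(amplitude=0.04, length_scale=2500.0),
    )


def default_config(seed: int = 0) -> SyntheticConfig:
    """The default study conditions.

    3700 grid points on [400, 4000] cm^-1 so that trimming 500 + 400 points
    leaves exactly 2800 variables; 13 dose levels with 20 replicates per
    calibration level (140 samples) and 12 per prediction level (72);
    kappa = 0.06 so the talc contribution at the top dose is ~10% of the tea
    apex (the adulteration is invisible to the naked eye). Gain and baseline
    noise give scatter correction something to do; the additive noise floor
    is set so a full-spectrum SNV + PLS model reaches the accuracy scale an
    FT-IR study of this design reports (RMSEP on the order of 0.1 mg/g),
    not numerical perfection.
    """
    design = DoseDesign(
        levels=DOSE_LEVELS,
        replicates_per_level=tuple(
            20 if lv in CALIBRATION_LEVELS else 12 for lv in DOSE_LEVELS
        ),
        calibration_levels=CALIBRATION_LEVELS,
        prediction_levels=PREDICTION_LEVELS,
    )
    noise = NoiseModel(
        additive_sd=0.010,
        multiplicative_scale_sd=0.05,
        baseline_offset_sd=0.01,
        baseline_slope_sd=5e-6,
        resolution_fwhm=4.0,
        matrix_jitter_sd=0.03,
    )
    return SyntheticConfig(
        raw_grid=(400.0, 4000.0, 3700),
        tea=_default_tea(),
        talc=_default_talc(),
        kappa=0.06,
        design=design,
        noise=noise,
        seed=int(seed),
    )


def _line_shape_correlate(eps: np.ndarray, grid: np.ndarray, fwhm: float) -> np.ndarray:
    """Convolve white noise rows with a Gaussian line shape of given FWHM.

    The kernel has unit L2 norm so the per-channel standard deviation is
    preserved; only the channel-to-channel correlation changes.
    """
    dw = float(np.mean(np.diff(grid)))
    sigma_pts = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / dw
    if sigma_pts <= 0:
        return eps
    radius = max(1, int(np.ceil(4.0 * sigma_pts)))
    x = np.arange(-radius, radius + 1)
    kernel = np.exp(-0.5 * (x / sigma_pts) ** 2)
    kernel /= np.linalg.norm(kernel)
    out = signal.fftconvolve(eps, kernel[None, :], mode="same", axes=1)
    return out


def simulate_dataset(config: SyntheticConfig) -> SpectrumSet:
    """Simulate the raw (untrimmed) dataset defined by ``config``.

    Deterministic given the seed: the single integer seed expands into
    independent substreams for gain, baseline and additive noise, so turning
    one noise source on or off leaves the draws of the others unchanged.
    """
    design = config.design
    if design.n_samples == 0:
        raise ValueError("empty dose design")
    grid = config.grid()
    tea = evaluate_component(config.tea, grid)
    talc = evaluate_component(config.talc, grid)

    doses, labels = [], []
    cal = set(design.calibration_levels)
    for level, reps in zip(design.levels, design.replicates_per_level):
        doses.extend([level] * reps)
        labels.extend([CALIBRATION if level in cal else PREDICTION] * reps)
    dose = np.array(doses, dtype=float)
    n = dose.size

    gain_rng, base_rng, eps_rng, matrix_rng = (
        np.random.default_rng(s) for s in np.random.SeedSequence(config.seed).spawn(4)
    )
    nm = config.noise
    gain = 1.0 + gain_rng.normal(0.0, nm.multiplicative_scale_sd, size=n)
    offset = base_rng.normal(0.0, nm.baseline_offset_sd, size=n)
    slope = base_rng.normal(0.0, nm.baseline_slope_sd, size=n)
    eps = eps_rng.normal(0.0, nm.additive_sd, size=(n, grid.size))
    if nm.resolution_fwhm > 0 and nm.additive_sd > 0:
        eps = _line_shape_correlate(eps, grid, nm.resolution_fwhm)

    if nm.matrix_jitter_sd > 0:
        # per-sample tea spectrum: each band and the background fluctuate
        basis = np.vstack(
            [config.tea.broad_background.evaluate(grid)]
            + [pk.evaluate(grid) for pk in config.tea.peaks]
        )
        mult = 1.0 + matrix_rng.normal(0.0, nm.matrix_jitter_sd, size=(n, basis.shape[0]))
        tea_matrix = mult @ basis
    else:
        tea_matrix = np.broadcast_to(tea, (n, grid.size))

    clean = tea_matrix + dose[:, None] * config.kappa * talc[None, :]
    baseline = offset[:, None] + slope[:, None] * (grid - grid.mean())[None, :]
    absorbance = gain[:, None] * clean + baseline + eps
    return SpectrumSet(grid, absorbance, dose, np.array(labels, dtype=object))


def split_by_level(data: SpectrumSet, design: DoseDesign):
    """Partition samples into (calibration, prediction) purely by dose level."""
    cal = set(design.calibration_levels)
    pred = set(design.prediction_levels)
    assign = []
    for d in data.dose:
        if d in cal:
            assign.append(CALIBRATION)
        elif d in pred:
            assign.append(PREDICTION)
        else:
            raise ValueError(f"dose {d} mg/g is in neither level set of the design")
    assign = np.array(assign, dtype=object)
    relabeled = SpectrumSet(
        data.wavenumbers.copy(), data.absorbance.copy(), data.dose.copy(), assign
    )
    return relabeled.calibration(), relabeled.prediction()


# ---------------------------------------------------------------------------
# YAML config round-trip


def config_to_dict(config: SyntheticConfig) -> dict:
    return asdict(config)


def _component_from_dict(d: dict) -> ComponentSpectrum:
    return ComponentSpectrum(
        name=d["name"],
        peaks=[PeakSpec(**p) for p in d["peaks"]],
        broad_background=BroadBackground(**d.get("broad_background", {})),
    )


def config_from_dict(d: dict) -> SyntheticConfig:
    return SyntheticConfig(
        raw_grid=tuple(d["raw_grid"]),
        tea=_component_from_dict(d["tea"]),
        talc=_component_from_dict(d["talc"]),
        kappa=float(d["kappa"]),
        design=DoseDesign(**d["design"]),
        noise=NoiseModel(**d.get("noise", {})),
        seed=int(d.get("seed", 0)),
    )


def save_config(config: SyntheticConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)


def load_config(path) -> SyntheticConfig:
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh))
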