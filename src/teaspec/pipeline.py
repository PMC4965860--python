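"""End-to-end study orchestration.

Runs the whole analysis in order: simulate (or load) spectra, trim the noisy
band edges, compare the preprocessing treatments with PLS models, PCA for a
qualitative look, run the biPLS -> CARS -> SPA cascade on the calibration
set of the best-preprocessed spectra, and finish with a PLS and an ELM model
on the final wavenumber subset. All randomness descends from one master
seed. Prediction-set labels are touched only when final metrics are
computed: selection and the hidden-node sweep see calibration data alone.

"Best" is reported carefully: preprocessing treatments are ranked by R_P
(minimum RMSEP breaking ties), while the final model ranking is by RMSEP
with both orderings printed and a flag when they disagree.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from datetime import datetime, timezone
from decimal import Decimal, ROUND_HALF_UP

import numpy as np

from . import preprocessing as prep
from . import synthetic_data as synth
from .chemometrics import ModelMetrics, fit_pls, loo_cv, metrics, pca, predict_pls
from .dataset import SpectrumSet, read_csv
from .elm import fit_elm, predict_elm, sweep_hidden_nodes
from .variable_selection import (
    BiPLSConfig,
    CARSConfig,
    SPAConfig,
    SelectionResult,
    cascade,
)

__all__ = [
    "PipelineConfig",
    "PipelineReport",
    "fraction_of_full",
    "compare_preprocessing",
    "run_full_pipeline",
]

logger = logging.getLogger("teaspec")


def fraction_of_full(selected: int, full: int):
    """Percent of the full variable count, exact and rounded half-up to 2 dp."""
    if full <= 0:
        raise ValueError(f"full variable count must be > 0, got {full}")
    if not 0 <= selected <= full:
        raise ValueError(f"selected count {selected} outside [0, {full}]")
    exact = 100.0 * selected / full
    rounded = float(Decimal(repr(exact)).quantize(Decimal("0.01"), ROUND_HALF_UP))
    return exact, rounded


@dataclass
class PipelineConfig:
    """Everything one run needs; either a synthetic config or a CSV path."""

    synthetic: synth.SyntheticConfig | None = None
    csv_path: str | None = None
    trim_front: int = 500
    trim_back: int = 400
    methods: tuple = ("raw", "smoothing", "normalize", "snv")
    selection_input: str | None = None  # override the best-R_P treatment
    bipls: BiPLSConfig | None = field(default_factory=BiPLSConfig)
    cars: CARSConfig | None = field(default_factory=CARSConfig)
    spa: SPAConfig | None = field(default_factory=SPAConfig)
    elm_nodes: tuple = tuple(range(1, 81))
    max_components: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.synthetic is None and self.csv_path is None:
            self.synthetic = synth.default_config()
        self.elm_nodes = tuple(int(h) for h in self.elm_nodes)


@dataclass
class PipelineReport:
    """Machine-readable record of one full run."""

    provenance: dict
    preprocessing: dict
    pca: dict
    selection: list
    models: dict
    ranking: dict

    def to_dict(self) -> dict:
        return {
            "provenance": self.provenance,
            "preprocessing": self.preprocessing,
            "pca": self.pca,
            "selection": self.selection,
            "models": self.models,
            "ranking": self.ranking,
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent)

    def summary(self) -> str:
        lines = ["model                 R_C    RMSEC  R_CV   RMSECV R_P    RMSEP"]
        entries = dict(self.preprocessing["models"])
        entries.update(self.models)
        for name, entry in entries.items():
            m = entry["metrics"]
            label = entry.get("method", entry.get("stage", ""))
            lines.append(
                f"{name:<10s} {label:<10s} "
                + " ".join(f"{m[k]:<6.3f}" for k in
                           ("R_C", "RMSEC", "R_CV", "RMSECV", "R_P", "RMSEP"))
            )
        for st in self.selection:
            lines.append(
                f"{st['stage']:<6s} kept {st['n_selected']:>5d} variables "
                f"({st['pct_of_full']:.2f}% of {st['full_variables']})"
            )
        return "\n".join(lines)


def _pls_metrics(cal: SpectrumSet, pred: SpectrumSet, cols, max_components):
    """Fit a PLS model on calibration columns ``cols``; return the sextet."""
    Xc = cal.absorbance[:, cols]
    Xp = pred.absorbance[:, cols]
    cv = loo_cv(Xc, cal.dose, max_components)
    model = fit_pls(Xc, cal.dose, cv.n_components)
    r_c, rmsec = metrics(cal.dose, predict_pls(model, Xc))
    r_p, rmsep = metrics(pred.dose, predict_pls(model, Xp))
    mm = ModelMetrics(r_c, rmsec, cv.r_cv, cv.rmsecv, r_p, rmsep)
    return mm, cv.n_components


def compare_preprocessing(
    data: SpectrumSet,
    methods=("raw", "smoothing", "normalize", "snv"),
    max_components: int = 10,
    smoothing_window: int = 9,
):
    """One PLS model per treatment; Table-style fragment plus the processed sets.

    Best treatment = highest R_P, minimum RMSEP breaking ties.
    """
    if data.calibration().n_samples == 0 or data.prediction().n_samples == 0:
        raise ValueError("need both calibration and prediction samples")
    entries: dict = {}
    processed: dict = {}
    for i, name in enumerate(methods, start=1):
        method = prep.PreprocessMethod(name, window=smoothing_window)
        t0 = time.perf_counter()
        treated = prep.apply_method(data, method)
        mm, k = _pls_metrics(
            treated.calibration(), treated.prediction(),
            np.arange(treated.n_variables), max_components,
        )
        processed[name] = treated
        entries[f"Model {i}"] = {
            "method": name,
            "n_components": k,
            "metrics": mm.as_dict(),
        }
        logger.info(
            "preprocessing %-9s R_P=%.3f RMSEP=%.3f (%.1fs)",
            name, mm.r_p, mm.rmsep, time.perf_counter() - t0,
        )
    best_id = max(
        entries,
        key=lambda mid: (entries[mid]["metrics"]["R_P"],
                         -entries[mid]["metrics"]["RMSEP"]),
    )
    fragment = {
        "models": entries,
        "best_model": best_id,
        "best_method": entries[best_id]["method"],
    }
    return fragment, processed


def _selection_entry(res: SelectionResult, full: int) -> dict:
    exact, rounded = fraction_of_full(res.n_selected, full)
    return {
        "stage": res.stage,
        "n_selected": int(res.n_selected),
        "full_variables": int(full),
        "pct_of_full": rounded,
        "pct_of_full_exact": exact,
        "wavenumbers": res.display_wavenumbers().tolist(),
        "rmsecv_trace": [round(float(v), 5) for v in res.rmsecv_trace],
    }


def _config_hash(config: PipelineConfig) -> str:
    blob = repr(config).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_full_pipeline(config: PipelineConfig) -> PipelineReport:
    """Execute the ordered stages and assemble the report."""
    seeds = np.random.SeedSequence(config.seed).generate_state(3) % 2**31
    t_start = time.perf_counter()

    if config.csv_path is not None:
        data = read_csv(config.csv_path)
    else:
        sc = config.synthetic
        sc = synth.config_from_dict({**synth.config_to_dict(sc), "seed": int(seeds[0])})
        data = synth.simulate_dataset(sc)
    if config.trim_front or config.trim_back:
        data = prep.trim(data, config.trim_front, config.trim_back)
    logger.info("data: %d samples x %d variables", data.n_samples, data.n_variables)

    fragment, processed = compare_preprocessing(
        data, config.methods, config.max_components
    )
    sel_method = config.selection_input or fragment["best_method"]
    best_set = processed[sel_method]

    pca_res = pca(best_set.absorbance)
    pct = pca_res.explained_variance_pct
    pca_block = {
        "explained_variance_pct": [round(float(v), 1) for v in pct[:10]],
        "top3_cumulative_pct": round(float(pct[:3].sum()), 1),
        "preprocessing": sel_method,
    }

    cal = best_set.calibration()
    pred = best_set.prediction()
    full = best_set.n_variables

    selection_block: list = []
    models: dict = {}
    cars_cfg = config.cars
    if cars_cfg is not None:
        cars_cfg = CARSConfig(
            n_runs=cars_cfg.n_runs,
            calibration_fraction=cars_cfg.calibration_fraction,
            max_components=cars_cfg.max_components,
            seed=int(seeds[1]),
        )
    if any(c is not None for c in (config.bipls, cars_cfg, config.spa)):
        results = cascade(
            cal.absorbance, cal.dose, best_set.wavenumbers,
            config.bipls, cars_cfg, config.spa,
        )
        selection_block = [_selection_entry(r, full) for r in results]
        final_cols = results[-1].selected_indices

        mm, k = _pls_metrics(cal, pred, final_cols, config.max_components)
        models["PLS-subset"] = {
            "stage": results[-1].stage,
            "n_variables": int(final_cols.size),
            "n_components": k,
            "metrics": mm.as_dict(),
        }

        best_h, rmsecv_nodes, oof = sweep_hidden_nodes(
            cal.absorbance[:, final_cols], cal.dose,
            node_range=config.elm_nodes, seed=int(seeds[2]),
            return_predictions=True,
        )
        j = list(config.elm_nodes).index(best_h)
        elm_model = fit_elm(
            cal.absorbance[:, final_cols], cal.dose, best_h, seed=int(seeds[2])
        )
        r_c, rmsec = metrics(cal.dose, predict_elm(elm_model, cal.absorbance[:, final_cols]))
        r_cv, rmsecv = metrics(cal.dose, oof[j])
        r_p, rmsep = metrics(pred.dose, predict_elm(elm_model, pred.absorbance[:, final_cols]))
        models["ELM-subset"] = {
            "stage": results[-1].stage,
            "n_variables": int(final_cols.size),
            "n_hidden": int(best_h),
            "metrics": ModelMetrics(r_c, rmsec, r_cv, rmsecv, r_p, rmsep).as_dict(),
        }

    all_models = dict(fragment["models"])
    all_models.update(models)
    by_rmsep = sorted(all_models, key=lambda m: all_models[m]["metrics"]["RMSEP"])
    by_r_p = sorted(all_models, key=lambda m: -all_models[m]["metrics"]["R_P"])
    ranking = {
        "by_rmsep": by_rmsep,
        "by_r_p": by_r_p,
        "agreement": by_rmsep[0] == by_r_p[0],
    }

    report = PipelineReport(
        provenance={
            "seed": int(config.seed),
            "config_hash": _config_hash(config),
            "generated_at": datetime.now(timezone.utc).isoformat(),
        },
        preprocessing=fragment,
        pca=pca_block,
        selection=selection_block,
        models=models,
        ranking=ranking,
    )
    logger.info("pipeline finished in %.1fs", time.perf_counter() - t_start)
    return report
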