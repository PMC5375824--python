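"""End-to-end seeded runs: simulate -> preprocess -> calibrate -> search -> report.

One global seed fans out to per-stage child seeds through
``numpy.random.SeedSequence``, so any stage can be re-run independently yet
reproducibly.  The run directory receives the spectral libraries, the
pretreatment record, serialized models, evaluation reports, band-search
matrices, the method-comparison table and a machine-readable manifest.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import bandpair, calibrate, evaluate, preprocess
from .spectra import Mode, SpectraSet, write_spectra_table
from .synth import SimulationConfig, plant_outliers, simulate_dataset

logger = logging.getLogger(__name__)

METHODS = ("pcr", "plsr", "smlr", "bpnn")


@dataclass
class PipelineConfig:
    """Everything a run needs; fully serializable, reproducible from seed."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    modes: tuple[str, ...] = (Mode.BLACK_BACKGROUND.value, Mode.WHITE_BACKGROUND.value)
    n_outliers: int = 10            # gross measurement failures planted per mode
    outlier_magnitude: float = 3.0
    screen_k_components: int = 5
    screen_alpha: float = 0.005
    n_calibration: int = 600
    methods: tuple[str, ...] = METHODS
    pcr_variance_target: float = 0.80   # the "80% information" PC convention
    plsr_max_factors: int = 20
    smlr_p_enter: float = 0.05
    smlr_max_terms: int = 15
    bpnn_variance_target: float = 0.85
    bpnn_hidden_sizes: tuple[int, ...] = (3, 5, 8, 12)
    bpnn_n_restarts: int = 10
    index_kinds: tuple[str, ...] = ("dsi", "rsi", "ndsi")
    index_interval_nm: int = 10
    run_band_search: bool = True
    seed: int = 0


def child_seeds(seed: int, n: int) -> list[int]:
    """Deterministic per-stage seeds below 2^31."""
    ss = np.random.SeedSequence(seed)
    return [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(n)]


def pcr_components_for_variance(X: np.ndarray, variance_target: float,
                                cap: int = 30) -> int:
    """Smallest PC count reaching the cumulative-variance target (capped)."""
    Xc = X - X.mean(axis=0)
    s = np.linalg.svd(Xc, compute_uv=False)
    evr = np.cumsum(s**2) / np.sum(s**2)
    k = int(np.searchsorted(evr, variance_target) + 1)
    return min(k, cap, X.shape[0] - 1)


def fit_method(method: str, X, y, wl, cfg: PipelineConfig, seed: int
               ) -> calibrate.RegressionModel:
    method = method.lower()
    if method == "pcr":
        k = pcr_components_for_variance(X, cfg.pcr_variance_target)
        return calibrate.fit_pcr(X, y, n_components=k, wavelengths=wl)
    if method == "plsr":
        return calibrate.fit_plsr(X, y, max_factors=cfg.plsr_max_factors, wavelengths=wl)
    if method == "smlr":
        return calibrate.fit_smlr(X, y, p_enter=cfg.smlr_p_enter,
                                  max_terms=cfg.smlr_max_terms, wavelengths=wl)
    if method == "bpnn":
        return calibrate.fit_bpnn(
            X, y, variance_target=cfg.bpnn_variance_target,
            hidden_sizes=cfg.bpnn_hidden_sizes, n_restarts=cfg.bpnn_n_restarts,
            rng=np.random.default_rng(seed), wavelengths=wl)
    raise ValueError(f"unknown method {method!r}")


def preprocess_mode(raw: SpectraSet, cfg: PipelineConfig, seed: int
                    ) -> tuple[SpectraSet, SpectraSet, preprocess.PretreatmentRecord]:
    """PCA/T2 screen on raw spectra -> normalize -> random cal/val split.

    The screen runs before normalization: gross measurement failures are
    mostly scale anomalies, and unit-vector normalization would hide exactly
    those.
    """
    record = preprocess.PretreatmentRecord()
    work = raw
    if raw.mode is Mode.SOLAR_25DEG:
        work = preprocess.remove_atmospheric_bands(work, record=record)
    work, _removed = preprocess.pca_outlier_screen(
        work, k_components=cfg.screen_k_components, alpha=cfg.screen_alpha,
        record=record)
    work = preprocess.normalize_set(work, record=record)
    cal, val = preprocess.split_calibration_validation(
        work, cfg.n_calibration, seed=seed, record=record)
    return cal, val, record


def run_pipeline(config: PipelineConfig, outdir) -> Path:
    """Execute every stage for every configured mode; returns the run directory."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = child_seeds(config.seed, 4 * len(config.modes))
    reports: list[evaluate.EvaluationReport] = []
    manifest: dict = {"seed": config.seed, "modes": {}, "methods": list(config.methods)}

    for mi, mode_name in enumerate(config.modes):
        mode = Mode.coerce(mode_name)
        s_sim, s_out, s_split, s_fit = seeds[4 * mi:4 * mi + 4]
        sim_cfg = replace(config.simulation, mode=mode, seed=s_sim)
        raw = simulate_dataset(sim_cfg)
        if config.n_outliers:
            raw, planted = plant_outliers(raw, config.n_outliers,
                                          config.outlier_magnitude,
                                          np.random.default_rng(s_out))
        else:
            planted = []
        write_spectra_table(raw, out / f"library_{mode.value}.csv")

        cal, val, record = preprocess_mode(raw, config, seed=s_split)
        (out / f"pretreatment_{mode.value}.txt").write_text(record.as_text())
        logger.info("mode %s: %d raw -> %d kept -> %d cal + %d val",
                    mode.value, len(raw), len(cal) + len(val), len(cal), len(val))

        Xc, wl = cal.matrix()
        Xv, _ = val.matrix()
        mode_info = {
            "n_raw": len(raw), "n_planted_outliers": len(planted),
            "n_removed": len(record.removed_sample_ids),
            "n_cal": len(cal), "n_val": len(val), "models": {},
        }
        for method in config.methods:
            model = fit_method(method, Xc, cal.n_gkg, wl, config, s_fit)
            model.to_json(out / f"model_{method}_{mode.value}.json")
            rep = evaluate.evaluation_report(
                f"{method.upper()} ({mode.value})",
                cal.n_gkg, calibrate.predict(model, Xc),
                val.n_gkg, calibrate.predict(model, Xv))
            reports.append(rep)
            mode_info["models"][method] = {
                "meta": model.meta,
                "report": rep.as_dict(),
            }

        if config.run_band_search:
            screened = SpectraSet(cal.spectra + val.spectra,
                                  np.concatenate([cal.n_gkg, val.n_gkg]))
            mode_info["band_search"] = {}
            for kind in config.index_kinds:
                res = bandpair.exhaustive_search(screened, kind,
                                                 config.index_interval_nm)
                bandpair.export_contour(res, out / f"r2_{kind}_{mode.value}.csv")
                mode_info["band_search"][kind] = {
                    "best_pair_nm": list(res.best_pair),
                    "best_r2": res.best_r2,
                }
        manifest["modes"][mode.value] = mode_info

    if len(reports) >= 2:
        table = evaluate.compare_methods(reports)
        table.to_csv(out / "comparison.csv", index=False)
    else:
        (out / "report.json").write_text(json.dumps(reports[0].as_dict(), indent=2))
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return out
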