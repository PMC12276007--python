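"""Configurable multi-stage analysis pipeline.

An :class:`AnalysisConfig` (schema-validated; unknown keys rejected) names
the stages to run.  ``run_pipeline`` executes them in a fixed order
(scan -> enumerate -> simulate-folding -> cd-quant -> fits -> simulate-hdx),
writes JSON results and TSV tables under the output directory, and logs the
package version, a config hash, and the seed so a rerun with the same
config reproduces the bundle exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np
from pydantic import BaseModel, ConfigDict

from . import __version__
from .cd import fraction_folded, mean_folds_from_fraction, molar_cd, CDSpectrum
from .io import jsonify, read_table, write_report, write_table
from .kinetics import (ExchangeSeries, KineticTrace, fit_boltzmann_melt,
                       fit_hdx_biexponential, fit_hdx_mono,
                       fit_single_exponential)
from .placement import (adjacency_stats, enumerate_configurations,
                        simulate_sequential_folding)
from .register_exchange import RegisterExchangeModel, gillespie_hdx
from .repeats import scan_fasta
from .synth import default_hdx_schedule, gu12_reference

log = logging.getLogger("pugfold")


class _Stage(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ScanStage(_Stage):
    fasta: str
    min_repeats: float = 12.0


class EnumerateStage(_Stage):
    repeats: float
    fold_size: int = 12
    maximal: bool = True


class SimulateFoldingStage(_Stage):
    repeats: float
    molecules: int = 10_000
    fold_size: int = 12


class CDQuantStage(_Stage):
    sample: str
    concentration: float
    path_length: float
    n_nt: int
    reference: Optional[str] = None  # default: built-in (GU)12 basis
    ref_concentration: Optional[float] = None
    ref_path_length: Optional[float] = None
    ref_n_nt: int = 24


class FitFoldingStage(_Stage):
    path: str


class FitHdxStage(_Stage):
    path: str
    model: str = "mono"  # or "biexp"


class FitMeltStage(_Stage):
    path: str


class SimulateHdxStage(_Stage):
    k_flip: float
    k_unfold: float
    flank5: float = 1.0
    flank3: float = 1.0
    molecules: int = 10_000
    times: Optional[str] = None  # CSV of time_h; default HDX schedule


class AnalysisConfig(_Stage):
    """Validated pipeline configuration (unknown keys rejected)."""

    seed: int = 0
    output_dir: str = "results"
    scan: Optional[ScanStage] = None
    enumerate_folds: Optional[EnumerateStage] = None
    simulate_folding: Optional[SimulateFoldingStage] = None
    cd_quant: Optional[CDQuantStage] = None
    fit_folding: Optional[FitFoldingStage] = None
    fit_hdx: Optional[FitHdxStage] = None
    fit_melt: Optional[FitMeltStage] = None
    simulate_hdx: Optional[SimulateHdxStage] = None


def config_hash(config: AnalysisConfig) -> str:
    payload = json.dumps(config.model_dump(), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def bundle_hash(bundle: dict) -> str:
    payload = json.dumps(jsonify(bundle), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()


def _load_cd(path: str, c: float, l: float, n: int) -> CDSpectrum:
    df = read_table(path, ["wavelength_nm", "theta_mdeg"])
    return CDSpectrum(df["wavelength_nm"].to_numpy(),
                      df["theta_mdeg"].to_numpy(), c, l, n)


def run_pipeline(config: AnalysisConfig) -> dict:
    """Execute the configured stages and write the result bundle."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict = {}

    if config.scan is not None:
        table = scan_fasta(config.scan.fasta, config.scan.min_repeats)
        write_table(table, outdir / "scan_runs.tsv")
        results["scan"] = {"n_runs": int(len(table)),
                           "records": sorted(table["record_id"].unique().tolist())}

    if config.enumerate_folds is not None:
        st = config.enumerate_folds
        configs = enumerate_configurations(st.repeats, st.fold_size,
                                           maximal_only=st.maximal)
        stats = adjacency_stats(configs) if configs else None
        results["enumerate"] = {
            "n_configs": len(configs),
            "stats": jsonify(stats) if stats else None,
        }

    if config.simulate_folding is not None:
        st = config.simulate_folding
        ensemble = simulate_sequential_folding(st.repeats, st.molecules,
                                               seed=config.seed,
                                               fold_repeats=st.fold_size)
        stats = adjacency_stats(ensemble)
        mean_folds = float(np.mean([c.n_folds for c in ensemble]))
        results["simulate_folding"] = {"stats": jsonify(stats),
                                       "mean_folds": mean_folds}

    if config.cd_quant is not None:
        st = config.cd_quant
        sample = molar_cd(_load_cd(st.sample, st.concentration,
                                   st.path_length, st.n_nt))
        if st.reference is not None:
            ref = molar_cd(_load_cd(
                st.reference,
                st.ref_concentration or st.concentration,
                st.ref_path_length or st.path_length,
                st.ref_n_nt))
        else:
            ref = gu12_reference()
        frac = fraction_folded(sample, ref)
        results["cd_quant"] = {
            "per_peak": jsonify(frac.per_peak),
            "mean_fraction": frac.mean_fraction,
            "implied_mean_folds": mean_folds_from_fraction(
                min(frac.mean_fraction, 1.05), st.n_nt),
        }

    if config.fit_folding is not None:
        df = read_table(config.fit_folding.path, ["time_min", "signal"])
        fit = fit_single_exponential(KineticTrace(
            df["time_min"].to_numpy(), df["signal"].to_numpy(), "min"))
        results["fit_folding"] = jsonify(fit)

    if config.fit_hdx is not None:
        st = config.fit_hdx
        df = read_table(st.path, ["time_h", "integral"])
        series = ExchangeSeries(df["time_h"].to_numpy(),
                                df["integral"].to_numpy())
        fit = (fit_hdx_biexponential(series) if st.model == "biexp"
               else fit_hdx_mono(series))
        results["fit_hdx"] = jsonify(fit)

    if config.fit_melt is not None:
        df = read_table(config.fit_melt.path, ["temp_C", "signal"])
        fit = fit_boltzmann_melt(KineticTrace(
            df["temp_C"].to_numpy(), df["signal"].to_numpy(), "C"))
        results["fit_melt"] = jsonify(fit)

    if config.simulate_hdx is not None:
        st = config.simulate_hdx
        if st.times is not None:
            times = read_table(st.times, ["time_h"])["time_h"].to_numpy()
        else:
            times = default_hdx_schedule()
        model = RegisterExchangeModel(k_flip=st.k_flip, k_unfold=st.k_unfold,
                                      flank_5=st.flank5, flank_3=st.flank3)
        pred = gillespie_hdx(model, st.molecules, times, seed=config.seed)
        import pandas as pd

        write_table(pd.DataFrame({"time_h": pred.times,
                                  "survival": pred.survival}),
                    outdir / "hdx_survival.tsv")
        results["simulate_hdx"] = {
            "fast_amplitude": pred.fast_amplitude,
            "k_fast": pred.k_fast,
            "k_slow": pred.k_slow,
            "final_survival": float(pred.survival[-1]),
        }

    bundle = {
        "version": __version__,
        "config_hash": config_hash(config),
        "seed": config.seed,
        "results": results,
    }
    write_report(bundle, outdir / "results.json")
    log.info("pipeline complete: version=%s config=%s seed=%d stages=%s",
             __version__, config_hash(config), config.seed,
             sorted(results))
    return bundle
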