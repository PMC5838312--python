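"""End-to-end orchestration: data -> rates -> extended model -> FVA ->
per-phase FBA/NGAM -> energetics -> EFM table -> sampling -> report."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .constraints import PhaseConstraintSet
from .efm import EFMTable, substrate_product_table
from .energetics import (
    EnergeticsReport,
    ProtonReport,
    RedoxReport,
    atp_accounting,
    proton_accounting,
    redox_accounting,
)
from .extended import (
    AccumulationBounds,
    apply_experimental_constraints,
    build_extended_model,
    fva_accumulation,
    split_into_phase_models,
)
from .fba import (
    FluxDistribution,
    NGAMResult,
    SensitivityReport,
    estimate_ngam,
    ngam_sensitivity,
    solve_fba,
)
from .network import MetabolicNetwork, read_network
from .rates import RateSet, TimeCourse, estimate_rates, rates_to_frame
from .reduced_model import (
    PRODUCT_EXCHANGES,
    SUBSTRATE_EXCHANGES,
    load_reduced_oeni_model,
)
from .sampling import FlexibilityReport, flexibility_stats, sample_flux_space
from .synth import GeneratorConfig, default_config, simulate_culture

logger = logging.getLogger("oenoflux")

EXCHANGE_BY_NAME = {**SUBSTRATE_EXCHANGES, **PRODUCT_EXCHANGES}


class PipelineConfigError(ValueError):
    pass


def phase_constraints_from_rates(
    rate_sets: Sequence[RateSet],
    tolerance: float = 0.025,
    exchange_map: Optional[Dict[str, str]] = None,
    n_phases: int = 3,
) -> List[PhaseConstraintSet]:
    """Measured-rate constraint sets for the growth phases (IV excluded)."""
    exchange_map = exchange_map or EXCHANGE_BY_NAME
    out = []
    for rs in rate_sets[:n_phases]:
        fixed = {
            exchange_map[name]: rs.q[name]
            for name in exchange_map
            if name in rs.q
        }
        out.append(
            PhaseConstraintSet(
                phase_id=rs.phase_id,
                fixed_fluxes=fixed,
                biomass=rs.mu,
                tolerance=tolerance,
            )
        )
    return out


@dataclass
class PipelineConfig:
    model_path: Optional[str] = None  # None -> packaged reduced network
    timecourse_path: Optional[str] = None
    ethanol_levels: Tuple[float, ...] = (0.0, 3.0, 6.0, 9.0, 12.0)
    synth_noise_cv: float = 0.0
    seed: int = 0
    tolerance: float = 0.0
    ngam_grid_step: float = 0.01
    run_sensitivity: bool = False
    run_efm: bool = True
    run_sampling: bool = False
    sampling_n: int = 1000
    sampling_thinning: int = 100
    output_dir: str = "oenoflux_out"
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise PipelineConfigError(f"unknown config keys: {sorted(unknown)}")
        if "ethanol_levels" in raw:
            raw["ethanol_levels"] = tuple(float(x) for x in raw["ethanol_levels"])
        return cls(**raw)

    def validate(self) -> None:
        for attr in ("ngam_grid_step", "sampling_n", "sampling_thinning"):
            if getattr(self, attr) <= 0:
                raise PipelineConfigError(f"{attr} must be positive")
        if self.tolerance < 0 or self.synth_noise_cv < 0:
            raise PipelineConfigError("tolerance/noise must be non-negative")
        for path_attr in ("model_path", "timecourse_path"):
            path = getattr(self, path_attr)
            if path is not None and not os.path.exists(path):
                raise PipelineConfigError(f"{path_attr} {path!r} does not exist")


@dataclass
class PhaseResult:
    ethanol_level: float
    phase_id: int
    rates: RateSet
    ngam: NGAMResult
    fba: FluxDistribution
    energetics: EnergeticsReport
    redox: RedoxReport
    protons: ProtonReport
    sensitivity: Optional[SensitivityReport] = None
    flexibility: Optional[FlexibilityReport] = None


@dataclass
class RunReport:
    config: PipelineConfig
    phase_results: List[PhaseResult]
    accumulation_spans: Dict[float, AccumulationBounds]
    efm_table: Optional[EFMTable]
    provenance: Dict[str, str]

    def to_json_dict(self) -> dict:
        def flux_block(pr: PhaseResult) -> dict:
            mu = pr.rates.mu
            return {
                "ethanol_level": pr.ethanol_level,
                "phase": pr.phase_id,
                "mu": mu,
                "ngam": pr.ngam.ngam,
                "biomass_error": pr.ngam.biomass_error,
                "q": pr.rates.q,
                "fluxes": pr.fba.fluxes,
                "fluxes_per_mu": {
                    k: (v / mu if mu else float("nan"))
                    for k, v in pr.fba.fluxes.items()
                },
                "atp": {
                    "f0f1": pr.energetics.r_atp_f0f1,
                    "pkp": pr.energetics.r_atp_pkp,
                    "fraction_f0f1": pr.energetics.fraction_f0f1,
                    "non_unique": pr.energetics.non_unique,
                },
                "nadh_total": pr.redox.nadh_total,
                "nadph_total": pr.redox.nadph_total,
                "polyol_regeneration_share": pr.redox.regeneration_share,
                "protons": {
                    "in_f0f1": pr.protons.protons_in_f0f1,
                    "mlf_lactate": pr.protons.protons_out_mlf_lactate,
                    "diacetyl": pr.protons.protons_consumed_diacetyl,
                },
                "sensitivity_max_rate": (
                    pr.sensitivity.max_change_rate if pr.sensitivity else None
                ),
                "flexibility_aggregate_sd": (
                    pr.flexibility.aggregate_sd if pr.flexibility else None
                ),
            }

        return {
            "package_version": __version__,
            "provenance": self.provenance,
            "phases": [flux_block(pr) for pr in self.phase_results],
            "accumulation_spans": {
                str(e): dict(spans.spans)
                for e, spans in self.accumulation_spans.items()
            },
            "efm_table": (
                self.efm_table.counts.to_dict() if self.efm_table else None
            ),
        }


def _config_hash(config: PipelineConfig) -> str:
    payload = dataclasses.asdict(config)
    payload.pop("output_dir", None)  # location does not change the result
    payload.pop("log_level", None)
    blob = json.dumps(payload, sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute all stages; any stage failure aborts with a stage-named error."""
    config.validate()
    logging.basicConfig(level=config.log_level)
    if config.model_path:
        base = read_network(config.model_path, format="json")
    else:
        base = load_reduced_oeni_model()
    logger.info("stage=model reactions=%d", len(base.reactions))

    timecourses: List[TimeCourse] = []
    if config.timecourse_path:
        df = pd.read_csv(config.timecourse_path, sep="\t")
        levels = sorted(df["ethanol_pct"].unique()) if "ethanol_pct" in df else [0.0]
        for e in levels:
            timecourses.append(TimeCourse.from_long_frame(df, ethanol_level=float(e)))
    else:
        gen = default_config()
        gen.seed = config.seed
        for e in config.ethanol_levels:
            tc, _ = simulate_culture(gen, e, noise_cv=config.synth_noise_cv,
                                     seed=config.seed)
            timecourses.append(tc)
    os.makedirs(config.output_dir, exist_ok=True)

    ext = build_extended_model(base, 3)
    phase_results: List[PhaseResult] = []
    spans_by_level: Dict[float, AccumulationBounds] = {}
    for tc in timecourses:
        e = tc.ethanol_level
        rate_sets = estimate_rates(tc)
        logger.info("stage=rates ethanol=%s phases=%d", e, len(rate_sets))
        css = phase_constraints_from_rates(rate_sets, tolerance=config.tolerance)
        cext = apply_experimental_constraints(ext, css)
        spans = fva_accumulation(cext)
        spans_by_level[e] = spans
        logger.info("stage=accumulation_fva ethanol=%s", e)
        models = split_into_phase_models(cext, spans)
        for i, net in enumerate(models):
            cs, rs = css[i], rate_sets[i]
            ngam = estimate_ngam(net, cs, rs.mu, grid_step=config.ngam_grid_step)
            constrained = cs.apply(net)
            constrained.set_bounds("NGAM", ngam.ngam, ngam.ngam)
            fba = solve_fba(constrained)
            energetics = atp_accounting(fba, net, uniqueness_network=constrained)
            redox = redox_accounting(fba, net, uniqueness_network=constrained)
            protons = proton_accounting(fba, net)
            sens = None
            if config.run_sensitivity:
                sens = ngam_sensitivity(
                    net, cs, rs.mu,
                    grid_step=min(config.ngam_grid_step, 0.001),
                    coarse_step=0.01,
                )
            flex = None
            if config.run_sampling:
                ss = sample_flux_space(
                    constrained, config.sampling_n,
                    thinning=config.sampling_thinning, seed=config.seed,
                )
                flex = flexibility_stats(ss, network=net)
            phase_results.append(
                PhaseResult(
                    ethanol_level=e,
                    phase_id=rs.phase_id,
                    rates=rs,
                    ngam=ngam,
                    fba=fba,
                    energetics=energetics,
                    redox=redox,
                    protons=protons,
                    sensitivity=sens,
                    flexibility=flex,
                )
            )
            logger.info(
                "stage=phase_analysis ethanol=%s phase=%d ngam=%.3f",
                e, rs.phase_id, ngam.ngam,
            )

    efm_table = None
    if config.run_efm:
        efm_table = substrate_product_table(base)
        logger.info("stage=efm modes=%s", efm_table.total_modes)

    provenance = {
        "config_hash": _config_hash(config),
        "package_version": __version__,
        "seed": str(config.seed),
    }
    report = RunReport(
        config=config,
        phase_results=phase_results,
        accumulation_spans=spans_by_level,
        efm_table=efm_table,
        provenance=provenance,
    )
    _write_outputs(report, config.output_dir)
    return report


def _write_outputs(report: RunReport, outdir: str) -> None:
    with open(os.path.join(outdir, "report.json"), "w", encoding="utf-8") as fh:
        json.dump(report.to_json_dict(), fh, indent=1, sort_keys=True)
        fh.write("\n")
    rows = []
    for pr in report.phase_results:
        rows.append(
            {
                "ethanol_pct": pr.ethanol_level,
                "phase": pr.phase_id,
                "mu": pr.rates.mu,
                "ngam": pr.ngam.ngam,
                "biomass_error": pr.ngam.biomass_error,
                "atp_f0f1": pr.energetics.r_atp_f0f1,
                "atp_pkp": pr.energetics.r_atp_pkp,
                "fraction_f0f1": pr.energetics.fraction_f0f1,
            }
        )
    pd.DataFrame(rows).to_csv(
        os.path.join(outdir, "phase_summary.tsv"), sep="\t", index=False
    )
    if report.efm_table is not None:
        report.efm_table.counts.to_csv(
            os.path.join(outdir, "efm_table.tsv"), sep="\t"
        )
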