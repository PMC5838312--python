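"""In-silico batch cultures with known ground truth.

Each simulated culture follows the four-phase batch layout: three growth
phases with ethanol-dependent growth rates (phase-I values anchored to the
measured 0.021 ... 0.013 h⁻¹ series) and a stationary phase in which
nothing changes.  For every (ethanol level, growth phase) a *witness* flux
distribution is computed on the packaged reduced network — augmented with
inter-phase sink/demand reactions — so that the generated specific rates
are stoichiometrically consistent by construction and the inverse problem
(rates -> extended model -> NGAM) is well posed.

Witness construction per phase:

1. malate/citrate uptake is pinned so that both acids are nearly depleted
   during phase I; amino-acid uptakes are capped slightly above the biomass
   requirement; mannitol/erythritol exports are forced to ethanol-dependent
   minimum rates; the maintenance flux is fixed at its ground-truth value;
2. the glucose/fructose uptake scale is calibrated (scalar root find) so
   that the maximal biomass rate equals the target growth rate;
3. with biomass pinned at the target, total carry-over to the next phase is
   maximized, which places the witness on the boundary of the feasible
   region that the extended-model FVA later recovers.

Concentration series integrate ``dC/dt = q·X`` exactly for exponential
``X(t)``; OD600 is back-computed through the inverse of the biomass
calibration.  Optional multiplicative Gaussian noise (fixed seed) is
applied to OD and concentrations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import brentq

from .extended import demand_reaction_id, sink_reaction_id
from .fba import InfeasibleModelError, LinearModel
from .network import MetabolicNetwork, Reaction
from .rates import DEFAULT_PHASE_BOUNDARIES, TimeCourse, dcw_to_od, od_to_dcw
from .reduced_model import (
    ACCUMULATION_COMPOUNDS,
    BIOMASS_COMPOSITION,
    BIOMASS_ID,
    NGAM_ID,
    PRODUCT_EXCHANGES,
    SUBSTRATE_EXCHANGES,
    load_reduced_oeni_model,
)
from .units import g_per_l_to_mmol_per_l

#: phase-I maximum specific growth rates (h⁻¹) by ethanol level (% v/v)
TABLE_MU_PHASE1 = {0.0: 0.021, 3.0: 0.018, 6.0: 0.016, 9.0: 0.014, 12.0: 0.013}

#: growth-rate multipliers for phases II and III relative to phase I
MU_PHASE_RATIOS = {1: 1.0, 2: 0.45, 3: 0.25}

#: ground-truth maintenance flux (mmol·gDCW⁻¹·h⁻¹) by (phase, ethanol);
#: phase-I values reproduce the ~3/3/10/17-fold increases over the
#: ethanol-free culture; monotone non-decreasing in ethanol in every phase.
TRUE_NGAM = {
    1: {0.0: 0.25, 3.0: 0.90, 6.0: 1.45, 9.0: 2.10, 12.0: 3.40},
    2: {0.0: 0.15, 3.0: 0.45, 6.0: 0.55, 9.0: 0.70, 12.0: 0.85},
    3: {0.0: 0.20, 3.0: 0.55, 6.0: 0.65, 9.0: 0.80, 12.0: 0.95},
}

#: relative glucose/fructose uptake (fructose twice as fast in phase I,
#: glucose faster than fructose afterwards)
SUGAR_RATIOS = {1: (1.0, 2.0), 2: (1.0, 0.9), 3: (1.0, 0.45)}

#: fraction of malate / citrate depleted during phase I
DEPLETION_FRACTION = {"malate": 0.97, "citrate": 0.95}

MEASURED_COMPOUNDS = list(SUBSTRATE_EXCHANGES) + list(PRODUCT_EXCHANGES)

_DEFAULT_MEDIUM_G_PER_L = {
    "glucose": 12.5,
    "fructose": 12.5,
    "malate": 5.0,
    "citrate": 1.0,
    "cysteine": 0.54,
    "threonine": 0.27,
    "valine": 0.27,
    "phenylalanine": 0.37,
    "serine": 0.24,
}


@dataclass
class GeneratorConfig:
    ethanol_levels: Tuple[float, ...] = (0.0, 3.0, 6.0, 9.0, 12.0)
    phase_boundaries: Tuple[float, ...] = DEFAULT_PHASE_BOUNDARIES
    true_mu_phase1: Dict[float, float] = field(
        default_factory=lambda: dict(TABLE_MU_PHASE1)
    )
    mu_phase_ratios: Dict[int, float] = field(
        default_factory=lambda: dict(MU_PHASE_RATIOS)
    )
    true_ngam: Dict[int, Dict[float, float]] = field(
        default_factory=lambda: {p: dict(v) for p, v in TRUE_NGAM.items()}
    )
    initial_medium: Dict[str, float] = field(default_factory=dict)  # mmol/L
    inoculum_od600: float = 0.2
    sampling_interval: float = 8.0
    noise_cv: float = 0.02
    n_replicates: int = 3  # noisy replicates averaged into the series
    seed: int = 0

    def mu_target(self, ethanol: float, phase: int) -> float:
        return self.true_mu_phase1[ethanol] * self.mu_phase_ratios[phase]

    def ngam_target(self, ethanol: float, phase: int) -> float:
        return self.true_ngam[phase][ethanol]


def default_config() -> GeneratorConfig:
    """Defaults matching the wine-like medium and measured growth anchors."""
    medium = {
        name: g_per_l_to_mmol_per_l(gl, name)
        for name, gl in _DEFAULT_MEDIUM_G_PER_L.items()
    }
    return GeneratorConfig(initial_medium=medium)


@dataclass
class PhaseTruth:
    """Ground truth for one (ethanol, phase) witness."""

    phase_id: int
    mu: float
    ngam: float
    t_start: float
    t_end: float
    biomass_start: float
    biomass_end: float
    biomass_integral: float
    q: Dict[str, float]  # compound name -> specific rate (signed)
    fluxes: Dict[str, float]  # full witness flux vector (phase-model ids)
    accumulation_out: Dict[str, float]  # compound -> demand flux to next phase
    accumulation_in: Dict[str, float]  # compound -> sink flux from previous


@dataclass
class GroundTruth:
    ethanol_level: float
    phases: List[PhaseTruth]
    config: GeneratorConfig

    def phase(self, phase_id: int) -> PhaseTruth:
        return self.phases[phase_id - 1]


# ---------------------------------------------------------------------------
# witness construction
# ---------------------------------------------------------------------------

_AA_NAMES = ("cysteine", "threonine", "valine", "phenylalanine", "serine")
_AA_MET = {
    "cysteine": "cys_c",
    "threonine": "thr_c",
    "valine": "val_c",
    "phenylalanine": "phe_c",
    "serine": "ser_c",
}


#: phase-I polyol export floors anchored to the measured ethanol-free rates
#: (1.25 / 0.95 mmol·gDCW⁻¹·h⁻¹), rising with ethanol content
MANNITOL_PHASE1_RATE = 1.25
ERYTHRITOL_PHASE1_RATE = 0.95


def _mannitol_floor(ethanol: float, phase: int, f_uptake: float) -> float:
    if phase == 1:
        return MANNITOL_PHASE1_RATE * (1.0 + 0.05 * ethanol)
    frac = {2: 0.30 + 0.010 * ethanol, 3: 0.18 + 0.008 * ethanol}[phase]
    return frac * f_uptake


def _erythritol_floor(ethanol: float, phase: int, f_uptake: float) -> float:
    if phase == 1:
        return ERYTHRITOL_PHASE1_RATE * (1.0 + 0.01 * ethanol)
    frac = {2: 0.05 + 0.002 * ethanol, 3: 0.03 + 0.001 * ethanol}[phase]
    return frac * f_uptake


def _phase_model(
    base: MetabolicNetwork,
    phase: int,
    sink_fluxes: Mapping[str, float],
    demand_bounds: Mapping[str, Tuple[float, float]],
) -> MetabolicNetwork:
    """Base network + sink (inflow) and demand (outflow) accumulation arms."""
    net = base.copy(name=f"{base.name}__witness_p{phase}")
    if phase > 1:
        for compound, mid in ACCUMULATION_COMPOUNDS.items():
            v = float(sink_fluxes.get(compound, 0.0))
            net.add_reaction(
                Reaction(
                    id=sink_reaction_id(compound),
                    stoichiometry={mid: 1.0},
                    lower_bound=v,
                    upper_bound=v,
                    subsystem="accumulation",
                    role_tags={"sink", "accumulation"},
                )
            )
    if phase < 3:
        for compound, mid in ACCUMULATION_COMPOUNDS.items():
            lo, hi = demand_bounds.get(compound, (0.0, 0.0))
            net.add_reaction(
                Reaction(
                    id=demand_reaction_id(compound),
                    stoichiometry={mid: -1.0},
                    lower_bound=float(lo),
                    upper_bound=float(hi),
                    subsystem="accumulation",
                    role_tags={"demand", "accumulation"},
                )
            )
    return net


def _scenario_overrides(
    ethanol: float,
    phase: int,
    mu_target: float,
    ngam: float,
    scale: float,
    q_fixed_acids: Mapping[str, float],
    mu_next: Optional[float],
    has_demands: bool,
) -> Dict[str, Tuple[float, float]]:
    g_ratio, f_ratio = SUGAR_RATIOS[phase]
    ov: Dict[str, Tuple[float, float]] = {}
    ov["EX_glc"] = (-g_ratio * scale, -g_ratio * scale)
    ov["EX_fru"] = (-f_ratio * scale, -f_ratio * scale)
    for name in ("malate", "citrate"):
        q = q_fixed_acids.get(name, 0.0) if phase == 1 else 0.0
        ov[SUBSTRATE_EXCHANGES[name]] = (-q, -q)
    for name in _AA_NAMES:
        coef = -BIOMASS_COMPOSITION[_AA_MET[name]]
        cap = (coef + 0.05) * mu_target * 2.0
        ov[SUBSTRATE_EXCHANGES[name]] = (-cap, 0.0)
    f_uptake = f_ratio * scale
    ov["EX_man"] = (_mannitol_floor(ethanol, phase, f_uptake), 1000.0)
    ov["EX_ery"] = (_erythritol_floor(ethanol, phase, f_uptake), 1000.0)
    # pin oxygen below the network's micro-aerobic capacity and keep a
    # small NADH-oxidase reserve: the witness then has no exploitable
    # oxygen/redox slack, while small rate perturbations stay absorbable
    ov["EX_o2"] = (-0.25, -0.25)
    ov["NQOR"] = (0.028, 1000.0)
    ov[NGAM_ID] = (ngam, ngam)
    if has_demands:
        # s-dependent mannitol carry-over window (other compounds are on
        # the model itself, see _demand_bounds)
        frac = 0.02 if phase == 1 else 0.01
        ov[demand_reaction_id("mannitol")] = (
            frac * f_ratio * scale, 3.0 * frac * f_ratio * scale
        )
    return ov


def _demand_bounds(
    phase: int,
    mu_next: Optional[float],
    mu_next2: Optional[float],
    q_mal_phase1: float,
) -> Dict[str, Tuple[float, float]]:
    """(lb, ub) carry-over windows; minimum levels guarantee the later
    phases an oxaloacetate (malate) and amino-acid supply."""
    if phase >= 3 or mu_next is None:
        return {}
    mal_lo = 0.45 * mu_next + 0.45 * (mu_next2 or 0.0)
    bounds = {
        "mannitol": (0.0, 1000.0),  # set per-scale in the overrides
        "malate": (mal_lo, max(0.04 * q_mal_phase1, 2.0 * mal_lo)),
        "cysteine": (0.3 * 0.12 * mu_next, 0.8 * 0.12 * mu_next),
        "threonine": (0.3 * 0.18 * mu_next, 0.8 * 0.18 * mu_next),
        "valine": (0.2 * 0.22 * mu_next, 0.5 * 0.22 * mu_next),
        "phenylalanine": (0.2 * 0.14 * mu_next, 0.5 * 0.14 * mu_next),
    }
    return bounds


def _solve_witness_phase(
    base: MetabolicNetwork,
    ethanol: float,
    phase: int,
    mu_target: float,
    ngam: float,
    q_fixed_acids: Mapping[str, float],
    sink_fluxes: Mapping[str, float],
    mu_next: Optional[float],
    mu_next2: Optional[float],
    q_mal_phase1: float,
) -> Tuple[Dict[str, float], float]:
    """Calibrate the sugar scale and return (witness fluxes, scale)."""
    dm_bounds = _demand_bounds(phase, mu_next, mu_next2, q_mal_phase1)
    model = _phase_model(base, phase, sink_fluxes, dm_bounds)
    lp = LinearModel(model)
    has_demands = phase < 3

    def mu_max(scale: float) -> float:
        ov = _scenario_overrides(
            ethanol, phase, mu_target, ngam, scale,
            q_fixed_acids, mu_next, has_demands,
        )
        status, _, value = lp.solve({BIOMASS_ID: 1.0}, sense="max",
                                    bound_overrides=ov)
        if status != "optimal":
            return -mu_target  # treat infeasible as "too little substrate"
        return value

    lo, hi = 1e-6, 0.05
    f_lo = mu_max(lo) - mu_target
    if f_lo > 0:
        raise InfeasibleModelError(
            f"phase {phase} at {ethanol}% ethanol: growth target {mu_target} "
            "already exceeded without sugars; lower the acid/sink supply"
        )
    while mu_max(hi) - mu_target < 0:
        hi *= 2.0
        if hi > 50.0:
            raise InfeasibleModelError(
                f"phase {phase} at {ethanol}% ethanol: cannot reach growth "
                f"target {mu_target} with any sugar supply"
            )
    scale = brentq(lambda s: mu_max(s) - mu_target, lo, hi, xtol=1e-12)
    if abs(mu_max(scale) - mu_target) > 1e-6 * mu_target:
        raise InfeasibleModelError(
            f"phase {phase} at {ethanol}% ethanol: smallest feasible "
            f"substrate supply already yields mu_max {mu_max(scale):.4g} "
            f"above the target {mu_target}; adjust the energy parameters"
        )

    ov = _scenario_overrides(
        ethanol, phase, mu_target, ngam, scale,
        q_fixed_acids, mu_next, has_demands,
    )
    status, x, mu_w = lp.solve({BIOMASS_ID: 1.0}, sense="max", bound_overrides=ov)
    assert status == "optimal"
    # pin biomass, maximize total carry-over to the next phase
    if has_demands:
        objective = {
            demand_reaction_id(c): 1.0 for c in ACCUMULATION_COMPOUNDS
        }
        for slack in (1e-10, 1e-8, 1e-6):
            ov2 = dict(ov)
            ov2[BIOMASS_ID] = (mu_w * (1.0 - slack), mu_w)
            status, x2, _ = lp.solve(objective, sense="max", bound_overrides=ov2)
            if status == "optimal":
                x = x2
                break
        else:  # pragma: no cover - solver tolerance pathology
            raise InfeasibleModelError(
                f"phase {phase}: carry-over maximization infeasible"
            )
    fluxes = dict(zip(lp.reaction_ids, map(float, x)))
    return fluxes, scale


def build_ground_truth(
    config: GeneratorConfig,
    ethanol_level: float,
    base: Optional[MetabolicNetwork] = None,
) -> GroundTruth:
    """Witness fluxes, growth rates and carry-overs for one ethanol level."""
    if ethanol_level not in config.true_mu_phase1:
        raise KeyError(f"no growth anchor for ethanol level {ethanol_level}")
    base = base if base is not None else load_reduced_oeni_model()
    bounds = config.phase_boundaries
    x0 = od_to_dcw(config.inoculum_od600)
    medium = config.initial_medium
    phases: List[PhaseTruth] = []
    sink_fluxes: Dict[str, float] = {}
    q_mal_phase1 = 0.0
    for phase in (1, 2, 3):
        t_start, t_end = bounds[phase - 1], bounds[phase]
        mu = config.mu_target(ethanol_level, phase)
        ngam = config.ngam_target(ethanol_level, phase)
        integral = x0 * (math.exp(mu * (t_end - t_start)) - 1.0) / mu
        q_fixed_acids = {}
        if phase == 1:
            for name in ("malate", "citrate"):
                q_fixed_acids[name] = (
                    DEPLETION_FRACTION[name] * medium[name] / integral
                )
            q_mal_phase1 = q_fixed_acids["malate"]
        mu_next = (
            config.mu_target(ethanol_level, phase + 1) if phase < 3 else None
        )
        mu_next2 = (
            config.mu_target(ethanol_level, phase + 2) if phase < 2 else None
        )
        fluxes, _ = _solve_witness_phase(
            base, ethanol_level, phase, mu, ngam,
            q_fixed_acids, sink_fluxes, mu_next, mu_next2, q_mal_phase1,
        )
        q = {
            name: fluxes[SUBSTRATE_EXCHANGES[name]]
            for name in SUBSTRATE_EXCHANGES
        }
        q.update(
            {name: fluxes[PRODUCT_EXCHANGES[name]] for name in PRODUCT_EXCHANGES}
        )
        acc_out = {
            c: fluxes.get(demand_reaction_id(c), 0.0)
            for c in ACCUMULATION_COMPOUNDS
        } if phase < 3 else {c: 0.0 for c in ACCUMULATION_COMPOUNDS}
        acc_in = dict(sink_fluxes)
        phases.append(
            PhaseTruth(
                phase_id=phase,
                mu=mu,
                ngam=ngam,
                t_start=t_start,
                t_end=t_end,
                biomass_start=x0,
                biomass_end=x0 * math.exp(mu * (t_end - t_start)),
                biomass_integral=integral,
                q=q,
                fluxes=fluxes,
                accumulation_out=acc_out,
                accumulation_in=acc_in,
            )
        )
        sink_fluxes = acc_out
        x0 = phases[-1].biomass_end
    return GroundTruth(
        ethanol_level=ethanol_level, phases=phases, config=config
    )


# ---------------------------------------------------------------------------
# time-course generation
# ---------------------------------------------------------------------------

def simulate_culture(
    config: GeneratorConfig,
    ethanol_level: float,
    noise_cv: Optional[float] = None,
    seed: Optional[int] = None,
    base: Optional[MetabolicNetwork] = None,
) -> Tuple[TimeCourse, GroundTruth]:
    """Generate one culture's TimeCourse plus its GroundTruth.

    ``noise_cv``/``seed`` default to the config values; pass
    ``noise_cv=0`` for noiseless output.
    """
    truth = build_ground_truth(config, ethanol_level, base=base)
    noise_cv = config.noise_cv if noise_cv is None else noise_cv
    seed = config.seed if seed is None else seed
    bounds = config.phase_boundaries
    t_final = bounds[-1]
    dt = config.sampling_interval
    times = np.arange(0.0, t_final + 0.5 * dt, dt)
    times = np.unique(np.clip(times, 0.0, t_final))

    X = np.empty_like(times)
    conc = {name: np.empty_like(times) for name in MEASURED_COMPOUNDS}
    c_state = {
        name: config.initial_medium.get(name, 0.0) for name in MEASURED_COMPOUNDS
    }

    def phase_of(t: float) -> int:
        for k in range(len(bounds) - 1):
            if t < bounds[k + 1] or k == len(bounds) - 2:
                if t >= bounds[k]:
                    return k + 1
        return len(bounds) - 1  # pragma: no cover

    # evaluate piecewise: within growth phases use the witness (mu, q);
    # stationary phase holds everything constant.
    for i, t in enumerate(times):
        p = phase_of(t)
        if p <= 3:
            ph = truth.phase(p)
            tau = t - ph.t_start
            X[i] = ph.biomass_start * math.exp(ph.mu * tau)
            integral = ph.biomass_start * (math.exp(ph.mu * tau) - 1.0) / ph.mu
            # concentration at phase start:
            for name in MEASURED_COMPOUNDS:
                c_start = _phase_start_concentration(truth, config, name, p)
                conc[name][i] = c_start + ph.q[name] * integral
        else:
            ph = truth.phase(3)
            X[i] = ph.biomass_end
            for name in MEASURED_COMPOUNDS:
                conc[name][i] = _phase_start_concentration(truth, config, name, 4)

    for name, series in conc.items():
        if np.any(series < -1e-6):
            raise InfeasibleModelError(
                f"generated concentration of {name} became negative; the "
                "configured rates deplete it below zero"
            )
        np.clip(series, 0.0, None, out=series)

    od = dcw_to_od(X)
    if noise_cv and noise_cv > 0:
        rng = np.random.default_rng(seed)
        reps = max(1, config.n_replicates)
        od = od * (1.0 + noise_cv * rng.standard_normal((reps, od.size))).mean(axis=0)
        od = np.clip(od, 1e-6, None)
        for name in conc:
            noisy = conc[name] * (
                1.0 + noise_cv * rng.standard_normal((reps, conc[name].size))
            )
            conc[name] = np.clip(noisy.mean(axis=0), 0.0, None)
    tc = TimeCourse(
        times=times,
        ethanol_level=ethanol_level,
        od600=od,
        concentrations=conc,
    )
    return tc, truth


def _phase_start_concentration(
    truth: GroundTruth, config: GeneratorConfig, name: str, phase: int
) -> float:
    c = config.initial_medium.get(name, 0.0)
    for p in range(1, phase):
        ph = truth.phase(p)
        c += ph.q[name] * ph.biomass_integral
    return c
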