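"""Uniform sampling of the constrained flux polytope (hit-and-run).

The sampler walks in the null space of the stoichiometric matrix (so every
point satisfies ``S·v = 0`` exactly, up to round-off) using the
artificial-centering hit-and-run scheme: directions are drawn through the
running center of previously accepted points, which adapts the step
geometry to elongated polytopes.  Reactions fixed by their bounds are held
at their fixed value and excluded from the walk.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy.linalg import null_space
from scipy.optimize import linprog

from .network import MetabolicNetwork, stoichiometric_matrix

FEAS_TOL = 1e-6
DIRECTION_TOL = 1e-10


class SamplingError(RuntimeError):
    pass


@dataclass
class SampleSet:
    """Retained flux samples (rows) over ``reaction_ids`` (columns)."""

    samples: np.ndarray
    reaction_ids: List[str]
    seed: int
    thinning: int
    warmup: int
    network_fingerprint: str

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    def column(self, rxn_id: str) -> np.ndarray:
        return self.samples[:, self.reaction_ids.index(rxn_id)]


@dataclass
class FlexibilityReport:
    """Per-reaction sampling moments and an aggregate flexibility score."""

    mean: Dict[str, float]
    sd: Dict[str, float]
    focus_ids: List[str]
    aggregate_sd: float  # median SD over the focus set


def _fingerprint(network: MetabolicNetwork) -> str:
    h = hashlib.sha256()
    for r in network.reactions:
        h.update(r.id.encode())
        h.update(repr(sorted(r.stoichiometry.items())).encode())
        h.update(repr((r.lower_bound, r.upper_bound)).encode())
    return h.hexdigest()[:16]


def _chebyshev_start(
    N: np.ndarray, x_part: np.ndarray, lb: np.ndarray, ub: np.ndarray
) -> np.ndarray:
    """Interior start: maximize the margin to the bound faces in t-space."""
    k = N.shape[1]
    rows = []
    rhs = []
    norms = np.linalg.norm(N, axis=1)
    for i in range(N.shape[0]):
        if norms[i] < DIRECTION_TOL:
            continue
        rows.append(np.append(N[i], norms[i]))
        rhs.append(ub[i] - x_part[i])
        rows.append(np.append(-N[i], norms[i]))
        rhs.append(x_part[i] - lb[i])
    c = np.zeros(k + 1)
    c[-1] = -1.0  # maximize margin
    bounds = [(None, None)] * k + [(0.0, None)]
    res = linprog(
        c, A_ub=np.array(rows), b_ub=np.array(rhs), bounds=bounds,
        method="highs",
    )
    if res.status != 0:
        raise SamplingError(f"no feasible interior start ({res.message})")
    return res.x[:k]


def sample_flux_space(
    network: MetabolicNetwork,
    n_samples: int,
    thinning: int = 500,
    seed: int = 0,
    warmup: Optional[int] = None,
) -> SampleSet:
    """Artificial-centering hit-and-run over ``{S·v=0, lb <= v <= ub}``.

    ``thinning`` steps are taken between retained samples; ``warmup``
    (default ``2·m``) steps precede the first retained sample.  Identical
    arguments reproduce the identical chain.
    """
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    S = stoichiometric_matrix(network)
    lb, ub = network.bounds()
    if np.any(lb > ub):
        raise SamplingError("inconsistent bounds (lb > ub)")
    if np.any(ub > 999.5) and np.any(lb < -999.5):
        pass  # default caps keep the polytope bounded
    m = len(network.reactions)
    warmup = 2 * m if warmup is None else warmup

    # equality system: S v = 0 plus rows pinning lb == ub reactions
    fixed = np.isclose(lb, ub)
    A_rows = [S]
    b_rows = [np.zeros(S.shape[0])]
    if fixed.any():
        E = np.zeros((fixed.sum(), m))
        E[np.arange(fixed.sum()), np.where(fixed)[0]] = 1.0
        A_rows.append(E)
        b_rows.append(lb[fixed])
    A = np.vstack(A_rows)
    b = np.concatenate(b_rows)
    x_part, *_ = np.linalg.lstsq(A, b, rcond=None)
    if np.max(np.abs(A @ x_part - b)) > FEAS_TOL:
        raise SamplingError("no flux vector satisfies the equality system")
    N = null_space(A)
    if N.shape[1] == 0:
        # fully determined: single point
        v = np.clip(x_part, lb, ub)
        samples = np.tile(v, (n_samples, 1))
        return SampleSet(samples, network.reaction_ids, seed, thinning,
                         warmup, _fingerprint(network))

    t0 = _chebyshev_start(N, x_part, lb, ub)
    rng = np.random.default_rng(seed)
    k = N.shape[1]

    def to_v(t: np.ndarray) -> np.ndarray:
        return x_part + N @ t

    t = t0.copy()
    center = t0.copy()
    n_accepted = 1
    anchors: List[np.ndarray] = [t0.copy()]  # reservoir of accepted points
    max_anchors = 128
    retained = []
    total_steps = warmup + n_samples * thinning
    for step in range(total_steps):
        if step < warmup or len(anchors) < 4:
            d = rng.standard_normal(k)
        else:
            ref = anchors[rng.integers(len(anchors))]
            d = ref - center
            if np.linalg.norm(d) < DIRECTION_TOL:
                d = rng.standard_normal(k)
        nd = np.linalg.norm(d)
        if nd < DIRECTION_TOL:
            continue
        d = d / nd
        vdir = N @ d
        v = to_v(t)
        with np.errstate(divide="ignore", invalid="ignore"):
            hi_caps = np.where(vdir > DIRECTION_TOL, (ub - v) / vdir, np.inf)
            lo_caps = np.where(vdir < -DIRECTION_TOL, (lb - v) / vdir, np.inf)
            hi_neg = np.where(vdir < -DIRECTION_TOL, (ub - v) / vdir, -np.inf)
            lo_neg = np.where(vdir > DIRECTION_TOL, (lb - v) / vdir, -np.inf)
        alpha_max = min(np.min(hi_caps), np.min(lo_caps))
        alpha_min = max(np.max(hi_neg), np.max(lo_neg))
        if not np.isfinite(alpha_max) or not np.isfinite(alpha_min):
            raise SamplingError(
                "unbounded direction encountered; cap the open exchange bounds"
            )
        if alpha_max <= alpha_min:
            continue
        alpha = rng.uniform(alpha_min, alpha_max)
        t = t + alpha * d
        n_accepted += 1
        center = center + (t - center) / n_accepted
        if len(anchors) < max_anchors:
            anchors.append(t.copy())
        else:
            anchors[rng.integers(max_anchors)] = t.copy()
        if step >= warmup and (step - warmup + 1) % thinning == 0:
            retained.append(to_v(t))
    while len(retained) < n_samples:  # rare skipped-step top-up
        retained.append(to_v(t))
    samples = np.array(retained[:n_samples])
    # audit feasibility of every retained sample
    if np.max(np.abs(S @ samples.T)) > FEAS_TOL:
        raise AssertionError("sampler produced a non-steady-state point")
    viol = np.maximum(lb - samples, samples - ub).max()
    if viol > FEAS_TOL:
        raise AssertionError("sampler produced an out-of-bounds point")
    np.clip(samples, lb, ub, out=samples)
    return SampleSet(samples, network.reaction_ids, seed, thinning, warmup,
                     _fingerprint(network))


def flexibility_stats(
    samples: SampleSet,
    reaction_ids: Optional[Sequence[str]] = None,
    network: Optional[MetabolicNetwork] = None,
    focus_subsystem: str = "phosphoketolase",
) -> FlexibilityReport:
    """Mean/SD per reaction; aggregate = median SD over the focus set.

    The focus set is ``reaction_ids`` when given, else all reactions of
    ``focus_subsystem`` in ``network``, else every sampled reaction.
    """
    if samples.n_samples == 0:
        raise ValueError("empty sample set")
    if reaction_ids is not None:
        focus = list(reaction_ids)
        unknown = [r for r in focus if r not in samples.reaction_ids]
        if unknown:
            raise KeyError(f"unknown reaction ids: {unknown}")
    elif network is not None:
        focus = [
            r.id for r in network.reactions_in_subsystem(focus_subsystem)
            if r.id in samples.reaction_ids
        ]
    else:
        focus = list(samples.reaction_ids)
    mean = dict(zip(samples.reaction_ids, samples.samples.mean(axis=0)))
    sd = dict(zip(samples.reaction_ids, samples.samples.std(axis=0, ddof=1)))
    aggregate = float(np.median([sd[r] for r in focus])) if focus else 0.0
    return FlexibilityReport(
        mean={k: float(v) for k, v in mean.items()},
        sd={k: float(v) for k, v in sd.items()},
        focus_ids=focus,
        aggregate_sd=aggregate,
    )
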