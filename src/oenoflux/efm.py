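"""Elementary flux mode enumeration and substrate-product tabulation.

The enumerator is a double-description pass over the flux cone
``{v : S·v = 0, v_i >= 0 for irreversible i}``.  Reversible reactions are
split into forward/backward parts so the cone is pointed in the positive
orthant; extreme rays of the split cone are exactly the elementary modes of
the original network plus the trivial forward/backward two-cycles, which
are discarded on re-mapping.  All arithmetic is exact (integer rays over a
rationalized stoichiometry), so support minimality needs no epsilons.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import gcd
from typing import Dict, FrozenSet, List, Optional, Tuple

import numpy as np
import pandas as pd

from .network import MetabolicNetwork, stoichiometric_matrix
from .reduced_model import PRODUCT_EXCHANGES, SUBSTRATE_EXCHANGES

DEFAULT_SIZE_GUARD = 70


class NetworkTooLargeError(ValueError):
    """Combinatorial guard for the exact enumerator."""


@dataclass(frozen=True)
class ElementaryFluxMode:
    """One minimal steady-state pathway, scaled so min |coeff| = 1."""

    coefficients: Tuple[Tuple[str, float], ...]

    @property
    def support(self) -> FrozenSet[str]:
        return frozenset(r for r, c in self.coefficients if c != 0)

    def as_dict(self) -> Dict[str, float]:
        return dict(self.coefficients)

    def flux(self, rxn_id: str) -> float:
        return dict(self.coefficients).get(rxn_id, 0.0)


@dataclass
class EFMTable:
    """Counts of modes producing each product from each sole substrate."""

    counts: pd.DataFrame  # rows: substrates, columns: products
    total_modes: Dict[str, int]  # modes per substrate run

    def __getitem__(self, key: Tuple[str, str]) -> int:
        substrate, product = key
        return int(self.counts.loc[substrate, product])


# ---------------------------------------------------------------------------
# exact double description
# ---------------------------------------------------------------------------

def _rationalize(S: np.ndarray) -> List[List[Fraction]]:
    return [
        [Fraction(x).limit_denominator(10**9) for x in row] for row in S
    ]


def _normalize_int(ray: List[int]) -> Tuple[int, ...]:
    g = 0
    for x in ray:
        g = gcd(g, abs(x))
    if g > 1:
        ray = [x // g for x in ray]
    return tuple(ray)


def _extreme_rays(S_rows: List[List[Fraction]], m: int) -> List[Tuple[int, ...]]:
    """Extreme rays of {v >= 0, S v = 0} via iterative double description."""
    rays: List[Tuple[int, ...]] = [
        tuple(1 if j == i else 0 for j in range(m)) for i in range(m)
    ]
    # denser rows last keeps intermediate ray counts lower
    ordered = sorted(S_rows, key=lambda row: sum(1 for x in row if x != 0))
    for row in ordered:
        if all(x == 0 for x in row):
            continue
        num = [x.numerator for x in row]
        den = [x.denominator for x in row]
        scale = 1
        for d in den:
            scale = scale * d // gcd(scale, d)
        irow = [n * (scale // d) for n, d in zip(num, den)]
        dots = [
            sum(c * r[j] for j, c in enumerate(irow) if r[j]) for r in rays
        ]
        keep = [r for r, d in zip(rays, dots) if d == 0]
        pos = [(r, d) for r, d in zip(rays, dots) if d > 0]
        neg = [(r, d) for r, d in zip(rays, dots) if d < 0]
        if not pos or not neg:
            rays = keep
            continue
        zero_masks = {r: _zero_mask(r) for r in rays}
        new_rays = list(keep)
        for rp, dp in pos:
            zp = zero_masks[rp]
            for rn, dn in neg:
                zmask = zp & zero_masks[rn]
                if not _adjacent(zmask, rp, rn, rays, zero_masks):
                    continue
                combo = [dp * b - dn * a for a, b in zip(rp, rn)]
                new_rays.append(_normalize_int(combo))
        # dedupe
        rays = list(dict.fromkeys(new_rays))
    return rays


def _zero_mask(ray: Tuple[int, ...]) -> int:
    mask = 0
    for j, x in enumerate(ray):
        if x == 0:
            mask |= 1 << j
    return mask


def _adjacent(zmask, rp, rn, rays, zero_masks) -> bool:
    for r in rays:
        if r is rp or r is rn:
            continue
        if zero_masks[r] & zmask == zmask:
            return False
    return True


def _remove_blocked(network: MetabolicNetwork) -> MetabolicNetwork:
    """Drop reactions that can carry no flux in the cone (LP per reaction)."""
    from .fba import LinearModel

    capped = network.copy()
    for r in capped.reactions:  # magnitudes are irrelevant for the cone
        r.lower_bound = -1.0 if r.lower_bound < 0 else 0.0
        r.upper_bound = 1.0 if r.upper_bound > 0 else 0.0
    lp = LinearModel(capped)
    alive = []
    for rid in capped.reaction_ids:
        _, _, hi = lp.solve({rid: 1.0}, sense="max")
        _, _, lo = lp.solve({rid: 1.0}, sense="min")
        if max(abs(hi), abs(lo)) > 1e-9:
            alive.append(rid)
    alive_set = set(alive)
    from .network import MetabolicNetwork as MN

    rxns = [r.copy() for r in network.reactions if r.id in alive_set]
    used = {m for r in rxns for m in r.stoichiometry}
    mets = [m for m in network.metabolites if m.id in used]
    return MN(mets, rxns, objective_id=None, name=network.name + "__live")


def enumerate_efms(
    network: MetabolicNetwork,
    max_reactions: int = DEFAULT_SIZE_GUARD,
    compress: bool = True,
) -> List[ElementaryFluxMode]:
    """Complete, duplicate-free elementary-mode set, lexicographic order.

    Raises :class:`NetworkTooLargeError` above ``max_reactions`` (after
    blocked-reaction removal when ``compress`` is on).
    """
    net = _remove_blocked(network) if compress else network
    m = len(net.reactions)
    if m > max_reactions:
        raise NetworkTooLargeError(
            f"{m} active reactions exceed the enumeration guard "
            f"({max_reactions}); reduce the network or raise max_reactions"
        )
    if m == 0:
        return []
    S = stoichiometric_matrix(net)
    reversible = [r.reversible for r in net.reactions]
    # orient columns by their admissible sign; reversible gets both
    cols: List[Tuple[int, int]] = []  # (original index, sign)
    for j, r in enumerate(net.reactions):
        if r.upper_bound > 0:
            cols.append((j, +1))
        if r.lower_bound < 0:
            cols.append((j, -1))
    S_split = np.column_stack([S[:, j] * sign for j, sign in cols])
    rays = _extreme_rays(_rationalize(S_split), S_split.shape[1])

    modes: Dict[Tuple[Fraction, ...], None] = {}
    rxn_ids = net.reaction_ids
    results: List[ElementaryFluxMode] = []
    seen = set()
    for ray in rays:
        v = [Fraction(0)] * m
        for (j, sign), x in zip(cols, ray):
            v[j] += sign * x
        if all(x == 0 for x in v):  # forward/backward two-cycle
            continue
        # canonical sign for fully-reversible modes
        if all(v[j] == 0 or reversible[j] for j in range(m)):
            first = next(x for x in v if x != 0)
            if first < 0:
                v = [-x for x in v]
        smallest = min(abs(x) for x in v if x != 0)
        v = [x / smallest for x in v]
        key = tuple(v)
        if key in seen:
            continue
        seen.add(key)
        results.append(
            ElementaryFluxMode(
                coefficients=tuple(
                    (rid, float(x)) for rid, x in zip(rxn_ids, v) if x != 0
                )
            )
        )
    results.sort(key=lambda mode: tuple(sorted(mode.support)))
    return results


# ---------------------------------------------------------------------------
# substrate-product relationships
# ---------------------------------------------------------------------------

def substrate_product_table(
    network: MetabolicNetwork,
    substrates: Optional[Dict[str, str]] = None,
    products: Optional[Dict[str, str]] = None,
    max_reactions: int = DEFAULT_SIZE_GUARD,
) -> EFMTable:
    """Mode counts producing each product from each substrate *separately*.

    For every substrate, all other substrate uptakes are closed, the
    network's elementary modes are enumerated, and the modes with nonzero
    flux through each product's export exchange are counted.  Mineral and
    cofactor exchanges stay open.
    """
    if substrates is None:
        substrates = {
            name: SUBSTRATE_EXCHANGES[name]
            for name in (
                "fructose", "glucose", "citrate", "malate",
                "cysteine", "serine", "threonine",
            )
        }
    if products is None:
        products = {
            name: PRODUCT_EXCHANGES.get(name, f"EX_{name}")
            for name in (
                "mannitol", "D-lactate", "L-lactate", "diacetyl",
                "ethanol", "acetate", "erythritol",
            )
        }
        products["diacetyl"] = "EX_dia"
        products["ethanol"] = "EX_etoh"
    for name, rid in {**substrates, **products}.items():
        if not network.has_reaction(rid):
            raise KeyError(f"no exchange reaction {rid!r} for {name!r}")
    counts = pd.DataFrame(
        0, index=list(substrates), columns=list(products), dtype=int
    )
    totals: Dict[str, int] = {}
    for sub_name, sub_ex in substrates.items():
        net = network.copy()
        for other, other_ex in substrates.items():
            rxn = net.reaction(other_ex)
            if other == sub_name:
                rxn.lower_bound = -1000.0
                rxn.upper_bound = 0.0
            else:
                rxn.lower_bound = 0.0  # uptake closed, export still allowed
        for prod_ex in products.values():
            rxn = net.reaction(prod_ex)
            rxn.upper_bound = 1000.0
        modes = enumerate_efms(net, max_reactions=max_reactions)
        totals[sub_name] = len(modes)
        for prod_name, prod_ex in products.items():
            counts.loc[sub_name, prod_name] = sum(
                1 for mode in modes if mode.flux(prod_ex) > 0
            )
    return EFMTable(counts=counts, total_modes=totals)
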