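"""Experimental constraint containers shared across modules."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

from .network import MetabolicNetwork


@dataclass
class PhaseConstraintSet:
    """Measured specific rates to impose on one growth phase.

    ``fixed_fluxes`` maps reaction ids (typically the nine substrate and
    five product exchanges) to measured values, each imposed as an interval
    ``value ± tolerance·|value|``.  ``biomass`` (h⁻¹) is fixed the same way
    when given; ``ngam`` is fixed exactly when given.  ``range_bounds``
    carries plain (lb, ub) intervals, e.g. accumulation spans from the
    extended-model FVA.
    """

    phase_id: int
    fixed_fluxes: Dict[str, float] = field(default_factory=dict)
    biomass: Optional[float] = None
    ngam: Optional[float] = None
    tolerance: float = 0.025
    range_bounds: Dict[str, Tuple[float, float]] = field(default_factory=dict)
    #: absolute slack floor so that "fixed" values survive float round-off
    absolute_slack: float = 1e-9

    def interval(self, value: float) -> Tuple[float, float]:
        slack = max(self.tolerance * abs(value), self.absolute_slack)
        return value - slack, value + slack

    def apply(
        self,
        network: MetabolicNetwork,
        biomass_id: str = "BIOMASS",
        ngam_id: str = "NGAM",
    ) -> MetabolicNetwork:
        """Return a constrained copy of ``network``."""
        missing = [
            rid
            for rid in list(self.fixed_fluxes) + list(self.range_bounds)
            if not network.has_reaction(rid)
        ]
        if missing:
            raise KeyError(
                f"constrained reactions absent from model: {sorted(missing)}"
            )
        net = network.copy()
        for rid, value in self.fixed_fluxes.items():
            lo, hi = self.interval(value)
            net.set_bounds(rid, lo, hi)
        for rid, (lo, hi) in self.range_bounds.items():
            net.set_bounds(rid, lo, hi)
        if self.biomass is not None:
            lo, hi = self.interval(self.biomass)
            net.set_bounds(biomass_id, max(lo, 0.0), hi)
        if self.ngam is not None:
            net.set_bounds(ngam_id, self.ngam, self.ngam)
        return net
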