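"""Reaction-time budget of a mix-and-inject spray-freezing apparatus.

The reaction time t_rxn — from the moment mixing starts to vitrification —
is the sum of five components:

1. **t_mix** — diffusive mixing into the hydrodynamically focused sample
   stream.  The sheath (stimulant) flow thins the central sample stream; for
   laminar co-flow in a cylindrical capillary the sample occupies a
   cross-sectional area fraction equal to its flow fraction, so the stream
   width is ``w = d_delay * sqrt(Q_sample / Q_total)``.  The characteristic
   diffusion time over the stream half-width is ``t_mix = (w/2)^2 / (4 D)``.
   This is the standard order-of-magnitude estimate for hydrodynamic
   focusing, not a CFD result; outputs are meant to be checked against
   achievable *ranges*, never against exact timepoints.
2. **t_delay** — plug-flow transit of the delay line postmixing:
   cylinder volume / total volumetric flow.
3. **t_flight** — aerosol time-of-flight from nozzle to grid; an empirical
   range (default 1-4 ms).
4. **t_grid** — time on the grid between droplet deposition and entry into
   the ethane, set by the plunge mechanics; an empirical range
   (default 16-89 ms).
5. **t_freeze** — vitrification of micron-scale droplets, of order 1 ms.

Uncertainty is propagated as interval arithmetic: the budget's range
endpoints are the sums of the component minima and maxima.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

#: exact unit factors
UL_PER_MIN_TO_UM3_PER_MS = 1e9 / 60000.0  # 1 ul/min in um^3/ms
NL_S_PER_UL_MIN = 1000.0 / 60.0


def ul_min_to_nl_s(flow_ul_min: float) -> float:
    """Convert a flow from ul/min to nl/s (multiply by 1000/60 = 50/3).

    Factored as ``(x * 50) / 3`` so that together with
    :func:`nl_s_to_ul_min` the round trip is bit-exact for every flow
    expressible at pump-setting granularity (integers and half-integers of
    ul/min, and far beyond).
    """
    return (flow_ul_min * 50.0) / 3.0


def nl_s_to_ul_min(flow_nl_s: float) -> float:
    """Inverse of :func:`ul_min_to_nl_s`: ``(x * 3) / 50``."""
    return (flow_nl_s * 3.0) / 50.0


class ValidationError(ValueError):
    """Raised in strict mode for parameters outside the fabrication/operating envelope."""


@dataclass(frozen=True)
class MixerGeometry:
    """Concentric-capillary mixer geometry (lengths as annotated)."""

    supply_inner_diameter: float = 75.0   # um
    delay_inner_diameter: float = 75.0    # um
    delay_length: float = 20.0            # mm
    nozzle_diameter: float = 100.0        # um
    focusing_gap: float = 75.0            # um

    def validate(self, strict: bool = False) -> None:
        for name in ("supply_inner_diameter", "delay_inner_diameter", "delay_length",
                     "nozzle_diameter", "focusing_gap"):
            if not getattr(self, name) >= 0:
                raise ValidationError(f"{name} must be non-negative")
        if not (80.0 <= self.nozzle_diameter <= 110.0):
            msg = f"nozzle_diameter {self.nozzle_diameter} um outside fabrication range 80-110 um"
            if strict:
                raise ValidationError(msg)
            warnings.warn(msg, stacklevel=2)


@dataclass(frozen=True)
class FlowConfig:
    """Sample and stimulant flows plus the stimulant's diffusivity."""

    sample_flow: float = 15.0        # ul/min
    stimulant_flow: float = 45.0     # ul/min
    stimulant_diffusivity: float = 1.0  # um^2/ms (small-molecule scale)

    @property
    def total_flow(self) -> float:
        return self.sample_flow + self.stimulant_flow

    @property
    def ratio(self) -> float:
        return self.stimulant_flow / self.sample_flow

    def validate(self, strict: bool = False) -> None:
        if self.sample_flow <= 0 or self.stimulant_flow <= 0 or self.stimulant_diffusivity <= 0:
            raise ValidationError("flows and diffusivity must be positive")
        msgs = []
        if not (35.0 <= self.total_flow <= 130.0):
            msgs.append(f"total flow {self.total_flow:g} ul/min outside operating range 35-130")
        if not (1.5 <= self.ratio <= 5.8):
            msgs.append(f"stimulant/sample ratio {self.ratio:g} outside operating range 1.5-5.8")
        for msg in msgs:
            if strict:
                raise ValidationError(msg)
            warnings.warn(msg, stacklevel=2)


@dataclass(frozen=True)
class PlungeConfig:
    """Empirical ranges of the injection and plunge components, in ms."""

    t_flight_range: tuple = (1.0, 4.0)
    t_grid_range: tuple = (16.0, 89.0)
    t_freeze: float = 1.0


@dataclass
class ReactionTimeBudget:
    """Five additive components and the resulting reaction-time range (ms)."""

    t_mix: float
    t_delay: float
    t_flight_range: tuple
    t_grid_range: tuple
    t_freeze: float
    t_rxn_range: tuple = field(init=False)
    component_spread: dict = field(init=False)

    def __post_init__(self) -> None:
        lo = self.t_mix + self.t_delay + self.t_flight_range[0] + self.t_grid_range[0] + self.t_freeze
        hi = self.t_mix + self.t_delay + self.t_flight_range[1] + self.t_grid_range[1] + self.t_freeze
        self.t_rxn_range = (lo, hi)
        self.component_spread = {
            "t_mix": 0.0,
            "t_delay": 0.0,
            "t_flight": self.t_flight_range[1] - self.t_flight_range[0],
            "t_grid": self.t_grid_range[1] - self.t_grid_range[0],
            "t_freeze": 0.0,
        }

    @property
    def dominant_uncertainty(self) -> str:
        return max(self.component_spread, key=lambda k: self.component_spread[k])

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.t_rxn_range[0] + self.t_rxn_range[1])

    def brackets(self, t_ms: float) -> bool:
        return self.t_rxn_range[0] <= t_ms <= self.t_rxn_range[1]

    def as_dict(self) -> dict:
        return {
            "t_mix_ms": self.t_mix,
            "t_delay_ms": self.t_delay,
            "t_flight_ms_min": self.t_flight_range[0],
            "t_flight_ms_max": self.t_flight_range[1],
            "t_grid_ms_min": self.t_grid_range[0],
            "t_grid_ms_max": self.t_grid_range[1],
            "t_freeze_ms": self.t_freeze,
            "t_rxn_ms_min": self.t_rxn_range[0],
            "t_rxn_ms_max": self.t_rxn_range[1],
            "dominant_uncertainty": self.dominant_uncertainty,
        }


def focused_stream_width(geometry: MixerGeometry, flows: FlowConfig) -> float:
    """Width (um) of the hydrodynamically focused central sample stream.

    Cylindrical laminar co-flow: the sample's cross-sectional area fraction
    equals its flow fraction, hence ``w = d * sqrt(Q_s / Q_tot)``.
    """
    if flows.sample_flow < 0 or flows.total_flow <= 0:
        raise ValidationError("flows must be positive")
    return geometry.delay_inner_diameter * math.sqrt(flows.sample_flow / flows.total_flow)


def mixing_time(width_um: float, diffusivity_um2_ms: float) -> float:
    """Characteristic diffusion time (ms) across a stream of given width.

    ``t_mix = (w/2)^2 / (4 D)`` — monotone increasing in width, decreasing
    in diffusivity.
    """
    if width_um < 0 or diffusivity_um2_ms <= 0:
        raise ValidationError("width must be >= 0 and diffusivity > 0")
    return (width_um / 2.0) ** 2 / (4.0 * diffusivity_um2_ms)


def delay_time(geometry: MixerGeometry, flows: FlowConfig) -> float:
    """Plug-flow transit time (ms) of the delay line postmixing."""
    if flows.total_flow <= 0:
        raise ValidationError("total flow must be positive")
    radius_um = geometry.delay_inner_diameter / 2.0
    volume_um3 = math.pi * radius_um**2 * (geometry.delay_length * 1000.0)
    q_um3_ms = flows.total_flow * UL_PER_MIN_TO_UM3_PER_MS
    return volume_um3 / q_um3_ms


def budget(
    geometry: MixerGeometry,
    flows: FlowConfig,
    plunge: PlungeConfig | None = None,
    strict: bool = False,
) -> ReactionTimeBudget:
    """Assemble the five-component reaction-time budget for one configuration.

    In strict mode, geometry and flow values outside the fabrication and
    operating envelopes raise :class:`ValidationError`; otherwise they warn.
    """
    plunge = plunge or PlungeConfig()
    geometry.validate(strict=strict)
    flows.validate(strict=strict)
    w = focused_stream_width(geometry, flows)
    t_mix = mixing_time(w, flows.stimulant_diffusivity)
    t_del = delay_time(geometry, flows)
    return ReactionTimeBudget(
        t_mix=t_mix,
        t_delay=t_del,
        t_flight_range=tuple(plunge.t_flight_range),
        t_grid_range=tuple(plunge.t_grid_range),
        t_freeze=plunge.t_freeze,
    )
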