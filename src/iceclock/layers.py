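"""Marine-ice layer bookkeeping and age-depth extraction.

The ice column is modeled as an ordered stack of marine-ice layers under
the meteoric ice.  Index 1 is the oldest layer (at the meteoric/marine
interface); the newest layer sits at the ice-ocean interface.  Per
flowline segment the basal mass balance either accretes a new layer or
melts existing layers newest-first, and every layer is then thinned by
the vertical strain rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import EmptyStackError, ProfileRangeError

_MASS_TOL = 1e-9


@dataclass
class Layer:
    """One marine-ice layer.

    ``accretion_time`` is the cumulative transit time (yr since departure
    from the grounding line) at which the layer finished accreting;
    ``accretion_span`` is the duration over which it accreted (used only to
    date the very top of the column).
    """

    thickness: float
    accretion_time: float
    accretion_span: float = 0.0


@dataclass
class LayerStack:
    """Ordered marine-ice layers, oldest first."""

    layers: list = field(default_factory=list)

    @property
    def total_thickness(self) -> float:
        return float(sum(l.thickness for l in self.layers))

    def __len__(self) -> int:
        return len(self.layers)

    def thicknesses(self) -> np.ndarray:
        return np.array([l.thickness for l in self.layers])

    def accretion_times(self) -> np.ndarray:
        return np.array([l.accretion_time for l in self.layers])


@dataclass(frozen=True)
class StepRecord:
    """Diagnostics for one segment step of the layer model."""

    index: int
    dHm: float  # signed basal thickness change this step (m)
    Hm: float  # total marine-ice thickness after the step (m)
    n_layers: int
    melt_deficit: float  # ice demanded beyond available marine ice (m, >= 0)


def basal_mass_change(ab: float, dt: float) -> float:
    """Marine-ice thickness change over one segment: ``-ab * dt``.

    ``ab`` is positive for melting, so a negative basal rate (accretion)
    yields a positive thickness change.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    return -ab * dt


def accrete(stack: LayerStack, dHm: float, t_now: float, span: float = 0.0) -> LayerStack:
    """Append a new layer of thickness ``dHm`` accreted at time ``t_now``.

    Mutates and returns ``stack``.
    """
    if dHm <= 0:
        raise ValueError(f"accretion requires dHm > 0, got {dHm}")
    stack.layers.append(Layer(thickness=dHm, accretion_time=t_now, accretion_span=span))
    return stack


def melt(stack: LayerStack, dHm: float) -> tuple:
    """Remove ``|dHm|`` of ice from the newest layer downward (LIFO).

    Exhausted layers are deleted together with their ages; if the stack
    empties before the demand is met, the remainder is returned as
    ``melt_deficit``.  Mutates ``stack``; returns ``(stack, melt_deficit)``.
    """
    if dHm >= 0:
        raise ValueError(f"melting requires dHm < 0, got {dHm}")
    demand = -dHm
    while demand > 0 and stack.layers:
        top = stack.layers[-1]
        if top.thickness > demand:
            top.thickness -= demand
            demand = 0.0
        else:
            demand -= top.thickness
            stack.layers.pop()
    return stack, demand


def apply_thinning(
    stack: LayerStack, ezz: float, dt: float, scheme: str = "exp"
) -> LayerStack:
    """Thin (or thicken) every layer by the vertical strain rate over ``dt``.

    ``scheme="exp"`` multiplies each thickness by ``exp(ezz * dt)`` — the
    exact solution of ``dh/dt = ezz * h`` over the segment.  ``scheme="linear"``
    uses the first-order factor ``1 + ezz * dt``.  Ages are unchanged.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if scheme == "exp":
        f = math.exp(ezz * dt)
    elif scheme == "linear":
        f = 1.0 + ezz * dt
        if f < 0:
            raise ValueError("linear thinning factor went negative; use scheme='exp'")
    else:
        raise ValueError(f"unknown thinning scheme {scheme!r}")
    for l in stack.layers:
        l.thickness *= f
    return stack


def run_flowline(
    segments,
    ab_offset: float = 0.0,
    ab_perturb=None,
    thinning: str = "exp",
) -> tuple:
    """Run the layer model over an ordered sequence of flowline segments.

    Per segment: compute the basal thickness change from
    ``(basal_rate + ab_offset + perturbation, duration)``, accrete or melt,
    then apply strain thinning to all layers (including any layer accreted
    this segment).  Transit time accumulates segment durations.

    Parameters
    ----------
    ab_offset : constant shift added to every segment's basal rate (m/yr).
    ab_perturb : optional per-segment additive perturbation array (m/yr),
        used for uncertainty propagation.
    thinning : "exp" (default) or "linear" first-order factor.

    Returns
    -------
    (LayerStack, list[StepRecord])
    """
    segments = list(segments)
    if not segments:
        raise ValueError("segments must be non-empty")
    if ab_perturb is not None and len(ab_perturb) != len(segments):
        raise ValueError("ab_perturb length must match number of segments")
    stack = LayerStack()
    records = []
    t_now = 0.0
    for k, seg in enumerate(segments):
        dt = seg.duration
        ab = seg.basal_rate + ab_offset
        if ab_perturb is not None:
            ab += float(ab_perturb[k])
        dHm = basal_mass_change(ab, dt)
        deficit = 0.0
        if dHm > 0:
            accrete(stack, dHm, t_now + dt, span=dt)
        elif dHm < 0:
            _, deficit = melt(stack, dHm)
        apply_thinning(stack, seg.strain_rate, dt, scheme=thinning)
        t_now += dt
        records.append(
            StepRecord(
                index=seg.index,
                dHm=dHm,
                Hm=stack.total_thickness,
                n_layers=len(stack),
                melt_deficit=deficit,
            )
        )
    return stack, records


@dataclass(frozen=True)
class AgeDepthProfile:
    """Piecewise-linear age vs depth below the meteoric/marine interface.

    Depth 0 is the interface (oldest marine ice); depth increases downward
    to the ice-ocean interface at the total marine thickness.  Ages are
    years before arrival at the drill site and are non-increasing with
    depth.  Optional ``age_lo``/``age_hi`` carry uncertainty bounds.
    """

    depth: np.ndarray
    age: np.ndarray
    age_lo: np.ndarray = None
    age_hi: np.ndarray = None

    @property
    def total_thickness(self) -> float:
        return float(self.depth[-1])

    def age_at(self, depth: float) -> float:
        """Linearly interpolated age at ``depth`` (m below the interface)."""
        if depth < -_MASS_TOL or depth > self.depth[-1] + _MASS_TOL:
            raise ProfileRangeError(
                f"depth {depth} m outside modeled marine column "
                f"[0, {self.depth[-1]:.3f}] m"
            )
        return float(np.interp(depth, self.depth, self.age))


def age_depth_profile(
    stack: LayerStack, total_transit_time: float, drill_lag: float = 0.0
) -> AgeDepthProfile:
    """Convert a layer stack into an age-depth profile.

    The bottom of layer k lies at the cumulative thickness of layers 1..k;
    its age is ``total_transit_time - accretion_time + drill_lag``.  The top
    of the column (depth 0) is dated to the start of layer 1's accretion
    segment.  Ages between layer boundaries are linear.
    """
    if not stack.layers:
        raise EmptyStackError("cannot build an age-depth profile from an empty stack")
    h = stack.thicknesses()
    tau = stack.accretion_times()
    depths = np.concatenate([[0.0], np.cumsum(h)])
    top_time = stack.layers[0].accretion_time - stack.layers[0].accretion_span
    times = np.concatenate([[top_time], tau])
    ages = total_transit_time - times + drill_lag
    return AgeDepthProfile(depth=depths, age=ages)


def age_with_uncertainty(
    segments,
    depth: float,
    sigma_mode: str = "systematic",
    n_mc: int = 100,
    seed=None,
    drill_lag: float = 0.0,
    thinning: str = "exp",
) -> tuple:
    """Age at ``depth`` with bounds from basal-rate uncertainty.

    ``sigma_mode="systematic"`` reruns the model with every segment's basal
    rate shifted together by -sigma and +sigma; ``sigma_mode="mc"`` takes
    the envelope of ``n_mc`` Monte-Carlo reruns with independent per-segment
    Gaussian perturbations drawn under ``seed``.

    Returns ``(age_lo, age_best, age_hi)``.

    Raises
    ------
    ProfileRangeError
        If the depth exceeds the modeled thickness in any scenario (the
        message names the scenario).
    """
    segments = list(segments)
    total_t = sum(s.duration for s in segments)
    sigmas = np.array([s.basal_rate_sigma for s in segments])

    def scenario_age(name, perturb):
        stack, _ = run_flowline(segments, ab_perturb=perturb, thinning=thinning)
        if not stack.layers:
            raise ProfileRangeError(f"scenario {name!r}: no marine ice accumulated")
        prof = age_depth_profile(stack, total_t, drill_lag=drill_lag)
        try:
            return prof.age_at(depth)
        except ProfileRangeError as exc:
            raise ProfileRangeError(f"scenario {name!r}: {exc}") from exc

    best = scenario_age("best", None)
    ages = [best]
    if sigma_mode == "systematic":
        # ab positive = melting: -sigma melts less / accretes more
        ages.append(scenario_age("minus", -sigmas))
        ages.append(scenario_age("plus", +sigmas))
    elif sigma_mode == "mc":
        rng = np.random.default_rng(seed)
        for k in range(n_mc):
            perturb = rng.normal(0.0, sigmas)
            ages.append(scenario_age(f"mc[{k}]", perturb))
    else:
        raise ValueError(f"unknown sigma_mode {sigma_mode!r}")
    return (min(ages), best, max(ages))
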