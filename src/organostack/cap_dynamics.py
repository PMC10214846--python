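"""Pump-free flow measurement and feeding simulation.

The spherical cap on an input stack is the platform's built-in flow meter:
images give the cap height above the rim, heights give cap volumes through
the spherical-cap relation, and the rate of volume loss is the throughflow.
The same geometry drives the feeding simulation: cap states set boundary
pressures on the circuit's resistance network, the network is solved for
flows, and cap volumes are stepped forward — with over-filled output caps
budding off (self-emptying) once buoyancy beats contact-line pinning.
"""

from __future__ import annotations


import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd

from . import fluid_mechanics as fm
from .circuits import CircuitSpec
from .darcy_network import HydraulicNetwork, solve_network

__all__ = [
    "CapSeries",
    "FlowEstimate",
    "FeedingEvent",
    "FeedingSchedule",
    "FeedingTrajectory",
    "series_to_flow",
    "recovered_volume_flow",
    "replenishment_time",
    "simulate_feeding",
]

#: default moving-average window (samples) applied to heights before differencing
DEFAULT_SMOOTHING_WINDOW = 3
#: default integration step for simulate_feeding, s
DEFAULT_STEP_S = 10.0
#: adaptive halving floor, as a fraction of the requested step
MIN_STEP_FRACTION = 2.0 ** -20
#: allowed drift in the volume budget over a simulation (relative)
CONSERVATION_TOLERANCE = 1e-3
#: caps at or below this volume count as drained (flow-limited), m^3
EMPTY_VOLUME = 1e-13


@dataclass(frozen=True)
class CapSeries:
    """A cap-height time series measured on one stack opening."""

    times: np.ndarray  # s, strictly increasing
    heights: np.ndarray  # m, >= 0
    base_radius: float  # m

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        h = np.asarray(self.heights, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "heights", h)
        if t.shape != h.shape or t.ndim != 1:
            raise ValueError("times and heights must be matching 1-D arrays")
        if t.size >= 2 and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(h < 0):
            raise fm.InvalidGeometryError("cap heights must be >= 0")
        if np.any(h > 2 * self.base_radius):
            raise fm.InvalidGeometryError(
                "cap height exceeds the opening diameter")

    @classmethod
    def from_csv(cls, path: Union[str, Path], base_radius: float) -> "CapSeries":
        """Load the ``time_s,height_mm`` CSV dialect."""
        df = pd.read_csv(path)
        return cls(df["time_s"].to_numpy(float),
                   df["height_mm"].to_numpy(float) * 1e-3, base_radius)

    def to_csv(self, path: Union[str, Path]) -> None:
        pd.DataFrame({"time_s": self.times,
                      "height_mm": self.heights / 1e-3}).to_csv(path, index=False)


@dataclass(frozen=True)
class FlowEstimate:
    """Derived cap volumes and flow rates (positive = cap shrinking)."""

    times: np.ndarray  # s
    volumes: np.ndarray  # m^3
    flow_rates: np.ndarray  # m^3/s at each sample (central differences)
    cumulative_volume: np.ndarray  # m^3 delivered since t0

    @property
    def mean_rate(self) -> float:
        return float(np.mean(self.flow_rates))


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return x
    if window % 2 == 0:
        raise ValueError("smoothing window must be odd")
    half = window // 2
    padded = np.pad(x, half, mode="edge")
    kernel = np.ones(window) / window
    return np.convolve(padded, kernel, mode="valid")


def series_to_flow(series: CapSeries,
                   smoothing_window: int = DEFAULT_SMOOTHING_WINDOW,
                   ) -> FlowEstimate:
    """Convert a cap-height series into volumes and flow rates.

    Heights are optionally smoothed with a centred moving average
    (edge-padded; ``smoothing_window=1`` disables smoothing), converted to
    volumes via the spherical-cap relation, and differentiated by central
    finite differences; ``Q = -dV/dt`` so a shrinking input cap gives a
    positive delivery rate.  On a noiseless series whose volume declines
    linearly the recovered rate is exact.
    """
    if series.times.size < 2:
        raise ValueError("need at least two samples to estimate a flow rate")
    heights = _moving_average(series.heights, smoothing_window)
    volumes = np.array([fm.cap_from_height(series.base_radius, h).volume
                        for h in heights])
    rates = -np.gradient(volumes, series.times)
    cumulative = volumes[0] - volumes
    return FlowEstimate(series.times, volumes, rates, cumulative)


def recovered_volume_flow(volume: float, interval: float) -> float:
    """Flow rate from the recovered-volume method: volume removed / time.

    The output reservoir is filled to the brim at t=0 and the excess
    (including any budded-off drops) removed after ``interval`` seconds.
    """
    if interval <= 0:
        raise ValueError(f"interval must be positive, got {interval}")
    return volume / interval


def replenishment_time(module_volumes: Sequence[float], input_rate: float) -> float:
    """Time to replace the total module volume at the given input rate, s."""
    if input_rate <= 0:
        raise ValueError(f"input rate must be positive, got {input_rate}")
    return float(np.sum(np.asarray(module_volumes, dtype=float)) / input_rate)


# --- feeding simulation -------------------------------------------------------

@dataclass(frozen=True)
class FeedingEvent:
    """One scheduled pipetting action on a stack's cap/reservoir."""

    time: float  # s
    volume: float  # m^3, >= 0
    stack: str
    kind: str = "add"  # "add" or "withdraw"

    def __post_init__(self) -> None:
        if self.volume < 0:
            raise ValueError("event volumes must be >= 0")
        if self.kind not in ("add", "withdraw"):
            raise ValueError(f"unknown event kind {self.kind!r}")


@dataclass
class FeedingSchedule:
    """Discrete pipetting events plus optional continuous delivery rates."""

    events: list[FeedingEvent] = field(default_factory=list)
    rates: dict[str, float] = field(default_factory=dict)  # stack -> m^3/s

    def add(self, time: float, volume: float, stack: str) -> None:
        self.events.append(FeedingEvent(time, volume, stack, "add"))

    def withdraw(self, time: float, volume: float, stack: str) -> None:
        self.events.append(FeedingEvent(time, volume, stack, "withdraw"))


@dataclass
class FeedingTrajectory:
    """Result of :func:`simulate_feeding`."""

    frame: pd.DataFrame  # time_s + one volume column per stack (m^3)
    bud_events: list[tuple[float, str, float]]  # (time, stack, volume removed)
    total_input: float
    total_budded: float
    total_withdrawn: float
    conservation_error: float  # relative budget drift

    def cap_volumes(self, stack: str) -> np.ndarray:
        return self.frame[f"V_{stack}_m3"].to_numpy()


def _stack_potential(stack: fm.StackSpec, cap: fm.SphericalCap,
                     env: fm.Environment) -> float:
    """Driving potential of a stack node at the shared wetted base.

    ``-drho*g*h_stack`` (a taller stack displaces more dense FC40, so its
    base sits at lower pressure) plus the cap's Laplace pressure.  Cap
    self-weight is neglected, as is conventional for mm-scale caps.
    """
    head = -env.density_difference * env.gravity * stack.stack_height
    laplace = fm.laplace_at_angle(env.gamma, cap.base_radius,
                                  cap.contact_angle) if cap.height > 0 else 0.0
    return head + laplace


def simulate_feeding(circuit: CircuitSpec, schedule: FeedingSchedule,
                     duration: float, step: float = DEFAULT_STEP_S,
                     record_every: int = 1) -> FeedingTrajectory:
    """Explicit time-stepping of cap volumes in a fed circuit.

    At each step the boundary pressures of every stack node are recomputed
    from the current cap state, the resistance network is solved, cap
    volumes are advanced by the net flows plus any schedule events, and
    caps whose volume exceeds the budding threshold
    (:func:`~organostack.fluid_mechanics.bud_volume`) are reset to the
    90-degree hemisphere with the excess logged as a bud.  Steps that would
    drive a cap volume negative are halved adaptively (down to a floor of
    ``step * 2**-20``, then an error is raised).

    The volume budget (inputs = cap changes + buds + withdrawals) is
    checked to 0.1% relative drift at the end.
    """
    if step <= 0 or duration <= 0:
        raise ValueError("duration and step must be positive")
    env = circuit.environment
    stacks = circuit.stacks
    if not stacks:
        raise ValueError("circuit has no stacks")
    for label in schedule.rates:
        if label not in stacks:
            raise KeyError(f"schedule rate targets unknown stack {label!r}")

    caps: dict[str, fm.SphericalCap] = {}
    for label, stack in stacks.items():
        caps[label] = stack.cap if stack.cap is not None else \
            fm.cap_from_height(stack.opening_diameter / 2.0, 0.0)
    volumes = {label: caps[label].volume for label in stacks}
    initial_total = sum(volumes.values())
    bud_thresholds = {
        label: fm.bud_volume(stack.opening_diameter, env.gamma,
                             env.density_difference, env.gravity)
        for label, stack in stacks.items()
    }
    hemi_volumes = {
        label: fm.cap_from_height(stack.opening_diameter / 2.0,
                                  stack.opening_diameter / 2.0).volume
        for label, stack in stacks.items()
    }

    events = sorted(schedule.events, key=lambda e: e.time)
    next_event = 0
    bud_log: list[tuple[float, str, float]] = []
    total_input = 0.0
    total_budded = 0.0
    total_withdrawn = 0.0

    times = [0.0]
    records = {label: [volumes[label]] for label in stacks}

    def net_outflows(limited: set[str]) -> dict[str, float]:
        """Solve the network for the current cap state.

        Stacks in ``limited`` have drained empty and can deliver no more
        than their external supply; they enter as fixed-inflow boundaries
        (net outflow equals supply) instead of fixed pressures.
        """
        inflows = dict(circuit.network.inflows)
        for label in limited:
            inflows[label] = inflows.get(label, 0.0) + schedule.rates.get(label, 0.0)
        net = HydraulicNetwork(
            edges=list(circuit.network.edges),
            pressures={label: _stack_potential(stacks[label], caps[label], env)
                       for label in stacks if label not in limited},
            inflows=inflows,
        )
        sol = solve_network(net)
        out = {label: 0.0 for label in stacks}
        for e, q in zip(net.edges, sol.edge_flows):
            if e.node_a in out:
                out[e.node_a] += q
            if e.node_b in out:
                out[e.node_b] -= q
        return out

    t = 0.0
    min_step = step * MIN_STEP_FRACTION
    while t < duration - 1e-12:
        # apply due events
        while next_event < len(events) and events[next_event].time <= t + 1e-12:
            ev = events[next_event]
            next_event += 1
            if ev.stack not in volumes:
                raise KeyError(f"event targets unknown stack {ev.stack!r}")
            if ev.kind == "add":
                volumes[ev.stack] += ev.volume
                total_input += ev.volume
            else:
                taken = min(ev.volume, volumes[ev.stack])
                if taken < ev.volume:
                    warnings.warn(
                        f"withdrawal at t={ev.time} s truncated: cap "
                        f"{ev.stack!r} held only {volumes[ev.stack]:.3g} m^3",
                        stacklevel=2)
                volumes[ev.stack] -= taken
                total_withdrawn += taken
            caps[ev.stack] = fm.cap_from_volume(
                stacks[ev.stack].opening_diameter / 2.0, volumes[ev.stack])

        dt = min(step, duration - t)
        if next_event < len(events):
            dt = min(dt, max(events[next_event].time - t, min_step))

        # classify drained caps as flow-limited (complementarity loop), then
        # advance with adaptive halving if a cap would still empty mid-step
        limited: set[str] = set()
        while True:
            out = net_outflows(limited)
            newly = {label for label in volumes
                     if label not in limited
                     and volumes[label] <= EMPTY_VOLUME
                     and out[label] > schedule.rates.get(label, 0.0)}
            if len(limited) + len(newly) >= len(volumes) and newly:
                # keep the fullest cap as the pressure datum
                newly.discard(max(volumes, key=lambda s: volumes[s]))
            if not newly:
                break
            limited |= newly
        while True:
            trial = {}
            ok = True
            for label in volumes:
                dv = dt * (schedule.rates.get(label, 0.0) - out[label])
                v_new = volumes[label] + dv
                if v_new < -1e-18:
                    ok = False
                    break
                trial[label] = max(v_new, 0.0)
            if ok:
                break
            dt /= 2.0
            if dt < min_step:
                raise RuntimeError(
                    "adaptive step floor reached; a cap empties faster than "
                    "the integrator can follow")
        for label in volumes:
            total_input += dt * schedule.rates.get(label, 0.0)
            volumes[label] = trial[label]
            # budding: excess above the hemisphere detaches and floats away
            if volumes[label] > bud_thresholds[label]:
                removed = volumes[label] - hemi_volumes[label]
                volumes[label] = hemi_volumes[label]
                total_budded += removed
                bud_log.append((t + dt, label, removed))
            caps[label] = fm.cap_from_volume(
                stacks[label].opening_diameter / 2.0, volumes[label])
        t += dt
        times.append(t)
        for label in volumes:
            records[label].append(volumes[label])

    delta_caps = sum(volumes.values()) - initial_total
    budget = total_input - (delta_caps + total_budded + total_withdrawn)
    scale = max(total_input, initial_total, 1e-30)
    conservation_error = abs(budget) / scale
    if conservation_error > CONSERVATION_TOLERANCE:
        warnings.warn(
            f"volume budget drifted by {conservation_error:.2e} (relative)",
            stacklevel=2)

    frame = pd.DataFrame({"time_s": times[::record_every],
                          **{f"V_{label}_m3": np.array(v)[::record_every]
                             for label, v in records.items()}})
    return FeedingTrajectory(frame, bud_log, total_input, total_budded,
                             total_withdrawn, conservation_error)
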