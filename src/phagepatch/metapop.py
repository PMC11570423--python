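"""Cycle-structured stochastic metapopulation of ephemeral host patches.

Many transient resource patches are suspended in a well-mixed medium.  Hosts
A and B settle in patches containing their resource, grow with
Michaelis–Menten kinetics (one resource unit per division), detach as
resources deplete, and decay.  Generalist and specialist phage migrate
between medium and patches, infect hosts inside patches only, and reproduce
via Poisson-distributed bursts; infected cells that leave a patch lyse
immediately into the medium.  Specialists never infect host B.

Time advances in fixed cycles (20 min by default).  Within a cycle each
patch is advanced independently by a Gillespie simulation (order randomized
to avoid priority artifacts), then medium populations are thinned once for
decay, exhausted patches are culled (their occupants spill into the medium),
and new patches are added on a fixed schedule: the *together* treatment adds
one patch endowed with both resources, the *apart* treatment two patches
with one resource each.

Two state representations coexist: the dataclasses
(:class:`PatchState`/:class:`MediumState`/:class:`SystemState`) are the
readable API, while long simulations run on a packed integer-array
representation (:class:`ArraySystem`) whose inner loop is compiled; both
views share the same kernels, so they cannot drift apart.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from . import _kernels
from ._kernels import N_COUNTERS
from .params import MetapopParams

__all__ = [
    "PatchState",
    "MediumState",
    "SystemState",
    "ArraySystem",
    "ProbeLayer",
    "event_rates",
    "step_patch",
    "run_cycle",
    "cull_patches",
    "add_patches",
    "run_simulation",
    "new_patch",
]

STATE_LEN = 16

CHANNEL_NAMES = (
    "arrival_A", "arrival_B", "division_A", "division_B",
    "detach_A", "detach_B", "decay_A", "decay_B",
    "resource_decay_A", "resource_decay_B",
    "arrival_G", "arrival_S", "exit_G", "exit_S", "decay_G", "decay_S",
    "infect_GA", "infect_GB", "infect_SA",
    "burst_IGA", "burst_IGB", "burst_ISA",
    "decay_IGA", "decay_IGB", "decay_ISA",
    "detach_IGA", "detach_IGB", "detach_ISA",
)

# column indices in the packed patch array
_XA, _XB, _A, _B, _G, _S, _IGA, _IGB, _ISA = range(9)
_Y0A, _Y0B, _CONSA, _CONSB, _DECA, _DECB, _V = range(9, 16)


@dataclass
class PatchState:
    """Nine-variable state of one patch plus bookkeeping ledgers.

    ``cons_*`` and ``dec_*`` record resource units consumed by host
    divisions and lost to decay, so ``y0 = x + cons + dec`` holds exactly
    at all times.  ``virtual`` counts opportunity-cost tracer particles
    (zero outside probe runs).
    """

    x_A: int
    x_B: int
    A: int = 0
    B: int = 0
    G: int = 0
    S: int = 0
    I_GA: int = 0
    I_GB: int = 0
    I_SA: int = 0
    y0_A: int = 0
    y0_B: int = 0
    cons_A: int = 0
    cons_B: int = 0
    dec_A: int = 0
    dec_B: int = 0
    virtual: int = 0
    age: int = 0

    def __post_init__(self) -> None:
        if self.y0_A == 0 and self.y0_B == 0:
            self.y0_A = self.x_A
            self.y0_B = self.x_B

    def to_array(self) -> np.ndarray:
        return np.array(
            [
                self.x_A, self.x_B, self.A, self.B, self.G, self.S,
                self.I_GA, self.I_GB, self.I_SA, self.y0_A, self.y0_B,
                self.cons_A, self.cons_B, self.dec_A, self.dec_B,
                self.virtual,
            ],
            dtype=np.int64,
        )

    @classmethod
    def from_array(cls, arr: np.ndarray, age: int = 0) -> "PatchState":
        p = cls(*(int(x) for x in arr))
        p.age = age
        return p

    def update_from(self, arr: np.ndarray) -> None:
        (
            self.x_A, self.x_B, self.A, self.B, self.G, self.S,
            self.I_GA, self.I_GB, self.I_SA, self.y0_A, self.y0_B,
            self.cons_A, self.cons_B, self.dec_A, self.dec_B, self.virtual,
        ) = (int(x) for x in arr)

    @property
    def exhausted(self) -> bool:
        return (self.x_A + self.x_B) < 0.05 * (self.y0_A + self.y0_B)


@dataclass
class MediumState:
    """Well-mixed medium: planktonic hosts and free phage (no infections)."""

    M_A: int = 0
    M_B: int = 0
    M_G: int = 0
    M_S: int = 0
    M_V: int = 0

    def to_array(self) -> np.ndarray:
        return np.array(
            [self.M_A, self.M_B, self.M_G, self.M_S, self.M_V], dtype=np.int64
        )

    def update_from(self, arr: np.ndarray) -> None:
        self.M_A, self.M_B, self.M_G, self.M_S, self.M_V = (
            int(x) for x in arr
        )


@dataclass
class SystemState:
    """Whole-system state: patches, medium, and the cycle clock."""

    patches: list[PatchState] = field(default_factory=list)
    medium: MediumState = field(default_factory=MediumState)
    cycle: int = 0
    treatment: str = "together"

    def time(self, params: MetapopParams) -> float:
        return self.cycle * params.cycle_length

    def to_arrays(self) -> "ArraySystem":
        n = len(self.patches)
        patches = np.zeros((n, STATE_LEN), dtype=np.int64)
        ages = np.zeros(n, dtype=np.int64)
        for i, p in enumerate(self.patches):
            patches[i] = p.to_array()
            ages[i] = p.age
        return ArraySystem(
            patches=patches,
            ages=ages,
            medium=self.medium.to_array(),
            cycle=self.cycle,
            treatment=self.treatment,
        )


@dataclass
class ArraySystem:
    """Packed-array view of the system used by long-running simulations."""

    patches: np.ndarray  # (n_patches, STATE_LEN) int64
    ages: np.ndarray  # (n_patches,) int64, cycles since creation
    medium: np.ndarray  # (5,) int64
    cycle: int = 0
    treatment: str = "together"

    @classmethod
    def empty(cls, treatment: str = "together") -> "ArraySystem":
        return cls(
            patches=np.zeros((0, STATE_LEN), dtype=np.int64),
            ages=np.zeros(0, dtype=np.int64),
            medium=np.zeros(5, dtype=np.int64),
            treatment=treatment,
        )

    def time(self, params: MetapopParams) -> float:
        return self.cycle * params.cycle_length

    def to_system(self) -> SystemState:
        medium = MediumState()
        medium.update_from(self.medium)
        return SystemState(
            patches=[
                PatchState.from_array(self.patches[i], int(self.ages[i]))
                for i in range(self.patches.shape[0])
            ],
            medium=medium,
            cycle=self.cycle,
            treatment=self.treatment,
        )

    def totals(self) -> dict[str, int]:
        """Aggregate counts over the medium and all patches."""
        cols = self.patches.sum(axis=0) if len(self.patches) else np.zeros(
            STATE_LEN, dtype=np.int64
        )
        m = self.medium
        return {
            "n_patches": int(self.patches.shape[0]),
            "M_A": int(m[0]), "M_B": int(m[1]), "M_G": int(m[2]),
            "M_S": int(m[3]), "M_V": int(m[4]),
            "A": int(cols[_A]), "B": int(cols[_B]),
            "G": int(cols[_G]), "S": int(cols[_S]),
            "I_GA": int(cols[_IGA]), "I_GB": int(cols[_IGB]),
            "I_SA": int(cols[_ISA]),
            "x_A": int(cols[_XA]), "x_B": int(cols[_XB]),
            "V": int(cols[_V]),
        }


@dataclass
class ProbeLayer:
    """Virtual-tracer layer threaded through a simulation.

    ``vrng`` is a dedicated stream so the real trajectory is bit-identical
    with and without the probe; ``spawning`` gates tracer creation (off
    during burn-in and the terminal buffer).
    """

    vrng: np.random.Generator
    spawning: bool = True


def new_patch(params: MetapopParams, resource: str = "both") -> PatchState:
    """Create an empty patch endowed with ``Y`` units of each listed resource."""
    y = int(params.Y)
    if resource == "both":
        return PatchState(x_A=y, x_B=y)
    if resource == "A":
        return PatchState(x_A=y, x_B=0)
    if resource == "B":
        return PatchState(x_A=0, x_B=y)
    raise ValueError(f"unknown resource endowment {resource!r}")


def _new_patch_rows(params: MetapopParams, treatment: str) -> np.ndarray:
    y = int(params.Y)
    if treatment == "together":
        rows = np.zeros((1, STATE_LEN), dtype=np.int64)
        rows[0, _XA] = rows[0, _XB] = y
        rows[0, _Y0A] = rows[0, _Y0B] = y
    elif treatment == "a_only":
        # diagnostic treatment: host B absent from the whole system
        rows = np.zeros((1, STATE_LEN), dtype=np.int64)
        rows[0, _XA] = rows[0, _Y0A] = y
    elif treatment == "apart":
        rows = np.zeros((2, STATE_LEN), dtype=np.int64)
        rows[0, _XA] = rows[0, _Y0A] = y
        rows[1, _XB] = rows[1, _Y0B] = y
    else:
        raise ValueError(f"unknown treatment {treatment!r}")
    return rows


def event_rates(
    patch: PatchState, medium: MediumState, params: MetapopParams
) -> pd.Series:
    """Instantaneous rates (per hour) of the 28 per-patch event channels."""
    out = np.empty(_kernels.N_CHANNELS)
    _kernels.compute_rates(
        patch.to_array(), medium.to_array(), params.to_array(), out
    )
    return pd.Series(out, index=list(CHANNEL_NAMES))


def step_patch(
    patch: PatchState,
    medium: MediumState,
    params: MetapopParams,
    horizon: float,
    rng: np.random.Generator,
    counters: np.ndarray | None = None,
    probe: ProbeLayer | None = None,
) -> None:
    """Advance one patch by ``horizon`` hours in place (medium too)."""
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    if counters is None:
        counters = np.zeros(N_COUNTERS, dtype=np.int64)
    s = patch.to_array()
    m = medium.to_array()
    if probe is None:
        _kernels.step_patch_kernel(
            s, m, params.to_array(), horizon, rng, counters,
            False, False, rng,
        )
    else:
        _kernels.step_patch_kernel(
            s, m, params.to_array(), horizon, rng, counters,
            True, probe.spawning, probe.vrng,
        )
    patch.update_from(s)
    medium.update_from(m)


def _thin(count: int, rate: float, dt: float, rng: np.random.Generator) -> int:
    """Binomial survival thinning with per-cycle survival exp(-rate*dt)."""
    if count == 0 or rate == 0:
        return int(count)
    return int(rng.binomial(count, np.exp(-rate * dt)))


def _cull_arrays(
    sys: ArraySystem, params: MetapopParams, rng: np.random.Generator
) -> None:
    """Cull exhausted patches, spilling occupants into the medium.

    A patch is culled when its remaining resource is below 5% of its
    starting endowment and five or fewer susceptible hosts remain.  Infected
    cells lyse on transfer, releasing Poisson bursts into the medium.
    """
    p = sys.patches
    if not len(p):
        return
    res = p[:, _XA] + p[:, _XB]
    y0 = p[:, _Y0A] + p[:, _Y0B]
    cull = (res < 0.05 * y0) & ((p[:, _A] + p[:, _B]) <= 5)
    if not cull.any():
        return
    culled = p[cull]
    m = sys.medium
    m[0] += culled[:, _A].sum()
    m[1] += culled[:, _B].sum()
    m[2] += culled[:, _G].sum()
    m[3] += culled[:, _S].sum()
    m[4] += culled[:, _V].sum()
    m[2] += rng.poisson(params.F_A, int(culled[:, _IGA].sum())).sum()
    m[2] += rng.poisson(params.F_B, int(culled[:, _IGB].sum())).sum()
    m[3] += rng.poisson(params.F_A, int(culled[:, _ISA].sum())).sum()
    sys.patches = p[~cull]
    sys.ages = sys.ages[~cull]


def _add_arrays(sys: ArraySystem, params: MetapopParams) -> None:
    if sys.cycle % int(params.chi) != 0:
        return
    rows = _new_patch_rows(params, sys.treatment)
    sys.patches = np.concatenate([sys.patches, rows], axis=0)
    sys.ages = np.concatenate(
        [sys.ages, np.zeros(len(rows), dtype=np.int64)]
    )


def _cycle_arrays(
    sys: ArraySystem,
    params: MetapopParams,
    params_arr: np.ndarray,
    rng: np.random.Generator,
    counters: np.ndarray,
    probe: ProbeLayer | None,
) -> None:
    """One full cycle on the packed representation (in place)."""
    dt = params.cycle_length
    order = rng.permutation(sys.patches.shape[0]).astype(np.int64)
    if len(order):
        if probe is None:
            _kernels.cycle_kernel(
                sys.patches, order, sys.medium, params_arr, dt, rng,
                counters, False, False, rng,
            )
        else:
            _kernels.cycle_kernel(
                sys.patches, order, sys.medium, params_arr, dt, rng,
                counters, True, probe.spawning, probe.vrng,
            )
        sys.ages += 1
    m = sys.medium
    m[0] = _thin(m[0], params.lam_h, dt, rng)
    m[1] = _thin(m[1], params.lam_h, dt, rng)
    m[2] = _thin(m[2], params.lam_p, dt, rng)
    m[3] = _thin(m[3], params.lam_p, dt, rng)
    if probe is not None:
        m[4] = _thin(m[4], params.lam_p, dt, probe.vrng)
    _cull_arrays(sys, params, rng)
    sys.cycle += 1
    _add_arrays(sys, params)


def cull_patches(
    system: SystemState,
    params: MetapopParams,
    rng: np.random.Generator,
) -> SystemState:
    """Cull exhausted patches of a :class:`SystemState` (see `_cull_arrays`)."""
    sys = system.to_arrays()
    _cull_arrays(sys, params, rng)
    refreshed = sys.to_system()
    system.patches = refreshed.patches
    system.medium = refreshed.medium
    return system


def add_patches(
    system: SystemState, params: MetapopParams, treatment: str | None = None
) -> SystemState:
    """Add scheduled patches when the cycle counter hits the period chi."""
    treatment = treatment or system.treatment
    if system.cycle % int(params.chi) != 0:
        return system
    if treatment == "together":
        system.patches.append(new_patch(params, "both"))
    elif treatment == "a_only":
        system.patches.append(new_patch(params, "A"))
    elif treatment == "apart":
        system.patches.append(new_patch(params, "A"))
        system.patches.append(new_patch(params, "B"))
    else:
        raise ValueError(f"unknown treatment {treatment!r}")
    return system


def run_cycle(
    system: SystemState,
    params: MetapopParams,
    rng: np.random.Generator,
    counters: np.ndarray | None = None,
    probe: ProbeLayer | None = None,
) -> SystemState:
    """Advance the system by one cycle.

    Sequence: internal patch dynamics (random order), once-per-cycle decay
    of medium populations, culling of exhausted patches, the cycle-counter
    increment, and scheduled patch additions.
    """
    if counters is None:
        counters = np.zeros(N_COUNTERS, dtype=np.int64)
    sys = system.to_arrays()
    _cycle_arrays(sys, params, params.to_array(), rng, counters, probe)
    refreshed = sys.to_system()
    system.patches = refreshed.patches
    system.medium = refreshed.medium
    system.cycle = sys.cycle
    return system


def run_simulation(
    params: MetapopParams,
    treatment: str,
    duration: float,
    initial: MediumState,
    rng: np.random.Generator,
    recorders: Sequence[Callable[[ArraySystem], None]] | None = None,
    per_cycle: Callable[[ArraySystem, np.random.Generator], None] | None = None,
    record_every: int = 1,
    counters: np.ndarray | None = None,
    probe: ProbeLayer | None = None,
    probe_spawn_window: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Run the metapopulation for ``duration`` hours and record totals.

    Parameters
    ----------
    initial : MediumState
        Starting medium populations (patches start empty; the first patches
        appear at cycle 0).
    per_cycle : callable, optional
        Hook invoked with the live :class:`ArraySystem` after every cycle
        (used for trickle migration).
    record_every : int
        Record aggregate totals every this many cycles.
    probe, probe_spawn_window : optional
        Virtual-tracer layer and the (start, stop) times in hours between
        which tracers may be spawned.

    Returns a DataFrame of per-record medium and patch-aggregated counts;
    ``df.attrs`` carries the event counters and the final
    :class:`SystemState`.
    """
    if duration < 0:
        raise ValueError("duration must be non-negative")
    n_cycles = int(round(duration / params.cycle_length))
    sys = ArraySystem.empty(treatment)
    sys.medium[:] = initial.to_array()
    _add_arrays(sys, params)  # schedule starts at cycle 0
    if counters is None:
        counters = np.zeros(N_COUNTERS, dtype=np.int64)
    params_arr = params.to_array()
    records = []

    def record() -> None:
        row = {"cycle": sys.cycle, "time": sys.time(params)}
        row.update(sys.totals())
        records.append(row)
        if recorders:
            for fn in recorders:
                fn(sys)

    record()
    for _ in range(n_cycles):
        if probe is not None and probe_spawn_window is not None:
            t = sys.time(params)
            probe.spawning = probe_spawn_window[0] <= t < probe_spawn_window[1]
        _cycle_arrays(sys, params, params_arr, rng, counters, probe)
        if per_cycle is not None:
            per_cycle(sys, rng)
        if sys.cycle % record_every == 0:
            record()
    df = pd.DataFrame.from_records(records)
    df.attrs["counters"] = counters
    df.attrs["final_state"] = sys.to_system()
    return df
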