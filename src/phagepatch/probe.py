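"""Virtual-particle estimation of the opportunity cost P(A|B).

P(A|B) is the probability that a phage which has just contacted a host-B
individual would, if it declined to infect it, go on to contact a host-A
individual before decaying.  It measures the expected value a generalist
forgoes by infecting the worse host, integrating the spatial and temporal
correlation of the two hosts with the phage's dispersal and lifespan.

The measurement runs a specialist-only system (so real dynamics carry no
generalists) and spawns a non-interacting "virtual" tracer particle at
every specialist–host-B contact.  Tracers diffuse out of patches, re-enter
them from the medium, and decay exactly like real phage, but never infect;
a tracer is absorbed as a success the moment it contacts a host-A
individual.  Tracers draw all their randomness from a dedicated RNG
stream, so the real trajectory is bit-identical to a probe-free run with
the same seed.  Spawning is disabled during a burn-in phase and a terminal
buffer, the latter leaving time for the last tracers' fates to resolve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from ._kernels import CNT_V_CREATED, CNT_V_SUCCEEDED, N_COUNTERS
from .metapop import MediumState, ProbeLayer, run_simulation
from .params import MetapopParams
from .pipeline import HOURS_PER_YEAR

__all__ = ["ProbeConfig", "ProbeResult", "run_probe", "regress_rstar_on_cost"]


@dataclass(frozen=True)
class ProbeConfig:
    """Timing and replication of the opportunity-cost measurement."""

    total_years: float = 20.0
    burn_in_years: float = 5.0
    terminal_buffer_years: float = 5.0
    min_replicates: int = 30
    init_count: int = 100_000

    def __post_init__(self) -> None:
        if self.burn_in_years + self.terminal_buffer_years >= self.total_years:
            raise ValueError(
                "burn-in plus terminal buffer must leave a spawning window"
            )


@dataclass
class ProbeResult:
    """Aggregate tracer fates across replicates."""

    created: int
    succeeded: int
    p_a_given_b: float
    per_replicate: list[float]


def run_probe(
    params: MetapopParams,
    config: ProbeConfig,
    rng: np.random.Generator,
    treatment: str = "together",
) -> ProbeResult:
    """Estimate P(A|B) for one parameter set.

    Averages the per-replicate success fraction over ``min_replicates``
    specialist-only simulations.  Tracers still airborne at the end of a
    replicate count as failures (the terminal buffer keeps them rare).
    """
    total_h = config.total_years * HOURS_PER_YEAR
    window = (
        config.burn_in_years * HOURS_PER_YEAR,
        total_h - config.terminal_buffer_years * HOURS_PER_YEAR,
    )
    created = succeeded = 0
    per_replicate = []
    for _ in range(config.min_replicates):
        counters = np.zeros(N_COUNTERS, dtype=np.int64)
        probe = ProbeLayer(
            vrng=np.random.default_rng(rng.integers(2**31)), spawning=False
        )
        init = MediumState(
            M_A=config.init_count,
            M_B=config.init_count,
            M_S=config.init_count,
        )
        run_simulation(
            params, treatment, total_h, init, rng,
            record_every=10**9, counters=counters,
            probe=probe, probe_spawn_window=window,
        )
        c = int(counters[CNT_V_CREATED])
        s = int(counters[CNT_V_SUCCEEDED])
        created += c
        succeeded += s
        if c > 0:
            per_replicate.append(s / c)
    if created == 0:
        raise ZeroDivisionError(
            "no virtual particles were created: the specialist never "
            "contacted host B during the spawning window"
        )
    return ProbeResult(
        created=created,
        succeeded=succeeded,
        p_a_given_b=float(np.mean(per_replicate)),
        per_replicate=per_replicate,
    )


def regress_rstar_on_cost(
    pairs: list[tuple[float, float]],
) -> tuple[float, float, float]:
    """OLS regression of inferred R* on measured P(A|B).

    ``pairs`` holds (p_a_given_b, r_star) per parameter set; returns
    (slope, intercept, R^2).
    """
    if len(pairs) < 3:
        raise ValueError("need at least 3 (P(A|B), R*) pairs")
    x = np.array([p[0] for p in pairs])
    y = np.array([p[1] for p in pairs])
    if np.ptp(x) == 0:
        raise ValueError("P(A|B) values have zero variance")
    fit = stats.linregress(x, y)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue**2)
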