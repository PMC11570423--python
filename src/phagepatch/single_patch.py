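"""Individual-based simulation of phage fate inside one mixed host patch.

Each trial follows a single phage particle until its fate is decided: it
leaves the aggregation (fitness 1), decays (fitness 0), or infects a host.
An infection is worth the host's burst size F if the infected cell drifts
out of the patch before lysing, which happens with probability ``1 - omega``.
With probability ``omega`` the cell bursts inside the patch, and the
infecting phage is credited with ``F`` times the expected reproductive
success of one progeny particle, where secondary infections are valued at
the expected burst size of the host contacted (a single closed-form level of
recursion, which keeps trial variance low without biasing the mean).

Specialists treat contacts with host B as non-events, so their fates are
drawn from the renormalized distribution over {exit, decay, contact-A}.

Patch-to-patch variation in host composition is modeled by drawing the
realized host-A fraction for each block of trials from
``Binomial(n_eff, p) / n_eff``, emulating sampling noise in small
aggregations of effective size ``n_eff``.

The breakeven quality ratio R* is inferred exactly as one would from
simulated fitness curves: generalist fitness is an affine function of F_B,
specialist fitness is flat, and the lines' intersection F_B* gives
``R* = (F_B* - 1) / (F_A - 1)``.  Uncertainty comes from a within-grid-point
bootstrap with a swapping pass for the rare resamples whose fitted lines
fail to intersect.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .analytic import InvalidParametersError, PatchRates

__all__ = [
    "SinglePatchConfig",
    "FitnessEstimate",
    "RStarEstimate",
    "InferenceFailureError",
    "sample_fate",
    "estimate_fitness",
    "simulate_trials",
    "infer_r_star",
    "bootstrap_r_star",
]

_STRATEGIES = ("generalist", "specialist")


class InferenceFailureError(RuntimeError):
    """Raised when the fitted fitness lines cannot produce a breakeven point."""


@dataclass(frozen=True)
class SinglePatchConfig:
    """Monte-Carlo configuration for single-patch fitness estimation.

    Parameters
    ----------
    rates : PatchRates
        Within-patch rates; ``rates.F_B`` is the burst size on host B used
        by :func:`estimate_fitness` (the R* grid overrides it per point).
    omega : float
        Probability that an infected host bursts inside the patch.
    n_eff : int or None
        Effective patch size for binomial draws of the host-A fraction;
        ``None`` keeps ``p`` fixed at its nominal value.
    n_trials : int
        Monte-Carlo trials per fitness estimate (per grid point).
    seed : int or None
        Seed for the trial RNG; the bootstrap uses an independent stream
        spawned from the same seed.
    block_size : int
        Trials sharing one binomial draw of the host fraction.
    """

    rates: PatchRates
    omega: float = 0.0
    n_eff: int | None = None
    n_trials: int = 100_000
    seed: int | None = None
    block_size: int = 1000

    def __post_init__(self) -> None:
        if not 0.0 <= self.omega <= 1.0:
            raise InvalidParametersError("omega must lie in [0, 1]")
        if self.n_trials < 1:
            raise InvalidParametersError("n_trials must be >= 1")
        if self.n_eff is not None and self.n_eff < 1:
            raise InvalidParametersError("n_eff must be >= 1 when present")
        if self.block_size < 1:
            raise InvalidParametersError("block_size must be >= 1")


@dataclass(frozen=True)
class FitnessEstimate:
    """Mean per-virion reproductive success with its standard error."""

    mean: float
    se: float
    n: int


@dataclass(frozen=True)
class RStarEstimate:
    """Inferred breakeven ratio R* with bootstrap uncertainty.

    ``swap_fraction`` is the fraction of bootstrap resamples that initially
    produced non-intersecting lines and were re-drawn by the swapping pass.
    ``fb_star`` is the breakeven burst size of host B (the crossing of the
    two fitted fitness lines) from which ``point`` is derived.
    """

    point: float
    ci_low: float
    ci_high: float
    n_boot: int
    swap_fraction: float
    fb_star: float = float("nan")
    diagnostics: dict = field(default_factory=dict)


def _fate_table(
    rates: PatchRates, strategy: str, omega: float, p_hat: float
) -> tuple[np.ndarray, np.ndarray]:
    """Outcome values and probabilities for one trial at realized fraction p_hat.

    Outcomes are (exit, decay, infect-A outside, infect-A inside,
    infect-B outside, infect-B inside); the B entries have probability zero
    for specialists.
    """
    th, a, lm = rates.theta, rates.alpha, rates.lam
    fa, fb = rates.F_A, rates.F_B
    if strategy == "generalist":
        denom = a + th + lm
        p_contact_a = th * p_hat / denom if denom > 0 else 0.0
        p_contact_b = th * (1.0 - p_hat) / denom if denom > 0 else 0.0
        # expected success of one progeny particle, secondary infections
        # valued at the expected burst size of the host contacted
        progeny = (a + th * (p_hat * fa + (1.0 - p_hat) * fb)) / denom
    elif strategy == "specialist":
        denom = a + th * p_hat + lm
        p_contact_a = th * p_hat / denom if denom > 0 else 0.0
        p_contact_b = 0.0
        progeny = (a + th * p_hat * fa) / denom if denom > 0 else 0.0
    else:
        raise ValueError(f"unknown strategy {strategy!r}")
    if denom <= 0:
        raise InvalidParametersError(
            f"all fate rates vanish for the {strategy} at p_hat={p_hat}"
        )
    probs = np.array(
        [
            a / denom,
            lm / denom,
            p_contact_a * (1.0 - omega),
            p_contact_a * omega,
            p_contact_b * (1.0 - omega),
            p_contact_b * omega,
        ]
    )
    values = np.array([1.0, 0.0, fa, fa * progeny, fb, fb * progeny])
    return values, probs


def sample_fate(
    config: SinglePatchConfig, strategy: str, rng: np.random.Generator
) -> float:
    """Draw the fitness outcome of a single phage trial."""
    if config.n_eff is not None:
        p_hat = rng.binomial(config.n_eff, config.rates.p) / config.n_eff
    else:
        p_hat = config.rates.p
    values, probs = _fate_table(config.rates, strategy, config.omega, p_hat)
    return float(values[rng.choice(len(values), p=probs)])


def _counts_table(
    config: SinglePatchConfig, strategy: str, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """All trials compressed to (distinct outcome values, their counts).

    Trials are exchangeable, so multinomial draws of outcome counts are an
    exact, allocation-free equivalent of trial-by-trial sampling.
    """
    n = config.n_trials
    tally: dict[float, int] = {}
    if config.n_eff is None:
        values, probs = _fate_table(
            config.rates, strategy, config.omega, config.rates.p
        )
        counts = rng.multinomial(n, probs)
        for v, c in zip(values, counts):
            if c:
                tally[float(v)] = tally.get(float(v), 0) + int(c)
    else:
        done = 0
        while done < n:
            block = min(config.block_size, n - done)
            p_hat = rng.binomial(config.n_eff, config.rates.p) / config.n_eff
            values, probs = _fate_table(
                config.rates, strategy, config.omega, p_hat
            )
            counts = rng.multinomial(block, probs)
            for v, c in zip(values, counts):
                if c:
                    tally[float(v)] = tally.get(float(v), 0) + int(c)
            done += block
    vals = np.fromiter(tally.keys(), dtype=float, count=len(tally))
    cnts = np.fromiter(tally.values(), dtype=np.int64, count=len(tally))
    order = np.argsort(vals)
    return vals[order], cnts[order]


def simulate_trials(
    config: SinglePatchConfig, strategy: str, rng: np.random.Generator
) -> np.ndarray:
    """Simulate ``config.n_trials`` independent fate draws (expanded array)."""
    vals, cnts = _counts_table(config, strategy, rng)
    return np.repeat(vals, cnts)


def _summarize(vals: np.ndarray, cnts: np.ndarray) -> FitnessEstimate:
    n = int(cnts.sum())
    mean = float(np.dot(vals, cnts) / n)
    var = float(np.dot((vals - mean) ** 2, cnts) / n)
    se = float(np.sqrt(var / n))
    return FitnessEstimate(mean=mean, se=se, n=n)


def estimate_fitness(
    config: SinglePatchConfig,
    strategy: str,
    rng: np.random.Generator | None = None,
) -> FitnessEstimate:
    """Monte-Carlo estimate of per-virion reproductive success.

    At ``omega = 0`` the mean is an unbiased estimator of the closed-form
    generalist/specialist fitness.
    """
    if strategy not in _STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    vals, cnts = _counts_table(config, strategy, rng)
    return _summarize(vals, cnts)


def _fit_lines(
    fb_grid: np.ndarray, gen_means: np.ndarray, spec_flat: float
) -> tuple[float, float, float]:
    """OLS line through generalist means; returns (slope, intercept, fb_star)."""
    slope, intercept = np.polyfit(fb_grid, gen_means, 1)
    if slope <= 0:
        return float(slope), float(intercept), float("nan")
    return float(slope), float(intercept), float((spec_flat - intercept) / slope)


def _resample_mean(
    vals: np.ndarray, cnts: np.ndarray, rng: np.random.Generator
) -> float:
    n = int(cnts.sum())
    boot_counts = rng.multinomial(n, cnts / n)
    return float(np.dot(vals, boot_counts) / n)


def bootstrap_r_star(
    fb_grid: Sequence[float],
    gen_tables: Sequence[tuple[np.ndarray, np.ndarray]],
    spec_tables: Sequence[tuple[np.ndarray, np.ndarray]],
    n_A: float,
    n_boot: int,
    rng: np.random.Generator,
    max_failure_frac: float = 0.01,
    max_swap_attempts: int = 200,
) -> tuple[np.ndarray, float]:
    """Bootstrap distribution of R* from per-grid-point trial tables.

    Each replicate resamples trials with replacement within every grid point
    (for both strategies), refits the two lines and records the implied R*.
    Replicates whose generalist line has non-positive slope do not intersect
    the flat specialist line; when such failures are no more than
    ``max_failure_frac`` of replicates, each failed replicate is re-paired
    with freshly drawn resamples until the fit succeeds (the swapping pass).
    More frequent failures raise :class:`InferenceFailureError`.

    Returns the array of bootstrap R* values and the fraction of replicates
    that needed swapping.
    """
    fb = np.asarray(fb_grid, dtype=float)

    def one_replicate() -> float:
        gmeans = np.array([_resample_mean(v, c, rng) for v, c in gen_tables])
        smeans = np.array([_resample_mean(v, c, rng) for v, c in spec_tables])
        slope, _, fb_star = _fit_lines(fb, gmeans, float(smeans.mean()))
        if not np.isfinite(fb_star):
            return float("nan")
        return (fb_star - 1.0) / n_A

    draws = np.array([one_replicate() for _ in range(n_boot)])
    failed = np.flatnonzero(~np.isfinite(draws))
    swap_fraction = len(failed) / n_boot
    if swap_fraction > max_failure_frac:
        raise InferenceFailureError(
            f"{len(failed)}/{n_boot} bootstrap resamples produced "
            "non-intersecting fitness lines; increase n_trials or widen "
            "the F_B grid"
        )
    for i in failed:
        for _ in range(max_swap_attempts):
            value = one_replicate()
            if np.isfinite(value):
                draws[i] = value
                break
        else:
            raise InferenceFailureError(
                "swapping pass could not repair a non-intersecting "
                "bootstrap resample; increase n_trials"
            )
    return draws, swap_fraction


def infer_r_star(
    config: SinglePatchConfig,
    fb_grid: Sequence[float],
    n_boot: int = 1000,
) -> RStarEstimate:
    """Infer R* from simulated fitness curves over a grid of F_B values.

    Generalist fitness is simulated at every ``F_B`` in ``fb_grid``;
    specialist fitness (independent of F_B) is simulated once per grid point
    and fitted as a flat line.  The crossing F_B* of the generalist OLS line
    with the specialist level is converted to ``R* = (F_B* - 1)/(F_A - 1)``.
    If the observed fitness difference never changes sign over the grid, the
    grid is extended upward once before giving up.
    """
    rates = config.rates
    if rates.n_A <= 0:
        raise InvalidParametersError("R* inference requires F_A > 1")
    fb = np.asarray(sorted(fb_grid), dtype=float)
    if len(fb) < 3:
        raise ValueError("fb_grid needs at least 3 points")
    seq = np.random.SeedSequence(config.seed)
    trial_seed, boot_seed = seq.spawn(2)
    rng = np.random.default_rng(trial_seed)

    def simulate_grid(grid: np.ndarray):
        gen_tables, spec_tables = [], []
        for f_b in grid:
            cfg = replace(config, rates=replace(rates, F_B=float(f_b)))
            gen_tables.append(_counts_table(cfg, "generalist", rng))
            spec_tables.append(_counts_table(cfg, "specialist", rng))
        return gen_tables, spec_tables

    gen_tables, spec_tables = simulate_grid(fb)

    def sign_change(gt, st) -> bool:
        diffs = np.array(
            [
                _summarize(*g).mean - _summarize(*s).mean
                for g, s in zip(gt, st)
            ]
        )
        return bool(diffs.min() < 0 < diffs.max())

    if not sign_change(gen_tables, spec_tables):
        # one automatic upward extension of the grid before erroring
        step = fb[-1] - fb[-2] if len(fb) > 1 else max(fb[-1], 1.0)
        extra = fb[-1] + step * np.arange(1, 5)
        egen, espec = simulate_grid(extra)
        fb = np.concatenate([fb, extra])
        gen_tables += egen
        spec_tables += espec

    gen_summaries = [_summarize(v, c) for v, c in gen_tables]
    spec_summaries = [_summarize(v, c) for v, c in spec_tables]
    gmeans = np.array([s.mean for s in gen_summaries])
    smeans = np.array([s.mean for s in spec_summaries])
    spec_flat = float(smeans.mean())
    slope, intercept, fb_star = _fit_lines(fb, gmeans, spec_flat)
    if not np.isfinite(fb_star):
        raise InferenceFailureError(
            "generalist fitness line has non-positive slope "
            f"({slope:.4g}); no breakeven point exists on the grid "
            f"[{fb[0]}, {fb[-1]}]"
        )
    point = (fb_star - 1.0) / rates.n_A

    boot_rng = np.random.default_rng(boot_seed)
    draws, swap_fraction = bootstrap_r_star(
        fb, gen_tables, spec_tables, rates.n_A, n_boot, boot_rng
    )
    lo, hi = np.percentile(draws, [2.5, 97.5])
    return RStarEstimate(
        point=float(point),
        ci_low=float(min(lo, point)),
        ci_high=float(max(hi, point)),
        n_boot=n_boot,
        swap_fraction=float(swap_fraction),
        fb_star=float(fb_star),
        diagnostics={
            "slope": slope,
            "intercept": intercept,
            "specialist_level": spec_flat,
            "fb_grid": fb.tolist(),
            "generalist_means": gmeans.tolist(),
            "generalist_ses": [s.se for s in gen_summaries],
            "specialist_means": smeans.tolist(),
            "specialist_ses": [s.se for s in spec_summaries],
        },
    )
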