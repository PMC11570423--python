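"""Parameter sampling, suitability screening, competition experiments and
metapopulation R* inference.

The workflow mirrors how one studies host-range selection in the patch
metapopulation:

1. draw candidate parameter sets log-uniformly over broad ranges
   (:func:`sample_parameter_set`);
2. keep only sets whose generalist-only dynamics are large and stable over
   a randomized sweep of host-B quality (:func:`screen_suitability`);
3. for a suitable set, compete generalists against specialists under
   trickle migration across a grid of ``F_B`` values
   (:func:`competition_experiment`);
4. fit a generalized sigmoid to specialist frequency versus ``F_B`` and
   convert its midpoint to the breakeven quality ratio
   ``R* = (F_B^mid - 1)/(F_A - 1)`` (:func:`fit_sigmoid`,
   :func:`infer_r_star_metapop`), applying the exclusion heuristics for
   host-B extinction, poor host-B utilization, and migration-dominated
   (flat) frequency profiles.

Durations, abundance thresholds and replicate counts are plain fields of
the config dataclasses: published-scale values are the defaults, and
reduced-scale studies simply pass smaller ones.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import OptimizeWarning, curve_fit

from .metapop import ArraySystem, MediumState, run_simulation
from .params import MetapopParams

__all__ = [
    "ParameterRanges",
    "SuitabilityCriteria",
    "SuitabilityVerdict",
    "CompetitionConfig",
    "CompetitionResult",
    "SigmoidFit",
    "RStarResult",
    "SigmoidFitError",
    "sample_parameter_set",
    "screen_suitability",
    "competition_experiment",
    "fit_sigmoid",
    "infer_r_star_metapop",
    "utilization_ratio",
]

HOURS_PER_YEAR = 8766.0


class SigmoidFitError(RuntimeError):
    """Raised when the specialist-frequency sigmoid cannot be fitted."""


@dataclass(frozen=True)
class ParameterRanges:
    """Log-uniform sampling intervals for the nine varied rate parameters.

    Defaults span roughly three orders of magnitude around rates that give
    patch lifetimes of days to weeks; ``chi`` is rounded to whole cycles.
    """

    v: tuple[float, float] = (1e-5, 1e-2)
    r_A: tuple[float, float] = (0.01, 1.0)
    r_B: tuple[float, float] = (0.01, 1.0)
    phi: tuple[float, float] = (1e-5, 1e-2)
    alpha: tuple[float, float] = (1e-3, 1.0)
    lam_p: tuple[float, float] = (1e-4, 1e-1)
    lam_h: tuple[float, float] = (1e-4, 1e-1)
    theta: tuple[float, float] = (1e-5, 1e-2)
    chi: tuple[float, float] = (3.0, 3000.0)

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            low, high = getattr(self, name)
            if not (0 < low < high):
                raise ValueError(
                    f"range for {name!r} must satisfy 0 < low < high"
                )


def sample_parameter_set(
    ranges: ParameterRanges,
    rng: np.random.Generator,
    base: MetapopParams | None = None,
) -> MetapopParams:
    """Draw one parameter set: varied rates log-uniform, the rest defaults."""
    base = base or MetapopParams()
    draws = {}
    for name in ranges.__dataclass_fields__:
        low, high = getattr(ranges, name)
        value = float(np.exp(rng.uniform(np.log(low), np.log(high))))
        draws[name] = max(1, int(round(value))) if name == "chi" else value
    return base.replace(**draws)


@dataclass(frozen=True)
class SuitabilityCriteria:
    """Heuristic thresholds for accepting a parameter set.

    Published-scale defaults: mean abundance of each host and of the phage
    above ``min_mean``, pointwise ensemble minima above ``min_floor``, and
    the OLS trend of each mean trajectory, accumulated over the whole
    measurement window, below ``max_slope_frac`` of the window mean.
    ``max_patches`` bounds runaway patch accumulation (a practical guard on
    simulation size, counted as instability).
    """

    min_mean: float = 10_000.0
    min_floor: float = 5_000.0
    max_slope_frac: float = 0.005
    burn_in_years: float = 5.0
    measure_years: float = 5.0
    n_fb_draws: int = 20
    fb_range: tuple[float, float] = (0.0, 25.0)
    init_count: int = 100_000
    max_patches: int = 100_000


@dataclass
class SuitabilityVerdict:
    """Outcome of screening with per-criterion detail."""

    suitable: bool
    cause: str
    means: dict[str, float] = field(default_factory=dict)
    floors: dict[str, float] = field(default_factory=dict)
    slope_fracs: dict[str, float] = field(default_factory=dict)
    n_replicates: int = 0


_CLASSES = ("hostA", "hostB", "phage")


def _class_series(df: pd.DataFrame) -> dict[str, pd.Series]:
    """Abundance of each host and of the (generalist) phage over time.

    Hosts count planktonic plus attached uninfected cells; phage count free
    particles in medium and patches (infected cells are neither).
    """
    return {
        "hostA": df["M_A"] + df["A"],
        "hostB": df["M_B"] + df["B"],
        "phage": df["M_G"] + df["G"] + df["M_S"] + df["S"],
    }


def screen_suitability(
    params: MetapopParams,
    criteria: SuitabilityCriteria,
    rng: np.random.Generator,
    treatment: str = "together",
) -> SuitabilityVerdict:
    """Run the generalist-only ensemble and apply the suitability criteria.

    One replicate is run per random ``F_B`` draw (``n_fb_draws`` total),
    starting from ``init_count`` of each host and the generalist phage.
    Extinction of the phage, or of both hosts, in any replicate fails the
    set outright.
    """
    burn = criteria.burn_in_years * HOURS_PER_YEAR
    total = burn + criteria.measure_years * HOURS_PER_YEAR
    ensemble = []
    for _ in range(criteria.n_fb_draws):
        f_b = float(rng.uniform(*criteria.fb_range))
        p = params.replace(F_B=f_b)
        init = MediumState(
            M_A=criteria.init_count,
            M_B=criteria.init_count,
            M_G=criteria.init_count,
        )
        guard = _PatchGuard(criteria.max_patches)
        try:
            df = run_simulation(
                p, treatment, total, init, rng,
                per_cycle=guard, record_every=_record_stride(p),
            )
        except _PatchGuardTripped:
            return SuitabilityVerdict(
                False, "patch-count runaway", n_replicates=len(ensemble)
            )
        series = _class_series(df)
        final = {name: s.iloc[-1] for name, s in series.items()}
        if final["phage"] == 0:
            return SuitabilityVerdict(
                False, "phage extinction", n_replicates=len(ensemble)
            )
        if final["hostA"] == 0 and final["hostB"] == 0:
            return SuitabilityVerdict(
                False, "host extinction", n_replicates=len(ensemble)
            )
        window = df["time"] >= burn
        ensemble.append(
            pd.DataFrame(
                {name: s[window].to_numpy() for name, s in series.items()},
                index=df.loc[window, "time"],
            )
        )
    n_rows = min(len(e) for e in ensemble)
    stack = np.stack([e.iloc[:n_rows].to_numpy() for e in ensemble])
    times = ensemble[0].index.to_numpy()[:n_rows]
    mean_traj = stack.mean(axis=0)  # (time, class)
    means = dict(zip(_CLASSES, mean_traj.mean(axis=0)))
    floors = dict(zip(_CLASSES, stack.min(axis=(0, 1))))
    span = times[-1] - times[0]
    slope_fracs = {}
    for j, name in enumerate(_CLASSES):
        slope = np.polyfit(times, mean_traj[:, j], 1)[0]
        slope_fracs[name] = abs(slope) * span / max(means[name], 1e-12)

    if any(means[c] < criteria.min_mean for c in _CLASSES):
        cause = "mean abundance below threshold"
    elif any(floors[c] < criteria.min_floor for c in _CLASSES):
        cause = "ensemble floor below threshold"
    elif any(s > criteria.max_slope_frac for s in slope_fracs.values()):
        cause = "trend in mean abundance too steep"
    else:
        cause = "ok"
    return SuitabilityVerdict(
        suitable=cause == "ok",
        cause=cause,
        means=means,
        floors=floors,
        slope_fracs=slope_fracs,
        n_replicates=len(ensemble),
    )


class _PatchGuardTripped(RuntimeError):
    pass


class _PatchGuard:
    """Per-cycle hook aborting runs whose patch count explodes."""

    def __init__(self, max_patches: int):
        self.max_patches = max_patches

    def __call__(self, sys: ArraySystem, rng: np.random.Generator) -> None:
        if sys.patches.shape[0] > self.max_patches:
            raise _PatchGuardTripped()


def _record_stride(params: MetapopParams) -> int:
    """Record roughly every 8 hours to keep trajectory frames small."""
    return max(1, int(round(8.0 / params.cycle_length)))


@dataclass(frozen=True)
class CompetitionConfig:
    """Configuration of one generalist-versus-specialist competition run.

    Migration: after ``migration_start_years``, each cycle adds independent
    Poisson numbers of generalists and of specialists to the medium, both
    with mean ``migration_fraction`` times the current total number of
    phage in the medium.  The specialist share of all phage (medium plus
    patches) is averaged over the last ``average_last_years``.
    """

    migration_fraction: float = 2e-5
    migration_start_years: float = 5.0
    total_years: float = 100.0
    average_last_years: float = 90.0
    min_replicates: int = 25
    reduced_migration_factor: float = 0.2
    init_count: int = 100_000
    init_specialist_fraction: float = 0.0
    max_patches: int = 100_000

    def __post_init__(self) -> None:
        if self.total_years <= self.migration_start_years:
            raise ValueError("total_years must exceed migration_start_years")
        if self.average_last_years > self.total_years:
            raise ValueError("averaging window must fit inside the run")


@dataclass
class CompetitionResult:
    """Per-parameter-point competition outcome."""

    specialist_fraction: float
    replicate_fractions: list[float]
    n_replicates: int
    n_excluded_host_b: int
    host_b_extinct_majority: bool


def _migration_hook(fraction: float):
    def hook(sys: ArraySystem, rng: np.random.Generator) -> None:
        mean = fraction * (sys.medium[2] + sys.medium[3])
        if mean > 0:
            sys.medium[2] += rng.poisson(mean)
            sys.medium[3] += rng.poisson(mean)

    return hook


def competition_experiment(
    params: MetapopParams,
    f_b: float,
    config: CompetitionConfig,
    rng: np.random.Generator,
    treatment: str = "together",
    migration_fraction: float | None = None,
) -> CompetitionResult:
    """Compete the two phage strategies at one value of ``F_B``.

    Returns the replicate-averaged time-mean specialist fraction among all
    phage.  Replicates in which host B goes extinct are excluded and
    counted; if they are the majority the whole parameter point is flagged.
    """
    p = params.replace(F_B=float(f_b))
    fraction = (
        config.migration_fraction
        if migration_fraction is None
        else migration_fraction
    )
    burn_h = config.migration_start_years * HOURS_PER_YEAR
    total_h = config.total_years * HOURS_PER_YEAR
    window_h = config.average_last_years * HOURS_PER_YEAR
    stride = _record_stride(p)
    fractions: list[float] = []
    excluded = 0
    attempts = 0
    max_attempts = 3 * config.min_replicates
    while len(fractions) < config.min_replicates and attempts < max_attempts:
        attempts += 1
        init_s = int(round(config.init_count * config.init_specialist_fraction))
        init = MediumState(
            M_A=config.init_count,
            M_B=config.init_count,
            M_G=config.init_count - init_s,
            M_S=init_s,
        )
        hooks = _migration_hook(fraction)
        guard = _PatchGuard(config.max_patches)

        def per_cycle(sys: ArraySystem, r: np.random.Generator) -> None:
            guard(sys, r)
            if sys.time(p) >= burn_h:
                hooks(sys, r)

        df = run_simulation(
            p, treatment, total_h, init, rng,
            per_cycle=per_cycle, record_every=stride,
        )
        host_b = df["M_B"].iloc[-1] + df["B"].iloc[-1] + df["I_GB"].iloc[-1]
        if host_b == 0 and (df["M_B"] + df["B"]).max() > 0:
            excluded += 1
            continue
        window = df["time"] >= (total_h - window_h)
        spec = (df.loc[window, "M_S"] + df.loc[window, "S"]).to_numpy(float)
        gen = (df.loc[window, "M_G"] + df.loc[window, "G"]).to_numpy(float)
        tot = spec + gen
        valid = tot > 0
        if not valid.any():
            excluded += 1
            continue
        fractions.append(float((spec[valid] / tot[valid]).mean()))
    majority_extinct = excluded > len(fractions)
    mean_frac = float(np.mean(fractions)) if fractions else float("nan")
    return CompetitionResult(
        specialist_fraction=mean_frac,
        replicate_fractions=fractions,
        n_replicates=len(fractions),
        n_excluded_host_b=excluded,
        host_b_extinct_majority=majority_extinct,
    )


@dataclass
class SigmoidFit:
    """Generalized sigmoid ``y = a + f / (1 + exp(b*(x - c)))``."""

    a: float
    b: float
    c: float
    f: float
    midpoint: float


def _sigmoid(x: np.ndarray, a: float, b: float, c: float, f: float):
    return a + f / (1.0 + np.exp(np.clip(b * (x - c), -500, 500)))


def _midpoint(a: float, b: float, c: float, f: float) -> float:
    """Solve a + f/(1 + exp(b*(x-c))) = 0.5 for x."""
    if f == 0 or b == 0:
        return float("nan")
    ratio = f / (0.5 - a) - 1.0
    if ratio <= 0:
        return float("nan")
    return c + np.log(ratio) / b


def fit_sigmoid(
    points: list[tuple[float, float]],
    c_starts: list[float] | None = None,
    midpoint_spread_tol: float = 0.1,
) -> SigmoidFit:
    """Fit the generalized sigmoid to (F_B, specialist-fraction) points.

    Several starting values of the midpoint parameter ``c`` are tried;
    midpoints from successful fits are averaged when they agree to within
    ``midpoint_spread_tol`` times the F_B span, otherwise a
    :class:`SigmoidFitError` asks for more data.
    """
    pts = sorted(points)
    if len(pts) < 4:
        raise SigmoidFitError("need at least 4 (F_B, fraction) points")
    x = np.array([q[0] for q in pts])
    y = np.array([q[1] for q in pts])
    if float(np.ptp(y)) < 0.02:
        raise SigmoidFitError(
            "specialist fractions are flat across F_B (low signal); "
            "consider reduced migration"
        )
    if c_starts is None:
        c_starts = list(np.quantile(x, [0.25, 0.5, 0.75]))
    span = x.max() - x.min()
    fits: list[tuple[float, tuple[float, float, float, float]]] = []
    for c0 in c_starts:
        try:
            with warnings.catch_warnings():
                # 4-parameter fits to few points often have singular
                # covariance; only the point estimate is used here
                warnings.simplefilter("ignore", OptimizeWarning)
                popt, _ = curve_fit(
                    _sigmoid, x, y,
                    p0=[float(y.min()), 2.0 / max(span / 4, 1e-6), c0,
                        float(y.max() - y.min())],
                    maxfev=20_000,
                )
        except RuntimeError:
            continue
        mid = _midpoint(*popt)
        if np.isfinite(mid):
            fits.append((float(mid), tuple(float(v) for v in popt)))
    if not fits:
        raise SigmoidFitError("sigmoid fit failed from all starting values")
    mids = np.array([m for m, _ in fits])
    if np.ptp(mids) > midpoint_spread_tol * max(span, 1e-12):
        raise SigmoidFitError(
            f"inferred midpoints disagree across starts ({mids}); "
            "more data are required"
        )
    a, b, c, f = fits[int(np.argmin(np.abs(mids - mids.mean())))][1]
    return SigmoidFit(a=a, b=b, c=c, f=f, midpoint=float(mids.mean()))


@dataclass
class RStarResult:
    """Metapopulation R* inference with exclusion bookkeeping."""

    r_star: float | None
    fb_points: list[tuple[float, float, int]]
    exclusion_flags: list[str]
    fit: SigmoidFit | None
    ci_low: float | None = None
    ci_high: float | None = None
    utilization: float | None = None
    midpoint_outside_range: bool = False


def utilization_ratio(
    params: MetapopParams,
    rng: np.random.Generator,
    treatment: str = "together",
    burn_in_years: float = 5.0,
    measure_years: float = 5.0,
    init_count: int = 100_000,
    max_patches: int = 100_000,
) -> float:
    """How often the generalist infects host B relative to host A.

    Runs a generalist-only system and returns cumulative infections of B
    divided by cumulative infections of A over the measurement window.
    """
    burn_h = burn_in_years * HOURS_PER_YEAR
    total_h = burn_h + measure_years * HOURS_PER_YEAR
    init = MediumState(M_A=init_count, M_B=init_count, M_G=init_count)
    counters = np.zeros(7, dtype=np.int64)
    at_burn = {"inf_A": 0, "inf_B": 0, "done": False}

    def per_cycle(sys: ArraySystem, r: np.random.Generator) -> None:
        if sys.patches.shape[0] > max_patches:
            raise _PatchGuardTripped()
        if not at_burn["done"] and sys.time(params) >= burn_h:
            at_burn.update(inf_A=int(counters[0]), inf_B=int(counters[1]),
                           done=True)

    run_simulation(
        params, treatment, total_h, init, rng,
        per_cycle=per_cycle, record_every=_record_stride(params),
        counters=counters,
    )
    inf_a = int(counters[0]) - at_burn["inf_A"]
    inf_b = int(counters[1]) - at_burn["inf_B"]
    if inf_a == 0:
        raise ZeroDivisionError(
            "no host-A infections in the measurement window; "
            "utilization ratio undefined"
        )
    return inf_b / inf_a


def infer_r_star_metapop(
    params: MetapopParams,
    fb_sweep: list[float],
    config: CompetitionConfig,
    rng: np.random.Generator,
    treatment: str = "together",
    utilization_min: float = 0.02,
    check_utilization: bool = True,
    utilization_kwargs: dict | None = None,
    n_boot: int = 200,
) -> RStarResult:
    """Infer R* for one parameter set from a sweep of competition runs.

    Exclusion heuristics: (a) host-B extinction in the majority of
    replicates at any F_B point excludes the set; (b) generalist-only
    utilization of host B below ``utilization_min`` excludes it; (c) a flat
    frequency profile triggers one rerun at reduced migration before the
    set is excluded for low signal.  The bootstrap CI resamples replicate
    fractions within each F_B point and refits the sigmoid.
    """
    flags: list[str] = []
    util = None
    if check_utilization:
        util = utilization_ratio(
            params, rng, treatment, **(utilization_kwargs or {})
        )
        if util < utilization_min:
            return RStarResult(
                r_star=None, fb_points=[], fit=None,
                exclusion_flags=["low-utilization"], utilization=util,
            )

    def run_sweep(migration: float):
        results = []
        for f_b in fb_sweep:
            res = competition_experiment(
                params, f_b, config, rng, treatment,
                migration_fraction=migration,
            )
            if res.host_b_extinct_majority:
                return None, f_b
            results.append((f_b, res))
        return results, None

    migration = config.migration_fraction
    results, bad_fb = run_sweep(migration)
    if results is None:
        return RStarResult(
            r_star=None, fb_points=[], fit=None, utilization=util,
            exclusion_flags=[f"host-B-extinction (F_B={bad_fb})"],
        )
    points = [(f_b, r.specialist_fraction) for f_b, r in results]
    try:
        fit = fit_sigmoid(points)
    except SigmoidFitError:
        flags.append("low-signal: retried at reduced migration")
        migration *= config.reduced_migration_factor
        results, bad_fb = run_sweep(migration)
        if results is None:
            return RStarResult(
                r_star=None, fb_points=[], fit=None, utilization=util,
                exclusion_flags=flags
                + [f"host-B-extinction (F_B={bad_fb})"],
            )
        points = [(f_b, r.specialist_fraction) for f_b, r in results]
        try:
            fit = fit_sigmoid(points)
        except SigmoidFitError:
            return RStarResult(
                r_star=None,
                fb_points=[
                    (f_b, r.specialist_fraction, r.n_replicates)
                    for f_b, r in results
                ],
                fit=None, utilization=util,
                exclusion_flags=flags + ["low-signal"],
            )
    n_a = params.F_A - 1.0
    r_star = (fit.midpoint - 1.0) / n_a
    fb_lo = min(f for f, _ in points)
    fb_hi = max(f for f, _ in points)
    outside = not (fb_lo <= fit.midpoint <= fb_hi)

    # bootstrap over replicates within each F_B point
    boots = []
    for _ in range(n_boot):
        bpoints = []
        for f_b, r in results:
            reps = np.asarray(r.replicate_fractions)
            draw = rng.choice(reps, size=len(reps), replace=True)
            bpoints.append((f_b, float(draw.mean())))
        try:
            bfit = fit_sigmoid(bpoints)
        except SigmoidFitError:
            continue
        boots.append((bfit.midpoint - 1.0) / n_a)
    ci_low = ci_high = None
    if len(boots) >= max(20, n_boot // 2):
        ci_low, ci_high = (
            float(v) for v in np.percentile(boots, [2.5, 97.5])
        )
    return RStarResult(
        r_star=float(r_star),
        fb_points=[
            (f_b, r.specialist_fraction, r.n_replicates)
            for f_b, r in results
        ],
        exclusion_flags=flags,
        fit=fit,
        ci_low=ci_low,
        ci_high=ci_high,
        utilization=util,
        midpoint_outside_range=outside,
    )
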