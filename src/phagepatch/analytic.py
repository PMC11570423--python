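"""Closed-form within-patch fitness for generalist and specialist phage.

A phage particle inside a transient host aggregation ("patch") faces three
competing fates: it may exit the patch by diffusion (rate ``alpha``), decay
(rate ``lam``), or make an infectious contact with a host (rate ``theta``).
A fraction ``p`` of contacts are with host A, the better host; the rest are
with host B.  Infections are assumed to burst only after the aggregation has
dispersed, so progeny of an infection and phage that simply diffuse out are
treated alike: both enter the dilute medium between patches.

Under these assumptions the expected per-virion reproductive success of a
generalist (infects either host) is

    W_G = (theta*p*F_A + theta*(1-p)*F_B + alpha) / (alpha + theta + lam)

and of a host-A specialist, for whom contacts with B are non-events,

    W_S = (theta*p*F_A + alpha) / (alpha + theta*p + lam)

Setting W_G = W_S and writing net fecundities n = F - 1 (the parental virion
is destroyed by reproduction) gives the breakeven net fecundity of host B,

    n_B = (n_A*theta*p - lam) / (alpha + theta*p + lam)

and the breakeven quality ratio

    R* = n_B/n_A  ~=  theta*p / (alpha + theta*p + lam)

where the approximation drops ``lam`` from the numerator (valid when
``n_A*theta*p >> lam``).  R* close to one means a specialist is favored
unless host B is nearly as productive as host A.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "InvalidParametersError",
    "PatchRates",
    "fitness_generalist",
    "fitness_specialist",
    "breakeven_net_fecundity",
    "r_star",
]


class InvalidParametersError(ValueError):
    """Raised when patch rates violate the model's preconditions."""


@dataclass(frozen=True)
class PatchRates:
    """Within-patch rates and fecundities.

    Parameters
    ----------
    theta : float
        Per-capita infectious-contact rate (per hour).
    p : float
        Fraction of contacts that are with host A (dimensionless, in [0, 1]).
    alpha : float
        Patch-exit rate (per hour).
    lam : float
        Phage decay rate (per hour).
    F_A, F_B : float
        Mean fecundity (burst size, virions per infection) on hosts A and B.
        ``F_B`` is ignored by the breakeven operations, which solve for it.
    """

    theta: float
    p: float
    alpha: float
    lam: float
    F_A: float
    F_B: float = 0.0

    def __post_init__(self) -> None:
        if self.theta < 0 or self.alpha < 0 or self.lam < 0:
            raise InvalidParametersError(
                "rates theta, alpha, lam must be non-negative"
            )
        if not 0.0 <= self.p <= 1.0:
            raise InvalidParametersError("p must lie in [0, 1]")
        if self.F_A < 0 or self.F_B < 0:
            raise InvalidParametersError("fecundities must be non-negative")
        if self.alpha + self.theta * self.p + self.lam <= 0:
            raise InvalidParametersError(
                "alpha + theta*p + lam must be positive "
                "(specialist fate probabilities undefined otherwise)"
            )

    @property
    def n_A(self) -> float:
        """Net fecundity on host A (burst size minus the parental virion)."""
        return self.F_A - 1.0

    @property
    def n_B(self) -> float:
        """Net fecundity on host B."""
        return self.F_B - 1.0


def fitness_generalist(rates: PatchRates) -> float:
    """Expected reproductive success of a generalist phage in the patch.

    Weighted average over the particle's fate: exit (value 1), decay
    (value 0), infect A (value ``F_A``) or infect B (value ``F_B``).
    """
    denom = rates.alpha + rates.theta + rates.lam
    if denom <= 0:
        raise InvalidParametersError("alpha + theta + lam must be positive")
    num = (
        rates.theta * rates.p * rates.F_A
        + rates.theta * (1.0 - rates.p) * rates.F_B
        + rates.alpha
    )
    return num / denom


def fitness_specialist(rates: PatchRates) -> float:
    """Expected reproductive success of a host-A specialist.

    Contacts with host B are non-events: the F_B term drops from the
    numerator and the denominator shrinks to ``alpha + theta*p + lam``.
    """
    denom = rates.alpha + rates.theta * rates.p + rates.lam
    if denom <= 0:
        raise InvalidParametersError("alpha + theta*p + lam must be positive")
    return (rates.theta * rates.p * rates.F_A + rates.alpha) / denom


def breakeven_net_fecundity(rates: PatchRates) -> float:
    """Net fecundity of host B at which generalist and specialist tie.

    Solves ``fitness_generalist == fitness_specialist`` for ``F_B`` and
    returns ``n_B = F_B - 1``.  A negative value (possible when
    ``n_A*theta*p < lam``) means any host of positive net value should be
    accepted; it is returned unclamped.  ``rates.F_B`` is ignored.
    """
    denom = rates.alpha + rates.theta * rates.p + rates.lam
    if denom <= 0:
        raise InvalidParametersError("alpha + theta*p + lam must be positive")
    return (rates.n_A * rates.theta * rates.p - rates.lam) / denom


def r_star(rates: PatchRates, mode: str = "approximate") -> float:
    """Breakeven host-quality ratio ``R* = n_B / n_A``.

    Parameters
    ----------
    rates : PatchRates
        ``F_B`` is ignored.
    mode : {"approximate", "exact"}
        ``"approximate"`` returns ``theta*p / (alpha + theta*p + lam)``,
        which is independent of ``F_A`` and always in [0, 1).  ``"exact"``
        divides the exact breakeven net fecundity by ``n_A`` (requires
        ``n_A > 0``); it is never larger than the approximation and the two
        coincide as ``n_A*theta*p`` dwarfs ``lam``.
    """
    denom = rates.alpha + rates.theta * rates.p + rates.lam
    if denom <= 0:
        raise InvalidParametersError("alpha + theta*p + lam must be positive")
    if mode == "approximate":
        return rates.theta * rates.p / denom
    if mode == "exact":
        if rates.n_A <= 0:
            raise InvalidParametersError(
                "exact R* requires net fecundity n_A = F_A - 1 > 0"
            )
        return breakeven_net_fecundity(rates) / rates.n_A
    raise ValueError(f"unknown mode {mode!r}; use 'exact' or 'approximate'")
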