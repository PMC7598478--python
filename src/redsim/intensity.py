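"""Time-varying intensity (hazard) functions and inter-event-time samplers.

An intensity function :math:`\\lambda(t_\\Delta)` gives the instantaneous
probability rate that an agent fires after residence :math:`t_\\Delta`,
conditional on not having fired yet.  It encodes an inter-event time
distribution through the renewal relations

.. math::

    \\lambda(t) = \\frac{\\gamma(t)}{1 - \\int_0^t \\gamma}, \\qquad
    \\gamma(t) = \\lambda(t)\\, e^{-\\int_0^t \\lambda},

where :math:`\\gamma` is the probability density of the delay.  When the
cumulative hazard :math:`\\Lambda(\\infty)` is finite the delay law is
*defective*: with probability :math:`e^{-\\Lambda(\\infty)}` the agent never
fires, which we represent with the :data:`NO_FIRE` sentinel (``+inf``).

Three samplers are provided:

* inversion — draw a unit-rate exponential area ``x`` and solve
  :math:`\\Lambda(t) = x`;
* thinning — propose from a dominating constant rate ``c`` and accept a
  proposal at ``t`` with probability :math:`\\lambda(t)/c`;
* exponential mixture (Laplace–Gillespie) — for laws expressible as
  continuous mixtures of exponentials, draw a rate and then an
  exponential delay.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import integrate, optimize

__all__ = [
    "NO_FIRE",
    "IntensityFunction",
    "pdf_to_intensity",
    "intensity_to_pdf",
    "sample_inversion",
    "sample_thinning",
    "sample_exponential_mixture",
    "uniform_mixture_rate_sampler",
    "constant_hazard",
    "uniform_hazard",
    "exponential_decay_hazard",
    "sin_squared_hazard",
    "voter_hazard",
    "BoundViolationError",
    "NumericalError",
]

#: Sentinel for "the process never fires (within the horizon)".
NO_FIRE = math.inf


class BoundViolationError(RuntimeError):
    """The intensity exceeded its declared dominating bound."""


class NumericalError(RuntimeError):
    """Quadrature or root-finding failed to converge."""


@dataclass
class IntensityFunction:
    """A nonnegative hazard ``rate(t)`` for delays ``t >= 0``.

    Parameters
    ----------
    rate
        Pointwise evaluable hazard; must be nonnegative.
    cumulative
        Optional closed form for ``Lambda(t) = int_0^t rate``; a numeric
        piecewise quadrature is used otherwise.
    inverse_cumulative
        Optional closed form for the smallest ``t`` with ``Lambda(t) = x``.
    total_mass
        ``Lambda(inf)``; finite values make the delay law defective.
    support
        Time beyond which ``Lambda`` no longer increases toward the target
        (``inf`` for full-line hazards; e.g. ``2.0`` for the uniform[1,2]
        hazard whose cumulative diverges at 2).
    breakpoints
        Discontinuities of ``rate`` handed to the quadrature so no mass is
        missed (e.g. ``(1.0, 2.0)`` for the uniform[1,2] hazard).
    """

    rate: Callable[[float], float]
    cumulative: Optional[Callable[[float], float]] = None
    inverse_cumulative: Optional[Callable[[float], float]] = None
    total_mass: float = math.inf
    support: float = math.inf
    breakpoints: Sequence[float] = field(default_factory=tuple)
    name: str = ""

    def __call__(self, t: float) -> float:
        r = self.rate(t)
        if r < 0:
            raise ValueError(f"negative intensity {r!r} at t={t!r}")
        return r

    def cumulative_at(self, t: float) -> float:
        """Cumulative hazard ``Lambda(t)``, closed form or piecewise quadrature."""
        if t <= 0:
            return 0.0
        if self.cumulative is not None:
            return self.cumulative(t)
        return _piecewise_quad(self, 0.0, t)


def _piecewise_quad(intensity: IntensityFunction, a: float, b: float) -> float:
    """Integrate ``intensity.rate`` on [a, b], splitting at breakpoints."""
    if b <= a:
        return 0.0
    cuts = [a] + [p for p in sorted(intensity.breakpoints) if a < p < b] + [b]
    total = 0.0
    for lo, hi in zip(cuts[:-1], cuts[1:]):
        val, err = integrate.quad(intensity.rate, lo, hi, limit=200,
                                  epsabs=1e-9, epsrel=1e-9)
        if not math.isfinite(val):
            raise NumericalError(f"divergent hazard integral on [{lo}, {hi}]")
        if err > max(1e-6, 1e-6 * abs(val)):
            raise NumericalError(f"hazard quadrature did not converge on [{lo}, {hi}]")
        total += val
    return total


# ---------------------------------------------------------------------------
# Renewal-theory conversions
# ---------------------------------------------------------------------------

def pdf_to_intensity(pdf: Callable[[float], float],
                     breakpoints: Sequence[float] = ()) -> IntensityFunction:
    """Convert a delay density into its hazard via the renewal relation.

    ``rate(t) = pdf(t) / (1 - int_0^t pdf)``, with the convention that the
    hazard is zero wherever the survival denominator vanishes.  The survival
    integral is computed by adaptive quadrature; the returned cumulative
    hazard uses ``Lambda(t) = -ln(survival(t))``.
    """

    def survival(t: float) -> float:
        if t <= 0:
            return 1.0
        cuts = [0.0] + [p for p in sorted(breakpoints) if 0.0 < p < t] + [t]
        mass = 0.0
        for lo, hi in zip(cuts[:-1], cuts[1:]):
            val, _ = integrate.quad(pdf, lo, hi, limit=200, epsabs=1e-12, epsrel=1e-10)
            mass += val
        return max(0.0, 1.0 - mass)

    def rate(t: float) -> float:
        g = pdf(t)
        if g < 0:
            raise ValueError(f"negative density {g!r} at t={t!r}")
        s = survival(t)
        if s <= 0.0:
            return 0.0
        return g / s

    def cumulative(t: float) -> float:
        s = survival(t)
        if s <= 0.0:
            return math.inf
        return -math.log(s)

    return IntensityFunction(rate=rate, cumulative=cumulative,
                             breakpoints=tuple(breakpoints),
                             name="pdf_to_intensity")


def intensity_to_pdf(intensity: IntensityFunction) -> Callable[[float], float]:
    """Delay density ``gamma(t) = rate(t) * exp(-Lambda(t))``.

    If the total hazard mass is finite the returned density is defective and
    integrates to ``1 - exp(-total_mass) < 1``.
    """

    def pdf(t: float) -> float:
        if t < 0:
            return 0.0
        lam = intensity(t)
        if lam == 0.0:
            return 0.0
        return lam * math.exp(-intensity.cumulative_at(t))

    return pdf


# ---------------------------------------------------------------------------
# Samplers
# ---------------------------------------------------------------------------

def sample_inversion(intensity: IntensityFunction,
                     rng: Optional[np.random.Generator] = None,
                     x: Optional[float] = None) -> float:
    """Inversion sampling: solve ``Lambda(t) = x`` for a unit-exponential ``x``.

    ``x`` may be forced (deterministic worked examples); otherwise it is
    drawn from ``rng``.  Returns :data:`NO_FIRE` when ``x`` exceeds the total
    hazard mass.  Root-finding uses bisection/Brent with relative tolerance
    1e-9 on a bracket found by doubling (capped just below ``support`` where
    the cumulative diverges).
    """
    if x is None:
        if rng is None:
            raise ValueError("provide either rng or a forced x")
        x = rng.exponential()
    if x <= 0.0:
        return 0.0
    if x >= intensity.total_mass:
        return NO_FIRE
    if intensity.inverse_cumulative is not None:
        return intensity.inverse_cumulative(x)

    cum = intensity.cumulative_at

    # Bracket the root: grow hi until Lambda(hi) >= x.  With a finite support
    # endpoint (where Lambda may diverge) approach it geometrically from
    # below instead of stepping past it.
    lo, hi = 0.0, None
    if math.isfinite(intensity.support):
        cap = intensity.support
        for k in range(1, 120):
            probe = cap * (1.0 - 2.0 ** -k)
            if probe <= lo:
                continue
            if cum(probe) >= x:
                hi = probe
                break
            lo = probe
        if hi is None:
            return NO_FIRE  # mass up to the support never reaches x
    else:
        probe = 1.0
        for _ in range(80):
            if cum(probe) >= x:
                hi = probe
                break
            lo = probe
            probe *= 2.0
        if hi is None:
            return NO_FIRE  # undeclared finite total mass

    try:
        root = optimize.brentq(lambda t: cum(t) - x, lo, hi,
                               xtol=1e-12, rtol=1e-9, maxiter=200)
    except Exception as exc:  # noqa: BLE001 - re-raise with context, never silent
        raise NumericalError(f"inversion root-finding failed: {exc}") from exc
    return float(root)


def sample_thinning(intensity: IntensityFunction, c: float,
                    rng: np.random.Generator,
                    max_horizon: float) -> float:
    """Thinning (rejection) sampling under a dominating constant rate ``c``.

    Candidates arrive as a Poisson process of rate ``c``; a candidate at
    ``t`` is accepted with probability ``rate(t)/c``.  Returns
    :data:`NO_FIRE` once the candidate stream passes ``max_horizon``.
    Raises :class:`BoundViolationError` if the hazard is observed above
    ``c``, which signals an invalid dominator.
    """
    if c < 0:
        raise ValueError("dominating constant must be nonnegative")
    if c == 0.0:
        return NO_FIRE
    t = 0.0
    while True:
        t += rng.exponential(1.0 / c)
        if t > max_horizon:
            return NO_FIRE
        lam = intensity(t)
        if lam > c * (1.0 + 1e-12):
            raise BoundViolationError(
                f"intensity {lam} exceeds dominating constant {c} at t={t}")
        if rng.random() < lam / c:
            return t


def sample_exponential_mixture(rate_sampler: Callable[[np.random.Generator], float],
                               rng: np.random.Generator) -> float:
    """Laplace–Gillespie sampling for mixtures of exponentials.

    Draw a rate ``lam`` from the mixing density (via ``rate_sampler``), then
    a delay ``-ln(u)/lam``; a zero rate yields :data:`NO_FIRE`.
    """
    lam = rate_sampler(rng)
    if lam < 0:
        raise ValueError("mixture rate must be nonnegative")
    if lam == 0.0:
        return NO_FIRE
    return -math.log(rng.random()) / lam


def uniform_mixture_rate_sampler(upper: float, elapsed: float = 0.0
                                 ) -> Callable[[np.random.Generator], float]:
    """Rate sampler for the uniform-on-[0, upper] exponential mixture.

    With ``elapsed == 0`` the rate is uniform on [0, upper].  For a process
    that has already survived ``elapsed`` time units, the posterior mixing
    density is proportional to ``exp(-lam * elapsed)`` on [0, upper]
    (completely monotone survival), sampled by inverse CDF; the remaining
    delay is then still an exponential mixture, so regeneration from a
    positive residence stays exact.
    """
    if upper < 0:
        raise ValueError("mixture upper rate must be nonnegative")

    def sampler(rng: np.random.Generator) -> float:
        if upper == 0.0:
            return 0.0
        u = rng.random()
        if elapsed <= 0.0:
            return u * upper
        z = -math.expm1(-upper * elapsed)  # 1 - exp(-upper*elapsed)
        return -math.log1p(-u * z) / elapsed

    return sampler


# ---------------------------------------------------------------------------
# Registered closed-form hazards
# ---------------------------------------------------------------------------

def constant_hazard(r: float) -> IntensityFunction:
    """Memoryless hazard ``lambda == r`` (exponential delays)."""
    if r < 0:
        raise ValueError("rate must be nonnegative")
    if r == 0.0:
        return IntensityFunction(rate=lambda t: 0.0, cumulative=lambda t: 0.0,
                                 total_mass=0.0, name="constant(0)")
    return IntensityFunction(
        rate=lambda t: r,
        cumulative=lambda t: r * t,
        inverse_cumulative=lambda x: x / r,
        total_mass=math.inf,
        name=f"constant({r})",
    )


def uniform_hazard(a: float, b: float) -> IntensityFunction:
    """Hazard of the uniform delay density on [a, b]: ``1/(b-t)`` on [a, b).

    The cumulative hazard is ``ln((b-a)/(b-t))`` on [a, b) and diverges at
    ``b`` (the delay law is proper: the agent certainly fires by ``b``).
    """
    if not 0 <= a < b:
        raise ValueError("need 0 <= a < b")
    width = b - a

    def rate(t: float) -> float:
        if a <= t < b:
            return 1.0 / (b - t)
        return 0.0

    def cumulative(t: float) -> float:
        if t < a:
            return 0.0
        if t >= b:
            return math.inf
        return math.log(width / (b - t))

    def inverse(x: float) -> float:
        if x <= 0:
            return 0.0
        return b - width * math.exp(-x)

    return IntensityFunction(rate=rate, cumulative=cumulative,
                             inverse_cumulative=inverse,
                             total_mass=math.inf, support=b,
                             breakpoints=(a, b), name=f"uniform({a},{b})")


def exponential_decay_hazard(amplitude: float, decay: float) -> IntensityFunction:
    """Hazard ``A * exp(-u t)`` with finite total mass ``A/u`` (defective).

    This is the effective infection hazard of the non-Markovian SIS model:
    a superposition of attack rates ``u e^{-u t'}`` has this form with
    ``A`` the summed pressure at delay zero.
    """
    if amplitude < 0 or decay <= 0:
        raise ValueError("need amplitude >= 0 and decay > 0")
    if amplitude == 0.0:
        return constant_hazard(0.0)
    total = amplitude / decay

    def inverse(x: float) -> float:
        return -math.log1p(-decay * x / amplitude) / decay

    return IntensityFunction(
        rate=lambda t: amplitude * math.exp(-decay * t),
        cumulative=lambda t: total * -math.expm1(-decay * t),
        inverse_cumulative=inverse,
        total_mass=total,
        name=f"exp_decay({amplitude},{decay})",
    )


def sin_squared_hazard(omega: float = 2.0) -> IntensityFunction:
    """Oscillating hazard ``sin^2(omega t)`` with closed-form cumulative."""

    return IntensityFunction(
        rate=lambda t: math.sin(omega * t) ** 2,
        cumulative=lambda t: 0.5 * t - math.sin(2 * omega * t) / (4 * omega),
        total_mass=math.inf,
        name=f"sin2({omega})",
    )


def voter_hazard(o: float, shift: float = 0.0) -> IntensityFunction:
    """Hazard of the uniform-on-[0, o] exponential mixture, shifted by ``shift``.

    The mixture delay density ``gamma(t) = int_0^o (1/o) lam e^{-lam t} dlam``
    has survival ``(1 - e^{-o t})/(o t)`` and hazard

    ``lambda(t) = 1/t - o/(e^{o t} - 1)``,

    evaluated by series for ``o*t < 1e-4`` to avoid catastrophic
    cancellation (``lambda -> o/2`` as ``t -> 0``).  With ``shift = r`` the
    returned hazard is ``lambda(r + t)`` with cumulative
    ``Lambda(r + t) - Lambda(r)``: the delay law conditioned on having
    already survived ``r``.
    """
    if o < 0:
        raise ValueError("mixture upper rate must be nonnegative")
    if o == 0.0:
        return constant_hazard(0.0)

    def raw_rate(t: float) -> float:
        s = o * t
        if s < 1e-4:
            return o * (0.5 - s / 12.0 + s ** 3 / 720.0)
        return 1.0 / t - o / math.expm1(s)

    def raw_cumulative(t: float) -> float:
        if t <= 0:
            return 0.0
        s = o * t
        if s < 1e-4:
            # -ln((1-e^{-s})/s) = s/2 - s^2/24 + O(s^4)
            return s / 2.0 - s * s / 24.0
        return -math.log(-math.expm1(-s) / s)

    if shift == 0.0:
        return IntensityFunction(rate=raw_rate, cumulative=raw_cumulative,
                                 total_mass=math.inf, name=f"voter({o})")
    base = raw_cumulative(shift)
    return IntensityFunction(
        rate=lambda t: raw_rate(shift + t),
        cumulative=lambda t: raw_cumulative(shift + t) - base,
        total_mass=math.inf,
        name=f"voter({o})+{shift}",
    )
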