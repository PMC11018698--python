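"""Exact and Monte Carlo statistical mechanics of the 1D hard-rod fluid.

The Tonks (Gursey) fluid — N impenetrable rods of diameter ``a`` on a line
of length ``L`` with hard walls — is one of the few exactly solvable models
in statistical mechanics. Because the rods cannot pass one another, the
configuration integral factorises after mapping away the excluded length:

    Q_N = (L - N*a)**N / N!

This module provides that exact finite-N thermodynamics, an exact direct
sampler of equilibrium configurations, and a Widom test-rod insertion
estimator of the excess chemical potential. Together they form an
independent numerical route to the thermodynamic-limit result

    mu_ex(phi) = phi/(1-phi) - ln(1-phi),    phi = N*a/L,

implemented in closed form by :func:`singlefile.theory.mu_excess`.

Conventions: hard walls at 0 and L, rod centres confined to
[a/2, L - a/2], free length L - N*a. The finite-N excess chemical
potential uses the insertion form -ln(Q_{N+1}/Q_N) with the ideal part
ln((N+1)/L) subtracted; it converges to mu_ex(phi) as O(1/N) at fixed phi.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .errors import DomainError

__all__ = [
    "RodSystem",
    "WidomEstimate",
    "log_config_integral",
    "mu_excess_finite",
    "sample_configuration",
    "sample_configurations",
    "gap_survival",
    "widom_mu_excess",
]


@dataclass(frozen=True)
class RodSystem:
    """N hard rods of diameter a in a box of length L (hard walls)."""

    N: int
    a: float
    L: float

    def __post_init__(self) -> None:
        if self.N < 0:
            raise DomainError("rod count N must be >= 0")
        if not (self.a > 0 and self.L > 0):
            raise DomainError("a and L must be positive")
        if self.N * self.a >= self.L:
            raise DomainError(
                f"N*a = {self.N * self.a:g} >= L = {self.L:g}: no free volume"
            )

    @property
    def phi(self) -> float:
        """Occupancy fraction N*a/L."""
        return self.N * self.a / self.L

    @property
    def free_length(self) -> float:
        return self.L - self.N * self.a

    @classmethod
    def at_occupancy(cls, N: int, phi: float, a: float = 1.0) -> "RodSystem":
        """System of N rods with box length chosen so that N*a/L = phi."""
        if not 0 < phi < 1:
            raise DomainError("phi must lie in (0, 1)")
        return cls(N=N, a=a, L=N * a / phi)


def log_config_integral(sys: RodSystem) -> float:
    """ln Q_N = N*ln(L - N*a) - ln N! for the hard-rod fluid.

    Exact log-gamma is used for ln N!; no Stirling truncation.
    """
    N = sys.N
    if N == 0:
        return 0.0
    return N * math.log(sys.free_length) - float(gammaln(N + 1))


def mu_excess_finite(sys: RodSystem) -> float:
    """Finite-N excess chemical potential of inserting rod N+1.

    -[ln Q_{N+1} - ln Q_N] - ln((N+1)/L): the full insertion chemical
    potential minus its ideal-gas part. Converges to the closed-form
    mu_ex(phi) with an O(1/N) deficit at fixed phi = N*a/L.
    """
    if sys.N < 1:
        raise DomainError("need at least one rod for a meaningful excess")
    if (sys.N + 1) * sys.a >= sys.L:
        raise DomainError(
            f"cannot insert rod {sys.N + 1}: ({sys.N + 1})*a >= L"
        )
    grown = RodSystem(N=sys.N + 1, a=sys.a, L=sys.L)
    dlnQ = log_config_integral(grown) - log_config_integral(sys)
    return -dlnQ - math.log((sys.N + 1) / sys.L)


def sample_configuration(sys: RodSystem, rng: np.random.Generator) -> np.ndarray:
    """Draw one equilibrium configuration of rod centres, exactly.

    Classic excluded-length construction: N uniform points in a box of
    length L - N*a are sorted and the i-th is shifted right by
    a/2 + i*a. The result is strictly increasing with all neighbour gaps
    >= a and centres inside [a/2, L - a/2], distributed by the uniform
    hard-rod measure.
    """
    y = np.sort(rng.uniform(0.0, sys.free_length, size=sys.N))
    return y + sys.a / 2 + sys.a * np.arange(sys.N)


def sample_configurations(
    sys: RodSystem, n_samples: int, rng: np.random.Generator
) -> np.ndarray:
    """Vectorised: (n_samples, N) array of independent configurations."""
    y = np.sort(rng.uniform(0.0, sys.free_length, size=(n_samples, sys.N)), axis=1)
    return y + sys.a / 2 + sys.a * np.arange(sys.N)


def gap_survival(sys: RodSystem, x: np.ndarray) -> np.ndarray:
    """Exact survival function P(gap - a > x) for a neighbour gap.

    A gap between adjacent rod centres, minus the rod diameter, is one of
    N+1 exchangeable uniform spacings of total length L - N*a, so its
    marginal survival is (1 - x/(L - N*a))**N.
    """
    x = np.asarray(x, dtype=float)
    frac = np.clip(1.0 - x / sys.free_length, 0.0, 1.0)
    return frac ** sys.N


@dataclass(frozen=True)
class WidomEstimate:
    """Widom insertion estimate of mu_ex with a delta-method standard error."""

    mu: float
    se: float
    p_accept: float
    n_samples: int
    infinite: bool = False


def widom_mu_excess(
    sys: RodSystem, n_samples: int, rng: np.random.Generator
) -> WidomEstimate:
    """Estimate mu_ex by test-rod insertion into sampled configurations.

    For each of ``n_samples`` independent equilibrium configurations a test
    rod centre is drawn uniformly on [a/2, L - a/2]; the insertion succeeds
    if it is at least ``a`` from every rod centre. With acceptance fraction
    p over the test interval of length L - a,

        mu_ex = -ln(p * (L - a)/L)

    the (L-a)/L factor converting the conditional acceptance probability to
    the full-box average required by the Q_{N+1}/Q_N insertion identity.
    The standard error follows from the binomial variance of p by the delta
    method, se = sqrt((1-p)/(n*p)).
    """
    if n_samples < 100:
        raise DomainError("n_samples must be at least 100")
    if (sys.N + 1) * sys.a >= sys.L:
        raise DomainError("test rod cannot fit: (N+1)*a >= L")

    batch = min(n_samples, 200_000 // max(sys.N, 1) + 1)
    accepted = 0
    done = 0
    half = sys.a / 2
    while done < n_samples:
        m = min(batch, n_samples - done)
        if sys.N == 0:
            accepted += m  # empty box: only the walls constrain the test rod
        else:
            conf = sample_configurations(sys, m, rng)
            t = rng.uniform(half, sys.L - half, size=(m, 1))
            accepted += int(np.count_nonzero(np.abs(conf - t).min(axis=1) >= sys.a))
        done += m

    p = accepted / n_samples
    if accepted == 0:
        warnings.warn(
            f"no successful insertion in {n_samples} samples at phi = {sys.phi:.3f}; "
            "reduce the occupancy or raise n_samples",
            RuntimeWarning,
            stacklevel=2,
        )
        return WidomEstimate(
            mu=math.inf, se=math.inf, p_accept=0.0, n_samples=n_samples, infinite=True
        )
    mu = -math.log(p * (sys.L - sys.a) / sys.L)
    se = math.sqrt((1.0 - p) / (n_samples * p))
    return WidomEstimate(mu=mu, se=se, p_accept=p, n_samples=n_samples)
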