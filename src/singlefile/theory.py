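"""Closed-form hard-sphere single-file permeability theory.

A membrane is pierced by ``n`` identical channels of length ``L`` so narrow
that water molecules — modelled as hard rods of diameter ``a`` — traverse
them strictly in single file. The single state variable of the model is the
occupancy fraction ``phi = N*a/L``, the average fraction of the channel
length covered by rods.

From the exact statistical mechanics of the one-dimensional hard-rod
(Tonks) fluid, the excess chemical potential in units of kT is

    mu_ex(phi) = phi/(1 - phi) - ln(1 - phi)

and the thermodynamic factor (collective over tracer diffusivity)

    D/D* = 1 + d mu_ex / d ln phi = 1/(1 - phi)^2

which is also the ratio of the osmotic to the diffusive permeability,

    Pf/Pd = 1/(1 - phi)^2.

With a random-walk estimate of the in-channel self-diffusion the individual
permeabilities follow:

    Pd = B * phi * (1 - phi)^2,     Pf = B * phi,
    B  = D0 * n * vw0 / (a * A * L)

where D0 is the dilute-limit in-pore self-diffusion coefficient and vw0 the
volume per water molecule. Everything here is CGS: cm, s, cm/s, cm^3/s.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from .errors import DomainError, ModelInconsistencyWarning, SingularLimitError

__all__ = [
    "PoreGeometry",
    "TransportParams",
    "PermeabilityResult",
    "mu_excess",
    "thermodynamic_factor",
    "pf_pd_ratio",
    "occupancy_from_ratio",
    "occupancy_from_counts",
    "partition_coefficient",
    "prefactor_B",
    "pd_permeability",
    "pf_permeability",
    "per_pore_pf",
    "convective_component",
    "predict",
]


def _check_phi(phi: float, *, allow_one: bool = False) -> float:
    phi = float(phi)
    if not math.isfinite(phi) or phi < 0.0 or phi > 1.0:
        raise DomainError(
            f"occupancy fraction phi={phi!r} outside the valid interval "
            f"[0, 1{']' if allow_one else ')'}"
        )
    if phi == 1.0 and not allow_one:
        raise SingularLimitError(
            "phi = 1 is the closest-packed singular limit; this quantity diverges there"
        )
    return phi


@dataclass(frozen=True)
class PoreGeometry:
    """Channel/membrane geometry, CGS units.

    a : rod (water) diameter, cm
    L : channel length = membrane thickness, cm
    n : number of single-file channels
    A : membrane cross-sectional area, cm^2
    """

    a: float
    L: float
    n: int = 1
    A: float = 1.0

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.L > 0 and self.A > 0):
            raise DomainError("a, L and A must all be positive")
        if self.n < 1:
            raise DomainError("channel count n must be >= 1")
        if self.a > self.L:
            raise DomainError("rod diameter a cannot exceed channel length L")


@dataclass(frozen=True)
class TransportParams:
    """Kinetic parameters entering the permeability prefactor.

    D0   : dilute-limit in-pore self-diffusion coefficient, cm^2/s,
           identified with (1/2)*nu*l0**2 of the random-walk picture
    v_w0 : volume per molecule of pure water, cm^3
    nu   : collision frequency, 1/s (optional)
    l0   : dilute-limit mean free path, cm (optional)

    If both ``nu`` and ``l0`` are supplied they must reproduce ``D0``.
    """

    D0: float
    v_w0: float
    nu: float | None = None
    l0: float | None = None

    def __post_init__(self) -> None:
        if not (self.D0 > 0 and self.v_w0 > 0):
            raise DomainError("D0 and v_w0 must be positive")
        if self.nu is not None and self.l0 is not None:
            implied = 0.5 * self.nu * self.l0 ** 2
            if abs(implied - self.D0) > 1e-12 * self.D0:
                raise DomainError(
                    f"(1/2)*nu*l0^2 = {implied:g} does not match D0 = {self.D0:g}"
                )

    @classmethod
    def from_random_walk(cls, nu: float, l0: float, v_w0: float) -> "TransportParams":
        """Build from collision frequency and dilute mean free path."""
        return cls(D0=0.5 * nu * l0 ** 2, v_w0=v_w0, nu=nu, l0=l0)


@dataclass(frozen=True)
class PermeabilityResult:
    """Bundle of predicted transport coefficients (CGS)."""

    phi: float
    Pf: float            # osmotic permeability, cm/s
    Pd: float            # diffusion (exchange) permeability, cm/s
    ratio: float         # Pf/Pd, dimensionless
    Pc: float            # convective component Pf - Pd, cm/s
    B: float | None = None            # prefactor, cm/s
    K: float | None = None            # partition coefficient
    pf_per_pore: float | None = None  # per-pore osmotic permeability, cm^3/s


def mu_excess(phi: float) -> float:
    """Excess chemical potential (units of kT) of the 1D hard-rod fluid.

    mu_ex = phi/(1-phi) - ln(1-phi); zero in the dilute limit, strictly
    increasing, divergent at close packing.
    """
    phi = _check_phi(phi)
    return phi / (1.0 - phi) - math.log1p(-phi)


def _dmu_dphi(phi: float) -> float:
    # d/dphi [phi/(1-phi) - ln(1-phi)] = 1/(1-phi)^2 + 1/(1-phi)
    return 1.0 / (1.0 - phi) ** 2 + 1.0 / (1.0 - phi)


def thermodynamic_factor(phi: float) -> float:
    """Ratio D/D* of collective to self diffusivity: 1 + d mu_ex/d ln phi.

    Evaluated from the analytic derivative of :func:`mu_excess`; algebra
    reduces it to 1/(1-phi)^2, which is checked as an invariant in the
    test suite rather than assumed here.
    """
    phi = _check_phi(phi)
    return 1.0 + phi * _dmu_dphi(phi)


def pf_pd_ratio(phi: float) -> float:
    """Osmotic-to-diffusive permeability ratio Pf/Pd = 1/(1-phi)^2."""
    phi = _check_phi(phi)
    return 1.0 / (1.0 - phi) ** 2


def occupancy_from_ratio(ratio: float) -> float:
    """Invert Pf/Pd = 1/(1-phi)^2 for the occupancy fraction.

    phi = 1 - ratio**(-1/2). A measured ratio below one has no hard-sphere
    solution and raises :class:`DomainError`.
    """
    ratio = float(ratio)
    if not math.isfinite(ratio) or ratio < 1.0:
        raise DomainError(
            f"Pf/Pd = {ratio!r}: the hard-sphere single-file model cannot "
            "produce a ratio below 1"
        )
    return 1.0 - ratio ** -0.5


def occupancy_from_counts(N: int, a: float, L: float) -> float:
    """Occupancy fraction phi = N*a/L from rod count and geometry."""
    if N < 0 or a <= 0 or L <= 0:
        raise DomainError("need N >= 0, a > 0, L > 0")
    if N * a > L:
        raise DomainError(f"N*a = {N * a:g} exceeds channel length L = {L:g}")
    return N * a / L


def partition_coefficient(geom: PoreGeometry, tp: TransportParams, phi: float) -> float:
    """Water partition coefficient K = (n*v_w0 / (a*A)) * phi.

    Ratio of the water concentration inside the membrane (n channels, each a
    fraction phi full) to that of the ideally dilute bathing reservoir.
    """
    phi = _check_phi(phi, allow_one=True)
    return geom.n * tp.v_w0 / (geom.a * geom.A) * phi


def prefactor_B(geom: PoreGeometry, tp: TransportParams) -> float:
    """Permeability prefactor B = D0 * n * v_w0 / (a*A*L), cm/s."""
    return tp.D0 * geom.n * tp.v_w0 / (geom.a * geom.A * geom.L)


def pd_permeability(phi: float, B: float) -> float:
    """Diffusion permeability Pd = B*phi*(1-phi)^2, cm/s.

    Vanishes both in the empty channel and at close packing; maximal at
    phi = 1/3.
    """
    phi = _check_phi(phi, allow_one=True)
    if B <= 0:
        raise DomainError("prefactor B must be positive")
    return B * phi * (1.0 - phi) ** 2


def pf_permeability(phi: float, B: float) -> float:
    """Osmotic permeability Pf = B*phi, cm/s; rises linearly to B at phi=1."""
    phi = _check_phi(phi, allow_one=True)
    if B <= 0:
        raise DomainError("prefactor B must be positive")
    return B * phi


def per_pore_pf(geom: PoreGeometry, tp: TransportParams, phi: float) -> float:
    """Per-channel osmotic permeability pf = (A/n)*Pf = D0*v_w0*phi/(a*L), cm^3/s.

    The membrane area A and channel count n cancel exactly, so pf is a
    single-channel property.
    """
    phi = _check_phi(phi, allow_one=True)
    return tp.D0 * tp.v_w0 * phi / (geom.a * geom.L)


def convective_component(Pf: float, Pd: float) -> float:
    """Convective part of osmotic flow, Pc = Pf - Pd.

    Measured pairs with Pf < Pd occasionally occur experimentally; such
    input yields a negative Pc together with a
    :class:`ModelInconsistencyWarning` rather than an exception.
    """
    if Pf < 0 or Pd < 0:
        raise DomainError("permeabilities must be non-negative")
    Pc = Pf - Pd
    if Pc < 0:
        warnings.warn(
            f"Pf = {Pf:g} < Pd = {Pd:g}: negative convective component; the "
            "hard-sphere model cannot produce Pf/Pd < 1",
            ModelInconsistencyWarning,
            stacklevel=2,
        )
    return Pc


def predict(
    phi: float,
    B: float | None = None,
    geom: PoreGeometry | None = None,
    tp: TransportParams | None = None,
) -> PermeabilityResult:
    """Evaluate the full set of transport coefficients at occupancy ``phi``.

    Either supply the prefactor ``B`` directly, or supply ``geom`` and
    ``tp`` so that B, K and the per-pore pf can all be computed.
    """
    phi = _check_phi(phi, allow_one=True)
    K = pf_pp = None
    if geom is not None and tp is not None:
        B = prefactor_B(geom, tp)
        K = partition_coefficient(geom, tp, phi)
        pf_pp = per_pore_pf(geom, tp, phi)
    elif B is None:
        raise DomainError("supply either B or both geometry and transport parameters")
    Pf = pf_permeability(phi, B)
    Pd = pd_permeability(phi, B)
    # equals Pf/Pd wherever Pd > 0, and carries the analytic limit at phi = 0
    ratio = 1.0 / (1.0 - phi) ** 2 if phi < 1.0 else math.inf
    return PermeabilityResult(
        phi=phi, Pf=Pf, Pd=Pd, ratio=ratio, Pc=Pf - Pd, B=B, K=K, pf_per_pore=pf_pp
    )
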