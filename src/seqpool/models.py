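"""Vesicle-pool kinetics of Ca²⁺-dependent neurosecretion.

Two mechanistic models of the chromaffin-cell secretory pathway are
implemented:

``SequentialPoolModel`` (SPM)
    Depot → NRP ⇌ RRP → (3-site Ca²⁺ sensor) → Fused.  The NRP⇌RRP
    priming step is accelerated by a Ca²⁺-dependent *catalyst* that
    raises forward and backward rates by the same factor, leaving the
    NRP/RRP equilibrium Ca²⁺-invariant.

``ParallelPoolModel`` (PPM)
    Depot → SRP ⇌ RRP with two parallel fusion pathways, each gated by
    its own three-site cooperative Ca²⁺ sensor.  Optionally the SRP→RRP
    interconversion carries the same catalyst (the "PPM+cat" variant).

Pools are carried in femtofarads (fF), the capacitance proxy for vesicle
number used in flash-photolysis experiments; Ca²⁺ concentrations are in
µM and all rate constants in 1/s (per-site Ca²⁺ on-rates in 1/(s·µM)).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "CatalystParams",
    "SPMParams",
    "PPMParams",
    "SequentialPoolModel",
    "ParallelPoolModel",
    "catalyst_activation",
    "priming_rates",
    "recruitment_rate",
]


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CatalystParams:
    """Ca²⁺-dependent priming-catalyst parameters.

    The catalyst binds ``n`` Ca²⁺ ions independently with per-site
    dissociation constant ``K_D``; the activated fraction is
    ``g(Ca) = (Ca/(K_D+Ca))**n``.  The overall priming rates are
    ``k2 = k20 + k2cat*g`` and ``k_minus2 = k_minus20 + k_minus2cat*g``
    with ``k_minus2cat = k2cat*k_minus20/k20`` imposed by the
    thermodynamic requirement that a catalyst must not shift the
    NRP/RRP equilibrium.
    """

    k20: float = 0.021  # uncatalyzed priming, 1/s
    k2cat: float = 20.0  # catalyzed priming ceiling, 1/s
    k_minus20: float = 0.017  # uncatalyzed unpriming, 1/s
    K_D: float = 100.0  # catalyst Ca2+ dissociation constant, uM
    n: int = 1  # catalyst Ca2+ cooperativity

    def __post_init__(self) -> None:
        if self.k20 <= 0:
            raise ValueError(
                "k20 must be > 0: k_minus2cat = k2cat*k_minus20/k20 is "
                "otherwise undefined"
            )
        if self.K_D <= 0:
            raise ValueError("K_D must be > 0")
        if self.n < 1 or int(self.n) != self.n:
            raise ValueError("catalyst cooperativity n must be an integer >= 1")
        for name in ("k2cat", "k_minus20"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def k_minus2cat(self) -> float:
        """Catalyzed unpriming ceiling, fixed by detailed balance."""
        return self.k2cat * self.k_minus20 / self.k20


@dataclass(frozen=True)
class SPMParams:
    """Rate constants of the sequential pool model (chromaffin-cell set).

    Defaults are the published wild-type chromaffin-cell values.
    """

    k1max: float = 55.0  # recruitment ceiling, fF/s
    K_M: float = 2.3  # recruitment Michaelis constant, uM
    k_minus1: float = 0.05  # NRP -> Depot unpriming, 1/s
    k20: float = 0.021
    k2cat: float = 20.0
    k_minus20: float = 0.017
    K_D: float = 100.0
    n: int = 1
    k3: float = 4.4  # sensor per-site on-rate, 1/(s*uM)
    k_minus3: float = 56.0  # sensor per-site off-rate, 1/s
    k4: float = 1450.0  # final fusion rate, 1/s

    def __post_init__(self) -> None:
        # shares the catalyst invariants; also validates k20 > 0 etc.
        object.__setattr__(self, "_catalyst", CatalystParams(
            self.k20, self.k2cat, self.k_minus20, self.K_D, self.n))
        if self.K_M <= 0:
            raise ValueError("K_M must be > 0")
        for name in ("k1max", "k_minus1", "k3", "k_minus3", "k4"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def catalyst(self) -> CatalystParams:
        return self._catalyst

    @property
    def k_minus2cat(self) -> float:
        return self._catalyst.k_minus2cat


@dataclass(frozen=True)
class PPMParams:
    """Rate constants of the parallel pool model (chromaffin-cell set).

    ``catalyst`` switches on the PPM+cat variant: the fixed ``k2`` /
    ``k_minus2`` SRP⇌RRP rates are then replaced by the Ca²⁺-dependent
    catalyst rate law.
    """

    k1max: float = 55.0
    K_M: float = 2.3
    k_minus1: float = 0.05
    k2: float = 0.12  # SRP -> RRP, 1/s
    k_minus2: float = 0.1  # RRP -> SRP, 1/s
    k3s: float = 0.5  # slow sensor per-site on-rate, 1/(s*uM)
    k_minus3s: float = 4.0
    k4s: float = 20.0
    k3r: float = 4.4  # fast sensor per-site on-rate, 1/(s*uM)
    k_minus3r: float = 56.0
    k4r: float = 1450.0
    catalyst: Optional[CatalystParams] = None

    def __post_init__(self) -> None:
        if self.K_M <= 0:
            raise ValueError("K_M must be > 0")
        for name in ("k1max", "k_minus1", "k2", "k_minus2", "k3s",
                     "k_minus3s", "k4s", "k3r", "k_minus3r", "k4r"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


# ---------------------------------------------------------------------------
# Elementary rate laws
# ---------------------------------------------------------------------------


def catalyst_activation(ca, K_D: float, n: int = 1):
    """Fraction of catalyst with all ``n`` Ca²⁺ sites occupied.

    ``g(Ca) = (Ca/(K_D+Ca))**n`` for ``n`` independent, identical sites
    in instantaneous equilibrium with Ca²⁺.  Monotone in Ca, 0 at Ca=0,
    approaching 1 as Ca → ∞; for n=1, g(K_D) = 1/2 exactly.
    """
    ca = np.asarray(ca, dtype=float)
    if np.any(ca < 0):
        raise ValueError("Ca2+ concentration must be >= 0")
    if K_D <= 0:
        raise ValueError("K_D must be > 0")
    if n < 1:
        raise ValueError("n must be >= 1")
    g = (ca / (K_D + ca)) ** n
    return g if g.ndim else float(g)


def priming_rates(ca, p, destabilization: float = 1.0):
    """Overall priming rates (k2, k_minus2) at concentration ``ca``.

    ``p`` is anything carrying catalyst fields (``SPMParams`` or
    ``CatalystParams``).  ``destabilization`` multiplies both backward
    components (uncatalyzed and catalyzed), which raises the RRP free
    energy uniformly and is how the RRP-destabilized synaptotagmin-null
    variant is modelled.  The forward/backward ratio k2/k_minus2 equals
    k20/(destabilization*k_minus20) at every Ca²⁺ by construction.
    """
    g = catalyst_activation(ca, p.K_D, p.n)
    k2 = p.k20 + p.k2cat * g
    k_minus2 = destabilization * (p.k_minus20 + p.k_minus2cat * g)
    return k2, k_minus2


def recruitment_rate(ca, p):
    """Michaelis-Menten Ca²⁺-dependent supply flux from the Depot, fF/s.

    The Depot is treated as infinite, so this is a flux (fF/s), not a
    first-order rate.
    """
    ca = np.asarray(ca, dtype=float)
    if np.any(ca < 0):
        raise ValueError("Ca2+ concentration must be >= 0")
    r = p.k1max * ca / (p.K_M + ca)
    return r if r.ndim else float(r)


# ---------------------------------------------------------------------------
# Model classes
# ---------------------------------------------------------------------------


class SequentialPoolModel:
    """Sequential pool model: Depot → NRP ⇌ RRP → sensor cascade → F.

    State vector (fF): ``[NRP, RRP, RRPCa, RRPCa2, RRPCa3, F]``.  The
    fusion sensor is the standard three-identical-site scheme with
    forward rates 3·k3·Ca, 2·k3·Ca, k3·Ca, backward rates k₋3, 2·k₋3,
    3·k₋3 and a fast Ca²⁺-independent final step k4.

    Parameters
    ----------
    params : SPMParams
    unclamped : bool
        Synaptotagmin-null variant in which the final fusion barrier is
        absent: every RRP sensor state additionally fuses at the maximal
        rate k4 irrespective of Ca²⁺.
    destabilization : float
        Multiplies both components of the backward priming rate
        (default 1 = wild type; the published syt-null variant uses 10).
    """

    state_names = ("NRP", "RRP", "RRPCa", "RRPCa2", "RRPCa3", "F")
    fused_names = ("F",)
    n_states = 6

    def __init__(self, params: SPMParams | None = None, *,
                 unclamped: bool = False, destabilization: float = 1.0):
        if destabilization <= 0:
            raise ValueError("destabilization factor must be > 0")
        self.params = params if params is not None else SPMParams()
        self.unclamped = bool(unclamped)
        self.destabilization = float(destabilization)

    # -- kinetics -----------------------------------------------------------

    def rhs(self, state: np.ndarray, ca: float) -> np.ndarray:
        p = self.params
        k2, km2 = priming_rates(ca, p, self.destabilization)
        k1 = recruitment_rate(ca, p)
        nrp, r0, r1, r2, r3 = state[:5]
        k3ca = p.k3 * ca
        u = p.k4 if self.unclamped else 0.0
        d = np.empty(6)
        d[0] = k1 - (p.k_minus1 + k2) * nrp + km2 * r0
        d[1] = k2 * nrp - (km2 + 3 * k3ca + u) * r0 + p.k_minus3 * r1
        d[2] = 3 * k3ca * r0 - (p.k_minus3 + 2 * k3ca + u) * r1 + 2 * p.k_minus3 * r2
        d[3] = 2 * k3ca * r1 - (2 * p.k_minus3 + k3ca + u) * r2 + 3 * p.k_minus3 * r3
        d[4] = k3ca * r2 - (3 * p.k_minus3 + p.k4 + u) * r3
        d[5] = p.k4 * r3 + u * (r0 + r1 + r2 + r3)
        return d

    def _balance_matrix(self, ca: float) -> np.ndarray:
        """Linear system A·x + b = dx/dt for the five pre-fusion pools."""
        p = self.params
        k2, km2 = priming_rates(ca, p, self.destabilization)
        k3ca = p.k3 * ca
        u = p.k4 if self.unclamped else 0.0
        km3 = p.k_minus3
        return np.array([
            [-(p.k_minus1 + k2), km2, 0.0, 0.0, 0.0],
            [k2, -(km2 + 3 * k3ca + u), km3, 0.0, 0.0],
            [0.0, 3 * k3ca, -(km3 + 2 * k3ca + u), 2 * km3, 0.0],
            [0.0, 0.0, 2 * k3ca, -(2 * km3 + k3ca + u), 3 * km3],
            [0.0, 0.0, 0.0, k3ca, -(3 * km3 + p.k4 + u)],
        ])

    def steady_state(self, ca: float) -> tuple[np.ndarray, float]:
        """Resting occupancies and fusion flux at fixed Ca²⁺.

        Solves the linear balance of the five pre-fusion pools (F is
        absorbing and excluded); returns the full 6-state vector with
        F = 0 together with the steady fusion flux in fF/s.
        """
        p = self.params
        if ca == 0:
            return np.zeros(6), 0.0  # no recruitment: the system drains
        A = self._balance_matrix(ca)
        b = np.zeros(5)
        b[0] = -recruitment_rate(ca, p)
        try:
            pools = np.linalg.solve(A, b)
        except np.linalg.LinAlgError as exc:  # pragma: no cover
            raise ValueError(f"singular steady-state system at ca={ca}") from exc
        flux = p.k4 * pools[4]
        if self.unclamped:
            flux += p.k4 * pools[1:5].sum()
        state = np.zeros(6)
        state[:5] = pools
        return state, float(flux)


class ParallelPoolModel:
    """Parallel pool model with two sensor-gated fusion pathways.

    State vector (fF):
    ``[SRP, SRPCa, SRPCa2, SRPCa3, RRP, RRPCa, RRPCa2, RRPCa3, Fs, Fr]``
    where Fs/Fr accumulate fusion through the slow (SRP) and fast (RRP)
    pathway.  SRP⇌RRP interconversion couples the Ca²⁺-free pool states
    only; it is Ca²⁺-independent unless ``params.catalyst`` is set
    (PPM+cat), in which case the catalyst rate law replaces k2/k_minus2.
    """

    state_names = ("SRP", "SRPCa", "SRPCa2", "SRPCa3",
                   "RRP", "RRPCa", "RRPCa2", "RRPCa3", "Fs", "Fr")
    fused_names = ("Fs", "Fr")
    n_states = 10

    def __init__(self, params: PPMParams | None = None):
        self.params = params if params is not None else PPMParams()

    def _interconversion(self, ca: float) -> tuple[float, float]:
        p = self.params
        if p.catalyst is not None:
            return priming_rates(ca, p.catalyst)
        return p.k2, p.k_minus2

    def rhs(self, state: np.ndarray, ca: float) -> np.ndarray:
        p = self.params
        k2, km2 = self._interconversion(ca)
        k1 = recruitment_rate(ca, p)
        s0, s1, s2, s3, r0, r1, r2, r3 = state[:8]
        ks, kms = p.k3s * ca, p.k_minus3s
        kr, kmr = p.k3r * ca, p.k_minus3r
        d = np.empty(10)
        d[0] = k1 - (p.k_minus1 + k2 + 3 * ks) * s0 + km2 * r0 + kms * s1
        d[1] = 3 * ks * s0 - (kms + 2 * ks) * s1 + 2 * kms * s2
        d[2] = 2 * ks * s1 - (2 * kms + ks) * s2 + 3 * kms * s3
        d[3] = ks * s2 - (3 * kms + p.k4s) * s3
        d[4] = k2 * s0 - (km2 + 3 * kr) * r0 + kmr * r1
        d[5] = 3 * kr * r0 - (kmr + 2 * kr) * r1 + 2 * kmr * r2
        d[6] = 2 * kr * r1 - (2 * kmr + kr) * r2 + 3 * kmr * r3
        d[7] = kr * r2 - (3 * kmr + p.k4r) * r3
        d[8] = p.k4s * s3
        d[9] = p.k4r * r3
        return d

    def steady_state(self, ca: float) -> tuple[np.ndarray, float]:
        """Resting occupancies and total fusion flux at fixed Ca²⁺."""
        p = self.params
        if ca == 0:
            return np.zeros(10), 0.0
        k2, km2 = self._interconversion(ca)
        ks, kms = p.k3s * ca, p.k_minus3s
        kr, kmr = p.k3r * ca, p.k_minus3r
        A = np.zeros((8, 8))
        A[0, 0] = -(p.k_minus1 + k2 + 3 * ks); A[0, 1] = kms; A[0, 4] = km2
        A[1, 0] = 3 * ks; A[1, 1] = -(kms + 2 * ks); A[1, 2] = 2 * kms
        A[2, 1] = 2 * ks; A[2, 2] = -(2 * kms + ks); A[2, 3] = 3 * kms
        A[3, 2] = ks; A[3, 3] = -(3 * kms + p.k4s)
        A[4, 0] = k2; A[4, 4] = -(km2 + 3 * kr); A[4, 5] = kmr
        A[5, 4] = 3 * kr; A[5, 5] = -(kmr + 2 * kr); A[5, 6] = 2 * kmr
        A[6, 5] = 2 * kr; A[6, 6] = -(2 * kmr + kr); A[6, 7] = 3 * kmr
        A[7, 6] = kr; A[7, 7] = -(3 * kmr + p.k4r)
        b = np.zeros(8)
        b[0] = -recruitment_rate(ca, p)
        pools = np.linalg.solve(A, b)
        flux = p.k4s * pools[3] + p.k4r * pools[7]
        state = np.zeros(10)
        state[:8] = pools
        return state, float(flux)
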