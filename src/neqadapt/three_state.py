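"""Three-state cycle theory: net flux, critical values, and flux sweeps.

For an irreducible three-state chain the stationary condition forces a
common net probability flux around the cycle,

    J = mu_1 q_12 - mu_2 q_21 = mu_2 q_23 - mu_3 q_32 = mu_3 q_31 - mu_1 q_13,

and J = 0 is equivalent to detailed balance.  With the edge sums
``a = mu_1 q_12 + mu_2 q_21``, ``b = mu_2 q_23 + mu_3 q_32`` and
``c = mu_3 q_31 + mu_1 q_13`` the generator is fully parametrized by
``(mu, a, b, c, J)``:

    q_12 = (a+J)/2mu_1   q_13 = (c-J)/2mu_1
    q_21 = (a-J)/2mu_2   q_23 = (b+J)/2mu_2
    q_31 = (c+J)/2mu_3   q_32 = (b-J)/2mu_3

Positive J points along the 1 -> 2 -> 3 -> 1 direction; the nonnegativity of
the off-diagonal rates bounds the feasible flux by ``min(a, b, c)``.

The nonzero eigenvalues are complex iff J exceeds the critical flux

    beta^2 = (mu_1 mu_2 mu_3 / 4) [(c+a)/mu_1 + (a+b)/mu_2 + (b+c)/mu_3]^2
             - (ab + bc + ca),

so the response rings (oscillatory overshoot) only beyond beta.  Below beta,
with ``E = phi'(0)`` and ``F = phi_inf - phi_0`` and ``lambda_2`` the more
negative eigenvalue, simple overshoot occurs iff ``E + lambda_2 F > 0``;
the root of that expression in J is the second critical flux.  Along
increasing J the phase can only move NON -> SIMPLE -> OSCILLATORY.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from . import overshoot as ovs
from .markov import (
    GeneratorMatrix,
    as_observable,
    as_probability,
    edge_fluxes,
    spectral_response,
    stationary_distribution,
    validate_generator,
)

__all__ = [
    "ThreeStateParams",
    "CriticalFluxes",
    "TransientIndicators",
    "build_three_state_Q",
    "params_from_Q",
    "beta_critical",
    "transient_indicators",
    "alpha_flux_critical",
    "critical_fluxes",
    "sweep_flux",
    "eliminate_fast_state",
    "fast_state_reduction",
    "ReducedModel",
]


@dataclasses.dataclass(frozen=True)
class ThreeStateParams:
    """Cycle parametrization ``(mu, a, b, c, J)`` of a three-state generator."""

    mu: np.ndarray
    a: float
    b: float
    c: float
    J: float

    def __post_init__(self) -> None:
        mu = as_probability(self.mu)
        if mu.size != 3:
            raise ValueError("mu must have three entries")
        if np.any(mu <= 0):
            raise ValueError("all stationary weights must be positive")
        object.__setattr__(self, "mu", mu)
        for name in ("a", "b", "c"):
            if getattr(self, name) < 0:
                raise ValueError(f"edge sum {name} must be nonnegative")
        if not (0 <= self.J <= self.J_max + 1e-15 * max(1.0, self.J_max)):
            raise ValueError(
                f"infeasible flux J={self.J}: must lie in [0, min(a,b,c)={self.J_max}]"
            )

    @property
    def J_max(self) -> float:
        """Feasibility bound: beyond min(a, b, c) an off-diagonal rate of the
        built generator would be negative."""
        return min(self.a, self.b, self.c)

    def with_flux(self, J: float) -> "ThreeStateParams":
        return ThreeStateParams(self.mu, self.a, self.b, self.c, J)


def build_three_state_Q(p: ThreeStateParams) -> GeneratorMatrix:
    """Assemble the generator from the cycle parametrization.

    By construction the stationary distribution of the result is ``p.mu``
    and every cycle edge carries net flux ``p.J``.
    """
    m1, m2, m3 = p.mu
    a, b, c, J = p.a, p.b, p.c, p.J
    Q = np.array(
        [
            [-(c + a) / (2 * m1), (a + J) / (2 * m1), (c - J) / (2 * m1)],
            [(a - J) / (2 * m2), -(a + b) / (2 * m2), (b + J) / (2 * m2)],
            [(c + J) / (2 * m3), (b - J) / (2 * m3), -(b + c) / (2 * m3)],
        ]
    )
    return validate_generator(Q)


def params_from_Q(Q: GeneratorMatrix) -> ThreeStateParams:
    """Recover ``(mu, a, b, c, J)`` from an irreducible 3-state generator.

    Round-trips with :func:`build_three_state_Q` to machine precision.
    """
    if Q.n != 3:
        raise ValueError("params_from_Q requires a 3-state generator")
    mu = stationary_distribution(Q)
    A = Q.rates
    a = mu[0] * A[0, 1] + mu[1] * A[1, 0]
    b = mu[1] * A[1, 2] + mu[2] * A[2, 1]
    c = mu[2] * A[2, 0] + mu[0] * A[0, 2]
    Jmat = edge_fluxes(Q, mu)
    J = float(Jmat[0, 1])
    # single-cycle consistency of the three edge fluxes
    if not np.allclose([Jmat[1, 2], Jmat[2, 0]], J, atol=1e-10 * max(1.0, abs(A).max())):
        raise ValueError("edge fluxes are not cyclic; not a stationary 3-cycle")
    if J < 0:
        # positive flux convention is 1 -> 2 -> 3 -> 1; relabel by reversal
        raise ValueError(
            "net flux is negative under the 1->2->3 orientation; "
            "relabel states (reverse the cycle) to use the positive-J convention"
        )
    return ThreeStateParams(mu, float(a), float(b), float(c), J)


def beta_critical(p: ThreeStateParams) -> float:
    """Critical flux beta: eigenvalues of the built generator are complex iff J > beta.

    Closed form
    ``beta^2 = (mu1 mu2 mu3/4) [(c+a)/mu1 + (a+b)/mu2 + (b+c)/mu3]^2 - (ab+bc+ca)``.
    A negative radicand (never observed for valid parameters) raises rather
    than silently clipping.
    """
    m1, m2, m3 = p.mu
    a, b, c = p.a, p.b, p.c
    bracket = (c + a) / m1 + (a + b) / m2 + (b + c) / m3
    rad = (m1 * m2 * m3 / 4.0) * bracket**2 - (a * b + b * c + c * a)
    if rad < 0:
        if rad > -1e-12 * max(1.0, bracket**2):
            return 0.0
        raise ArithmeticError(f"negative radicand {rad} in critical-flux formula")
    return math.sqrt(rad)


@dataclasses.dataclass(frozen=True)
class TransientIndicators:
    """Initial slope E, output gap F, and the two nonzero (real) eigenvalues."""

    E: float
    F: float
    lambda1: float  # larger (closer to zero)
    lambda2: float  # smaller (more negative)

    @property
    def simple_overshoot_criterion(self) -> float:
        """``E + lambda_2 F``: positive iff the response shows simple overshoot
        (valid in the real-eigenvalue regime J <= beta)."""
        return self.E + self.lambda2 * self.F


def _nonzero_eigs(Q: GeneratorMatrix) -> np.ndarray:
    lams = np.linalg.eigvals(Q.rates)
    k0 = int(np.argmin(np.abs(lams)))
    return np.delete(lams, k0)


def transient_indicators(
    p: ThreeStateParams,
    pi0: Sequence[float],
    g: Sequence[float],
) -> TransientIndicators:
    """Evaluate E = phi'(0), F = phi_inf - phi_0 and the nonzero eigenvalues.

    Only meaningful in the real-eigenvalue regime; raises when J > beta.
    """
    beta = beta_critical(p)
    if p.J > beta + 1e-12 * max(1.0, beta):
        raise ValueError(
            f"J={p.J} > beta={beta}: eigenvalues complex, E + lambda2 F criterion inapplicable"
        )
    pi = as_probability(pi0)
    gv = as_observable(g)
    Q = build_three_state_Q(p)
    E = float(pi @ Q.rates @ gv)
    F = float(p.mu @ gv - pi @ gv)
    lam = np.sort(np.real(_nonzero_eigs(Q)))  # ascending: lam[0] <= lam[1]
    return TransientIndicators(E=E, F=F, lambda1=float(lam[1]), lambda2=float(lam[0]))


@dataclasses.dataclass(frozen=True)
class CriticalFluxes:
    """Critical fluxes of the phase diagram in J.

    ``phase(J)`` is NON for J <= alpha_flux, SIMPLE for
    alpha_flux < J <= beta, OSCILLATORY for J > beta.  ``alpha_reached`` is
    False when the overshoot criterion stays negative up to the end of the
    real-eigenvalue/feasible range, i.e. the NON phase is never left there.
    """

    beta: float
    alpha_flux: float
    alpha_reached: bool = True


def alpha_flux_critical(
    p: ThreeStateParams,
    pi0: Sequence[float],
    g: Sequence[float],
    *,
    n_bracket: int = 200,
) -> tuple[float, bool]:
    """Critical flux for overshoot onset: root of ``E(J) + lambda_2(J) F = 0``.

    Searched on ``[0, min(beta, min(a,b,c))]`` by bracketing on an
    ``n_bracket``-point grid then Brent refinement (relative 1e-10); grid
    ties resolve to the lower J.  Returns ``(0, True)`` when the criterion
    is already positive at J = 0 (overshoot exists in equilibrium) and
    ``(J_hi, False)`` when it never turns positive on the searched range.
    """
    beta = beta_critical(p)
    J_hi = min(beta, p.J_max)

    def h(J: float) -> float:
        return transient_indicators(p.with_flux(J), pi0, g).simple_overshoot_criterion

    # positivity threshold: a trivial response (pi = mu gives E = F = 0 up to
    # roundoff) must not register as an overshoot onset
    ti0 = transient_indicators(p.with_flux(0.0), pi0, g)
    g_span = float(np.ptp(np.asarray(g, dtype=float)))
    tol = 1e-12 * max(abs(ti0.lambda2) * max(g_span, 1.0), 1.0)
    if h(0.0) > tol:
        return 0.0, True
    if J_hi == 0:
        return 0.0, False
    grid = np.linspace(0.0, J_hi, n_bracket)
    vals = np.array([h(J) for J in grid])
    pos = np.nonzero(vals > tol)[0]
    if pos.size == 0:
        return float(J_hi), False
    k = int(pos[0])
    root = optimize.brentq(h, grid[k - 1], grid[k], xtol=1e-30, rtol=1e-12)
    return float(root), True


def critical_fluxes(
    p: ThreeStateParams,
    pi0: Sequence[float],
    g: Sequence[float],
) -> CriticalFluxes:
    """Both critical fluxes of the phase diagram for a given (pi, g)."""
    beta = beta_critical(p)
    alpha, reached = alpha_flux_critical(p, pi0, g)
    return CriticalFluxes(beta=beta, alpha_flux=alpha, alpha_reached=reached)


def sweep_flux(
    p: ThreeStateParams,
    pi0: Sequence[float],
    g: Sequence[float],
    J_grid: Sequence[float],
) -> pd.DataFrame:
    """Step-response summary along a grid of net fluxes.

    ``phi_0`` and ``phi_inf`` depend only on (pi, mu, g) and stay constant
    along the sweep; the peak output and the efficiency eta are
    nondecreasing in J over the overshoot regime.
    """
    rows = []
    for J in J_grid:
        pj = p.with_flux(float(J))
        Q = build_three_state_Q(pj)
        resp = spectral_response(Q, pi0, g)
        peak = ovs.find_peak(resp)
        phase = ovs.classify_phase(resp)
        met = ovs.adaptation_metrics(
            resp.phi0, peak.phi_peak, resp.phi_inf, t_peak=peak.t_peak, phase=phase
        )
        lam = _nonzero_eigs(Q)
        lam = lam[np.argsort(lam.real)[::-1]]  # lambda1 first (larger real part)
        rows.append(
            {
                "J": float(J),
                "phi0": resp.phi0,
                "phi_peak": peak.phi_peak,
                "t_peak": peak.t_peak,
                "phi_inf": resp.phi_inf,
                "eta": met.eta,
                "phase": phase.value,
                "lambda1_re": lam[0].real,
                "lambda1_im": lam[0].imag,
                "lambda2_re": lam[1].real,
                "lambda2_im": lam[1].imag,
            }
        )
    return pd.DataFrame(rows)


@dataclasses.dataclass(frozen=True)
class ReducedModel:
    """Effective slow dynamics after quasi-steady-state elimination."""

    Q: GeneratorMatrix
    pi: np.ndarray
    g: np.ndarray
    slow_states: tuple[int, ...]
    timescale_ratio: float


def eliminate_fast_state(
    Q: GeneratorMatrix,
    fast_state: int,
    pi0: Sequence[float],
    g: Sequence[float],
    *,
    min_ratio: float = 100.0,
) -> ReducedModel:
    """Quasi-steady-state elimination of one fast state from any generator.

    The fast state's probability is slaved to the slow states,
    ``p_f = sum_i p_i q_if / (-q_ff)``, giving effective slow-state rates
    ``q~_ij = q_ij + q_if q_fj / (-q_ff)`` (a proper generator), an initial
    distribution that redistributes the fast state's mass by its jump
    probabilities, and an effective observable
    ``g~_i = g_i + g_f q_if / (-q_ff)``.  Accurate to O(1/ratio) once the
    fast state has relaxed; a warning is issued below ``min_ratio``.
    """
    f = int(fast_state)
    pi = as_probability(pi0)
    gv = as_observable(g)
    A = Q.rates
    slow = [i for i in range(Q.n) if i != f]
    exit_f = -A[f, f]
    exit_slow = max(-A[i, i] for i in slow)
    ratio = exit_f / exit_slow if exit_slow > 0 else math.inf
    if ratio < min_ratio:
        warnings.warn(
            f"time-scale ratio {ratio:.3g} < {min_ratio}: "
            "fast-state elimination accuracy not guaranteed",
            stacklevel=2,
        )
    w = A[slow, f] / exit_f  # slaving weights of the fast state
    A_red = A[np.ix_(slow, slow)] + np.outer(A[slow, f], A[f, slow]) / exit_f
    jump = A[f, slow] / exit_f  # fast state's exit distribution
    pi_red = pi[slow] + pi[f] * jump
    g_red = gv[slow] + gv[f] * w
    Q_red = validate_generator(A_red, [Q.labels[i] for i in slow])
    return ReducedModel(
        Q=Q_red,
        pi=as_probability(pi_red),
        g=g_red,
        slow_states=tuple(slow),
        timescale_ratio=float(ratio),
    )


def fast_state_reduction(
    p: ThreeStateParams,
    fast_state: int,
    pi0: Sequence[float],
    g: Sequence[float],
    *,
    min_ratio: float = 100.0,
) -> ReducedModel:
    """Two-state effective dynamics of a three-state cycle with one fast state."""
    Q = build_three_state_Q(p)
    return eliminate_fast_state(Q, fast_state, pi0, g, min_ratio=min_ratio)
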