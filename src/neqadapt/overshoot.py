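"""Peak detection, overshoot phase classification and adaptation metrics.

A step increase of the input drives the output ``phi(t)`` from its initial
value ``phi_0`` toward a new steady value ``phi_inf``.  The response
*overshoots* when ``phi(t)`` transiently exceeds both; it is *simple* when
the contributing modes are real (one rise, one monotone return) and
*oscillatory* when conjugate complex modes ring around the plateau.  A
two-state system has a single exponential mode and can never overshoot.

Adaptation performance for a step from ``I0`` to ``I1`` is quantified by

    sensitivity  gamma = [(phi_peak - phi_0)/phi_0] / [(I1 - I0)/I0]
    error        eps   = [(phi_inf  - phi_0)/phi_0] / [(I1 - I0)/I0]
    accuracy     delta = 1/eps
    efficiency   eta   = 1 - eps/gamma = (phi_peak - phi_inf)/(phi_peak - phi_0)

``eta`` lies in [0, 1] and, unlike gamma and eps, does not depend on the
input levels, so it is defined for any overshooting response.
"""

from __future__ import annotations

import dataclasses
import enum
import math

import numpy as np
from scipy import optimize

from .markov import (
    SpectralResponse,
    default_time_grid,
    is_complex_eigenvalue,
    output_trajectory,
)

__all__ = [
    "Phase",
    "StepProtocol",
    "PeakResult",
    "AdaptationMetrics",
    "check_response_preconditions",
    "find_peak",
    "classify_phase",
    "adaptation_metrics",
]

# Overshoot requires phi_peak > max(phi0, phi_inf) strictly; the margin
# guards the strict inequality against floating-point roundoff.
OVERSHOOT_REL = 1e-9
OVERSHOOT_ABS = 1e-12


class Phase(str, enum.Enum):
    NON = "NON"
    SIMPLE = "SIMPLE"
    OSCILLATORY = "OSCILLATORY"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclasses.dataclass(frozen=True)
class StepProtocol:
    """Step input protocol: the input jumps from ``I0`` to ``I1`` at t = 0."""

    I0: float
    I1: float

    def __post_init__(self) -> None:
        if not (self.I1 > self.I0 > 0):
            raise ValueError("step protocol requires I1 > I0 > 0")

    @property
    def relative_step(self) -> float:
        return (self.I1 - self.I0) / self.I0


def check_response_preconditions(resp: SpectralResponse) -> dict[str, bool]:
    """Flags for the standing assumptions phi'(0) > 0 and phi_inf >= phi_0.

    The initial slope is evaluated analytically (``pi Q g``, equivalently
    the coefficient-weighted eigenvalue sum); nothing is enforced.
    """
    slope = resp.slope0()
    tol = 1e-12 * max(1.0, resp.output_scale)
    return {
        "slope0_positive": bool(slope > 0),
        "steady_ge_initial": bool(resp.phi_inf >= resp.phi0 - tol),
    }


@dataclasses.dataclass(frozen=True)
class PeakResult:
    t_peak: float
    phi_peak: float
    interior: bool  # False when phi is monotone and the "peak" is the t->inf plateau


def _phi_deriv(resp: SpectralResponse, t: float) -> float:
    lam = resp.eigenvalues[:-1]
    c = resp.coefficients[:-1]
    return float(np.real(np.sum(c * lam * np.exp(lam * t))))


def find_peak(resp: SpectralResponse, n_grid: int = 2000) -> PeakResult:
    """Global maximum of ``phi(t)`` on t in (0, inf).

    Sign changes of ``phi'(t)`` are bracketed on a dense log grid (augmented
    with linear coverage of the first oscillation periods when complex modes
    are present) and refined by Brent root finding; candidate maxima are
    compared and ties broken toward the earliest time.  A monotone response
    yields ``interior=False`` with the plateau value ``phi_inf``.
    """
    grid = default_time_grid(resp, n_grid)
    modes = [] if resp.defective else resp.damped_modes()
    if modes:
        # make sure several periods of the slowest oscillation are resolved
        omega_min = min(m["omega"] for m in modes)
        t_osc = np.linspace(0.0, 6 * 2 * math.pi / omega_min, n_grid)[1:]
        grid = np.unique(np.concatenate([grid, t_osc]))

    if resp.defective:
        return _find_peak_sampled(resp, grid)

    ts = np.concatenate([[0.0], grid])
    lam = resp.eigenvalues[:-1]
    c = resp.coefficients[:-1]
    d = np.real(np.exp(np.outer(ts, lam)) @ (c * lam))
    candidates: list[tuple[float, float]] = []
    for k in range(len(ts) - 1):
        if d[k] > 0 and d[k + 1] <= 0:
            if d[k + 1] == 0:
                t_star = ts[k + 1]
            else:
                t_star = optimize.brentq(
                    lambda t: _phi_deriv(resp, t), ts[k], ts[k + 1],
                    xtol=1e-30, rtol=1e-12, maxiter=200,
                )
            candidates.append((t_star, float(output_trajectory(resp, t_star)[0])))
    if not candidates:
        return PeakResult(math.inf, resp.phi_inf, interior=False)
    # global max; ties (within roundoff) broken toward the earliest time
    best = max(candidates, key=lambda tp: tp[1])
    for t_star, val in candidates:
        if val >= best[1] * (1 - 1e-12) - 1e-15:
            best = (t_star, val)
            break
    return PeakResult(best[0], best[1], interior=True)


def _find_peak_sampled(resp: SpectralResponse, grid: np.ndarray) -> PeakResult:
    """Fallback peak search by dense sampling + golden-section refinement."""
    ts = np.concatenate([[0.0], grid])
    vals = output_trajectory(resp, ts)
    k = int(np.argmax(vals))
    if k == 0 or k == len(ts) - 1:
        return PeakResult(math.inf, resp.phi_inf, interior=False)
    res = optimize.minimize_scalar(
        lambda t: -output_trajectory(resp, t)[0],
        bounds=(ts[k - 1], ts[k + 1]),
        method="bounded",
        options={"xatol": 1e-12},
    )
    return PeakResult(float(res.x), float(-res.fun), interior=True)


def _has_overshoot(phi0: float, phi_inf: float, phi_peak: float) -> bool:
    base = max(phi0, phi_inf)
    return phi_peak > base * (1 + OVERSHOOT_REL) + OVERSHOOT_ABS


def classify_phase(
    resp: SpectralResponse,
    tol_coeff: float | None = None,
) -> Phase:
    """Classify the response as NON, SIMPLE or OSCILLATORY overshoot.

    OSCILLATORY requires at least one conjugate complex mode whose
    coefficient magnitude exceeds ``tol_coeff`` (default ``1e-12`` times the
    observable range: complex modes the observable is blind to do not make
    the *output* oscillatory) together with an interior peak exceeding both
    ``phi_0`` and ``phi_inf``; SIMPLE is an overshoot carried by real modes
    only; anything else - in particular every two-state response - is NON.
    """
    if tol_coeff is None:
        tol_coeff = 1e-12 * max(1.0, resp.output_scale)
    peak = find_peak(resp)
    overshoot = peak.interior and _has_overshoot(resp.phi0, resp.phi_inf, peak.phi_peak)
    if not overshoot:
        return Phase.NON
    if resp.defective:
        # no modal information: decide from trajectory ringing below phi_inf
        grid = default_time_grid(resp, 2000)
        vals = output_trajectory(resp, grid)
        after = vals[grid > peak.t_peak]
        tol = 1e-9 * max(1.0, resp.output_scale)
        return Phase.OSCILLATORY if np.any(after < resp.phi_inf - tol) else Phase.SIMPLE
    oscillatory = any(
        abs(c) > tol_coeff
        for lam, c in zip(resp.eigenvalues[:-1], resp.coefficients[:-1])
        if is_complex_eigenvalue(lam)
    )
    return Phase.OSCILLATORY if oscillatory else Phase.SIMPLE


@dataclasses.dataclass(frozen=True)
class AdaptationMetrics:
    """Scalar summary of a step response; undefined entries are ``None``."""

    phi0: float
    phi_peak: float
    t_peak: float
    phi_inf: float
    gamma: float | None
    epsilon: float | None
    delta: float | None
    eta: float | None
    phase: Phase

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["phase"] = self.phase.value
        return d


def adaptation_metrics(
    phi0: float,
    phi_peak: float,
    phi_inf: float,
    protocol: StepProtocol | None = None,
    *,
    t_peak: float = math.nan,
    phase: Phase = Phase.NON,
) -> AdaptationMetrics:
    """Compute gamma, eps, delta and eta from the three output levels.

    gamma/eps/delta need a step protocol and ``phi0 != 0`` (otherwise left
    ``None``); ``delta`` is ``inf`` at eps = 0 (perfect adaptation).  ``eta``
    is input-independent and defined whenever ``phi_peak > phi0``.
    """
    gamma = epsilon = delta = eta = None
    if protocol is not None and phi0 != 0:
        rel = protocol.relative_step
        gamma = ((phi_peak - phi0) / phi0) / rel
        epsilon = ((phi_inf - phi0) / phi0) / rel
        delta = math.inf if epsilon == 0 else 1.0 / epsilon
    if phi_peak > phi0:
        eta = (phi_peak - phi_inf) / (phi_peak - phi0)
    return AdaptationMetrics(
        phi0=phi0,
        phi_peak=phi_peak,
        t_peak=t_peak,
        phi_inf=phi_inf,
        gamma=gamma,
        epsilon=epsilon,
        delta=delta,
        eta=eta,
        phase=phase,
    )
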