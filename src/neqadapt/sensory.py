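"""Ten-state MCP receptor model of the E. coli chemotactic sensory system.

A methyl-accepting chemotaxis protein (MCP) receptor is described by its
activity ``a in {0, 1}`` and methylation level ``m in {0..4}``; the ten
states ``(a, m)`` form a two-row ladder.  Activity flips on the fast time
scale ``tau_a`` with rates set by the free-energy difference

    E(m, I) = e0 (m0 - m) + f(I),
    f(I) = kBT log[(1 + I/Ki) / (1 + I/Ka)],

between the inactive and active columns: the inactive -> active rate is
``exp(-E/2kBT)/tau_a`` and the reverse ``exp(+E/2kBT)/tau_a``.  (The sign
convention is fixed by the requirement, checked numerically in the test
suite, that the Kolmogorov cycle criterion yields equilibrium exactly at
``alpha = exp(e0/2kBT)``.)  Methylation moves along a row on the slow time
scale ``tau_m ~ 1/k + 1/l``: an active receptor methylates at rate
``alpha k`` and demethylates at rate ``k``; an inactive receptor methylates
at rate ``l`` and demethylates at rate ``alpha l``.  The drive parameter
``alpha`` encodes the chemical potential of the SAM-fueled
methylation/demethylation cycle; ``alpha < exp(e0/2)`` breaks detailed
balance and drives the ladder's four basic cycles.

The model output is the total inactive probability
``phi(t) = sum_m p_(0,m)(t)``; a step increase of the ligand level I makes
phi jump up on the tau_a scale and, when the drive is strong enough,
relax back down (adaptation).
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
import pandas as pd

from . import overshoot as ovs
from .markov import (
    GeneratorMatrix,
    SpectralResponse,
    count_complex_eigenvalues,
    spectral_response,
    stationary_distribution,
    validate_generator,
)

__all__ = [
    "SensoryParams",
    "N_METHYL",
    "state_index",
    "inactive_observable",
    "ligand_potential",
    "free_energy",
    "build_sensory_Q",
    "step_response",
    "scan_alpha",
    "default_alpha_grid",
    "critical_alpha_adaptation",
    "critical_alpha_oscillation",
]

N_METHYL = 5  # methylation levels m = 0..4 (four methylation sites)


@dataclasses.dataclass(frozen=True)
class SensoryParams:
    """MCP receptor model constants.

    Defaults are the standard parameter set for the E. coli chemoreceptor:
    methylation energy ``e0 = 2`` (kBT units), offset level ``m0 = 1``,
    ligand dissociation constants ``Ki = 18.2 uM`` (inactive) and
    ``Ka = 3000 uM`` (active), activity-switching time ``tau_a = 0.1 s``
    and methylation/demethylation base rates ``k = l = 0.01 /s`` (so the
    methylation cycle time is ``tau_m ~ 1/k + 1/l = 200 s``).  The drive
    ``alpha`` must lie in ``(0, exp(e0/2kBT)]``; the upper end is the
    equilibrium point and larger values would reverse the drive direction.
    """

    e0: float = 2.0
    m0: float = 1.0
    Ki: float = 18.2
    Ka: float = 3000.0
    kBT: float = 1.0
    tau_a: float = 0.1
    k: float = 0.01
    l: float = 0.01
    alpha_drive: float = 0.5

    def __post_init__(self) -> None:
        for name in ("e0", "m0", "Ki", "Ka", "kBT", "tau_a", "k", "l"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 < self.alpha_drive <= self.alpha_equilibrium * (1 + 1e-12)):
            raise ValueError(
                f"alpha_drive must lie in (0, exp(e0/2kBT) = {self.alpha_equilibrium:.6g}]"
            )

    @property
    def alpha_equilibrium(self) -> float:
        """Drive value at which every cycle satisfies detailed balance."""
        return math.exp(self.e0 / (2.0 * self.kBT))

    @property
    def tau_m(self) -> float:
        """Typical methylation-demethylation cycle time, 1/k + 1/l."""
        return 1.0 / self.k + 1.0 / self.l

    def with_alpha(self, alpha: float) -> "SensoryParams":
        return dataclasses.replace(self, alpha_drive=alpha)


def state_index(a: int, m: int) -> int:
    """Flat index of receptor state (activity a, methylation m): 5a + m."""
    if a not in (0, 1):
        raise ValueError("activity must be 0 or 1")
    if not 0 <= m < N_METHYL:
        raise ValueError(f"methylation level must be in 0..{N_METHYL - 1}")
    return N_METHYL * a + m


def inactive_observable() -> np.ndarray:
    """Observable selecting the five inactive states: phi = total inactive probability."""
    g = np.zeros(2 * N_METHYL)
    g[:N_METHYL] = 1.0
    return g


def ligand_potential(I: float, p: SensoryParams) -> float:
    """Ligand-binding free-energy shift f(I) = kBT log[(1 + I/Ki)/(1 + I/Ka)].

    Zero at I = 0, increasing in I, saturating at ``kBT log(Ka/Ki)``.
    """
    if I < 0:
        raise ValueError("ligand concentration must be nonnegative")
    return p.kBT * math.log((1.0 + I / p.Ki) / (1.0 + I / p.Ka))


def free_energy(m: int, I: float, p: SensoryParams) -> float:
    """Free-energy difference E(m, I) = e0 (m0 - m) + f(I) between the
    inactive and active state at methylation level m (kBT units)."""
    if not 0 <= m < N_METHYL:
        raise ValueError(f"methylation level must be in 0..{N_METHYL - 1}")
    return p.e0 * (p.m0 - m) + ligand_potential(I, p)


def build_sensory_Q(p: SensoryParams, I: float) -> GeneratorMatrix:
    """Assemble the 10-state ladder generator at ligand concentration I.

    Vertical edges (activity flips) carry rates ``exp(-E/2kBT)/tau_a``
    (inactive -> active) and ``exp(+E/2kBT)/tau_a`` (active -> inactive).
    Horizontal edges: active row methylation ``alpha k`` / demethylation
    ``k``; inactive row methylation ``l`` / demethylation ``alpha l``.
    Boundary levels m = 0 (no demethylation) and m = 4 (no methylation)
    terminate the ladder; there is no wraparound.
    """
    n = 2 * N_METHYL
    A = np.zeros((n, n))
    al = p.alpha_drive
    for m in range(N_METHYL):
        E = free_energy(m, I, p)
        A[state_index(0, m), state_index(1, m)] = math.exp(-E / (2 * p.kBT)) / p.tau_a
        A[state_index(1, m), state_index(0, m)] = math.exp(+E / (2 * p.kBT)) / p.tau_a
    for m in range(N_METHYL - 1):
        A[state_index(1, m), state_index(1, m + 1)] = al * p.k  # active methylation
        A[state_index(1, m + 1), state_index(1, m)] = p.k  # active demethylation
        A[state_index(0, m), state_index(0, m + 1)] = p.l  # inactive methylation
        A[state_index(0, m + 1), state_index(0, m)] = al * p.l  # inactive demethylation
    np.fill_diagonal(A, 0.0)
    np.fill_diagonal(A, -A.sum(axis=1))
    labels = [f"a{a}m{m}" for a in (0, 1) for m in range(N_METHYL)]
    return validate_generator(A, labels)


def step_response(
    p: SensoryParams,
    I0: float,
    I1: float,
) -> tuple[SpectralResponse, ovs.AdaptationMetrics]:
    """Response of the inactive probability to a ligand step I0 -> I1.

    The initial distribution is stationary under the pre-step generator
    Q(I0); the system then evolves under Q(I1); the output observable is 1
    on the five inactive states.  Metrics use the (I0, I1) protocol when
    the step is a strict increase.
    """
    if I1 < I0:
        raise ValueError("step_response expects a step increase, I1 >= I0")
    pi = stationary_distribution(build_sensory_Q(p, I0))
    Q1 = build_sensory_Q(p, I1)
    resp = spectral_response(Q1, pi, inactive_observable())
    peak = ovs.find_peak(resp)
    phase = ovs.classify_phase(resp)
    protocol = ovs.StepProtocol(I0, I1) if I1 > I0 else None
    met = ovs.adaptation_metrics(
        resp.phi0, peak.phi_peak, resp.phi_inf, protocol,
        t_peak=peak.t_peak, phase=phase,
    )
    return resp, met


def default_alpha_grid(p: SensoryParams, step: float = 0.01) -> np.ndarray:
    """Drive grid 0.01-steps over (0, exp(e0/2kBT)]."""
    n = int(math.floor(p.alpha_equilibrium / step + 1e-9))
    return np.round(np.arange(1, n + 1) * step, 10)


def scan_alpha(
    p: SensoryParams,
    I0: float,
    I1: float,
    alpha_grid: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Step-response summary along a grid of drive values.

    For each alpha the row records the phase label, the number of complex
    eigenvalues of the post-step generator Q(I1) (the generator that sets
    the response shape), and the adaptation metrics.  As alpha decreases
    (stronger drive) the efficiency and sensitivity rise, the error falls,
    and the phase can only move NON -> SIMPLE -> OSCILLATORY.
    """
    if alpha_grid is None:
        alpha_grid = default_alpha_grid(p)
    rows = []
    for al in alpha_grid:
        pa = p.with_alpha(float(al))
        n_cplx = count_complex_eigenvalues(build_sensory_Q(pa, I1))
        _, met = step_response(pa, I0, I1)
        rows.append(
            {
                "alpha": float(al),
                "phase": met.phase.value,
                "n_complex": n_cplx,
                "gamma": met.gamma,
                "epsilon": met.epsilon,
                "delta": met.delta,
                "eta": met.eta,
            }
        )
    return pd.DataFrame(rows)


def critical_alpha_adaptation(scan: pd.DataFrame) -> float:
    """Boundary between adaptation and non-adaptation on a scanned grid.

    Reported as the smallest grid alpha whose response shows no overshoot
    (the phase is NON from there up to the equilibrium point).
    """
    non = scan.loc[scan["phase"] == ovs.Phase.NON.value, "alpha"]
    if non.empty:
        raise ValueError("no non-adapting response on the scanned grid")
    return float(non.min())


def critical_alpha_oscillation(scan: pd.DataFrame) -> float:
    """Boundary between simple and oscillatory adaptation on a scanned grid.

    Reported as the largest grid alpha classified OSCILLATORY.
    """
    osc = scan.loc[scan["phase"] == ovs.Phase.OSCILLATORY.value, "alpha"]
    if osc.empty:
        raise ValueError("no oscillatory response on the scanned grid")
    return float(osc.max())
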