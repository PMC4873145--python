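"""Generator matrices, stationary distributions and spectral response.

A continuous-time Markov jump process on ``N`` states is specified by a
generator matrix ``Q`` whose off-diagonal entry ``q_ij`` is the transition
rate from state ``i`` to state ``j`` and whose rows sum to zero.  The
probability row vector evolves by the master equation ``dp/dt = p Q``, so
``p(t) = pi @ expm(Q t)``.  For an observable ``g`` the scalar output is
``phi(t) = p(t) @ g``; when the spectrum of ``Q`` is simple this output is a
finite sum of exponential modes

    phi(t) = phi_inf + sum_i c_i exp(lambda_i t),

with exactly one eigenvalue equal to zero (Perron-Frobenius) and all other
eigenvalues in the open left half plane.  Complex eigenvalues come in
conjugate pairs; each pair contributes a damped cosine
``2|c| exp(-decay t) cos(omega t + phase)`` to the output.

This module validates generators, computes stationary distributions and the
spectral decomposition of the output, measures stationary edge fluxes and
detailed balance, and evaluates the Dmitriev-Dynkin-Karpelevich (DDK) bound
``decay/|omega| >= tan(pi/N)`` satisfied by every complex eigenvalue pair of
an N-state generator.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import networkx as nx
import numpy as np
from scipy import linalg as sla

__all__ = [
    "GeneratorMatrix",
    "SpectralResponse",
    "DetailedBalanceResult",
    "DDKResult",
    "IM_TOL_REL",
    "validate_generator",
    "as_probability",
    "as_observable",
    "stationary_distribution",
    "spectral_response",
    "output_trajectory",
    "default_time_grid",
    "edge_fluxes",
    "is_detailed_balanced",
    "reversible_spectrum_check",
    "ddk_bound",
    "count_complex_eigenvalues",
    "is_complex_eigenvalue",
]

# An eigenvalue is treated as genuinely complex iff |Im| > IM_TOL_REL * max(1, |lambda|).
# Numerical eig noise on matrices with a provably real spectrum is ~1e-13.
IM_TOL_REL = 1e-9

# Pairwise eigenvalue gaps below DEGENERACY_REL * spectral radius abort the
# modal construction; trajectory work then uses matrix-exponential propagation.
DEGENERACY_REL = 1e-8


@dataclasses.dataclass(frozen=True)
class GeneratorMatrix:
    """Validated transition-rate matrix of a Markov jump process.

    Attributes
    ----------
    rates : (N, N) ndarray
        Off-diagonal entries are nonnegative transition rates (1/time);
        each row sums to zero.
    labels : tuple of str
        State names, one per row.
    """

    rates: np.ndarray
    labels: tuple[str, ...]

    @property
    def n(self) -> int:
        return self.rates.shape[0]

    def __post_init__(self) -> None:
        object.__setattr__(self, "rates", np.asarray(self.rates, dtype=float))


def validate_generator(
    rates: np.ndarray | Sequence[Sequence[float]],
    labels: Sequence[str] | None = None,
    *,
    row_sum_rtol: float = 1e-12,
) -> GeneratorMatrix:
    """Check generator-matrix invariants and return a :class:`GeneratorMatrix`.

    Raises ``ValueError`` for a non-square matrix, fewer than two states,
    negative off-diagonal entries, or row sums that are not zero to within
    ``row_sum_rtol`` times the largest entry magnitude.
    """
    A = np.asarray(rates, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError(f"generator must be square, got shape {A.shape}")
    n = A.shape[0]
    if n < 2:
        raise ValueError("generator needs at least 2 states")
    if not np.all(np.isfinite(A)):
        raise ValueError("generator entries must be finite")
    off = A.copy()
    np.fill_diagonal(off, 0.0)
    if np.any(off < 0):
        i, j = np.argwhere(off < 0)[0]
        raise ValueError(f"negative off-diagonal rate q[{i},{j}] = {A[i, j]}")
    scale = max(1.0, float(np.abs(A).max()))
    row_sums = A.sum(axis=1)
    if np.any(np.abs(row_sums) > row_sum_rtol * scale):
        i = int(np.argmax(np.abs(row_sums)))
        raise ValueError(f"row {i} sums to {row_sums[i]!r}, not 0")
    if labels is None:
        labels = tuple(str(i) for i in range(n))
    else:
        labels = tuple(str(x) for x in labels)
        if len(labels) != n:
            raise ValueError("label count does not match matrix size")
    return GeneratorMatrix(A, labels)


def as_probability(weights: Sequence[float], *, tol: float = 1e-12) -> np.ndarray:
    """Validate a probability vector: nonnegative entries summing to one."""
    p = np.asarray(weights, dtype=float)
    if p.ndim != 1:
        raise ValueError("probability vector must be one-dimensional")
    if np.any(p < -tol):
        raise ValueError("probability vector has negative entries")
    s = p.sum()
    if abs(s - 1.0) > max(tol, 1e-12 * p.size):
        raise ValueError(f"probabilities sum to {s}, not 1")
    return np.clip(p, 0.0, None) / p.sum()


def as_observable(values: Sequence[float]) -> np.ndarray:
    """Validate an observable vector (finite real entries)."""
    g = np.asarray(values, dtype=float)
    if g.ndim != 1:
        raise ValueError("observable must be one-dimensional")
    if not np.all(np.isfinite(g)):
        raise ValueError("observable entries must be finite")
    return g


def _support_digraph(Q: GeneratorMatrix) -> nx.DiGraph:
    G = nx.DiGraph()
    G.add_nodes_from(range(Q.n))
    for i in range(Q.n):
        for j in range(Q.n):
            if i != j and Q.rates[i, j] > 0:
                G.add_edge(i, j)
    return G


def _check_irreducible(Q: GeneratorMatrix) -> None:
    G = _support_digraph(Q)
    comps = list(nx.strongly_connected_components(G))
    if len(comps) > 1:
        named = [sorted(Q.labels[i] for i in comp) for comp in comps]
        raise ValueError(
            "generator is reducible; strongly connected components: "
            + "; ".join("{" + ", ".join(c) + "}" for c in named)
        )


def stationary_distribution(Q: GeneratorMatrix) -> np.ndarray:
    """Unique stationary distribution ``mu`` with ``mu Q = 0``.

    Computed from the null space of ``Q^T`` (exact linear algebra, not
    long-time integration).  Requires an irreducible chain; a reducible
    generator raises ``ValueError`` naming the disconnected state groups.
    """
    _check_irreducible(Q)
    ns = sla.null_space(Q.rates.T)
    if ns.shape[1] != 1:  # pragma: no cover - excluded by irreducibility
        raise ValueError("stationary distribution is not unique")
    mu = ns[:, 0]
    mu = mu / mu.sum()
    if np.any(mu <= 0):
        raise ValueError("stationary distribution has non-positive entries")
    return mu


@dataclasses.dataclass
class SpectralResponse:
    """Modal decomposition of the output ``phi(t) = pi @ expm(Q t) @ g``.

    ``eigenvalues[-1]`` is exactly 0 by convention and ``coefficients[-1]``
    equals the steady output ``phi_inf = mu @ g``.  If the spectrum is too
    close to degenerate for a stable modal construction, ``defective`` is
    True and trajectory evaluation falls back to matrix-exponential
    propagation of the stored generator.
    """

    eigenvalues: np.ndarray  # complex, zero eigenvalue last
    coefficients: np.ndarray  # complex, steady output last
    steady_output: float
    phi0: float
    output_scale: float  # max(g) - min(g), used for tolerance scaling
    defective: bool = False
    # retained for propagation and diagnostics
    Q: GeneratorMatrix | None = None
    pi: np.ndarray | None = None
    g: np.ndarray | None = None

    @property
    def phi_inf(self) -> float:
        return self.steady_output

    @property
    def decay_modes(self) -> np.ndarray:
        """Nonzero eigenvalues (all with negative real part)."""
        return self.eigenvalues[:-1]

    def slope0(self) -> float:
        """Initial output slope ``phi'(0) = pi Q g``."""
        if self.Q is not None:
            return float(self.pi @ self.Q.rates @ self.g)
        return float(np.real(np.sum(self.coefficients[:-1] * self.eigenvalues[:-1])))

    def damped_modes(self, tol_rel: float = IM_TOL_REL) -> list[dict]:
        """Damped-cosine parameters for each conjugate eigenvalue pair.

        Each pair ``-decay +/- i omega`` with coefficient ``c`` contributes
        ``2 |c| exp(-decay t) cos(omega t + phase)``; one record per pair
        (the ``omega > 0`` member), with keys decay, omega, amplitude, phase.
        """
        out = []
        for lam, c in zip(self.eigenvalues[:-1], self.coefficients[:-1]):
            if is_complex_eigenvalue(lam, tol_rel) and lam.imag > 0:
                out.append(
                    {
                        "decay": -lam.real,
                        "omega": lam.imag,
                        "amplitude": 2.0 * abs(c),
                        "phase": float(np.angle(c)),
                    }
                )
        return out

    def __call__(self, times: np.ndarray | float) -> np.ndarray:
        return output_trajectory(self, times)


def is_complex_eigenvalue(lam: complex, tol_rel: float = IM_TOL_REL) -> bool:
    """Module-wide rule separating genuine complex modes from eig noise."""
    return abs(lam.imag) > tol_rel * max(1.0, abs(lam))


def count_complex_eigenvalues(Q: GeneratorMatrix, tol_rel: float = IM_TOL_REL) -> int:
    """Number of eigenvalues of ``Q`` with nonnegligible imaginary part."""
    lams = np.linalg.eigvals(Q.rates)
    return int(sum(is_complex_eigenvalue(l, tol_rel) for l in lams))


def spectral_response(
    Q: GeneratorMatrix,
    pi0: Sequence[float],
    g: Sequence[float],
) -> SpectralResponse:
    """Decompose the output of ``Q`` started from ``pi0`` into exponential modes.

    The coefficients are ``c_i = (pi V)_i (V^{-1} g)_i`` where ``Q = V L V^{-1}``
    is the eigendecomposition; the eigenvalue of minimum modulus is snapped to
    zero and placed last, its coefficient being the steady output.  If the
    smallest pairwise eigenvalue gap is below ``DEGENERACY_REL`` times the
    spectral radius the modal form is unreliable and the response is flagged
    ``defective``; trajectory evaluation then uses ``expm`` directly.
    """
    pi = as_probability(pi0)
    gv = as_observable(g)
    if pi.size != Q.n or gv.size != Q.n:
        raise ValueError("dimension mismatch between Q, pi0 and g")
    _check_irreducible(Q)

    lams, V = np.linalg.eig(Q.rates)
    # snap the (unique) eigenvalue of minimal modulus to exactly zero
    k0 = int(np.argmin(np.abs(lams)))
    lams[k0] = 0.0

    mu = stationary_distribution(Q)
    phi_inf = float(mu @ gv)
    phi0 = float(pi @ gv)
    scale = float(gv.max() - gv.min())

    radius = float(np.abs(lams).max())
    gap = np.inf
    for i in range(len(lams)):
        for j in range(i + 1, len(lams)):
            gap = min(gap, abs(lams[i] - lams[j]))
    if radius > 0 and gap < DEGENERACY_REL * radius:
        return SpectralResponse(
            eigenvalues=np.append(lams[np.arange(len(lams)) != k0], 0.0),
            coefficients=np.full(Q.n, np.nan, dtype=complex),
            steady_output=phi_inf,
            phi0=phi0,
            output_scale=scale,
            defective=True,
            Q=Q,
            pi=pi,
            g=gv,
        )

    coeff = (pi @ V) * np.linalg.solve(V, gv.astype(complex))
    order = [i for i in range(Q.n) if i != k0] + [k0]
    lams = lams[order]
    coeff = coeff[order]
    # the zero mode carries the steady output exactly
    coeff[-1] = phi_inf

    resp = SpectralResponse(
        eigenvalues=lams,
        coefficients=coeff,
        steady_output=phi_inf,
        phi0=phi0,
        output_scale=scale,
        defective=False,
        Q=Q,
        pi=pi,
        g=gv,
    )
    recon0 = float(np.real(coeff.sum()))
    if abs(recon0 - phi0) > 1e-10 * max(1.0, abs(phi0), scale):
        raise ArithmeticError(
            f"spectral decomposition inconsistent at t=0: {recon0} vs {phi0}"
        )
    return resp


def output_trajectory(resp: SpectralResponse, times: np.ndarray | float) -> np.ndarray:
    """Evaluate ``phi(t)`` on nonnegative times.

    Uses the modal sum when available; a defective response propagates the
    stored generator with ``scipy.linalg.expm``.  Imaginary residue below
    1e-10 (relative to the output scale) is discarded; larger residue raises.
    """
    t = np.atleast_1d(np.asarray(times, dtype=float))
    if np.any(t < 0):
        raise ValueError("times must be nonnegative")
    if resp.defective:
        vals = np.array(
            [float(resp.pi @ sla.expm(resp.Q.rates * ti) @ resp.g) for ti in t]
        )
        return vals if np.ndim(times) else vals
    phase = np.exp(np.outer(t, resp.eigenvalues))
    vals_c = phase @ resp.coefficients
    resid = float(np.abs(vals_c.imag).max()) if vals_c.size else 0.0
    if resid > 1e-10 * max(1.0, resp.output_scale):
        raise ArithmeticError(f"imaginary residue {resid} in output trajectory")
    return vals_c.real


def default_time_grid(resp: SpectralResponse, n: int = 400) -> np.ndarray:
    """Log-spaced grid resolving both the response and relaxation time scales.

    Runs from ``1e-3 * t_fast`` to ``20 * t_slow`` where ``t_fast``/``t_slow``
    are the inverse largest/smallest nonzero decay rates.
    """
    re = np.abs(np.real(resp.eigenvalues))
    re = re[re > 0]
    if re.size == 0:
        return np.linspace(0.0, 1.0, n)
    t_fast = 1.0 / re.max()
    t_slow = 1.0 / re.min()
    return np.geomspace(1e-3 * t_fast, 20.0 * t_slow, n)


def edge_fluxes(
    Q: GeneratorMatrix,
    mu: Sequence[float] | None = None,
    *,
    tol: float = 1e-8,
) -> np.ndarray:
    """Stationary net probability fluxes ``J_ij = mu_i q_ij - mu_j q_ji``.

    ``mu`` defaults to the stationary distribution of ``Q``; a supplied
    ``mu`` is checked for stationarity (``||mu Q|| <= tol`` relative to the
    largest rate) and rejected otherwise.  The result is antisymmetric; for a
    single-cycle three-state chain all cycle edges carry a common flux J.
    """
    if mu is None:
        m = stationary_distribution(Q)
    else:
        m = as_probability(mu)
        scale = max(1.0, float(np.abs(Q.rates).max()))
        resid = float(np.abs(m @ Q.rates).max())
        if resid > tol * scale:
            raise ValueError(f"mu is not stationary for Q (residual {resid})")
    return m[:, None] * Q.rates - (m[:, None] * Q.rates).T


@dataclasses.dataclass(frozen=True)
class DetailedBalanceResult:
    balanced: bool
    worst_cycle: tuple[int, ...] | None
    max_log_ratio: float  # |log(forward product / backward product)| on that cycle

    def __bool__(self) -> bool:
        return self.balanced


def is_detailed_balanced(Q: GeneratorMatrix, tol: float = 1e-9) -> DetailedBalanceResult:
    """Test the equilibrium (detailed balance) condition ``mu_i q_ij = mu_j q_ji``.

    Equivalently (Kolmogorov's criterion) the product of rates around every
    cycle equals the product around the reversed cycle.  The result reports
    the basis cycle of the transition graph with the largest absolute
    log-ratio of forward to backward rate products; an edge with no reverse
    rate makes that ratio infinite.
    """
    mu = stationary_distribution(Q)
    A = Q.rates
    viol = np.abs(mu[:, None] * A - (mu[:, None] * A).T)
    np.fill_diagonal(viol, 0.0)
    scale = max(1.0, float(np.abs(A).max()))
    balanced = bool(viol.max() <= tol * scale)

    G = nx.Graph()
    G.add_nodes_from(range(Q.n))
    for i in range(Q.n):
        for j in range(i + 1, Q.n):
            if A[i, j] > 0 or A[j, i] > 0:
                G.add_edge(i, j)
    worst_cycle: tuple[int, ...] | None = None
    worst = 0.0
    for cyc in nx.cycle_basis(G):
        log_ratio = 0.0
        for k in range(len(cyc)):
            i, j = cyc[k], cyc[(k + 1) % len(cyc)]
            fwd, bwd = A[i, j], A[j, i]
            if fwd <= 0 or bwd <= 0:
                log_ratio = math.inf
                break
            log_ratio += math.log(fwd) - math.log(bwd)
        if abs(log_ratio) > worst:
            worst = abs(log_ratio)
            worst_cycle = tuple(cyc)
    return DetailedBalanceResult(balanced, worst_cycle, worst)


def reversible_spectrum_check(Q: GeneratorMatrix, tol: float = 1e-9) -> bool:
    """Confirm a detailed-balanced generator has an all-real spectrum.

    Uses the similarity transform ``S_ij = sqrt(mu_i / mu_j) q_ij``: detailed
    balance makes S symmetric, so Q's spectrum is that of a symmetric matrix.
    Raises if called on a non-reversible generator.
    """
    db = is_detailed_balanced(Q)
    if not db.balanced:
        raise ValueError("reversible_spectrum_check requires a detailed-balanced Q")
    mu = stationary_distribution(Q)
    root = np.sqrt(mu)
    S = root[:, None] * Q.rates / root[None, :]
    if np.abs(S - S.T).max() > 1e-12 * max(1.0, np.abs(S).max()):
        raise AssertionError("symmetrized matrix is not symmetric under detailed balance")
    lams = np.linalg.eigvals(S)
    return bool(np.abs(lams.imag).max() <= tol * max(1.0, np.abs(lams).max()))


@dataclasses.dataclass(frozen=True)
class DDKResult:
    min_ratio: float  # min over conjugate pairs of decay/|omega|; inf if spectrum real
    bound: float  # tan(pi/N)
    satisfied: bool


def ddk_bound(Q: GeneratorMatrix, tol: float = 1e-9) -> DDKResult:
    """Dmitriev-Dynkin-Karpelevich bound on complex generator eigenvalues.

    Every conjugate pair ``-decay +/- i omega`` of an N-state generator obeys
    ``decay / |omega| >= tan(pi / N)``, with equality exactly for the uniform
    unidirectional cycle.  Returns the minimum ratio over complex pairs
    (``inf`` for a real spectrum) alongside the bound.
    """
    lams = np.linalg.eigvals(Q.rates)
    ratios = [
        -l.real / abs(l.imag)
        for l in lams
        if is_complex_eigenvalue(l) and l.imag > 0
    ]
    min_ratio = min(ratios) if ratios else math.inf
    bound = math.tan(math.pi / Q.n)
    return DDKResult(min_ratio, bound, min_ratio >= bound - tol)
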