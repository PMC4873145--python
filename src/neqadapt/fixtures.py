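"""Seeded random-model factory.

Every generator family here is reproducible from ``(kind, n, seed,
rate_scale)`` and exists so the property suites can run with no external
data: reversible chains (detailed-balanced by construction, hence all-real
spectra), uniform unidirectional cycles (the exact equality case of the DDK
bound), densely driven chains, and random three-state cycle
parametrizations with a feasible net flux.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .markov import GeneratorMatrix, validate_generator
from .three_state import ThreeStateParams, build_three_state_Q

__all__ = [
    "FixtureSpec",
    "make_fixture",
    "random_reversible_Q",
    "random_driven_Q",
    "random_cycle_params",
    "random_three_state",
    "uniform_cycle_Q",
]

KINDS = ("reversible", "driven", "three_state_cycle", "uniform_cycle")


@dataclasses.dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a reproducible random generator matrix."""

    kind: str
    n_states: int
    seed: int
    rate_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown fixture kind {self.kind!r}; choose from {KINDS}")
        if self.rate_scale <= 0:
            raise ValueError("rate_scale must be positive")


def make_fixture(spec: FixtureSpec) -> GeneratorMatrix:
    if spec.kind == "reversible":
        return random_reversible_Q(spec.n_states, spec.seed, spec.rate_scale)
    if spec.kind == "driven":
        return random_driven_Q(spec.n_states, spec.seed, spec.rate_scale)
    if spec.kind == "three_state_cycle":
        return random_three_state(spec.seed, spec.rate_scale)[1]
    return uniform_cycle_Q(spec.n_states, spec.rate_scale)


def random_reversible_Q(n: int, seed: int, rate_scale: float = 1.0) -> GeneratorMatrix:
    """Random detailed-balanced generator.

    Built from random positive stationary weights ``mu`` and symmetric edge
    conductances ``s_ij`` via ``q_ij = s_ij / mu_i``, which satisfies
    ``mu_i q_ij = mu_j q_ji`` identically; the spectrum is therefore real.
    """
    if n < 2:
        raise ValueError("need at least 2 states")
    rng = np.random.default_rng(seed)
    mu = rng.dirichlet(np.ones(n))
    S = rng.uniform(0.1, 1.0, size=(n, n)) * rate_scale
    S = (S + S.T) / 2.0
    A = S / mu[:, None]
    np.fill_diagonal(A, 0.0)
    np.fill_diagonal(A, -A.sum(axis=1))
    return validate_generator(A)


def random_driven_Q(n: int, seed: int, rate_scale: float = 1.0) -> GeneratorMatrix:
    """Random dense generator with independent off-diagonal rates.

    Generically breaks detailed balance; used to probe the DDK bound and
    trajectory-level invariants away from equilibrium.
    """
    if n < 2:
        raise ValueError("need at least 2 states")
    rng = np.random.default_rng(seed)
    A = rng.exponential(rate_scale, size=(n, n))
    np.fill_diagonal(A, 0.0)
    np.fill_diagonal(A, -A.sum(axis=1))
    return validate_generator(A)


def random_cycle_params(seed: int, rate_scale: float = 1.0) -> ThreeStateParams:
    """Random feasible three-state cycle parametrization.

    ``mu`` is a random simplex point (bounded away from the boundary),
    the edge sums a, b, c are random positive rates, and the net flux J is
    uniform on the feasible range ``[0, min(a, b, c)]``.
    """
    rng = np.random.default_rng(seed)
    mu = rng.dirichlet(np.ones(3))
    mu = (mu + 0.05) / (mu + 0.05).sum()  # keep all states populated
    a, b, c = rng.uniform(0.1, 2.0, size=3) * rate_scale
    J = rng.uniform(0.0, min(a, b, c))
    return ThreeStateParams(mu, float(a), float(b), float(c), float(J))


def random_three_state(
    seed: int, rate_scale: float = 1.0
) -> tuple[ThreeStateParams, GeneratorMatrix]:
    """Random three-state cycle generator together with its parametrization."""
    p = random_cycle_params(seed, rate_scale)
    return p, build_three_state_Q(p)


def uniform_cycle_Q(n: int, rate: float = 1.0) -> GeneratorMatrix:
    """Unidirectional n-cycle with a common forward rate and zero backward rates.

    Its eigenvalues are ``rate (exp(2 pi i k / n) - 1)``, so the complex
    pairs sit exactly on the DDK boundary ``decay/|omega| = tan(pi/n)``.
    """
    if n < 3:
        raise ValueError("a cycle needs at least 3 states")
    if rate <= 0:
        raise ValueError("rate must be positive")
    A = np.zeros((n, n))
    for i in range(n):
        A[i, (i + 1) % n] = rate
    np.fill_diagonal(A, -rate)
    return validate_generator(A)
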