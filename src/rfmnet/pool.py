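"""Networks of translating chains competing for a shared pool of free ribosomes.

Each of the ``m`` chains is an input/output ribosome flow model whose
effective initiation rate is ``lambda_0^i * G_i(z)``, where ``z`` is the
density of free ribosomes in the pool and ``G_i`` a strictly increasing
pool output function with ``G_i(0) = 0``.  Ribosomes exiting a chain
return to the pool, so the total density

    ``s = z + sum_i sum_j x_j^i``

is a first integral: trajectories evolve on its level sets, and each level
set contains exactly one equilibrium, which attracts every trajectory on it.

The equilibrium is found by a one-dimensional monotone root-find: for a
candidate pool density ``e_z``, each chain's steady state follows from the
spectral representation at input ``G_i(e_z)``, and the total density
``D(e_z) = e_z + sum of chain densities`` is continuous and strictly
increasing with ``D(0) = 0``, so ``D(e_z) = s`` has a unique root.

Identical chains are stored as a single group with a copy count, so a
network of 1e5 equal mRNAs costs the same per solver iteration as a single
chain.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .core import ChainEquilibrium, RateProfile, chain_vector_field, spectral_steady_state

__all__ = [
    "PoolFunction",
    "ChainGroup",
    "NetworkSpec",
    "NetworkState",
    "NetworkEquilibrium",
    "SimulationResult",
    "network_vector_field",
    "total_density",
    "simulate",
    "solve_equilibrium",
    "equilibrium_vs_copy_number",
]

_AUDIT_GRID_SIZE = 64


@dataclass(frozen=True)
class PoolFunction:
    """Pool output function ``G``: monotone, ``G(0) = 0``.

    ``G(z)`` scales a chain's initiation rate by the availability of free
    ribosomes.  Supported families: ``linear`` (``G(z) = c z``), ``tanh``
    (``G(z) = alpha * tanh(beta z)``) and ``custom`` (arbitrary callable,
    audited for strict monotonicity on a log-spaced grid at construction).
    ``derivative_at_zero`` is analytic for the built-in families and either
    supplied or forward-differenced for custom functions.
    """

    family: str
    params: tuple[tuple[str, float], ...]
    derivative_at_zero: float
    _fn: object = field(default=None, repr=False, compare=False)

    @classmethod
    def linear(cls, slope: float) -> "PoolFunction":
        if slope <= 0:
            raise ValueError(f"linear pool function needs slope > 0, got {slope}")
        return cls("linear", (("slope", float(slope)),), float(slope))

    @classmethod
    def tanh(cls, alpha: float, beta: float) -> "PoolFunction":
        if alpha <= 0 or beta <= 0:
            raise ValueError(f"tanh pool function needs alpha, beta > 0, got {alpha}, {beta}")
        return cls(
            "tanh",
            (("alpha", float(alpha)), ("beta", float(beta))),
            float(alpha * beta),
        )

    @classmethod
    def custom(
        cls,
        fn,
        derivative_at_zero: float | None = None,
        audit_upper: float = 10.0,
    ) -> "PoolFunction":
        """Wrap an arbitrary output function, enforcing the model's contract.

        The callable must satisfy ``fn(0) = 0`` and be strictly increasing;
        this is audited on a log-spaced grid over ``(0, audit_upper]``.  If
        ``derivative_at_zero`` is not given it is estimated by a forward
        difference with step ``1e-6 * audit_upper``.
        """
        if abs(fn(0.0)) > 1e-12:
            raise ValueError(f"custom pool function must satisfy G(0) = 0, got G(0) = {fn(0.0)}")
        grid = np.concatenate(([0.0], np.geomspace(1e-9 * audit_upper, audit_upper, _AUDIT_GRID_SIZE)))
        vals = np.array([fn(z) for z in grid])
        if np.any(np.diff(vals) <= 0):
            raise ValueError(
                "custom pool function is not strictly increasing on the audit grid "
                f"(0, {audit_upper}]"
            )
        if derivative_at_zero is None:
            h = 1e-6 * audit_upper
            derivative_at_zero = fn(h) / h
        if derivative_at_zero < 0:
            raise ValueError("derivative_at_zero must be nonnegative")
        return cls("custom", (), float(derivative_at_zero), fn)

    def __call__(self, z: float):
        if self.family == "linear":
            return dict(self.params)["slope"] * z
        if self.family == "tanh":
            p = dict(self.params)
            return p["alpha"] * np.tanh(p["beta"] * z)
        return self._fn(z)


@dataclass(frozen=True)
class ChainGroup:
    """``copies`` identical chains sharing a rate profile and pool function."""

    profile: RateProfile
    pool_fn: PoolFunction
    copies: int = 1

    def __post_init__(self) -> None:
        if self.copies < 1:
            raise ValueError(f"copies must be >= 1, got {self.copies}")


@dataclass(frozen=True)
class NetworkSpec:
    """A pool-coupled network: chain groups plus total ribosome density ``s``."""

    groups: tuple[ChainGroup, ...]
    s: float

    def __post_init__(self) -> None:
        if self.s <= 0 or not math.isfinite(self.s):
            raise ValueError(f"total density s must be finite and > 0, got {self.s}")

    @classmethod
    def from_chains(cls, chains, s: float) -> "NetworkSpec":
        """Build from an explicit list of ``(RateProfile, PoolFunction)`` pairs."""
        return cls(tuple(ChainGroup(p, g, 1) for p, g in chains), float(s))

    @classmethod
    def identical(cls, profile: RateProfile, pool_fn: PoolFunction, m: int, s: float) -> "NetworkSpec":
        """``m`` copies of one chain — the homogeneous competition setting."""
        return cls((ChainGroup(profile, pool_fn, m),), float(s))

    @property
    def m(self) -> int:
        """Total number of chains."""
        return sum(g.copies for g in self.groups)

    @property
    def chains(self) -> list[tuple[RateProfile, PoolFunction]]:
        """Flat per-chain view (avoid for very large copy counts)."""
        return [(g.profile, g.pool_fn) for g in self.groups for _ in range(g.copies)]


@dataclass
class NetworkState:
    """Pool density ``z`` plus the per-chain occupancy vectors."""

    z: float
    chain_states: list[np.ndarray]

    def __post_init__(self) -> None:
        if self.z < 0:
            raise ValueError(f"pool density must be >= 0, got {self.z}")
        self.chain_states = [np.asarray(x, dtype=float) for x in self.chain_states]


@dataclass(frozen=True)
class NetworkEquilibrium:
    """Network steady state, stored per group (one entry per distinct chain)."""

    e_z: float
    group_equilibria: tuple[ChainEquilibrium, ...]
    copies: tuple[int, ...]
    TPR: float
    q: float
    s: float

    @property
    def chain_equilibria(self) -> list[ChainEquilibrium]:
        """Flat per-chain view of the steady states."""
        return [eq for eq, c in zip(self.group_equilibria, self.copies) for _ in range(c)]

    @property
    def total_chain_density(self) -> float:
        return sum(c * eq.total_density for eq, c in zip(self.group_equilibria, self.copies))


@dataclass(frozen=True)
class SimulationResult:
    """Sampled trajectory of a network simulation plus its terminal state."""

    t: np.ndarray
    z: np.ndarray
    chain_trajectories: list[np.ndarray]  # one (len(t), n_i) array per chain
    terminal: NetworkState
    residual: float


def _expanded_profiles(spec: NetworkSpec) -> list[tuple[RateProfile, PoolFunction]]:
    chains = spec.chains
    if spec.m > 10_000:
        raise ValueError(
            f"refusing to expand {spec.m} chains for trajectory work; "
            "use solve_equilibrium, which exploits the group structure"
        )
    return chains


def network_vector_field(spec: NetworkSpec, state: NetworkState) -> tuple[float, list[np.ndarray]]:
    """Time derivative of ``(z, x^1, ..., x^m)``.

    Chain ``i`` is driven by input ``u_i = G_i(z)``; the pool collects every
    chain's exit flow and feeds every chain's initiation flow, so the
    component sum of the derivative is identically zero (the total density
    is conserved).
    """
    chains = _expanded_profiles(spec)
    if len(state.chain_states) != len(chains):
        raise ValueError(
            f"state has {len(state.chain_states)} chains, spec has {len(chains)}"
        )
    z = state.z
    z_dot = 0.0
    x_dots = []
    for (profile, pool_fn), x in zip(chains, state.chain_states):
        u = float(pool_fn(z))
        dx = chain_vector_field(profile, x, u)
        x_dots.append(dx)
        z_dot += profile.rates[-1] * x[-1]                # exit flow back to pool
        z_dot -= profile.lambda0 * u * (1.0 - x[0])       # initiation drain
    return z_dot, x_dots


def total_density(state: NetworkState) -> float:
    """First integral: pool density plus the sum of all site occupancies."""
    return float(state.z + sum(np.sum(x) for x in state.chain_states))


def _pack(state: NetworkState) -> np.ndarray:
    return np.concatenate([[state.z]] + [np.asarray(x) for x in state.chain_states])


def _unpack(spec: NetworkSpec, y: np.ndarray) -> NetworkState:
    chains = _expanded_profiles(spec)
    xs, k = [], 1
    for profile, _ in chains:
        xs.append(y[k:k + profile.n])
        k += profile.n
    return NetworkState(z=max(float(y[0]), 0.0), chain_states=xs)


def default_initial_state(spec: NetworkSpec) -> NetworkState:
    """All ribosomes start in the pool, all chains empty."""
    return NetworkState(z=spec.s, chain_states=[np.zeros(p.n) for p, _ in _expanded_profiles(spec)])


def simulate(
    spec: NetworkSpec,
    initial: NetworkState | None = None,
    horizon: float = 1e4,
    tol: float = 1e-8,
    n_samples: int = 200,
    rescale: bool = False,
) -> SimulationResult:
    """Integrate the network ODE and return a sampled trajectory.

    The initial condition defaults to the whole density in the pool.  Its
    total density must equal ``spec.s`` (to 1e-9 relative); pass
    ``rescale=True`` to scale the initial state onto the level set instead
    of rejecting it.  Integration runs over doubling horizons until the
    vector-field max-norm falls below ``tol`` or the horizon cap is hit
    (then a warning reports the residual).
    """
    chains = _expanded_profiles(spec)
    if initial is None:
        initial = default_initial_state(spec)
    dens = total_density(initial)
    if abs(dens - spec.s) > 1e-9 * spec.s:
        if not rescale:
            raise ValueError(
                f"initial total density {dens} does not match spec.s={spec.s}; "
                "pass rescale=True to project onto the level set"
            )
        factor = spec.s / dens
        initial = NetworkState(
            z=initial.z * factor,
            chain_states=[np.clip(x * factor, 0.0, 1.0) for x in initial.chain_states],
        )
        # clipping can lose density; dump any remainder into the pool
        initial = NetworkState(
            z=initial.z + (spec.s - total_density(initial)),
            chain_states=initial.chain_states,
        )

    def rhs(_t, y):
        st = _unpack(spec, y)
        st.chain_states = [np.clip(x, 0.0, 1.0) for x in st.chain_states]
        z_dot, x_dots = network_vector_field(spec, st)
        return np.concatenate([[z_dot]] + x_dots)

    y0 = _pack(initial)
    t0, t1 = 0.0, float(horizon)
    ts_all: list[np.ndarray] = []
    ys_all: list[np.ndarray] = []
    max_horizon = horizon * 2 ** 12
    while True:
        sol = solve_ivp(
            rhs, (t0, t1), y0, method="LSODA",
            t_eval=np.linspace(t0, t1, max(n_samples // 2, 2)),
            rtol=1e-11, atol=1e-13,
        )
        skip = 1 if ts_all else 0  # segments share their junction point
        ts_all.append(sol.t[skip:])
        ys_all.append(sol.y[:, skip:])
        y0 = sol.y[:, -1]
        residual = float(np.max(np.abs(rhs(0.0, y0))))
        if residual < tol:
            break
        if t1 >= max_horizon:
            warnings.warn(
                f"network did not settle to tolerance {tol} by t={t1}; "
                f"residual max-norm {residual:.3e}",
                RuntimeWarning,
                stacklevel=2,
            )
            break
        t0, t1 = t1, t1 * 2.0

    t = np.concatenate(ts_all)
    y = np.concatenate(ys_all, axis=1)
    terminal = _unpack(spec, y[:, -1])
    offsets = np.cumsum([1] + [p.n for p, _ in chains])
    chain_traj = [y[a:b, :].T for a, b in zip(offsets[:-1], offsets[1:])]
    return SimulationResult(
        t=t, z=y[0, :], chain_trajectories=chain_traj, terminal=terminal, residual=residual
    )


def _group_density_at(group: ChainGroup, e_z: float) -> tuple[float, ChainEquilibrium | None]:
    """Total occupancy of one chain of the group at pool density ``e_z``."""
    u = float(group.pool_fn(e_z))
    if u <= 0.0:
        return 0.0, None
    eq = spectral_steady_state(group.profile, u)
    return eq.total_density, eq


def solve_equilibrium(spec: NetworkSpec, xtol: float = 1e-12) -> NetworkEquilibrium:
    """Unique network steady state on the level set of total density ``s``.

    Solves ``D(e_z) = e_z + sum_i (density of chain i at input G_i(e_z)) = s``
    by a bracketed Brent root-find on ``e_z`` in ``(0, s)``.  ``D`` is
    strictly increasing with ``D(0) = 0`` and ``D(s) > s``, so the bracket
    always holds and the root is unique.  Each evaluation costs one spectral
    steady-state solve per *distinct* chain group.
    """
    if not spec.groups:
        raise ValueError("cannot solve the equilibrium of an empty network")

    def excess(e_z: float) -> float:
        if e_z <= 0.0:
            return -spec.s
        acc = e_z - spec.s
        for g in spec.groups:
            dens, _ = _group_density_at(g, e_z)
            acc += g.copies * dens
        return acc

    hi = spec.s
    f_hi = excess(hi)
    if f_hi < 0:  # numerically possible only if all G vanish; report diagnostics
        raise ArithmeticError(
            f"root bracket failed: D(s) - s = {f_hi} < 0 at e_z = s = {spec.s}"
        )
    e_z = brentq(excess, 0.0, hi, xtol=xtol * max(spec.s, 1.0), rtol=1e-15)
    e_z = float(max(e_z, 0.0))

    group_eqs, copies = [], []
    for g in spec.groups:
        _, eq = _group_density_at(g, e_z)
        if eq is None:  # fully starved pool (degenerate root at 0)
            eq = ChainEquilibrium(e=np.zeros(g.profile.n), R=0.0)
        group_eqs.append(eq)
        copies.append(g.copies)
    tpr = float(sum(c * eq.R for eq, c in zip(group_eqs, copies)))
    return NetworkEquilibrium(
        e_z=e_z,
        group_equilibria=tuple(group_eqs),
        copies=tuple(copies),
        TPR=tpr,
        q=e_z / spec.s,
        s=spec.s,
    )


def equilibrium_vs_copy_number(spec_builder, m_values, s: float) -> pd.DataFrame:
    """Solve the network equilibrium along a schedule of chain counts.

    ``spec_builder(i)`` must return the ``(RateProfile, PoolFunction)`` tuple
    of chain ``i`` (0-based); the network with ``m`` chains uses chains
    ``0..m-1``.  Returns a tidy table with one row per ``m``: pool density
    ``e_z``, pool fraction ``q``, total production rate ``TPR``, and the
    per-site densities of the first chain (columns ``e1, e2, ...``).

    Adding a chain at fixed ``s`` strictly decreases ``e_z``, and for an
    ever-growing network ``e_z`` tends to zero.
    """
    m_values = list(m_values)
    if any(m2 <= m1 for m1, m2 in zip(m_values, m_values[1:])) or any(m < 1 for m in m_values):
        raise ValueError("m_values must be strictly increasing positive integers")
    rows = []
    cache: list[tuple[RateProfile, PoolFunction]] = []
    for m in m_values:
        while len(cache) < m:
            cache.append(spec_builder(len(cache)))
        # group consecutive identical tuples so homogeneous families stay cheap
        groups: list[ChainGroup] = []
        for profile, pool_fn in cache[:m]:
            if groups and groups[-1].profile == profile and groups[-1].pool_fn == pool_fn:
                groups[-1] = ChainGroup(profile, pool_fn, groups[-1].copies + 1)
            else:
                groups.append(ChainGroup(profile, pool_fn, 1))
        eq = solve_equilibrium(NetworkSpec(tuple(groups), s))
        row = {"m": m, "e_z": eq.e_z, "q": eq.q, "TPR": eq.TPR}
        for j, ej in enumerate(eq.group_equilibria[0].e, start=1):
            row[f"e{j}"] = ej
        rows.append(row)
    return pd.DataFrame(rows)
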