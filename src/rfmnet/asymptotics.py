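"""Closed-form limits of the pool-coupled network in the starved regime.

When the free-ribosome pool is depleted (``e_z -> 0``, reached by adding
chains at fixed total density ``s`` or by shrinking ``s``), initiation
becomes every chain's bottleneck and the steady state admits closed forms:

* site densities scale with the pool output, ``e_j^i / G_i(e_z) ->
  lambda_0^i / lambda_j^i``, and, for ``G_i`` differentiable at zero,
  ``e_j^i / e_z -> lambda_0^i G_i'(0) / lambda_j^i``;
* the total production rate satisfies ``TPR / e_z -> sum_i lambda_0^i
  G_i'(0)``, independent of the elongation rates (no traffic jams on a
  starved chain);
* the pool fraction ``q = e_z / s`` tends to
  ``(1 + sum_i lambda_0^i G_i'(0) * n_i / H_i)**-1``, where ``H_i`` is the
  harmonic mean of chain ``i``'s elongation/exit rates.

These limits hold under mild uniformity conditions (initiation rates
bounded below, exit rates bounded above, pool outputs bounded below by a
line near zero), which :func:`audit_assumptions` checks numerically.  They
also justify replacing a network of ``m`` identical chains with linear
pool output by a single one-site chain with matched asymptotics
(:func:`reduce_identical_network`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import RateProfile
from .pool import NetworkSpec, PoolFunction, solve_equilibrium

__all__ = [
    "AssumptionBounds",
    "AsymptoticSummary",
    "audit_assumptions",
    "harmonic_mean",
    "asymptotic_density_ratios",
    "asymptotic_tpr_slope",
    "asymptotic_pool_fraction",
    "reduce_identical_network",
    "convergence_table",
    "summarize",
]


@dataclass(frozen=True)
class AssumptionBounds:
    """Uniformity bounds under which the starved-pool limits hold."""

    lambda_lower: float   # infimum of initiation rates
    lambda_upper: float   # supremum of exit rates
    g_lower: float        # slope of a linear lower bound for all G on [0, p]
    p: float


@dataclass(frozen=True)
class AsymptoticSummary:
    """All starved-pool closed forms of one network in one record."""

    density_ratios: tuple[np.ndarray, ...]
    tpr_slope: float
    q_limit: float


def audit_assumptions(chains, p: float, grid_size: int = 128) -> AssumptionBounds:
    """Verify the uniformity conditions on a list of ``(profile, pool_fn)`` tuples.

    Checks that every initiation rate is positive (returning their minimum),
    every exit rate is finite (returning their maximum), and that every pool
    output admits a common linear lower bound ``G(z) >= g * z`` on a
    log-spaced grid over ``(0, p]``.  Raises ``ValueError`` when a pool
    function has (numerically) zero slope at the origin — no ``g > 0``
    bounded away from zero exists; "numerically zero" means below ``1e-9``
    of the secant slope ``G(p) / p``.
    """
    if p <= 0:
        raise ValueError(f"interval endpoint p must be > 0, got {p}")
    chains = list(chains)
    if not chains:
        raise ValueError("need at least one chain to audit")
    lam0 = [profile.lambda0 for profile, _ in chains]
    lam_exit = [profile.rates[-1] for profile, _ in chains]
    grid = np.geomspace(1e-12 * p, p, grid_size)
    g_lower, secant = np.inf, 0.0
    for _, pool_fn in chains:
        slopes = np.array([pool_fn(z) / z for z in grid])
        g_lower = min(g_lower, float(slopes.min()))
        secant = max(secant, float(pool_fn(p) / p))
    if not np.isfinite(g_lower) or g_lower <= 1e-9 * secant:
        raise ValueError(
            f"no positive linear lower bound for the pool outputs on (0, {p}]: "
            f"minimal slope {g_lower}"
        )
    return AssumptionBounds(
        lambda_lower=float(min(lam0)),
        lambda_upper=float(max(lam_exit)),
        g_lower=g_lower,
        p=float(p),
    )


def harmonic_mean(rates) -> float:
    """``n / sum(1 / rate_j)`` over a chain's elongation and exit rates."""
    rates = np.asarray(rates, dtype=float)
    if rates.size == 0 or np.any(rates <= 0):
        raise ValueError(f"harmonic mean needs a nonempty vector of positive rates, got {rates}")
    return float(rates.size / np.sum(1.0 / rates))


def asymptotic_density_ratios(profile: RateProfile, pool_fn: PoolFunction) -> np.ndarray:
    """Limits of ``e_j / e_z`` as the pool starves: ``lambda_0 G'(0) / lambda_j``."""
    return profile.lambda0 * pool_fn.derivative_at_zero / profile.elongation


def asymptotic_tpr_slope(spec: NetworkSpec) -> float:
    """Limit of ``TPR / e_z``: the sum of effective initiation slopes."""
    return float(
        sum(
            g.copies * g.profile.lambda0 * g.pool_fn.derivative_at_zero
            for g in spec.groups
        )
    )


def asymptotic_pool_fraction(spec: NetworkSpec) -> float:
    """Limit of the pool fraction ``q = e_z / s`` as the pool starves.

    Equals ``(1 + sum_i lambda_0^i G_i'(0) * sum_j 1/lambda_j^i)**-1``; the
    inner sum is ``n_i`` over the harmonic mean of chain ``i``'s rates.
    """
    acc = 0.0
    for g in spec.groups:
        inv_sum = float(np.sum(1.0 / g.profile.elongation))
        acc += g.copies * g.profile.lambda0 * g.pool_fn.derivative_at_zero * inv_sum
    return 1.0 / (1.0 + acc)


def summarize(spec: NetworkSpec) -> AsymptoticSummary:
    """Collect all starved-pool closed forms of a network."""
    return AsymptoticSummary(
        density_ratios=tuple(
            asymptotic_density_ratios(g.profile, g.pool_fn) for g in spec.groups
        ),
        tpr_slope=asymptotic_tpr_slope(spec),
        q_limit=asymptotic_pool_fraction(spec),
    )


def reduce_identical_network(
    profile: RateProfile, g: float, m: int, s: float = 1.0
) -> NetworkSpec:
    """Collapse ``m`` identical chains with linear pool output to one site.

    The reduced network has a single chain of length one with linear pool
    output of slope ``g_bar``, initiation rate ``lambda0_bar`` and exit rate
    ``lambda1_bar`` chosen so that

        ``lambda0_bar * g_bar = lambda_0 * g * m``   and
        ``1 / lambda1_bar = sum_j 1 / lambda_j``.

    Only the product ``lambda0_bar * g_bar`` is constrained; the convention
    here fixes ``g_bar = g`` and puts the copy-number factor in
    ``lambda0_bar``.  The reduced network then shares the full network's
    starved-pool limits of ``TPR / e_z`` and of the pool fraction ``q``.
    The reduction is exact only asymptotically and only for linear pool
    outputs.
    """
    if g <= 0:
        raise ValueError(f"linear pool slope must be > 0, got {g}")
    if m < 1:
        raise ValueError(f"copy number must be >= 1, got {m}")
    lambda0_bar = profile.lambda0 * m
    lambda1_bar = 1.0 / float(np.sum(1.0 / profile.elongation))
    reduced_profile = RateProfile((lambda0_bar, lambda1_bar))
    return NetworkSpec.identical(reduced_profile, PoolFunction.linear(g), m=1, s=s)


def convergence_table(spec_builder, schedule, vary: str = "m") -> pd.DataFrame:
    """Track the approach to the starved-pool limits along a schedule.

    ``spec_builder(v)`` returns the :class:`NetworkSpec` for schedule value
    ``v`` (a chain count when ``vary='m'``, a total density when
    ``vary='s'``).  For each value the exact equilibrium is solved and the
    observed ``e_j / e_z`` (first group), ``TPR / e_z`` and ``q`` are
    tabulated next to their closed-form limits and absolute errors.

    A schedule that fails to deplete the pool (terminal ``e_z`` not below
    the initial one) triggers a warning: the limits are then not probed and
    no convergence claim is made.
    """
    schedule = list(schedule)
    if not schedule:
        raise ValueError("schedule must be nonempty")
    if vary not in ("m", "s"):
        raise ValueError(f"vary must be 'm' or 's', got {vary!r}")
    rows = []
    for v in schedule:
        spec = spec_builder(v)
        eq = solve_equilibrium(spec)
        g0 = spec.groups[0]
        ratios = asymptotic_density_ratios(g0.profile, g0.pool_fn)
        slope = asymptotic_tpr_slope(spec)
        q_lim = asymptotic_pool_fraction(spec)
        row = {
            vary: v,
            "e_z": eq.e_z,
            "tpr_over_ez": eq.TPR / eq.e_z,
            "tpr_slope_limit": slope,
            "tpr_slope_error": abs(eq.TPR / eq.e_z - slope),
            "q": eq.q,
            "q_limit": q_lim,
            "q_error": abs(eq.q - q_lim),
        }
        e1 = eq.group_equilibria[0].e
        for j, (ej, lim) in enumerate(zip(e1, ratios), start=1):
            row[f"ratio{j}"] = ej / eq.e_z
            row[f"ratio{j}_limit"] = lim
            row[f"ratio{j}_error"] = abs(ej / eq.e_z - lim)
        rows.append(row)
    table = pd.DataFrame(rows)
    if table["e_z"].iloc[-1] >= table["e_z"].iloc[0]:
        warnings.warn(
            "schedule does not deplete the pool (e_z did not decrease); "
            "convergence to the starved-pool limits is not probed",
            RuntimeWarning,
            stacklevel=2,
        )
    return table
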