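"""Worked examples and a cell-free-system pipeline on synthetic decoding rates.

Two settings are covered.

The homogeneous two-site network: ``m`` identical chains with all rates 1
and linear pool output ``G(z) = z``.  Writing ``c = e_z**-0.5``, the
spectral steady state is available in closed form, the total-density first
integral becomes a scalar identity ``s = c**-2 + m (e1(c) + e2(c))`` that
can be inverted numerically, and in the starved regime the total
production rate approaches ``m s / (1 + 2 m)`` — hence ``s / 2`` for many
chains.

A heterologous-expression pipeline mirroring how per-codon decoding times
are turned into a coarse-grained chain: consecutive codons are grouped
into sites (default 10 codons per site), each site's rate is the
reciprocal of its summed decoding times, rates are normalized to a target
mean per-codon decoding rate (default 10 codons/s, a typical eukaryotic
value), and the linear pool-coupling slope ``c`` is calibrated so that the
effective initiation rate is maximal while remaining the bottleneck:
``lambda_0 * c * e_z = min(lambda_1..lambda_n)``.  Decoding times are
generated synthetically (log-normal by default); no measured profile is
shipped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .core import RateProfile
from .pool import NetworkSpec, PoolFunction, solve_equilibrium

__all__ = [
    "DecodingProfile",
    "CalibrationResult",
    "TwoSiteSteadyState",
    "two_site_closed_forms",
    "total_density_identity",
    "invert_total_density",
    "approx_tpr",
    "synthesize_decoding_times",
    "coarse_grain_rates",
    "calibrate_pool_coupling",
    "sweep_experiment",
]

#: typical eukaryotic decoding speed used to normalize site rates, codons/s
DEFAULT_CODON_RATE = 10.0


@dataclass(frozen=True)
class DecodingProfile:
    """Per-codon decoding times (s) plus the grouping into coarse sites.

    ``group_size`` codons form one site; ``first_group_size`` optionally
    makes the first site a different length (initiation-proximal codons are
    sometimes folded into a longer first group); a shorter final group
    absorbs the remainder.
    """

    times: np.ndarray
    group_size: int = 10
    first_group_size: int | None = None

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        if times.ndim != 1 or times.size == 0:
            raise ValueError("decoding times must be a nonempty 1-d vector")
        if np.any(times <= 0) or not np.all(np.isfinite(times)):
            raise ValueError("all decoding times must be finite and > 0")
        if self.group_size < 1:
            raise ValueError(f"group_size must be >= 1, got {self.group_size}")
        first = self.first_group_size
        if first is not None and (first < 1 or first > times.size):
            raise ValueError(f"first_group_size {first} does not fit {times.size} codons")
        object.__setattr__(self, "times", times)

    @property
    def n_codons(self) -> int:
        return int(self.times.size)

    def groups(self) -> list[np.ndarray]:
        """Split the times into site groups, covering every codon exactly once."""
        first = self.first_group_size if self.first_group_size is not None else self.group_size
        first = min(first, self.n_codons)
        bounds = list(range(first, self.n_codons, self.group_size)) + [self.n_codons]
        out = [self.times[:first]]
        out += [self.times[a:b] for a, b in zip(bounds[:-1], bounds[1:])]
        return [g for g in out if g.size]

    @property
    def n_sites(self) -> int:
        return len(self.groups())


@dataclass(frozen=True)
class CalibrationResult:
    """Calibrated linear pool-coupling slope and its defining residual."""

    c: float
    e_z_at_c: float
    residual: float
    target: float  # min of the elongation/exit rates


class TwoSiteSteadyState(NamedTuple):
    sigma: float
    e1: float
    e2: float
    R: float


def two_site_closed_forms(c: float) -> TwoSiteSteadyState:
    """Closed-form steady state of a homogeneous two-site chain.

    For the chain with ``lambda_0 = lambda_1 = lambda_2 = 1`` fed at
    effective initiation rate ``e_z = c**-2`` (so ``c = e_z**-0.5``):

        ``sigma = sqrt((sqrt(c**4 + 4) + c**2 + 2) / 2)``
        ``e1 = 2 / (sqrt(c**4 + 4) + c**2)``
        ``e2 = 2 / (sqrt(c**4 + 4) + c**2 + 2) = sigma**-2 = R``
    """
    if c <= 0:
        raise ValueError(f"c must be > 0, got {c}")
    root = math.sqrt(c ** 4 + 4.0)
    sigma = math.sqrt((root + c ** 2 + 2.0) / 2.0)
    e1 = 2.0 / (root + c ** 2)
    e2 = 2.0 / (root + c ** 2 + 2.0)
    return TwoSiteSteadyState(sigma=sigma, e1=e1, e2=e2, R=e2)


def total_density_identity(c: float, m: int) -> float:
    """Total density of the homogeneous two-site network at parameter ``c``.

    ``s = e_z + m (e1 + e2) = c**-2 + m (e1(c) + e2(c))``.
    """
    ss = two_site_closed_forms(c)
    return c ** -2 + m * (ss.e1 + ss.e2)


def invert_total_density(s: float, m: int) -> float:
    """Recover ``c`` (hence ``e_z = c**-2``) from total density ``s`` and ``m``.

    ``total_density_identity`` is strictly decreasing in ``c`` (larger ``c``
    means a smaller pool and emptier chains), so a bracketed root-find
    applies.
    """
    if s <= 0 or m < 1:
        raise ValueError(f"need s > 0 and m >= 1, got s={s}, m={m}")

    def f(c: float) -> float:
        return total_density_identity(c, m) - s

    lo, hi = 1.0, 1.0
    while f(lo) < 0:  # density too small -> decrease c (grow the pool)
        lo /= 2.0
        if lo < 1e-12:
            raise ArithmeticError("failed to bracket the density identity from below")
    while f(hi) > 0:
        hi *= 2.0
        if hi > 1e12:
            raise ArithmeticError("failed to bracket the density identity from above")
    return float(brentq(f, lo, hi, xtol=1e-15, rtol=1e-15))


def approx_tpr(m: int, s: float) -> float:
    """Starved-regime estimate of the total production rate: ``m s / (1 + 2 m)``."""
    return m * s / (1.0 + 2.0 * m)


def synthesize_decoding_times(
    n_codons: int,
    seed: int,
    mean_time: float = 0.4,
    sigma: float = 0.35,
    law: str = "lognormal",
    group_size: int = 10,
    first_group_size: int | None = None,
) -> DecodingProfile:
    """Generate a synthetic per-codon decoding-time profile.

    Default law is log-normal with the given arithmetic mean (s) and
    log-scale ``sigma``; ``sigma = 0`` degenerates to constant times.  The
    defaults put a 10-codon site's unnormalized rate near 0.25 1/s, the
    scale of coarse-grained yeast decoding-rate estimates.  Deterministic
    for a fixed seed.  This is a synthetic stand-in for ribo-seq-derived
    decoding rates, not measured data.
    """
    if n_codons < 1:
        raise ValueError(f"n_codons must be >= 1, got {n_codons}")
    if mean_time <= 0 or sigma < 0:
        raise ValueError(f"need mean_time > 0 and sigma >= 0, got {mean_time}, {sigma}")
    if law != "lognormal":
        raise ValueError(f"unsupported decoding-time law {law!r}")
    rng = np.random.default_rng(seed)
    if sigma == 0.0:
        times = np.full(n_codons, mean_time)
    else:
        mu = math.log(mean_time) - sigma ** 2 / 2.0  # arithmetic mean = mean_time
        times = rng.lognormal(mean=mu, sigma=sigma, size=n_codons)
    return DecodingProfile(times=times, group_size=group_size, first_group_size=first_group_size)


def coarse_grain_rates(
    profile: DecodingProfile,
    target_mean_rate: float | None = None,
    lambda0: float | None = None,
):
    """Turn per-codon decoding times into site transition rates.

    Each site's rate is the reciprocal of the summed decoding times of its
    codons.  If ``target_mean_rate`` (codons/s) is given, all site rates are
    multiplied by one common factor so that the mean per-codon decoding rate
    (site rate times codons in the site, averaged over sites) equals the
    target.  Multiplying all decoding times by ``k`` divides all rates by
    ``k``; the normalized rates are invariant to such rescaling.

    Returns the elongation-rate vector ``lambda_1..lambda_n``; the
    initiation rate is not derivable from decoding times, so pass
    ``lambda0`` to get a full :class:`RateProfile` instead.
    """
    groups = profile.groups()
    rates = np.array([1.0 / g.sum() for g in groups])
    if target_mean_rate is not None:
        if target_mean_rate <= 0:
            raise ValueError(f"target_mean_rate must be > 0, got {target_mean_rate}")
        sizes = np.array([g.size for g in groups])
        rates = rates * target_mean_rate / np.mean(rates * sizes)
    if lambda0 is not None:
        return RateProfile((lambda0, *rates))
    return rates


def calibrate_pool_coupling(
    profile: RateProfile,
    m: int,
    s: float,
    tol: float = 1e-10,
    c_max: float = 1e8,
) -> CalibrationResult:
    """Find the linear pool-coupling slope pinning initiation to the bottleneck.

    Solves for ``c`` such that the network of ``m`` copies of ``profile``
    with pool outputs ``G(z) = c z`` and total density ``s`` has effective
    initiation rate equal to the slowest elongation/exit rate:

        ``lambda_0 * c * e_z(c) = min(lambda_1..lambda_n)``.

    The left-hand side increases with ``c``, so bisection (Brent) applies on
    an expanding bracket.  If the product stays below the target for every
    ``c`` up to ``c_max`` (e.g. too few ribosomes in the system), a
    calibration error is raised with the achieved value.
    """
    if m < 1 or s <= 0:
        raise ValueError(f"need m >= 1 and s > 0, got m={m}, s={s}")
    target = float(profile.elongation.min())

    def effective_initiation(c: float) -> float:
        eq = solve_equilibrium(
            NetworkSpec.identical(profile, PoolFunction.linear(c), m=m, s=s)
        )
        return profile.lambda0 * c * eq.e_z

    def gap(c: float) -> float:
        return effective_initiation(c) - target

    lo = 1e-12
    hi = 1.0
    while gap(hi) < 0:
        hi *= 8.0
        if hi > c_max:
            raise ArithmeticError(
                f"calibration infeasible: lambda0*c*e_z reaches only "
                f"{effective_initiation(c_max):.6g} < target {target:.6g} "
                f"for c up to {c_max:g} (m={m}, s={s})"
            )
    c = float(brentq(gap, lo, hi, xtol=1e-15, rtol=8.9e-16))
    eq = solve_equilibrium(NetworkSpec.identical(profile, PoolFunction.linear(c), m=m, s=s))
    residual = abs(profile.lambda0 * c * eq.e_z - target)
    if residual > tol * max(target, 1.0):
        raise ArithmeticError(
            f"calibration residual {residual:.3e} exceeds tolerance {tol:.1e}"
        )
    return CalibrationResult(c=c, e_z_at_c=eq.e_z, residual=residual, target=target)


def sweep_experiment(
    spec_builder,
    vary: str,
    grid,
    out: str | None = None,
) -> pd.DataFrame:
    """Solve equilibria along a grid of ``m`` or ``s`` values.

    ``spec_builder(v)`` returns the :class:`NetworkSpec` at grid value
    ``v``.  The result is a tidy table sorted by ``m/s`` with columns
    ``m, s, m_over_s, e_z, q, TPR, tpr_over_ez``; a failed grid point is
    recorded with NaNs and an ``error`` message rather than aborting the
    sweep.  Optionally written as CSV to ``out``.
    """
    if vary not in ("m", "s"):
        raise ValueError(f"vary must be 'm' or 's', got {vary!r}")
    grid = list(grid)
    if not grid or any(v <= 0 for v in grid):
        raise ValueError("grid must be nonempty with positive values")
    rows = []
    for v in grid:
        spec = spec_builder(v)
        row = {"m": spec.m, "s": spec.s, "m_over_s": spec.m / spec.s}
        try:
            eq = solve_equilibrium(spec)
            row.update(
                e_z=eq.e_z, q=eq.q, TPR=eq.TPR,
                tpr_over_ez=eq.TPR / eq.e_z, error="",
            )
        except (ArithmeticError, ValueError) as exc:  # record, keep sweeping
            row.update(e_z=np.nan, q=np.nan, TPR=np.nan, tpr_over_ez=np.nan, error=str(exc))
        rows.append(row)
    table = pd.DataFrame(rows).sort_values("m_over_s", kind="stable").reset_index(drop=True)
    if out is not None:
        table.to_csv(out, index=False)
    return table
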