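"""Single-chain ribosome flow model (RFM) dynamics and steady states.

The RFM is the deterministic mean-field limit of TASEP for ribosome
traffic along one mRNA: ``n`` coarse-grained sites with occupancies
``x_1..x_n`` in [0, 1] and ``n + 1`` positive transition rates
``lambda_0..lambda_n`` (1/s), where ``lambda_0`` controls initiation and
``lambda_n`` the exit.  The variant with a scalar input ``u`` scaling the
initiation rate and output ``y = lambda_n * x_n`` (RFMIO) is what this
module implements; ``u = 1`` recovers the isolated chain.

The unique attracting equilibrium has a spectral representation: build a
symmetric nonnegative tridiagonal (Jacobi) matrix of order ``n + 2`` from
the reciprocal square roots of the rates; its Perron root ``sigma`` and
positive eigenvector ``zeta`` give the steady-state occupancies and the
production rate ``R = sigma**-2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import eigh, eigh_tridiagonal

__all__ = [
    "RateProfile",
    "SpectralDecomposition",
    "ChainEquilibrium",
    "chain_vector_field",
    "build_jacobi_matrix",
    "spectral_decomposition",
    "spectral_steady_state",
    "relax_to_steady_state",
]


@dataclass(frozen=True)
class RateProfile:
    """Transition rates of one chain: ``lambda_0..lambda_n``, all > 0, in 1/s."""

    rates: tuple[float, ...]

    def __init__(self, rates) -> None:
        rates = tuple(float(r) for r in np.atleast_1d(np.asarray(rates, dtype=float)))
        if len(rates) < 2:
            raise ValueError(
                f"a chain needs at least one site, i.e. >= 2 rates; got {len(rates)}"
            )
        if any(not np.isfinite(r) or r <= 0.0 for r in rates):
            raise ValueError(f"all transition rates must be finite and > 0; got {rates}")
        object.__setattr__(self, "rates", rates)

    @property
    def n(self) -> int:
        """Number of sites."""
        return len(self.rates) - 1

    @property
    def lambda0(self) -> float:
        """Initiation rate (1/s)."""
        return self.rates[0]

    @property
    def elongation(self) -> np.ndarray:
        """Rates ``lambda_1..lambda_n`` out of each site (1/s)."""
        return np.asarray(self.rates[1:])

    def as_array(self) -> np.ndarray:
        return np.asarray(self.rates)


@dataclass(frozen=True)
class SpectralDecomposition:
    """Perron root and unit-norm positive Perron eigenvector of the Jacobi matrix."""

    sigma: float
    zeta: np.ndarray = field(repr=False)


@dataclass(frozen=True)
class ChainEquilibrium:
    """Steady state of one chain: occupancies ``e`` and production rate ``R`` (1/s)."""

    e: np.ndarray
    R: float

    @property
    def total_density(self) -> float:
        return float(np.sum(self.e))


def _check_state(profile: RateProfile, x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.shape != (profile.n,):
        raise ValueError(
            f"state has shape {x.shape}, expected ({profile.n},) for this profile"
        )
    return x


def chain_vector_field(profile: RateProfile, x, u: float = 1.0) -> np.ndarray:
    """Right-hand side of the chain balance equations at state ``x``.

    Site ``j`` changes at the rate (flow in from site ``j - 1``) minus
    (flow out to site ``j + 1``); initiation flows in at ``u * lambda_0 *
    (1 - x_1)`` and the last site drains at ``lambda_n * x_n``.
    """
    x = _check_state(profile, x)
    if u < 0:
        raise ValueError(f"input u must be nonnegative, got {u}")
    lam = profile.as_array()
    # flows[j] = flow from site j into site j+1 (j=0 is initiation, j=n exit)
    occ = np.concatenate(([1.0], x))          # source occupancy per flow
    free = np.concatenate((1.0 - x, [1.0]))   # target free space per flow
    flows = lam * occ * free
    flows[0] *= u
    return flows[:-1] - flows[1:]


def build_jacobi_matrix(profile: RateProfile, u: float = 1.0) -> np.ndarray:
    """Symmetric nonnegative tridiagonal matrix of order ``n + 2``.

    Zero main diagonal; off-diagonal entries ``(u*lambda_0)**-0.5,
    lambda_1**-0.5, ..., lambda_n**-0.5``.  The input ``u`` scales the
    effective initiation rate, as when the chain is fed by a ribosome pool.
    """
    off = _offdiagonal(profile, u)
    m = np.zeros((profile.n + 2, profile.n + 2))
    idx = np.arange(profile.n + 1)
    m[idx, idx + 1] = off
    m[idx + 1, idx] = off
    return m


def _offdiagonal(profile: RateProfile, u: float) -> np.ndarray:
    if u <= 0:
        raise ValueError(f"the Jacobi matrix requires u > 0, got {u}")
    lam = profile.as_array().copy()
    lam[0] *= u
    return lam ** -0.5


def spectral_decomposition(profile: RateProfile, u: float = 1.0) -> SpectralDecomposition:
    """Largest eigenpair of the chain's Jacobi matrix.

    The matrix is irreducible and nonnegative, so by Perron-Frobenius the
    maximal eigenvalue ``sigma`` is simple and its eigenvector can be taken
    strictly positive; the eigenvector is returned with unit Euclidean norm.
    """
    off = _offdiagonal(profile, u)
    k = profile.n + 2
    diag = np.zeros(k)
    try:
        w, v = eigh_tridiagonal(diag, off, select="i", select_range=(k - 1, k - 1))
        sigma = float(w[0])
        zeta = v[:, 0]
    except Exception:
        w, v = eigh(build_jacobi_matrix(profile, u))
        sigma = float(w[-1])
        zeta = v[:, -1]
    if zeta[0] < 0:
        zeta = -zeta
    if sigma <= 0 or np.any(zeta <= 0):
        raise ArithmeticError(
            "Perron pair computation failed: expected sigma > 0 and a strictly "
            f"positive eigenvector, got sigma={sigma}, min(zeta)={zeta.min()}"
        )
    return SpectralDecomposition(sigma=sigma, zeta=zeta)


def spectral_steady_state(profile: RateProfile, u: float = 1.0) -> ChainEquilibrium:
    """Steady state of the chain driven by constant input ``u``, spectrally.

    With Perron pair ``(sigma, zeta)`` of the Jacobi matrix (initiation rate
    ``u * lambda_0``), the occupancies are

        ``e_i = zeta_{i+2} / (lambda_i**0.5 * sigma * zeta_{i+1})``,  i = 1..n

    (1-based indices; ``lambda_1..lambda_n`` are the site exit rates) and the
    production rate is ``R = sigma**-2``.
    """
    dec = spectral_decomposition(profile, u)
    zeta, sigma = dec.zeta, dec.sigma
    lam_site = profile.elongation
    e = zeta[2:] / (np.sqrt(lam_site) * sigma * zeta[1:-1])
    if np.any(e <= 0) or np.any(e >= 1):
        raise ArithmeticError(
            f"spectral occupancies outside (0, 1): {e}; sigma={sigma}"
        )
    return ChainEquilibrium(e=e, R=sigma ** -2)


def relax_to_steady_state(
    profile: RateProfile,
    u: float = 1.0,
    x0=None,
    tol: float = 1e-10,
    max_horizon: float = 1e7,
) -> ChainEquilibrium:
    """Integrate the chain ODE until the derivative max-norm drops below ``tol``.

    Serves as an oracle independent of the spectral route: the chain is a
    totally positive differential system, so any initial condition in
    [0, 1]^n relaxes to the same equilibrium.  Integration proceeds over
    doubling horizons up to ``max_horizon`` seconds of model time.

    Raises ``ArithmeticError`` if the residual never reaches ``tol``.
    """
    if x0 is None:
        x0 = np.zeros(profile.n)
    x = _check_state(profile, np.asarray(x0, dtype=float))
    if np.any(x < 0) or np.any(x > 1):
        raise ValueError("initial state must lie in [0, 1]^n")
    if u == 0.0:
        # no initiation: the chain drains to empty
        return ChainEquilibrium(e=np.zeros(profile.n), R=0.0)

    horizon = max(10.0 / min(profile.rates), 1.0)
    while True:
        sol = solve_ivp(
            lambda _t, y: chain_vector_field(profile, np.clip(y, 0.0, 1.0), u),
            (0.0, horizon),
            x,
            method="LSODA",
            rtol=1e-12,
            atol=1e-14,
        )
        x = np.clip(sol.y[:, -1], 0.0, 1.0)
        residual = float(np.max(np.abs(chain_vector_field(profile, x, u))))
        if residual < tol:
            return ChainEquilibrium(e=x, R=float(profile.rates[-1] * x[-1]))
        if horizon >= max_horizon:
            raise ArithmeticError(
                f"chain did not relax to tolerance {tol} within horizon "
                f"{max_horizon}; residual max-norm {residual:.3e}"
            )
        horizon *= 2.0
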