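"""Tail probabilities of weighted sums of chi-squared variables.

The gene-based set test collapses the variants of a gene window into
``T = sum_j z_j**2``.  When the variant z-scores are jointly normal with
correlation matrix ``R`` (the LD matrix), ``T`` is a quadratic form whose
null distribution is ``sum_i lambda_i * chi2_1`` with ``lambda_i`` the
eigenvalues of ``R``.  This module evaluates the upper tail of that mixture:

* exactly, when the weights are all equal (the mixture collapses to a scaled
  chi-squared, which also covers the single-variant case);
* by Imhof-type numerical inversion of the characteristic function for the
  general case;
* by a Lugannani-Rice saddlepoint approximation deep in the tail, where the
  oscillatory inversion integral loses relative accuracy;
* by Satterthwaite moment matching as a last-resort fallback when the
  inversion integral fails to converge.

Every entry point reports which branch produced the returned p-value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import integrate
from scipy.optimize import brentq
from scipy.stats import chi2, norm

__all__ = ["wchi2_sf", "QuadFormResult", "truncate_eigenvalues"]

# Below this tail probability the Imhof integral (absolute-error quadrature)
# can no longer resolve the value and the saddlepoint branch takes over.
_IMHOF_FLOOR = 1e-9
_P_FLOOR = 1e-300


@dataclass(frozen=True)
class QuadFormResult:
    """Upper-tail probability of a weighted chi-squared mixture."""

    p: float
    method: str


def truncate_eigenvalues(lambdas: np.ndarray, rel_tol: float = 1e-10) -> np.ndarray:
    """Zero out eigenvalues below ``rel_tol * max(lambdas)``.

    Tiny (possibly slightly negative) eigenvalues arise from numerically
    near-singular LD matrices; they carry no mass but destabilise the
    inversion integrand.
    """
    lambdas = np.asarray(lambdas, dtype=float)
    if lambdas.size == 0:
        raise ValueError("empty eigenvalue vector")
    cutoff = rel_tol * float(np.max(lambdas))
    out = np.where(lambdas > cutoff, lambdas, 0.0)
    if not np.any(out > 0):
        raise ValueError("all eigenvalues are zero after truncation")
    return out[out > 0]


def _imhof_integrand(u: np.ndarray, x: float, lambdas: np.ndarray) -> np.ndarray:
    lu = np.outer(np.atleast_1d(u), lambdas)
    theta = 0.5 * np.arctan(lu).sum(axis=-1) - 0.5 * x * np.atleast_1d(u)
    rho = np.exp(0.25 * np.log1p(lu**2).sum(axis=-1))
    return np.sin(theta) / (np.atleast_1d(u) * rho)


def _gl_nodes(a: np.ndarray, b: np.ndarray, order: int) -> tuple[np.ndarray, np.ndarray]:
    """Gauss-Legendre nodes/weights mapped onto the segments [a_i, b_i]."""
    x0, w0 = np.polynomial.legendre.leggauss(order)
    half = 0.5 * (b - a)
    mid = 0.5 * (a + b)
    nodes = mid[:, None] + half[:, None] * x0[None, :]
    weights = half[:, None] * w0[None, :]
    return nodes.ravel(), weights.ravel()


def _imhof_sf(x: float, lambdas: np.ndarray, epsabs: float = 1e-9) -> tuple[float, float]:
    """Imhof (1961) inversion: P(Q > x) = 1/2 + (1/pi) * int_0^inf integrand.

    For statistics well below the null mean the integrand barely oscillates
    and adaptive quadrature on the infinite interval is reliable and cheap.
    Otherwise the integrand oscillates with period ~= 4*pi/x and decays like
    u**-(1 + k/2): composite Gauss-Legendre with segments short enough to
    resolve both the oscillation and the arctan phase scale (1/lambda_max),
    truncated where the van-der-Corput bound on the oscillatory tail drops
    below ``epsabs``.
    """
    k = lambdas.size
    if x < 0.2 * lambdas.sum():  # upper-half of the distribution: few oscillations
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", integrate.IntegrationWarning)
            val, err = integrate.quad(
                lambda u: float(_imhof_integrand(u, x, lambdas)[0]),
                0.0, np.inf, limit=250, epsabs=epsabs, epsrel=1e-8,
            )
        return 0.5 + val / np.pi, err / np.pi

    log_prod_sqrt = 0.5 * float(np.sum(np.log(lambdas)))
    # tail beyond U: |int| <~ (2/x) * envelope(U), envelope u**-(1+k/2)/prod(sqrt(lam))
    power = 1.0 + 0.5 * k
    log_u = (np.log(2.0) - np.log(np.pi * x * epsabs) - log_prod_sqrt) / power
    U = float(np.clip(np.exp(log_u), 20.0, 1e6))
    seg_len = min(2.0 * np.pi / x, 0.5 / float(lambdas.max()))
    n_seg = int(min(np.ceil(U / seg_len), 300_000))
    bounds = np.linspace(0.0, U, n_seg + 1)

    def compose(order: int) -> float:
        nodes, weights = _gl_nodes(bounds[:-1], bounds[1:], order)
        return float(weights @ _imhof_integrand(nodes, x, lambdas))

    v8, v16 = compose(8), compose(16)
    tail_bound = (2.0 / x) * np.exp(-power * np.log(U) - log_prod_sqrt)
    err = abs(v16 - v8) / np.pi + tail_bound / np.pi
    return 0.5 + v16 / np.pi, err


def _saddlepoint_sf(x: float, lambdas: np.ndarray) -> float:
    """Lugannani-Rice tail approximation for Q = sum lambda_i chi2_1.

    Accurate to small *relative* error in the far tail, which the
    absolute-error inversion integral cannot deliver.
    """
    lam = lambdas
    mean = lam.sum()
    if x <= mean:  # saddlepoint w=0 singularity; caller avoids this regime
        return 0.5
    tmax = 1.0 / (2.0 * lam.max())

    def kprime(t: float) -> float:
        return float(np.sum(lam / (1.0 - 2.0 * t * lam)))

    # K'(t) is increasing on (0, tmax); solve K'(t) = x
    hi = tmax * (1.0 - 1e-12)
    that = brentq(lambda t: kprime(t) - x, 0.0, hi, xtol=1e-14)
    k = -0.5 * float(np.sum(np.log1p(-2.0 * that * lam)))
    kpp = float(np.sum(2.0 * lam**2 / (1.0 - 2.0 * that * lam) ** 2))
    w = np.sign(that) * np.sqrt(2.0 * (that * x - k))
    v = that * np.sqrt(kpp)
    if abs(w) < 1e-8:
        return 0.5
    return float(norm.sf(w + np.log(v / w) / w))


def _satterthwaite_sf(x: float, lambdas: np.ndarray) -> float:
    """Moment-matched scaled chi-squared: Q ~ a * chi2_nu."""
    s1 = lambdas.sum()
    s2 = (lambdas**2).sum()
    a = s2 / s1
    nu = s1**2 / s2
    return float(chi2.sf(x / a, nu))


def wchi2_sf(x: float, lambdas, rel_tol: float = 1e-10) -> QuadFormResult:
    """Upper tail P(sum_i lambda_i chi2_1 > x).

    Parameters
    ----------
    x
        Observed statistic (must be finite and >= 0).
    lambdas
        Mixture weights — eigenvalues of the LD correlation matrix.
    rel_tol
        Relative eigenvalue truncation tolerance.

    Returns
    -------
    QuadFormResult
        p in (0, 1] and the branch used: ``exact`` (equal weights),
        ``imhof``, ``saddlepoint`` or ``satterthwaite``.
    """
    if not np.isfinite(x):
        raise ValueError("non-finite statistic")
    if x < 0:
        raise ValueError("statistic must be non-negative")
    lam = truncate_eigenvalues(np.asarray(lambdas, dtype=float), rel_tol)
    if x == 0.0:
        return QuadFormResult(1.0, "exact")

    # Equal weights (includes the single-variant case): scaled chi-squared.
    if np.allclose(lam, lam[0], rtol=1e-12, atol=0.0):
        p = float(chi2.sf(x / lam[0], lam.size))
        return QuadFormResult(max(p, _P_FLOOR), "exact")

    try:
        p, err = _imhof_sf(x, lam)
    except Exception:
        return QuadFormResult(max(_satterthwaite_sf(x, lam), _P_FLOOR), "satterthwaite")

    if p > _IMHOF_FLOOR and err < max(1e-10, 0.05 * p) and p <= 1.0 + 1e-8:
        return QuadFormResult(min(max(p, _P_FLOOR), 1.0), "imhof")

    # Deep tail (or unreliable quadrature): saddlepoint, then Satterthwaite.
    if x > lam.sum():
        try:
            p = _saddlepoint_sf(x, lam)
            return QuadFormResult(min(max(p, _P_FLOOR), 1.0), "saddlepoint")
        except Exception:
            pass
    return QuadFormResult(
        min(max(_satterthwaite_sf(x, lam), _P_FLOOR), 1.0), "satterthwaite"
    )
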