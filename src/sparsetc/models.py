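"""Genomic prediction of general combining ability from testcross data.

Two marker models are fitted by REML ridge regression (RRBLUP):

* the *testcross model* ``y = 1 mu + Z alpha + e`` with line dosages coded
  0/2 and a single i.i.d. marker-effect variance, used for single-tester
  designs where GCA and SCA effects are confounded; and
* the *hybrid pool-specific additive + dominance model*
  ``y = 1 mu + Z1 a1 + Z2 a2 + W 1 mu_d + W d* + e`` with line and tester
  genotypes coded 0/1, a heterozygosity incidence matrix W, a fixed mean
  dominance effect mu_d (directional dominance), and three independent
  marker-effect variances, used for sparse designs with several testers.

Pool-specific GCA allele effects combine additive and dominance estimates
with the opposite pool's allele frequencies:
``alpha1 = (a1 + d (q2 - p2)) / 2``.

Variance components are estimated in observation space: the single-component
model by exact REML via spectral decomposition of the marker covariance
(EMMA-style one-dimensional profile likelihood), the three-component model by
average-information REML with expectation-maximisation fallback steps.
Marker-effect BLUPs are recovered from the equivalent kernel fit, which is
identical to solving Henderson's mixed-model equations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import lapack
from scipy.optimize import minimize_scalar

__all__ = [
    "TestcrossFit",
    "PoolSpecificFit",
    "GcaEffects",
    "fit_testcross_model",
    "fit_pool_specific_model",
    "gca_marker_effects",
    "predict_gca",
    "select_parents",
]

_VAR_FLOOR = 1e-10


@dataclass
class TestcrossFit:
    """Ridge-BLUP solution of the testcross model."""

    mu: float
    alpha: np.ndarray
    var_components: tuple[float, float]  # (marker-effect variance, residual)
    lambda_: float
    degenerate: bool = False


@dataclass
class PoolSpecificFit:
    """REML solution of the pool-specific additive + dominance model."""

    mu: float
    mu_d: float
    a1: np.ndarray
    a2: np.ndarray
    d_star: np.ndarray
    var_components: tuple[float, float, float, float]  # (s2_a1, s2_a2, s2_d, s2_e)
    converged: bool = True
    mu_d_dropped: bool = False

    @property
    def d_total(self) -> np.ndarray:
        """Per-marker dominance effect including the directional mean."""
        return self.d_star + self.mu_d


@dataclass
class GcaEffects:
    """Per-marker GCA allele effects for both pools."""

    alpha_pool1: np.ndarray
    alpha_pool2: np.ndarray
    freqs_pool1: np.ndarray
    freqs_pool2: np.ndarray


def _gls_intercept(M_inv_y: np.ndarray, M_inv_1: np.ndarray) -> float:
    return float(np.sum(M_inv_y) / np.sum(M_inv_1))


def fit_testcross_model(
    y: np.ndarray, Z: np.ndarray, lambda_: float | None = None
) -> TestcrossFit:
    """Fit ``y = 1 mu + Z alpha + e`` with alpha ~ N(0, s2_alpha I).

    With ``lambda_`` given, the ridge parameter (s2_e / s2_alpha) is fixed and
    only the GLS intercept and BLUPs are computed; otherwise both variance
    components are estimated by exact REML on the spectrum of Z Z'. Constant
    phenotypes yield a zero effect vector flagged as degenerate.
    """
    y = np.asarray(y, dtype=float).ravel()
    Z = np.asarray(Z, dtype=float)
    n, m = Z.shape
    if len(y) != n or n < 2 or m < 1:
        raise ValueError("need n >= 2 phenotypes matching Z's rows and m >= 1 markers")

    vary = float(np.var(y))
    if vary < 1e-14 * max(1.0, np.mean(y) ** 2) or vary == 0.0:
        return TestcrossFit(
            mu=float(np.mean(y)), alpha=np.zeros(m),
            var_components=(0.0, 0.0), lambda_=np.inf, degenerate=True,
        )

    # marker kernel: entries are small-integer sums, exact in float32 BLAS
    K = (Z.astype(np.float32) @ Z.T.astype(np.float32)).astype(float)
    if lambda_ is None:
        # restricted likelihood on the spectrum of the intercept-projected K
        yc = y - y.mean()
        Kc = K - K.mean(axis=0)
        Kc -= Kc.mean(axis=1)[:, None]
        xi, U = np.linalg.eigh((Kc + Kc.T) / 2.0)
        xi, U = xi[1:], U[:, 1:]  # drop the projected-out intercept direction
        xi = np.clip(xi, 0.0, None)
        eta2 = (U.T @ yc) ** 2

        def neg_restricted_ll(log_gamma: float) -> float:
            g = np.exp(log_gamma)
            w = g * xi + 1.0
            s2e = float(np.sum(eta2 / w)) / (n - 1)
            return (n - 1) * np.log(s2e) + float(np.sum(np.log(w)))

        grid = np.linspace(-14.0, 14.0, 29)
        vals = [neg_restricted_ll(g) for g in grid]
        g0 = grid[int(np.argmin(vals))]
        res = minimize_scalar(
            neg_restricted_ll, bounds=(g0 - 2.0, g0 + 2.0), method="bounded",
            options={"xatol": 1e-8},
        )
        gamma = float(np.exp(res.x))
        w = gamma * xi + 1.0
        s2e = float(np.sum(eta2 / w)) / (n - 1)
        s2a = gamma * s2e
        lam = 1.0 / gamma
    else:
        lam = float(lambda_)
        s2a, s2e = np.nan, np.nan

    M = K + lam * np.eye(n)
    Minv = np.linalg.inv(M)
    mu = _gls_intercept(Minv @ y, Minv @ np.ones(n))
    alpha = Z.T @ (Minv @ (y - mu))
    if lambda_ is None:
        return TestcrossFit(mu=mu, alpha=alpha, var_components=(s2a, s2e), lambda_=lam)
    return TestcrossFit(mu=mu, alpha=alpha, var_components=(np.nan, np.nan), lambda_=lam)


def _sym_inv(V: np.ndarray) -> np.ndarray:
    """Cholesky-based inverse of a symmetric positive-definite matrix."""
    c, info = lapack.dpotrf(V, lower=1)
    if info != 0:
        raise np.linalg.LinAlgError("V not positive definite")
    inv, info = lapack.dpotri(c, lower=1)
    if info != 0:
        raise np.linalg.LinAlgError("inversion failed")
    return inv + np.tril(inv, -1).T


def _projection(V: np.ndarray, X: np.ndarray):
    try:
        Vi = _sym_inv(V)
    except np.linalg.LinAlgError:
        # near-singular V (components collapsed): regularize minimally
        jitter = 1e-8 * float(np.trace(V)) / V.shape[0] + 1e-30
        Vi = np.linalg.inv(V + jitter * np.eye(V.shape[0]))
    XtVi = X.T @ Vi
    C = np.linalg.solve(XtVi @ X, XtVi)  # (p, n): GLS coefficient operator
    P = Vi - XtVi.T @ C
    return Vi, C, P


def fit_pool_specific_model(
    y: np.ndarray,
    Z1: np.ndarray,
    Z2: np.ndarray,
    W: np.ndarray | None = None,
    variances: tuple[float, float, float, float] | None = None,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> PoolSpecificFit:
    """Fit the pool-specific additive + dominance model by REML.

    ``Z1``/``Z2`` are line and tester marker genotypes coded 0/1; ``W`` marks
    heterozygous hybrid loci and must equal ``Z1 != Z2`` (computed when
    omitted). Fixed effects are the intercept and the heterozygosity count
    (whose coefficient is the mean dominance effect mu_d); random effects are
    the three i.i.d. marker-effect vectors a1, a2, d*. ``variances`` plugs in
    known components and skips estimation. A constant heterozygosity covariate
    is dropped (mu_d = 0); non-convergence returns the last iterate flagged.
    """
    y = np.asarray(y, dtype=float).ravel()
    Z1 = np.asarray(Z1, dtype=float)
    Z2 = np.asarray(Z2, dtype=float)
    n, m = Z1.shape
    if Z2.shape != (n, m) or len(y) != n:
        raise ValueError("y, Z1, Z2 must agree in shape")
    W_expected = (Z1 != Z2).astype(float)
    if W is None:
        W = W_expected
    else:
        W = np.asarray(W, dtype=float)
        if W.shape != (n, m) or not np.isin(W, (0.0, 1.0)).all():
            raise ValueError("W entries must be 0/1 with shape (n, m)")
        if not np.array_equal(W, W_expected):
            raise ValueError("W must mark exactly the loci where Z1 and Z2 differ")

    vary = float(np.var(y))
    if vary == 0.0:
        return PoolSpecificFit(
            mu=float(np.mean(y)), mu_d=0.0, a1=np.zeros(m), a2=np.zeros(m),
            d_star=np.zeros(m), var_components=(0.0, 0.0, 0.0, 0.0),
            converged=True, mu_d_dropped=True,
        )

    w1 = W.sum(axis=1)
    mu_d_dropped = bool(np.ptp(w1) == 0)
    X = np.ones((n, 1)) if mu_d_dropped else np.column_stack([np.ones(n), w1])

    def _kernel(A: np.ndarray) -> np.ndarray:
        A32 = A.astype(np.float32)
        return (A32 @ A32.T).astype(float)

    Ks = [_kernel(Z1), _kernel(Z2), _kernel(W)]
    sizes = np.array([m, m, m, n], dtype=float)
    I = np.eye(n)

    converged = True
    if variances is not None:
        theta = np.asarray(variances, dtype=float)
        if len(theta) != 4:
            raise ValueError("variances must be (s2_a1, s2_a2, s2_d, s2_e)")
    else:
        diag_means = np.array([max(np.mean(np.diag(K)), 1e-12) for K in Ks])
        theta = np.empty(4)
        theta[:3] = (vary / 2.0) / (3.0 * diag_means)
        theta[3] = vary / 2.0
        scale = vary / np.append(diag_means, 1.0)
        floor = np.maximum(_VAR_FLOOR * scale, 1e-300)
        floor[3] = 1e-8 * vary  # residual floor keeps V well conditioned
        converged = False
        for _ in range(max_iter):
            V = theta[3] * I
            for k in range(3):
                V += theta[k] * Ks[k]
            _, _, P = _projection(V, X)
            Py = P @ y
            KPy = [K @ Py for K in Ks] + [Py]
            q = np.array([Py @ t for t in KPy])
            tr = np.array([np.sum(P * K) for K in Ks] + [np.trace(P)])
            grad = 0.5 * (q - tr)
            em = np.maximum(theta + theta**2 * (q - tr) / sizes, floor)
            # damped average-information step; components the step would
            # drive negative fall back to their (non-negative) EM update
            PKPy = [P @ t for t in KPy]
            AI = 0.5 * np.array(
                [[KPy[j] @ PKPy[k] for k in range(4)] for j in range(4)]
            )
            try:
                cand = theta + np.linalg.solve(AI, grad)
                bad = (cand < floor) | ~np.isfinite(cand)
                cand[bad] = em[bad]
            except np.linalg.LinAlgError:
                cand = em
            # trust region: an AI proposal beyond a five-fold change reverts
            # to the (monotone, bounded) EM update for that component, so
            # near-singular AI systems cannot ping-pong against the bounds
            wild = (cand > theta * 5.0) | (cand < np.maximum(theta / 5.0, floor))
            cand[wild] = em[wild]
            new = np.maximum(cand, floor)
            # converged when the applied update is small on each component's
            # natural scale; weakly identified components then simply stay
            # near their start instead of wandering along flat directions of
            # the restricted likelihood
            done = np.max(np.abs(new - theta) / (theta + 1e-2 * scale)) < 3e-3
            theta = new
            if done:
                converged = True
                break

    V = theta[3] * I
    for k in range(3):
        V += theta[k] * Ks[k]
    _, C, P = _projection(V, X)
    beta = C @ y
    Py = P @ y
    a1 = theta[0] * (Z1.T @ Py)
    a2 = theta[1] * (Z2.T @ Py)
    d_star = theta[2] * (W.T @ Py)
    mu = float(beta[0])
    mu_d = 0.0 if mu_d_dropped else float(beta[1])
    return PoolSpecificFit(
        mu=mu, mu_d=mu_d, a1=a1, a2=a2, d_star=d_star,
        var_components=tuple(float(t) for t in theta),
        converged=converged, mu_d_dropped=mu_d_dropped,
    )


def gca_marker_effects(
    fit: PoolSpecificFit, freqs_pool1: np.ndarray, freqs_pool2: np.ndarray
) -> GcaEffects:
    """GCA allele effects per pool from pool-specific additive and dominance
    estimates: ``alpha1 = (a1 + d (q2 - p2)) / 2`` and symmetrically for pool
    2, with d the total dominance effect and p/q the allele frequencies of
    the *opposite* pool.
    """
    p1 = np.asarray(freqs_pool1, dtype=float)
    p2 = np.asarray(freqs_pool2, dtype=float)
    if len(p1) != len(fit.a1) or len(p2) != len(fit.a2):
        raise ValueError("frequency vectors must match the marker count")
    if (p1 < 0).any() or (p1 > 1).any() or (p2 < 0).any() or (p2 > 1).any():
        raise ValueError("allele frequencies must lie in [0, 1]")
    d = fit.d_total
    alpha1 = 0.5 * (fit.a1 + d * (1.0 - 2.0 * p2))
    alpha2 = 0.5 * (fit.a2 + d * (1.0 - 2.0 * p1))
    return GcaEffects(
        alpha_pool1=alpha1, alpha_pool2=alpha2, freqs_pool1=p1, freqs_pool2=p2
    )


def predict_gca(genotypes: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Predicted GCA score per line: dosage (0/2) times allele effect, summed."""
    genotypes = np.asarray(genotypes, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    if genotypes.shape[-1] != len(alpha):
        raise ValueError("genotype and effect dimensions disagree")
    return genotypes @ alpha


def select_parents(scores: np.ndarray, n_select: int) -> np.ndarray:
    """Indices of the top-scoring lines, ties broken by ascending index."""
    scores = np.asarray(scores)
    if n_select > len(scores):
        raise ValueError("cannot select more parents than lines")
    return np.argsort(-scores, kind="stable")[:n_select]
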