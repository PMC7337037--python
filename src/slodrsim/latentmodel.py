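"""Contemporary latent-variable criteria for ability differentiation.

This module owns the measurement-model machinery:

* a one-factor confirmatory factor analysis (CFA) estimated by normal-theory
  maximum likelihood on the sample covariance matrix, with the latent
  variance fixed at 1 and saturated means;
* an extension with a second, *quadratic* latent factor whose loadings are
  hard-constrained to the elementwise squares of the linear loadings, so it
  captures curvature (acceleration or deceleration) in the effect of g on
  each test;
* regression-method factor scores, a skewness significance test, per-person
  residual variance, and the likelihood-ratio comparison of the two models.

Together these implement the contemporary operationalization of Spearman's
law of diminishing returns: a negatively skewed latent g, residual variance
increasing with g, and a significant (negatively correlated) quadratic
factor.

Fitting works on covariances rescaled by one global factor (the root mean
diagonal of S) so all free parameters are O(1) for the optimizer; estimates
are mapped back to the raw metric before they are returned.  The quadratic
model's parameterisation is invariant under that uniform rescaling because
its latent variance and covariance absorb the constants.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = [
    "CFAFit",
    "QuadraticFit",
    "FactorScores",
    "SkewTest",
    "CriteriaResult",
    "fit_one_factor",
    "fit_linear_plus_quadratic",
    "predict_factor_scores",
    "skewness_test",
    "individual_log_residual_variance",
    "correlation_with_p",
    "likelihood_ratio_test",
    "evaluate_slodr_criteria",
]

_THETA_FLOOR = 1e-6          # lower bound on residual variances (scaled metric)
# Projected-gradient norm accepted as stationary.  The quadratic model's
# discrepancy surface has a long, nearly flat valley (the latent covariance
# matrix approaches singularity), where gradient norms plateau around 1e-3
# while the discrepancy itself is stable to ~1e-7 — far below anything a
# chi-square difference could notice.
_GRAD_TOL = 5e-3
_N_RESTARTS = 3              # jittered restarts on non-convergence
_N_POLISH = 6                # re-starts from the incumbent to escape plateaus
_LOG_RV_FLOOR = 1e-12        # floor before taking log of residual variance


@dataclass(frozen=True)
class CFAFit:
    """Maximum-likelihood one-factor solution (latent variance fixed at 1)."""

    loadings: np.ndarray            # (k,) raw-metric lambda_i
    residual_variances: np.ndarray  # (k,) theta_i
    intercepts: np.ndarray          # (k,) sample means
    implied_covariance: np.ndarray  # (k, k)
    sample_covariance: np.ndarray   # (k, k) biased (divide-by-n) estimate
    loglik: float
    discrepancy: float              # ML fit function at the solution
    n_free_params: int
    n_obs: int
    converged: bool
    heywood: bool                   # any residual variance at its floor


@dataclass(frozen=True)
class QuadraticFit(CFAFit):
    """Linear + quadratic latent solution.

    The second loading column is ``loadings**2`` by construction; the two
    extra free parameters are the quadratic factor's variance ``quad_variance``
    (>= 0) and its covariance ``quad_covariance`` with the linear factor.
    """

    quad_variance: float = 0.0
    quad_covariance: float = 0.0
    quad_covariance_se: float = float("nan")  # Wald SE of the latent covariance
    quad_at_boundary: bool = False  # quad variance pinned at 0

    @property
    def latent_correlation(self) -> float:
        """Model-implied correlation between the linear and quadratic factor."""
        if self.quad_variance <= 0:
            return float("nan")
        return float(np.clip(self.quad_covariance / np.sqrt(self.quad_variance), -1.0, 1.0))

    def quad_covariance_wald(self) -> tuple[float, float]:
        """Wald z and two-sided p for the latent covariance cov(g, g^2)."""
        if not np.isfinite(self.quad_covariance_se) or self.quad_covariance_se <= 0:
            return float("nan"), 1.0
        z = self.quad_covariance / self.quad_covariance_se
        return float(z), float(2.0 * stats.norm.sf(abs(z)))

    @property
    def factor_cov(self) -> np.ndarray:
        return np.array([[1.0, self.quad_covariance],
                         [self.quad_covariance, self.quad_variance]])

    @property
    def loading_matrix(self) -> np.ndarray:
        return np.column_stack([self.loadings, self.loadings**2])


@dataclass(frozen=True)
class FactorScores:
    """Regression-method latent-score estimates."""

    g_hat: np.ndarray
    q_hat: np.ndarray | None = None


@dataclass(frozen=True)
class SkewTest:
    skew: float
    se: float
    z: float
    p: float


@dataclass(frozen=True)
class CriteriaResult:
    """Per-run outcome of the contemporary differentiation criteria.

    The four *crucial* criteria are: significantly negatively skewed
    estimated g; significantly positive correlation of g with log residual
    variance; significant improvement from the quadratic factor; and a
    significantly negative association between the linear and quadratic
    latent factors (the latent covariance, tested by a signed 1-df LRT).
    ``all_crucial`` is their conjunction.
    """

    skew_value: float
    skew_p: float
    skew_direction: str              # "negative", "positive", or "none"
    res_corr: float
    res_corr_p: float
    quad_lrt_stat: float
    quad_lrt_p: float
    g_g2_corr: float
    g_g2_corr_p: float
    negatively_skewed_g: bool
    positive_res_corr: bool
    significant_quadratic: bool
    negative_g_g2_corr: bool
    all_crucial: bool
    converged: bool

    def __post_init__(self):
        expected = (self.negatively_skewed_g and self.positive_res_corr
                    and self.significant_quadratic and self.negative_g_g2_corr)
        if self.all_crucial != expected:
            raise ValueError("all_crucial must be the conjunction of the four flags")


# ---------------------------------------------------------------------------
# ML discrepancy and gradients
# ---------------------------------------------------------------------------

def _ml_discrepancy(sigma: np.ndarray, s: np.ndarray, logdet_s: float) -> tuple[float, np.ndarray]:
    """Normal-theory fit function F = ln|Sigma| + tr(S Sigma^-1) - ln|S| - k.

    Returns (F, A) with A = Sigma^-1 (Sigma - S) Sigma^-1, the matrix such
    that dF = tr(A dSigma) — everything a chain rule needs.
    """
    k = s.shape[0]
    try:
        chol = np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError:
        return np.inf, np.zeros_like(s)
    logdet = 2.0 * np.sum(np.log(np.diag(chol)))
    sigma_inv = np.linalg.inv(sigma)
    f = logdet + np.trace(sigma_inv @ s) - logdet_s - k
    a = sigma_inv @ (sigma - s) @ sigma_inv
    return float(f), a


def _sample_cov(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    x = np.asarray(x, dtype=float)
    if x.ndim != 2:
        raise ValueError("score matrix must be 2-D")
    n, k = x.shape
    if k < 3:
        raise ValueError(f"need at least 3 tests, got {k}")
    if n <= k:
        raise ValueError(f"need more observations than tests, got shape {x.shape}")
    if np.any(x.std(axis=0) == 0):
        raise ValueError("zero-variance column in score matrix")
    mu = x.mean(axis=0)
    xc = x - mu
    s = (xc.T @ xc) / n  # ML (divide-by-n) covariance
    if np.linalg.matrix_rank(s) < k:
        raise ValueError("singular sample covariance")
    return s, mu, n


def _loglik(n: int, k: int, s: np.ndarray, sigma: np.ndarray) -> float:
    sign, logdet = np.linalg.slogdet(sigma)
    tr = np.trace(np.linalg.solve(sigma, s))
    return float(-0.5 * n * (k * np.log(2 * np.pi) + logdet + tr))


def _projected_grad_norm(x, grad, bounds) -> float:
    """Max-norm of the gradient projected onto the feasible directions."""
    g = np.array(grad, dtype=float)
    for i, (lo, _hi) in enumerate(bounds):
        if lo is not None and x[i] <= lo + 1e-12 and g[i] > 0:
            g[i] = 0.0
    return float(np.max(np.abs(g)))


def _minimize_discrepancy(objective, starts, bounds):
    """Minimize a discrepancy function robustly over several starts.

    L-BFGS-B can stall on narrow curved valleys of the ML discrepancy
    (tiny per-step reduction triggers the ftol exit far from a stationary
    point), so each start is polished by restarting from the incumbent
    until the projected gradient is small or no further progress is made.
    Returns (x, fun, converged).
    """
    best_x, best_f = None, np.inf
    for x0 in starts:
        x, f = x0, np.inf
        for _ in range(_N_POLISH):
            res = optimize.minimize(objective, x, jac=True, method="L-BFGS-B",
                                    bounds=bounds,
                                    options={"maxiter": 4000, "ftol": 1e-15,
                                             "gtol": 1e-9, "maxcor": 30})
            improved = res.fun < f - 1e-12
            x, f = res.x, res.fun
            if _projected_grad_norm(x, res.jac, bounds) < _GRAD_TOL or not improved:
                break
        if f < best_f:
            best_x, best_f = x, f
        if _projected_grad_norm(best_x, objective(best_x)[1], bounds) < _GRAD_TOL:
            break
    converged = _projected_grad_norm(best_x, objective(best_x)[1], bounds) < _GRAD_TOL
    return best_x, float(best_f), converged


def _quad_param_covariance(
    lam: np.ndarray, theta: np.ndarray, phi: float, psi: float, n: int
) -> np.ndarray | None:
    """Asymptotic covariance of the quadratic-model ML estimates.

    Inverse expected information with I_ij = (n/2) tr(S^-1 dS_i S^-1 dS_j);
    parameter order (lambda, theta, phi, psi).  Returns None if the
    information matrix is numerically singular.
    """
    k = lam.size
    big_l = np.column_stack([lam, lam**2])
    phi_m = np.array([[1.0, phi], [phi, psi]])
    sigma = big_l @ phi_m @ big_l.T + np.diag(theta)
    try:
        sigma_inv = np.linalg.inv(sigma)
    except np.linalg.LinAlgError:
        return None
    derivs: list[np.ndarray] = []
    for i in range(k):
        w = big_l @ phi_m @ np.array([1.0, 2.0 * lam[i]])
        d = np.zeros((k, k))
        d[i, :] += w
        d[:, i] += w
        derivs.append(d)
    for i in range(k):
        d = np.zeros((k, k))
        d[i, i] = 1.0
        derivs.append(d)
    derivs.append(np.outer(lam, lam**2) + np.outer(lam**2, lam))
    derivs.append(np.outer(lam**2, lam**2))
    t_mats = [sigma_inv @ d @ sigma_inv for d in derivs]
    p = len(derivs)
    info = np.empty((p, p))
    for i in range(p):
        for j in range(i, p):
            info[i, j] = info[j, i] = 0.5 * np.sum(t_mats[i] * derivs[j])
    try:
        acov = np.linalg.inv(info) / n
    except np.linalg.LinAlgError:
        return None
    return acov


def fit_one_factor(observed_scores: np.ndarray) -> CFAFit:
    """Fit a one-factor CFA by maximum likelihood.

    Minimizes the ML discrepancy over the k loadings and k residual
    variances with var(g) = 1; intercepts are the sample means.  The sign
    convention makes the loading sum positive.  Residual variances are
    bounded below by a small floor; hitting it is flagged as a Heywood case.
    """
    s_raw, mu, n = _sample_cov(observed_scores)
    k = s_raw.shape[0]
    scale = np.sqrt(np.mean(np.diag(s_raw)))
    s = s_raw / scale**2
    _, logdet_s = np.linalg.slogdet(s)

    # start from the first principal component of the scaled covariance
    evals, evecs = np.linalg.eigh(s)
    lam0 = evecs[:, -1] * np.sqrt(max(evals[-1], 1e-3))
    if lam0.sum() < 0:
        lam0 = -lam0
    theta0 = np.maximum(np.diag(s) - lam0**2, 1e-2)

    def objective(params):
        lam, theta = params[:k], params[k:]
        sigma = np.outer(lam, lam) + np.diag(theta)
        f, a = _ml_discrepancy(sigma, s, logdet_s)
        if not np.isfinite(f):
            return 1e10, np.zeros(2 * k)
        grad = np.concatenate([2.0 * (a @ lam), np.diag(a)])
        return f, grad

    bounds = [(None, None)] * k + [(_THETA_FLOOR, None)] * k
    rng = np.random.default_rng(0)
    starts = [np.concatenate([lam0, theta0])]
    for _ in range(_N_RESTARTS):
        jitter = 1.0 + 0.2 * rng.standard_normal(2 * k)
        starts.append(np.concatenate([lam0 * jitter[:k],
                                      np.abs(theta0 * jitter[k:]) + 1e-3]))
    best_x, best_f, converged = _minimize_discrepancy(objective, starts, bounds)

    lam = best_x[:k] * scale
    theta = best_x[k:] * scale**2
    if lam.sum() < 0:
        lam = -lam
    sigma = np.outer(lam, lam) + np.diag(theta)
    return CFAFit(
        loadings=lam,
        residual_variances=theta,
        intercepts=mu,
        implied_covariance=sigma,
        sample_covariance=s_raw,
        loglik=_loglik(n, k, s_raw, sigma),
        discrepancy=best_f,
        n_free_params=2 * k,
        n_obs=n,
        converged=converged,
        heywood=bool(np.any(best_x[k:] <= _THETA_FLOOR * 1.001)),
    )


def fit_linear_plus_quadratic(
    observed_scores: np.ndarray,
    linear_fit: CFAFit | None = None,
    covariance_free: bool = True,
    extra_starts: list[np.ndarray] | None = None,
) -> QuadraticFit:
    """Fit the linear + quadratic latent model by maximum likelihood.

    The implied covariance is ``L Phi L' + diag(theta)`` where L has columns
    (lambda_i) and (lambda_i^2) — the squared-loading constraint is built
    into the parameterisation — and Phi = [[1, phi], [phi, psi]] with the
    quadratic variance psi bounded at 0.  Two free parameters (phi, psi)
    beyond the one-factor model, so the nested LRT has 2 df.

    With ``covariance_free=False`` the latent covariance phi is pinned at 0
    (an orthogonal quadratic factor, one extra parameter); comparing the
    two variants isolates the g-by-g-squared association with a 1-df LRT.
    ``extra_starts`` supplies additional optimizer starting points in the
    internal scaled parameterisation (lam, theta, phi, psi).
    """
    s_raw, mu, n = _sample_cov(observed_scores)
    k = s_raw.shape[0]
    if k < 4:
        raise ValueError(f"quadratic model needs at least 4 tests, got {k}")
    scale = np.sqrt(np.mean(np.diag(s_raw)))
    s = s_raw / scale**2
    _, logdet_s = np.linalg.slogdet(s)

    if linear_fit is None:
        linear_fit = fit_one_factor(observed_scores)
    lam0 = linear_fit.loadings / scale
    theta0 = np.maximum(linear_fit.residual_variances / scale**2, 2 * _THETA_FLOOR)

    # params: lam (k), theta (k), phi, psi
    def objective(params):
        lam, theta = params[:k], params[k:2 * k]
        phi, psi = params[2 * k], params[2 * k + 1]
        big_l = np.column_stack([lam, lam**2])
        phi_m = np.array([[1.0, phi], [phi, psi]])
        sigma = big_l @ phi_m @ big_l.T + np.diag(theta)
        f, a = _ml_discrepancy(sigma, s, logdet_s)
        if not np.isfinite(f):
            return 1e10, np.zeros(2 * k + 2)
        g_l = 2.0 * a @ big_l @ phi_m          # dF/dL
        g_lam = g_l[:, 0] + 2.0 * lam * g_l[:, 1]
        h = big_l.T @ a @ big_l                # dF/dPhi
        grad = np.concatenate([g_lam, np.diag(a), [2.0 * h[0, 1], h[1, 1]]])
        return f, grad

    phi_bound = (None, None) if covariance_free else (0.0, 0.0)
    bounds = ([(None, None)] * k + [(_THETA_FLOOR, None)] * k
              + [phi_bound, (0.0, None)])
    rng = np.random.default_rng(1)
    starts = [np.concatenate([lam0, theta0, [0.0, 1e-3]]),
              np.concatenate([lam0, theta0, [0.0 if not covariance_free else -0.01,
                                             1e-4]])]
    if extra_starts:
        starts = list(extra_starts) + starts
    for _ in range(_N_RESTARTS):
        jitter = 1.0 + 0.2 * rng.standard_normal(k)
        phi0 = 0.0 if not covariance_free else 0.02 * rng.standard_normal()
        starts.append(np.concatenate(
            [lam0 * jitter,
             np.abs(theta0 * (1 + 0.2 * rng.standard_normal(k))) + 1e-3,
             [phi0, 1e-2 * rng.random()]]))
    best_x, best_f, converged = _minimize_discrepancy(objective, starts, bounds)

    # the one-factor solution (phi = psi = 0) is in the feasible set; if the
    # optimizer cannot beat it, the quadratic MLE sits on that boundary
    if best_f > linear_fit.discrepancy:
        best_x = np.concatenate([lam0, np.maximum(linear_fit.residual_variances
                                                  / scale**2, _THETA_FLOOR), [0.0, 0.0]])
        best_f = linear_fit.discrepancy
        converged = linear_fit.converged

    lam = best_x[:k]
    theta = best_x[k:2 * k] * scale**2
    phi, psi = best_x[2 * k], best_x[2 * k + 1]
    # back to the raw metric: lam_raw = c*lam; the quadratic column becomes
    # lam_raw^2 = c^2 lam^2 = c * (c lam^2), so psi and phi absorb 1/c^2, 1/c
    sign = 1.0 if lam.sum() >= 0 else -1.0
    lam_raw = sign * lam * scale
    phi_raw = sign * phi / scale
    psi_raw = psi / scale**2
    big_l = np.column_stack([lam_raw, lam_raw**2])
    phi_m = np.array([[1.0, phi_raw], [phi_raw, psi_raw]])
    sigma = big_l @ phi_m @ big_l.T + np.diag(theta)
    acov = _quad_param_covariance(sign * lam, best_x[k:2 * k], sign * phi, psi, n)
    if acov is not None and acov[2 * k, 2 * k] > 0:
        phi_se = float(np.sqrt(acov[2 * k, 2 * k]) / scale)
    else:
        phi_se = float("nan")
    return QuadraticFit(
        loadings=lam_raw,
        residual_variances=theta,
        intercepts=mu,
        implied_covariance=sigma,
        sample_covariance=s_raw,
        loglik=_loglik(n, k, s_raw, sigma),
        discrepancy=best_f,
        n_free_params=2 * k + 2 if covariance_free else 2 * k + 1,
        n_obs=n,
        converged=converged,
        heywood=bool(np.any(best_x[k:2 * k] <= _THETA_FLOOR * 1.001)),
        quad_variance=float(psi_raw),
        quad_covariance=float(phi_raw),
        quad_covariance_se=phi_se,
        quad_at_boundary=bool(psi <= 1e-12),
    )


# ---------------------------------------------------------------------------
# Factor scores and per-person diagnostics
# ---------------------------------------------------------------------------

def predict_factor_scores(fit: CFAFit, observed_scores: np.ndarray) -> FactorScores:
    """Regression-method factor scores.

    For the one-factor model, ``g_hat = lambda' Sigma^-1 (x - mu)``; for the
    quadratic model the joint predictor over both latents is
    ``Phi L' Sigma^-1 (x - mu)``.  On the var(g)=1 metric these scores are
    shrunken: their variance never exceeds the latent variance.
    """
    x = np.asarray(observed_scores, dtype=float)
    xc = x - fit.intercepts
    try:
        sig_inv = np.linalg.inv(fit.implied_covariance)
    except np.linalg.LinAlgError as err:
        raise ValueError("singular implied covariance") from err
    if isinstance(fit, QuadraticFit):
        weights = fit.factor_cov @ fit.loading_matrix.T @ sig_inv  # (2, k)
        scores = xc @ weights.T
        return FactorScores(g_hat=scores[:, 0], q_hat=scores[:, 1])
    g_hat = xc @ (sig_inv @ fit.loadings)
    return FactorScores(g_hat=g_hat)


def skewness_test(values: np.ndarray) -> SkewTest:
    """Sample skewness with its exact-normal-theory significance test.

    Skewness is the moment ratio g1 = m3 / m2^{3/2}; its null standard
    error under normality is sqrt(6n(n-1) / ((n-2)(n+1)(n+3))), and the
    two-sided p-value comes from the normal reference distribution.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 8:
        raise ValueError(f"need at least 8 values for the skewness test, got {n}")
    xc = x - x.mean()
    m2 = np.mean(xc**2)
    if m2 == 0:
        raise ValueError("zero variance; skewness undefined")
    g1 = np.mean(xc**3) / m2**1.5
    se = np.sqrt(6.0 * n * (n - 1) / ((n - 2) * (n + 1) * (n + 3)))
    z = g1 / se
    p = 2.0 * stats.norm.sf(abs(z))
    return SkewTest(skew=float(g1), se=float(se), z=float(z), p=float(p))


def individual_log_residual_variance(
    fit: CFAFit,
    scores: np.ndarray,
    g_hat: np.ndarray,
    floor: float = _LOG_RV_FLOOR,
) -> np.ndarray:
    """Log of each person's mean squared deviation from model-predicted scores.

    The predicted score on test i is ``mu_i + lambda_i * g_hat``; the mean
    over tests of the squared observed-minus-predicted differences is that
    person's residual variance.  Values are floored before the log so
    noiseless degenerate inputs do not produce -inf.
    """
    x = np.asarray(scores, dtype=float)
    g_hat = np.asarray(g_hat, dtype=float)
    if x.shape[0] != g_hat.shape[0]:
        raise ValueError("scores and factor scores must have the same length")
    predicted = fit.intercepts[None, :] + g_hat[:, None] * fit.loadings[None, :]
    rv = np.mean((x - predicted) ** 2, axis=1)
    return np.log(np.maximum(rv, floor))


def correlation_with_p(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Pearson correlation with its two-sided t-test p-value."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("need two equal-length vectors of at least 3 values")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("correlation undefined for a constant input")
    res = stats.pearsonr(a, b)
    return float(res.statistic), float(res.pvalue)


def likelihood_ratio_test(
    fit_restricted: CFAFit,
    fit_full: CFAFit,
    tol: float = 1e-6,
) -> tuple[float, int, float]:
    """Chi-square difference test of two nested ML fits on the same data.

    Returns (delta_chi2, df, p).  The statistic is n times the drop in the
    ML discrepancy (equivalently twice the log-likelihood gain).  A
    materially negative statistic signals an optimizer failure and raises.
    """
    if fit_restricted.n_obs != fit_full.n_obs:
        raise ValueError("fits must be on the same data")
    df = fit_full.n_free_params - fit_restricted.n_free_params
    if df <= 0:
        raise ValueError("full model must have more free parameters")
    delta = fit_restricted.n_obs * (fit_restricted.discrepancy - fit_full.discrepancy)
    if delta < -tol * fit_restricted.n_obs:
        raise ValueError(
            f"negative chi-square difference ({delta:.3g}); optimizer failure"
        )
    delta = max(delta, 0.0)
    p = float(stats.chi2.sf(delta, df))
    return float(delta), df, p


# ---------------------------------------------------------------------------
# Criterion evaluation
# ---------------------------------------------------------------------------

def evaluate_slodr_criteria(observed_scores: np.ndarray, alpha: float = 0.05) -> CriteriaResult:
    """Run the full contemporary-criteria pipeline on one score matrix.

    One-factor CFA -> factor scores -> skewness test; correlation of g with
    log individual residual variance; quadratic-model LRT; correlation of
    the estimated linear and quadratic factor scores.  Each criterion flag
    requires two-sided significance at ``alpha`` with the required sign.
    Non-converged fits leave their criteria unfulfilled rather than
    dropping the run.
    """
    linear = fit_one_factor(observed_scores)
    scores = predict_factor_scores(linear, observed_scores)
    sk = skewness_test(scores.g_hat)
    log_rv = individual_log_residual_variance(linear, observed_scores, scores.g_hat)
    res_r, res_p = correlation_with_p(scores.g_hat, log_rv)

    # orthogonal (phi = 0) quadratic fit first; its solution seeds the free
    # fit so the nesting orth >= full holds numerically
    orth = fit_linear_plus_quadratic(observed_scores, linear_fit=linear,
                                     covariance_free=False)
    scale = np.sqrt(np.mean(np.diag(orth.sample_covariance)))
    seed_start = np.concatenate([orth.loadings / scale,
                                 np.maximum(orth.residual_variances / scale**2,
                                            2 * _THETA_FLOOR),
                                 [0.0, max(orth.quad_variance * scale**2, 1e-4)]])
    quad = fit_linear_plus_quadratic(observed_scores, linear_fit=linear,
                                     extra_starts=[seed_start])
    lrt_stat, _, lrt_p = likelihood_ratio_test(linear, quad)
    # the g-by-g^2 association is the latent covariance: a 1-df LRT of
    # phi = 0 vs free, signed by the estimate.  (Wald tests on phi are
    # unstable here because the latent covariance matrix of the fitted
    # quadratic model is typically close to singular, and score-level
    # correlations are pinned near +/-1 by the same near-collinearity.)
    gg2_stat, _, gg2_p = likelihood_ratio_test(orth, quad)
    gg2_r = quad.latent_correlation

    converged = linear.converged and quad.converged
    neg_skew = linear.converged and sk.p < alpha and sk.skew < 0
    pos_res = linear.converged and res_p < alpha and res_r > 0
    sig_quad = converged and lrt_p < alpha
    neg_gg2 = (quad.converged and orth.converged and gg2_p < alpha
               and quad.quad_covariance < 0)
    if sk.p < alpha:
        direction = "negative" if sk.skew < 0 else "positive"
    else:
        direction = "none"
    return CriteriaResult(
        skew_value=sk.skew,
        skew_p=sk.p,
        skew_direction=direction,
        res_corr=res_r,
        res_corr_p=res_p,
        quad_lrt_stat=lrt_stat,
        quad_lrt_p=lrt_p,
        g_g2_corr=gg2_r,
        g_g2_corr_p=gg2_p,
        negatively_skewed_g=neg_skew,
        positive_res_corr=pos_res,
        significant_quadratic=sig_quad,
        negative_g_g2_corr=neg_gg2,
        all_crucial=neg_skew and pos_res and sig_quad and neg_gg2,
        converged=converged,
    )
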