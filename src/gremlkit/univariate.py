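"""Single-trait GREML: restricted maximum likelihood for y = Xb + g + e.

The model is g ~ N(0, G sigma_g^2), e ~ N(0, I sigma_e^2), with G a
genomic relationship matrix.  The restricted log-likelihood is

    logL = -1/2 [ log|V| + log|X' V^-1 X| + y' P y ],
    V = G sigma_g^2 + I sigma_e^2,
    P = V^-1 - V^-1 X (X' V^-1 X)^-1 X' V^-1,

with the (n - p)/2 log(2 pi) constant dropped (documented so external
grid-search checks can use the same convention).  Fitting uses one (or
more) EM warm-up iterations followed by average-information (AI) REML
updates with step-halving, components floored at a small fraction of the
phenotypic variance.  Internally G is eigendecomposed once so that every
iteration works with a diagonal V — identical to the dense path, just
O(n) per iteration after the one-off O(n^3) rotation.

Heritability h^2 = sigma_g^2 / (sigma_g^2 + sigma_e^2); its standard
error comes from the inverse-AI sampling covariance by the delta method
with gradient (sigma_e^2, -sigma_g^2) / Vp^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as sla

from .data import GRM
from .errors import NonIdentifiableError, ValidationError


@dataclass
class RemlSettings:
    """Optimizer knobs shared by the univariate and bivariate fitters."""

    max_iterations: int = 100
    loglik_tolerance: float = 1e-4
    em_warmup_iterations: int = 1
    variance_floor_fraction: float = 1e-6

    def __post_init__(self) -> None:
        if self.loglik_tolerance <= 0:
            raise ValidationError("loglik_tolerance must be > 0")
        if not 0 < self.variance_floor_fraction <= 0.01:
            raise ValidationError("variance_floor_fraction must be in (0, 0.01]")


@dataclass
class VarianceComponents:
    """Univariate REML estimates and their sampling uncertainty."""

    sigma_g2: float
    sigma_e2: float
    sigma_p2: float
    h2: float
    se_sigma_g2: float
    se_sigma_e2: float
    se_h2: float
    loglik: float
    n_iterations: int
    converged: bool
    sampling_covariance: np.ndarray
    loglik_trace: list[float] = field(default_factory=list, repr=False)


def _as_design(X: np.ndarray | None, n: int) -> np.ndarray:
    if X is None:
        return np.ones((n, 1))
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    if X.shape[0] != n:
        X = X.T
    if X.shape[0] != n:
        raise ValidationError(f"design matrix rows != {n}")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValidationError("design matrix X is rank deficient")
    return X


def reml_loglikelihood(y: np.ndarray, X: np.ndarray | None, grm: GRM,
                       sigma_g2: float, sigma_e2: float) -> float:
    """Dense evaluation of the restricted log-likelihood (see module doc)."""
    y = np.asarray(y, dtype=np.float64).ravel()
    n = y.size
    if grm.n != n:
        raise ValidationError("y length does not match GRM")
    X = _as_design(X, n)
    V = sigma_g2 * grm.values + sigma_e2 * np.eye(n)
    sign, logdet_v = np.linalg.slogdet(V)
    if sign <= 0:
        raise ValidationError("V is not positive definite")
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    sign_x, logdet_x = np.linalg.slogdet(XtViX)
    if sign_x <= 0:
        raise ValidationError("X' V^-1 X is singular")
    beta = np.linalg.solve(XtViX, X.T @ (Vi @ y))
    Py = Vi @ (y - X @ beta)
    return float(-0.5 * (logdet_v + logdet_x + y @ Py))


class _Rotated:
    """The model after rotation by the eigenvectors of G (V diagonal)."""

    def __init__(self, grm_values: np.ndarray, y: np.ndarray, X: np.ndarray):
        lam, U = np.linalg.eigh(grm_values)
        self.lam = np.clip(lam, 0.0, None)
        self.ys = U.T @ y
        self.Xs = U.T @ X
        self.n = y.size
        self.p = X.shape[1]

    def _core(self, sg2: float, se2: float):
        v = sg2 * self.lam + se2
        if v.min() <= 0:
            return None
        w = 1.0 / v
        Xw = self.Xs * w[:, None]
        C = self.Xs.T @ Xw
        cho = sla.cho_factor(C, lower=True)
        beta = sla.cho_solve(cho, self.Xs.T @ (self.ys * w))
        q = (self.ys - self.Xs @ beta) * w  # = P y
        logdet_c = 2.0 * np.log(np.diag(cho[0])).sum()
        ll = -0.5 * (np.log(v).sum() + logdet_c + self.ys @ q)
        return v, w, cho, q, float(ll)

    def loglik(self, sg2: float, se2: float) -> float:
        core = self._core(sg2, se2)
        return -np.inf if core is None else core[4]

    def _apply_p(self, vec: np.ndarray, w: np.ndarray, cho) -> np.ndarray:
        alpha = sla.cho_solve(cho, self.Xs.T @ (vec * w))
        return (vec - self.Xs @ alpha) * w

    def _traces(self, w: np.ndarray, cho, weights: np.ndarray) -> float:
        # tr(P diag(weights)) without forming P
        t1 = float((weights * w).sum())
        B = self.Xs * (weights * w * w)[:, None]
        t2 = float(np.trace(sla.cho_solve(cho, self.Xs.T @ B)))
        return t1 - t2

    def score_ai(self, sg2: float, se2: float):
        """Score vector, AI matrix, Py-quadratics and logL at (sg2, se2)."""
        core = self._core(sg2, se2)
        if core is None:
            raise ValidationError("V not positive definite")
        v, w, cho, q, ll = core
        tr_pg = self._traces(w, cho, self.lam)
        tr_p = self._traces(w, cho, np.ones(self.n))
        y_pgp = float(q @ (self.lam * q))
        y_pp = float(q @ q)
        score = np.array([-0.5 * (tr_pg - y_pgp), -0.5 * (tr_p - y_pp)])
        gq = self.lam * q
        pg = self._apply_p(gq, w, cho)
        pe = self._apply_p(q, w, cho)
        ai = 0.5 * np.array([[gq @ pg, gq @ pe], [q @ pg, q @ pe]])
        ai = 0.5 * (ai + ai.T)
        return score, ai, (y_pgp, tr_pg, y_pp, tr_p), ll

    def em_step(self, sg2: float, se2: float) -> tuple[float, float]:
        _, _, (y_pgp, tr_pg, y_pp, tr_p), _ = self.score_ai(sg2, se2)
        return (sg2 + (sg2 * sg2 / self.n) * (y_pgp - tr_pg),
                se2 + (se2 * se2 / self.n) * (y_pp - tr_p))


def fit_greml_univariate(y: np.ndarray, grm: GRM,
                         X: np.ndarray | None = None,
                         settings: RemlSettings | None = None
                         ) -> VarianceComponents:
    """AI-REML fit of (sigma_g^2, sigma_e^2) for one trait.

    ``y`` must be complete and aligned with ``grm.individual_ids``
    (higher-level pipelines handle ID matching).  Raises
    :class:`NonIdentifiableError` when G is (numerically) proportional
    to the identity, in which case only sigma_g^2 + sigma_e^2 is
    identified and the AI matrix is singular.
    """
    settings = settings or RemlSettings()
    y = np.asarray(y, dtype=np.float64).ravel()
    n = y.size
    if grm.n != n:
        raise ValidationError("y length does not match GRM")
    if n < 10:
        raise ValidationError(f"need n >= 10 individuals, got {n}")
    if not np.isfinite(y).all():
        raise ValidationError("y contains missing values; drop them first")
    X = _as_design(X, n)

    rot = _Rotated(grm.values, y, X)
    if np.ptp(rot.lam) < 1e-9 * max(1.0, rot.lam.max()):
        raise NonIdentifiableError(
            "GRM is numerically proportional to the identity; "
            "sigma_g^2 and sigma_e^2 are not separately identifiable")

    resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
    vp = float(resid.var(ddof=X.shape[1]))
    if vp <= 0:
        raise ValidationError("phenotype has zero variance")
    floor = settings.variance_floor_fraction * vp
    theta = np.array([vp / 2.0, vp / 2.0])
    ll = rot.loglik(*theta)
    trace = [ll]

    n_iter = 0
    converged = False
    for _ in range(settings.em_warmup_iterations):
        theta = np.maximum(rot.em_step(*theta), floor)
        new_ll = rot.loglik(*theta)
        trace.append(new_ll)
        n_iter += 1
        if abs(new_ll - ll) < settings.loglik_tolerance:
            converged = True
        ll = new_ll

    while n_iter < settings.max_iterations and not converged:
        score, ai, _, _ = rot.score_ai(*theta)
        try:
            delta = np.linalg.solve(ai, score)
        except np.linalg.LinAlgError as e:
            raise NonIdentifiableError(f"singular AI matrix: {e}") from None
        if not np.isfinite(delta).all() or np.linalg.cond(ai) > 1e12:
            raise NonIdentifiableError("singular AI matrix")
        step = 1.0
        for _ in range(30):  # step-halving
            cand = np.maximum(theta + step * delta, floor)
            cand_ll = rot.loglik(*cand)
            if cand_ll >= ll - 1e-10:
                break
            step *= 0.5
        theta, new_ll = cand, cand_ll
        trace.append(new_ll)
        n_iter += 1
        if abs(new_ll - ll) < settings.loglik_tolerance:
            converged = True
        ll = new_ll

    sg2, se2 = float(theta[0]), float(theta[1])
    _, ai, _, ll = rot.score_ai(sg2, se2)
    try:
        sampling_cov = np.linalg.inv(ai)
    except np.linalg.LinAlgError as e:
        raise NonIdentifiableError(f"singular AI matrix at optimum: {e}") from None
    vp_hat = sg2 + se2
    h2 = sg2 / vp_hat
    grad = np.array([se2, -sg2]) / vp_hat ** 2
    var_h2 = float(grad @ sampling_cov @ grad)
    return VarianceComponents(
        sigma_g2=sg2,
        sigma_e2=se2,
        sigma_p2=vp_hat,
        h2=h2,
        se_sigma_g2=float(np.sqrt(max(sampling_cov[0, 0], 0.0))),
        se_sigma_e2=float(np.sqrt(max(sampling_cov[1, 1], 0.0))),
        se_h2=float(np.sqrt(max(var_h2, 0.0))),
        loglik=float(ll),
        n_iterations=n_iter,
        converged=converged,
        sampling_covariance=sampling_cov,
        loglik_trace=trace,
    )
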