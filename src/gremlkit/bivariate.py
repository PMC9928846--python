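"""Bivariate GREML: genetic covariance, rG and rP for a trait pair.

The two-trait animal model stacks both traits (one record per animal, so
the random-effect incidence matrix is the identity) and puts

    V = Sigma_g (x) G  +  Sigma_e (x) I

with 2x2 trait covariance matrices Sigma_g (genetic) and Sigma_e
(residual).  The six free parameters are ordered
(sg1^2, sg12, sg2^2, se1^2, se12, se2^2) — fixed for the
sampling-covariance contract.  Fitting rotates by the eigenvectors of G,
turning V into n independent 2x2 blocks ``lam_i Sigma_g + Sigma_e``, and
runs EM warm-up plus AI-REML with step-halving; after every update the
trait covariance matrices are bent (negative eigenvalues floored) so the
model stays valid.  Standard errors of rG and rP come from the 6x6
inverse-AI sampling covariance by the delta method.

Numerical determinism: internally the pair is fitted in a canonical
trait order (lexicographic on the phenotype bytes) and mapped back, so
swapping the input traits yields bit-identical rG, rP and logL.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as sla

from .data import GRM
from .errors import NonIdentifiableError, ValidationError
from .univariate import RemlSettings, _as_design

# symmetric basis matrices for (var1, cov12, var2)
_BASIS = np.array([
    [[1.0, 0.0], [0.0, 0.0]],
    [[0.0, 1.0], [1.0, 0.0]],
    [[0.0, 0.0], [0.0, 1.0]],
])


@dataclass
class BivariateEstimates:
    """Bivariate REML estimates; parameter order (g1, g12, g2, e1, e12, e2)."""

    sigma_g2_1: float
    sigma_g2_2: float
    cov_g_12: float
    sigma_e2_1: float
    sigma_e2_2: float
    cov_e_12: float
    r_g: float
    r_p: float
    se_r_g: float
    se_r_p: float
    loglik: float
    converged: bool
    sampling_covariance: np.ndarray
    boundary: bool = False
    n_iterations: int = 0
    loglik_trace: list[float] = field(default_factory=list, repr=False)


def genetic_correlation(cov_g: float, var_g1: float, var_g2: float) -> float:
    """rG = cov_g / sqrt(var_g1 var_g2); values outside [-1, 1] warn."""
    if var_g1 <= 0 or var_g2 <= 0:
        raise ValidationError("genetic variances must be positive")
    r = cov_g / np.sqrt(var_g1 * var_g2)
    if abs(r) > 1:
        warnings.warn(f"genetic correlation {r:.4f} outside [-1, 1]",
                      stacklevel=2)
    return float(r)


def phenotypic_correlation(cov_g: float, cov_e: float, var_g1: float,
                           var_e1: float, var_g2: float, var_e2: float
                           ) -> float:
    """rP = (cov_g + cov_e) / sqrt((var_g1+var_e1)(var_g2+var_e2))."""
    vp1 = var_g1 + var_e1
    vp2 = var_g2 + var_e2
    if vp1 <= 0 or vp2 <= 0:
        raise ValidationError("phenotypic variances must be positive")
    return float((cov_g + cov_e) / np.sqrt(vp1 * vp2))


def _bend(sigma: np.ndarray, eig_floor: float, diag_floor: np.ndarray
          ) -> np.ndarray:
    """Floor the eigenvalues (bending) and the diagonal of a 2x2 matrix."""
    sigma = 0.5 * (sigma + sigma.T)
    w, v = np.linalg.eigh(sigma)
    if w.min() < eig_floor:
        sigma = (v * np.maximum(w, eig_floor)) @ v.T
        sigma = 0.5 * (sigma + sigma.T)
    d = np.diag(sigma).copy()
    if (d < diag_floor).any():
        d = np.maximum(d, diag_floor)
        r = sigma[0, 1] / np.sqrt(sigma[0, 0] * sigma[1, 1]) \
            if sigma[0, 0] > 0 and sigma[1, 1] > 0 else 0.0
        sigma = np.array([
            [d[0], r * np.sqrt(d[0] * d[1])],
            [r * np.sqrt(d[0] * d[1]), d[1]],
        ])
    return sigma


class _RotatedBivariate:
    """Two-trait model rotated by the eigenvectors of G: V is n 2x2 blocks."""

    def __init__(self, grm_values: np.ndarray, y1, y2, X1, X2):
        lam, U = np.linalg.eigh(grm_values)
        self.lam = np.clip(lam, 0.0, None)
        self.n = y1.size
        self.ys = np.column_stack([U.T @ y1, U.T @ y2])  # (n, 2)
        X1s, X2s = U.T @ X1, U.T @ X2
        p1, p2 = X1.shape[1], X2.shape[1]
        self.p = p1 + p2
        self.Xf = np.zeros((self.n, 2, self.p))
        self.Xf[:, 0, :p1] = X1s
        self.Xf[:, 1, p1:] = X2s

    # -- block algebra -----------------------------------------------------

    def _core(self, sg: np.ndarray, se: np.ndarray):
        Vb = self.lam[:, None, None] * sg + se  # (n, 2, 2)
        det = Vb[:, 0, 0] * Vb[:, 1, 1] - Vb[:, 0, 1] ** 2
        if det.min() <= 0 or Vb[:, 0, 0].min() <= 0:
            return None
        Vinv = np.empty_like(Vb)
        Vinv[:, 0, 0] = Vb[:, 1, 1] / det
        Vinv[:, 1, 1] = Vb[:, 0, 0] / det
        Vinv[:, 0, 1] = Vinv[:, 1, 0] = -Vb[:, 0, 1] / det
        Z = np.einsum("nrs,nsp->nrp", Vinv, self.Xf)
        C = np.einsum("nrp,nrq->pq", self.Xf, Z)
        try:
            cho = sla.cho_factor(C, lower=True)
        except sla.LinAlgError:
            return None
        t = np.einsum("nrs,ns->nr", Vinv, self.ys)
        beta = sla.cho_solve(cho, np.einsum("nrp,nr->p", self.Xf, t))
        resid = self.ys - np.einsum("nrp,p->nr", self.Xf, beta)
        q = np.einsum("nrs,ns->nr", Vinv, resid)  # = P y
        logdet_c = 2.0 * np.log(np.diag(cho[0])).sum()
        ll = -0.5 * (np.log(det).sum() + logdet_c + (self.ys * q).sum())
        return Vinv, Z, cho, q, float(ll)

    def loglik(self, sg: np.ndarray, se: np.ndarray) -> float:
        core = self._core(sg, se)
        return -np.inf if core is None else core[4]

    def _apply_p(self, w: np.ndarray, Vinv, cho) -> np.ndarray:
        tw = np.einsum("nrs,ns->nr", Vinv, w)
        alpha = sla.cho_solve(cho, np.einsum("nrp,nr->p", self.Xf, tw))
        u = w - np.einsum("nrp,p->nr", self.Xf, alpha)
        return np.einsum("nrs,ns->nr", Vinv, u)

    def iteration_quantities(self, sg: np.ndarray, se: np.ndarray):
        """Score, AI matrix, EM trace/quadratic matrices and logL."""
        core = self._core(sg, se)
        if core is None:
            raise ValidationError("V not positive definite")
        Vinv, Z, cho, q, ll = core
        Cinv = sla.cho_solve(cho, np.eye(self.p))
        Pb = Vinv - np.einsum("nrp,pq,nsq->nrs", Z, Cinv, Z)  # 2x2 blocks of P
        Tg = np.einsum("n,nab->ab", self.lam, Pb)
        Te = Pb.sum(axis=0)
        Qg = np.einsum("n,na,nb->ab", self.lam, q, q)
        Qe = q.T @ q

        score = np.empty(6)
        wvecs = []
        for k in range(3):
            B = _BASIS[k]
            score[k] = -0.5 * ((Tg * B).sum() - (Qg * B).sum())
            score[3 + k] = -0.5 * ((Te * B).sum() - (Qe * B).sum())
            wvecs.append(self.lam[:, None] * (q @ B))
        for k in range(3):
            wvecs.append(q @ _BASIS[k])
        pw = [self._apply_p(w, Vinv, cho) for w in wvecs]
        ai = 0.5 * np.array([[float((wvecs[k] * pw[l]).sum())
                              for l in range(6)] for k in range(6)])
        ai = 0.5 * (ai + ai.T)
        return score, ai, (Qg, Tg, Qe, Te), ll

    def em_step(self, sg: np.ndarray, se: np.ndarray):
        _, _, (Qg, Tg, Qe, Te), _ = self.iteration_quantities(sg, se)
        sg_new = sg + (sg @ (Qg - Tg) @ sg) / self.n
        se_new = se + (se @ (Qe - Te) @ se) / self.n
        return sg_new, se_new


def _pack(sg: np.ndarray, se: np.ndarray) -> np.ndarray:
    return np.array([sg[0, 0], sg[0, 1], sg[1, 1],
                     se[0, 0], se[0, 1], se[1, 1]])


def _unpack(theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    sg = np.array([[theta[0], theta[1]], [theta[1], theta[2]]])
    se = np.array([[theta[3], theta[4]], [theta[4], theta[5]]])
    return sg, se


def fit_greml_bivariate(y1: np.ndarray, y2: np.ndarray, grm: GRM,
                        X1: np.ndarray | None = None,
                        X2: np.ndarray | None = None,
                        settings: RemlSettings | None = None
                        ) -> BivariateEstimates:
    """AI-REML fit of the six (co)variance parameters for a trait pair.

    Both traits must be complete on the same individuals, aligned with
    the GRM order (complete-case analysis; higher levels drop
    single-trait records with a logged count).
    """
    settings = settings or RemlSettings()
    y1 = np.asarray(y1, dtype=np.float64).ravel()
    y2 = np.asarray(y2, dtype=np.float64).ravel()
    n = y1.size
    if y2.size != n or grm.n != n:
        raise ValidationError("y1, y2 and GRM sizes do not match")
    if n < 20:
        raise ValidationError(f"need n >= 20 individuals, got {n}")
    if not (np.isfinite(y1).all() and np.isfinite(y2).all()):
        raise ValidationError("phenotypes contain missing values")
    X1 = _as_design(X1, n)
    X2 = _as_design(X2, n)

    # canonical trait order => exact swap symmetry of rG, rP, logL
    swapped = y1.tobytes() > y2.tobytes()
    if swapped:
        y1, y2, X1, X2 = y2, y1, X2, X1

    rot = _RotatedBivariate(grm.values, y1, y2, X1, X2)
    if np.ptp(rot.lam) < 1e-9 * max(1.0, rot.lam.max()):
        raise NonIdentifiableError(
            "GRM is numerically proportional to the identity")

    vp = np.empty(2)
    resids = []
    for j, (yj, Xj) in enumerate(((y1, X1), (y2, X2))):
        r = yj - Xj @ np.linalg.lstsq(Xj, yj, rcond=None)[0]
        resids.append(r)
        vp[j] = r.var(ddof=Xj.shape[1])
    if vp.min() <= 0:
        raise ValidationError("a phenotype has zero variance")
    c12 = float(np.cov(resids[0], resids[1])[0, 1])
    diag_floor = settings.variance_floor_fraction * vp
    eig_floor = settings.variance_floor_fraction * float(vp.mean())

    sg = np.array([[vp[0] / 2, c12 / 2], [c12 / 2, vp[1] / 2]])
    se = sg.copy()
    sg = _bend(sg, eig_floor, diag_floor)
    se = _bend(se, eig_floor, diag_floor)
    ll = rot.loglik(sg, se)
    trace = [ll]

    n_iter = 0
    converged = False
    for _ in range(settings.em_warmup_iterations):
        sg, se = rot.em_step(sg, se)
        sg = _bend(sg, eig_floor, diag_floor)
        se = _bend(se, eig_floor, diag_floor)
        new_ll = rot.loglik(sg, se)
        trace.append(new_ll)
        n_iter += 1
        if abs(new_ll - ll) < settings.loglik_tolerance:
            converged = True
        ll = new_ll

    while n_iter < settings.max_iterations and not converged:
        score, ai, _, _ = rot.iteration_quantities(sg, se)
        try:
            delta = np.linalg.solve(
                ai + 1e-12 * np.eye(6) * max(1.0, np.abs(np.diag(ai)).max()),
                score)
        except np.linalg.LinAlgError as e:
            raise NonIdentifiableError(f"singular AI matrix: {e}") from None
        if not np.isfinite(delta).all():
            raise NonIdentifiableError("singular AI matrix")
        theta = _pack(sg, se)
        step = 1.0
        for _ in range(30):
            cand_sg, cand_se = _unpack(theta + step * delta)
            cand_sg = _bend(cand_sg, eig_floor, diag_floor)
            cand_se = _bend(cand_se, eig_floor, diag_floor)
            cand_ll = rot.loglik(cand_sg, cand_se)
            if cand_ll >= ll - 1e-10:
                break
            step *= 0.5
        sg, se, new_ll = cand_sg, cand_se, cand_ll
        trace.append(new_ll)
        n_iter += 1
        if abs(new_ll - ll) < settings.loglik_tolerance:
            converged = True
        ll = new_ll

    _, ai, _, ll = rot.iteration_quantities(sg, se)
    try:
        sampling_cov = np.linalg.inv(ai)
    except np.linalg.LinAlgError:
        sampling_cov = np.linalg.pinv(ai)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r_g = genetic_correlation(sg[0, 1], sg[0, 0], sg[1, 1])
    r_p = phenotypic_correlation(sg[0, 1], se[0, 1], sg[0, 0], se[0, 0],
                                 sg[1, 1], se[1, 1])
    boundary = abs(r_g) >= 1.0 - 1e-3

    # delta-method gradients in the order (g1, g12, g2, e1, e12, e2)
    g1, g12, g2 = sg[0, 0], sg[0, 1], sg[1, 1]
    e1, e12, e2 = se[0, 0], se[0, 1], se[1, 1]
    grad_rg = np.array([-r_g / (2 * g1), 1.0 / np.sqrt(g1 * g2),
                        -r_g / (2 * g2), 0.0, 0.0, 0.0])
    vp1, vp2 = g1 + e1, g2 + e2
    grad_rp = np.array([-r_p / (2 * vp1), 1.0 / np.sqrt(vp1 * vp2),
                        -r_p / (2 * vp2), -r_p / (2 * vp1),
                        1.0 / np.sqrt(vp1 * vp2), -r_p / (2 * vp2)])
    se_rg = float(np.sqrt(max(grad_rg @ sampling_cov @ grad_rg, 0.0)))
    se_rp = float(np.sqrt(max(grad_rp @ sampling_cov @ grad_rp, 0.0)))

    if swapped:
        g1, g2 = g2, g1
        e1, e2 = e2, e1
        perm = np.array([2, 1, 0, 5, 4, 3])
        sampling_cov = sampling_cov[np.ix_(perm, perm)]

    return BivariateEstimates(
        sigma_g2_1=float(g1), sigma_g2_2=float(g2), cov_g_12=float(g12),
        sigma_e2_1=float(e1), sigma_e2_2=float(e2), cov_e_12=float(e12),
        r_g=r_g, r_p=r_p, se_r_g=se_rg, se_r_p=se_rp,
        loglik=float(ll), converged=converged,
        sampling_covariance=sampling_cov, boundary=boundary,
        n_iterations=n_iter, loglik_trace=trace,
    )
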