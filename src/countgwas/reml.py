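"""Variance-component REML on a genetic relationship matrix.

Univariate model:  y = X b + g + e,  cov(g) = sigma2_g * A,  cov(e) = sigma2_e * I.
Bivariate model: two traits measured on the same individuals share the GRM;
the genetic and residual (co)variance structures are 2x2 matrices G and E,
and the genetic correlation is r_g = G12 / sqrt(G11 * G22) (r_e analogous).

Both fits work in the eigenbasis of A (one symmetric eigendecomposition per
fit), where V is diagonal (univariate) or 2x2-block-diagonal (bivariate),
making every average-information (AI) iteration O(n). The update scheme is
AI steps with step-halving, falling back to EM (univariate) or a bounded
derivative-free search (bivariate) when the AI step is unusable. Standard
errors come from the inverse AI matrix at the optimum; the heritability and
correlation SEs use the delta method. The heritability likelihood-ratio test
against sigma2_g = 0 is referenced to chi-square(1) by default, with the
0.5*chi2(0) + 0.5*chi2(1) boundary mixture available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.stats import chi2

from .grm import GRM

_TOL_LOGLIK = 1e-6
_TOL_PARAM = 1e-6
_MAX_ITER = 100


class RemlConvergenceError(RuntimeError):
    def __init__(self, message: str, trajectory: list[float]):
        super().__init__(message)
        self.trajectory = trajectory


@dataclass
class RemlFit:
    h2: float
    se_h2: float
    var_g: float
    var_e: float
    loglik: float
    lrt_stat: float
    lrt_df: int
    p_value: float
    n: int
    converged: bool
    n_iter: int
    trajectory: list[float] = field(default_factory=list, repr=False)


@dataclass
class BivarRemlFit:
    rg: float
    se_rg: float
    re: float
    se_re: float
    var_g1: float
    var_g2: float
    cov_g12: float
    var_e1: float
    var_e2: float
    cov_e12: float
    loglik: float
    n: int
    converged: bool
    rg_defined: bool
    re_defined: bool


def _grm_values(A) -> tuple[np.ndarray, list[str] | None]:
    if isinstance(A, GRM):
        return A.values, A.sample_ids
    return np.asarray(A, dtype=float), None


# ---------------------------------------------------------------------------
# univariate


class _UniREML:
    """AI-REML for one trait in the eigenbasis of the GRM."""

    def __init__(self, d: np.ndarray, yt: np.ndarray, Xt: np.ndarray):
        self.d = d
        self.y = yt
        self.X = Xt
        self.n, self.p = Xt.shape

    def loglik(self, sg: float, se: float) -> float:
        v = sg * self.d + se
        if np.min(v) <= 0:
            return -np.inf
        Xw = self.X / v[:, None]
        XtVX = self.X.T @ Xw
        sign, logdet_x = np.linalg.slogdet(XtVX)
        if sign <= 0:
            return -np.inf
        beta = np.linalg.solve(XtVX, Xw.T @ self.y)
        r = self.y - self.X @ beta
        return -0.5 * (np.sum(np.log(v)) + logdet_x + float(r @ (r / v)))

    def _state(self, sg: float, se: float):
        v = sg * self.d + se
        Xw = self.X / v[:, None]
        XtVX = self.X.T @ Xw
        XtVX_inv = np.linalg.inv(XtVX)
        beta = XtVX_inv @ (Xw.T @ self.y)
        r = self.y - self.X @ beta
        Py = r / v
        return v, Xw, XtVX_inv, Py

    def _applyP(self, w: np.ndarray, v, Xw, XtVX_inv) -> np.ndarray:
        wv = w / v
        return wv - Xw @ (XtVX_inv @ (self.X.T @ wv))

    def score_ai(self, sg: float, se: float):
        v, Xw, XtVX_inv, Py = self._state(sg, se)
        derivs = (self.d, np.ones(self.n))
        score = np.empty(2)
        u = []
        for i, dv in enumerate(derivs):
            tr_VinvD = float(np.sum(dv / v))
            M = self.X.T @ (self.X * (dv / v**2)[:, None])
            trPD = tr_VinvD - float(np.trace(XtVX_inv @ M))
            yPDPy = float(np.sum(Py * Py * dv))
            score[i] = -0.5 * (trPD - yPDPy)
            u.append(dv * Py)
        AI = np.empty((2, 2))
        for i in range(2):
            Pu = self._applyP(u[i], v, Xw, XtVX_inv)
            for j in range(2):
                AI[i, j] = 0.5 * float(u[j] @ Pu)
        AI = 0.5 * (AI + AI.T)
        return score, AI

    def em_step(self, sg: float, se: float) -> tuple[float, float]:
        v, Xw, XtVX_inv, Py = self._state(sg, se)
        out = []
        for s, dv in ((sg, self.d), (se, np.ones(self.n))):
            tr_VinvD = float(np.sum(dv / v))
            M = self.X.T @ (self.X * (dv / v**2)[:, None])
            trPD = tr_VinvD - float(np.trace(XtVX_inv @ M))
            yPDPy = float(np.sum(Py * Py * dv))
            out.append(s + s * s * (yPDPy - trPD) / self.n)
        return out[0], out[1]


def _prepare(A, y, covariates):
    values, ids = _grm_values(A)
    y = np.asarray(y, dtype=float)
    if y.shape[0] != values.shape[0]:
        raise ValueError("phenotype length does not match GRM dimension")
    if covariates is not None:
        covariates = np.asarray(covariates, dtype=float)
        if covariates.ndim == 1:
            covariates = covariates[:, None]
        ok = np.isfinite(y) & np.all(np.isfinite(covariates), axis=1)
    else:
        ok = np.isfinite(y)
    idx = np.flatnonzero(ok)
    Av = values[np.ix_(idx, idx)]
    yv = y[idx]
    X = np.ones((idx.size, 1))
    if covariates is not None:
        X = np.column_stack([X, covariates[idx]])
    return Av, yv, X


def reml_univariate(
    A,
    y,
    covariates: np.ndarray | None = None,
    constrain: bool = True,
    lrt_mixture: bool = False,
    max_iter: int = _MAX_ITER,
) -> RemlFit:
    """SNP-heritability by restricted maximum likelihood.

    ``A`` is a :class:`~countgwas.grm.GRM` or plain relatedness matrix; ``y``
    is the (typically rank-transformed) phenotype aligned to it, missing
    values dropped. Raises :class:`RemlConvergenceError` (carrying the
    log-likelihood trajectory) if the fit does not converge, and
    ``ValueError`` when the GRM spectrum is too flat to separate the genetic
    from the residual component (e.g. an identity GRM).
    """
    Av, yv, X = _prepare(A, y, covariates)
    n = yv.size
    d, U = np.linalg.eigh(Av)
    if np.ptp(d) < 1e-8:
        raise ValueError(
            "GRM eigenvalue spectrum is (near-)constant: sigma2_g and sigma2_e "
            "are not separately identifiable"
        )
    eng = _UniREML(d, U.T @ yv, U.T @ X)
    vary = float(np.var(yv, ddof=1))
    floor = 1e-8 * vary if constrain else -np.inf
    sg, se = 0.5 * vary, 0.5 * vary
    ll = eng.loglik(sg, se)
    trajectory = [ll]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        try:
            score, AI = eng.score_ai(sg, se)
            delta = np.linalg.solve(AI, score)
        except np.linalg.LinAlgError:
            delta = None
        new = None
        if delta is not None and np.all(np.isfinite(delta)):
            step = 1.0
            for _ in range(12):
                cand = (
                    max(sg + step * delta[0], floor),
                    max(se + step * delta[1], floor),
                )
                cll = eng.loglik(*cand)
                if np.isfinite(cll) and cll >= ll - 1e-10:
                    new = (cand, cll)
                    break
                step *= 0.5
        if new is None:  # EM fallback: guaranteed ascent
            cand = eng.em_step(sg, se)
            cand = (max(cand[0], floor), max(cand[1], floor))
            new = (cand, eng.loglik(*cand))
        (sg_n, se_n), ll_n = new
        dpar = max(abs(sg_n - sg), abs(se_n - se))
        dll = abs(ll_n - ll)
        sg, se, ll = sg_n, se_n, ll_n
        trajectory.append(ll)
        if dll < _TOL_LOGLIK and dpar < _TOL_PARAM * max(vary, 1e-12):
            converged = True
            break
    if not converged:
        raise RemlConvergenceError(
            f"REML did not converge in {max_iter} iterations", trajectory
        )

    total = sg + se
    h2 = sg / total
    _, AI = eng.score_ai(sg, se)
    try:
        cov = np.linalg.inv(AI)
        grad = np.array([se, -sg]) / total**2
        se_h2 = float(np.sqrt(max(grad @ cov @ grad, 0.0)))
    except np.linalg.LinAlgError:
        se_h2 = float("nan")

    # null model: sigma2_g = 0, residual variance profiled out
    beta0, *_ = np.linalg.lstsq(X, yv, rcond=None)
    rss = float(np.sum((yv - X @ beta0) ** 2))
    se0 = rss / (n - X.shape[1])
    ll0 = eng.loglik(0.0, se0)
    lrt = max(0.0, 2.0 * (ll - ll0))
    p = float(chi2.sf(lrt, df=1))
    if lrt_mixture:
        p = 0.5 * p if lrt > 0 else 1.0
    return RemlFit(
        h2=float(h2),
        se_h2=se_h2,
        var_g=float(sg),
        var_e=float(se),
        loglik=float(ll),
        lrt_stat=float(lrt),
        lrt_df=1,
        p_value=p,
        n=n,
        converged=converged,
        n_iter=it,
        trajectory=trajectory,
    )


def reml_univariate_em(A, y, covariates=None, n_iter: int = 50) -> list[float]:
    """Pure-EM trajectory of REML log-likelihoods (ascent is guaranteed);
    exposed for diagnostics."""
    Av, yv, X = _prepare(A, y, covariates)
    d, U = np.linalg.eigh(Av)
    eng = _UniREML(d, U.T @ yv, U.T @ X)
    vary = float(np.var(yv, ddof=1))
    sg, se = 0.5 * vary, 0.5 * vary
    ll = [eng.loglik(sg, se)]
    for _ in range(n_iter):
        sg, se = eng.em_step(sg, se)
        ll.append(eng.loglik(sg, se))
    return ll


# ---------------------------------------------------------------------------
# bivariate

_EBASIS = (
    np.array([[1.0, 0.0], [0.0, 0.0]]),
    np.array([[0.0, 1.0], [1.0, 0.0]]),
    np.array([[0.0, 0.0], [0.0, 1.0]]),
)


class _BivarREML:
    """Two traits, shared GRM, complete sample overlap; everything is
    block-diagonal (2x2 per eigenvalue) in the eigenbasis."""

    def __init__(self, d: np.ndarray, Y: np.ndarray, c: np.ndarray):
        self.d = d          # (n,) eigenvalues
        self.Y = Y          # (n, 2) rotated traits
        self.c = c          # (n,) rotated intercept column
        self.n = d.size

    @staticmethod
    def _theta_to_mats(theta):
        G = np.array([[theta[0], theta[1]], [theta[1], theta[2]]])
        E = np.array([[theta[3], theta[4]], [theta[4], theta[5]]])
        return G, E

    def _blocks(self, theta):
        G, E = self._theta_to_mats(theta)
        V = self.d[:, None, None] * G[None] + E[None]          # (n,2,2)
        det = V[:, 0, 0] * V[:, 1, 1] - V[:, 0, 1] ** 2
        if np.min(det) <= 0 or np.min(V[:, 0, 0]) <= 0 or np.min(V[:, 1, 1]) <= 0:
            return None
        Vinv = np.empty_like(V)
        Vinv[:, 0, 0] = V[:, 1, 1] / det
        Vinv[:, 1, 1] = V[:, 0, 0] / det
        Vinv[:, 0, 1] = Vinv[:, 1, 0] = -V[:, 0, 1] / det
        return V, Vinv, det

    def _state(self, theta):
        blocks = self._blocks(theta)
        if blocks is None:
            return None
        V, Vinv, det = blocks
        c2 = self.c**2
        XtVX = np.einsum("n,nij->ij", c2, Vinv)
        XtVX_inv = np.linalg.inv(XtVX)
        rhs = np.einsum("n,nij,nj->i", self.c, Vinv, self.Y)
        beta = XtVX_inv @ rhs
        r = self.Y - self.c[:, None] * beta[None, :]
        Py = np.einsum("nij,nj->ni", Vinv, r)
        return V, Vinv, det, XtVX, XtVX_inv, r, Py

    def loglik(self, theta) -> float:
        st = self._state(theta)
        if st is None:
            return -np.inf
        V, Vinv, det, XtVX, XtVX_inv, r, Py = st
        sign, logdet_x = np.linalg.slogdet(XtVX)
        if sign <= 0:
            return -np.inf
        return -0.5 * (float(np.sum(np.log(det))) + logdet_x + float(np.sum(r * Py)))

    def _applyP(self, W, Vinv, XtVX_inv):
        VW = np.einsum("nij,nj->ni", Vinv, W)
        s = XtVX_inv @ np.einsum("n,ni->i", self.c, VW)
        return VW - self.c[:, None] * np.einsum("nij,j->ni", Vinv, s)

    def score_ai(self, theta):
        st = self._state(theta)
        if st is None:
            raise np.linalg.LinAlgError("non-PD V")
        V, Vinv, det, XtVX, XtVX_inv, r, Py = st
        facs = [self.d, self.d, self.d, None, None, None]
        ones = np.ones(self.n)
        score = np.empty(6)
        u = []
        c2 = self.c**2
        for a in range(6):
            E = _EBASIS[a % 3]
            f = facs[a] if facs[a] is not None else ones
            # tr(V^-1 D) per block, summed
            VinvE = np.einsum("nij,jk->nik", Vinv, E)
            tr_VinvD = float(np.sum(f * np.trace(VinvE, axis1=1, axis2=2)))
            M = np.einsum("n,nij,njk->ik", c2 * f, VinvE, Vinv)
            trPD = tr_VinvD - float(np.trace(XtVX_inv @ M))
            DPy = f[:, None] * (Py @ E.T)
            yPDPy = float(np.sum(Py * DPy))
            score[a] = -0.5 * (trPD - yPDPy)
            u.append(DPy)
        AI = np.empty((6, 6))
        for a in range(6):
            Pu = self._applyP(u[a], Vinv, XtVX_inv)
            for b in range(6):
                AI[a, b] = 0.5 * float(np.sum(u[b] * Pu))
        return score, 0.5 * (AI + AI.T)


def _project_theta(theta, floor1, floor2, max_corr=0.9999):
    t = np.array(theta, dtype=float)
    t[0] = max(t[0], floor1)
    t[2] = max(t[2], floor2)
    t[3] = max(t[3], floor1)
    t[5] = max(t[5], floor2)
    for off, a, b in ((1, 0, 2), (4, 3, 5)):
        lim = max_corr * np.sqrt(t[a] * t[b])
        t[off] = np.clip(t[off], -lim, lim)
    return t


def reml_bivariate(
    A,
    y1,
    y2,
    covariates: np.ndarray | None = None,
    max_iter: int = _MAX_ITER,
    h2_zero_tol: float = 0.01,
) -> BivarRemlFit:
    """Genetic and residual correlation between two traits sharing a GRM.

    Individuals missing either trait are dropped. When a trait's genetic
    variance collapses to (near) zero the corresponding correlation is
    undefined and returned as ``NaN`` with its ``*_defined`` flag unset.
    """
    values, _ = _grm_values(A)
    y1 = np.asarray(y1, dtype=float)
    y2 = np.asarray(y2, dtype=float)
    if y1.shape[0] != values.shape[0] or y2.shape[0] != values.shape[0]:
        raise ValueError("phenotype length does not match GRM dimension")
    ok = np.isfinite(y1) & np.isfinite(y2)
    if covariates is not None:
        raise NotImplementedError(
            "bivariate REML expects pre-adjusted (rank-transformed residual) traits"
        )
    idx = np.flatnonzero(ok)
    Av = values[np.ix_(idx, idx)]
    n = idx.size
    d, U = np.linalg.eigh(Av)
    if np.ptp(d) < 1e-8:
        raise ValueError("GRM eigenvalue spectrum is (near-)constant")
    Y = np.column_stack([U.T @ y1[idx], U.T @ y2[idx]])
    c = U.T @ np.ones(n)
    eng = _BivarREML(d, Y, c)

    v1 = float(np.var(y1[idx], ddof=1))
    v2 = float(np.var(y2[idx], ddof=1))
    c12 = float(np.cov(y1[idx], y2[idx])[0, 1])
    floor1, floor2 = 1e-8 * v1, 1e-8 * v2
    theta = np.array([0.5 * v1, 0.5 * c12, 0.5 * v2, 0.5 * v1, 0.5 * c12, 0.5 * v2])
    theta = _project_theta(theta, floor1, floor2)
    ll = eng.loglik(theta)
    converged = False
    for _ in range(max_iter):
        try:
            score, AI = eng.score_ai(theta)
            delta = np.linalg.solve(AI, score)
        except np.linalg.LinAlgError:
            delta = None
        new = None
        if delta is not None and np.all(np.isfinite(delta)):
            step = 1.0
            for _ in range(14):
                cand = _project_theta(theta + step * delta, floor1, floor2)
                cll = eng.loglik(cand)
                if np.isfinite(cll) and cll >= ll - 1e-10:
                    new = (cand, cll)
                    break
                step *= 0.5
        if new is None:
            break
        cand, cll = new
        dpar = float(np.max(np.abs(cand - theta)))
        dll = abs(cll - ll)
        theta, ll = cand, cll
        if dll < _TOL_LOGLIK and dpar < _TOL_PARAM * max(v1, v2):
            converged = True
            break
    if not converged:
        # derivative-free polish on the constrained surface
        res = minimize(
            lambda t: -eng.loglik(_project_theta(t, floor1, floor2)),
            theta,
            method="Nelder-Mead",
            options={"maxiter": 4000, "xatol": 1e-8, "fatol": 1e-8},
        )
        cand = _project_theta(res.x, floor1, floor2)
        if eng.loglik(cand) >= ll:
            theta = cand
            ll = eng.loglik(theta)
        converged = bool(res.success) or abs(ll - -res.fun) < 1e-4

    g11, g12, g22, e11, e12, e22 = theta
    rg_def = g11 > h2_zero_tol * v1 and g22 > h2_zero_tol * v2
    re_def = e11 > h2_zero_tol * v1 and e22 > h2_zero_tol * v2
    rg = g12 / np.sqrt(g11 * g22) if rg_def else float("nan")
    re = e12 / np.sqrt(e11 * e22) if re_def else float("nan")

    se_rg = se_re = float("nan")
    try:
        _, AI = eng.score_ai(theta)
        cov = np.linalg.pinv(AI)
        if rg_def:
            grad = np.zeros(6)
            grad[0] = -0.5 * rg / g11
            grad[1] = 1.0 / np.sqrt(g11 * g22)
            grad[2] = -0.5 * rg / g22
            se_rg = float(np.sqrt(max(grad @ cov @ grad, 0.0)))
        if re_def:
            grad = np.zeros(6)
            grad[3] = -0.5 * re / e11
            grad[4] = 1.0 / np.sqrt(e11 * e22)
            grad[5] = -0.5 * re / e22
            se_re = float(np.sqrt(max(grad @ cov @ grad, 0.0)))
    except np.linalg.LinAlgError:
        pass

    return BivarRemlFit(
        rg=float(np.clip(rg, -1.0, 1.0)) if rg_def else float("nan"),
        se_rg=se_rg,
        re=float(np.clip(re, -1.0, 1.0)) if re_def else float("nan"),
        se_re=se_re,
        var_g1=float(g11),
        var_g2=float(g22),
        cov_g12=float(g12),
        var_e1=float(e11),
        var_e2=float(e22),
        cov_e12=float(e12),
        loglik=float(ll),
        n=n,
        converged=bool(converged),
        rg_defined=bool(rg_def),
        re_defined=bool(re_def),
    )
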