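"""Per-SNP quasi-Poisson association and genomic control.

Counts are modelled with a Poisson log link fitted by iteratively
reweighted least squares; the quasi-likelihood dispersion
``phi = Pearson X^2 / (n - p)`` inflates the Poisson standard errors by
``sqrt(phi)``, so Wald statistics stay calibrated under overdispersion.
Effect sizes are changes in log counts per effect allele. Genome-wide
inflation is summarised by ``lambda_GC = median(Wald^2) / 0.4549`` (the
chi-square(1) median) and corrected statistics divide by ``max(lambda, 1)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import ndtr, xlogy
from scipy.stats import chi2

from .data import GenotypeMatrix, PhenotypePanel

CHI2_1_MEDIAN = float(chi2.ppf(0.5, df=1))  # 0.454936...

ASSOC_COLUMNS = [
    "snp_id", "chr", "bp", "ea", "oa", "eaf", "n",
    "beta", "se", "phi", "wald", "p", "p_gc",
]

_IRLS_MAX_ITER = 50
_IRLS_TOL = 1e-8


@dataclass
class GlmFit:
    beta: np.ndarray            # coefficient vector (last entry = dosage in scans)
    se_beta: np.ndarray         # quasi-Poisson SEs (Poisson SE * sqrt(phi))
    dispersion_phi: float
    wald_stat: np.ndarray       # beta / quasi SE
    p_value: np.ndarray
    n_used: int
    converged: bool
    se_beta_poisson: np.ndarray = None
    p_value_poisson: np.ndarray = None


def fit_quasi_poisson(
    y: np.ndarray,
    X: np.ndarray,
    colnames: list[str] | None = None,
    max_iter: int = _IRLS_MAX_ITER,
    tol: float = _IRLS_TOL,
) -> GlmFit:
    """Poisson log-link IRLS with Pearson dispersion.

    ``X`` must include the intercept column. Wald statistics are referenced
    to the standard normal. A zero dispersion (perfect fit) leaves the
    quasi SEs at zero; such fits are degenerate and non-inferential.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if y.shape[0] != n:
        raise ValueError("y and X have different lengths")
    if np.any(y < 0) or np.any(y != np.round(y)):
        raise ValueError("y must contain non-negative integer counts")
    if not np.all(y.sum() > 0):
        raise ValueError("all-zero response: no finite intercept")
    if np.linalg.matrix_rank(X) < p:
        names = colnames or [f"x{j}" for j in range(p)]
        dep = []
        q, r = np.linalg.qr(X)
        diag = np.abs(np.diag(r))
        dep = [names[j] for j in range(p) if diag[j] < 1e-8 * diag.max()]
        raise ValueError(f"collinear design matrix (columns {dep or names})")

    beta = np.zeros(p)
    beta[0] = np.log(y.mean() + 0.5)
    eta = X @ beta
    mu = np.exp(eta)
    dev = 2.0 * float(np.sum(xlogy(y, y / np.maximum(mu, 1e-300)) - (y - mu)))
    converged = False
    for _ in range(max_iter):
        w = mu
        z = eta + (y - mu) / mu
        Xw = X * w[:, None]
        XtWX = X.T @ Xw
        try:
            beta = np.linalg.solve(XtWX, Xw.T @ z)
        except np.linalg.LinAlgError:
            break
        eta = np.clip(X @ beta, -30.0, 30.0)
        mu = np.exp(eta)
        dev_new = 2.0 * float(np.sum(xlogy(y, y / np.maximum(mu, 1e-300)) - (y - mu)))
        if abs(dev_new - dev) < tol * (abs(dev_new) + 0.1):
            dev = dev_new
            converged = True
            break
        dev = dev_new

    pearson = float(np.sum((y - mu) ** 2 / mu))
    phi = pearson / (n - p) if n > p else float("nan")
    XtWX = X.T @ (X * mu[:, None])
    cov_pois = np.linalg.inv(XtWX)
    se_pois = np.sqrt(np.diag(cov_pois))
    se_quasi = se_pois * np.sqrt(max(phi, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        wald = np.where(se_quasi > 0, beta / se_quasi, np.inf * np.sign(beta))
        pvals = 2.0 * ndtr(-np.abs(wald))
        wald_pois = np.where(se_pois > 0, beta / se_pois, np.inf * np.sign(beta))
        p_pois = 2.0 * ndtr(-np.abs(wald_pois))
    return GlmFit(
        beta=beta,
        se_beta=se_quasi,
        dispersion_phi=float(phi),
        wald_stat=wald,
        p_value=pvals,
        n_used=n,
        converged=converged,
        se_beta_poisson=se_pois,
        p_value_poisson=p_pois,
    )


def gwas_scan(
    G: GenotypeMatrix,
    panel: PhenotypePanel,
    age: float,
    apply_gc: bool = False,
) -> pd.DataFrame:
    """One quasi-Poisson fit per SNP for a single time-point.

    The design is intercept, age at measurement, sex, PC1, PC2 and allele
    dosage, on untransformed counts; individuals missing the score or a
    covariate at this age are dropped, and per-SNP missing dosages are
    dropped per SNP. Per-SNP failures are recorded (NaN row) and the scan
    continues. Returns an association table in fixed column order.
    """
    scores = panel.scores(age)
    covars = panel.covariates(age)
    base_ok = np.isfinite(scores) & np.all(np.isfinite(covars), axis=1)
    if panel.n_individuals != G.n_individuals:
        raise ValueError("panel and genotypes have different sample counts")
    m = G.n_snps
    stats = np.full((m, 7), np.nan)  # eaf, n, beta, se, phi, wald, p
    any_missing = np.isnan(G.dosages).any()
    y_base = scores[base_ok].astype(int)
    X_base = np.column_stack([np.ones(base_ok.sum()), covars[base_ok]])
    for j in range(m):
        dos = G.dosages[:, j]
        if any_missing and np.isnan(dos[base_ok]).any():
            ok = base_ok & np.isfinite(dos)
            yv = scores[ok].astype(int)
            X = np.column_stack([np.ones(ok.sum()), covars[ok], dos[ok]])
        else:
            ok = base_ok
            yv = y_base
            X = np.column_stack([X_base, dos[base_ok]])
        stats[j, 0] = dos[ok].mean() / 2.0 if ok.any() else np.nan
        stats[j, 1] = ok.sum()
        try:
            fit = fit_quasi_poisson(yv, X)
            stats[j, 2:] = (
                fit.beta[-1], fit.se_beta[-1], fit.dispersion_phi,
                fit.wald_stat[-1], fit.p_value[-1],
            )
        except (ValueError, np.linalg.LinAlgError):
            pass
    table = pd.DataFrame(
        {
            "snp_id": G.snp_map["snp_id"].to_numpy(),
            "chr": G.snp_map["chrom"].to_numpy(),
            "bp": G.snp_map["bp"].to_numpy(),
            "ea": G.snp_map["ea"].to_numpy(),
            "oa": G.snp_map["oa"].to_numpy(),
            "eaf": stats[:, 0],
            "n": stats[:, 1].astype(int),
            "beta": stats[:, 2],
            "se": stats[:, 3],
            "phi": stats[:, 4],
            "wald": stats[:, 5],
            "p": stats[:, 6],
            "p_gc": np.nan,
        }
    )[ASSOC_COLUMNS]
    if apply_gc:
        _, table = genomic_control(table)
    return table


@dataclass
class GcResult:
    lambda_gc: float
    lambda_applied: float   # after flooring (if enabled)
    n_tests: int


def genomic_control(
    table: pd.DataFrame, floor_at_one: bool = True
) -> tuple[GcResult, pd.DataFrame]:
    """Median-based genomic-control correction of an association table.

    ``lambda_GC = median(Wald^2) / median(chi-square_1)``; corrected
    statistics are ``Wald^2 / max(lambda, 1)`` (flooring configurable) and
    corrected p-values come from the chi-square(1) upper tail. Ordering of
    p-values is preserved.
    """
    wald2 = table["wald"].to_numpy(dtype=float) ** 2
    valid = np.isfinite(wald2)
    if not valid.any():
        raise ValueError("no valid Wald statistics")
    lam = float(np.median(wald2[valid]) / CHI2_1_MEDIAN)
    lam_applied = max(lam, 1.0) if floor_at_one else lam
    corrected = wald2 / lam_applied
    out = table.copy()
    out["p_gc"] = chi2.sf(corrected, df=1)
    return GcResult(lambda_gc=lam, lambda_applied=lam_applied, n_tests=int(valid.sum())), out
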