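"""Comparative analysis: relative testes mass and phylogenetic GLS.

Relative testes mass — observed testes mass over the allometric
expectation a * body_mass^b — proxies the intensity of sperm competition.
The pGLS regresses a per-species response (root-to-tip omega) on that
predictor under an error covariance that decays exponentially with
patristic distance, C_ij = exp(-alpha * d_ij): alpha -> infinity removes
all phylogenetic signal (ordinary least squares), alpha -> 0 makes
species fully exchangeable with their relatives.  alpha is estimated by
maximising the GLS likelihood; the slope CI uses the normal
approximation conditional on the fitted alpha (a t-based CI is available
by flag).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .trees import Phylogeny

__all__ = [
    "SpeciesTraits", "PGLSFit", "relative_testes_mass", "pgls_fit",
    "significance_by_ci",
]

_MAX_CONDITION = 1e10
_ALPHA_LO, _ALPHA_HI = 1e-4, 1e3


@dataclass
class SpeciesTraits:
    """Per-species masses, the derived sperm-competition proxy and omega."""

    species: str
    body_mass_g: float
    testes_mass_g: float
    relative_testes_mass: float | None = None
    omega_path: float | None = None

    def __post_init__(self) -> None:
        if self.body_mass_g <= 0 or self.testes_mass_g <= 0:
            raise ValueError("masses must be positive")


@dataclass
class PGLSFit:
    """A fitted phylogenetic GLS regression."""

    alpha: float
    slope: float
    intercept: float
    ci: tuple[float, float]
    se_slope: float
    lnL: float
    correlation: float
    n: int
    ci_method: str = "normal"


def relative_testes_mass(
    body_mass: float | np.ndarray,
    testes_mass: float | np.ndarray,
    coeff_a: float | None = None,
    coeff_b: float | None = None,
):
    """Observed / allometrically expected testes mass.

    The rodent regression coefficients (expected testes mass =
    a * body_mass^b) must be supplied explicitly — there are no hidden
    defaults.
    """
    if coeff_a is None or coeff_b is None:
        raise ValueError(
            "allometric coefficients coeff_a and coeff_b are required "
            "(rodent regression, supplied via config)"
        )
    body = np.asarray(body_mass, dtype=float)
    testes = np.asarray(testes_mass, dtype=float)
    if np.any(body <= 0) or np.any(testes <= 0):
        raise ValueError("masses must be positive")
    out = testes / (coeff_a * body**coeff_b)
    return float(out) if out.ndim == 0 else out


def _gls_solve(C: np.ndarray, X: np.ndarray, y: np.ndarray):
    """GLS estimates, whitened residual sum of squares and log|C|."""
    cond = np.linalg.cond(C)
    if not np.isfinite(cond) or cond > _MAX_CONDITION:
        raise np.linalg.LinAlgError(
            f"phylogenetic covariance is near-singular (cond={cond:.3g})"
        )
    L = np.linalg.cholesky(C)
    Xw = np.linalg.solve(L, X)
    yw = np.linalg.solve(L, y)
    beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    resid = yw - Xw @ beta
    rss = float(resid @ resid)
    logdet = 2.0 * float(np.log(np.diag(L)).sum())
    XtX_inv = np.linalg.inv(Xw.T @ Xw)
    return beta, rss, logdet, XtX_inv


def _gls_lnl(C, X, y) -> float:
    n = len(y)
    _, rss, logdet, _ = _gls_solve(C, X, y)
    sigma2 = rss / n
    return -0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + n)


def pgls_fit(
    tree: Phylogeny,
    x: pd.Series | dict,
    y: pd.Series | dict,
    *,
    alpha: float | None = None,
    log_x: bool = False,
    t_ci: bool = False,
) -> PGLSFit:
    """Phylogenetic GLS of y on x with exponential covariance exp(-alpha d).

    ``x`` and ``y`` map species (tree tips) to values; species missing
    from either are dropped.  ``alpha=None`` estimates alpha by ML on a
    log scale over [1e-4, 1e3]; a fixed alpha skips that search.  The
    reported correlation is the GLS correlation coefficient — the
    standardized slope computed from phylogenetically corrected sums of
    squares.
    """
    x = pd.Series(x, dtype=float).dropna()
    y = pd.Series(y, dtype=float).dropna()
    species = [t for t in tree.tip_labels if t in x.index and t in y.index]
    n = len(species)
    if n < 4:
        raise ValueError(f"pGLS needs at least 4 species, got {n}")
    xv = x.loc[species].to_numpy()
    if log_x:
        xv = np.log(xv)
    yv = y.loc[species].to_numpy()
    D = tree.patristic_distances(species)
    X = np.column_stack([np.ones(n), xv])

    def lnl_of(a: float) -> float:
        return _gls_lnl(np.exp(-a * D), X, yv)

    if alpha is None:
        res = optimize.minimize_scalar(
            lambda la: -lnl_of(np.exp(la)),
            bounds=(np.log(_ALPHA_LO), np.log(_ALPHA_HI)),
            method="bounded",
            options={"xatol": 1e-6},
        )
        alpha = float(np.exp(res.x))
    lnL = lnl_of(alpha)
    C = np.exp(-alpha * D)
    beta, rss, _logdet, XtX_inv = _gls_solve(C, X, yv)
    intercept, slope = float(beta[0]), float(beta[1])
    dof = n - 2
    sigma2 = rss / dof
    se = float(np.sqrt(sigma2 * XtX_inv[1, 1]))
    if t_ci:
        crit = float(stats.t.ppf(0.975, dof))
        method = "t"
    else:
        crit = float(stats.norm.ppf(0.975))
        method = "normal"
    ci = (slope - crit * se, slope + crit * se)
    # GLS correlation: phylogenetically corrected sums of squares
    Cinv_1 = np.linalg.solve(C, np.ones(n))
    s1 = float(np.ones(n) @ Cinv_1)
    xc = float(xv @ Cinv_1) / s1
    yc = float(yv @ Cinv_1) / s1
    Cinv_x = np.linalg.solve(C, xv - xc)
    Sxx = float((xv - xc) @ Cinv_x)
    Sxy = float((yv - yc) @ Cinv_x)
    Syy = float((yv - yc) @ np.linalg.solve(C, yv - yc))
    corr = Sxy / np.sqrt(Sxx * Syy) if Sxx > 0 and Syy > 0 else 0.0
    return PGLSFit(
        alpha=float(alpha), slope=slope, intercept=intercept, ci=ci,
        se_slope=se, lnL=float(lnL), correlation=float(corr), n=n,
        ci_method=method,
    )


def significance_by_ci(fit: PGLSFit) -> str:
    """"significant" iff the 95% slope CI strictly excludes zero."""
    lo, hi = fit.ci
    return "significant" if (lo > 0 or hi < 0) else "ns"
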