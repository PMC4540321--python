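"""Constrained ordination: redundancy analysis with permutation inference.

This module implements the multivariate core from scratch:

* a correspondence-analysis total-inertia gate for choosing between linear
  (RDA) and unimodal (CCA) response models — total inertia below 2.6
  indicates short gradients and a linear model;
* redundancy analysis (RDA): the response matrix is column-centered and
  globally scaled to total variance 1, regressed on standardized predictors,
  and the fitted values are decomposed into canonical axes whose eigenvalues
  are fractions of total community variance;
* marginal effects (each predictor fitted alone), forward selection with
  conditional effects (the extra variance a predictor adds given those
  already selected), and Monte Carlo permutation tests of each entering
  predictor using reduced-model (residual) permutation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .types import ENV_VARIABLES, CupSample

__all__ = [
    "CaGate",
    "ca_total_inertia",
    "OrdinationInput",
    "build_ordination_input",
    "RdaResult",
    "rda",
    "marginal_effects",
    "PermutationTest",
    "permutation_test",
    "forward_selection",
    "INERTIA_LINEAR_THRESHOLD",
]

log = logging.getLogger(__name__)

INERTIA_LINEAR_THRESHOLD = 2.6


# ---------------------------------------------------------------------------
# response-model gate

@dataclass(frozen=True)
class CaGate:
    total_inertia: float
    recommendation: str  # "linear (RDA)" or "unimodal (CCA)"
    threshold: float = INERTIA_LINEAR_THRESHOLD


def ca_total_inertia(y_counts: np.ndarray) -> CaGate:
    """Correspondence-analysis total inertia (χ²/N) of a non-negative matrix.

    Rows/columns with zero sums are dropped (with a log notice) before the
    chi-square statistic is formed. Detrending does not alter total inertia,
    so this equals the total inertia a detrended CA would report; a value
    below 2.6 recommends the linear (RDA) model.
    """
    y = np.asarray(y_counts, dtype=float)
    if y.ndim != 2:
        raise ValueError("y_counts must be a 2-D matrix")
    if np.any(y < 0):
        raise ValueError("y_counts must be non-negative")
    grand = y.sum()
    if grand == 0:
        raise ValueError("all-zero matrix has no defined inertia")
    rs, cs = y.sum(axis=1), y.sum(axis=0)
    if np.any(rs == 0) or np.any(cs == 0):
        log.info("dropping %d zero rows and %d zero columns before CA",
                 int((rs == 0).sum()), int((cs == 0).sum()))
        y = y[rs > 0][:, cs > 0]
        grand = y.sum()
    p = y / grand
    r = p.sum(axis=1, keepdims=True)
    c = p.sum(axis=0, keepdims=True)
    e = r @ c
    inertia = float(np.sum((p - e) ** 2 / e))
    rec = "linear (RDA)" if inertia < INERTIA_LINEAR_THRESHOLD else "unimodal (CCA)"
    return CaGate(total_inertia=inertia, recommendation=rec)


# ---------------------------------------------------------------------------
# input assembly

@dataclass(frozen=True)
class OrdinationInput:
    """Complete-case response and predictor matrices for ordination.

    ``y`` holds log10(x+1)-transformed areal abundances (cups × taxa);
    ``x`` holds standardized environmental predictors (cups × variables).
    """

    y: np.ndarray
    x: np.ndarray
    taxa: tuple[str, ...]
    variables: tuple[str, ...]
    cup_keys: tuple[tuple[str, str, str], ...]
    excluded: tuple[tuple[str, str, str], ...] = ()


def build_ordination_input(
    cups: Sequence[CupSample],
    variables: Sequence[str] = ENV_VARIABLES,
    taxa: Sequence[str] | None = None,
) -> OrdinationInput:
    """Assemble log10(x+1) densities and standardized predictors.

    Cups with any missing regarded predictor are excluded listwise and
    logged (never imputed). Abundances are individuals per 100 cm².
    """
    variables = tuple(variables)
    if taxa is None:
        taxa = tuple(sorted({t for cup in cups for t in cup.counts}))
    else:
        taxa = tuple(taxa)
    env_idx = [ENV_VARIABLES.index(v) for v in variables]
    keep, excluded = [], []
    for cup in cups:
        if any(getattr(cup.env, v) is None for v in variables):
            excluded.append(cup.key)
        else:
            keep.append(cup)
    if excluded:
        log.info("listwise exclusion of %d cups with missing predictors: %s",
                 len(excluded), excluded)
    if len(keep) <= len(variables):
        raise ValueError(
            f"need more complete cups ({len(keep)}) than predictors ({len(variables)})"
        )
    dens = np.array([
        [cup.total_count(t) * 100.0 / cup.bottom_area for t in taxa] for cup in keep
    ])
    y = np.log10(dens + 1.0)
    x = np.array([[cup.env.as_vector()[i] for i in env_idx] for cup in keep])
    sd = x.std(axis=0)
    if np.any(sd == 0):
        bad = [variables[j] for j in np.flatnonzero(sd == 0)]
        raise ValueError(f"constant predictor column(s) after exclusion: {bad}")
    x = (x - x.mean(axis=0)) / sd
    return OrdinationInput(
        y=y, x=x, taxa=taxa, variables=variables,
        cup_keys=tuple(c.key for c in keep), excluded=tuple(excluded),
    )


# ---------------------------------------------------------------------------
# core linear algebra

def _prepare_y(y: np.ndarray) -> np.ndarray:
    """Center species columns and scale globally so total variance is 1."""
    y = np.asarray(y, dtype=float)
    yc = y - y.mean(axis=0)
    tot = float(np.sum(yc ** 2))
    if tot == 0:
        raise ValueError("response matrix has no variance")
    return yc / np.sqrt(tot)


def _standardize_x(x: np.ndarray, names: Sequence[str] | None = None) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    sd = x.std(axis=0)
    if np.any(sd == 0):
        bad = ([str(j) for j in np.flatnonzero(sd == 0)] if names is None
               else [names[j] for j in np.flatnonzero(sd == 0)])
        raise ValueError(f"constant predictor column(s): {bad}")
    return (x - x.mean(axis=0)) / sd


def _orthonormal_basis(x: np.ndarray, names: Sequence[str] | None = None,
                       tol: float = 1e-10) -> np.ndarray:
    """Orthonormal basis of the column space; raises on rank deficiency."""
    q, r = np.linalg.qr(x)
    diag = np.abs(np.diag(r))
    scale = diag.max() if diag.size else 0.0
    bad = np.flatnonzero(diag <= tol * max(scale, 1.0))
    if bad.size:
        labels = [str(j) for j in bad] if names is None else [names[j] for j in bad]
        raise ValueError(f"rank-deficient predictors; collinear column(s): {labels}")
    return q


def _explained_fraction(ys: np.ndarray, q: np.ndarray) -> float:
    """Fraction of (unit) total variance captured by projection onto Q."""
    return float(np.sum((q.T @ ys) ** 2))


@dataclass(frozen=True)
class RdaResult:
    """Redundancy-analysis summary on the total-variance-1 scale."""

    canonical_eigenvalues: np.ndarray        # fractions of total variance
    species_env_correlations: np.ndarray     # per canonical axis
    cum_pct_species: np.ndarray              # cumulative % of species variance
    cum_pct_species_env_relation: np.ndarray
    site_scores: np.ndarray                  # WA scores: Y projected on axes
    lc_scores: np.ndarray                    # fitted-value (constrained) scores
    species_scores: np.ndarray
    biplot_scores: np.ndarray                # corr(predictor, lc axis)
    sum_canonical: float
    taxa: tuple[str, ...]
    variables: tuple[str, ...]

    @property
    def n_axes(self) -> int:
        return len(self.canonical_eigenvalues)

    def axis_summary(self, n_axes: int = 4) -> pd.DataFrame:
        """Axis table in the conventional ordination-report layout."""
        k = min(n_axes, self.n_axes)
        return pd.DataFrame({
            "axis": np.arange(1, k + 1),
            "eigenvalue": np.round(self.canonical_eigenvalues[:k], 3),
            "species_env_correlation": np.round(self.species_env_correlations[:k], 3),
            "cum_pct_species": np.round(self.cum_pct_species[:k], 1),
            "cum_pct_species_env_relation":
                np.round(self.cum_pct_species_env_relation[:k], 1),
        })


def rda(y: np.ndarray, x: np.ndarray,
        taxa: Sequence[str] | None = None,
        variables: Sequence[str] | None = None) -> RdaResult:
    """Redundancy analysis of response ``y`` on predictors ``x``.

    ``y`` (n × p) is centered by species and scaled globally to total
    variance 1; ``x`` (n × m) is standardized. The canonical axes are the
    principal axes of the fitted values of the multivariate least-squares
    regression of Y on X; eigenvalues are fractions of total variance, so
    their sum is the constrained R². Axis signs follow a deterministic
    convention (the species with the largest |loading| scores positive).
    """
    ys = _prepare_y(y)
    xs = _standardize_x(x, variables)
    n, p = ys.shape
    if xs.shape[0] != n:
        raise ValueError("y and x must have the same number of rows")
    if n <= xs.shape[1]:
        raise ValueError(f"need n > m (n={n}, m={xs.shape[1]})")
    q = _orthonormal_basis(xs, variables)
    yhat = q @ (q.T @ ys)
    u, s, vt = np.linalg.svd(yhat, full_matrices=False)
    k = min(xs.shape[1], p, n - 1)
    u, s, vt = u[:, :k], s[:k], vt[:k]
    # deterministic sign: largest-|loading| species positive on each axis
    for i in range(k):
        j = int(np.argmax(np.abs(vt[i])))
        if vt[i, j] < 0:
            vt[i] *= -1.0
            u[:, i] *= -1.0
    v = vt.T
    eig = s ** 2
    sum_canon = float(eig.sum())
    site = ys @ v
    lc = u * s
    corr = np.zeros(k)
    for i in range(k):
        denom = np.linalg.norm(site[:, i]) * np.linalg.norm(lc[:, i])
        corr[i] = 0.0 if denom == 0 else float(site[:, i] @ lc[:, i] / denom)
    cum = np.cumsum(eig)
    biplot = np.zeros((xs.shape[1], k))
    for i in range(k):
        norm_lc = np.linalg.norm(lc[:, i])
        if norm_lc > 0:
            biplot[:, i] = xs.T @ lc[:, i] / (np.linalg.norm(xs, axis=0) * norm_lc)
    return RdaResult(
        canonical_eigenvalues=eig,
        species_env_correlations=corr,
        cum_pct_species=100.0 * cum,
        cum_pct_species_env_relation=(100.0 * cum / sum_canon if sum_canon > 0
                                      else np.zeros(k)),
        site_scores=site,
        lc_scores=lc,
        species_scores=v * s,
        biplot_scores=biplot,
        sum_canonical=sum_canon,
        taxa=tuple(taxa) if taxa is not None else tuple(f"sp{i}" for i in range(p)),
        variables=(tuple(variables) if variables is not None
                   else tuple(f"x{i}" for i in range(xs.shape[1]))),
    )


def marginal_effects(y: np.ndarray, x: np.ndarray,
                     variables: Sequence[str] | None = None) -> pd.DataFrame:
    """Constrained variance (λ) of each predictor fitted alone.

    Returns a table sorted by λ descending (ties keep input column order).
    """
    x = np.asarray(x, dtype=float)
    if variables is None:
        variables = [f"x{i}" for i in range(x.shape[1])]
    ys = _prepare_y(y)
    lam = []
    for j in range(x.shape[1]):
        q = _orthonormal_basis(_standardize_x(x[:, [j]], [variables[j]]))
        lam.append(_explained_fraction(ys, q))
    out = pd.DataFrame({"variable": list(variables), "marginal_lambda": lam})
    return (out.sort_values("marginal_lambda", ascending=False, kind="stable")
               .reset_index(drop=True))


@dataclass(frozen=True)
class PermutationTest:
    f: float
    p: float
    n_perm: int


def permutation_test(
    y: np.ndarray,
    x_candidate: np.ndarray,
    x_conditioning: np.ndarray | None = None,
    n_perm: int = 999,
    seed: int | np.random.Generator = 0,
) -> PermutationTest:
    """Monte Carlo significance of one candidate predictor.

    The pseudo-F is (added canonical variance / df_added) over (residual
    variance / df_residual). Rows of the response residualized on the
    conditioning predictors are permuted without restriction (reduced-model
    permutation); with no conditioning this is a free permutation of the
    centered response. ``p = (1 + #{F* ≥ F}) / (n_perm + 1)``, so the
    smallest attainable p is 1/(n_perm+1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    ys = _prepare_y(y)
    n = ys.shape[0]
    xc = np.asarray(x_candidate, dtype=float)
    if xc.ndim == 1:
        xc = xc[:, None]
    if xc.shape[1] != 1:
        raise ValueError("x_candidate must be a single column")
    xc = _standardize_x(xc)

    if x_conditioning is not None and np.size(x_conditioning):
        x0 = _standardize_x(np.asarray(x_conditioning, dtype=float))
        q0 = _orthonormal_basis(x0)
        k0 = q0.shape[1]
    else:
        q0 = np.zeros((n, 0))
        k0 = 0

    yres = ys - q0 @ (q0.T @ ys)
    xres = xc[:, 0] - q0 @ (q0.T @ xc[:, 0])
    norm = np.linalg.norm(xres)
    if norm < 1e-12:
        raise ValueError("candidate is collinear with the conditioning predictors")
    q1 = xres / norm

    df_resid = n - 1 - k0 - 1
    if df_resid <= 0:
        raise ValueError("not enough residual degrees of freedom")
    ss_tot = float(np.sum(yres ** 2))

    def f_stat(ymat: np.ndarray) -> float:
        ss_add = float(np.sum((q1 @ ymat) ** 2))
        ss_cond = float(np.sum((q0.T @ ymat) ** 2)) if k0 else 0.0
        ss_resid = ss_tot - ss_cond - ss_add
        return ss_add / (ss_resid / df_resid)

    f_obs = f_stat(yres)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if f_stat(yres[perm]) >= f_obs - 1e-12:
            count += 1
    return PermutationTest(f=f_obs, p=(count + 1) / (n_perm + 1), n_perm=n_perm)


def forward_selection(
    y: np.ndarray,
    x: np.ndarray,
    variables: Sequence[str] | None = None,
    n_perm: int = 999,
    alpha: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Forward selection of predictors with conditional effects.

    At each step the candidate adding the most canonical variance given the
    already-selected predictors enters (ties broken by input column order)
    and is tested by reduced-model permutation. All predictors are ranked
    and reported regardless of significance; ``alpha`` only annotates the
    ``significant`` column. The conditional λ values telescope: the first
    equals its marginal λ and their sum equals the full-model constrained
    variance.

    Permutation streams are derived independently per (step, variable) from
    the single ``seed``.
    """
    x = np.asarray(x, dtype=float)
    if variables is None:
        variables = [f"x{i}" for i in range(x.shape[1])]
    variables = list(variables)
    ys = _prepare_y(y)
    marg = marginal_effects(y, x, variables).set_index("variable")["marginal_lambda"]

    selected: list[int] = []
    explained = 0.0
    rows = []
    remaining = list(range(x.shape[1]))
    step = 0
    while remaining:
        best_j, best_inc = None, -np.inf
        for j in remaining:
            cols = selected + [j]
            q = _orthonormal_basis(_standardize_x(x[:, cols]))
            inc = _explained_fraction(ys, q) - explained
            if inc > best_inc + 1e-15:
                best_j, best_inc = j, inc
        assert best_j is not None
        rng = np.random.default_rng(np.random.SeedSequence([seed, step, best_j]))
        test = permutation_test(
            y, x[:, best_j],
            x_conditioning=x[:, selected] if selected else None,
            n_perm=n_perm, seed=rng,
        )
        rows.append(dict(
            order=step + 1,
            variable=variables[best_j],
            marginal_lambda=float(marg[variables[best_j]]),
            conditional_lambda=float(best_inc),
            f=test.f,
            p=test.p,
            significant=test.p <= alpha,
        ))
        selected.append(best_j)
        explained += best_inc
        remaining.remove(best_j)
        step += 1
    return pd.DataFrame(rows)
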