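"""Mixed models with one or several genomic random effects.

Fits ``y = X b + sum_f g_f + e`` with ``g_f ~ N(0, G_f s2_f)`` and
``e ~ N(0, I s2_e)`` by restricted maximum likelihood using
average-information updates (with an EM fallback when an AI step leaves the
parameter space), then computes BLUP breeding values for all individuals in
the relationship matrices — including masked (unphenotyped) validation
animals — from the equivalent variance-based form of Henderson's equations:

    b_hat  = (X' V^-1 X)^-1 X' V^-1 y          over phenotyped rows,
    g_f    = s2_f * G_f[:, obs] V^-1 (y - X b_hat),

which coincides with the joint mixed-model-equation solution and stays
well-defined when a feature GRM is rank-deficient (fewer SNPs than animals).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .kinship import GRM

logger = logging.getLogger(__name__)

__all__ = [
    "FixedDesign",
    "VarianceComponents",
    "ModelFit",
    "RemlError",
    "wilmink_covariate",
    "build_fixed_design",
    "reml_fit",
    "blup_solve",
    "heritability",
]

WILMINK_RATE = 0.05


class RemlError(RuntimeError):
    """REML failure (non-convergence or singular system); carries the trace."""

    def __init__(self, message: str, trace: list | None = None):
        super().__init__(message)
        self.trace = trace or []


def wilmink_covariate(dim):
    """Exponential lactation-curve covariate exp(-0.05 * DIM)."""
    dim = np.asarray(dim, dtype=float)
    if (dim < 0).any():
        raise ValueError("DIM must be nonnegative")
    out = np.exp(-WILMINK_RATE * dim)
    return float(out) if out.ndim == 0 else out


@dataclass
class FixedDesign:
    """Full-column-rank fixed-effect design: mean, parity and herd contrasts
    (treatment coding, first level as reference), DIM and Wilmink covariates."""

    matrix: np.ndarray
    column_names: list[str]
    row_ids: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape[1] != len(self.column_names):
            raise ValueError("column_names length mismatch")
        if self.matrix.shape[0] != len(self.row_ids):
            raise ValueError("row_ids length mismatch")
        if np.linalg.matrix_rank(self.matrix) < self.matrix.shape[1]:
            raise ValueError("design matrix is rank deficient")

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]

    def rows_for(self, ids) -> np.ndarray:
        pos = {iid: i for i, iid in enumerate(self.row_ids)}
        missing = [i for i in ids if i not in pos]
        if missing:
            raise KeyError(f"ids absent from design: {missing[:5]}")
        return self.matrix[[pos[i] for i in ids]]


def build_fixed_design(phenos: pd.DataFrame) -> FixedDesign:
    """Treatment-coded design from a phenotype table (herd, parity, dim).

    Columns that are collinear with earlier ones are dropped with a warning
    (e.g. the Wilmink column when DIM is constant).
    """
    required = {"animal_id", "herd", "parity", "dim"}
    missing = required - set(phenos.columns)
    if missing:
        raise ValueError(f"phenotype table missing columns: {sorted(missing)}")
    if phenos[["herd", "parity", "dim"]].isna().any().any():
        raise ValueError("herd/parity/dim contain missing values")

    n = len(phenos)
    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["mu"]

    for factor in ("parity", "herd"):
        levels = pd.unique(phenos[factor])
        for lev in levels[1:]:  # first level is the reference
            cols.append((phenos[factor] == lev).to_numpy(dtype=float))
            names.append(f"{factor}[{lev}]")

    dim = phenos["dim"].to_numpy(dtype=float)
    cols.append(dim)
    names.append("dim")
    cols.append(wilmink_covariate(dim))
    names.append("wilmink")

    X = np.column_stack(cols)
    # greedy rank filter: keep columns that increase rank
    keep: list[int] = []
    rank = 0
    for j in range(X.shape[1]):
        cand = X[:, keep + [j]]
        r = np.linalg.matrix_rank(cand)
        if r > rank:
            keep.append(j)
            rank = r
        else:
            logger.warning("dropping collinear design column %r", names[j])
    X = X[:, keep]
    names = [names[j] for j in keep]
    return FixedDesign(
        matrix=X,
        column_names=names,
        row_ids=phenos["animal_id"].to_numpy(dtype=object),
    )


@dataclass
class VarianceComponents:
    """REML estimates: one genetic variance per GRM plus the residual."""

    genetic: dict[str, float]
    residual: float
    n_iterations: int = 0
    loglik: float = float("nan")
    final_loglik_change: float = float("nan")
    converged: bool = True
    boundary: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.genetic.values()):
            raise ValueError("genetic variances must be >= 0")
        # REML always returns residual > 0; zero is tolerated here so that
        # boundary heritability (h2 = 1) can be expressed.
        if self.residual < 0:
            raise ValueError("residual variance must be >= 0")

    @property
    def total_genetic(self) -> float:
        return float(sum(self.genetic.values()))


@dataclass
class ModelFit:
    """Fixed-effect solutions, per-component and total GBVs, fit diagnostics."""

    beta: pd.Series
    gbv: dict[str, np.ndarray]
    individual_ids: np.ndarray
    vc: VarianceComponents
    fitted: np.ndarray
    residuals: np.ndarray
    observed_ids: np.ndarray
    design: FixedDesign
    total_gbv: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.total_gbv = np.sum(list(self.gbv.values()), axis=0)

    def gbv_for(self, ids, component: str | None = None) -> np.ndarray:
        pos = {iid: i for i, iid in enumerate(self.individual_ids)}
        idx = np.array([pos[i] for i in ids], dtype=int)
        vec = self.total_gbv if component is None else self.gbv[component]
        return vec[idx]


def _component_names(grms: list[GRM]) -> list[str]:
    return [f"g{i + 1}" for i in range(len(grms))]


def _projection(V: np.ndarray, X: np.ndarray):
    """Return (Vinv, P, logdetV, logdetXtVinvX) with P the REML projector."""
    c, low = cho_factor(V, lower=True)
    logdetV = 2.0 * float(np.sum(np.log(np.diag(c))))
    Vinv = cho_solve((c, low), np.eye(V.shape[0]))
    XtVinvX = X.T @ Vinv @ X
    cx, lowx = cho_factor(XtVinvX)
    logdetX = 2.0 * float(np.sum(np.log(np.diag(cx))))
    XtVinvXinv = cho_solve((cx, lowx), np.eye(X.shape[1]))
    VinvX = Vinv @ X
    P = Vinv - VinvX @ XtVinvXinv @ VinvX.T
    return Vinv, P, logdetV, logdetX


def reml_fit(
    y: np.ndarray,
    X: FixedDesign | np.ndarray,
    grms: list[GRM],
    names: list[str] | None = None,
    max_iter: int = 200,
    tol_loglik: float = 1e-6,
    tol_param: float = 1e-5,
) -> VarianceComponents:
    """AI-REML variance components for one or several genomic kernels.

    Start values split half of var(y) equally across the genetic components
    and give the other half to the residual.  AI steps that would leave the
    parameter space are first halved, then replaced by an EM update;
    components pinned at the lower boundary (1e-8 * var(y)) are flagged.
    """
    if not grms:
        raise ValueError("at least one GRM required")
    Xm = X.matrix if isinstance(X, FixedDesign) else np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = Xm.shape
    if len(y) != n:
        raise ValueError("y and X row counts differ")
    n_comp = len(grms)
    if n <= p + n_comp:
        raise ValueError("not enough records to estimate all components")
    for g in grms:
        if g.matrix.shape[0] != n:
            raise ValueError("GRM dimension does not match record count")
    if names is None:
        names = _component_names(grms)

    vy = float(np.var(y))
    if vy <= 0:
        raise ValueError("response has zero variance")
    floor = 1e-8 * vy

    Gs = [g.matrix for g in grms]
    theta = np.array([0.5 * vy / n_comp] * n_comp + [0.5 * vy])
    trace: list[dict] = []
    prev_ll = -np.inf
    final_change = np.nan
    converged = False

    def restricted_ll(th: np.ndarray) -> float:
        V = th[-1] * np.eye(n)
        for t, G in zip(th[:-1], Gs):
            V += t * G
        _, _, logdetV, logdetX = _projection(V, Xm)
        # recompute quadratic form at th
        c, low = cho_factor(V, lower=True)
        Vinv_y = cho_solve((c, low), y)
        Vinv_Xm = cho_solve((c, low), Xm)
        XtVinvX = Xm.T @ Vinv_Xm
        beta = np.linalg.solve(XtVinvX, Xm.T @ Vinv_y)
        Py_loc = Vinv_y - Vinv_Xm @ beta
        return -0.5 * (logdetV + logdetX + float(y @ Py_loc))

    for it in range(1, max_iter + 1):
        V = theta[-1] * np.eye(n)
        for t, G in zip(theta[:-1], Gs):
            V += t * G
        try:
            _, P, logdetV, logdetX = _projection(V, Xm)
        except np.linalg.LinAlgError as exc:
            raise RemlError(
                f"singular coefficient matrix at iteration {it}; "
                "consider a small ridge on the GRMs", trace
            ) from exc

        Py = P @ y
        ll = -0.5 * (logdetV + logdetX + float(y @ Py))

        # scores and AI matrix over all components (residual last, G = I)
        GPy = [G @ Py for G in Gs] + [Py]
        scores = np.empty(n_comp + 1)
        for i, (G, gpy) in enumerate(zip(Gs + [np.eye(n)], GPy)):
            tr = float(np.sum(P * G))  # tr(P G) for symmetric G
            scores[i] = -0.5 * (tr - float(Py @ gpy))
        AI = np.empty((n_comp + 1, n_comp + 1))
        PGPy = [P @ gpy for gpy in GPy]
        for i in range(n_comp + 1):
            for j in range(i, n_comp + 1):
                AI[i, j] = AI[j, i] = 0.5 * float(GPy[i] @ PGPy[j])

        change = ll - prev_ll
        trace.append({"iter": it, "loglik": ll, "theta": theta.copy()})
        rel_param = np.nan

        if it > 1 and abs(change) < tol_loglik:
            final_change = change
            converged = True
            prev_ll = ll
            break

        try:
            # lstsq tolerates a singular AI matrix (e.g. two identical GRMs:
            # the split is non-identifiable and that direction gets no step)
            delta = np.linalg.lstsq(AI, scores, rcond=1e-10)[0]
        except np.linalg.LinAlgError:
            delta = None

        new_theta = None
        if delta is not None:
            # projected AI step with backtracking on the restricted loglik
            step = 1.0
            for _ in range(8):
                cand = np.maximum(theta + step * delta, floor)
                if restricted_ll(cand) >= ll - 1e-10:
                    new_theta = cand
                    break
                step *= 0.5
        if new_theta is None:
            # EM update: theta_i + theta_i^2/n * (y'P G P y - tr(P G))
            new_theta = theta.copy()
            for i, (G, gpy) in enumerate(zip(Gs + [np.eye(n)], GPy)):
                tr = float(np.sum(P * G))
                new_theta[i] = theta[i] + theta[i] ** 2 / n * (float(Py @ gpy) - tr)
            new_theta = np.maximum(new_theta, floor)

        rel_param = float(np.max(np.abs(new_theta - theta) / np.maximum(theta, floor)))
        theta = new_theta
        prev_ll = ll
        final_change = change
        if it > 1 and abs(change) < tol_loglik and rel_param < tol_param:
            converged = True
            break

    if not converged:
        raise RemlError(
            f"REML did not converge in {max_iter} iterations "
            f"(last loglik change {final_change:.3g})",
            trace,
        )

    boundary = tuple(
        name for name, t in zip(names, theta[:-1]) if t <= floor * (1 + 1e-12)
    )
    if boundary:
        logger.info("components at lower boundary: %s", boundary)
    return VarianceComponents(
        genetic={name: float(max(t, 0.0)) for name, t in zip(names, theta[:-1])},
        residual=float(theta[-1]),
        n_iterations=len(trace),
        loglik=prev_ll,
        final_loglik_change=float(final_change),
        converged=True,
        boundary=boundary,
    )


def blup_solve(
    y: np.ndarray,
    X: FixedDesign,
    grms: list[GRM],
    vc: VarianceComponents,
    masked_ids=(),
    names: list[str] | None = None,
) -> ModelFit:
    """BLUP solutions for all GRM individuals with masked phenotypes excluded.

    ``y`` and ``X`` cover the phenotyped candidates (aligned with
    ``X.row_ids``); individuals in ``masked_ids`` are dropped from the data
    vector but keep their rows in every GRM, so they receive predicted GBVs.
    """
    if not grms:
        raise ValueError("at least one GRM required")
    all_ids = grms[0].individual_ids
    for g in grms[1:]:
        if not np.array_equal(g.individual_ids, all_ids):
            raise ValueError("GRMs must share identical individual ordering")
    if names is None:
        names = list(vc.genetic.keys()) if len(vc.genetic) == len(grms) else _component_names(grms)
    sigma = [vc.genetic[nm] for nm in names]

    masked = set(masked_ids)
    unknown = masked - set(all_ids)
    if unknown:
        raise ValueError(f"masked ids absent from GRMs: {sorted(unknown)[:5]}")

    row_ids = X.row_ids
    obs_mask = np.array([rid not in masked for rid in row_ids])
    if not obs_mask.any():
        raise ValueError("all individuals masked: nothing to fit on")
    obs_ids = row_ids[obs_mask]
    y_o = np.asarray(y, dtype=float)[obs_mask]
    X_o = X.matrix[obs_mask]

    pos = {iid: i for i, iid in enumerate(all_ids)}
    try:
        obs_idx = np.array([pos[i] for i in obs_ids], dtype=int)
    except KeyError as exc:
        raise ValueError(f"phenotyped id missing from GRMs: {exc}") from exc

    n_o = len(y_o)
    V = vc.residual * np.eye(n_o)
    for s2, g in zip(sigma, grms):
        if s2 > 0:
            V += s2 * g.matrix[np.ix_(obs_idx, obs_idx)]
    try:
        c, low = cho_factor(V, lower=True)
    except np.linalg.LinAlgError:
        V += 1e-6 * np.mean(np.diag(V)) * np.eye(n_o)  # solve-time ridge only
        c, low = cho_factor(V, lower=True)
    Vinv_y = cho_solve((c, low), y_o)
    Vinv_X = cho_solve((c, low), X_o)
    XtVinvX = X_o.T @ Vinv_X
    beta = np.linalg.solve(XtVinvX, X_o.T @ Vinv_y)
    resid_gls = y_o - X_o @ beta
    Pr = cho_solve((c, low), resid_gls)

    gbv = {}
    for nm, s2, g in zip(names, sigma, grms):
        gbv[nm] = s2 * (g.matrix[:, obs_idx] @ Pr) if s2 > 0 else np.zeros(len(all_ids))

    total = np.sum(list(gbv.values()), axis=0)
    fitted = X_o @ beta + total[obs_idx]
    residuals = y_o - fitted
    return ModelFit(
        beta=pd.Series(beta, index=X.column_names),
        gbv=gbv,
        individual_ids=np.asarray(all_ids, dtype=object),
        vc=vc,
        fitted=fitted,
        residuals=residuals,
        observed_ids=obs_ids,
        design=X,
    )


def heritability(vc: VarianceComponents, model: str = "gblup") -> float:
    """h2 = genetic / (genetic + residual); multi-kernel fits use the summed
    genetic variance as the total."""
    if model not in ("gblup", "gfblup"):
        raise ValueError("model must be 'gblup' or 'gfblup'")
    total = vc.total_genetic
    if total == 0 and vc.residual == 0:
        raise ValueError("all variances zero: heritability undefined")
    return total / (total + vc.residual)
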