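"""Cross-validation design, corrected phenotypes, scaled prediction
reliability, variance proportions, replicate summaries and trait preprocessing.

Two split strategies are supported, both built to avoid sibling and
dam-progeny links between validation and reference sets:

``unrelated_subset``
    validation cows are sampled from the pool of cows with no sibling (shared
    sire or shared dam) and whose dam is not in the dataset; non-sampled
    eligible cows return to the reference.

``sire_group_holdout``
    one sire group (>= n_val cows) is chosen, n_val of its cows form the
    validation set, and the group's remaining cows are excluded from the
    reference.

Prediction reliability is the squared correlation between GBV and the
phenotype corrected for fixed effects, divided by the scenario's estimated
heritability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .mixedmodel import ModelFit

logger = logging.getLogger(__name__)

__all__ = [
    "ValidationPlan",
    "ReliabilityEntry",
    "ReliabilityReport",
    "VarianceProportionTable",
    "filter_dim",
    "desaturation_indexes",
    "residual_diagnostics",
    "make_validation_plan",
    "corrected_phenotypes",
    "prediction_reliability",
    "variance_proportions",
    "summarize_replicates",
]


@dataclass
class ValidationPlan:
    """One replicate's reference/validation split (plus exclusions)."""

    replicate: int
    strategy: str
    validation_ids: np.ndarray
    reference_ids: np.ndarray
    excluded_ids: np.ndarray

    def __post_init__(self) -> None:
        val = set(self.validation_ids)
        ref = set(self.reference_ids)
        exc = set(self.excluded_ids)
        if val & ref:
            raise ValueError("validation and reference sets overlap")
        if val & exc or ref & exc:
            raise ValueError("excluded ids overlap another set")
        if len(val) != len(self.validation_ids):
            raise ValueError("duplicate validation ids")


@dataclass
class ReliabilityEntry:
    """Per-replicate accuracy numbers."""

    replicate: int
    correlation: float
    reliability: float
    slope: float
    n_validation: int
    flagged_above_one: bool = False


@dataclass
class ReliabilityReport:
    """Replicate entries plus their summary (mean reliability, correlation MAD)."""

    entries: list[ReliabilityEntry]
    h2: float
    mean_reliability: float = field(init=False)
    mean_correlation: float = field(init=False)
    mad_correlation: float = field(init=False)
    mean_slope: float = field(init=False)

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("at least one replicate entry required")
        r = np.array([e.correlation for e in self.entries])
        rel = np.array([e.reliability for e in self.entries])
        self.mean_reliability = float(rel.mean())
        self.mean_correlation = float(r.mean())
        self.mad_correlation = float(np.abs(r - r.mean()).mean())
        self.mean_slope = float(np.mean([e.slope for e in self.entries]))

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "replicate": e.replicate,
                    "correlation": e.correlation,
                    "reliability": e.reliability,
                    "slope": e.slope,
                    "n_validation": e.n_validation,
                }
                for e in self.entries
            ]
        )


@dataclass
class VarianceProportionTable:
    """Percent of the total genetic variance attributed to each component."""

    proportions: dict[str, float]

    def __post_init__(self) -> None:
        vals = np.array(list(self.proportions.values()))
        if (vals < 0).any():
            raise ValueError("proportions must be nonnegative")
        if abs(vals.sum() - 100.0) > 1e-6:
            raise ValueError(f"proportions sum to {vals.sum()}, expected 100")

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"component": list(self.proportions), "percent": list(self.proportions.values())}
        )


# -----------------------------------------------------------------------------
# Trait preprocessing
# -----------------------------------------------------------------------------

def filter_dim(phenos: pd.DataFrame, min_dim: float = 60) -> pd.DataFrame:
    """Keep rows at ``min_dim`` days in milk or more (inclusive threshold)."""
    if "dim" not in phenos.columns:
        raise ValueError("phenotype table has no 'dim' column")
    keep = phenos["dim"] >= min_dim
    n_removed = int((~keep).sum())
    logger.info("DIM filter (>= %s): removed %d of %d rows", min_dim, n_removed, len(phenos))
    out = phenos[keep].reset_index(drop=True)
    if out.empty:
        logger.warning("DIM filter removed every row")
    return out


def desaturation_indexes(fa: pd.DataFrame) -> pd.DataFrame:
    """Unsaturated / (unsaturated + saturated) x 100 for the C14, C16 and C18
    fatty-acid pairs.

    Expects columns ``C14:0, C14:1, C16:0, C16:1, C18:0, C18:1c9``; rows with
    a zero denominator get a missing index and a warning.
    """
    pairs = {
        "C14_index": ("C14:1", "C14:0"),
        "C16_index": ("C16:1", "C16:0"),
        "C18_index": ("C18:1c9", "C18:0"),
    }
    out = {}
    for name, (unsat, sat) in pairs.items():
        if unsat not in fa.columns or sat not in fa.columns:
            raise ValueError(f"missing fatty-acid columns for {name}: {unsat}, {sat}")
        denom = fa[unsat] + fa[sat]
        bad = denom <= 0
        if bad.any():
            logger.warning("%s: %d rows with zero denominator set to missing", name, int(bad.sum()))
        vals = np.where(bad, np.nan, fa[unsat] / denom.where(~bad) * 100.0)
        out[name] = vals
    return pd.DataFrame(out, index=fa.index)


def residual_diagnostics(fit: ModelFit, min_n: int = 10, plot_path=None) -> dict:
    """Heteroscedasticity check: Spearman correlation between |residual| and
    fitted value; recommends a log transform when rho > 0.2 with p < 0.01.
    """
    resid = np.asarray(fit.residuals, dtype=float)
    fitted = np.asarray(fit.fitted, dtype=float)
    if len(resid) < min_n:
        return {"verdict": "insufficient_data", "recommend_log_transform": None,
                "spearman_rho": np.nan, "p_value": np.nan}
    if np.ptp(resid) == 0 or np.ptp(fitted) == 0:
        return {"verdict": "degenerate", "recommend_log_transform": None,
                "spearman_rho": np.nan, "p_value": np.nan}
    rho, p = stats.spearmanr(np.abs(resid), fitted)
    recommend = bool(rho > 0.2 and p < 0.01)
    if plot_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 4))
        ax.scatter(fitted, resid, s=8, alpha=0.6)
        ax.axhline(0.0, color="grey", lw=0.8)
        ax.set_xlabel("fitted value")
        ax.set_ylabel("residual")
        fig.tight_layout()
        fig.savefig(plot_path, dpi=120)
        plt.close(fig)
    return {
        "verdict": "heteroscedastic" if recommend else "homoscedastic",
        "recommend_log_transform": recommend,
        "spearman_rho": float(rho),
        "p_value": float(p),
    }


# -----------------------------------------------------------------------------
# Validation plans
# -----------------------------------------------------------------------------

def make_validation_plan(
    phenos: pd.DataFrame,
    strategy: str,
    n_val: int = 100,
    n_reps: int = 5,
    seed: int = 0,
) -> list[ValidationPlan]:
    """Build ``n_reps`` reference/validation splits under ``strategy``.

    Sampling is without replacement within a replicate and independent across
    replicates (sets may overlap between replicates).
    """
    if strategy not in ("unrelated_subset", "sire_group_holdout"):
        raise ValueError(f"unknown strategy {strategy!r}")
    for col in ("animal_id", "sire_id"):
        if col not in phenos.columns:
            raise ValueError(f"phenotype table missing {col!r}")

    ids = phenos["animal_id"].to_numpy(dtype=object)
    sires = phenos["sire_id"].to_numpy(dtype=object)
    dams = (
        phenos["dam_id"].to_numpy(dtype=object)
        if "dam_id" in phenos.columns
        else np.array([None] * len(ids), dtype=object)
    )
    id_set = set(ids)

    plans = []
    for rep in range(1, n_reps + 1):
        rng = np.random.default_rng(np.random.SeedSequence([seed, rep]))
        if strategy == "unrelated_subset":
            sire_counts = pd.Series(sires).value_counts(dropna=True)
            dam_counts = pd.Series(dams).value_counts(dropna=True)
            eligible = []
            for i, (iid, s, d) in enumerate(zip(ids, sires, dams)):
                has_sib = (s is not None and sire_counts.get(s, 0) > 1) or (
                    d is not None and dam_counts.get(d, 0) > 1
                )
                dam_in_data = d in id_set
                if not has_sib and not dam_in_data:
                    eligible.append(iid)
            if len(eligible) < n_val:
                raise ValueError(
                    f"unrelated_subset: only {len(eligible)} eligible cows "
                    f"(no siblings, dam not in data), need {n_val}"
                )
            val = rng.choice(np.asarray(eligible, dtype=object), size=n_val, replace=False)
            val_set = set(val)
            # non-sampled eligible cows go back to the reference
            ref = np.asarray([i for i in ids if i not in val_set], dtype=object)
            excluded = np.asarray([], dtype=object)
        else:  # sire_group_holdout
            groups = pd.Series(ids).groupby(pd.Series(sires)).groups
            big = {s: np.asarray(ids[list(ix)], dtype=object)
                   for s, ix in groups.items() if len(ix) >= n_val}
            if not big:
                raise ValueError(
                    f"sire_group_holdout: no sire group with >= {n_val} cows"
                )
            sire = rng.choice(sorted(big.keys()))
            group = big[sire]
            val = rng.choice(group, size=n_val, replace=False)
            val_set = set(val)
            excluded = np.asarray([i for i in group if i not in val_set], dtype=object)
            drop = val_set | set(excluded)
            ref = np.asarray([i for i in ids if i not in drop], dtype=object)
        plans.append(
            ValidationPlan(
                replicate=rep,
                strategy=strategy,
                validation_ids=np.asarray(val, dtype=object),
                reference_ids=ref,
                excluded_ids=excluded,
            )
        )
    return plans


# -----------------------------------------------------------------------------
# Reliability
# -----------------------------------------------------------------------------

def corrected_phenotypes(
    phenos: pd.DataFrame, trait: str, fit1: ModelFit
) -> pd.Series:
    """y minus the estimated fixed part of the single-population model
    (random effects are not subtracted).

    ``fit1`` must have been fitted on the cows' own population with all its
    individuals; requesting a cow absent from that fit raises.
    """
    ids = phenos["animal_id"].to_numpy(dtype=object)
    design_rows = fit1.design.rows_for(ids)  # raises for absent cows
    # align beta to design columns
    beta = fit1.beta.reindex(fit1.design.column_names).to_numpy()
    fixed = design_rows @ beta
    y = phenos[trait].to_numpy(dtype=float)
    return pd.Series(y - fixed, index=pd.Index(ids, name="animal_id"), name=f"{trait}_corrected")


def prediction_reliability(
    gbv: np.ndarray, y_corr: np.ndarray, h2: float, replicate: int = 1
) -> ReliabilityEntry:
    """Reliability = cor(gbv, y_corr)^2 / h2, plus the raw correlation and the
    regression slope of corrected phenotype on GBV.  Values above 1 are kept
    but flagged."""
    gbv = np.asarray(gbv, dtype=float)
    y_corr = np.asarray(y_corr, dtype=float)
    if len(gbv) != len(y_corr):
        raise ValueError("gbv and corrected phenotypes differ in length")
    if len(gbv) < 3:
        raise ValueError("need at least 3 validation records")
    if not (0 < h2 <= 1):
        raise ValueError("h2 must be in (0, 1]")
    if gbv.std() == 0 or y_corr.std() == 0:
        raise ValueError("zero-variance GBV or corrected phenotype")
    r = float(np.corrcoef(gbv, y_corr)[0, 1])
    rel = r ** 2 / h2
    slope = float(np.cov(y_corr, gbv)[0, 1] / np.var(gbv, ddof=1))
    flagged = rel > 1
    if flagged:
        logger.warning("reliability %.3f exceeds 1 (replicate %d)", rel, replicate)
    return ReliabilityEntry(
        replicate=replicate,
        correlation=r,
        reliability=float(rel),
        slope=slope,
        n_validation=len(gbv),
        flagged_above_one=flagged,
    )


def variance_proportions(vc) -> VarianceProportionTable:
    """Percent share of each genetic component in the summed genetic variance."""
    total = vc.total_genetic
    if total <= 0:
        raise ValueError("total genetic variance is zero: proportions undefined")
    props = {name: v / total * 100.0 for name, v in vc.genetic.items()}
    return VarianceProportionTable(proportions=props)


def summarize_replicates(entries: list[ReliabilityEntry], h2: float) -> ReliabilityReport:
    """Mean reliability and the mean absolute deviation of correlations."""
    return ReliabilityReport(entries=list(entries), h2=h2)
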