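"""Scenario orchestration: single- or combined-population GBLUP/GFBLUP runs.

A scenario executes QC -> relationship matrices -> full-data REML (h2 and
variance proportions) -> replicated masked-validation BLUP -> corrected
phenotypes (always from the single-population fixed-effect model of the
validation cows' own population) -> reliability summary.  All randomness is
derived from the scenario seed through a stable hash, so reruns are
byte-identical.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .evaluation import (
    ReliabilityReport,
    VarianceProportionTable,
    corrected_phenotypes,
    filter_dim,
    make_validation_plan,
    prediction_reliability,
    summarize_replicates,
    variance_proportions,
)
from .genotypes import GenotypeMatrix, intersect_common_snps, mean_impute_missing, qc_filter
from .kinship import feature_grms, vanraden_grm
from .mixedmodel import ModelFit, blup_solve, build_fixed_design, heritability, reml_fit

logger = logging.getLogger(__name__)

__all__ = ["ScenarioSpec", "ScenarioResult", "derive_seed", "run_scenario", "compare_scenarios"]

SCENARIOS = ("single_gblup", "combined_gblup", "combined_gfblup", "single_gfblup")


def derive_seed(parent: int, *tokens) -> int:
    """Child seed = stable hash of (parent seed, tokens); avoids collisions
    between pipeline stages and replicates."""
    h = hashlib.sha256(repr((int(parent),) + tuple(map(str, tokens))).encode())
    return int.from_bytes(h.digest()[:4], "big")


@dataclass(frozen=True)
class ScenarioSpec:
    """What to run: model family, trait, validation population and options."""

    scenario: str
    trait: str
    populations: tuple[str, ...]
    feature_chromosomes: tuple[str, ...] = ()
    log_transform: bool = False
    strategy: str = "sire_group_holdout"
    n_val: int = 100
    n_reps: int = 5
    seed: int = 0
    maf_min: float = 0.05
    min_class_count: int = 10
    min_dim: float | None = None

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"scenario must be one of {SCENARIOS}")
        if self.scenario.startswith("single") and len(self.populations) != 1:
            raise ValueError("single-population scenarios name exactly one population")
        if not self.populations:
            raise ValueError("at least one target population required")
        if self.is_gfblup and not self.feature_chromosomes:
            raise ValueError("gfblup scenarios need at least one feature chromosome")

    @property
    def is_gfblup(self) -> bool:
        return self.scenario.endswith("gfblup")

    @property
    def is_combined(self) -> bool:
        return self.scenario.startswith("combined")

    @property
    def target_population(self) -> str:
        return self.populations[0]


@dataclass
class ScenarioResult:
    spec: ScenarioSpec
    report: ReliabilityReport
    proportions: VarianceProportionTable | None
    h2: float
    vc: object
    full_fit: ModelFit
    plans: list

    def as_frame(self) -> pd.DataFrame:
        df = self.report.as_frame()
        df.insert(0, "scenario", self.spec.scenario)
        df.insert(1, "trait", self.spec.trait)
        df.insert(2, "population", self.spec.target_population)
        return df


def _qc_and_assemble(geno: GenotypeMatrix, spec: ScenarioSpec) -> GenotypeMatrix:
    """Per-population QC then the common-SNP intersection (combined) or the
    single population's post-QC matrix."""
    per_pop = geno.split_by_population()
    if spec.is_combined:
        filtered = []
        for pop, sub in per_pop.items():
            kept, rep = qc_filter(sub, spec.maf_min, spec.min_class_count)
            logger.info("scenario %s: population %s QC removed %d SNPs",
                        spec.scenario, pop, rep.n_removed)
            filtered.append(kept)
        if len(filtered) == 1:
            return filtered[0]
        return intersect_common_snps(filtered)
    target = per_pop[spec.target_population]
    kept, rep = qc_filter(target, spec.maf_min, spec.min_class_count)
    logger.info("scenario %s: population %s QC removed %d SNPs",
                spec.scenario, spec.target_population, rep.n_removed)
    return kept


def _fit_single_population_model1(
    geno: GenotypeMatrix, phenos: pd.DataFrame, spec: ScenarioSpec
) -> ModelFit:
    """Single-population traditional model on all of the target population's
    individuals — the source of corrected phenotypes in every scenario."""
    pop = spec.target_population
    pop_phenos = phenos[phenos["population"] == pop].reset_index(drop=True)
    pop_geno = mean_impute_missing(
        geno.subset_individuals(pop_phenos["animal_id"].tolist())
    )
    # GRM restricted to the population's own individuals (post scenario QC set)
    grm = vanraden_grm(pop_geno)
    X = build_fixed_design(pop_phenos)
    y = pop_phenos[spec.trait].to_numpy(dtype=float)
    vc = reml_fit(y, X, [grm], names=["g"])
    return blup_solve(y, X, [grm], vc, masked_ids=(), names=["g"])


def run_scenario(
    spec: ScenarioSpec, geno: GenotypeMatrix, phenos: pd.DataFrame
) -> ScenarioResult:
    """Execute one scenario end to end on in-memory data."""
    if spec.min_dim is not None:
        phenos = filter_dim(phenos, spec.min_dim)
    phenos = phenos.dropna(subset=[spec.trait]).reset_index(drop=True)
    if spec.log_transform:
        if (phenos[spec.trait] <= 0).any():
            raise ValueError("log transform requires strictly positive trait values")
        phenos = phenos.assign(**{spec.trait: np.log(phenos[spec.trait])})

    scenario_pops = (
        sorted(pd.unique(phenos["population"]).tolist())
        if spec.is_combined
        else [spec.target_population]
    )
    phenos = phenos[phenos["population"].isin(scenario_pops)].reset_index(drop=True)
    geno = geno.subset_individuals(phenos["animal_id"].tolist())

    geno_qc = _qc_and_assemble(geno, spec)
    # align rows with phenotypes (intersection may reorder by population)
    geno_qc = mean_impute_missing(geno_qc.subset_individuals(phenos["animal_id"].tolist()))
    logger.info("scenario %s: %d individuals x %d SNPs after QC",
                spec.scenario, geno_qc.n_individuals, geno_qc.n_snps)

    if spec.is_gfblup:
        grm_set = feature_grms(geno_qc, spec.feature_chromosomes)
        comps = grm_set.components
        grms = list(comps.values())
        names = list(comps.keys())
    else:
        grms = [vanraden_grm(geno_qc)]
        names = ["g"]

    X = build_fixed_design(phenos)
    y = phenos[spec.trait].to_numpy(dtype=float)

    vc = reml_fit(y, X, grms, names=names)
    h2 = heritability(vc, "gfblup" if spec.is_gfblup else "gblup")
    props = variance_proportions(vc) if spec.is_gfblup else None
    full_fit = blup_solve(y, X, grms, vc, masked_ids=(), names=names)

    # corrected phenotypes from the target population's own traditional model
    fit1 = _fit_single_population_model1(geno_qc, phenos, spec)
    target_phenos = phenos[phenos["population"] == spec.target_population].reset_index(drop=True)
    y_corr = corrected_phenotypes(target_phenos, spec.trait, fit1)

    plans = make_validation_plan(
        target_phenos,
        spec.strategy,
        n_val=spec.n_val,
        n_reps=spec.n_reps,
        # scenario name deliberately left out: models are compared on the
        # same replicated validation sets
        seed=derive_seed(spec.seed, "crossval", spec.trait, spec.target_population),
    )

    entries = []
    for plan in plans:
        masked = set(plan.validation_ids) | set(plan.excluded_ids)
        fit = blup_solve(y, X, grms, vc, masked_ids=masked, names=names)
        gbv_val = fit.gbv_for(plan.validation_ids)
        yc_val = y_corr.loc[list(plan.validation_ids)].to_numpy()
        entries.append(
            prediction_reliability(gbv_val, yc_val, h2, replicate=plan.replicate)
        )
    report = summarize_replicates(entries, h2=h2)
    return ScenarioResult(
        spec=spec, report=report, proportions=props, h2=h2, vc=vc,
        full_fit=full_fit, plans=plans,
    )


def compare_scenarios(reports: dict) -> pd.DataFrame:
    """Pairwise differences of mean reliabilities between named reports.

    ``reports`` maps a scenario name to a :class:`ReliabilityReport` (or to a
    dict of {key: report} sharing identical keys, compared key by key).
    """
    if not reports:
        raise ValueError("no reports supplied")
    first = next(iter(reports.values()))
    if isinstance(first, dict):
        keysets = {frozenset(v.keys()) for v in reports.values()}
        if len(keysets) != 1:
            raise ValueError("reports do not share trait/population keys")
        rows = []
        for key in sorted(next(iter(keysets))):
            sub = {name: v[key] for name, v in reports.items()}
            d = compare_scenarios(sub)
            d.insert(0, "key", str(key))
            rows.append(d)
        return pd.concat(rows, ignore_index=True)

    names = list(reports)
    rows = []
    for a in names:
        for b in names:
            if a == b:
                continue
            ra, rb = reports[a], reports[b]
            rows.append(
                {
                    "scenario_a": a,
                    "scenario_b": b,
                    "delta_reliability": ra.mean_reliability - rb.mean_reliability,
                    "mad_a": ra.mad_correlation,
                    "mad_b": rb.mad_correlation,
                }
            )
    return pd.DataFrame(rows)


def write_scenario_outputs(result: ScenarioResult, outdir: str | Path) -> dict[str, Path]:
    """Persist reliability, variance-component and GBV tables as TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tag = f"{result.spec.scenario}_{result.spec.trait}_{result.spec.target_population}"
    paths = {}

    rel_path = outdir / f"reliability_{tag}.tsv"
    df = result.as_frame()
    df["mean_reliability"] = result.report.mean_reliability
    df["mad_correlation"] = result.report.mad_correlation
    df["h2"] = result.h2
    df.to_csv(rel_path, sep="\t", index=False)
    paths["reliability"] = rel_path

    vc_rows = [{"component": k, "variance": v} for k, v in result.vc.genetic.items()]
    vc_rows.append({"component": "residual", "variance": result.vc.residual})
    vc_path = outdir / f"variance_components_{tag}.tsv"
    pd.DataFrame(vc_rows).to_csv(vc_path, sep="\t", index=False)
    paths["variance_components"] = vc_path

    if result.proportions is not None:
        prop_path = outdir / f"variance_proportions_{tag}.tsv"
        result.proportions.as_frame().to_csv(prop_path, sep="\t", index=False)
        paths["variance_proportions"] = prop_path

    gbv = pd.DataFrame({"animal_id": result.full_fit.individual_ids})
    for comp, vec in result.full_fit.gbv.items():
        gbv[f"gbv_{comp}"] = vec
    gbv["gbv_total"] = result.full_fit.total_gbv
    gbv_path = outdir / f"gbv_{tag}.tsv"
    gbv.to_csv(gbv_path, sep="\t", index=False)
    paths["gbv"] = gbv_path
    return paths
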