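"""Synthetic multi-population genotype/phenotype generator.

Produces data with the structural properties the prediction pipeline depends
on: several related populations drawn from a shared founder allele-frequency
pool (with bounded per-population drift), half-sib sire groups within each
population, block-structured linkage disequilibrium that decays with physical
distance, major QTL concentrated on designated "feature" chromosomes, and
phenotypes built from a fixed-effect structure (parity, herd, a linear
days-in-milk covariate and an exponential lactation-curve covariate) plus an
additive genetic value and residual noise tuned to a target heritability.

Founder haplotypes are mosaics of a small ancestral pool; switching between
pool haplotypes at rate ``recomb_rate_per_bp`` creates LD blocks.  Offspring
paternal gametes are recombinant copies of the two sire haplotypes, giving
half sibs an expected genomic relationship of ~0.25.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .genotypes import GenotypeMatrix, write_plink_text

__all__ = [
    "SimulationConfig",
    "TrueGeneticValues",
    "simulate_genotypes",
    "assign_qtl_effects",
    "simulate_phenotypes",
    "simulate_dataset",
    "write_phenotypes",
    "write_true_values",
]

WILMINK_RATE = 0.05  # fixed exponent of the lactation-curve covariate, per day


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic study design.

    Defaults give a desk-scale mirror of a three-population design:
    3 populations x (250, 200, 500) cows, 5 chromosomes x 600 SNPs with the
    first three chromosomes carrying concentrated QTL.
    """

    n_populations: int = 3
    n_per_population: tuple[int, ...] = (250, 200, 500)
    n_sires_per_population: int = 5
    chromosomes: tuple[tuple[str, int, int], ...] = (
        ("chr1", 600, 50_000_000),
        ("chr2", 600, 50_000_000),
        ("chr3", 600, 50_000_000),
        ("chr4", 600, 50_000_000),
        ("chr5", 600, 50_000_000),
    )
    feature_chromosomes: tuple[str, ...] = ("chr1", "chr2", "chr3")
    h2_target: float = 0.4
    feature_variance_fractions: tuple[float, ...] = (0.3, 0.2, 0.1)
    n_qtl: int = 200
    qtl_effect_scaling_per_population: tuple[float, ...] | None = None
    parity_levels: int = 3
    n_herds_per_population: int = 4
    dim_range: tuple[float, float] = (5.0, 400.0)
    wilmink_b1: float = -0.002
    wilmink_b2: float = -2.0
    residual_cv_multiplicative: float | None = None
    mu: float = 10.0
    herd_sd: float = 0.5
    parity_sd: float = 0.3
    drift: float = 0.01
    recomb_rate_per_bp: float = 1e-6
    ancestral_pool_size: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        chrom_labels = [c[0] for c in self.chromosomes]
        if len(set(chrom_labels)) != len(chrom_labels):
            raise ValueError("duplicate chromosome labels")
        if not set(self.feature_chromosomes) <= set(chrom_labels):
            raise ValueError("feature chromosomes must be a subset of chromosome labels")
        if len(self.n_per_population) != self.n_populations:
            raise ValueError("n_per_population length must equal n_populations")
        if len(self.feature_variance_fractions) != len(self.feature_chromosomes):
            raise ValueError("one variance fraction per feature chromosome required")
        if any(f < 0 for f in self.feature_variance_fractions):
            raise ValueError("variance fractions must be nonnegative")
        if sum(self.feature_variance_fractions) > 1 + 1e-12:
            raise ValueError("feature variance fractions must sum to <= 1")
        if not (0 <= self.h2_target < 1):
            raise ValueError("h2_target must be in [0, 1)")
        if self.dim_range[0] < 0:
            raise ValueError("dim_range minimum must be >= 0")
        if self.dim_range[1] < self.dim_range[0]:
            raise ValueError("dim_range must be (min, max) with min <= max")
        if self.qtl_effect_scaling_per_population is not None:
            if len(self.qtl_effect_scaling_per_population) != self.n_populations:
                raise ValueError("one QTL scaling multiplier per population required")
            if any(s <= 0 for s in self.qtl_effect_scaling_per_population):
                raise ValueError("QTL scaling multipliers must be positive")

    @property
    def rest_variance_fraction(self) -> float:
        return 1.0 - sum(self.feature_variance_fractions)

    @property
    def population_names(self) -> list[str]:
        return [f"pop{k + 1}" for k in range(self.n_populations)]


@dataclass
class TrueGeneticValues:
    """True additive values: total plus one partial value per GRM component.

    ``partials`` is keyed by feature-chromosome label plus ``"rest"``; the
    total is constructed as the exact sum of the partials.
    """

    individual_ids: np.ndarray
    partials: dict[str, np.ndarray]
    total: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.total = np.sum(list(self.partials.values()), axis=0)

    def as_frame(self) -> pd.DataFrame:
        data = {"animal_id": self.individual_ids, "g_total": self.total}
        for name, v in self.partials.items():
            data[f"g_{name}"] = v
        return pd.DataFrame(data)


# -----------------------------------------------------------------------------
# Genotypes
# -----------------------------------------------------------------------------

def _snp_positions(rng: np.random.Generator, n_snps: int, length_bp: int) -> np.ndarray:
    pos = rng.choice(length_bp - 1, size=n_snps, replace=False) + 1
    return np.sort(pos)


def _mosaic_gamete(
    rng: np.random.Generator,
    source_haps: np.ndarray,
    switch_prob: np.ndarray,
) -> np.ndarray:
    """Copy a gamete as a mosaic of source haplotypes.

    ``switch_prob[j]`` is the probability of jumping to a random source
    haplotype between SNP j-1 and j (first entry unused).
    """
    k, m = source_haps.shape
    switches = rng.random(m) < switch_prob
    switches[0] = True
    picks = rng.integers(0, k, size=int(switches.sum()))
    hap_at = np.zeros(m, dtype=int)
    hap_at[switches] = picks
    last_switch = np.maximum.accumulate(np.where(switches, np.arange(m), -1))
    hap_choice = hap_at[last_switch]
    return source_haps[hap_choice, np.arange(m)]


def simulate_genotypes(config: SimulationConfig) -> GenotypeMatrix:
    """Simulate allele counts for all populations under ``config``.

    Returns a :class:`GenotypeMatrix` with population, sire and dam labels.
    Dams are unique per cow and are not genotyped.
    """
    if config.n_sires_per_population == 0:
        raise ValueError("n_sires_per_population must be >= 1")
    for label, n_snps, _length in config.chromosomes:
        if n_snps < 2:
            raise ValueError(f"chromosome {label} must carry at least 2 SNPs")

    rng = np.random.default_rng(config.seed)

    chrom_pos = []
    snp_rows = []
    for label, n_snps, length in config.chromosomes:
        pos = _snp_positions(rng, n_snps, length)
        chrom_pos.append((label, pos))
        for j, p in enumerate(pos):
            snp_rows.append((f"{label}_snp{j + 1}", label, int(p)))
    snp_map = pd.DataFrame(snp_rows, columns=["snp_id", "chrom", "pos"])
    m_total = len(snp_map)

    # founder frequencies, shared across populations
    p_founder = np.clip(rng.beta(2.0, 2.0, size=m_total), 0.05, 0.95)

    # per-chromosome switch probabilities from inter-SNP distances
    switch_probs = []
    offsets = []
    off = 0
    for label, pos in chrom_pos:
        d = np.diff(pos, prepend=pos[0])
        sp = 1.0 - np.exp(-config.recomb_rate_per_bp * d)
        sp[0] = 1.0
        switch_probs.append(sp)
        offsets.append((off, off + len(pos)))
        off += len(pos)

    all_counts = []
    iids, pops, sires, dams = [], [], [], []

    # one founder haplotype pool shared by all populations: cross-population
    # relationships and LD consistency come from shared pool haplotypes
    global_pool = (
        rng.random((config.ancestral_pool_size, m_total)) < p_founder[None, :]
    ).astype(np.int8)

    for k, pop in enumerate(config.population_names):
        if config.drift > 0:
            p_pop = expit(
                logit(p_founder) + rng.normal(0.0, np.sqrt(config.drift), size=m_total)
            )
            # realize drift by flipping pool entries toward the drifted
            # frequency while keeping haplotype identity mostly shared
            pool = global_pool.copy()
            delta = p_pop - p_founder
            up = delta > 0
            prob_up = np.zeros(m_total)
            prob_up[up] = delta[up] / (1.0 - p_founder[up])
            flip_up = (pool == 0) & (rng.random(pool.shape) < prob_up[None, :])
            prob_dn = np.zeros(m_total)
            dn = ~up
            prob_dn[dn] = -delta[dn] / p_founder[dn]
            flip_dn = (pool == 1) & (rng.random(pool.shape) < prob_dn[None, :])
            pool[flip_up] = 1
            pool[flip_dn] = 0
        else:
            pool = global_pool

        def fresh_gamete() -> np.ndarray:
            pieces = []
            for (lo, hi), sp in zip(offsets, switch_probs):
                pieces.append(_mosaic_gamete(rng, pool[:, lo:hi], sp))
            return np.concatenate(pieces)

        sire_haps = [
            (fresh_gamete(), fresh_gamete()) for _ in range(config.n_sires_per_population)
        ]

        n = config.n_per_population[k]
        sire_assign = np.arange(n) % config.n_sires_per_population
        counts = np.empty((n, m_total), dtype=np.int8)
        for i in range(n):
            h0, h1 = sire_haps[sire_assign[i]]
            two = np.stack([h0, h1])
            pieces = []
            for (lo, hi), sp in zip(offsets, switch_probs):
                pieces.append(_mosaic_gamete(rng, two[:, lo:hi], sp))
            paternal = np.concatenate(pieces)
            maternal = fresh_gamete()
            counts[i] = paternal + maternal
        all_counts.append(counts)
        iids.extend(f"{pop}_cow{i + 1}" for i in range(n))
        pops.extend([pop] * n)
        sires.extend(f"{pop}_sire{s + 1}" for s in sire_assign)
        dams.extend(f"{pop}_dam{i + 1}" for i in range(n))

    return GenotypeMatrix(
        allele_counts=np.vstack(all_counts).astype(float),
        snp_map=snp_map,
        individual_ids=np.asarray(iids, dtype=object),
        population_labels=np.asarray(pops, dtype=object),
        sire_ids=np.asarray(sires, dtype=object),
        dam_ids=np.asarray(dams, dtype=object),
    )


# -----------------------------------------------------------------------------
# QTL effects and true genetic values
# -----------------------------------------------------------------------------

def assign_qtl_effects(
    geno: GenotypeMatrix, config: SimulationConfig
) -> tuple[pd.DataFrame, TrueGeneticValues]:
    """Sample QTL per chromosome group and rescale effects so each group's
    partial genetic value realizes its configured variance fraction.

    Total genetic variance is normalized to 1.0 trait-units^2 (0 when
    ``h2_target == 0``).  Per-population effect multipliers, when configured,
    scale the partial values of each population after the variance
    calibration (calibration uses the unscaled values).

    Returns (effects table with columns snp_id/group/effect, TrueGeneticValues).
    """
    chroms = geno.snp_map["chrom"].to_numpy()
    present = set(chroms.tolist())
    missing = [c for c in config.feature_chromosomes if c not in present]
    if missing:
        raise ValueError(f"feature chromosomes absent from SNP map: {missing}")
    if config.n_qtl > geno.n_snps:
        raise ValueError(
            f"n_qtl={config.n_qtl} exceeds available SNP count {geno.n_snps}"
        )

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 17]))

    groups: dict[str, np.ndarray] = {}
    for c in config.feature_chromosomes:
        groups[c] = np.flatnonzero(chroms == c)
    rest_mask = ~np.isin(chroms, list(config.feature_chromosomes))
    groups["rest"] = np.flatnonzero(rest_mask)

    fractions = dict(zip(config.feature_chromosomes, config.feature_variance_fractions))
    fractions["rest"] = config.rest_variance_fraction

    # split QTL count across groups proportional to SNP counts (>=1 per
    # group with a nonzero fraction)
    sizes = {g: len(ix) for g, ix in groups.items()}
    total_snps = sum(sizes.values())
    n_qtl_group = {
        g: max(1, round(config.n_qtl * sizes[g] / total_snps)) if fractions[g] > 0 else 0
        for g in groups
    }

    counts = geno.allele_counts
    centered = counts - counts.mean(axis=0, keepdims=True)

    zero_out = config.h2_target == 0
    effect_rows = []
    partials: dict[str, np.ndarray] = {}
    for g, ix in groups.items():
        nq = min(n_qtl_group[g], len(ix))
        target_var = fractions[g] * 1.0
        if nq == 0 or zero_out or target_var == 0:
            partials[g] = np.zeros(geno.n_individuals)
            continue
        qtl_ix = rng.choice(ix, size=nq, replace=False)
        a = rng.normal(0.0, 1.0, size=nq)
        value = centered[:, qtl_ix] @ a
        realized = value.var()
        if realized <= 0:
            raise ValueError(f"group {g}: sampled QTL are monomorphic, cannot scale")
        scale = np.sqrt(target_var / realized)
        a *= scale
        partials[g] = value * scale
        for j, eff in zip(qtl_ix, a):
            effect_rows.append((geno.snp_ids[j], g, eff))

    if config.qtl_effect_scaling_per_population is not None:
        mult = dict(
            zip(config.population_names, config.qtl_effect_scaling_per_population)
        )
        row_mult = np.array([mult[p] for p in geno.population_labels])
        partials = {g: v * row_mult for g, v in partials.items()}

    effects = pd.DataFrame(effect_rows, columns=["snp_id", "group", "effect"])
    tgv = TrueGeneticValues(individual_ids=geno.individual_ids.copy(), partials=partials)
    return effects, tgv


# -----------------------------------------------------------------------------
# Phenotypes
# -----------------------------------------------------------------------------

def simulate_phenotypes(
    geno: GenotypeMatrix,
    tgv: TrueGeneticValues,
    config: SimulationConfig,
    trait_name: str = "trait",
) -> pd.DataFrame:
    """Build a phenotype table with the fixed-effect structure
    ``y = mu + parity + herd + b1*DIM + b2*exp(-0.05*DIM) + g + e``.

    Residual variance is chosen from the realized genetic variance so that the
    sample ratio var(g)/(var(g)+var(e)) equals ``h2_target`` (the residual
    vector is standardized to its target sample variance).  When
    ``residual_cv_multiplicative`` is set the phenotype is generated
    multiplicatively, ``y = base * exp(e_log)``, producing residual scatter
    proportional to the mean (right-skewed; a candidate for log transform).
    """
    if not np.array_equal(tgv.individual_ids, geno.individual_ids):
        raise ValueError("true genetic values not aligned to genotype individuals")
    if config.dim_range[0] < 0:
        raise ValueError("dim_range would produce negative DIM")

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 29]))
    n = geno.n_individuals

    parity = rng.integers(1, config.parity_levels + 1, size=n)
    parity_eff = rng.normal(0.0, config.parity_sd, size=config.parity_levels)

    herd_codes = []
    for pop in pd.unique(geno.population_labels):
        idx = np.flatnonzero(geno.population_labels == pop)
        herd_codes_pop = rng.integers(1, config.n_herds_per_population + 1, size=len(idx))
        for i, h in zip(idx, herd_codes_pop):
            herd_codes.append((i, f"{pop}_herd{h}"))
    herd = np.empty(n, dtype=object)
    for i, h in herd_codes:
        herd[i] = h
    herd_levels = pd.unique(herd)
    herd_eff = dict(zip(herd_levels, rng.normal(0.0, config.herd_sd, size=len(herd_levels))))

    dim = rng.uniform(config.dim_range[0], config.dim_range[1], size=n)

    g = tgv.total
    var_g = g.var()
    h2 = config.h2_target
    fixed_part = (
        config.mu
        + parity_eff[parity - 1]
        + np.array([herd_eff[h] for h in herd])
        + config.wilmink_b1 * dim
        + config.wilmink_b2 * np.exp(-WILMINK_RATE * dim)
    )

    if config.residual_cv_multiplicative is not None:
        cv = config.residual_cv_multiplicative
        base = fixed_part + g
        if (base <= 0).any():
            raise ValueError("multiplicative mode requires a positive linear predictor; "
                             "increase mu")
        e_log = rng.normal(0.0, cv, size=n)
        y = base * np.exp(e_log)
    else:
        if var_g > 0 and 0 < h2 < 1:
            var_e = var_g * (1 - h2) / h2
        else:
            var_e = 1.0
        e = rng.normal(0.0, 1.0, size=n)
        e = e - e.mean()
        sd = e.std()
        e = e / sd * np.sqrt(var_e) if sd > 0 else e
        y = fixed_part + g + e

    return pd.DataFrame(
        {
            "animal_id": geno.individual_ids,
            "population": geno.population_labels,
            "sire_id": geno.sire_ids if geno.sire_ids is not None else [None] * n,
            "dam_id": geno.dam_ids if geno.dam_ids is not None else [None] * n,
            "herd": herd,
            "parity": parity,
            "dim": dim,
            trait_name: y,
        }
    )


def simulate_dataset(
    config: SimulationConfig, trait_name: str = "trait"
) -> tuple[GenotypeMatrix, pd.DataFrame, TrueGeneticValues, pd.DataFrame]:
    """Convenience wrapper: genotypes -> QTL effects -> phenotypes.

    Returns (genotypes, phenotypes, true genetic values, effects table).
    """
    geno = simulate_genotypes(config)
    effects, tgv = assign_qtl_effects(geno, config)
    phenos = simulate_phenotypes(geno, tgv, config, trait_name=trait_name)
    return geno, phenos, tgv, effects


def write_phenotypes(phenos: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    phenos.to_csv(path, sep="\t", index=False)
    return path


def write_true_values(tgv: TrueGeneticValues, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tgv.as_frame().to_csv(path, sep="\t", index=False)
    return path


def write_dataset(
    config: SimulationConfig, out_prefix: str | Path, trait_name: str = "trait"
) -> dict[str, Path]:
    """Simulate and persist genotypes (.ped/.map), phenotypes and true values."""
    geno, phenos, tgv, effects = simulate_dataset(config, trait_name=trait_name)
    out_prefix = Path(out_prefix)
    ped, mp = write_plink_text(geno, out_prefix)
    phen = write_phenotypes(phenos, out_prefix.with_suffix(".pheno.tsv"))
    truth = write_true_values(tgv, out_prefix.with_suffix(".truth.tsv"))
    eff_path = out_prefix.with_suffix(".effects.tsv")
    effects.to_csv(eff_path, sep="\t", index=False)
    return {"ped": ped, "map": mp, "pheno": phen, "truth": truth, "effects": eff_path}
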