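"""Genotype matrix container, file readers/writers, per-population QC and
common-SNP intersection.

The central type is :class:`GenotypeMatrix`: an individuals x SNPs matrix of
counted-allele dosages in {0, 1, 2} (``NaN`` marks a missing genotype),
together with a SNP map (id, chromosome, 1-based bp position) and individual
metadata (population, sire, dam).

QC follows the rule applied within each population: a SNP is removed when its
minor allele frequency is below ``maf_min`` *or* when any of the three
genotype classes has fewer than ``min_class_count`` carriers.  Multi-population
analyses run on the intersection of the per-population post-QC SNP sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeMatrix",
    "QCReport",
    "GenotypeParseError",
    "HarmonizationError",
    "read_genotypes",
    "write_plink_text",
    "qc_filter",
    "intersect_common_snps",
    "mean_impute_missing",
]


class GenotypeParseError(ValueError):
    """Raised when a genotype file does not parse under its declared format."""


class HarmonizationError(ValueError):
    """Raised when shared SNP ids carry conflicting alleles across inputs."""


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs allele-count matrix plus maps and labels.

    Parameters
    ----------
    allele_counts
        Float array of shape ``(n_individuals, n_snps)`` with entries in
        ``{0, 1, 2}`` or ``NaN`` for missing.  Mean-imputed matrices hold
        real values in ``[0, 2]``.
    snp_map
        DataFrame with columns ``snp_id``, ``chrom``, ``pos`` (1-based bp)
        and optionally ``a1``/``a2`` (non-counted / counted allele).
    individual_ids, population_labels, sire_ids, dam_ids
        Per-row metadata; sire/dam ids may be ``None``.
    """

    allele_counts: np.ndarray
    snp_map: pd.DataFrame
    individual_ids: np.ndarray
    population_labels: np.ndarray
    sire_ids: np.ndarray | None = None
    dam_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.allele_counts = np.asarray(self.allele_counts, dtype=float)
        self.individual_ids = np.asarray(self.individual_ids, dtype=object)
        self.population_labels = np.asarray(self.population_labels, dtype=object)
        if self.sire_ids is not None:
            self.sire_ids = np.asarray(self.sire_ids, dtype=object)
        if self.dam_ids is not None:
            self.dam_ids = np.asarray(self.dam_ids, dtype=object)
        n, m = self.allele_counts.shape
        if len(self.snp_map) != m:
            raise ValueError(
                f"snp_map has {len(self.snp_map)} rows but matrix has {m} columns"
            )
        if len(self.individual_ids) != n or len(self.population_labels) != n:
            raise ValueError("individual metadata length does not match row count")
        if len(set(self.individual_ids)) != n:
            raise ValueError("duplicate individual ids")
        if (self.snp_map["pos"].to_numpy() <= 0).any():
            raise ValueError("SNP positions must be strictly positive (1-based)")
        self.snp_map = self.snp_map.reset_index(drop=True)

    # -- convenience accessors -------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return self.allele_counts.shape[0]

    @property
    def n_snps(self) -> int:
        return self.allele_counts.shape[1]

    @property
    def snp_ids(self) -> np.ndarray:
        return self.snp_map["snp_id"].to_numpy()

    def subset_snps(self, mask_or_ids) -> "GenotypeMatrix":
        """Column subset by boolean mask or iterable of SNP ids (order kept)."""
        if isinstance(mask_or_ids, np.ndarray) and mask_or_ids.dtype == bool:
            idx = np.flatnonzero(mask_or_ids)
        else:
            wanted = set(mask_or_ids)
            idx = np.flatnonzero(self.snp_map["snp_id"].isin(wanted).to_numpy())
        return replace(
            self,
            allele_counts=self.allele_counts[:, idx],
            snp_map=self.snp_map.iloc[idx].reset_index(drop=True),
        )

    def subset_individuals(self, ids: Iterable) -> "GenotypeMatrix":
        """Row subset by individual ids, in the order given."""
        pos = {iid: i for i, iid in enumerate(self.individual_ids)}
        idx = np.array([pos[i] for i in ids], dtype=int)
        return replace(
            self,
            allele_counts=self.allele_counts[idx],
            individual_ids=self.individual_ids[idx],
            population_labels=self.population_labels[idx],
            sire_ids=None if self.sire_ids is None else self.sire_ids[idx],
            dam_ids=None if self.dam_ids is None else self.dam_ids[idx],
        )

    def split_by_population(self) -> dict:
        """Return {population label: GenotypeMatrix of that population}."""
        out = {}
        for pop in pd.unique(self.population_labels):
            ids = self.individual_ids[self.population_labels == pop]
            out[pop] = self.subset_individuals(ids)
        return out


@dataclass
class QCReport:
    """Per-SNP QC metrics and removal flags with reason codes."""

    table: pd.DataFrame = field(repr=False)
    maf_min: float = 0.05
    min_class_count: int = 10

    REASON_MAF = "maf_below_threshold"
    REASON_CLASS = "genotype_class_count_below_threshold"

    def __post_init__(self) -> None:
        t = self.table
        expected = (t["maf"] < self.maf_min) | (t["min_class_count"] < self.min_class_count)
        if not (t["removed"].to_numpy() == expected.to_numpy()).all():
            raise ValueError("removal flags inconsistent with thresholds")

    @property
    def n_removed(self) -> int:
        return int(self.table["removed"].sum())

    @property
    def removed_snps(self) -> pd.DataFrame:
        return self.table[self.table["removed"]]


# -----------------------------------------------------------------------------
# Readers / writers
# -----------------------------------------------------------------------------

def read_genotypes(
    path: str | Path,
    format: str = "plink-text",
    population: str = "pop1",
) -> GenotypeMatrix:
    """Read genotypes from PLINK text (.ped/.map prefix) or an uncompressed VCF.

    Biallelic SNPs are loaded as counts of the designated counted allele
    (ALT for VCF, allele ``a2`` for PLINK text written by this package;
    otherwise the minor allele).  Multi-allelic VCF records are skipped with
    a warning.  Missing genotypes stay missing (NaN).
    """
    if format == "plink-text":
        return _read_plink_text(Path(path), population)
    if format == "vcf":
        return _read_vcf(Path(path), population)
    raise ValueError(f"unknown genotype format: {format!r}")


def _read_map(map_path: Path) -> pd.DataFrame:
    rows = []
    with open(map_path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 4:
                raise GenotypeParseError(f"{map_path}:{ln}: expected 4 columns, got {len(parts)}")
            chrom, snp_id, _cm, pos = parts[:4]
            try:
                pos = int(pos)
            except ValueError as exc:
                raise GenotypeParseError(f"{map_path}:{ln}: bad position {parts[3]!r}") from exc
            rows.append((snp_id, chrom, pos))
    return pd.DataFrame(rows, columns=["snp_id", "chrom", "pos"])


def _read_plink_text(prefix: Path, population: str) -> GenotypeMatrix:
    ped_path = prefix.with_suffix(".ped")
    map_path = prefix.with_suffix(".map")
    snp_map = _read_map(map_path)
    m = len(snp_map)

    iids, sires, dams, allele_rows = [], [], [], []
    with open(ped_path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * m:
                raise GenotypeParseError(
                    f"{ped_path}:{ln}: expected {6 + 2 * m} fields for {m} SNPs, got {len(parts)}"
                )
            _fid, iid, sire, dam = parts[0], parts[1], parts[2], parts[3]
            iids.append(iid)
            sires.append(None if sire == "0" else sire)
            dams.append(None if dam == "0" else dam)
            allele_rows.append(parts[6:])

    alleles = np.asarray(allele_rows, dtype=object).reshape(len(iids), m, 2)
    counts = np.full((len(iids), m), np.nan)
    a1_list, a2_list = [], []
    for j in range(m):
        col = alleles[:, j, :]
        observed = col[col != "0"]
        uniq = sorted(set(observed.tolist()))
        if len(uniq) > 2:
            raise GenotypeParseError(
                f"{ped_path}: SNP {snp_map['snp_id'][j]} has >2 alleles: {uniq}"
            )
        if not uniq:
            a1_list.append("0")
            a2_list.append("0")
            continue
        if len(uniq) == 1:
            a1, a2 = uniq[0], uniq[0]
        else:
            # counted allele = minor allele (ties broken by sort order)
            n0 = int((observed == uniq[0]).sum())
            n1 = int((observed == uniq[1]).sum())
            a1, a2 = (uniq[0], uniq[1]) if n1 <= n0 else (uniq[1], uniq[0])
        a1_list.append(a1)
        a2_list.append(a2)
        non_missing = (col != "0").all(axis=1)
        counts[non_missing, j] = (col[non_missing] == a2).sum(axis=1)

    snp_map = snp_map.assign(a1=a1_list, a2=a2_list)
    return GenotypeMatrix(
        allele_counts=counts,
        snp_map=snp_map,
        individual_ids=np.asarray(iids, dtype=object),
        population_labels=np.asarray([population] * len(iids), dtype=object),
        sire_ids=np.asarray(sires, dtype=object),
        dam_ids=np.asarray(dams, dtype=object),
    )


def _read_vcf(path: Path, population: str) -> GenotypeMatrix:
    try:
        from cyvcf2 import VCF
    except ImportError:  # pragma: no cover - cyvcf2 is a soft dependency
        return _read_vcf_text(path, population)

    vcf = VCF(str(path))
    iids = list(vcf.samples)
    rows, records = [], []
    n_multi = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        # cyvcf2 gt_types: 0=hom-ref 1=het 2=unknown 3=hom-alt
        gt = var.gt_types.astype(float)
        gt[gt == 2] = np.nan
        gt[gt == 3] = 2.0
        rows.append(gt)
        records.append((var.ID or f"{var.CHROM}:{var.POS}", var.CHROM, var.POS, var.REF, var.ALT[0]))
    if n_multi:
        logger.warning("skipped %d multi-allelic records in %s", n_multi, path)
    if not records:
        raise GenotypeParseError(f"{path}: no biallelic records found")
    counts = np.asarray(rows).T
    snp_map = pd.DataFrame(records, columns=["snp_id", "chrom", "pos", "a1", "a2"])
    return GenotypeMatrix(
        allele_counts=counts,
        snp_map=snp_map,
        individual_ids=np.asarray(iids, dtype=object),
        population_labels=np.asarray([population] * len(iids), dtype=object),
    )


def _read_vcf_text(path: Path, population: str) -> GenotypeMatrix:
    """Minimal fallback VCF parser (GT field only, uncompressed)."""
    iids: list[str] = []
    rows, records = [], []
    n_multi = 0
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                iids = line.rstrip("\n").split("\t")[9:]
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 10:
                raise GenotypeParseError(f"{path}:{ln}: malformed VCF record")
            chrom, pos, vid, ref, alt = parts[0], parts[1], parts[2], parts[3], parts[4]
            if "," in alt:
                n_multi += 1
                continue
            gts = []
            for sample in parts[9:]:
                gt = sample.split(":")[0].replace("|", "/")
                if gt in ("./.", "."):
                    gts.append(np.nan)
                else:
                    gts.append(sum(int(a) for a in gt.split("/")))
            rows.append(gts)
            records.append((vid if vid != "." else f"{chrom}:{pos}", chrom, int(pos), ref, alt))
    if n_multi:
        logger.warning("skipped %d multi-allelic records in %s", n_multi, path)
    if not records:
        raise GenotypeParseError(f"{path}: no biallelic records found")
    counts = np.asarray(rows, dtype=float).T
    snp_map = pd.DataFrame(records, columns=["snp_id", "chrom", "pos", "a1", "a2"])
    return GenotypeMatrix(
        allele_counts=counts,
        snp_map=snp_map,
        individual_ids=np.asarray(iids, dtype=object),
        population_labels=np.asarray([population] * len(iids), dtype=object),
    )


def write_plink_text(geno: GenotypeMatrix, prefix: str | Path) -> tuple[Path, Path]:
    """Write PLINK text .ped/.map.  Counted allele written as 'B', other as 'A'.

    Genotypes must be integer dosages; missing entries become '0 0'.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    map_path = prefix.with_suffix(".map")
    ped_path = prefix.with_suffix(".ped")

    with open(map_path, "w") as fh:
        for _, row in geno.snp_map.iterrows():
            fh.write(f"{row['chrom']}\t{row['snp_id']}\t0\t{int(row['pos'])}\n")

    code = {0.0: "A A", 1.0: "A B", 2.0: "B B"}
    with open(ped_path, "w") as fh:
        for i, iid in enumerate(geno.individual_ids):
            sire = geno.sire_ids[i] if geno.sire_ids is not None else None
            dam = geno.dam_ids[i] if geno.dam_ids is not None else None
            fid = geno.population_labels[i]
            lead = [str(fid), str(iid), str(sire or 0), str(dam or 0), "0", "-9"]
            gts = []
            for x in geno.allele_counts[i]:
                if np.isnan(x):
                    gts.append("0 0")
                else:
                    gts.append(code[float(round(x))])
            fh.write(" ".join(lead + gts) + "\n")
    return ped_path, map_path


# -----------------------------------------------------------------------------
# QC and assembly
# -----------------------------------------------------------------------------

def qc_filter(
    geno: GenotypeMatrix,
    maf_min: float = 0.05,
    min_class_count: int = 10,
) -> tuple[GenotypeMatrix, QCReport]:
    """Remove SNPs with MAF below ``maf_min`` or any genotype class rarer than
    ``min_class_count``.  Boundary values (MAF == maf_min, count ==
    min_class_count) are retained.

    Intended to be applied within a single population; a warning is logged if
    the matrix mixes populations.
    """
    if len(pd.unique(geno.population_labels)) > 1:
        logger.warning("qc_filter called on a multi-population matrix; "
                       "the QC rule is defined within each population")

    counts = geno.allele_counts
    n0 = np.nansum(counts == 0, axis=0)
    n1 = np.nansum(counts == 1, axis=0)
    n2 = np.nansum(counts == 2, axis=0)
    n_obs = n0 + n1 + n2
    if (n_obs == 0).any():
        bad = geno.snp_ids[n_obs == 0]
        raise ValueError(f"SNPs with no observed genotypes: {bad[:5].tolist()}")
    p = (n1 + 2 * n2) / (2 * n_obs)
    maf = np.minimum(p, 1 - p)
    min_class = np.minimum(np.minimum(n0, n1), n2)

    removed = (maf < maf_min) | (min_class < min_class_count)
    reasons = []
    for j in range(geno.n_snps):
        if not removed[j]:
            reasons.append("")
            continue
        rs = []
        if maf[j] < maf_min:
            rs.append(QCReport.REASON_MAF)
        if min_class[j] < min_class_count:
            rs.append(QCReport.REASON_CLASS)
        reasons.append(";".join(rs))

    table = pd.DataFrame(
        {
            "snp_id": geno.snp_ids,
            "maf": maf,
            "min_class_count": min_class.astype(int),
            "removed": removed,
            "reason": reasons,
        }
    )
    report = QCReport(table=table, maf_min=maf_min, min_class_count=min_class_count)
    kept = geno.subset_snps(~removed)
    if kept.n_snps == 0:
        raise ValueError("no SNPs survive QC filtering")
    logger.info("QC: removed %d of %d SNPs", report.n_removed, geno.n_snps)
    return kept, report


def _chrom_sort_key(c) -> tuple:
    s = str(c)
    digits = "".join(ch for ch in s if ch.isdigit())
    return (0, int(digits), s) if digits else (1, 0, s)


def intersect_common_snps(genos: Sequence[GenotypeMatrix]) -> GenotypeMatrix:
    """Row-concatenate matrices over their common SNPs (matched on id + position).

    SNP order in the result follows (chromosome, position).  Allele annotations
    (``a1``/``a2``), when present in several inputs, must agree.
    """
    if len(genos) < 2:
        raise ValueError("need at least two matrices to intersect")
    all_ids = [set(g.individual_ids) for g in genos]
    for i in range(len(genos)):
        for j in range(i + 1, len(genos)):
            if all_ids[i] & all_ids[j]:
                raise ValueError("individual ids overlap between input matrices")

    keys = [set(zip(g.snp_map["snp_id"], g.snp_map["pos"])) for g in genos]
    common = set.intersection(*keys)
    if not common:
        raise ValueError("no common SNPs across inputs")

    # harmonization check on allele annotations
    allele_seen: dict = {}
    offenders = []
    for g in genos:
        if not {"a1", "a2"}.issubset(g.snp_map.columns):
            continue
        for sid, pos, a1, a2 in zip(
            g.snp_map["snp_id"], g.snp_map["pos"], g.snp_map["a1"], g.snp_map["a2"]
        ):
            if (sid, pos) not in common:
                continue
            pair = frozenset((a1, a2))
            prev = allele_seen.setdefault((sid, pos), pair)
            if prev != pair:
                offenders.append(sid)
    if offenders:
        raise HarmonizationError(
            f"conflicting alleles for shared SNPs: {sorted(set(offenders))[:10]}"
        )

    ref = genos[0].snp_map
    sel = ref[[(s, p) in common for s, p in zip(ref["snp_id"], ref["pos"])]]
    order = sorted(
        range(len(sel)),
        key=lambda i: (_chrom_sort_key(sel["chrom"].iloc[i]), sel["pos"].iloc[i]),
    )
    ordered_ids = sel["snp_id"].iloc[order].tolist()

    parts = [g.subset_snps(ordered_ids) for g in genos]
    snp_map = parts[0].snp_map
    return GenotypeMatrix(
        allele_counts=np.vstack([p.allele_counts for p in parts]),
        snp_map=snp_map,
        individual_ids=np.concatenate([p.individual_ids for p in parts]),
        population_labels=np.concatenate([p.population_labels for p in parts]),
        sire_ids=(
            None
            if any(p.sire_ids is None for p in parts)
            else np.concatenate([p.sire_ids for p in parts])
        ),
        dam_ids=(
            None
            if any(p.dam_ids is None for p in parts)
            else np.concatenate([p.dam_ids for p in parts])
        ),
    )


def mean_impute_missing(geno: GenotypeMatrix) -> GenotypeMatrix:
    """Replace missing entries by the per-SNP mean allele count."""
    counts = geno.allele_counts
    if not np.isnan(counts).any():
        return geno
    all_missing = np.isnan(counts).all(axis=0)
    if all_missing.any():
        raise ValueError(
            f"SNPs with all entries missing: {geno.snp_ids[all_missing][:5].tolist()}"
        )
    col_means = np.nanmean(counts, axis=0)
    filled = np.where(np.isnan(counts), col_means[None, :], counts)
    return replace(geno, allele_counts=filled)
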