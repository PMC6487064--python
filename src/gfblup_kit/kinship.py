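"""Genomic relationship matrices (VanRaden method 1) and feature partitions.

G = (M - P)(M - P)' / (2 * sum_j p_j (1 - p_j)) where M holds allele counts
and P the column matrix of 2 p_j.  A :class:`GRMSet` holds one GRM per
feature chromosome plus a rest-of-genome GRM; because every member records its
scaling denominator, the whole-genome GRM is recoverable exactly as
``sum_f (s_f / s_total) * G_f``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .genotypes import GenotypeMatrix

__all__ = ["GRM", "GRMSet", "allele_frequencies", "vanraden_grm", "feature_grms"]


@dataclass
class GRM:
    """Symmetric genomic relationship matrix with its scaling denominator."""

    matrix: np.ndarray
    individual_ids: np.ndarray
    snp_ids_used: np.ndarray
    denominator: float

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = self.matrix.shape[0]
        if self.matrix.shape != (n, n):
            raise ValueError("GRM must be square")
        if len(self.individual_ids) != n:
            raise ValueError("individual_ids length must match matrix dimension")
        if self.denominator <= 0:
            raise ValueError("GRM denominator must be > 0")
        asym = np.abs(self.matrix - self.matrix.T).max()
        if asym > 1e-8 * max(1.0, np.abs(self.matrix).max()):
            raise ValueError(f"GRM not symmetric (max asymmetry {asym:.3g})")
        self.matrix = 0.5 * (self.matrix + self.matrix.T)

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def submatrix(self, ids) -> np.ndarray:
        pos = {iid: i for i, iid in enumerate(self.individual_ids)}
        idx = np.array([pos[i] for i in ids], dtype=int)
        return self.matrix[np.ix_(idx, idx)]

    def write_lower_triangle(self, path: str | Path) -> Path:
        """Persist as delimited lower-triangle text: id_i, id_j, value."""
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            fh.write(f"# denominator\t{float(self.denominator)!r}\n")
            for i in range(self.n):
                for j in range(i + 1):
                    fh.write(
                        f"{self.individual_ids[i]}\t{self.individual_ids[j]}\t"
                        f"{float(self.matrix[i, j])!r}\n"
                    )
        return path

    @classmethod
    def read_lower_triangle(cls, path: str | Path) -> "GRM":
        path = Path(path)
        denominator = None
        rows = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#"):
                    denominator = float(line.split("\t")[1])
                    continue
                a, b, v = line.rstrip("\n").split("\t")
                rows.append((a, b, float(v)))
        if denominator is None:
            raise ValueError(f"{path}: missing denominator header")
        ids = list(dict.fromkeys(a for a, _, _ in rows))
        pos = {iid: i for i, iid in enumerate(ids)}
        n = len(ids)
        mat = np.zeros((n, n))
        for a, b, v in rows:
            i, j = pos[a], pos[b]
            mat[i, j] = mat[j, i] = v
        return cls(
            matrix=mat,
            individual_ids=np.asarray(ids, dtype=object),
            snp_ids_used=np.asarray([], dtype=object),
            denominator=denominator,
        )


@dataclass
class GRMSet:
    """Feature GRMs keyed by label plus a rest-of-genome GRM.

    The members' SNP sets partition the full SNP set of the source matrix.
    """

    features: dict[str, GRM]
    rest: GRM

    def __post_init__(self) -> None:
        sets = [set(g.snp_ids_used) for g in self.features.values()]
        sets.append(set(self.rest.snp_ids_used))
        total = sum(len(s) for s in sets)
        union = set().union(*sets)
        if total != len(union):
            raise ValueError("feature/rest SNP sets are not disjoint")

    @property
    def components(self) -> dict[str, GRM]:
        out = dict(self.features)
        out["rest"] = self.rest
        return out

    def whole_genome(self) -> GRM:
        """Reconstruct the whole-genome GRM from the partition."""
        comps = self.components
        s_total = sum(g.denominator for g in comps.values())
        mat = sum(g.denominator * g.matrix for g in comps.values()) / s_total
        snp_ids = np.concatenate([g.snp_ids_used for g in comps.values()])
        first = next(iter(comps.values()))
        return GRM(
            matrix=mat,
            individual_ids=first.individual_ids,
            snp_ids_used=snp_ids,
            denominator=s_total,
        )


def allele_frequencies(geno: GenotypeMatrix) -> np.ndarray:
    """Per-SNP counted-allele frequency p_j = mean allele count / 2."""
    counts = geno.allele_counts
    if np.isnan(counts).all(axis=0).any():
        raise ValueError("SNP with all entries missing")
    return np.nanmean(counts, axis=0) / 2.0


def vanraden_grm(
    geno: GenotypeMatrix,
    snp_subset=None,
    freqs: np.ndarray | None = None,
) -> GRM:
    """VanRaden method-1 GRM over ``snp_subset`` (default: all SNPs).

    ``freqs`` must cover all SNPs of ``geno`` (same order); defaults to the
    sample frequencies of the supplied individuals.  Genotypes are expected to
    be mean-imputed (no NaN).
    """
    if np.isnan(geno.allele_counts).any():
        raise ValueError("genotypes contain missing values; mean-impute first")
    if freqs is None:
        freqs = allele_frequencies(geno)
    freqs = np.asarray(freqs, dtype=float)
    if freqs.shape[0] != geno.n_snps:
        raise ValueError("freqs must align with geno's SNP columns")

    if snp_subset is None:
        idx = np.arange(geno.n_snps)
    else:
        wanted = set(snp_subset)
        idx = np.flatnonzero(geno.snp_map["snp_id"].isin(wanted).to_numpy())
        if len(idx) == 0:
            raise ValueError("snp_subset selects no SNPs")

    p = freqs[idx]
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    if denom <= 0:
        raise ValueError("all subset SNPs monomorphic: VanRaden denominator is zero")
    W = geno.allele_counts[:, idx] - 2.0 * p[None, :]
    G = (W @ W.T) / denom
    return GRM(
        matrix=G,
        individual_ids=geno.individual_ids.copy(),
        snp_ids_used=geno.snp_ids[idx],
        denominator=denom,
    )


def feature_grms(
    geno: GenotypeMatrix,
    feature_chromosomes,
    freqs: np.ndarray | None = None,
) -> GRMSet:
    """One GRM per feature chromosome plus a rest-of-genome GRM.

    All members are centered with the same allele frequencies (by default the
    scenario-wide sample frequencies), so the partition identity
    ``sum_f (s_f/s_total) G_f == G_whole`` holds exactly.
    """
    feature_chromosomes = list(feature_chromosomes)
    chroms = geno.snp_map["chrom"].to_numpy()
    present = set(chroms.tolist())
    missing = [c for c in feature_chromosomes if c not in present]
    if missing:
        raise ValueError(f"feature chromosomes not in SNP map: {missing}")
    if freqs is None:
        freqs = allele_frequencies(geno)

    features = {}
    for c in feature_chromosomes:
        sub = geno.snp_ids[chroms == c]
        if len(sub) == 0:
            raise ValueError(f"feature chromosome {c} has no SNPs after QC")
        features[c] = vanraden_grm(geno, snp_subset=sub, freqs=freqs)

    rest_ids = geno.snp_ids[~np.isin(chroms, feature_chromosomes)]
    if len(rest_ids) == 0:
        raise ValueError(
            "every chromosome is a feature: rest-of-genome GRM would be empty"
        )
    rest = vanraden_grm(geno, snp_subset=rest_ids, freqs=freqs)
    return GRMSet(features=features, rest=rest)
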