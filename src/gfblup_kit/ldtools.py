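"""Pairwise linkage disequilibrium (r^2) within a distance window and
binwise mean LD per chromosome.

r^2 is the squared Pearson correlation of allele-count vectors (composite,
phase-free LD); pairs with a monomorphic member are skipped and counted.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = ["pairwise_r2", "binwise_mean_ld"]


def pairwise_r2(
    geno: GenotypeMatrix,
    chromosome,
    max_distance: int = 1_000_000,
) -> pd.DataFrame:
    """All SNP pairs on ``chromosome`` within ``max_distance`` bp.

    Returns a DataFrame with columns ``snp_i, snp_j, distance, r2``;
    ``df.attrs["n_monomorphic_skipped"]`` counts pairs dropped because a
    member had zero variance.
    """
    chroms = geno.snp_map["chrom"].to_numpy()
    sel = np.flatnonzero(chroms == chromosome)
    if len(sel) < 2:
        raise ValueError(f"chromosome {chromosome!r} has fewer than 2 SNPs")
    pos = geno.snp_map["pos"].to_numpy()[sel]
    order = np.argsort(pos)
    sel = sel[order]
    pos = pos[order]
    ids = geno.snp_ids[sel]

    counts = geno.allele_counts[:, sel]
    # per-column stats over non-missing individuals
    with np.errstate(invalid="ignore"):
        sd = np.nanstd(counts, axis=0)
    poly = sd > 0

    rows = []
    n_skipped = 0
    m = len(sel)
    for a in range(m - 1):
        for b in range(a + 1, m):
            d = int(pos[b] - pos[a])
            if d > max_distance:
                break
            if d == 0:
                continue
            if not (poly[a] and poly[b]):
                n_skipped += 1
                continue
            xa, xb = counts[:, a], counts[:, b]
            ok = ~(np.isnan(xa) | np.isnan(xb))
            if ok.sum() < 2:
                n_skipped += 1
                continue
            va, vb = xa[ok], xb[ok]
            if va.std() == 0 or vb.std() == 0:
                n_skipped += 1
                continue
            r = np.corrcoef(va, vb)[0, 1]
            rows.append((ids[a], ids[b], d, float(r * r)))

    df = pd.DataFrame(rows, columns=["snp_i", "snp_j", "distance", "r2"])
    df.attrs["n_monomorphic_skipped"] = n_skipped
    df.attrs["chromosome"] = chromosome
    if n_skipped:
        logger.info("chromosome %s: skipped %d pairs with a monomorphic member",
                    chromosome, n_skipped)
    return df


def binwise_mean_ld(pairs: pd.DataFrame, bin_size: int) -> pd.DataFrame:
    """Unweighted mean r^2 per half-open distance bin [k*bin, (k+1)*bin).

    Bins tile the full observed distance range; empty bins are reported with
    ``n_pairs == 0`` and a missing mean.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    if pairs.empty:
        raise ValueError("no pairs supplied")
    dist = pairs["distance"].to_numpy()
    r2 = pairs["r2"].to_numpy()
    n_bins = int(dist.max() // bin_size) + 1
    which = (dist // bin_size).astype(int)
    rows = []
    chrom = pairs.attrs.get("chromosome")
    for k in range(n_bins):
        mask = which == k
        n = int(mask.sum())
        rows.append(
            {
                "chromosome": chrom,
                "bin_start": k * bin_size,
                "bin_end": (k + 1) * bin_size,
                "mean_r2": float(r2[mask].mean()) if n else np.nan,
                "n_pairs": n,
            }
        )
    return pd.DataFrame(rows)
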