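"""Phase-free composite linkage disequilibrium and decay with distance.

The Burrows composite disequilibrium Delta is estimated from unphased
diploid genotypes — no Hardy-Weinberg or known-phase assumption — as half
the (population, 1/n) covariance of allele counts at the two sites. The
squared composite correlation r^2 divides by Hardy-Weinberg-departure-
corrected single-site variances, which makes it identically the squared
Pearson correlation of the two dosage vectors and keeps it in [0, 1]
(the naive p*q denominator is not a bounded correlation).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .association import SiteAssociation
from .variants import GenotypeMatrix

logger = logging.getLogger("hzscan")


@dataclass
class LDRecord:
    locus_i: str
    pos_i: int
    locus_j: str
    pos_j: int
    distance: float  # bp on the shared axis, NaN if either locus unplaced
    n_used: int
    delta: float
    r2: float
    pair_class: str = "other"  # or "both_associated"
    within_gene: bool = False
    reason: str = ""  # "insufficient n" / "monomorphic" when r2 is NA


def _complete(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ok = ~np.isnan(x) & ~np.isnan(y)
    return x[ok], y[ok]


def composite_delta(dosage_i: np.ndarray, dosage_j: np.ndarray) -> float:
    """Burrows composite Delta = cov(X, Y)/2 on allele counts X, Y = 2*dosage.

    Uses the 1/n covariance, matching the count formula n_AB/n - 2 pA pB.
    NaN when either site is monomorphic among complete pairs.
    """
    x, y = _complete(np.asarray(dosage_i, float), np.asarray(dosage_j, float))
    if len(x) < 2:
        raise ValueError("composite_delta needs >=2 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return math.nan
    X, Y = 2 * x, 2 * y
    return float(np.mean(X * Y) - np.mean(X) * np.mean(Y)) / 2


def composite_r2(dosage_i: np.ndarray, dosage_j: np.ndarray) -> float:
    """Squared composite correlation; equals the squared dosage Pearson r.

    r = Delta / sqrt((pA qA + DA)(pB qB + DB)) with DA, DB the within-locus
    Hardy-Weinberg departures; the denominator terms are exactly half the
    per-site allele-count variances, so r reduces to the Pearson correlation
    of the dosage vectors.
    """
    x, y = _complete(np.asarray(dosage_i, float), np.asarray(dosage_j, float))
    if len(x) < 2:
        raise ValueError("composite_r2 needs >=2 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return math.nan
    r = float(np.corrcoef(x, y)[0, 1])
    return r * r


def ld_matrix(gm: GenotypeMatrix, min_n: int = 20) -> list[LDRecord]:
    """All unordered site pairs of an informative-filtered matrix.

    Pairs with fewer than ``min_n`` complete individuals are emitted with
    NaN statistics and reason "insufficient n" rather than dropped, so the
    exclusion count is visible downstream.
    """
    m = len(gm.sites)
    if m < 2:
        raise ValueError("LD needs >=2 sites")
    records = []
    for i in range(m):
        si = gm.sites[i]
        for j in range(i + 1, m):
            sj = gm.sites[j]
            xi, xj = gm.dosage[:, i], gm.dosage[:, j]
            ok = ~np.isnan(xi) & ~np.isnan(xj)
            n_used = int(ok.sum())
            if si.global_pos is not None and sj.global_pos is not None:
                distance = float(abs(si.global_pos - sj.global_pos))
            else:
                distance = math.nan
            rec = LDRecord(
                locus_i=si.locus_id, pos_i=si.position,
                locus_j=sj.locus_id, pos_j=sj.position,
                distance=distance, n_used=n_used,
                delta=math.nan, r2=math.nan,
                within_gene=si.locus_id == sj.locus_id,
            )
            if n_used < min_n:
                rec.reason = "insufficient n"
            else:
                d = composite_delta(xi, xj)
                if math.isnan(d):
                    rec.reason = "monomorphic"
                else:
                    rec.delta = d
                    rec.r2 = composite_r2(xi, xj)
            records.append(rec)
    n_skipped = sum(1 for r in records if r.reason == "insufficient n")
    if n_skipped:
        logger.info("LD: %d pair(s) below min_n=%d reported as NA", n_skipped, min_n)
    return records


def ld_decay(
    records: Sequence[LDRecord], bin_edges: Sequence[float]
) -> pd.DataFrame:
    """Mean r^2 per inter-site distance bin.

    Only records with a defined distance and r^2 contribute. Bins are
    [edge_k, edge_{k+1}); empty bins are reported with n_pairs = 0 and NaN
    mean rather than dropped.
    """
    usable = [r for r in records if not math.isnan(r.distance)]
    if not usable:
        raise ValueError("no LD records with defined distance")
    edges = np.asarray(bin_edges, dtype=float)
    dist = np.array([r.distance for r in usable])
    r2 = np.array([r.r2 for r in usable])
    idx = np.digitize(dist, edges) - 1
    rows = []
    for k in range(len(edges) - 1):
        in_bin = (idx == k) & ~np.isnan(r2)
        rows.append({
            "bin_mid": (edges[k] + edges[k + 1]) / 2,
            "mean_r2": float(r2[in_bin].mean()) if in_bin.any() else math.nan,
            "n_pairs": int(in_bin.sum()),
        })
    return pd.DataFrame(rows)


def partition_sites_by_association(
    records: Sequence[LDRecord], assoc: Sequence[SiteAssociation]
) -> list[LDRecord]:
    """Set pair_class = "both_associated" on pairs where both sites are
    significant in the association scan; everything else stays "other".
    Sites without an association record count as not significant (warning).
    """
    sig = {(a.locus_id, a.position): a.significant for a in assoc}
    missing = set()
    for rec in records:
        flags = []
        for key in ((rec.locus_i, rec.pos_i), (rec.locus_j, rec.pos_j)):
            if key not in sig:
                missing.add(key)
            flags.append(sig.get(key, False))
        rec.pair_class = "both_associated" if all(flags) else "other"
    if missing:
        logger.warning("%d LD site(s) without association records treated as "
                       "not significant", len(missing))
    return list(records)


def filter_pairs(
    records: Sequence[LDRecord],
    mode: str,
    assoc: Sequence[SiteAssociation] | None = None,
) -> list[LDRecord]:
    """Subset pairs: "all", "associated_only" (both sites significant), or
    "associated_removed" (no pair touching a significant site)."""
    if mode == "all":
        return list(records)
    if assoc is None:
        raise ValueError("association results required for this filter mode")
    sig = {(a.locus_id, a.position) for a in assoc if a.significant}
    if mode == "associated_only":
        return [r for r in records
                if (r.locus_i, r.pos_i) in sig and (r.locus_j, r.pos_j) in sig]
    if mode == "associated_removed":
        return [r for r in records
                if (r.locus_i, r.pos_i) not in sig and (r.locus_j, r.pos_j) not in sig]
    raise ValueError(f"unknown filter mode {mode!r}")


def square_r2_matrix(gm: GenotypeMatrix, records: Sequence[LDRecord]) -> pd.DataFrame:
    """Symmetric site-by-site r^2 matrix (diagonal 1) for heatmap-style output."""
    labels = [f"{s.locus_id}:{s.position}" for s in gm.sites]
    index = {lab: i for i, lab in enumerate(labels)}
    mat = np.full((len(labels), len(labels)), np.nan)
    np.fill_diagonal(mat, 1.0)
    for r in records:
        i = index[f"{r.locus_i}:{r.pos_i}"]
        j = index[f"{r.locus_j}:{r.pos_j}"]
        mat[i, j] = mat[j, i] = r.r2
    return pd.DataFrame(mat, index=labels, columns=labels)
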