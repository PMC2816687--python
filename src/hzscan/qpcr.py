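"""Relative qPCR expression and Bayesian Model Averaging over covariates.

Expression is the classic delta-Ct ratio, efficiency^(Ct_reference -
Ct_target) with efficiency fixed at 2 by default. Covariate importance for
log2 expression is summarized by BIC-weight Bayesian Model Averaging: every
subset of the candidate covariates is fit by ordinary least squares, models
are weighted by exp(-BIC/2), and a covariate's inclusion probability
(reported on the percent scale, as Pr(beta != 0)) is the summed weight of
the models containing it.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("hzscan")

REPLICATE_SPREAD_LIMIT = 0.05  # max fold-spread between replicates


@dataclass
class CtRecord:
    sample_id: str
    gene: str
    ct_target: float
    ct_reference: float
    covariates: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, v in (("ct_target", self.ct_target),
                        ("ct_reference", self.ct_reference)):
            if not (math.isfinite(v) and v > 0):
                raise ValueError(
                    f"{self.sample_id}/{self.gene}: {name} must be finite and "
                    f"positive, got {v}"
                )


@dataclass
class BmaModel:
    covariates: tuple[str, ...]
    rss: float
    k: int  # number of regression coefficients (incl. intercept)
    bic: float
    weight: float


@dataclass
class BmaSummary:
    inclusion: dict[str, float]  # percent scale, Pr(beta != 0)
    coefficients: dict[str, float]  # model-averaged (excluded model -> 0)
    models: list[BmaModel]
    n: int


def relative_expression(
    ct_target: float, ct_reference: float, efficiency: float = 2.0
) -> float:
    """Expression relative to the housekeeping reference: eff^(ref - target)."""
    if efficiency <= 1:
        raise ValueError(f"amplification efficiency must exceed 1, got {efficiency}")
    for name, v in (("ct_target", ct_target), ("ct_reference", ct_reference)):
        if v is None or not math.isfinite(v):
            raise ValueError(f"missing or non-finite {name}")
    return float(efficiency ** (ct_reference - ct_target))


def record_expression(rec: CtRecord, efficiency: float = 2.0) -> float:
    return relative_expression(rec.ct_target, rec.ct_reference, efficiency)


def read_ct_table(path: str | Path, efficiency: float = 2.0) -> pd.DataFrame:
    """Read a Ct CSV and return one row per (sample, gene) with expression.

    Required columns: sample_id, gene, ct_target, ct_reference; any further
    columns are treated as covariates. Replicate rows for the same
    (sample, gene) are averaged on the Ct scale after checking that their
    spread on the relative-expression scale is below 0.05-fold.
    """
    df = pd.read_csv(path)
    required = {"sample_id", "gene", "ct_target", "ct_reference"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: Ct table missing columns {sorted(missing)}")
    covar_cols = [c for c in df.columns if c not in required]
    rows = []
    for (sample, gene), grp in df.groupby(["sample_id", "gene"], sort=False):
        expr = [
            relative_expression(t, r, efficiency)
            for t, r in zip(grp["ct_target"], grp["ct_reference"])
        ]
        if len(expr) > 1:
            spread = (max(expr) - min(expr)) / stats_gmean(expr)
            if spread >= REPLICATE_SPREAD_LIMIT:
                raise ValueError(
                    f"{sample}/{gene}: replicate expression spread {spread:.3f} "
                    f"exceeds the {REPLICATE_SPREAD_LIMIT}-fold criterion"
                )
        row = {
            "sample_id": sample,
            "gene": gene,
            "ct_target": float(grp["ct_target"].mean()),
            "ct_reference": float(grp["ct_reference"].mean()),
        }
        row["expression"] = relative_expression(
            row["ct_target"], row["ct_reference"], efficiency
        )
        for c in covar_cols:
            vals = grp[c].unique()
            if len(vals) > 1:
                raise ValueError(f"{sample}/{gene}: inconsistent covariate {c}")
            row[c] = vals[0]
        rows.append(row)
    return pd.DataFrame(rows)


def stats_gmean(values: Sequence[float]) -> float:
    v = np.asarray(values, dtype=float)
    if (v <= 0).any():
        raise ValueError("geometric mean requires strictly positive values")
    return float(np.exp(np.mean(np.log(v))))


def group_fold_change(
    expressions: Sequence[float],
    group_labels: Sequence[str],
    group_a: str,
    group_b: str,
) -> float:
    """Fold change group_a / group_b as a ratio of geometric means."""
    expr = np.asarray(expressions, dtype=float)
    labels = np.asarray(group_labels)
    a = expr[labels == group_a]
    b = expr[labels == group_b]
    if len(a) == 0 or len(b) == 0:
        raise ValueError(f"empty group(s): {group_a}={len(a)}, {group_b}={len(b)}")
    return stats_gmean(a) / stats_gmean(b)


def _design(covariate_table: pd.DataFrame, subset: Sequence[str]) -> np.ndarray:
    n = len(covariate_table)
    blocks = [np.ones((n, 1))]
    for cov in subset:
        col = covariate_table[cov]
        if pd.api.types.is_numeric_dtype(col):
            blocks.append(col.to_numpy(dtype=float).reshape(-1, 1))
        else:
            dummies = pd.get_dummies(col.astype(str), prefix=cov, drop_first=True)
            blocks.append(dummies.to_numpy(dtype=float))
    return np.hstack(blocks)


def _design_names(covariate_table: pd.DataFrame, subset: Sequence[str]) -> list[str]:
    names = ["intercept"]
    for cov in subset:
        col = covariate_table[cov]
        if pd.api.types.is_numeric_dtype(col):
            names.append(cov)
        else:
            dummies = pd.get_dummies(col.astype(str), prefix=cov, drop_first=True)
            names.extend(dummies.columns)
    return names


def bma_inclusion(
    log_expressions: Sequence[float],
    covariate_table: pd.DataFrame,
    candidate_covariates: Sequence[str],
) -> BmaSummary:
    """Per-covariate inclusion probabilities by exhaustive BIC-weight BMA.

    Fits all 2^K covariate subsets by OLS on the (log2) response with
    BIC = n ln(RSS/n) + k ln(n); model weights are proportional to
    exp(-BIC/2). Rank-deficient designs are skipped with a warning and the
    remaining weights renormalized.
    """
    y = np.asarray(log_expressions, dtype=float)
    n = len(y)
    candidates = list(candidate_covariates)
    if len(covariate_table) != n:
        raise ValueError("covariate table and response length differ")
    full_p = _design(covariate_table, candidates).shape[1]
    if n <= full_p:
        raise ValueError(
            f"full model not identifiable: n={n} <= {full_p} parameters"
        )
    models: list[BmaModel] = []
    coef_store: list[dict[str, float]] = []
    for size in range(len(candidates) + 1):
        for subset in itertools.combinations(candidates, size):
            X = _design(covariate_table, subset)
            if np.linalg.matrix_rank(X) < X.shape[1]:
                logger.warning("BMA: rank-deficient design for %s skipped", subset)
                continue
            beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
            resid = y - X @ beta
            rss = max(float(resid @ resid), 1e-300)
            k = X.shape[1]
            bic = n * math.log(rss / n) + k * math.log(n)
            models.append(BmaModel(subset, rss, k, bic, weight=0.0))
            coef_store.append(dict(zip(_design_names(covariate_table, subset), beta)))
    if not models:
        raise ValueError("no estimable model in the BMA enumeration")
    bics = np.array([m.bic for m in models])
    w = np.exp(-(bics - bics.min()) / 2)
    w /= w.sum()
    for m, wi in zip(models, w):
        m.weight = float(wi)
    inclusion = {
        c: 100 * float(sum(m.weight for m in models if c in m.covariates))
        for c in candidates
    }
    all_terms = _design_names(covariate_table, candidates)
    coefficients = {
        t: float(sum(m.weight * cs.get(t, 0.0) for m, cs in zip(models, coef_store)))
        for t in all_terms
    }
    return BmaSummary(inclusion, coefficients, models, n)


def qpcr_gene_analysis(
    table: pd.DataFrame,
    candidate_covariates: Sequence[str],
    fold_groups: tuple[str, str, str] | None = None,
) -> dict[str, dict]:
    """Per-gene BMA summary (and optional fold change) from a Ct table.

    ``fold_groups`` is (covariate, group_a, group_b) for a geometric-mean
    fold change of group_a over group_b.
    """
    out = {}
    for gene, grp in table.groupby("gene", sort=False):
        summary = bma_inclusion(
            np.log2(grp["expression"].to_numpy()),
            grp[list(candidate_covariates)].reset_index(drop=True),
            candidate_covariates,
        )
        entry: dict = {"bma": summary}
        if fold_groups is not None:
            cov, ga, gb = fold_groups
            entry["fold_change"] = group_fold_change(
                grp["expression"], grp[cov], ga, gb
            )
        out[gene] = entry
    return out
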