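"""Regulator impact scoring across two conditions.

For regulator i and differentially expressed gene j, with within-condition
Pearson correlations r_ij1 and r_ij2, per-condition means e_j1 and e_j2,
average abundance a_j = (e_j1 + e_j2) / 2 and d_j = log2 fold-change:

    score1_i = (1/n_de) * sum_j a_j * d_j * (r_ij1 - r_ij2)^2
    score2_i = (1/n_de) * sum_j (e_j1 * r_ij1)^2 - (e_j2 * r_ij2)^2

Raw scores are z-standardized across regulators; a regulator is flagged
significant when either |z| >= 1.96.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, ValidationError
from .expression import ExpressionMatrix

logger = logging.getLogger(__name__)

DEFAULT_Z_CUT = 1.96


@dataclass
class RIFResult:
    """Scores per regulator plus the per-condition correlation matrices
    retained for audit (regulators x DE genes)."""

    table: pd.DataFrame  # index tf; rif1_raw, rif2_raw, rif1_z, rif2_z, significant
    corr_cond1: pd.DataFrame
    corr_cond2: pd.DataFrame
    n_de: int
    degenerate: bool = False  # all raw scores equal -> z undefined


def _rowwise_corr(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson correlation between every row of x and every row of y
    (observations in columns).  Zero-variance rows yield correlation 0."""
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    xs = np.sqrt((xc**2).sum(axis=1))
    ys = np.sqrt((yc**2).sum(axis=1))
    bad_x = xs == 0
    bad_y = ys == 0
    if bad_x.any() or bad_y.any():
        logger.warning(
            "%d zero-variance series; their correlations are set to 0",
            int(bad_x.sum() + bad_y.sum()),
        )
    xs[bad_x] = 1.0
    ys[bad_y] = 1.0
    r = (xc @ yc.T) / np.outer(xs, ys)
    r[bad_x, :] = 0.0
    r[:, bad_y] = 0.0
    return np.clip(r, -1.0, 1.0)


def compute_rif(
    matrix: ExpressionMatrix,
    tfs: list[str],
    de_table: pd.DataFrame,
    z_cut: float = DEFAULT_Z_CUT,
) -> RIFResult:
    """Score every regulator in ``tfs`` against the DE genes of ``de_table``.

    ``matrix`` must be log2-normalized with >=3 samples per condition; the
    regulator and DE gene sets must be disjoint and the DE set nonempty.
    """
    if matrix.kind != "log2":
        raise ValidationError("compute_rif expects log2-normalized values")
    matrix.require_min_replication(3)
    de_genes = [g for g in de_table.index if de_table.loc[g, "is_de"]]
    if not de_genes:
        raise DegenerateInputError("DE gene set is empty; nothing to score against")
    overlap = set(tfs) & set(de_genes)
    if overlap:
        raise ValidationError(f"regulator and DE sets must be disjoint: {sorted(overlap)}")
    missing = [g for g in list(tfs) + de_genes if g not in matrix.genes]
    if missing:
        raise ValidationError(f"genes absent from matrix: {missing[:5]}")

    s1 = matrix.samples_in_condition(1)
    s2 = matrix.samples_in_condition(2)
    tf_vals1 = matrix.values.loc[tfs, s1].values
    tf_vals2 = matrix.values.loc[tfs, s2].values
    de_vals1 = matrix.values.loc[de_genes, s1].values
    de_vals2 = matrix.values.loc[de_genes, s2].values

    r1 = _rowwise_corr(tf_vals1, de_vals1)
    r2 = _rowwise_corr(tf_vals2, de_vals2)

    e1 = de_table.loc[de_genes, "mean_1"].values.astype(float)
    e2 = de_table.loc[de_genes, "mean_2"].values.astype(float)
    a = 0.5 * (e1 + e2)
    d = de_table.loc[de_genes, "log2fc"].values.astype(float)

    n_de = len(de_genes)
    rif1 = (a * d * (r1 - r2) ** 2).sum(axis=1) / n_de
    rif2 = ((e1 * r1) ** 2 - (e2 * r2) ** 2).sum(axis=1) / n_de

    def zscore(v: np.ndarray) -> tuple[np.ndarray, bool]:
        sd = v.std(ddof=1) if len(v) > 1 else 0.0
        if sd == 0:
            return np.full_like(v, np.nan, dtype=float), True
        return (v - v.mean()) / sd, False

    z1, deg1 = zscore(rif1)
    z2, deg2 = zscore(rif2)
    degenerate = deg1 and deg2
    if degenerate:
        logger.warning("all raw scores identical; z-scores undefined")
    with np.errstate(invalid="ignore"):
        significant = (np.abs(z1) >= z_cut) | (np.abs(z2) >= z_cut)
    significant[np.isnan(z1) & np.isnan(z2)] = False

    table = pd.DataFrame(
        {
            "rif1_raw": rif1,
            "rif2_raw": rif2,
            "rif1_z": z1,
            "rif2_z": z2,
            "significant": significant,
        },
        index=pd.Index(tfs, name="tf"),
    )
    return RIFResult(
        table=table,
        corr_cond1=pd.DataFrame(r1, index=tfs, columns=de_genes),
        corr_cond2=pd.DataFrame(r2, index=tfs, columns=de_genes),
        n_de=n_de,
        degenerate=degenerate,
    )


def significant_regulators(result: RIFResult, z_cut: float = DEFAULT_Z_CUT) -> list[str]:
    """Regulators with |z| >= z_cut on either metric, sorted by max |z|
    descending with a deterministic tie-break on gene id.  Returns an empty
    list (with a warning) when the score distribution is degenerate."""
    if result.degenerate:
        logger.warning("degenerate score distribution; no significant regulators")
        return []
    t = result.table
    with np.errstate(invalid="ignore"):
        max_abs_z = np.nanmax(
            np.abs(t[["rif1_z", "rif2_z"]].values), axis=1
        )
    hits = [
        (z, tf)
        for tf, z in zip(t.index, max_abs_z)
        if not np.isnan(z) and z >= z_cut
    ]
    hits.sort(key=lambda pair: (-pair[0], pair[1]))
    return [tf for _, tf in hits]
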