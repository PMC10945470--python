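"""Expression-matrix container, normalization, differential expression and
pathway summaries.

The differential-expression caller here is a deliberate stand-in for an
external negative-binomial tool: per-gene Welch t-tests on log-normalized
counts with Benjamini-Hochberg adjustment.  It shares the significance
semantics (adjusted p < 0.05 and |log2 fold-change| >= 0.5) and its table
schema accepts externally computed results.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateInputError, ValidationError

logger = logging.getLogger(__name__)

DEFAULT_PADJ_CUT = 0.05
DEFAULT_LFC_CUT = 0.5

#: genes with any zero count have an (effectively) zero geometric mean and
#: are excluded from the median-of-ratios reference
_GEOMEAN_EPS = 0.0


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix with per-sample condition labels.

    Parameters
    ----------
    values : pandas.DataFrame
        Genes as rows, samples as columns.  Nonnegative counts when
        ``kind == "counts"``, log2-normalized values when ``kind == "log2"``.
    condition : pandas.Series
        Sample -> condition label in {1, 2}.
    is_tf : pandas.Series, optional
        Gene -> bool flag marking transcription factors.
    pathways : dict, optional
        Gene -> set of pathway ids.
    kind : str
        ``"counts"`` or ``"log2"``.
    size_factors : pandas.Series, optional
        Per-sample size factors recorded by :func:`normalize_counts`.
    """

    values: pd.DataFrame
    condition: pd.Series
    is_tf: pd.Series | None = None
    pathways: dict[str, set[str]] = field(default_factory=dict)
    kind: str = "counts"
    size_factors: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("counts", "log2"):
            raise ValidationError(f"unknown matrix kind {self.kind!r}")
        if (self.values.values < 0).any():
            raise ValidationError("expression values must be nonnegative")
        missing = [s for s in self.values.columns if s not in self.condition.index]
        if missing:
            raise ValidationError(f"samples without a condition label: {missing}")
        conds = set(self.condition.loc[self.values.columns])
        if not conds <= {1, 2}:
            raise ValidationError(f"condition labels must be 1 or 2, got {sorted(conds)}")
        if self.is_tf is None:
            self.is_tf = pd.Series(False, index=self.values.index)

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def samples_in_condition(self, cond: int) -> list[str]:
        labels = self.condition.loc[self.values.columns]
        return [s for s in self.values.columns if labels[s] == cond]

    def require_min_replication(self, n: int = 3) -> None:
        for cond in (1, 2):
            k = len(self.samples_in_condition(cond))
            if k < n:
                raise ValidationError(
                    f"condition {cond} has {k} samples; at least {n} required"
                )


def size_factors_median_of_ratios(counts: pd.DataFrame) -> tuple[pd.Series, bool]:
    """Median-of-ratios size factors.

    For each sample, the factor is the median over reference genes (those
    with a strictly positive count in every sample, hence nonzero geometric
    mean) of count / gene geometric mean.  Returns ``(factors, fallback)``
    where ``fallback`` is True when no reference gene exists and
    total-count scaling was used instead.
    """
    vals = counts.values.astype(float)
    all_positive = (vals > _GEOMEAN_EPS).all(axis=1)
    if all_positive.any():
        ref = vals[all_positive]
        log_geomean = np.log(ref).mean(axis=1)
        ratios = np.exp(np.log(ref) - log_geomean[:, None])
        factors = np.median(ratios, axis=0)
        return pd.Series(factors, index=counts.columns, name="size_factor"), False
    logger.warning(
        "every gene contains a zero count; falling back to total-count scaling"
    )
    totals = vals.sum(axis=0)
    if (totals <= 0).any():
        raise DegenerateInputError("sample with zero total count cannot be normalized")
    factors = totals / np.exp(np.mean(np.log(totals)))
    return pd.Series(factors, index=counts.columns, name="size_factor"), True


def normalize_counts(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Median-of-ratios normalization followed by log2(x + 1) transform."""
    if matrix.kind != "counts":
        raise ValidationError("normalize_counts expects a raw count matrix")
    factors, _ = size_factors_median_of_ratios(matrix.values)
    scaled = matrix.values.astype(float).div(factors, axis=1)
    logged = np.log2(scaled + 1.0)
    return replace(matrix, values=logged, kind="log2", size_factors=factors)


def differential_expression(
    matrix: ExpressionMatrix,
    padj_cut: float = DEFAULT_PADJ_CUT,
    lfc_cut: float = DEFAULT_LFC_CUT,
) -> pd.DataFrame:
    """Per-gene Welch two-sample t-test with Benjamini-Hochberg adjustment.

    Operates on log2-normalized values; ``log2fc`` is mean(condition 2) -
    mean(condition 1).  A gene is flagged ``is_de`` when
    ``p_adjusted < padj_cut`` and ``|log2fc| >= lfc_cut`` (inclusive).

    Returns a DataFrame indexed by gene with columns
    ``mean_1, mean_2, log2fc, p_value, p_adjusted, is_de, degenerate``.
    """
    if matrix.kind != "log2":
        raise ValidationError("differential_expression expects log2-normalized values")
    s1 = matrix.samples_in_condition(1)
    s2 = matrix.samples_in_condition(2)
    if len(s1) < 2 or len(s2) < 2:
        raise ValidationError("need >=2 samples per condition for a t-test")
    a = matrix.values[s1].values
    b = matrix.values[s2].values
    mean1 = a.mean(axis=1)
    mean2 = b.mean(axis=1)
    log2fc = mean2 - mean1

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        _, pvals = stats.ttest_ind(b, a, axis=1, equal_var=False)

    # zero within-group variance in both groups: equal means -> p = 1,
    # unequal means -> smallest positive float, flagged degenerate
    degenerate = np.zeros(len(pvals), dtype=bool)
    zero_var = (a.var(axis=1) == 0) & (b.var(axis=1) == 0)
    equal = np.isclose(mean1, mean2)
    pvals = np.asarray(pvals, dtype=float)
    pvals[zero_var & equal] = 1.0
    tiny = np.nextafter(0.0, 1.0)
    pvals[zero_var & ~equal] = tiny
    degenerate[zero_var & ~equal] = True
    pvals[np.isnan(pvals)] = 1.0

    _, padj, _, _ = multipletests(pvals, method="fdr_bh")
    is_de = (padj < padj_cut) & (np.abs(log2fc) >= lfc_cut)
    return pd.DataFrame(
        {
            "mean_1": mean1,
            "mean_2": mean2,
            "log2fc": log2fc,
            "p_value": pvals,
            "p_adjusted": padj,
            "is_de": is_de,
            "degenerate": degenerate,
        },
        index=matrix.genes,
    )


def pathway_expression_ratio(
    de_table: pd.DataFrame, membership: dict[str, set[str]]
) -> pd.DataFrame:
    """Per-pathway DE-gene fraction with a direction sign.

    ``membership`` maps gene -> set of pathway ids and must cover all
    annotated genome genes of each pathway (not only DE genes).  The ratio
    is (number of DE genes in the pathway) / (number of genome genes in the
    pathway); the sign is the sign of the summed log2 fold-changes of the
    pathway's DE genes (0 when the pathway has none, or when they cancel).
    """
    pathways: dict[str, list[str]] = {}
    for gene, pws in membership.items():
        for pw in pws:
            pathways.setdefault(pw, []).append(gene)

    rows = []
    de_genes = set(de_table.index[de_table["is_de"]])
    for pw in sorted(pathways):
        genes = pathways[pw]
        if not genes:
            logger.warning("pathway %s has no genome genes; excluded", pw)
            continue
        de_members = [g for g in genes if g in de_genes]
        lfc_sum = float(de_table.loc[de_members, "log2fc"].sum()) if de_members else 0.0
        rows.append(
            {
                "pathway": pw,
                "n_de": len(de_members),
                "n_genome": len(genes),
                "expression_ratio": len(de_members) / len(genes),
                "direction_sign": int(np.sign(lfc_sum)),
            }
        )
    return pd.DataFrame(
        rows, columns=["pathway", "n_de", "n_genome", "expression_ratio", "direction_sign"]
    )
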