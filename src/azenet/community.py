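"""Amplicon community statistics: alpha diversity, Bray-Curtis/PCoA,
PERMANOVA, rank-sum tests, a differential-abundance stand-in and per-taxon
proportion summaries.

No rarefaction is applied anywhere; proportions are computed on raw counts.
The differential-abundance caller mirrors the expression stand-in (size
factors, Welch t on log-normalized counts, Benjamini-Hochberg).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests
from sympy.utilities.iterables import multiset_permutations

from .errors import DegenerateInputError, ValidationError
from .expression import size_factors_median_of_ratios

logger = logging.getLogger(__name__)


@dataclass
class ASVTable:
    """ASV x sample integer counts with taxonomy strings and group labels.

    ``taxonomy`` is indexed by ASV id with columns ``family`` and ``genus``
    (missing ASVs are treated as "unclassified"); ``group`` maps sample ->
    arbitrary label.
    """

    counts: pd.DataFrame
    taxonomy: pd.DataFrame
    group: pd.Series

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValidationError("ASV counts must be nonnegative")
        missing = [s for s in self.counts.columns if s not in self.group.index]
        if missing:
            raise ValidationError(f"samples without a group label: {missing}")
        absent = self.counts.index.difference(self.taxonomy.index)
        if len(absent):
            filler = pd.DataFrame(
                {"family": "unclassified", "genus": "unclassified"}, index=absent
            )
            self.taxonomy = pd.concat([self.taxonomy, filler])

    def samples_in_group(self, label: str) -> list[str]:
        g = self.group.loc[self.counts.columns]
        return [s for s in self.counts.columns if g[s] == label]


# ---------------------------------------------------------------------------
# alpha diversity


def alpha_diversity(
    counts: pd.DataFrame, shannon_base: float = np.e, simpson_variant: str = "gini"
) -> pd.DataFrame:
    """Per-sample observed richness, bias-corrected Chao1, Shannon and
    Simpson indices.

    chao1 = S_obs + F1*(F1-1) / (2*(F2+1)) with F1/F2 the singleton and
    doubleton counts; shannon = -sum p*log(p) (natural log by default);
    simpson defaults to the Gini-Simpson form 1 - sum p^2
    (``simpson_variant="inverse"`` gives 1 / sum p^2).
    """
    rows = []
    for sample in counts.columns:
        c = counts[sample].values.astype(float)
        total = c.sum()
        if total <= 0:
            raise DegenerateInputError(f"sample {sample!r} has no reads")
        nz = c[c > 0]
        p = nz / total
        f1 = int((nz == 1).sum())
        f2 = int((nz == 2).sum())
        chao1 = len(nz) + f1 * (f1 - 1) / (2.0 * (f2 + 1))
        shannon = float(-(p * np.log(p)).sum() / np.log(shannon_base))
        d = float((p**2).sum())
        simpson = 1.0 - d if simpson_variant == "gini" else 1.0 / d
        rows.append(
            {
                "sample": sample,
                "observed": int(len(nz)),
                "chao1": chao1,
                "shannon": shannon,
                "simpson": simpson,
            }
        )
    return pd.DataFrame(rows).set_index("sample")


# ---------------------------------------------------------------------------
# beta diversity


def bray_curtis(counts: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity between samples (columns):
    BC(a, b) = 1 - 2 * sum(min(a_i, b_i)) / (sum(a) + sum(b))."""
    if counts.shape[1] < 2:
        raise ValidationError("need at least 2 samples")
    vals = counts.values.astype(float)
    totals = vals.sum(axis=0)
    if (totals <= 0).any():
        raise DegenerateInputError("zero-total sample; distance undefined")
    n = vals.shape[1]
    d = np.zeros((n, n))
    for i in range(n):
        mins = np.minimum(vals[:, i][:, None], vals[:, i + 1 :]).sum(axis=0)
        d[i, i + 1 :] = 1.0 - 2.0 * mins / (totals[i] + totals[i + 1 :])
    d = d + d.T
    return pd.DataFrame(d, index=counts.columns, columns=counts.columns)


@dataclass
class PCoAResult:
    coordinates: pd.DataFrame  # samples x axes
    eigenvalues: np.ndarray  # positive eigenvalues, descending
    proportion_explained: np.ndarray  # relative to the positive spectrum
    negative_eigenvalue_mass: float  # |sum of dropped negative eigenvalues|


def pcoa(dist: pd.DataFrame) -> PCoAResult:
    """Classical principal-coordinate analysis (metric MDS).

    Eigendecomposition of the double-centered -D^2/2 matrix; negative
    eigenvalues are dropped from both the coordinates and the
    variance-explained denominator (their mass is recorded).
    """
    d = np.asarray(dist, dtype=float)
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = max(abs(evals[0]), 1.0) * 1e-10
    pos = evals > tol
    neg_mass = float(abs(evals[evals < -tol].sum()))
    lam = evals[pos]
    coords = evecs[:, pos] * np.sqrt(lam)
    axes = [f"PCoA{i + 1}" for i in range(coords.shape[1])]
    return PCoAResult(
        coordinates=pd.DataFrame(coords, index=dist.index, columns=axes),
        eigenvalues=lam,
        proportion_explained=lam / lam.sum() if lam.size else lam,
        negative_eigenvalue_mass=neg_mass,
    )


# ---------------------------------------------------------------------------
# PERMANOVA


def _permanova_ss(d2: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in np.unique(labels):
        idx = np.flatnonzero(labels == g)
        if len(idx) > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    return ss_total, ss_within


def _pseudo_f(d2: np.ndarray, labels: np.ndarray, k: int) -> tuple[float, float]:
    n = d2.shape[0]
    ss_total, ss_within = _permanova_ss(d2, labels)
    ss_between = ss_total - ss_within
    if ss_within <= 0:
        return np.inf, 1.0 if ss_total > 0 else 0.0
    f = (ss_between / (k - 1)) / (ss_within / (n - k))
    r2 = ss_between / ss_total if ss_total > 0 else 0.0
    return f, r2


def permanova(
    dist: pd.DataFrame,
    groups: pd.Series,
    n_permutations: int | str = 999,
    seed: int | None = None,
) -> dict:
    """One-factor PERMANOVA (pseudo-F on a distance matrix).

    ``n_permutations`` is either an integer (seeded random label
    permutations; p = (1 + #{F_perm >= F_obs}) / (1 + n)) or ``"exact"``
    (enumerate every distinct labeling; p = #{F >= F_obs} / #labelings,
    the identity labeling included in the enumeration).
    """
    labels = np.asarray(groups.loc[dist.index])
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValidationError("need at least 2 groups")
    if (counts < 2).any():
        raise DegenerateInputError("every group needs at least 2 samples")
    d2 = np.asarray(dist, dtype=float) ** 2
    k = len(uniq)
    f_obs, r2 = _pseudo_f(d2, labels, k)

    if n_permutations == "exact":
        hits = 0
        total = 0
        for perm in multiset_permutations(list(labels)):
            f_p, _ = _pseudo_f(d2, np.asarray(perm), k)
            hits += f_p >= f_obs - 1e-12
            total += 1
        p = hits / total
        n_used = total
    else:
        rng = np.random.default_rng(seed)
        hits = 0
        lab = labels.copy()
        for _ in range(int(n_permutations)):
            rng.shuffle(lab)
            f_p, _ = _pseudo_f(d2, lab, k)
            hits += f_p >= f_obs - 1e-12
        p = (1 + hits) / (1 + int(n_permutations))
        n_used = int(n_permutations)
    return {
        "pseudo_F": float(f_obs),
        "R2": float(r2),
        "p_value": float(p),
        "n_permutations": n_used,
    }


# ---------------------------------------------------------------------------
# univariate tests


def wilcoxon_rank_sum(a, b) -> float:
    """Two-sided rank-sum p-value: exact when min(n) <= 10 and there are no
    ties, normal approximation with tie correction otherwise."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both samples must be nonempty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (min(a.size, b.size) <= 10 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.pvalue)


# ---------------------------------------------------------------------------
# differential abundance (stand-in caller)


def differential_abundance(
    table: ASVTable,
    group_pair: tuple[str, str],
    padj_cut: float = 0.05,
) -> pd.DataFrame:
    """Two-group differential-abundance stand-in.

    Size-factor normalization (median-of-ratios with total-count fallback),
    per-ASV Welch t on log2-normalized counts, BH adjustment.  ``log2fc``
    is group_pair[1] minus group_pair[0].  ASVs with zero counts in every
    selected sample are excluded.  ``significant`` marks padj < padj_cut;
    ``enriched`` additionally requires a positive log2fc.
    """
    ref, trt = group_pair
    s_ref = table.samples_in_group(ref)
    s_trt = table.samples_in_group(trt)
    if len(s_ref) < 2 or len(s_trt) < 2:
        raise DegenerateInputError("need >=2 samples in each group")
    sub = table.counts[s_ref + s_trt]
    sub = sub.loc[sub.sum(axis=1) > 0]
    factors, _ = size_factors_median_of_ratios(sub)
    logged = np.log2(sub.div(factors, axis=1) + 1.0)
    x = logged[s_ref].values
    y = logged[s_trt].values
    log2fc = y.mean(axis=1) - x.mean(axis=1)
    import warnings as _w

    with _w.catch_warnings():
        _w.simplefilter("ignore", RuntimeWarning)
        _, pvals = stats.ttest_ind(y, x, axis=1, equal_var=False)
    pvals = np.asarray(pvals, dtype=float)
    zero_var = (x.var(axis=1) == 0) & (y.var(axis=1) == 0)
    pvals[zero_var & np.isclose(log2fc, 0.0)] = 1.0
    pvals[zero_var & ~np.isclose(log2fc, 0.0)] = np.nextafter(0.0, 1.0)
    pvals[np.isnan(pvals)] = 1.0
    _, padj, _, _ = multipletests(pvals, method="fdr_bh")
    out = pd.DataFrame(
        {
            "log2fc": log2fc,
            "p_value": pvals,
            "p_adjusted": padj,
            "significant": padj < padj_cut,
        },
        index=sub.index,
    )
    out["enriched"] = out["significant"] & (out["log2fc"] > 0)
    return out


# ---------------------------------------------------------------------------
# taxon proportions


def mean_taxonomic_proportion(
    table: ASVTable, asv_set: list[str], level: str = "family"
) -> pd.Series:
    """Per-ASV share of its taxon's reads: (mean over samples of the ASV's
    reads) / (mean over samples of the summed reads of all ASVs with the
    same classification at ``level``).  Taxa with zero mean reads are
    reported as missing (NaN)."""
    if level not in table.taxonomy.columns:
        raise ValidationError(f"unknown taxonomy level {level!r}")
    asv_means = table.counts.mean(axis=1)
    taxon_of = table.taxonomy[level]
    taxon_means = asv_means.groupby(taxon_of).sum()
    out = {}
    for asv in asv_set:
        if asv not in table.counts.index:
            raise ValidationError(f"ASV {asv!r} not in table")
        taxon = taxon_of.loc[asv]
        denom = taxon_means.loc[taxon]
        if denom <= 0:
            logger.warning("taxon %s has zero mean reads; proportion undefined", taxon)
            out[asv] = np.nan
        else:
            out[asv] = asv_means.loc[asv] / denom
    return pd.Series(out, name="mean_taxonomic_proportion")
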