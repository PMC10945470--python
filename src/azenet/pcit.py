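"""Partial-correlation-and-information-theory (PCIT) edge pruning and
coexpression-network construction.

For every ordered triple of genes (x, y, z) the first-order partial
correlations are computed and a triad tolerance

    eps = mean of |partial / direct| over the three pairs

is formed, skipping ratio terms whose direct correlation is (numerically)
zero or whose partial correlation is undefined.  The edge (x, y) is
eliminated when some conditioning gene z satisfies

    |r_xy| < eps * |r_xz|  and  |r_xy| < eps * |r_yz|.

Edges never eliminated by any triad are flagged significant.  A brute-force
triple-loop oracle (:func:`pcit_edges_bruteforce`) is provided alongside the
vectorized implementation; both use identical skip rules.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd

from .errors import DegenerateInputError, ValidationError

DEFAULT_R_CUT = 0.95

#: direct correlations below this magnitude are excluded from the
#: tolerance mean (their partial/direct ratio would blow up)
ZERO_DENOM_TOL = 1e-12


@dataclass
class TriadRecord:
    """Audit record for one gene triple."""

    x: int
    y: int
    z: int
    r_xy: float
    r_xz: float
    r_yz: float
    r_xy_z: float
    r_xz_y: float
    r_yz_x: float
    eps: float


def partial_correlation(r_xy: float, r_xz: float, r_yz: float) -> float:
    """First-order partial correlation of (x, y) conditioning on z:
    (r_xy - r_xz * r_yz) / sqrt((1 - r_xz^2) (1 - r_yz^2))."""
    for r in (r_xy, r_xz, r_yz):
        if not -1.0 <= r <= 1.0:
            raise ValidationError(f"correlation {r} outside [-1, 1]")
    denom_sq = (1.0 - r_xz**2) * (1.0 - r_yz**2)
    if denom_sq <= 0.0:
        raise DegenerateInputError(
            "partial correlation undefined: conditioning correlation is +/-1"
        )
    return (r_xy - r_xz * r_yz) / np.sqrt(denom_sq)


def _check_corr(corr: np.ndarray) -> np.ndarray:
    corr = np.asarray(corr, dtype=float)
    if corr.ndim != 2 or corr.shape[0] != corr.shape[1]:
        raise ValidationError("correlation matrix must be square")
    if not np.allclose(corr, corr.T, atol=1e-10):
        raise ValidationError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(corr), 1.0, atol=1e-8):
        raise ValidationError("correlation matrix must have unit diagonal")
    if corr.shape[0] < 2:
        raise ValidationError("need at least 2 genes")
    return corr


def pcit_significance(corr: np.ndarray) -> np.ndarray:
    """Boolean matrix of PCIT-significant pairs (vectorized).

    O(n^3) time via an O(n) loop of O(n^2) array operations; O(n^2) memory.
    """
    corr = _check_corr(corr)
    n = corr.shape[0]
    A = np.abs(corr)
    eliminated = np.zeros((n, n), dtype=bool)
    if n < 3:
        return ~eliminated & ~np.eye(n, dtype=bool)

    idx = np.arange(n)
    with np.errstate(divide="ignore", invalid="ignore"):
        one_minus_sq = 1.0 - corr**2
        for z in range(n):
            cz = corr[:, z]
            # ratio |partial/direct| for pair (x, y) given z
            dz = one_minus_sq[:, z]
            denom = np.sqrt(np.outer(dz, dz))
            p_z = (corr - np.outer(cz, cz)) / denom
            q1 = np.abs(p_z) / A
            q1[(A < ZERO_DENOM_TOL) | ~np.isfinite(q1)] = np.nan

            # m[x, w] = ratio for pair (x, z) given w; its transpose gives
            # the ratio for pair (y, z) given x
            num = np.abs(cz[:, None] - corr * cz[None, :])
            den = np.sqrt(one_minus_sq * dz[None, :]) * A[:, z][:, None]
            m = num / den
            m[(A[:, z][:, None] < ZERO_DENOM_TOL) | ~np.isfinite(m)] = np.nan

            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                eps = np.nanmean(np.stack([q1, m, m.T]), axis=0)
            cond = (A < eps * A[:, z][:, None]) & (A < eps * A[:, z][None, :])
            cond[z, :] = False
            cond[:, z] = False
            cond[idx, idx] = False
            eliminated |= cond

    significant = ~eliminated
    significant[idx, idx] = False
    return significant


def pcit_edges(
    corr: np.ndarray, gene_ids: list[str] | None = None
) -> pd.DataFrame:
    """Edge table for all gene pairs with PCIT significance flags.

    Columns: ``gene_x, gene_y, r, significant`` (one row per unordered
    pair, x-index < y-index).
    """
    corr = _check_corr(corr)
    sig = pcit_significance(corr)
    n = corr.shape[0]
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(n)]
    if len(gene_ids) != n:
        raise ValidationError("gene_ids length must match matrix size")
    iu, ju = np.triu_indices(n, k=1)
    return pd.DataFrame(
        {
            "gene_x": [gene_ids[i] for i in iu],
            "gene_y": [gene_ids[j] for j in ju],
            "r": corr[iu, ju],
            "significant": sig[iu, ju],
        }
    )


def pcit_edges_bruteforce(
    corr: np.ndarray, collect_triads: bool = False
) -> tuple[np.ndarray, list[TriadRecord]]:
    """Reference triple-loop implementation of the elimination rule.

    Returns the boolean significance matrix and, optionally, the full triad
    audit trail.  Kept deliberately naive as the oracle for the vectorized
    path.
    """
    corr = _check_corr(corr)
    n = corr.shape[0]
    eliminated = np.zeros((n, n), dtype=bool)
    records: list[TriadRecord] = []

    def partial(r_ab: float, r_ac: float, r_bc: float) -> float:
        """Partial of (a, b) given c; NaN when the conditioner is +/-1."""
        denom_sq = (1.0 - r_ac**2) * (1.0 - r_bc**2)
        if denom_sq <= 0.0:
            return np.nan
        return (r_ab - r_ac * r_bc) / np.sqrt(denom_sq)

    def ratio(p_ab: float, r_ab: float) -> float:
        """|partial/direct|; NaN when the direct correlation is ~0 or the
        partial is undefined."""
        if abs(r_ab) < ZERO_DENOM_TOL or np.isnan(p_ab):
            return np.nan
        return abs(p_ab / r_ab)

    for x, y, z in combinations(range(n), 3):
        r_xy, r_xz, r_yz = corr[x, y], corr[x, z], corr[y, z]
        p_xy_z = partial(r_xy, r_xz, r_yz)
        p_xz_y = partial(r_xz, r_xy, r_yz)
        p_yz_x = partial(r_yz, r_xy, r_xz)
        terms = [
            t
            for t in (ratio(p_xy_z, r_xy), ratio(p_xz_y, r_xz), ratio(p_yz_x, r_yz))
            if not np.isnan(t)
        ]
        eps = float(np.mean(terms)) if terms else np.nan
        if collect_triads:
            records.append(
                TriadRecord(
                    x, y, z, r_xy, r_xz, r_yz,
                    r_xy_z=p_xy_z, r_xz_y=p_xz_y, r_yz_x=p_yz_x, eps=eps,
                )
            )
        if np.isnan(eps):
            continue
        for (a, b, c) in ((x, y, z), (x, z, y), (y, z, x)):
            if abs(corr[a, b]) < eps * abs(corr[a, c]) and abs(corr[a, b]) < eps * abs(
                corr[b, c]
            ):
                eliminated[a, b] = eliminated[b, a] = True

    significant = ~eliminated
    np.fill_diagonal(significant, False)
    return significant, records


def triad_tolerance(r_xy: float, r_xz: float, r_yz: float) -> float:
    """Tolerance eps for one triad: mean of the defined |partial/direct|
    ratios over its three pairs."""
    terms = []
    for r_ab, r_ac, r_bc in (
        (r_xy, r_xz, r_yz),
        (r_xz, r_xy, r_yz),
        (r_yz, r_xy, r_xz),
    ):
        if abs(r_ab) < ZERO_DENOM_TOL:
            continue
        denom_sq = (1.0 - r_ac**2) * (1.0 - r_bc**2)
        if denom_sq <= 0.0:
            continue
        p = (r_ab - r_ac * r_bc) / np.sqrt(denom_sq)
        terms.append(abs(p / r_ab))
    if not terms:
        return np.nan
    return float(np.mean(terms))


def filter_edges(edges: pd.DataFrame, r_cut: float = DEFAULT_R_CUT) -> pd.DataFrame:
    """Keep PCIT-significant edges with |r| >= r_cut (inclusive)."""
    keep = edges["significant"] & (edges["r"].abs() >= r_cut)
    return edges.loc[keep].reset_index(drop=True)


def build_network(nodes: pd.DataFrame, edges: pd.DataFrame) -> nx.Graph:
    """Simple undirected graph from a node table (index = gene id, optional
    columns ``kind, mean_expr_treated, log2fc``) and a retained edge table.

    Self-edges are rejected; duplicate pairs collapse to one edge.
    """
    g = nx.Graph()
    for gene, row in nodes.iterrows():
        g.add_node(gene, **{k: row[k] for k in nodes.columns})
    for _, row in edges.iterrows():
        a, b = row["gene_x"], row["gene_y"]
        if a == b:
            raise ValidationError(f"self-edge on {a!r}")
        if a not in g or b not in g:
            raise ValidationError(f"edge endpoint not in node table: {a!r}-{b!r}")
        g.add_edge(a, b, r=float(row["r"]), sign=int(np.sign(row["r"])))
    return g


def degree_centrality(net: nx.Graph) -> dict[str, int]:
    """Plain connection counts per node."""
    return dict(net.degree())


def extract_hub_subnetwork(net: nx.Graph, hub: str) -> nx.Graph:
    """Induced subgraph on a hub and its first neighbors."""
    if hub not in net:
        raise ValidationError(f"hub {hub!r} not found in network")
    members = {hub} | set(net.neighbors(hub))
    # explicit rebuild in parent-graph node order keeps output deterministic
    # (subgraph views iterate in the order of the node set passed in)
    sub = nx.Graph()
    for n in net.nodes:
        if n in members:
            sub.add_node(n, **net.nodes[n])
    for a, b, data in net.edges(data=True):
        if a in members and b in members:
            sub.add_edge(a, b, **data)
    return sub


def rank_hubs(
    net: nx.Graph,
    rif_significant: set[str] | None = None,
    de_significant: set[str] | None = None,
) -> list[str]:
    """Nodes ranked by (regulator-impact significance, DE significance,
    degree), descending, with a deterministic tie-break on gene id."""
    rif_significant = rif_significant or set()
    de_significant = de_significant or set()
    deg = degree_centrality(net)
    return sorted(
        net.nodes,
        key=lambda n: (
            -(n in rif_significant),
            -(n in de_significant),
            -deg[n],
            str(n),
        ),
    )


def write_sif(net: nx.Graph, path: str) -> None:
    """Cytoscape SIF export: positive/negative correlation relation types;
    isolated nodes emitted as bare entries."""
    with open(path, "w", encoding="utf-8") as fh:
        seen = set()
        for a, b, data in sorted(net.edges(data=True)):
            rel = "pos" if data.get("sign", 1) >= 0 else "neg"
            fh.write(f"{a}\t{rel}\t{b}\n")
            seen.update((a, b))
        for n in sorted(net.nodes):
            if n not in seen:
                fh.write(f"{n}\n")


def write_edge_tsv(net: nx.Graph, path: str) -> None:
    rows = [
        {"gene_x": a, "gene_y": b, "r": d.get("r", np.nan), "sign": d.get("sign", 0)}
        for a, b, d in sorted(net.edges(data=True))
    ]
    pd.DataFrame(rows, columns=["gene_x", "gene_y", "r", "sign"]).to_csv(
        path, sep="\t", index=False
    )


def write_graphml(net: nx.Graph, path: str) -> None:
    g = net.copy()
    deg = degree_centrality(g)
    for n in g.nodes:
        g.nodes[n]["degree"] = deg[n]
        for k, v in list(g.nodes[n].items()):
            if isinstance(v, (np.floating, np.integer)):
                g.nodes[n][k] = v.item()
    nx.write_graphml(g, path)
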