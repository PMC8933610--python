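"""Admixture-graph inference from drift covariance and per-edge polygenic
selection estimation.

The drift covariance W_ij averages, over loci, the product of the two
populations' standardized deviations from the across-population mean
frequency.  A population tree is fit by neighbor joining on the induced
distances d_ij = W_ii + W_jj - 2 W_ij with branch lengths refit by
nonnegative least squares; optional admixture edges are placed greedily on
covariance residuals.

Per-edge selection: leaf polygenic scores Z_i = 2 sum_j beta_j q_ij over a
trait's significant loci evolve, under neutral drift, approximately as a
Brownian motion on the tree with per-edge variance V_A * c_e, where
V_A = 4 sum_j beta_j^2 qbar_j (1 - qbar_j) is the additive variance at the
pooled mean frequencies.  Ancestral node scores are reconstructed by
generalized least squares under that model; each tree edge's score change is
then standardized into a selection parameter alpha whose null distribution is
standard normal: alpha_e divides the reconstructed change by the exact
sampling standard deviation of that contrast under the Brownian null (a
quadratic form in the leaf covariance), so |alpha| measurably exceeding ~2
flags directional change beyond drift.  The unstandardized contrast
(z_child - z_parent)/sqrt(V_A c_e) is reported as ``raw`` and telescopes
along root-to-leaf paths.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
from scipy.optimize import nnls
from skbio import DistanceMatrix
from skbio.tree import nj

from .association import GwasResult
from .graph import AdmixtureGraph
from .io import AlleleFrequencyTable

logger = logging.getLogger(__name__)


@dataclass
class DriftCovariance:
    matrix: pd.DataFrame  # K x K symmetric
    n_loci: int


def drift_covariance(t: AlleleFrequencyTable) -> DriftCovariance:
    """Standardized allele-frequency covariance across populations.

    W_ij = mean_l (q_il - qbar_l)(q_jl - qbar_l) / (qbar_l (1 - qbar_l)) with
    qbar the unweighted across-population mean; loci fixed overall or with
    missing data are skipped.
    """
    Q = t.freq.to_numpy(float)
    ok = np.isfinite(Q).all(axis=0)
    Q = Q[:, ok]
    qbar = Q.mean(axis=0)
    keep = (qbar > 0) & (qbar < 1)
    Q = Q[:, keep]
    if Q.shape[1] == 0:
        raise ValueError("no usable loci for drift covariance")
    if Q.shape[1] < 50:
        logger.warning("only %d loci for drift covariance; estimates will be noisy", Q.shape[1])
    qbar = qbar[keep]
    Z = (Q - qbar) / np.sqrt(qbar * (1.0 - qbar))
    W = Z @ Z.T / Q.shape[1]
    pops = t.population_ids
    return DriftCovariance(pd.DataFrame(W, index=pops, columns=pops), Q.shape[1])


def _nnls_branch_lengths(
    leaves: list[str], edges: list[tuple[str, str]], paths: dict, d: pd.DataFrame
) -> np.ndarray:
    pairs = list(combinations(leaves, 2))
    A = np.zeros((len(pairs), len(edges)))
    b = np.zeros(len(pairs))
    eidx = {e: k for k, e in enumerate(edges)}
    for r, (u, v) in enumerate(pairs):
        for e in paths[(u, v)]:
            A[r, eidx[e]] = 1.0
        b[r] = d.loc[u, v]
    x, _ = nnls(A, b)
    return x


def fit_tree(w: DriftCovariance, root: str) -> AdmixtureGraph:
    """Neighbor-joining population tree from drift distances, branch lengths
    refit by nonnegative least squares, rooted at the attachment node of the
    stated root population.  Internal nodes are labeled a1, a2, ... in
    preorder."""
    W = w.matrix
    pops = list(W.index)
    if root not in pops:
        raise ValueError(f"root {root!r} is not a population id")
    diag = np.diag(W.to_numpy())
    D = diag[:, None] + diag[None, :] - 2.0 * W.to_numpy()
    np.fill_diagonal(D, 0.0)
    if not np.isfinite(D).all():
        raise ValueError("non-finite drift distances")
    D = np.maximum(D, 0.0)
    D = (D + D.T) / 2.0
    d = pd.DataFrame(D, index=pops, columns=pops)

    tree = nj(DistanceMatrix(D, ids=pops))  # unrooted, skbio TreeNode

    # undirected edge list with stable internal naming deferred until rooting
    g = nx.Graph()
    tmp_names: dict[int, str] = {}

    def name_of(node) -> str:
        if node.name:
            return node.name
        key = id(node)
        if key not in tmp_names:
            tmp_names[key] = f"__int{len(tmp_names) + 1}"
        return tmp_names[key]

    for node in tree.traverse():
        for child in node.children:
            g.add_edge(name_of(node), name_of(child))

    # collapse degree-2 internal nodes (skbio's arbitrary trifurcation root is
    # fine; a degree-2 node would distort path constraints)
    for n in [x for x in list(g.nodes) if g.degree(x) == 2 and x.startswith("__int")]:
        a, b = list(g.neighbors(n))
        g.remove_node(n)
        g.add_edge(a, b)

    # root at the neighbor (attachment) of the root population
    attach = next(iter(g.neighbors(root)))
    order = list(nx.dfs_preorder_nodes(g, attach))
    rename = {}
    k = 0
    for n in order:
        if n.startswith("__int") or n == attach:
            if n not in rename:
                k += 1
                rename[n] = f"a{k}"
    g = nx.relabel_nodes(g, rename)
    root_node = rename.get(attach, attach)

    directed = nx.bfs_tree(g, root_node)
    edges = list(directed.edges())

    # NNLS branch lengths against pairwise drift distances
    leaf_set = set(pops)
    paths: dict[tuple[str, str], list[tuple[str, str]]] = {}
    und_paths = dict(nx.all_pairs_shortest_path(g))
    canon = {frozenset(e): e for e in edges}
    for u, v in combinations(pops, 2):
        node_path = und_paths[u][v]
        paths[(u, v)] = [canon[frozenset((a, b))] for a, b in zip(node_path, node_path[1:])]
    lengths = _nnls_branch_lengths(pops, edges, paths, d)

    out = AdmixtureGraph(root=root_node)
    for (u, v), c in zip(edges, lengths):
        out.add_tree_edge(u, v, c)
    out.validate()
    if set(out.leaves()) != leaf_set:
        raise RuntimeError("tree leaves do not match populations")
    return out


def _expected_covariance(g: AdmixtureGraph) -> pd.DataFrame:
    """Graph-implied leaf covariance in drift units.

    Every tree edge contributes independent noise of variance c_e; a node's
    value is the weighted sum of the noises on its ancestry paths (an
    admixture target mixes its tree parent's lineage with weight 1-w and the
    source lineage with weight w).  For a plain tree this reduces to the
    shared root-to-MRCA path length.
    """
    adx = {v: (u, wt) for u, v, wt in g.admixture_edges()}
    tree_edges = [(u, v) for u, v, _ in g.tree_edges()]
    lengths = np.array([g.edge_length(u, v) for u, v in tree_edges])
    eidx = {e: k for k, e in enumerate(tree_edges)}
    coef: dict[str, np.ndarray] = {}
    for node in g.topological_nodes():
        p = g.tree_parent(node)
        if p is None:
            coef[node] = np.zeros(len(tree_edges))
            continue
        base = coef[p].copy()
        base[eidx[(p, node)]] = 1.0
        if node in adx:
            src, wt = adx[node]
            base = (1.0 - wt) * base + wt * coef[src]
        coef[node] = base
    leaves = g.leaves()
    B = np.vstack([coef[l] for l in leaves])
    C = (B * lengths) @ B.T
    return pd.DataFrame(C, index=leaves, columns=leaves)


def add_migration_edges(
    g: AdmixtureGraph, w: DriftCovariance, n_mig: int = 0
) -> AdmixtureGraph:
    """Greedily add up to ``n_mig`` admixture edges (source leaf clade ->
    target leaf) choosing, each round, the pair and least-squares weight that
    most reduces the residual sum of squares between the observed drift
    covariance and the graph-implied covariance."""
    if n_mig <= 0:
        return g
    g = g.copy()
    leaves = g.leaves()
    targets_used = {v for _, v, _ in g.admixture_edges()}

    def cen(M: np.ndarray) -> np.ndarray:
        # the observed covariance is centered on the across-population mean;
        # project the model the same way before comparing
        return M - M.mean(0, keepdims=True) - M.mean(1, keepdims=True) + M.mean()

    W = cen(w.matrix.loc[leaves, leaves].to_numpy())
    for _ in range(n_mig):
        C = _expected_covariance(g).loc[leaves, leaves]
        R = W - cen(C.to_numpy())
        base_ss = float((R**2).sum())
        best = None
        for src in leaves:
            for tgt in leaves:
                if src == tgt or tgt in targets_used:
                    continue
                # admixture of weight wt: target covariance row moves toward
                # the source's row (and the target variance toward W_ss)
                delta = (C.loc[src] - C.loc[tgt]).to_numpy()
                grad = np.zeros_like(R)
                ti = leaves.index(tgt)
                grad[ti, :] += delta
                grad[:, ti] += delta
                grad[ti, ti] += float(C.loc[src, src] - C.loc[tgt, tgt]) - 2 * delta[ti]
                grad = cen(grad)
                denom = float((grad**2).sum())
                if denom <= 0:
                    continue
                wt = float((R * grad).sum() / denom)
                wt = min(max(wt, 0.01), 0.99)
                ss = float(((R - wt * grad) ** 2).sum())
                if ss < base_ss - 1e-15 and (best is None or ss < best[0]):
                    best = (ss, src, tgt, wt)
        if best is None:
            break
        _, src, tgt, wt = best
        g.add_admixture_edge(src, tgt, weight=wt)
        targets_used.add(tgt)
    return g


# ---------------------------------------------------------------------------
# Polygenic scores and per-edge selection
# ---------------------------------------------------------------------------


def polygenic_scores(freqs: AlleleFrequencyTable, gwas: GwasResult) -> pd.Series:
    """Leaf scores Z_i = 2 sum_j beta_j q_ij over the trait's significant
    loci."""
    loci = [l for l in gwas.significant if l in set(freqs.locus_ids)]
    if not loci:
        raise ValueError(f"trait {gwas.trait!r} has no significant loci with frequencies")
    beta = gwas.table.loc[loci, "beta"].to_numpy()
    Q = freqs.freq[loci].to_numpy(float)
    return pd.Series(2.0 * Q @ beta, index=freqs.population_ids, name=gwas.trait)


def additive_variance(freqs: AlleleFrequencyTable, gwas: GwasResult) -> float:
    """V_A = 4 sum_j beta_j^2 qbar_j (1 - qbar_j) at pooled mean freqs."""
    loci = [l for l in gwas.significant if l in set(freqs.locus_ids)]
    if not loci:
        raise ValueError(f"trait {gwas.trait!r} has no significant loci")
    beta = gwas.table.loc[loci, "beta"].to_numpy()
    qbar = freqs.freq[loci].mean(axis=0).to_numpy(float)
    return float(4.0 * np.sum(beta**2 * qbar * (1.0 - qbar)))


@dataclass
class EdgeSelectionVector:
    trait: str
    edges: list[tuple[str, str]]
    alpha: pd.Series  # standardized selection parameter per tree edge
    raw: pd.Series  # (z_child - z_parent) / sqrt(V_A c_e)
    c: pd.Series  # drift length per edge
    node_scores: pd.Series  # reconstructed (and observed) node scores
    V_A: float


def estimate_edge_selection(
    g: AdmixtureGraph,
    Z: pd.Series,
    V_A: float,
    beta: pd.Series | None = None,
    trait_freqs: pd.DataFrame | None = None,
    null_panel: pd.DataFrame | None = None,
    n_freq_bins: int = 10,
) -> EdgeSelectionVector:
    """GLS ancestral-score reconstruction and standardized per-edge selection.

    Internal node scores minimize sum_e (z_c - z_p)^2 / (V_A c_e) over tree
    edges (admixture nodes constrained to the weighted mix of their parents).
    ``alpha`` standardizes each edge's reconstructed score change by its null
    SD under neutral drift, so drift alone gives alpha ~ mean 0, SD 1;
    positive alpha means selection toward larger trait values along that edge.
    Edges with c_e = 0 get alpha = 0.

    When ``beta`` (per-locus effects), ``trait_freqs`` (populations x trait
    loci frequencies) and ``null_panel`` (populations x reference loci, e.g.
    all genotyped SNPs) are supplied, the null SD is frequency-matched and
    empirical: panel loci are binned by pooled mean frequency and each trait
    locus contributes beta^2 times the mean squared edge contrast of its bin.
    This absorbs the strong dependence of drift dispersion on allele
    frequency that a q(1-q) variance model misses.  Without a panel the null
    SD falls back to the Brownian-model quadratic form in the tree covariance.
    """
    if V_A <= 0:
        raise ValueError("V_A must be positive")
    g.validate()
    tree_edges = [(u, v) for u, v, _ in g.tree_edges()]
    c = pd.Series({e: g.edge_length(*e) for e in tree_edges})
    total_c = float(c.sum())
    if total_c <= 0:
        raise ValueError("tree has zero total drift length")
    leaves = g.leaves()
    missing = set(leaves) - set(Z.index)
    if missing:
        raise ValueError(f"scores missing for leaves: {sorted(missing)}")
    internals = [n for n in g.nodes if n not in leaves]
    li = {n: k for k, n in enumerate(leaves)}
    ii = {n: k for k, n in enumerate(internals)}

    adx = {v: (u, wt) for u, v, wt in g.admixture_edges()}
    eps = 1e-6 * total_c
    n_e = len(tree_edges)
    A_int = np.zeros((n_e, len(internals)))
    A_leaf = np.zeros((n_e, len(leaves)))

    def add_coef(row: np.ndarray, node: str, coef: float, Ai, Al) -> None:
        if node in ii:
            Ai[row, ii[node]] += coef
        else:
            Al[row, li[node]] += coef

    for r, (u, v) in enumerate(tree_edges):
        wgt = 1.0 / np.sqrt(max(c[(u, v)], eps))
        if v in adx:
            # admixture target: its value is the weighted parent mix; the
            # residual measures the tree parent's contribution only
            src, mix = adx[v]
            add_coef(r, v, wgt, A_int, A_leaf)
            add_coef(r, u, -(1.0 - mix) * wgt, A_int, A_leaf)
            add_coef(r, src, -mix * wgt, A_int, A_leaf)
        else:
            add_coef(r, v, wgt, A_int, A_leaf)
            add_coef(r, u, -wgt, A_int, A_leaf)

    zl = Z.reindex(leaves).to_numpy(float)
    if internals:
        M, *_ = np.linalg.lstsq(A_int, -A_leaf, rcond=None)  # z_int = M z_leaf
        rank = np.linalg.matrix_rank(A_int)
        if rank < len(internals):
            raise np.linalg.LinAlgError(
                f"singular GLS system: rank {rank} < {len(internals)} internal nodes "
                f"(edges={n_e}, leaves={len(leaves)})"
            )
        zi = M @ zl
    else:
        M = np.zeros((0, len(leaves)))
        zi = np.array([])
    node_scores = pd.Series(
        np.concatenate([zl, zi]), index=leaves + internals, name=Z.name
    )

    # leaf null covariance (Brownian, in drift units); shift-invariant use
    C = _expected_covariance(g).loc[leaves, leaves].to_numpy()

    def coef_vector(node: str) -> np.ndarray:
        if node in ii:
            return M[ii[node]]
        b = np.zeros(len(leaves))
        b[li[node]] = 1.0
        return b

    empirical = beta is not None and trait_freqs is not None and null_panel is not None
    if empirical:
        panel = null_panel.reindex(leaves).to_numpy(float)
        panel = panel[:, np.isfinite(panel).all(axis=0)]
        pbar = panel.mean(axis=0)
        n_bins = max(1, min(n_freq_bins, panel.shape[1] // 20))
        qedges = np.quantile(pbar, np.linspace(0, 1, n_bins + 1))
        qedges[0], qedges[-1] = -np.inf, np.inf
        panel_bin = np.searchsorted(qedges, pbar, side="right") - 1
        tf = trait_freqs.reindex(leaves).to_numpy(float)
        tbar = np.nanmean(tf, axis=0)
        trait_bin = np.clip(np.searchsorted(qedges, tbar, side="right") - 1, 0, n_bins - 1)
        beta_v = beta.to_numpy(float)

    alpha, raw = {}, {}
    for u, v in tree_edges:
        ce = float(c[(u, v)])
        dz = float(node_scores[v] - node_scores[u])
        if v in adx:
            src, mix = adx[v]
            dz = float(node_scores[v] - (1 - mix) * node_scores[u] - mix * node_scores[src])
            b = coef_vector(v) - (1 - mix) * coef_vector(u) - mix * coef_vector(src)
        else:
            b = coef_vector(v) - coef_vector(u)
        raw[(u, v)] = dz / np.sqrt(V_A * max(ce, eps))
        if empirical:
            sq = (b @ panel) ** 2
            g_bin = np.array(
                [sq[panel_bin == k].mean() if (panel_bin == k).any() else sq.mean()
                 for k in range(n_bins)]
            )
            var_null = float(4.0 * np.sum(beta_v**2 * g_bin[trait_bin]))
        else:
            # Brownian-model quadratic form, in c-units; times V_A below
            var_null = float(V_A * (b @ C @ b))
        if ce <= 0 or var_null <= 0 or not np.isfinite(var_null):
            alpha[(u, v)] = 0.0
        else:
            alpha[(u, v)] = dz / np.sqrt(var_null)
    return EdgeSelectionVector(
        trait=str(Z.name),
        edges=tree_edges,
        alpha=pd.Series(alpha, name=Z.name),
        raw=pd.Series(raw, name=Z.name),
        c=c,
        node_scores=node_scores,
        V_A=V_A,
    )


def edge_selection_for_trait(
    g: AdmixtureGraph, freqs: AlleleFrequencyTable, gwas: GwasResult
) -> EdgeSelectionVector:
    """Convenience: polygenic scores + V_A from a GWAS result, then the
    per-edge selection estimate with the full frequency table as the
    frequency-matched null panel."""
    Z = polygenic_scores(freqs, gwas)
    loci = [l for l in gwas.significant if l in set(freqs.locus_ids)]
    return estimate_edge_selection(
        g,
        Z,
        additive_variance(freqs, gwas),
        beta=gwas.table.loc[loci, "beta"],
        trait_freqs=freqs.freq[loci],
        null_panel=freqs.freq,
    )
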