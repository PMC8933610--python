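"""The selection-on-edge-by-trait (SET) matrix and its PCA.

The SET matrix column-binds, over traits, the per-edge selection parameter
vectors estimated on a shared admixture graph: rows are tree edges, columns
traits.  PCA of this matrix finds coordinated multi-trait selection — a
leading component whose trait loadings group a set of traits marks edges of
the population history where those traits were selected together.
Environmental variables are projected into the same space through the
unconditioned environmental loading: the sum over traits of the trait's
loading times the among-population trait-environment correlation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.decomposition import PCA

from .graphsel import EdgeSelectionVector

logger = logging.getLogger(__name__)


@dataclass
class SETMatrix:
    values: pd.DataFrame  # edges x traits (index: "parent-child" strings)
    edges: list[tuple[str, str]]
    filled: pd.DataFrame | None = None  # True where a missing alpha was zero-filled
    omitted_traits: list[str] | None = None


def edge_label(e: tuple[str, str]) -> str:
    return f"{e[0]}-{e[1]}"


def build_set_matrix(
    vectors: list[EdgeSelectionVector], omitted_traits: list[str] | None = None
) -> SETMatrix:
    """Column-bind per-trait selection vectors sharing one graph; traits with
    no vector (no significant GWAS loci) are recorded as omitted."""
    if not vectors:
        raise ValueError("no selection vectors supplied")
    edges = vectors[0].edges
    for v in vectors[1:]:
        if v.edges != edges:
            raise ValueError("selection vectors come from different graphs")
    cols = {}
    fill = {}
    for v in vectors:
        s = v.alpha.reindex(edges)
        fill[v.trait] = s.isna()
        n_fill = int(s.isna().sum())
        if n_fill:
            logger.info("trait %s: %d missing alpha values set to 0", v.trait, n_fill)
        cols[v.trait] = s.fillna(0.0)
    labels = [edge_label(e) for e in edges]
    values = pd.DataFrame(cols)
    values.index = labels
    filled = pd.DataFrame(fill)
    filled.index = labels
    if omitted_traits:
        logger.info("traits omitted (no significant loci): %s", omitted_traits)
    return SETMatrix(values=values, edges=edges, filled=filled,
                     omitted_traits=list(omitted_traits or []))


@dataclass
class SetPcaResult:
    edge_scores: pd.DataFrame  # edges x components
    trait_loadings: pd.DataFrame  # traits x components
    explained_variance_ratio: np.ndarray
    env_loadings: pd.DataFrame | None = None
    standardized: bool = True


class SetPCA(BaseEstimator):
    """PCA of a SET matrix with optional column standardization.

    ``standardize=True`` (default) scales each trait's selection-parameter
    column to unit variance before the SVD, making traits comparable when
    their alpha scales differ.  Trait-loading columns are orthonormal; a
    deterministic sign convention makes the largest-|loading| element of each
    component positive.

    Attributes after ``fit``: ``edge_scores_``, ``trait_loadings_``,
    ``explained_variance_ratio_``, ``column_means_``, ``column_scales_``.
    """

    def __init__(self, n_components: int | None = None, standardize: bool = True):
        self.n_components = n_components
        self.standardize = standardize

    def fit(self, X, y=None) -> "SetPCA":
        df = X.values if isinstance(X, SETMatrix) else pd.DataFrame(X)
        if df.shape[0] < 2 or df.shape[1] < 2:
            raise ValueError("need at least 2 edges and 2 traits")
        self.column_means_ = df.mean()
        if self.standardize:
            sd = df.std(ddof=1)
            drop = sd <= 0
            if drop.any():
                logger.warning("dropping zero-variance columns: %s", list(df.columns[drop]))
                df = df.loc[:, ~drop]
                sd = sd[~drop]
                self.column_means_ = self.column_means_[~drop]
            self.column_scales_ = sd
            Xs = (df - self.column_means_) / sd
        else:
            self.column_scales_ = pd.Series(1.0, index=df.columns)
            Xs = df - self.column_means_
        k = self.n_components or min(Xs.shape)
        k = min(k, min(Xs.shape))
        pca = PCA(n_components=k, svd_solver="full")
        scores = pca.fit_transform(Xs.to_numpy())
        load = pca.components_.T  # traits x components, orthonormal columns
        for a in range(load.shape[1]):
            j = int(np.argmax(np.abs(load[:, a])))
            if load[j, a] < 0:
                load[:, a] *= -1.0
                scores[:, a] *= -1.0
        comps = [f"PC{i + 1}" for i in range(load.shape[1])]
        self.edge_scores_ = pd.DataFrame(scores, index=df.index, columns=comps)
        self.trait_loadings_ = pd.DataFrame(load, index=df.columns, columns=comps)
        self.explained_variance_ratio_ = pca.explained_variance_ratio_
        self.columns_ = list(df.columns)
        return self

    def transform(self, X) -> pd.DataFrame:
        df = X.values if isinstance(X, SETMatrix) else pd.DataFrame(X)
        Xs = (df[self.columns_] - self.column_means_) / self.column_scales_
        return pd.DataFrame(
            Xs.to_numpy() @ self.trait_loadings_.to_numpy(),
            index=df.index,
            columns=self.trait_loadings_.columns,
        )


def set_pca(m: SETMatrix, standardize: bool = True, n_components: int | None = None) -> SetPcaResult:
    est = SetPCA(n_components=n_components, standardize=standardize).fit(m)
    return SetPcaResult(
        edge_scores=est.edge_scores_,
        trait_loadings=est.trait_loadings_,
        explained_variance_ratio=est.explained_variance_ratio_,
        standardized=standardize,
    )


def environment_loadings(
    trait_loadings: pd.DataFrame, trait_env_r: pd.DataFrame
) -> pd.DataFrame:
    """Unconditioned environmental loadings: load(E, k) = sum_t load(t, k) *
    r(t, E).  Missing correlations count as 0 (logged).  The loading of a
    sign-reversed environment is analytically the negation, so only the raw
    orientation is returned."""
    shared = [t for t in trait_loadings.index if t in set(trait_env_r.index)]
    if not shared:
        raise ValueError("no shared traits between loadings and correlations")
    L = trait_loadings.loc[shared]
    R = trait_env_r.loc[shared]
    n_missing = int(R.isna().sum().sum())
    if n_missing:
        logger.info("%d missing trait-environment correlations treated as 0", n_missing)
    R = R.fillna(0.0)
    return pd.DataFrame(
        R.to_numpy().T @ L.to_numpy(), index=trait_env_r.columns, columns=L.columns
    )


def pc_edge_scores(m: SETMatrix, loadings: pd.DataFrame, k: int | str,
                   column_means: pd.Series | None = None,
                   column_scales: pd.Series | None = None) -> pd.Series:
    """Per-edge signed score on component ``k``: the linear combination of
    (centered, optionally scaled) selection parameters weighted by the trait
    loadings — identical to the PCA edge score.  Positive score = selection
    toward larger values of the component trait."""
    comp = f"PC{k}" if isinstance(k, int) else k
    if comp not in loadings.columns:
        raise ValueError(f"component {comp} not available")
    traits = list(loadings.index)
    df = m.values[traits]
    mu = column_means if column_means is not None else df.mean()
    sc = column_scales if column_scales is not None else pd.Series(1.0, index=traits)
    Xs = (df - mu) / sc
    return pd.Series(
        Xs.to_numpy() @ loadings[comp].to_numpy(), index=m.values.index, name=comp
    )
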