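"""Correspondence analysis of the composite population x (SNP, trait,
environment) table.

The composite table column-binds minor-allele SNP frequencies with min-max
scaled trait and environment means; each environment variable additionally
contributes a sign-reversed copy (1 - scaled value) so that negative
associations show up as proximity to the reversed column.  CA decomposes the
chi-square standardized residuals S = D_r^{-1/2}(P - r c^T)D_c^{-1/2} of the
correspondence matrix P by SVD; total inertia equals Pearson chi^2 / n.
Populations are annotated with psFST-derived age colors: small psFST = old.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .fst import FstResult
from .io import AlleleFrequencyTable

logger = logging.getLogger(__name__)


@dataclass
class CompositeTable:
    values: pd.DataFrame  # populations x columns, nonnegative
    column_class: pd.Series  # column -> {snp, trait, env_plus, env_minus}
    scaling: pd.DataFrame  # column -> (min, max) of the original variable

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < -1e-12).any():
            raise ValueError("composite table must be nonnegative")


def _minmax_scale(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    lo, hi = df.min(), df.max()
    keep = hi > lo
    dropped = list(df.columns[~keep])
    df = df.loc[:, keep]
    scaled = (df - lo[keep]) / (hi[keep] - lo[keep])
    meta = pd.DataFrame({"min": lo[keep], "max": hi[keep]})
    return scaled, meta, dropped


def build_composite_table(
    freqs: AlleleFrequencyTable, traits: pd.DataFrame, envs: pd.DataFrame
) -> CompositeTable:
    """Column-bind SNP frequencies (as-is), min-max scaled traits, and scaled
    environments with their sign-reversed (1 - scaled) copies.  Missing cells
    are mean-imputed within column; constant trait/env columns are dropped."""
    pops = freqs.population_ids
    if set(traits.index) != set(pops) or set(envs.index) != set(pops):
        raise ValueError("population ids must match across the three tables")
    traits = traits.reindex(pops)
    envs = envs.reindex(pops)

    snp = freqs.freq.copy()
    n_missing = int(snp.isna().sum().sum() + traits.isna().sum().sum() + envs.isna().sum().sum())
    if n_missing:
        logger.info("mean-imputing %d missing cells", n_missing)
    snp = snp.fillna(snp.mean())
    traits = traits.fillna(traits.mean())
    envs = envs.fillna(envs.mean())

    t_scaled, t_meta, t_drop = _minmax_scale(traits)
    e_scaled, e_meta, e_drop = _minmax_scale(envs)
    for col in t_drop + e_drop:
        logger.warning("dropping constant column %s", col)

    e_plus = e_scaled.add_prefix("+")
    e_minus = (1.0 - e_scaled).add_prefix("-")
    values = pd.concat([snp, t_scaled, e_plus, e_minus], axis=1)
    classes = pd.Series(
        ["snp"] * snp.shape[1]
        + ["trait"] * t_scaled.shape[1]
        + ["env_plus"] * e_plus.shape[1]
        + ["env_minus"] * e_minus.shape[1],
        index=values.columns,
    )
    scaling = pd.concat(
        [
            pd.DataFrame({"min": 0.0, "max": 1.0}, index=snp.columns),
            t_meta,
            e_meta.set_index("+" + e_meta.index),
            e_meta.set_index("-" + e_meta.index.str.lstrip("+")),
        ]
    )
    return CompositeTable(values=values, column_class=classes, scaling=scaling)


@dataclass
class CAResult:
    row_coords: pd.DataFrame
    col_coords: pd.DataFrame
    singular_values: np.ndarray
    inertia_proportions: np.ndarray
    total_inertia: float
    column_class: pd.Series | None = None
    psfst: pd.Series | None = None
    age_scalar: pd.Series | None = None


class CorrespondenceAnalysis(BaseEstimator):
    """SVD-based correspondence analysis.

    Attributes after ``fit``: ``row_coords_`` / ``col_coords_`` (principal
    coordinates), ``singular_values_``, ``inertia_proportions_``,
    ``total_inertia_``.  Axis signs follow a deterministic convention: the
    largest-|coordinate| column element on each axis is positive.
    """

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, X, y=None) -> "CorrespondenceAnalysis":
        df = X.values if isinstance(X, CompositeTable) else pd.DataFrame(X)
        M = df.to_numpy(float)
        if (M < -1e-12).any():
            raise ValueError("CA requires a nonnegative table")
        total = M.sum()
        if total <= 0:
            raise ValueError("grand total must be positive")
        row_ok = M.sum(axis=1) > 0
        col_ok = M.sum(axis=0) > 0
        if not row_ok.all() or not col_ok.all():
            logger.warning(
                "dropping %d zero-mass rows, %d zero-mass columns",
                (~row_ok).sum(), (~col_ok).sum(),
            )
            df = df.loc[row_ok, col_ok]
            M = df.to_numpy(float)
            total = M.sum()
        if min(M.shape) < 2:
            raise ValueError("need at least 2 rows and 2 columns")
        P = M / total
        r = P.sum(axis=1)
        c = P.sum(axis=0)
        S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
        U, sv, Vt = np.linalg.svd(S, full_matrices=False)
        k = min(len(sv), min(M.shape) - 1)  # trivial dimension removed by centering
        U, sv, Vt = U[:, :k], sv[:k], Vt[:k]
        # deterministic axis signs: largest-|coordinate| column element positive
        G_raw = Vt.T / np.sqrt(c)[:, None]
        for a in range(k):
            j = int(np.argmax(np.abs(G_raw[:, a])))
            if G_raw[j, a] < 0:
                U[:, a] *= -1.0
                Vt[a] *= -1.0
        F = (U / np.sqrt(r)[:, None]) * sv
        G = (Vt.T / np.sqrt(c)[:, None]) * sv
        d = self.n_components if self.n_components is not None else k
        axes = [f"axis{i + 1}" for i in range(k)]
        self.row_coords_ = pd.DataFrame(F, index=df.index, columns=axes)
        self.col_coords_ = pd.DataFrame(G, index=df.columns, columns=axes)
        self.singular_values_ = sv
        self.total_inertia_ = float((sv**2).sum())
        self.inertia_proportions_ = (
            sv**2 / self.total_inertia_ if self.total_inertia_ > 0 else np.zeros(k)
        )
        self.n_axes_ = k
        self.n_components_ = min(d, k)
        self.row_masses_ = pd.Series(r, index=df.index)
        self.col_masses_ = pd.Series(c, index=df.columns)
        return self

    def result_(self, X: CompositeTable | None = None) -> CAResult:
        d = self.n_components_
        return CAResult(
            row_coords=self.row_coords_.iloc[:, :d],
            col_coords=self.col_coords_.iloc[:, :d],
            singular_values=self.singular_values_[:d],
            inertia_proportions=self.inertia_proportions_,
            total_inertia=self.total_inertia_,
            column_class=X.column_class if X is not None else None,
        )


def correspondence_analysis(x: CompositeTable, d: int = 2) -> CAResult:
    """Principal row/column coordinates of the composite table (front-end)."""
    est = CorrespondenceAnalysis(n_components=d).fit(x)
    return est.result_(x if isinstance(x, CompositeTable) else None)


def annotate_population_ages(ca: CAResult, fst: FstResult) -> CAResult:
    """Attach psFST and a [0, 1] age color scalar to each population: 0 for
    the smallest psFST (oldest population), 1 for the largest (youngest)."""
    pops = list(ca.row_coords.index)
    missing = set(pops) - set(fst.psfst.index)
    if missing:
        raise ValueError(f"psFST missing for populations: {sorted(missing)}")
    ps = fst.psfst.reindex(pops)
    lo, hi = ps.min(), ps.max()
    if hi > lo:
        scalar = (ps - lo) / (hi - lo)
    else:
        scalar = pd.Series(0.5, index=pops)  # degenerate: constant psFST
    ca.psfst = ps
    ca.age_scalar = scalar
    return ca
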