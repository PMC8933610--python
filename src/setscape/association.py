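"""Per-trait association scans and gene/trait-environment correlations.

The GWAS model is ordinary least squares of the individual trait value on
allele dosage with population-membership indicators as covariates, which
absorbs the mean structure created by the stepping-stone history.  After the
population effects are projected out (Frisch-Waugh), each locus reduces to a
simple regression with a two-sided t test on n - K - 1 degrees of freedom.
Multiple testing is controlled with Benjamini-Hochberg FDR throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .io import AlleleFrequencyTable, GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class GwasResult:
    trait: str
    table: pd.DataFrame  # locus x (beta, se, p, q)
    significant: list[str]
    alpha: float

    @property
    def beta(self) -> pd.Series:
        return self.table["beta"]


class GwasScan(BaseEstimator):
    """OLS dosage scan for one trait with population-indicator covariates.

    Attributes after ``fit``: ``table_`` (beta, se, p, q per analyzed locus)
    and ``significant_`` (loci with q <= alpha).  Monomorphic loci are
    skipped.
    """

    def __init__(self, alpha: float = 0.05):
        self.alpha = alpha

    def fit(self, X: GenotypeMatrix, y, trait: str = "trait") -> "GwasScan":
        y = pd.Series(np.asarray(y, float), index=X.individual_ids)
        ok = y.notna()
        if ok.sum() < 10:
            raise ValueError("need at least 10 individuals with trait data")
        dose = X.to_frame().loc[ok]
        y = y[ok]
        groups = X.population_of.reindex(dose.index)
        K = groups.nunique()

        # project out population means (with missing dosages handled per locus)
        D = dose.to_numpy(float)
        mask = np.isfinite(D)
        yv = y.to_numpy(float)
        codes = pd.Categorical(groups).codes
        n_loci = D.shape[1]
        Dc = np.where(mask, D, 0.0)
        Yc = yv[:, None] * mask
        xbar = np.zeros_like(D)
        ybar = np.zeros_like(D)
        for g in range(K):
            sel = codes == g
            cnt = np.maximum(mask[sel].sum(axis=0), 1)
            xbar[sel] = Dc[sel].sum(axis=0) / cnt
            ybar[sel] = Yc[sel].sum(axis=0) / cnt
        Xt = np.where(mask, D - xbar, 0.0)
        Yt = np.where(mask, yv[:, None] - ybar, 0.0)

        sxx = (Xt**2).sum(axis=0)
        syy = (Yt**2).sum(axis=0)
        sxy = (Xt * Yt).sum(axis=0)
        nonmono = sxx > 1e-12
        n_eff = mask.sum(axis=0)
        df = n_eff - K - 1
        usable = nonmono & (df > 0)
        with np.errstate(invalid="ignore", divide="ignore"):
            beta = np.where(usable, sxy / np.maximum(sxx, 1e-300), np.nan)
            rss = syy - beta**2 * sxx
            sigma2 = np.maximum(rss, 0.0) / np.maximum(df, 1)
            se = np.sqrt(sigma2 / np.maximum(sxx, 1e-300))
            tstat = np.where(
                se > 0,
                beta / np.maximum(se, 1e-300),
                np.where(beta == 0, 0.0, np.inf * np.sign(np.where(beta == 0, 1.0, beta))),
            )
            p = 2.0 * stats.t.sf(np.abs(tstat), np.maximum(df, 1))
        p = np.where(np.isinf(tstat), 0.0, p)  # exact fit: beta != 0, no residual
        p = np.where(usable, p, np.nan)

        loci = np.array(X.locus_ids)
        keep = usable
        n_skipped = int((~keep).sum())
        if n_skipped:
            logger.info("skipped %d monomorphic/degenerate loci", n_skipped)
        table = pd.DataFrame(
            {"beta": beta[keep], "se": se[keep], "p": p[keep]}, index=loci[keep]
        )
        if len(table):
            table["q"] = benjamini_hochberg(table["p"].to_numpy())
        else:
            table["q"] = []
        self.table_ = table
        self.significant_ = list(table.index[table["q"] <= self.alpha])
        self.trait_ = trait
        return self

    def result_(self) -> GwasResult:
        return GwasResult(self.trait_, self.table_, self.significant_, self.alpha)


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH step-up q-values (monotone nondecreasing in p)."""
    return multipletests(p, method="fdr_bh")[1]


def gwas_scan(
    g: GenotypeMatrix, trait_values, alpha: float = 0.05, trait: str = "trait"
) -> GwasResult:
    """Per-locus OLS of a trait on dosage with population covariates."""
    return GwasScan(alpha=alpha).fit(g, trait_values, trait=trait).result_()


@dataclass
class EnvCorrelationResult:
    table: pd.DataFrame  # rows (locus, env) with r, p, q
    significant: pd.DataFrame
    alpha: float


def gene_env_correlations(
    freqs: AlleleFrequencyTable, envs: pd.DataFrame, alpha: float = 0.05
) -> EnvCorrelationResult:
    """Pearson correlation of minor-allele frequency vectors with environment
    vectors across populations; t-distributed p-values, BH within each
    environment.  Zero-variance vectors are skipped."""
    pops = freqs.population_ids
    if len(pops) < 4:
        raise ValueError("need at least 4 populations")
    envs = envs.reindex(pops)
    F = freqs.freq.to_numpy(float)
    rows = []
    for env in envs.columns:
        e = envs[env].to_numpy(float)
        ok_e = np.isfinite(e)
        recs = []
        for l, locus in enumerate(freqs.locus_ids):
            f = F[:, l]
            ok = ok_e & np.isfinite(f)
            n = ok.sum()
            if n < 4:
                continue
            fv, ev = f[ok], e[ok]
            if fv.std() == 0 or ev.std() == 0:
                continue
            r, p = stats.pearsonr(fv, ev)
            recs.append((locus, env, r, p, n))
        if not recs:
            continue
        df = pd.DataFrame(recs, columns=["locus", "env", "r", "p", "n"])
        df["q"] = benjamini_hochberg(df["p"].to_numpy())
        rows.append(df)
    table = (
        pd.concat(rows, ignore_index=True)
        if rows
        else pd.DataFrame(columns=["locus", "env", "r", "p", "n", "q"])
    )
    return EnvCorrelationResult(table, table[table["q"] <= alpha], alpha)


def trait_env_correlations(traits: pd.DataFrame, envs: pd.DataFrame) -> pd.DataFrame:
    """Traits x environments Pearson correlations over populations,
    pairwise-complete; NaN for zero-variance columns."""
    pops = [p for p in traits.index if p in set(envs.index)]
    if len(pops) < 3:
        raise ValueError("need at least 3 shared populations")
    t = traits.reindex(pops)
    e = envs.reindex(pops)
    out = pd.DataFrame(index=t.columns, columns=e.columns, dtype=float)
    for tc in t.columns:
        for ec in e.columns:
            ok = t[tc].notna() & e[ec].notna()
            if ok.sum() < 3:
                continue
            tv, ev = t.loc[ok, tc], e.loc[ok, ec]
            if tv.std() == 0 or ev.std() == 0:
                continue
            out.loc[tc, ec] = float(np.corrcoef(tv, ev)[0, 1])
    return out
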