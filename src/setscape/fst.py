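"""Matching-based population-specific FST and locus-wise global FST.

Population-specific FST measures each population's genetic deviation from the
shared ancestral pool by comparing the unbiased within-population allele
matching probability M_W (the chance two distinct sampled alleles are
identical) against the average between-population-pair matching M_B:

    psFST_i = sum_l (M_W,l,i - M_B,l) / sum_l (1 - M_B,l)

a ratio of sums over loci, not a mean of per-locus ratios.  Young, recently
founded populations have elevated M_W (reduced heterozygosity) and hence
large psFST; negative values are legal for populations more diverse than the
between-population average.  Standard errors come from a bootstrap over loci.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .io import AlleleFrequencyTable

logger = logging.getLogger(__name__)


def within_matching(counts) -> float:
    """Unbiased matching of two distinct alleles: sum_a n_a(n_a-1)/(n(n-1))."""
    counts = np.asarray(counts, float)
    n = counts.sum()
    if n < 2:
        raise ValueError("need at least 2 sampled alleles")
    return float((counts * (counts - 1)).sum() / (n * (n - 1)))


def between_matching(p_i, p_j) -> float:
    """Expected matching of one allele from each population: sum_a p_a q_a.

    For biallelic loci given counted-allele frequencies p and q this is
    pq + (1-p)(1-q).
    """
    return float(p_i * p_j + (1.0 - p_i) * (1.0 - p_j))


def _matching_components(t: AlleleFrequencyTable) -> tuple[np.ndarray, np.ndarray]:
    """Per-(population, locus) M_W and per-locus pair-averaged M_B.

    Undefined cells (missing data, n < 2) are NaN; a locus' M_B averages only
    over pairs where both members are defined.
    """
    a, b = t.counts()
    n = a + b
    with np.errstate(invalid="ignore", divide="ignore"):
        mw = (a * (a - 1) + b * (b - 1)) / (n * (n - 1))
    mw = np.where(n >= 2, mw, np.nan)

    p = t.freq.to_numpy(float)
    defined = np.isfinite(p) & (n > 0)
    pz = np.where(defined, p, 0.0)
    qz = np.where(defined, 1.0 - p, 0.0)
    m = defined.sum(axis=0).astype(float)
    # sum over unordered pairs of p_i p_j + (1-p_i)(1-p_j), defined pairs only
    cross = ((pz.sum(axis=0) ** 2 - (pz**2).sum(axis=0)) / 2.0) + (
        (qz.sum(axis=0) ** 2 - (qz**2).sum(axis=0)) / 2.0
    )
    n_pairs = m * (m - 1) / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        mb = np.where(n_pairs > 0, cross / np.maximum(n_pairs, 1), np.nan)
    return mw, mb


@dataclass
class FstResult:
    psfst: pd.Series  # per population
    se: pd.Series  # bootstrap SE per population
    locus_global_fst: pd.Series  # per locus (NaN where undefined)
    n_loci: int


class PopulationSpecificFst(BaseEstimator):
    """Estimator computing psFST per population plus locus-wise global FST.

    Parameters
    ----------
    n_bootstrap : bootstrap resamples over loci for the SE (0 disables).
    random_state : seed for the bootstrap.

    Attributes (after ``fit``)
    --------------------------
    psfst_ : pd.Series of per-population psFST (<= 1, may be negative).
    se_ : pd.Series of bootstrap standard errors.
    locus_global_fst_ : pd.Series of per-locus global FST.
    """

    def __init__(self, n_bootstrap: int = 200, random_state: int | None = None):
        self.n_bootstrap = n_bootstrap
        self.random_state = random_state

    def fit(self, X: AlleleFrequencyTable, y=None) -> "PopulationSpecificFst":
        t = X
        if len(t.population_ids) < 2:
            raise ValueError("need at least 2 populations")
        mw, mb = _matching_components(t)
        num = mw - mb[None, :]  # NaN where either undefined
        den = np.where(np.isfinite(num), (1.0 - mb)[None, :], np.nan)
        den_sum = np.nansum(den, axis=1)
        if np.all(den_sum == 0):
            raise ValueError("psFST undefined: every locus monomorphic everywhere")
        with np.errstate(invalid="ignore", divide="ignore"):
            psfst = np.nansum(num, axis=1) / den_sum
        pops = t.population_ids
        self.psfst_ = pd.Series(psfst, index=pops, name="psfst")

        rng = np.random.default_rng(self.random_state)
        L = num.shape[1]
        if self.n_bootstrap > 0 and L > 1:
            boots = np.empty((self.n_bootstrap, len(pops)))
            for b in range(self.n_bootstrap):
                idx = rng.integers(L, size=L)
                with np.errstate(invalid="ignore", divide="ignore"):
                    boots[b] = np.nansum(num[:, idx], axis=1) / np.nansum(den[:, idx], axis=1)
            se = np.nanstd(boots, axis=0, ddof=1)
        else:
            se = np.zeros(len(pops))
        self.se_ = pd.Series(se, index=pops, name="se")

        with np.errstate(invalid="ignore", divide="ignore"):
            glob = (np.nanmean(mw, axis=0) - mb) / (1.0 - mb)
        glob = np.where(np.isclose(mb, 1.0), np.nan, glob)
        self.locus_global_fst_ = pd.Series(glob, index=t.locus_ids, name="global_fst")
        self.n_loci_ = L
        return self

    def result_(self) -> FstResult:
        return FstResult(self.psfst_, self.se_, self.locus_global_fst_, self.n_loci_)


def population_specific_fst(
    t: AlleleFrequencyTable, n_bootstrap: int = 200, random_state: int | None = None
) -> FstResult:
    """psFST per population with bootstrap SEs (function front-end)."""
    est = PopulationSpecificFst(n_bootstrap=n_bootstrap, random_state=random_state).fit(t)
    return est.result_()


def locus_global_fst(t: AlleleFrequencyTable, locus: str | None = None):
    """Matching-based global FST: (mean_i M_W - M_B)/(1 - M_B) per locus."""
    est = PopulationSpecificFst(n_bootstrap=0).fit(t)
    if locus is None:
        return est.locus_global_fst_
    return float(est.locus_global_fst_[locus])


def top_snp_per_gene(
    t: AlleleFrequencyTable, gene_of: dict[str, str] | None = None
) -> AlleleFrequencyTable:
    """Keep, per gene, the SNP with the highest global FST (ties broken by
    locus id order); genes with no locus of defined FST are dropped."""
    gene_of = gene_of if gene_of is not None else t.gene_of
    if gene_of is None:
        raise ValueError("a locus -> gene map is required")
    fst = locus_global_fst(t)
    chosen: list[str] = []
    by_gene: dict[str, list[str]] = {}
    for locus in t.locus_ids:
        g = gene_of.get(locus)
        if g is not None:
            by_gene.setdefault(g, []).append(locus)
    for gene in by_gene:
        loci = sorted(by_gene[gene])
        vals = fst[loci]
        if vals.isna().all():
            logger.warning("gene %s has no locus with defined global FST; dropped", gene)
            continue
        chosen.append(vals.idxmax())
    chosen = [l for l in t.locus_ids if l in set(chosen)]
    return AlleleFrequencyTable(
        freq=t.freq[chosen].copy(),
        n_alleles=t.n_alleles[chosen].copy(),
        gene_of={l: gene_of[l] for l in chosen},
    )
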