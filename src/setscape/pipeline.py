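"""End-to-end analysis: simulator output (or equivalent tables) through
psFST, correspondence analysis, per-trait GWAS, tree fitting, per-edge
selection, and SET-matrix PCA with environmental loadings."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .association import GwasResult, gwas_scan, trait_env_correlations
from .ca import CAResult, annotate_population_ages, build_composite_table, correspondence_analysis
from .fst import FstResult, population_specific_fst
from .graph import AdmixtureGraph
from .graphsel import drift_covariance, edge_selection_for_trait, fit_tree
from .io import AlleleFrequencyTable, GenotypeMatrix, minor_allele_orientation
from .setpca import SETMatrix, SetPcaResult, build_set_matrix, environment_loadings, set_pca
from .simulate import SimOutput

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    fst: FstResult
    ca: CAResult
    gwas: dict[str, GwasResult]
    graph: AdmixtureGraph
    set_matrix: SETMatrix
    set_pca: SetPcaResult
    env_loadings: pd.DataFrame
    trait_env_r: pd.DataFrame
    omitted_traits: list[str]


def run_pipeline(
    genotypes: GenotypeMatrix,
    freqs: AlleleFrequencyTable,
    traits_population: pd.DataFrame,
    traits_individual: pd.DataFrame,
    env: pd.DataFrame,
    root: str,
    alpha: float = 0.05,
    n_bootstrap: int = 100,
    n_migrations: int = 0,
    standardize_set: bool = True,
    seed: int | None = None,
) -> PipelineResult:
    """Run the full exploratory analysis on population tables."""
    oriented = minor_allele_orientation(freqs)
    fst = population_specific_fst(oriented, n_bootstrap=n_bootstrap, random_state=seed)
    composite = build_composite_table(oriented, traits_population, env)
    ca = annotate_population_ages(correspondence_analysis(composite), fst)

    gwas: dict[str, GwasResult] = {}
    omitted: list[str] = []
    vectors = []
    graph = fit_tree(drift_covariance(freqs), root=root)
    if n_migrations:
        from .graphsel import add_migration_edges

        graph = add_migration_edges(graph, drift_covariance(freqs), n_migrations)
    for trait in traits_individual.columns:
        res = gwas_scan(genotypes, traits_individual[trait], alpha=alpha, trait=trait)
        gwas[trait] = res
        if not res.significant:
            omitted.append(trait)
            continue
        vectors.append(edge_selection_for_trait(graph, freqs, res))
    if len(vectors) < 2:
        raise ValueError("fewer than 2 traits with significant loci; SET PCA impossible")
    m = build_set_matrix(vectors, omitted_traits=omitted)
    pca = set_pca(m, standardize=standardize_set)
    r = trait_env_correlations(traits_population, env)
    env_load = environment_loadings(
        pca.trait_loadings, r.reindex(pca.trait_loadings.index)
    )
    pca.env_loadings = env_load
    return PipelineResult(
        fst=fst,
        ca=ca,
        gwas=gwas,
        graph=graph,
        set_matrix=m,
        set_pca=pca,
        env_loadings=env_load,
        trait_env_r=r,
        omitted_traits=omitted,
    )


def run_pipeline_on_simulation(sim: SimOutput, root: str = "pop1", **kwargs) -> PipelineResult:
    return run_pipeline(
        sim.genotypes,
        sim.freqs,
        sim.traits_population,
        sim.traits_individual,
        sim.env,
        root=root,
        **kwargs,
    )
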