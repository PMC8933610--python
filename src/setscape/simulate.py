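"""Forward simulator of one-dimensional stepping-stone colonization with
polygenic environmental selection.

The model tracks population allele frequencies (not individuals).  An
ancestral deme of size ``Ne_anc`` seeds a chain of ``K`` demes: every
``expansion_interval`` generations, a fraction ``founder_fraction`` of the
rightmost occupied deme emigrates into the adjacent vacant deme, which grows
to capacity ``Ne_cap`` in a single generation.  Ancestral polymorphism starts
at the neutral equilibrium density f(q) ∝ 1/(q(1-q)); new neutral and
adaptive mutations enter over time at frequency ``init_new_freq`` in one deme.

Two environment types act on disjoint trait sets.  Each adaptive (causal)
locus belongs to one latent trait; its derived allele has genic selection
coefficient s in a deme with environment value E = 1 and 1/(1+s) - 1 in a
deme with E = 0 (adaptation to stress at a cost in the benign environment),
linearly interpolated for fractional E.  Traits are polygenic sums of
monogenic latent traits, each latent contributing 2*gamma_G*q, with
gamma_G <= 0 so the derived, environmentally favoured allele lowers the
trait.  Drift is binomial with the deme's current size every generation.

Observation mimics SNP discovery: fixed numbers of initial-neutral and
new-neutral loci plus one surviving causal locus per latent trait, then 50
diploid individuals sampled per deme under Hardy-Weinberg and linkage
equilibrium.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .io import AlleleFrequencyTable, GenotypeMatrix

logger = logging.getLogger(__name__)

INIT_NEUTRAL, NEW_NEUTRAL, ADAPTIVE = "init_neutral", "new_neutral", "adaptive"


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------


def default_env_profiles(K: int) -> tuple[np.ndarray, np.ndarray]:
    """Environment profiles over the deme chain.

    For K = 25 these are the study conditions: E1 = 1 on demes 5..10 (a local
    patch) and 0 elsewhere; E2 = 0 on demes 1..14 then rising linearly to 1 at
    deme 25 (a geographical cline).  Other K get the same proportional layout.
    """
    demes = np.arange(1, K + 1)
    if K == 25:
        lo, hi, flat = 5, 10, 14
    else:
        lo = max(2, round(K * 5 / 25))
        hi = max(lo, round(K * 10 / 25))
        flat = max(hi, round(K * 14 / 25))
    e1 = ((demes >= lo) & (demes <= hi)).astype(float)
    e2 = np.zeros(K)
    ramp = demes > flat
    n_ramp = int(ramp.sum())
    if n_ramp:
        e2[ramp] = np.arange(1, n_ramp + 1) / n_ramp
    return e1, e2


@dataclass
class SimParams:
    """Scenario parameters; defaults are the full-scale study conditions."""

    K: int = 25
    Ne_anc: int = 100_000
    Ne_cap: int = 10_000
    founder_fraction: float = 0.01
    expansion_interval: int = 10
    total_generations: int = 260
    s: float = 0.01
    n_init_neutral_pool: int = 16_000
    neutral_mut_rate_per_gen: float = 5.0
    adaptive_mut_per_gen: int = 3
    n_env_types: int = 2
    traits_per_env: int = 15
    latents_per_trait: int = 10
    gamma_G: float = -1.0
    gamma_E: float = -1.0  # sign convention only; dynamics use effective_s
    env_profiles: np.ndarray | None = None  # (n_env_types, K)
    sample_n_individuals: int = 50
    n_obs_init_neutral: int = 10_000
    n_obs_new_neutral: int = 500
    init_new_freq: float = 0.01
    sigma_e: float | None = None  # None -> 0.5 * SD of genotypic values
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.founder_fraction < 1:
            raise ValueError("founder_fraction must be in (0, 1)")
        if self.s <= -1:
            raise ValueError("s must exceed -1")
        if self.gamma_G > 0:
            raise ValueError("gamma_G must be <= 0")
        if self.total_generations < (self.K - 1) * self.expansion_interval:
            raise ValueError(
                "total_generations too small to occupy all K demes "
                f"(need >= {(self.K - 1) * self.expansion_interval})"
            )
        if self.env_profiles is None:
            if self.n_env_types != 2:
                raise ValueError("default env profiles require n_env_types == 2")
            self.env_profiles = np.vstack(default_env_profiles(self.K))
        else:
            self.env_profiles = np.asarray(self.env_profiles, float)
        if self.env_profiles.shape != (self.n_env_types, self.K):
            raise ValueError("env_profiles must be (n_env_types, K)")
        if self.env_profiles.min() < 0 or self.env_profiles.max() > 1:
            raise ValueError("environment values must lie in [0, 1]")

    @property
    def n_traits(self) -> int:
        return self.n_env_types * self.traits_per_env

    @property
    def n_latents(self) -> int:
        return self.n_traits * self.latents_per_trait

    def env_type_of_latent(self, latent: int) -> int:
        return latent // (self.traits_per_env * self.latents_per_trait)

    def trait_of_latent(self, latent: int) -> int:
        return latent // self.latents_per_trait


def scaled_scenario(
    seed: int | None = None, s: float = 0.05, with_selection: bool = True
) -> SimParams:
    """Desk-scale scenario: K=10 demes, Ne 2000/1000, 2000 initial neutral
    loci, 110 generations; E1 selection (coefficient ``s``) on demes 3-5 and
    the E2 cline over demes 6-10.  Trait architecture is reduced to 5 traits
    per environment type with 4 latent traits each, and 8 adaptive mutations
    per generation so most latents acquire a surviving causal locus."""
    K = 10
    demes = np.arange(1, K + 1)
    e1 = ((demes >= 3) & (demes <= 5)).astype(float)
    e2 = np.where(demes > 5, (demes - 5) / 5.0, 0.0)
    return SimParams(
        K=K,
        Ne_anc=2000,
        Ne_cap=1000,
        total_generations=110,
        s=s if with_selection else 0.0,
        n_init_neutral_pool=2000,
        neutral_mut_rate_per_gen=2.0,
        adaptive_mut_per_gen=8,
        traits_per_env=5,
        latents_per_trait=4,
        env_profiles=np.vstack([e1, e2]),
        n_obs_init_neutral=2000,
        n_obs_new_neutral=100,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Elementary updates
# ---------------------------------------------------------------------------


def sample_equilibrium_frequencies(n_loci: int, Ne: float, rng: np.random.Generator) -> np.ndarray:
    """Draw i.i.d. frequencies from f(q) ∝ 1/(q(1-q)) truncated to
    [1/(2Ne), 1-1/(2Ne)] by inverse CDF: logit(q) is uniform under f."""
    if n_loci < 1 or Ne < 2:
        raise ValueError("need n_loci >= 1 and Ne >= 2")
    eps = 1.0 / (2.0 * Ne)
    a, b = logit(eps), logit(1.0 - eps)
    return expit(a + rng.random(n_loci) * (b - a))


def effective_s(E: float | np.ndarray, s: float) -> float | np.ndarray:
    """Environment-dependent genic selection coefficient: s at E = 1,
    1/(1+s) - 1 at E = 0 (reciprocal-fitness cost), linear in between."""
    E = np.asarray(E, float)
    if np.any(E < 0) or np.any(E > 1):
        raise ValueError("E must lie in [0, 1]")
    out = E * s + (1.0 - E) * (1.0 / (1.0 + s) - 1.0)
    return float(out) if out.ndim == 0 else out


def selection_update(q, s_eff):
    """One generation of genic selection: q' = q(1+s)/(1+qs).  Fixed points
    at 0 and 1; monotone in s_eff."""
    q = np.asarray(q, float)
    out = q * (1.0 + s_eff) / (1.0 + q * s_eff)
    return float(out) if out.ndim == 0 else out


def drift_update(q, deme_size: int, rng: np.random.Generator):
    """Binomial drift: q' = X/(2N), X ~ Binomial(2N, q)."""
    q = np.asarray(q, float)
    n = 2 * int(deme_size)
    out = np.asarray(rng.binomial(n, q)) / n
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# State
# ---------------------------------------------------------------------------


@dataclass
class LocusRecord:
    locus_id: str
    locus_class: str  # INIT_NEUTRAL | NEW_NEUTRAL | ADAPTIVE
    origin_generation: int
    origin_deme: int  # 1-based; 1 for initial loci
    latent_trait: int | None = None  # adaptive only
    gamma_G: float | None = None  # adaptive only

    def __post_init__(self) -> None:
        if self.locus_class == ADAPTIVE and self.latent_trait is None:
            raise ValueError("adaptive locus needs a latent trait target")
        if self.locus_class == INIT_NEUTRAL and self.origin_generation != 0:
            raise ValueError("initial loci originate at generation 0")


@dataclass
class SimState:
    generation: int
    deme_sizes: np.ndarray  # (K,) ints; 0 = vacant
    freq: np.ndarray  # (K, L) derived-allele frequencies; vacant rows all 0
    loci: list[LocusRecord]
    founding_generation: list[int] = field(default_factory=list)  # per deme

    @property
    def n_occupied(self) -> int:
        return int((self.deme_sizes > 0).sum())

    @property
    def occupied(self) -> np.ndarray:
        return np.flatnonzero(self.deme_sizes > 0)

    def pooled_frequency(self) -> np.ndarray:
        return self.freq[self.occupied].mean(axis=0)

    def polymorphic_mask(self) -> np.ndarray:
        p = self.pooled_frequency()
        return (p > 0) & (p < 1)


@dataclass
class SimOutput:
    genotypes: GenotypeMatrix
    freqs: AlleleFrequencyTable
    traits_population: pd.DataFrame  # K x n_traits true means
    traits_individual: pd.DataFrame  # (K*n) x n_traits
    env: pd.DataFrame  # K x n_env_types
    locus_records: pd.DataFrame
    colonization_order: pd.DataFrame  # population, founding generation
    lost_in_sampling: list[str]
    params: SimParams
    state: SimState


# ---------------------------------------------------------------------------
# Scenario steps
# ---------------------------------------------------------------------------


def colonize_next_deme(state: SimState, params: SimParams, rng: np.random.Generator) -> SimState:
    """Found the next vacant deme from its occupied neighbour: founder allele
    frequencies are binomial draws of 2*round(founder_fraction*Ne_source)
    copies; the new deme jumps to Ne_cap immediately."""
    occ = state.occupied
    nxt = occ.max() + 1
    if nxt >= params.K:
        raise ValueError("no vacant deme remains")
    src = occ.max()
    n_copies = max(2, 2 * int(round(params.founder_fraction * state.deme_sizes[src])))
    state.freq[nxt] = rng.binomial(n_copies, state.freq[src]) / n_copies
    state.deme_sizes[nxt] = params.Ne_cap
    state.founding_generation.append(state.generation)
    return state


def spawn_mutations(state: SimState, params: SimParams, rng: np.random.Generator) -> SimState:
    """Inject new neutral (Poisson rate) and adaptive (fixed count) loci, each
    at frequency ``init_new_freq`` in one uniformly chosen occupied deme."""
    n_neutral = rng.poisson(params.neutral_mut_rate_per_gen)
    n_adaptive = params.adaptive_mut_per_gen
    n_new = n_neutral + n_adaptive
    if n_new == 0:
        return state
    occ = state.occupied
    cols = np.zeros((params.K, n_new))
    demes = rng.choice(occ, size=n_new)
    cols[demes, np.arange(n_new)] = params.init_new_freq
    gen = state.generation
    start = len(state.loci)
    for j in range(n_neutral):
        state.loci.append(
            LocusRecord(f"nn{start + j}", NEW_NEUTRAL, gen, int(demes[j]) + 1)
        )
    for j in range(n_adaptive):
        latent = int(rng.integers(params.n_latents))
        state.loci.append(
            LocusRecord(
                f"ad{start + n_neutral + j}",
                ADAPTIVE,
                gen,
                int(demes[n_neutral + j]) + 1,
                latent_trait=latent,
                gamma_G=params.gamma_G,
            )
        )
    state.freq = np.hstack([state.freq, cols])
    return state


def run_simulation(params: SimParams, rng: np.random.Generator | None = None) -> SimState:
    """Run the colonization scenario to ``total_generations``.

    Per generation: mutation injection, genic selection on adaptive loci with
    the deme's environment, binomial drift in every occupied deme, and (every
    ``expansion_interval`` generations) colonization of the next vacant deme.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    q0 = sample_equilibrium_frequencies(params.n_init_neutral_pool, params.Ne_anc, rng)
    freq = np.zeros((params.K, params.n_init_neutral_pool))
    freq[0] = q0
    sizes = np.zeros(params.K, dtype=np.int64)
    sizes[0] = params.Ne_anc
    state = SimState(0, sizes, freq, [
        LocusRecord(f"in{j}", INIT_NEUTRAL, 0, 1) for j in range(params.n_init_neutral_pool)
    ], founding_generation=[0])

    # per-deme selection coefficient for each environment type
    s_eff_by_type = np.vstack(
        [effective_s(params.env_profiles[t], params.s) for t in range(params.n_env_types)]
    )  # (n_env_types, K)

    for gen in range(1, params.total_generations + 1):
        state.generation = gen
        state = spawn_mutations(state, params, rng)
        occ = state.occupied
        if params.s != 0.0:
            # group adaptive loci by environment type, update per type
            types = np.full(state.freq.shape[1], -1)
            for idx, rec in enumerate(state.loci):
                if rec.locus_class == ADAPTIVE:
                    types[idx] = params.env_type_of_latent(rec.latent_trait)
            for t in range(params.n_env_types):
                cols = np.flatnonzero(types == t)
                if cols.size == 0:
                    continue
                s_col = s_eff_by_type[t, occ][:, None]
                q = state.freq[np.ix_(occ, cols)]
                state.freq[np.ix_(occ, cols)] = q * (1.0 + s_col) / (1.0 + q * s_col)
        for i in occ:
            state.freq[i] = drift_update(state.freq[i], state.deme_sizes[i], rng)
        if gen % params.expansion_interval == 0 and state.n_occupied < params.K:
            state = colonize_next_deme(state, params, rng)
    return state


# ---------------------------------------------------------------------------
# Traits and observation
# ---------------------------------------------------------------------------


def _causal_loci_by_trait(state: SimState, params: SimParams) -> dict[int, list[int]]:
    out: dict[int, list[int]] = {t: [] for t in range(params.n_traits)}
    for idx, rec in enumerate(state.loci):
        if rec.locus_class == ADAPTIVE:
            out[params.trait_of_latent(rec.latent_trait)].append(idx)
    return out


def trait_names(params: SimParams) -> list[str]:
    return [
        f"T{t + 1}.{j + 1}"
        for t in range(params.n_env_types)
        for j in range(params.traits_per_env)
    ]


def compute_traits(state: SimState, params: SimParams) -> pd.DataFrame:
    """Population mean traits: each latent contributes 2*gamma_G*q of its
    surviving causal loci; a trait sums its latents.  Latents with no causal
    locus contribute 0."""
    names = trait_names(params)
    vals = np.zeros((params.K, params.n_traits))
    by_trait = _causal_loci_by_trait(state, params)
    for t, cols in by_trait.items():
        if not cols:
            logger.info("trait %s has no surviving causal locus", names[t])
            continue
        gammas = np.array([state.loci[c].gamma_G for c in cols])
        vals[:, t] = state.freq[:, cols] @ (2.0 * gammas)
    pops = [f"pop{i + 1}" for i in range(params.K)]
    return pd.DataFrame(vals, index=pops, columns=names)


def select_observed_snps(
    state: SimState, params: SimParams, rng: np.random.Generator
) -> SimOutput:
    """SNP discovery and sampling.

    Observes random subsets of pooled-polymorphic initial-neutral and
    new-neutral loci plus, per latent trait, the surviving causal locus with
    the highest across-deme frequency variance; then samples
    ``sample_n_individuals`` diploids per deme with dosages Binomial(2, q).
    """
    poly = state.polymorphic_mask()
    classes = np.array([rec.locus_class for rec in state.loci])

    def pick(cls: str, n_want: int) -> np.ndarray:
        avail = np.flatnonzero((classes == cls) & poly)
        if avail.size < n_want:
            logger.info("only %d %s loci available (wanted %d)", avail.size, cls, n_want)
            return avail
        return np.sort(rng.choice(avail, size=n_want, replace=False))

    obs_init = pick(INIT_NEUTRAL, params.n_obs_init_neutral)
    obs_new = pick(NEW_NEUTRAL, params.n_obs_new_neutral)

    occ = state.occupied
    var = state.freq[occ].var(axis=0)
    obs_adaptive = []
    by_latent: dict[int, list[int]] = {}
    for idx, rec in enumerate(state.loci):
        if rec.locus_class == ADAPTIVE and poly[idx]:
            by_latent.setdefault(rec.latent_trait, []).append(idx)
    for latent, cands in sorted(by_latent.items()):
        v = var[cands]
        best = np.flatnonzero(v == v.max())
        obs_adaptive.append(cands[int(rng.choice(best))])
    obs_adaptive = np.array(sorted(obs_adaptive), dtype=int)

    observed = np.concatenate([obs_init, obs_new, obs_adaptive]).astype(int)
    locus_ids = [state.loci[j].locus_id for j in observed]

    # all surviving causal loci are needed for individual trait values even
    # when unobserved (the trait is polygenic over every causal locus)
    causal_all = np.flatnonzero((classes == ADAPTIVE) & poly)
    sample_cols = np.union1d(observed, causal_all)
    col_pos = {c: k for k, c in enumerate(sample_cols)}

    n = params.sample_n_individuals
    pops = [f"pop{i + 1}" for i in range(params.K)]
    dosage = np.empty((params.K * n, sample_cols.size), dtype=np.int8)
    for row, i in enumerate(range(params.K)):
        dosage[row * n : (row + 1) * n] = rng.binomial(2, state.freq[i, sample_cols], size=(n, sample_cols.size))

    obs_pos = [col_pos[c] for c in observed]
    geno_obs = dosage[:, obs_pos]
    individual_ids = [f"{p}_ind{j + 1}" for p in pops for j in range(n)]
    pop_of = pd.Series(
        np.repeat(pops, n), index=individual_ids
    )
    genotypes = GenotypeMatrix(
        individual_ids=individual_ids,
        population_of=pop_of,
        locus_ids=locus_ids,
        dosage=geno_obs,
    )

    # sample allele frequencies of observed SNPs
    freq = np.stack([geno_obs[i * n : (i + 1) * n].mean(axis=0) / 2.0 for i in range(params.K)])
    n_alleles = pd.DataFrame(2 * n, index=pops, columns=locus_ids)
    freq_table = AlleleFrequencyTable(
        freq=pd.DataFrame(freq, index=pops, columns=locus_ids), n_alleles=n_alleles
    )
    pooled = freq.mean(axis=0)
    lost = [lid for lid, p in zip(locus_ids, pooled) if p <= 0 or p >= 1]

    # traits
    traits_pop = compute_traits(state, params)
    by_trait = _causal_loci_by_trait(state, params)
    genotypic = np.zeros((params.K * n, params.n_traits))
    for t, cols in by_trait.items():
        cols = [c for c in cols if c in col_pos]
        if not cols:
            continue
        gammas = np.array([state.loci[c].gamma_G for c in cols])
        genotypic[:, t] = dosage[:, [col_pos[c] for c in cols]] @ gammas
    sigma_e = params.sigma_e
    if sigma_e is None:
        sd = genotypic.std()
        sigma_e = 0.5 * sd if sd > 0 else 0.0
    traits_ind = genotypic + rng.normal(0.0, sigma_e, size=genotypic.shape) if sigma_e > 0 else genotypic
    traits_individual = pd.DataFrame(
        traits_ind, index=individual_ids, columns=trait_names(params)
    )

    env = pd.DataFrame(
        params.env_profiles.T, index=pops, columns=[f"E{t + 1}" for t in range(params.n_env_types)]
    )
    records = pd.DataFrame(
        [
            {
                "locus": state.loci[j].locus_id,
                "class": state.loci[j].locus_class,
                "origin_generation": state.loci[j].origin_generation,
                "origin_deme": state.loci[j].origin_deme,
                "latent_trait": state.loci[j].latent_trait,
                "gamma_G": state.loci[j].gamma_G,
                "lost_in_sampling": state.loci[j].locus_id in lost,
            }
            for j in observed
        ]
    ).set_index("locus")
    colonization = pd.DataFrame(
        {
            "population": pops[: len(state.founding_generation)],
            "founding_generation": state.founding_generation,
        }
    ).set_index("population")
    return SimOutput(
        genotypes=genotypes,
        freqs=freq_table,
        traits_population=traits_pop,
        traits_individual=traits_individual,
        env=env,
        locus_records=records,
        colonization_order=colonization,
        lost_in_sampling=lost,
        params=params,
        state=state,
    )


def simulate(params: SimParams, seed: int | None = None) -> SimOutput:
    """Run the scenario and observe it: the one-call synthetic-data source."""
    if seed is not None:
        params = replace(params, seed=seed)
    rng = np.random.default_rng(params.seed)
    state = run_simulation(params, rng)
    return select_observed_snps(state, params, rng)
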