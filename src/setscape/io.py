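"""Data model and readers/writers for genotype, frequency, trait, environment
and graph files.

The central containers are :class:`GenotypeMatrix` (individuals x loci dosage
of a consistently oriented counted allele) and :class:`AlleleFrequencyTable`
(populations x loci counted-allele frequencies with allele-count
denominators).  Genotypes are read from Genepop files (2- and 3-digit
dialects); frequency tables round-trip through TreeMix-style count files and
plain TSV.  Missing data are recorded, never imputed, at this layer.
"""

from __future__ import annotations

import gzip
import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .graph import AdmixtureGraph

logger = logging.getLogger(__name__)

MISSING = -1  # dosage sentinel in integer arrays; NaN used in float views


class GenepopParseError(ValueError):
    """Raised for malformed Genepop input, naming the offending line."""


@dataclass
class GenotypeMatrix:
    """Diploid dosage matrix with population assignment.

    dosage[i, l] counts copies of the counted allele (the numerically larger
    Genepop code) carried by individual i at locus l; ``MISSING`` marks no
    call.  Every individual belongs to exactly one population.
    """

    individual_ids: list[str]
    population_of: pd.Series  # individual id -> population id
    locus_ids: list[str]
    dosage: np.ndarray  # (n_individuals, n_loci) int8, MISSING for no call
    gene_of: dict[str, str] | None = None  # locus id -> gene id

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage)
        if self.dosage.shape != (len(self.individual_ids), len(self.locus_ids)):
            raise ValueError("dosage shape does not match ids")
        if len(set(self.locus_ids)) != len(self.locus_ids):
            raise ValueError("locus ids must be unique")
        valid = np.isin(self.dosage, [0, 1, 2, MISSING])
        if not valid.all():
            raise ValueError("dosage entries must be 0, 1, 2 or missing")
        missing_assign = set(self.individual_ids) - set(self.population_of.index)
        if missing_assign:
            raise ValueError(f"individuals without population: {sorted(missing_assign)[:5]}")

    @property
    def population_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for ind in self.individual_ids:
            seen.setdefault(self.population_of[ind], None)
        return list(seen)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.dosage.astype(float), index=self.individual_ids, columns=self.locus_ids
        )
        return df.replace(float(MISSING), np.nan)


@dataclass
class AlleleFrequencyTable:
    """Populations x loci frequencies of the counted allele.

    ``freq`` holds the counted-allele frequency, NaN where no alleles were
    sampled; ``n_alleles`` the per-cell denominator (2 x individuals with
    data).  ``flipped`` records loci re-oriented by
    :func:`minor_allele_orientation`.
    """

    freq: pd.DataFrame  # populations x loci, values in [0, 1] or NaN
    n_alleles: pd.DataFrame  # populations x loci, nonnegative ints
    flipped: pd.Series | None = None  # locus id -> bool
    gene_of: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if not self.freq.index.equals(self.n_alleles.index) or not self.freq.columns.equals(
            self.n_alleles.columns
        ):
            raise ValueError("freq and n_alleles must share index/columns")
        vals = self.freq.to_numpy(float)
        with np.errstate(invalid="ignore"):
            if np.nanmin(vals, initial=0.0) < -1e-12 or np.nanmax(vals, initial=0.0) > 1 + 1e-12:
                raise ValueError("frequencies must lie in [0, 1]")
        if (self.n_alleles.to_numpy() < 0).any():
            raise ValueError("allele counts must be nonnegative")
        # freq defined only where alleles were observed
        none_called = self.n_alleles.to_numpy() == 0
        if np.isfinite(vals[none_called]).any():
            raise ValueError("frequency defined where n_alleles == 0")

    @property
    def population_ids(self) -> list[str]:
        return list(self.freq.index)

    @property
    def locus_ids(self) -> list[str]:
        return list(self.freq.columns)

    def counts(self) -> tuple[np.ndarray, np.ndarray]:
        """Integer (counted, other) allele counts reconstructed per cell."""
        n = self.n_alleles.to_numpy(float)
        with np.errstate(invalid="ignore"):
            a = np.round(np.nan_to_num(self.freq.to_numpy(float)) * n)
        return a, n - a


# ---------------------------------------------------------------------------
# Genepop
# ---------------------------------------------------------------------------

_POP_RE = re.compile(r"^\s*pop\s*$", re.IGNORECASE)


def read_genepop(path, drop_multiallelic: bool = False) -> GenotypeMatrix:
    """Parse a Genepop file (2- or 3-digit diploid codes) into dosages.

    The counted allele at each locus is the numerically largest code seen, so
    a homozygote for the smaller code has dosage 0.  ``00``/``000`` codes mark
    missing alleles.  Loci with more than two alleles raise unless
    ``drop_multiallelic`` is set, in which case they are dropped with a
    warning.  Population labels come from the last token of the first
    individual line of each POP block when usable, else ``pop1..popK``.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) < 3:
        raise GenepopParseError("file too short to be Genepop")
    # locus names: one per line, or comma separated, until the first POP
    locus_ids: list[str] = []
    i = 1
    while i < len(lines) and not _POP_RE.match(lines[i]):
        locus_ids.extend(t.strip() for t in lines[i].split(",") if t.strip())
        i += 1
    if i == len(lines):
        raise GenepopParseError("no POP line found")

    blocks: list[list[tuple[str, list[str]]]] = []
    current: list[tuple[str, list[str]]] | None = None
    for lineno, line in enumerate(lines[i:], start=i + 1):
        if _POP_RE.match(line):
            current = []
            blocks.append(current)
            continue
        if not line.strip():
            continue
        if current is None:
            raise GenepopParseError(f"line {lineno}: genotypes before first POP")
        if "," not in line:
            raise GenepopParseError(f"line {lineno}: expected 'id , genotypes'")
        ident, geno = line.split(",", 1)
        tokens = geno.split()
        if len(tokens) != len(locus_ids):
            raise GenepopParseError(
                f"line {lineno}: {len(tokens)} genotype fields for {len(locus_ids)} loci"
            )
        current.append((ident.strip(), tokens))

    # allele width from the first genotype token
    first_tok = next((t for b in blocks for _, toks in b for t in toks), None)
    if first_tok is None:
        raise GenepopParseError("no individuals found")
    if len(first_tok) not in (4, 6):
        raise GenepopParseError(f"unsupported allele code width in token '{first_tok}'")
    width = len(first_tok) // 2

    individual_ids: list[str] = []
    pop_assign: dict[str, str] = {}
    pop_names: list[str] = []
    alleles_per_ind: list[list[tuple[int, int]]] = []
    for k, block in enumerate(blocks, start=1):
        if not block:
            continue
        cand = block[0][0].split()[-1] if block[0][0].split() else ""
        name = cand if cand and cand not in pop_names else f"pop{k}"
        pop_names.append(name)
        for j, (ident, tokens) in enumerate(block, start=1):
            iid = ident if ident and ident not in pop_assign else f"{name}_ind{j}"
            individual_ids.append(iid)
            pop_assign[iid] = name
            row = []
            for tok in tokens:
                if len(tok) != 2 * width:
                    raise GenepopParseError(
                        f"allele code '{tok}' for individual '{iid}' has width "
                        f"{len(tok)}, expected {2 * width}"
                    )
                row.append((int(tok[:width]), int(tok[width:])))
            alleles_per_ind.append(row)

    n, L = len(individual_ids), len(locus_ids)
    dosage = np.full((n, L), MISSING, dtype=np.int8)
    keep = np.ones(L, dtype=bool)
    for l in range(L):
        codes = sorted(
            {a for row in alleles_per_ind for a in row[l] if a != 0}
        )
        if len(codes) > 2:
            if not drop_multiallelic:
                raise GenepopParseError(
                    f"locus '{locus_ids[l]}' has {len(codes)} alleles; "
                    "pass drop_multiallelic to drop it"
                )
            logger.warning("dropping multiallelic locus %s", locus_ids[l])
            keep[l] = False
            continue
        counted = codes[-1] if codes else None
        for i_, row in enumerate(alleles_per_ind):
            a, b = row[l]
            if a == 0 or b == 0:
                continue
            dosage[i_, l] = (a == counted) + (b == counted)
    return GenotypeMatrix(
        individual_ids=individual_ids,
        population_of=pd.Series(pop_assign),
        locus_ids=[lid for lid, k_ in zip(locus_ids, keep) if k_],
        dosage=dosage[:, keep],
    )


def write_genepop(g: GenotypeMatrix, path, digits: int = 2, title: str = "setscape export") -> None:
    """Write dosages back to Genepop, coding the counted allele as 02/002."""
    w = digits
    lo, hi, miss = str(1).zfill(w), str(2).zfill(w), "0".zfill(w)
    with open(path, "w") as fh:
        fh.write(title + "\n")
        for lid in g.locus_ids:
            fh.write(lid + "\n")
        pops: dict[str, list[int]] = {}
        for idx, iid in enumerate(g.individual_ids):
            pops.setdefault(g.population_of[iid], []).append(idx)
        for pop, idxs in pops.items():
            fh.write("POP\n")
            for idx in idxs:
                codes = []
                for d in g.dosage[idx]:
                    if d == MISSING:
                        codes.append(miss + miss)
                    else:
                        codes.append({0: lo + lo, 1: lo + hi, 2: hi + hi}[int(d)])
                fh.write(f"{g.individual_ids[idx]} , " + " ".join(codes) + "\n")


# ---------------------------------------------------------------------------
# Frequencies
# ---------------------------------------------------------------------------


def frequencies_from_genotypes(g: GenotypeMatrix) -> AlleleFrequencyTable:
    """Per-population counted-allele frequencies; missing calls excluded from
    numerator and denominator."""
    df = g.to_frame()
    groups = g.population_of.reindex(g.individual_ids)
    called = df.notna()
    num = df.fillna(0.0).groupby(groups.values).sum()
    denom = 2.0 * called.groupby(groups.values).sum()
    order = g.population_ids
    num, denom = num.reindex(order), denom.reindex(order)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = num / denom
    freq = freq.where(denom > 0)
    return AlleleFrequencyTable(
        freq=freq, n_alleles=denom.astype(int), gene_of=g.gene_of
    )


def minor_allele_orientation(t: AlleleFrequencyTable) -> AlleleFrequencyTable:
    """Flip loci so the pooled, n-weighted mean frequency is <= 0.5.

    Stand-in for derived-allele orientation when outgroup information is
    unavailable: most derived alleles are expected to remain minor.  A pooled
    mean of exactly 0.5 keeps the reference orientation.
    """
    f = t.freq.to_numpy(float)
    n = t.n_alleles.to_numpy(float)
    with np.errstate(invalid="ignore"):
        pooled = np.nansum(np.nan_to_num(f) * n, axis=0) / np.maximum(n.sum(axis=0), 1)
    flip = pooled > 0.5
    freq = t.freq.copy()
    freq.loc[:, flip] = 1.0 - freq.loc[:, flip]
    return AlleleFrequencyTable(
        freq=freq,
        n_alleles=t.n_alleles.copy(),
        flipped=pd.Series(flip, index=t.freq.columns),
        gene_of=t.gene_of,
    )


# ---------------------------------------------------------------------------
# TreeMix interop
# ---------------------------------------------------------------------------


def _open_maybe_gz(path, mode="rt"):
    path = str(path)
    return gzip.open(path, mode) if path.endswith(".gz") else open(path, mode)


def write_treemix_input(t: AlleleFrequencyTable, path) -> None:
    """TreeMix frequency input: header of population ids, one row per locus of
    'countA,countB' pairs.  Missing cells are written as 0,0."""
    a, b = t.counts()
    with _open_maybe_gz(path, "wt") as fh:
        fh.write(" ".join(t.population_ids) + "\n")
        for l in range(len(t.locus_ids)):
            fh.write(
                " ".join(f"{int(a[i, l])},{int(b[i, l])}" for i in range(len(t.population_ids)))
                + "\n"
            )


def read_treemix_input(path, locus_ids: list[str] | None = None) -> AlleleFrequencyTable:
    with _open_maybe_gz(path) as fh:
        pops = fh.readline().split()
        rows_a, rows_b = [], []
        for line in fh:
            if not line.strip():
                continue
            pairs = [tuple(map(int, tok.split(","))) for tok in line.split()]
            rows_a.append([p[0] for p in pairs])
            rows_b.append([p[1] for p in pairs])
    a = np.array(rows_a, float).T
    b = np.array(rows_b, float).T
    n = a + b
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(n > 0, a / np.maximum(n, 1), np.nan)
    loci = locus_ids or [f"L{i+1}" for i in range(a.shape[1])]
    return AlleleFrequencyTable(
        freq=pd.DataFrame(freq, index=pops, columns=loci),
        n_alleles=pd.DataFrame(n.astype(int), index=pops, columns=loci),
    )


def read_treemix_output(vertices_file, edges_file) -> AdmixtureGraph:
    """Build an :class:`AdmixtureGraph` from TreeMix vertices/edges files.

    Supported dialect: vertices lines start with an integer node index and a
    name (``NA`` for internal nodes) and contain ``ROOT``/``TIP``/``MIG``
    flags; edges lines are ``from to length type`` with type ``MIG`` for
    admixture edges (length then read as the migration weight).
    """
    names: dict[int, str] = {}
    root_idx = None
    n_internal = 0
    with _open_maybe_gz(vertices_file) as fh:
        for line in fh:
            tok = line.split()
            if not tok:
                continue
            idx = int(tok[0])
            name = tok[1]
            flags = set(tok[2:])
            if name == "NA" or "NOT_TIP" in flags and name == "NA":
                n_internal += 1
                name = f"a{n_internal}"
            names[idx] = name
            if "ROOT" in flags:
                root_idx = idx
    edges = []
    with _open_maybe_gz(edges_file) as fh:
        for line in fh:
            tok = line.split()
            if not tok:
                continue
            u, v, w = int(tok[0]), int(tok[1]), float(tok[2])
            is_mig = len(tok) > 3 and tok[3].upper() == "MIG"
            edges.append((u, v, w, is_mig))
    if not edges:
        raise ValueError("edges file contains no edges")
    for u, v, _, _ in edges:
        if u not in names or v not in names:
            raise ValueError(f"edge references unknown vertex: {u}->{v}")
    if root_idx is None:
        targets = {v for _, v, _, m in edges if not m}
        sources = {u for u, _, _, m in edges if not m}
        roots = sources - targets
        if len(roots) != 1:
            raise ValueError("cannot determine a unique root")
        root_idx = roots.pop()
    g = AdmixtureGraph(root=names[root_idx])
    for u, v, w, is_mig in edges:
        if is_mig:
            g.add_admixture_edge(names[u], names[v], weight=w)
        else:
            g.add_tree_edge(names[u], names[v], length=max(w, 0.0))
    g.validate()
    return g


# ---------------------------------------------------------------------------
# Newick + TSV tables
# ---------------------------------------------------------------------------


def write_newick(g: AdmixtureGraph, path=None, strip_admixture: bool = False) -> str:
    """Serialize the tree part of the graph as Newick with drift branch
    lengths.  Admixture edges are rejected unless ``strip_admixture``."""
    if g.admixture_edges() and not strip_admixture:
        raise ValueError("graph has admixture edges; pass strip_admixture=True")
    s = g.to_newick()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(s + "\n")
    return s


def read_table(path) -> pd.DataFrame:
    """TSV with a header row and a leading id column."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_table(df: pd.DataFrame, path, index_label: str = "id") -> None:
    df.to_csv(path, sep="\t", index_label=index_label)


def write_frequency_table(t: AlleleFrequencyTable, freq_path, n_path=None) -> None:
    write_table(t.freq, freq_path, index_label="population")
    if n_path is not None:
        write_table(t.n_alleles, n_path, index_label="population")


def read_frequency_table(freq_path, n_path=None, default_n: int = 100) -> AlleleFrequencyTable:
    freq = read_table(freq_path)
    if n_path is not None:
        n = read_table(n_path).reindex(index=freq.index, columns=freq.columns)
    else:
        n = pd.DataFrame(default_n, index=freq.index, columns=freq.columns)
    n = n.where(freq.notna(), 0).astype(int)
    return AlleleFrequencyTable(freq=freq, n_alleles=n)
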