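"""Synthetic-data generators with known ground truth for every pipeline stage.

Each generator emulates one class of input the pipeline consumes: multi-genus
copy-number censuses with planted expansions, gene trees with planted
duplication/transfer events, codon-aligned sequence pairs evolved at a
controlled dN/dS, saturation-kinetics rate tables, and two-strain competition
counts.  All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import dendropy
import numpy as np
import pandas as pd

from .census import FunctionalCensus
from .selection import _code_tables

__all__ = [
    "CensusSpec",
    "TreeSpec",
    "CodonPairSpec",
    "KineticSimSpec",
    "CompetitionSimSpec",
    "gen_census",
    "gen_gene_tree",
    "gen_codon_pair",
    "gen_kinetic_data",
    "gen_competition",
    "hill_rate",
]


class ConfigurationError(ValueError):
    """A generator spec references entities that do not exist."""


# ---------------------------------------------------------------- census


@dataclass(frozen=True)
class CensusSpec:
    """Layout of a synthetic copy-number census.

    Genomes are grouped into genera, genera into suborders; copy counts are
    Poisson at ``base_copy_rate`` and planted expansions add a fixed amount to
    the Poisson mean of one (group, role) pair.  ``roles`` maps pathway name
    -> list of role names.
    """

    n_suborders: int = 2
    genera_per_suborder: int = 3
    genomes_per_genus: int = 4
    roles: dict[str, list[str]] = field(
        default_factory=lambda: {"GLY": [f"gly_enzyme_{i}" for i in range(1, 6)]}
    )
    base_copy_rate: float = 1.0
    planted_expansions: tuple[tuple[str, str, float], ...] = ()
    seed: int = 0

    def __post_init__(self):
        if min(self.n_suborders, self.genera_per_suborder, self.genomes_per_genus) < 1:
            raise ValueError("all counts must be >= 1")
        if self.base_copy_rate < 0:
            raise ValueError("base_copy_rate must be >= 0")
        for _, _, added in self.planted_expansions:
            if added <= 0:
                raise ValueError("planted added copies must be > 0")

    @property
    def role_list(self) -> list[str]:
        return [r for roles in self.roles.values() for r in roles]


def _taxonomy_frame(spec: CensusSpec) -> pd.DataFrame:
    rows = []
    g = 0
    for s in range(spec.n_suborders):
        suborder = f"Suborder{s + 1:02d}"
        for _ in range(spec.genera_per_suborder):
            g += 1
            genus = f"Genus{g:03d}"
            for k in range(spec.genomes_per_genus):
                rows.append((f"{genus}_genome{k + 1:02d}", genus, suborder))
    return pd.DataFrame(rows, columns=["genome_id", "genus", "suborder"]).set_index(
        "genome_id"
    )


def gen_census(spec: CensusSpec) -> FunctionalCensus:
    """Draw a genome x role copy-count matrix with planted expansions."""
    taxonomy = _taxonomy_frame(spec)
    roles = spec.role_list
    groups = set(taxonomy["genus"]) | set(taxonomy["suborder"])
    for group, role, _ in spec.planted_expansions:
        if group not in groups:
            raise ConfigurationError(f"planted group {group!r} not in taxonomy")
        if role not in roles:
            raise ConfigurationError(f"planted role {role!r} not in role catalog")
    rng = np.random.default_rng(spec.seed)
    lam = np.full((len(taxonomy), len(roles)), float(spec.base_copy_rate))
    for group, role, added in spec.planted_expansions:
        in_group = (
            (taxonomy["genus"] == group) | (taxonomy["suborder"] == group)
        ).to_numpy()
        lam[in_group, roles.index(role)] += added
    counts = pd.DataFrame(
        rng.poisson(lam), index=taxonomy.index, columns=roles, dtype=int
    )
    catalog = {r: name for name, rs in spec.roles.items() for r in rs}
    return FunctionalCensus(counts=counts, taxonomy=taxonomy, role_catalog=catalog)


# ---------------------------------------------------------------- gene trees


@dataclass(frozen=True)
class TreeSpec:
    """Planted-event gene-tree scenario on a given species topology.

    ``duplication_events`` lists the retained lineages of each duplication:
    the clade spanned by those species is replaced by two species-congruent
    copies of itself.  ``hgt_events`` lists (donor species, recipient species)
    pairs: an extra copy of the recipient is grafted as sister to the donor's
    tip, i.e. inside the donor clade.
    """

    species_topology: str
    duplication_events: tuple[tuple[str, ...], ...] = ()
    hgt_events: tuple[tuple[str, str], ...] = ()
    seed: int = 0


def _parse_struct(newick: str):
    tree = dendropy.Tree.get(
        data=newick, schema="newick", rooting="force-rooted",
        suppress_internal_node_taxa=True, preserve_underscores=True,
    )
    labels = [t.label for t in tree.taxon_namespace]
    if len(labels) != len(set(labels)):
        raise ValueError("duplicate tip labels in species topology")

    def rec(node):
        if node.is_leaf():
            return node.taxon.label
        return [rec(c) for c in node.child_nodes()]

    return rec(tree.seed_node)


def _tips(struct) -> list[str]:
    if isinstance(struct, str):
        return [struct]
    out = []
    for c in struct:
        out.extend(_tips(c))
    return out


def _find_mrca(struct, species: set[str]):
    """Smallest subtree containing all of ``species``; None if absent below."""
    if isinstance(struct, str):
        return struct if species == {struct} else None
    if not species.issubset(set(_tips(struct))):
        return None
    for c in struct:
        hit = _find_mrca(c, species)
        if hit is not None:
            return hit
    return struct


def _replace(struct, old, new):
    if struct is old:
        return new
    if isinstance(struct, str):
        return struct
    return [_replace(c, old, new) for c in struct]


def _copy(struct):
    return struct if isinstance(struct, str) else [_copy(c) for c in struct]


def _to_newick(struct) -> str:
    if isinstance(struct, str):
        return struct
    return "(" + ",".join(_to_newick(c) for c in struct) + ")"


def gen_gene_tree(spec: TreeSpec) -> tuple[str, dict[str, str]]:
    """Build a gene tree with planted events; returns (newick, tip->species)."""
    struct = _parse_struct(spec.species_topology)
    species = set(_tips(struct))
    for retained in spec.duplication_events:
        missing = set(retained) - species
        if missing:
            raise ConfigurationError(f"duplication lineages not in species tree: {missing}")
        clade = _find_mrca(struct, set(retained))
        clade_species = set(_tips(clade))
        if clade_species != set(retained):
            raise ConfigurationError(
                "retained lineages must span a full clade "
                f"(clade of {sorted(retained)} also contains "
                f"{sorted(clade_species - set(retained))}); partial retention "
                "(gene loss) is not modelled"
            )
        struct = _replace(struct, clade, [_copy(clade), _copy(clade)])
    for donor, recipient in spec.hgt_events:
        if donor not in species or recipient not in species:
            raise ConfigurationError(f"HGT event ({donor}, {recipient}) not in species tree")
        # graft the transferred copy as sister to the donor tip
        def graft(node):
            if isinstance(node, str):
                return [node, recipient] if node == donor else node
            out = []
            done = False
            for c in node:
                if not done and c == donor:
                    out.append([c, recipient])
                    done = True
                else:
                    out.append(graft(c))
            return out

        struct = graft(struct)
    # assign unique copy labels in tip order
    counts: dict[str, int] = {}
    tip_map: dict[str, str] = {}

    def label(node):
        if isinstance(node, str):
            counts[node] = counts.get(node, 0) + 1
            tip = f"{node}_{counts[node]}"
            tip_map[tip] = node
            return tip
        return [label(c) for c in node]

    labelled = label(struct)
    return _to_newick(labelled) + ";", tip_map


# ---------------------------------------------------------------- codon pairs


@dataclass(frozen=True)
class CodonPairSpec:
    """Divergent codon pair with a controlled nonsynonymous/synonymous ratio.

    Substitutions are proposed uniformly per site; a proposal is scored by
    the pathway-averaged nonsynonymous/synonymous difference increment it
    adds between the ancestral codon and the derived codon, and accepted with
    probability omega^max(d_nonsyn, 0) (for omega <= 1; the reciprocal
    damping applies to synonymous increments when omega > 1).  Proposals
    creating stop codons, or leaving only stop-traversing pathways, are
    always rejected.  At omega = 0 this guarantees that pathway counting
    finds zero nonsynonymous differences.
    """

    n_codons: int = 300
    target_omega: float = 0.5
    expected_substitutions_per_codon: float = 0.3
    seed: int = 0
    table_id: int = 1

    def __post_init__(self):
        if self.n_codons < 10:
            raise ValueError("n_codons must be >= 10")
        if self.target_omega < 0:
            raise ValueError("target_omega must be >= 0")
        if self.expected_substitutions_per_codon < 0:
            raise ValueError("substitution rate must be >= 0")


_NUCS = "ACGT"


def gen_codon_pair(spec: CodonPairSpec) -> tuple[str, str]:
    """Generate two in-frame sequences diverged at the target omega."""
    from .selection import codon_differences

    fwd, stops = _code_tables(spec.table_id)
    sense = sorted(fwd)
    rng = np.random.default_rng(spec.seed)
    codons_a = [sense[i] for i in rng.integers(0, len(sense), size=spec.n_codons)]
    codons_b = list(codons_a)
    n_sub = rng.poisson(spec.expected_substitutions_per_codon * spec.n_codons)
    omega = spec.target_omega
    accepted = 0
    attempts = 0
    max_attempts = 1000 * (n_sub + 1)
    while accepted < n_sub and attempts < max_attempts:
        attempts += 1
        ci = int(rng.integers(0, spec.n_codons))
        pos = int(rng.integers(0, 3))
        codon = codons_b[ci]
        nt = _NUCS[int(rng.integers(0, 4))]
        if nt == codon[pos]:
            continue
        mut = codon[:pos] + nt + codon[pos + 1 :]
        if mut in stops:
            continue
        try:
            nd_new, sd_new = codon_differences(codons_a[ci], mut, spec.table_id)
        except ValueError:  # only stop-traversing pathways would remain
            continue
        nd_cur, sd_cur = codon_differences(codons_a[ci], codon, spec.table_id)
        d_nd = nd_new - nd_cur
        d_sd = sd_new - sd_cur
        if omega <= 1:
            p_accept = omega ** max(d_nd, 0.0)  # 0**0 == 1: pure-syn steps pass
        else:
            p_accept = (1.0 / omega) ** max(d_sd, 0.0)
        if rng.random() < p_accept:
            codons_b[ci] = mut
            accepted += 1
    return "".join(codons_a), "".join(codons_b)


# ---------------------------------------------------------------- kinetics


def hill_rate(s, vmax: float, s50: float, hill_n: float = 1.0):
    """Hill rate law v = Vmax S^n / (S50^n + S^n); n = 1 is Michaelis-Menten."""
    s = np.asarray(s, dtype=float)
    sn = np.power(s, hill_n)
    return vmax * sn / (np.power(s50, hill_n) + sn)


@dataclass(frozen=True)
class KineticSimSpec:
    """Saturation-kinetics rate table with constant-CV multiplicative noise."""

    model: str = "MM"  # "MM" | "Hill"
    vmax: float = 10.0  # U/mg
    s50: float = 0.5  # mM
    hill_n: float = 1.0
    substrate_grid: tuple[float, ...] = (0.05, 0.1, 0.2, 0.5, 1.0, 2.0, 5.0)
    noise_cv: float = 0.05
    replicates: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.model not in ("MM", "Hill"):
            raise ValueError(f"model must be MM or Hill, got {self.model!r}")
        if self.vmax <= 0 or self.s50 <= 0:
            raise ValueError("vmax and s50 must be > 0")
        if self.hill_n < 1:
            raise ValueError("hill_n must be >= 1")
        if self.model == "MM" and self.hill_n != 1:
            raise ValueError("MM model requires hill_n = 1")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if len(self.substrate_grid) == 0:
            raise ValueError("substrate grid must be non-empty")


def gen_kinetic_data(spec: KineticSimSpec) -> pd.DataFrame:
    """Rate table (substrate_mM, rate_U_per_mg, replicate); rates >= 0."""
    rng = np.random.default_rng(spec.seed)
    s = np.asarray(spec.substrate_grid, dtype=float)
    rows = []
    for rep in range(1, spec.replicates + 1):
        v = hill_rate(s, spec.vmax, spec.s50, spec.hill_n)
        v = v * (1.0 + spec.noise_cv * rng.standard_normal(len(s)))
        v = np.clip(v, 0.0, None)
        for si, vi in zip(s, v):
            rows.append((si, vi, rep))
    return pd.DataFrame(rows, columns=["substrate_mM", "rate_U_per_mg", "replicate"])


# ---------------------------------------------------------------- competition


@dataclass(frozen=True)
class CompetitionSimSpec:
    """Two-strain competition: exponential growth with noisy plate counts.

    Defaults mirror a typical assay: ~1e5 CFU inoculum per strain, 68 h of
    growth, triplicate assays.
    """

    m1: float = 0.10  # per hour
    m2: float = 0.10
    n0: float = 1e5  # CFU per strain
    t: float = 68.0  # hours
    count_noise_cv: float = 0.0
    replicates: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.n0 <= 0:
            raise ValueError("n0 must be > 0")
        if self.t <= 0:
            raise ValueError("t must be > 0")
        if self.count_noise_cv < 0:
            raise ValueError("count_noise_cv must be >= 0")


def gen_competition(spec: CompetitionSimSpec) -> pd.DataFrame:
    """Competition table (strain, replicate, n0_cfu, nf_cfu, t_h)."""
    rng = np.random.default_rng(spec.seed)
    rows = []
    for rep in range(1, spec.replicates + 1):
        for strain, m in (("strain1", spec.m1), ("strain2", spec.m2)):
            n0 = spec.n0
            nf = spec.n0 * math.exp(m * spec.t)
            if spec.count_noise_cv > 0:
                n0 = max(n0 * (1.0 + spec.count_noise_cv * rng.standard_normal()), 1.0)
                nf = max(nf * (1.0 + spec.count_noise_cv * rng.standard_normal()), 1.0)
            rows.append((strain, rep, n0, nf, spec.t))
    return pd.DataFrame(rows, columns=["strain", "replicate", "n0_cfu", "nf_cfu", "t_h"])
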