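"""Species/gene-tree congruence and duplication-vs-HGT mechanism calling.

Extra gene copies in a lineage can arise by duplication (the gene tree then
contains two lineage-congruent paralog clades) or by horizontal transfer (the
extra copy sits inside a foreign lineage's clade).  The classifier here
encodes that topological reading as an explicit, reconciliation-free rule and
labels everything it cannot decide as ambiguous.  Trees are treated as rooted
as written.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "PhyloTree",
    "CoverageRecord",
    "MechanismCall",
    "read_newick",
    "write_newick",
    "coverage_filter",
    "congruence_score",
    "classify_mechanism",
]


@dataclass
class PhyloTree:
    """A rooted tree with unique tip labels and a tip -> species map."""

    tree: dendropy.Tree
    tip_to_species: dict[str, str]

    @classmethod
    def from_newick(
        cls, newick: str, tip_to_species: Optional[dict[str, str]] = None
    ) -> "PhyloTree":
        try:
            tree = dendropy.Tree.get(
                data=newick,
                schema="newick",
                rooting="force-rooted",
                suppress_internal_node_taxa=True,
                preserve_underscores=True,
            )
        except Exception as exc:  # dendropy raises several parse error types
            raise ValueError(f"Newick parse error: {exc}") from exc
        tips = [t.label for t in tree.taxon_namespace]
        dups = {t for t in tips if tips.count(t) > 1}
        if dups:
            raise ValueError(f"duplicate tip labels: {sorted(dups)}")
        if tip_to_species is None:
            tip_to_species = {t: t for t in tips}
        missing = set(tips) - set(tip_to_species)
        if missing:
            raise ValueError(f"tips without species mapping: {sorted(missing)}")
        return cls(tree=tree, tip_to_species=dict(tip_to_species))

    @property
    def tips(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    @property
    def species(self) -> set[str]:
        return {self.tip_to_species[t] for t in self.tips}

    def clades(self, nontrivial: bool = True) -> set[frozenset]:
        """Tip-label sets of every internal node (rooted clades)."""
        out = set()
        all_tips = frozenset(self.tips)
        for node in self.tree.preorder_node_iter():
            if node.is_leaf():
                continue
            clade = frozenset(
                leaf.taxon.label for leaf in node.leaf_iter()
            )
            if nontrivial and (len(clade) < 2 or clade == all_tips):
                continue
            out.add(clade)
        return out

    def as_newick(self) -> str:
        return self.tree.as_string(
            schema="newick", suppress_rooting=True, unquoted_underscores=True
        ).strip()


def read_newick(path, tip_to_species: Optional[dict[str, str]] = None) -> PhyloTree:
    return PhyloTree.from_newick(Path(path).read_text(), tip_to_species)


def write_newick(tree: PhyloTree, path) -> None:
    Path(path).write_text(tree.as_newick() + "\n")


# ---------------------------------------------------------------- coverage


@dataclass(frozen=True)
class CoverageRecord:
    """Alignment coverage of a subject sequence against the query."""

    query_id: str
    subject_id: str
    aligned_non_gap_columns: int
    query_length: int

    def __post_init__(self):
        if self.query_length <= 0:
            raise ValueError("query_length must be > 0")
        if self.aligned_non_gap_columns < 0:
            raise ValueError("aligned columns must be >= 0")

    @property
    def coverage(self) -> float:
        return self.aligned_non_gap_columns / self.query_length


def coverage_filter(
    records: Iterable[CoverageRecord], threshold: float = 0.25
) -> list[CoverageRecord]:
    """Retain records whose query coverage is >= threshold (inclusive)."""
    return [r for r in records if r.coverage >= threshold]


# ---------------------------------------------------------------- congruence


def congruence_score(
    tree_a: PhyloTree, tree_b: PhyloTree, seed: int = 0
) -> float:
    """Normalized Robinson-Foulds distance on rooted clades, in [0, 1].

    Species with multiple gene copies are collapsed to one randomly chosen
    copy (fixed seed) so that tips biject onto species; both trees are then
    restricted to the shared species set.  0 = identical clade sets, 1 = no
    shared nontrivial clade.
    """
    rng = np.random.default_rng(seed)

    def collapse(tree: PhyloTree) -> dict[str, str]:
        by_species: dict[str, list[str]] = {}
        for tip in tree.tips:
            by_species.setdefault(tree.tip_to_species[tip], []).append(tip)
        keep = {}
        for sp, tips in sorted(by_species.items()):
            keep[sp] = tips[int(rng.integers(0, len(tips)))] if len(tips) > 1 else tips[0]
        return keep

    keep_a, keep_b = collapse(tree_a), collapse(tree_b)
    shared = set(keep_a) & set(keep_b)
    if not shared:
        raise ValueError("trees share no species")

    def species_clades(tree: PhyloTree, keep: dict[str, str]) -> set[frozenset]:
        kept_tips = {keep[sp] for sp in shared}
        out = set()
        for clade in tree.clades(nontrivial=False):
            restricted = frozenset(
                tree.tip_to_species[t] for t in clade if t in kept_tips
            )
            if len(restricted) >= 2 and restricted != frozenset(shared):
                out.add(restricted)
        return out

    ca = species_clades(tree_a, keep_a)
    cb = species_clades(tree_b, keep_b)
    total = len(ca) + len(cb)
    if total == 0:
        return 0.0
    return len(ca ^ cb) / total


# ---------------------------------------------------------------- mechanism


@dataclass(frozen=True)
class MechanismCall:
    """Mechanism label for one gene copy from a focal-lineage species."""

    focal_lineage: str
    copy_id: str
    mechanism: str  # "duplication" | "hgt" | "ambiguous"
    evidence: str


def _node_species(node, tip_to_species) -> set[str]:
    return {tip_to_species[leaf.taxon.label] for leaf in node.leaf_iter()}


def classify_mechanism(
    species_tree: PhyloTree,
    gene_tree: PhyloTree,
    focal_lineage: set[str],
    lineage_name: str = "focal",
) -> list[MechanismCall]:
    """Label focal-lineage gene copies as duplication, HGT, or ambiguous.

    Rule: partition focal-lineage copies into maximal clades whose tip species
    all lie within the focal lineage.  If at least two such clades exist and
    each spans the full focal-lineage membership, their copies are labelled
    ``duplication`` (the bifurcating duplicated pattern).  A focal-species
    copy whose smallest enclosing clade of >= 2 tips contains only
    foreign-lineage species besides itself is labelled ``hgt``.  Everything
    else is ``ambiguous``.  Species with a single congruent copy produce no
    call (there is no expansion to classify).
    """
    focal_lineage = set(focal_lineage)
    unknown = focal_lineage - species_tree.species
    if unknown:
        raise ValueError(f"focal species not in species tree: {sorted(unknown)}")
    unmapped = set(gene_tree.tips) - set(gene_tree.tip_to_species)
    if unmapped:
        raise ValueError(f"unmapped gene-tree tips: {sorted(unmapped)}")
    tip_sp = gene_tree.tip_to_species

    focal_tips = [t for t in gene_tree.tips if tip_sp[t] in focal_lineage]
    copies_per_species: dict[str, int] = {}
    for t in focal_tips:
        copies_per_species[tip_sp[t]] = copies_per_species.get(tip_sp[t], 0) + 1
    if all(v <= 1 for v in copies_per_species.values()):
        return []  # single-copy: nothing to classify

    # paralog clades: minimal clades inside purely-focal regions whose
    # species set covers the whole focal lineage
    paralog_clades: list[set[str]] = []  # tip-label sets

    def collect_paralogs(node):
        """Descend within a purely-focal subtree to minimal full-coverage clades."""
        sp = _node_species(node, tip_sp)
        if sp != focal_lineage:
            return
        covering_children = [
            c for c in node.child_nodes()
            if _node_species(c, tip_sp) == focal_lineage
        ]
        if not covering_children:
            paralog_clades.append({leaf.taxon.label for leaf in node.leaf_iter()})
            return
        for c in covering_children:
            collect_paralogs(c)

    def walk(node):
        sp = _node_species(node, tip_sp)
        if sp <= focal_lineage:
            collect_paralogs(node)
            return
        for child in node.child_nodes():
            walk(child)

    walk(gene_tree.tree.seed_node)

    dup_tips: set[str] = set()
    full = paralog_clades
    if len(full) >= 2:
        for m in full:
            dup_tips |= m

    # smallest enclosing >=2-tip clade for HGT detection
    leaf_nodes = {leaf.taxon.label: leaf for leaf in gene_tree.tree.leaf_node_iter()}
    calls = []
    for tip in focal_tips:
        if tip in dup_tips:
            calls.append(
                MechanismCall(
                    focal_lineage=lineage_name,
                    copy_id=tip,
                    mechanism="duplication",
                    evidence="member of a species-congruent paralog clade "
                    f"({len(full)} full focal clades)",
                )
            )
            continue
        node = leaf_nodes[tip].parent_node
        while node is not None and sum(1 for _ in node.leaf_iter()) < 2:
            node = node.parent_node
        if node is None:
            mech, why = "ambiguous", "no enclosing clade"
        else:
            others = _node_species(node, tip_sp) - {tip_sp[tip]}
            if others and others.isdisjoint(focal_lineage):
                mech = "hgt"
                why = f"nested within foreign clade of {sorted(others)}"
            else:
                mech = "ambiguous"
                why = "placement neither species-congruent-duplicated nor foreign-nested"
        calls.append(
            MechanismCall(
                focal_lineage=lineage_name, copy_id=tip, mechanism=mech, evidence=why
            )
        )
    return calls


def calls_to_frame(calls: Iterable[MechanismCall]) -> pd.DataFrame:
    return pd.DataFrame([c.__dict__ for c in calls])
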