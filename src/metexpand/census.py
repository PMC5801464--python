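"""Functional-role copy-number census and gene-family expansion calling.

An expansion event is a (taxon group, functional role) pair whose mean copy
number is greater than or equal to the phylum-wide mean of the group means
plus one standard deviation of that role's copy number.  Group means are
computed per genus by default, with suborder-level aggregation available for
pathway-matrix reporting.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

__all__ = [
    "FunctionalCensus",
    "PathwayDefinition",
    "ExpansionCall",
    "PathwayExpansionMatrix",
    "build_census",
    "read_taxonomy",
    "group_means",
    "call_expansions",
    "pathway_matrix",
    "copy_number_summary",
]

LEVELS = ("genus", "suborder")


@dataclass
class FunctionalCensus:
    """Genome x functional-role copy-count matrix with taxonomy labels.

    counts: DataFrame indexed by genome_id, one integer column per role.
    taxonomy: DataFrame indexed by genome_id with columns genus, suborder.
    role_catalog: optional role -> pathway-name map.
    """

    counts: pd.DataFrame
    taxonomy: pd.DataFrame
    role_catalog: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        missing = set(self.counts.index) - set(self.taxonomy.index)
        if missing:
            raise ValueError(
                f"genomes without taxonomy entries: {sorted(missing)[:10]}"
            )
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("copy counts must be nonnegative")
        self.taxonomy = self.taxonomy.loc[self.counts.index]

    @property
    def genomes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def roles(self) -> list[str]:
        return list(self.counts.columns)

    def to_long_frame(self) -> pd.DataFrame:
        """Long-format table (genome_id, genus, suborder, role, count)."""
        long = (
            self.counts.reset_index()
            .melt(id_vars="genome_id", var_name="role", value_name="count")
            .merge(self.taxonomy.reset_index(), on="genome_id")
        )
        return long[["genome_id", "genus", "suborder", "role", "count"]].sort_values(
            ["genome_id", "role"], kind="stable"
        ).reset_index(drop=True)

    def write_tsv(self, path) -> None:
        self.to_long_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "FunctionalCensus":
        long = pd.read_csv(path, sep="\t")
        counts = (
            long.pivot_table(
                index="genome_id", columns="role", values="count", aggfunc="sum"
            )
            .fillna(0)
            .astype(int)
        )
        counts.columns.name = None
        taxonomy = (
            long[["genome_id", "genus", "suborder"]]
            .drop_duplicates()
            .set_index("genome_id")
        )
        return cls(counts=counts.sort_index(), taxonomy=taxonomy.sort_index())


@dataclass(frozen=True)
class PathwayDefinition:
    """Named pathway: ordered enzyme roles; min_size = number of enzymes."""

    name: str
    roles: tuple[str, ...]

    @property
    def min_size(self) -> int:
        return len(self.roles)

    @classmethod
    def load_json(cls, path) -> list["PathwayDefinition"]:
        defs = json.loads(Path(path).read_text())
        out = []
        for d in defs:
            p = cls(name=d["name"], roles=tuple(d["roles"]))
            if "min_size" in d and d["min_size"] != p.min_size:
                raise ValueError(
                    f"pathway {p.name}: min_size {d['min_size']} != {p.min_size} roles"
                )
            out.append(p)
        if len({p.name for p in out}) != len(out):
            raise ValueError("pathway names must be unique")
        return out


@dataclass(frozen=True)
class ExpansionCall:
    """One (group, role) pair scored against the phylum mean + SD threshold."""

    group: str
    role: str
    group_mean: float
    phylum_mean: float
    phylum_sd: float
    flagged: bool


@dataclass
class PathwayExpansionMatrix:
    """(suborder, pathway) percentage matrix; NaN cells mean "no expansion"."""

    percentages: pd.DataFrame  # suborders x pathways, NaN = NE
    flagged_counts: pd.DataFrame  # provenance: flagged (genus, role) pairs per cell
    denominators: pd.DataFrame

    def formatted(self, ne_marker: str = "NE") -> pd.DataFrame:
        """One-decimal strings with the NE marker for empty cells."""
        out = self.percentages.round(1).astype(object)
        return out.where(self.percentages.notna(), ne_marker)

    def write_csv(self, path, ne_marker: str = "NE") -> None:
        self.formatted(ne_marker).to_csv(path)


def read_taxonomy(path) -> pd.DataFrame:
    tax = pd.read_csv(path, sep="\t")
    required = {"genome_id", "genus", "suborder"}
    if not required.issubset(tax.columns):
        raise ValueError(f"taxonomy needs columns {sorted(required)}")
    return tax.set_index("genome_id")


def build_census(
    annotations: pd.DataFrame | str | Path,
    taxonomy: pd.DataFrame,
    role_catalog: Optional[dict[str, str]] = None,
) -> FunctionalCensus:
    """Count annotated features per genome per functional role.

    ``annotations`` is a table (or TSV path) with columns genome_id,
    feature_id, role; duplicate (genome, feature, role) rows are deduplicated
    with a warning, and genomes present in the taxonomy but absent from the
    annotation stream get zero counts for every role.
    """
    if not isinstance(annotations, pd.DataFrame):
        annotations = pd.read_csv(annotations, sep="\t")
    required = {"genome_id", "feature_id", "role"}
    if not required.issubset(annotations.columns):
        raise ValueError(f"annotation table needs columns {sorted(required)}")
    n0 = len(annotations)
    annotations = annotations.drop_duplicates(subset=["genome_id", "feature_id", "role"])
    if len(annotations) < n0:
        warnings.warn(
            f"dropped {n0 - len(annotations)} duplicate (genome, feature) rows",
            stacklevel=2,
        )
    missing = set(annotations["genome_id"]) - set(taxonomy.index)
    if missing:
        raise ValueError(f"genomes without taxonomy entries: {sorted(missing)[:10]}")
    counts = (
        annotations.groupby(["genome_id", "role"], sort=True)
        .size()
        .unstack(fill_value=0)
        .reindex(taxonomy.index, fill_value=0)
        .astype(int)
    )
    counts.columns.name = None
    counts.index.name = "genome_id"
    return FunctionalCensus(
        counts=counts, taxonomy=taxonomy, role_catalog=role_catalog or {}
    )


def _check_level(level: str) -> None:
    if level not in LEVELS:
        raise ValueError(f"level must be one of {LEVELS}, got {level!r}")


def group_means(census: FunctionalCensus, level: str = "genus") -> pd.DataFrame:
    """Mean copy number per (group, role): groups as rows, roles as columns."""
    _check_level(level)
    if census.counts.empty:
        raise ValueError("census is empty")
    return census.counts.groupby(census.taxonomy[level]).mean()


def call_expansions(
    census: FunctionalCensus,
    level: str = "genus",
    sd_multiplier: float = 1.0,
    sd_ddof: int = 1,
) -> list[ExpansionCall]:
    """Flag (group, role) pairs at or above the phylum mean + SD threshold.

    The phylum mean and SD of each role are taken over the group means across
    all groups (sample SD, ddof=1, by default).  The comparison is inclusive:
    group_mean >= phylum_mean + sd_multiplier * phylum_sd.
    """
    means = group_means(census, level)
    if len(means) < 2:
        raise ValueError("need >= 2 groups for the phylum SD to be defined")
    phylum_mean = means.mean(axis=0)
    phylum_sd = means.std(axis=0, ddof=sd_ddof)
    thresh = phylum_mean + sd_multiplier * phylum_sd
    calls = []
    for role in means.columns:
        for group in means.index:
            gm = float(means.at[group, role])
            calls.append(
                ExpansionCall(
                    group=str(group),
                    role=role,
                    group_mean=gm,
                    phylum_mean=float(phylum_mean[role]),
                    phylum_sd=float(phylum_sd[role]),
                    flagged=bool(gm >= thresh[role]),
                )
            )
    return calls


def calls_to_frame(calls: Iterable[ExpansionCall]) -> pd.DataFrame:
    return pd.DataFrame([c.__dict__ for c in calls])


def pathway_matrix(
    calls: Iterable[ExpansionCall],
    pathways: Iterable[PathwayDefinition],
    taxonomy: pd.DataFrame,
) -> PathwayExpansionMatrix:
    """Percentage of expansion events per (suborder, pathway).

    cell = 100 x (flagged (genus, role) pairs with the genus in the suborder
    and the role in the pathway) / (number of genera in the suborder x pathway
    size).  Cells with zero flagged pairs carry NaN ("no expansion").
    """
    pathways = list(pathways)
    calls = list(calls)
    known_roles = {c.role for c in calls}
    for p in pathways:
        unknown = set(p.roles) - known_roles
        if unknown:
            raise ValueError(f"pathway {p.name} references unknown roles: {sorted(unknown)}")
    genus_to_suborder = (
        taxonomy[["genus", "suborder"]].drop_duplicates().set_index("genus")["suborder"]
    )
    n_genera = genus_to_suborder.groupby(genus_to_suborder).size()
    suborders = list(dict.fromkeys(genus_to_suborder.values))
    names = [p.name for p in pathways]
    flagged = pd.DataFrame(0, index=suborders, columns=names, dtype=int)
    denom = pd.DataFrame(0, index=suborders, columns=names, dtype=int)
    for p in pathways:
        for sub in suborders:
            denom.at[sub, p.name] = int(n_genera[sub]) * p.min_size
    roleset = {p.name: set(p.roles) for p in pathways}
    for c in calls:
        if not c.flagged or c.group not in genus_to_suborder.index:
            continue
        sub = genus_to_suborder[c.group]
        for p in pathways:
            if c.role in roleset[p.name]:
                flagged.at[sub, p.name] += 1
    pct = 100.0 * flagged / denom
    pct = pct.where(flagged > 0)
    return PathwayExpansionMatrix(percentages=pct, flagged_counts=flagged, denominators=denom)


@dataclass(frozen=True)
class CopyNumberSummary:
    """Copy-number histogram over a genome partition."""

    histogram: dict[int, int]
    n_genomes: int
    single_copy_percent: int  # rounded to nearest integer for reporting
    single_copy_fraction: float

    @classmethod
    def from_histogram(cls, histogram: dict[int, int]) -> "CopyNumberSummary":
        n = sum(histogram.values())
        if n == 0:
            raise ValueError("empty histogram")
        frac = histogram.get(1, 0) / n
        return cls(
            histogram={int(k): int(v) for k, v in sorted(histogram.items())},
            n_genomes=n,
            single_copy_percent=int(round(100.0 * frac)),
            single_copy_fraction=frac,
        )


def copy_number_summary(
    census: FunctionalCensus, role: str, partition: Optional[Iterable[str]] = None
) -> CopyNumberSummary:
    """Histogram of per-genome copy numbers of one role, plus % single-copy."""
    if role not in census.counts.columns:
        raise ValueError(f"role {role!r} not in census")
    genomes = list(partition) if partition is not None else census.genomes
    if not genomes:
        raise ValueError("empty genome partition")
    unknown = set(genomes) - set(census.genomes)
    if unknown:
        raise ValueError(f"partition genomes not in census: {sorted(unknown)[:10]}")
    values = census.counts.loc[genomes, role]
    hist = values.value_counts().sort_index()
    frac = float((values == 1).sum()) / len(genomes)
    return CopyNumberSummary(
        histogram={int(k): int(v) for k, v in hist.items()},
        n_genomes=len(genomes),
        single_copy_percent=int(round(100.0 * frac)),
        single_copy_fraction=frac,
    )
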