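"""End-to-end pipeline: wire the stages into one reproducible run.

A run executes the enabled stages in dependency order (census -> phylo ->
selection, with kinetics and phenotype independent), writes per-stage CSVs, a
machine-readable ``summary.json`` and a human-readable ``report.md``.  All
randomness derives from a single global seed fanned out to per-stage
substreams, so stage-level reruns reproduce in isolation.
"""

from __future__ import annotations

import json
import logging
import math
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import census as census_mod
from . import kinetics as kin
from . import phenotype as phen
from . import phylo as phylo_mod
from . import selection as sel
from . import synth

log = logging.getLogger(__name__)

STAGES = ("census", "phylo", "selection", "kinetics", "phenotype")

# fixed per-stage substream indices: renaming or reordering STAGES must not
# silently change another stage's stream
_STAGE_STREAM = {name: i for i, name in enumerate(STAGES)}


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage substream seed (< 2^31)."""
    ss = np.random.SeedSequence(entropy=global_seed, spawn_key=(_STAGE_STREAM[stage],))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """Configuration of one pipeline run (JSON-serialisable)."""

    stages: tuple[str, ...] = STAGES
    seed: int = 0
    out_dir: Optional[str] = None
    grouping_level: str = "genus"
    expansion_sd_multiplier: float = 1.0
    coverage_threshold: float = 0.25
    n_bootstrap: int = 200
    alpha: float = 0.05

    def __post_init__(self):
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        doc = json.loads(Path(path).read_text())
        if "stages" in doc:
            doc["stages"] = tuple(doc["stages"])
        return cls(**doc)


@dataclass
class RunReport:
    """Stage outputs of one run; ``summary`` is the JSON-stable view."""

    config: RunConfig
    summary: dict = field(default_factory=dict)
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    failures: dict[str, str] = field(default_factory=dict)


def _round_floats(obj, ndigits=10):
    if isinstance(obj, float):
        return None if math.isnan(obj) else round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def _stage_census(config: RunConfig, report: RunReport) -> None:
    seed = stage_seed(config.seed, "census")
    spec = synth.CensusSpec(
        n_suborders=3,
        genera_per_suborder=7,
        genomes_per_genus=4,
        roles={
            "GLY": [f"gly_enzyme_{i}" for i in range(1, 11)],
            "TCA": [f"tca_enzyme_{i}" for i in range(1, 8)],
        },
        base_copy_rate=1.0,
        planted_expansions=(
            ("Genus001", "gly_enzyme_1", 3.0),
            ("Genus002", "gly_enzyme_2", 3.0),
            ("Genus008", "tca_enzyme_1", 3.0),
        ),
        seed=seed,
    )
    cen = synth.gen_census(spec)
    calls = census_mod.call_expansions(
        cen, level=config.grouping_level, sd_multiplier=config.expansion_sd_multiplier
    )
    pathways = [
        census_mod.PathwayDefinition(name, tuple(roles))
        for name, roles in spec.roles.items()
    ]
    matrix = census_mod.pathway_matrix(calls, pathways, cen.taxonomy)
    calls_df = census_mod.calls_to_frame(calls)
    report.tables["expansion_calls"] = calls_df
    report.tables["pathway_matrix"] = matrix.formatted()
    report.summary["census"] = {
        "n_genomes": len(cen.genomes),
        "n_roles": len(cen.roles),
        "n_flagged": int(calls_df["flagged"].sum()),
        "flagged_pairs": sorted(
            calls_df.loc[calls_df["flagged"], ["group", "role"]]
            .itertuples(index=False, name=None)
        ),
        "planted": [list(p[:2]) for p in spec.planted_expansions],
    }


def _stage_phylo(config: RunConfig, report: RunReport) -> None:
    seed = stage_seed(config.seed, "phylo")
    species_newick = "(((A,B),(C,D)),(E,F));"
    spec = synth.TreeSpec(
        species_topology=species_newick,
        duplication_events=(("A", "B", "C", "D"),),
        hgt_events=(("E", "A"),),
        seed=seed,
    )
    gene_newick, tip_map = synth.gen_gene_tree(spec)
    species_tree = phylo_mod.PhyloTree.from_newick(species_newick)
    gene_tree = phylo_mod.PhyloTree.from_newick(gene_newick, tip_map)
    calls = phylo_mod.classify_mechanism(
        species_tree, gene_tree, {"A", "B", "C", "D"}, lineage_name="focal_clade"
    )
    score = phylo_mod.congruence_score(species_tree, gene_tree, seed=seed)
    calls_df = phylo_mod.calls_to_frame(calls)
    report.tables["mechanism_calls"] = calls_df
    report.summary["phylo"] = {
        "congruence_rf": score,
        "n_duplication": int((calls_df["mechanism"] == "duplication").sum()),
        "n_hgt": int((calls_df["mechanism"] == "hgt").sum()),
        "n_ambiguous": int((calls_df["mechanism"] == "ambiguous").sum()),
    }


def _stage_selection(config: RunConfig, report: RunReport) -> None:
    seed = stage_seed(config.seed, "selection")
    rows = []
    for i, omega in enumerate((0.1, 0.5, 1.0)):
        spec = synth.CodonPairSpec(
            n_codons=500,
            target_omega=omega,
            expected_substitutions_per_codon=0.3,
            seed=seed + i,
        )
        a, b = synth.gen_codon_pair(spec)
        res = sel.dnds(
            sel.CodonAlignmentPair(a, b),
            n_bootstrap=config.n_bootstrap,
            seed=seed + i,
        )
        rows.append(
            {
                "target_omega": omega,
                "omega": res.omega,
                "se_omega": res.se_omega,
                "dn": res.dn,
                "ds": res.ds,
                "pn": res.pn,
                "ps": res.ps,
            }
        )
    df = pd.DataFrame(rows)
    report.tables["dnds"] = df
    report.summary["selection"] = _round_floats(df.to_dict(orient="records"))


def _stage_kinetics(config: RunConfig, report: RunReport) -> None:
    seed = stage_seed(config.seed, "kinetics")
    # generating parameters: the ADP-saturation (hyperbolic) and PEP-saturation
    # (cooperative) regimes of the two pyruvate-kinase isoforms with 1 mM AMP
    scenarios = [
        ("Pyk1_ADP_AMP", "MM", dict(vmax=73.3, s50=0.2, hill_n=1.0),
         tuple(np.geomspace(0.05, 5.0, 8))),
        ("Pyk2_ADP_AMP", "MM", dict(vmax=6.7, s50=0.1, hill_n=1.0),
         tuple(np.geomspace(0.02, 2.0, 8))),
        ("Pyk1_PEP_AMP", "Hill", dict(vmax=65.5, s50=1.1, hill_n=1.8),
         tuple(np.geomspace(0.2, 10.0, 10))),
        ("Pyk2_PEP_AMP", "Hill", dict(vmax=9.1, s50=8.6, hill_n=7.1),
         tuple(np.linspace(1.0, 20.0, 10))),
    ]
    rows = []
    for i, (label, model, params, grid) in enumerate(scenarios):
        spec = synth.KineticSimSpec(
            model=model, substrate_grid=grid, noise_cv=0.05, replicates=3,
            seed=seed + i, **params,
        )
        data = synth.gen_kinetic_data(spec)
        fit = kin.fit_mm(data) if model == "MM" else kin.fit_hill(data)
        rows.append(
            {
                "condition": label,
                "model": fit.model,
                "vmax": fit.vmax,
                "s50": fit.s50,
                "hill_n": fit.hill_n,
                "true_vmax": params["vmax"],
                "true_s50": params["s50"],
                "true_hill_n": params["hill_n"],
                "rss": fit.rss,
            }
        )
    df = pd.DataFrame(rows)
    report.tables["kinetic_fits"] = df
    report.summary["kinetics"] = _round_floats(df.to_dict(orient="records"))


def _stage_phenotype(config: RunConfig, report: RunReport) -> None:
    seed = stage_seed(config.seed, "phenotype")
    scenarios = [
        ("self_competition", synth.CompetitionSimSpec(m1=0.10, m2=0.10, seed=seed)),
        ("mutant_vs_wt", synth.CompetitionSimSpec(
            m1=0.09, m2=0.10, count_noise_cv=0.05, seed=seed + 1)),
    ]
    rows = []
    for label, spec in scenarios:
        res = phen.relative_fitness(synth.gen_competition(spec))
        rows.append(
            {
                "assay": label,
                "mean_w": res.mean_w,
                "sd_w": res.sd_w,
                "p_value_vs_1": res.p_value_vs_1,
                "true_w": spec.m1 / spec.m2,
            }
        )
    df = pd.DataFrame(rows)
    report.tables["fitness"] = df
    report.summary["phenotype"] = _round_floats(df.to_dict(orient="records"))


_STAGE_FN = {
    "census": _stage_census,
    "phylo": _stage_phylo,
    "selection": _stage_selection,
    "kinetics": _stage_kinetics,
    "phenotype": _stage_phenotype,
}

_DEPENDENTS = {"census": ("phylo", "selection"), "phylo": ("selection",)}


def run(config: RunConfig) -> RunReport:
    """Execute the enabled stages on synthetic demo data.

    A stage failure aborts its dependents but not independent stages; partial
    results are kept and failures recorded in the report.
    """
    report = RunReport(config=config)
    aborted: set[str] = set()
    for stage in STAGES:
        if stage not in config.stages:
            continue
        if stage in aborted:
            report.failures[stage] = "aborted: upstream stage failed"
            continue
        t0 = time.perf_counter()
        try:
            _STAGE_FN[stage](config, report)
            log.info("stage %s finished in %.2fs", stage, time.perf_counter() - t0)
        except Exception as exc:
            log.error("stage %s failed: %s", stage, exc)
            report.failures[stage] = str(exc)
            for dep in _DEPENDENTS.get(stage, ()):
                aborted.add(dep)
    report.summary = _round_floats(report.summary)
    report.summary["config"] = asdict(config)
    report.summary["config"]["stages"] = list(config.stages)
    del report.summary["config"]["out_dir"]  # path is environment, not content
    report.summary["failures"] = dict(report.failures)
    if config.out_dir is not None:
        _write_outputs(report, Path(config.out_dir))
    return report


def _write_outputs(report: RunReport, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "summary.json").write_text(
        json.dumps(report.summary, indent=2, sort_keys=True) + "\n"
    )
    for name, df in report.tables.items():
        df.to_csv(out_dir / f"{name}.csv", index=name == "pathway_matrix")
    (out_dir / "report.md").write_text(render_report(report))


def render_report(report: RunReport) -> str:
    lines = ["# Pipeline report", ""]
    for name, df in report.tables.items():
        lines.append(f"## {name}")
        lines.append("")
        lines.append(df.to_string(index=name == "pathway_matrix"))
        lines.append("")
    if report.failures:
        lines.append("## failures")
        for stage, msg in report.failures.items():
            lines.append(f"- {stage}: {msg}")
        lines.append("")
    return "\n".join(lines)


def consistency_check(recomputed: dict, printed_values: dict) -> pd.DataFrame:
    """Compare recomputed quantities against printed reference values.

    ``printed_values`` maps keys to numbers as printed (strings keep trailing
    precision, e.g. "73.3"); comparison is rounding-aware: a recomputed value
    passes when it rounds to the printed value at the printed precision.
    Unknown keys are listed with status "unknown key" rather than failing.
    """
    rows = []
    for key, printed in printed_values.items():
        if key not in recomputed:
            rows.append({"key": key, "printed": printed, "recomputed": None,
                         "abs_diff": None, "status": "unknown key"})
            continue
        value = float(recomputed[key])
        text = str(printed).replace(",", "")
        decimals = len(text.split(".")[1]) if "." in text else 0
        target = float(text)
        diff = abs(value - target)
        ok = round(value, decimals) == round(target, decimals) or diff <= 0.5 * 10**-decimals
        rows.append({"key": key, "printed": printed, "recomputed": value,
                     "abs_diff": diff, "status": "pass" if ok else "discrepancy"})
    return pd.DataFrame(rows, columns=["key", "printed", "recomputed", "abs_diff", "status"])
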