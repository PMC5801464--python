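"""Competitive-fitness, qPCR fold-change and specific-yield statistics.

Relative fitness follows the head-to-head competition design: each strain's
net (Malthusian) growth rate is m = ln(Nf/N0)/t from plate counts at the
start and end of co-culture, and the fitness of strain 1 relative to strain 2
is W = m1/m2.  Expression fold changes use the delta-delta-Ct method against
a reference gene (hrdB by default), generalised to an arbitrary amplification
efficiency E via fold = E^(-ddCt).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CompetitionAssay",
    "FitnessResult",
    "QpcrSet",
    "malthusian",
    "relative_fitness",
    "ddct_fold_change",
    "specific_yield",
]


def malthusian(n0: float, nf: float, t: float) -> float:
    """Net growth rate m = ln(nf/n0)/t in h^-1; negative rates allowed."""
    if n0 <= 0 or nf <= 0:
        raise ValueError("CFU counts must be > 0")
    if t <= 0:
        raise ValueError("duration must be > 0")
    return math.log(nf / n0) / t


@dataclass
class CompetitionAssay:
    """Paired CFU counts for two competing strains over a shared duration.

    data columns: strain, replicate, n0_cfu, nf_cfu, t_h.  Exactly two strain
    labels must be present, each once per replicate.
    """

    data: pd.DataFrame
    strain_1: Optional[str] = None
    strain_2: Optional[str] = None

    def __post_init__(self):
        required = {"strain", "replicate", "n0_cfu", "nf_cfu", "t_h"}
        if not required.issubset(self.data.columns):
            raise ValueError(f"competition table needs columns {sorted(required)}")
        strains = list(dict.fromkeys(self.data["strain"]))
        if len(strains) != 2:
            raise ValueError(f"need exactly 2 strains, got {strains}")
        if self.strain_1 is None:
            self.strain_1, self.strain_2 = strains
        if (self.data[["n0_cfu", "nf_cfu"]] <= 0).any().any():
            raise ValueError("CFU counts must be > 0")
        if (self.data["t_h"] <= 0).any():
            raise ValueError("durations must be > 0")
        per_rep = self.data.groupby("replicate")["strain"].nunique()
        if (per_rep != 2).any():
            raise ValueError("every replicate needs both strains")


@dataclass
class FitnessResult:
    """Per-replicate Malthusian rates and relative fitness, with summaries."""

    per_replicate: pd.DataFrame  # replicate, m1, m2, w
    strain_1: str
    strain_2: str
    mean_w: float
    sd_w: float
    t_stat_vs_1: Optional[float]
    p_value_vs_1: Optional[float]
    n_excluded: int = 0

    def significance_stars(self, thresholds=(0.05, 0.01, 0.001)) -> str:
        if self.p_value_vs_1 is None:
            return ""
        return "*" * sum(self.p_value_vs_1 <= t for t in thresholds)

    def summary(self) -> str:
        lines = [
            f"Relative fitness of {self.strain_1} vs {self.strain_2} "
            f"({len(self.per_replicate)} replicates)",
            f"  mean W = {self.mean_w:.4g} (SD {self.sd_w:.4g})",
        ]
        if self.p_value_vs_1 is not None:
            lines.append(
                f"  one-sample t vs W=1: t = {self.t_stat_vs_1:.3g}, "
                f"p = {self.p_value_vs_1:.3g} {self.significance_stars()}"
            )
        return "\n".join(lines)


def relative_fitness(assay: CompetitionAssay | pd.DataFrame) -> FitnessResult:
    """Per-replicate W = m1/m2 with mean, SD and a one-sample t-test vs 1.

    Replicates where the competitor's rate is zero are excluded with a
    warning.  The t-test (two-sided, vs W = 1) needs >= 2 informative
    replicates with nonzero spread; otherwise the test fields are None.
    """
    if isinstance(assay, pd.DataFrame):
        assay = CompetitionAssay(assay)
    rows = []
    excluded = 0
    for rep, grp in assay.data.groupby("replicate"):
        r1 = grp[grp["strain"] == assay.strain_1].iloc[0]
        r2 = grp[grp["strain"] == assay.strain_2].iloc[0]
        m1 = malthusian(r1["n0_cfu"], r1["nf_cfu"], r1["t_h"])
        m2 = malthusian(r2["n0_cfu"], r2["nf_cfu"], r2["t_h"])
        if m2 == 0:
            warnings.warn(
                f"replicate {rep}: competitor growth rate is zero, excluded",
                stacklevel=2,
            )
            excluded += 1
            continue
        rows.append((rep, m1, m2, m1 / m2))
    if not rows:
        raise ValueError("no informative replicates")
    per_rep = pd.DataFrame(rows, columns=["replicate", "m1", "m2", "w"])
    w = per_rep["w"].to_numpy()
    mean_w = float(np.mean(w))
    sd_w = float(np.std(w, ddof=1)) if len(w) > 1 else 0.0
    t_stat = p_val = None
    if len(w) >= 2 and sd_w > 0:
        t_res = stats.ttest_1samp(w, popmean=1.0)
        t_stat, p_val = float(t_res.statistic), float(t_res.pvalue)
    return FitnessResult(
        per_replicate=per_rep,
        strain_1=assay.strain_1,
        strain_2=assay.strain_2,
        mean_w=mean_w,
        sd_w=sd_w,
        t_stat_vs_1=t_stat,
        p_value_vs_1=p_val,
        n_excluded=excluded,
    )


def compare_fitness(a: FitnessResult, b: FitnessResult) -> tuple[float, float]:
    """Welch two-sample t-test between the per-replicate W of two assays."""
    res = stats.ttest_ind(
        a.per_replicate["w"], b.per_replicate["w"], equal_var=False
    )
    return float(res.statistic), float(res.pvalue)


@dataclass
class QpcrSet:
    """Ct values for target and reference genes across conditions.

    data columns: sample, condition, gene, ct.  The reference gene must be
    measured in every sample.
    """

    data: pd.DataFrame
    reference_gene: str = "hrdB"
    efficiency: float = 2.0  # amplification factor per cycle; 2.0 = 100%

    def __post_init__(self):
        required = {"sample", "condition", "gene", "ct"}
        if not required.issubset(self.data.columns):
            raise ValueError(f"qPCR table needs columns {sorted(required)}")
        if (self.data["ct"] <= 0).any():
            raise ValueError("Ct values must be > 0")
        samples = set(self.data["sample"])
        with_ref = set(self.data.loc[self.data["gene"] == self.reference_gene, "sample"])
        if samples - with_ref:
            raise ValueError(
                f"samples missing reference gene {self.reference_gene!r}: "
                f"{sorted(samples - with_ref)}"
            )


def ddct_fold_change(
    qpcr: QpcrSet,
    target_gene: str,
    condition_a: str,
    condition_b: str,
) -> dict:
    """Delta-delta-Ct fold change of condition_a relative to condition_b.

    dCt = Ct_target - Ct_reference per sample; ddCt = mean dCt(a) - mean
    dCt(b); fold = E^(-ddCt) with E the amplification efficiency (2.0 at
    100%).  A Welch t-test on the per-sample dCt values accompanies the
    estimate when both conditions have >= 2 samples.
    """
    data = qpcr.data

    def dcts(condition: str) -> np.ndarray:
        sub = data[data["condition"] == condition]
        if sub.empty:
            raise ValueError(f"no samples for condition {condition!r}")
        tgt = sub[sub["gene"] == target_gene].set_index("sample")["ct"]
        ref = sub[sub["gene"] == qpcr.reference_gene].set_index("sample")["ct"]
        if tgt.empty:
            raise ValueError(f"no {target_gene!r} measurements in {condition!r}")
        common = tgt.index.intersection(ref.index)
        return (tgt.loc[common] - ref.loc[common]).to_numpy(dtype=float)

    d_a, d_b = dcts(condition_a), dcts(condition_b)
    ddct = float(np.mean(d_a) - np.mean(d_b))
    fold = float(qpcr.efficiency ** (-ddct))
    t_stat = p_val = None
    if len(d_a) >= 2 and len(d_b) >= 2 and (np.std(d_a) > 0 or np.std(d_b) > 0):
        res = stats.ttest_ind(d_a, d_b, equal_var=False)
        t_stat, p_val = float(res.statistic), float(res.pvalue)
    return {
        "target_gene": target_gene,
        "condition_a": condition_a,
        "condition_b": condition_b,
        "ddct": ddct,
        "fold_change": fold,
        "t_stat": t_stat,
        "p_value": p_val,
    }


def specific_yield(absorbance_au: float, biomass_mg: float) -> float:
    """Specific metabolite yield in AU per mg biomass.

    Negative absorbances (blank over-subtraction) are clamped to zero with a
    warning rather than propagating a negative yield.
    """
    if biomass_mg <= 0:
        raise ValueError("biomass must be > 0")
    if absorbance_au < 0:
        warnings.warn(
            f"negative absorbance {absorbance_au} clamped to 0 (blank over-subtraction)",
            stacklevel=2,
        )
        absorbance_au = 0.0
    return absorbance_au / biomass_mg
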