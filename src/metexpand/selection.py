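"""Pairwise dN/dS by the Nei-Gojobori counting method with Jukes-Cantor correction.

The method assigns each codon position a fractional synonymous-site content
(the fraction of its single-nucleotide mutants that preserve the amino acid),
and averages synonymous/nonsynonymous step counts over every mutational
pathway between two codons.  Observed proportions pN = Nd/N and pS = Sd/S are
corrected for multiple hits with the Jukes-Cantor distance, and omega = dN/dS
summarises selective pressure (omega < 1: purifying selection).

Conventions (the upstream tooling this mirrors does not pin them down, so they
are explicit and configurable here):

* mutations to stop codons are excluded from the per-position site
  denominator, each position still contributing unit site mass, so
  N + S = 3 x (number of codons) exactly;
* mutational pathways that traverse a stop codon are dropped and the average
  renormalised over the surviving pathways;
* codons containing non-ACGT symbols in either sequence are removed pairwise
  (the count of dropped codons is reported).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import permutations
from typing import Optional

import numpy as np
from Bio.Data import CodonTable

__all__ = [
    "CodonAlignmentPair",
    "NGCounts",
    "DnDsResult",
    "codon_sites",
    "codon_differences",
    "nei_gojobori",
    "jukes_cantor",
    "dnds",
]

_NUCS = "ACGT"


def _code_tables(table_id: int = 1):
    """Return (codon -> amino acid map over sense codons, set of stop codons)."""
    table = CodonTable.unambiguous_dna_by_id[table_id]
    return dict(table.forward_table), set(table.stop_codons)


class SaturationError(ValueError):
    """Raised when an observed proportion is outside the Jukes-Cantor domain."""


class StopCodonError(ValueError):
    """Raised for stop codons where a sense codon is required."""


@dataclass(frozen=True)
class CodonAlignmentPair:
    """An in-frame, codon-aligned pair of nucleotide sequences.

    Codons with non-ACGT symbols are tolerated at construction and dropped
    pairwise during counting; internal stop codons are rejected outright.
    """

    seq_a: str
    seq_b: str
    table_id: int = 1

    def __post_init__(self):
        a = self.seq_a.upper()
        b = self.seq_b.upper()
        object.__setattr__(self, "seq_a", a)
        object.__setattr__(self, "seq_b", b)
        if len(a) != len(b):
            raise ValueError(f"sequence lengths differ: {len(a)} vs {len(b)}")
        if len(a) % 3 != 0:
            raise ValueError(f"length {len(a)} is not a multiple of 3")
        _, stops = _code_tables(self.table_id)
        for name, seq in (("seq_a", a), ("seq_b", b)):
            for i in range(0, len(seq), 3):
                if seq[i : i + 3] in stops:
                    raise ValueError(f"internal stop codon in {name} at nt {i}")

    @property
    def n_codons(self) -> int:
        return len(self.seq_a) // 3

    def codons(self):
        """Yield (codon_a, codon_b) tuples, including ambiguous ones."""
        for i in range(0, len(self.seq_a), 3):
            yield self.seq_a[i : i + 3], self.seq_b[i : i + 3]


@dataclass
class NGCounts:
    """Fractional site and difference counts for one sequence pair."""

    n_sites: float
    s_sites: float
    nd: float
    sd: float
    n_codons_used: int
    n_codons_dropped: int = 0

    @property
    def pn(self) -> float:
        return self.nd / self.n_sites if self.n_sites > 0 else 0.0

    @property
    def ps(self) -> Optional[float]:
        if self.s_sites == 0:
            return None
        return self.sd / self.s_sites


@dataclass
class DnDsResult:
    """Corrected distances and their ratio, with bootstrap uncertainty."""

    counts: NGCounts
    pn: float
    ps: Optional[float]
    dn: float
    ds: Optional[float]
    omega: Optional[float]
    se_omega: Optional[float]
    n_bootstrap: int
    seed: Optional[int]
    purifying: Optional[bool] = field(default=None)

    def __post_init__(self):
        if self.omega is not None and self.purifying is None:
            self.purifying = self.omega < 1.0


def codon_sites(codon: str, table_id: int = 1) -> tuple[float, float]:
    """Fractional (nonsynonymous, synonymous) site counts of a sense codon.

    Per position, the synonymous fraction is #synonymous single-nucleotide
    mutants / #non-stop single-nucleotide mutants; n + s = 3 always.
    """
    codon = codon.upper()
    fwd, stops = _code_tables(table_id)
    if codon in stops:
        raise StopCodonError(f"stop codon {codon} has no site decomposition")
    if codon not in fwd:
        raise ValueError(f"not a valid codon: {codon!r}")
    aa = fwd[codon]
    s = 0.0
    for pos in range(3):
        syn = 0
        valid = 0
        for nt in _NUCS:
            if nt == codon[pos]:
                continue
            mut = codon[:pos] + nt + codon[pos + 1 :]
            if mut in stops:
                continue
            valid += 1
            if fwd[mut] == aa:
                syn += 1
        if valid:
            s += syn / valid
    return 3.0 - s, s


def codon_differences(
    codon_a: str, codon_b: str, table_id: int = 1
) -> tuple[float, float]:
    """Average (nonsynonymous, synonymous) step counts over mutational pathways.

    All orderings of the differing positions are enumerated; pathways passing
    through a stop codon are excluded and the remainder renormalised.
    """
    codon_a, codon_b = codon_a.upper(), codon_b.upper()
    fwd, stops = _code_tables(table_id)
    for c in (codon_a, codon_b):
        if c in stops:
            raise StopCodonError(f"stop codon {c} in difference counting")
        if c not in fwd:
            raise ValueError(f"not a valid codon: {c!r}")
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return 0.0, 0.0
    pathways = []
    for order in permutations(diff_pos):
        cur = codon_a
        nd = sd = 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
            if nxt in stops:
                ok = False
                break
            if fwd[nxt] == fwd[cur]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            pathways.append((nd, sd))
    if not pathways:
        raise ValueError(
            f"all mutational pathways between {codon_a} and {codon_b} "
            "traverse stop codons"
        )
    nd = sum(p[0] for p in pathways) / len(pathways)
    sd = sum(p[1] for p in pathways) / len(pathways)
    return nd, sd


def _is_unambiguous(codon: str) -> bool:
    return all(c in _NUCS for c in codon)


def nei_gojobori(
    pair: CodonAlignmentPair, codon_indices: Optional[np.ndarray] = None
) -> NGCounts:
    """Site and difference counts for a pair, averaged over both sequences.

    ``codon_indices`` restricts/reweights the codon columns used (bootstrap
    support); by default every unambiguous column is used once.
    """
    codons = list(pair.codons())
    if codon_indices is None:
        codon_indices = np.arange(len(codons))
    n_a = s_a = n_b = s_b = 0.0
    nd = sd = 0.0
    used = 0
    dropped = 0
    for i in codon_indices:
        ca, cb = codons[int(i)]
        if not (_is_unambiguous(ca) and _is_unambiguous(cb)):
            dropped += 1
            continue
        na, sa = codon_sites(ca, pair.table_id)
        nb, sb = codon_sites(cb, pair.table_id)
        n_a += na
        s_a += sa
        n_b += nb
        s_b += sb
        d_n, d_s = codon_differences(ca, cb, pair.table_id)
        nd += d_n
        sd += d_s
        used += 1
    return NGCounts(
        n_sites=(n_a + n_b) / 2.0,
        s_sites=(s_a + s_b) / 2.0,
        nd=nd,
        sd=sd,
        n_codons_used=used,
        n_codons_dropped=dropped,
    )


def jukes_cantor(p: float) -> float:
    """Jukes-Cantor multiple-hit correction d = -(3/4) ln(1 - 4p/3)."""
    if p < 0:
        raise ValueError(f"proportion must be nonnegative, got {p}")
    if p >= 0.75:
        raise SaturationError(
            f"proportion {p} >= 0.75: Jukes-Cantor distance undefined (saturation)"
        )
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def _omega_from_counts(counts: NGCounts) -> tuple[float, Optional[float], Optional[float]]:
    """(dn, ds, omega) from counts; ds/omega None when undefined."""
    dn = jukes_cantor(counts.pn)
    ps = counts.ps
    if ps is None:
        return dn, None, None
    ds = jukes_cantor(ps)
    if ds == 0.0:
        return dn, ds, None
    return dn, ds, dn / ds


def dnds(
    pair: CodonAlignmentPair,
    n_bootstrap: int = 1000,
    seed: Optional[int] = None,
) -> DnDsResult:
    """Pairwise dN/dS with a codon-column bootstrap standard error.

    The bootstrap resamples codon columns with replacement and recomputes
    omega; replicates where omega is undefined (ds = 0 or saturated) are
    discarded from the SE.
    """
    counts = nei_gojobori(pair)
    dn, ds, omega = _omega_from_counts(counts)
    se = None
    if n_bootstrap > 0 and omega is not None:
        rng = np.random.default_rng(seed)
        n = len(list(pair.codons()))
        reps = []
        for _ in range(n_bootstrap):
            idx = rng.integers(0, n, size=n)
            c = nei_gojobori(pair, codon_indices=idx)
            try:
                _, _, w = _omega_from_counts(c)
            except SaturationError:
                continue
            if w is not None:
                reps.append(w)
        if len(reps) >= 2:
            se = float(np.std(reps, ddof=1))
    return DnDsResult(
        counts=counts,
        pn=counts.pn,
        ps=counts.ps,
        dn=dn,
        ds=ds,
        omega=omega,
        se_omega=se,
        n_bootstrap=n_bootstrap,
        seed=seed,
    )
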