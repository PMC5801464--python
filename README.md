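# metexpand

Analysis toolkit for studying **metabolic gene-family expansion in
actinobacteria** and the **functional divergence of duplicated enzymes**,
with pyruvate kinase (PK) as the flagship case.  Specialized-metabolite
producers such as *Streptomyces* carry extra copies of central-metabolic
enzymes; this package provides the computational stages needed to detect
those expansions in a genome census, decide whether each arose by gene
duplication or horizontal gene transfer (HGT), quantify the selection acting
on duplicate pairs, and characterise the biochemical and fitness divergence
of the retained copies.

It is aimed at comparative genomicists and enzymologists who have
RAST-style functional annotations, species/gene trees, codon alignments,
enzyme-assay rate tables or competition plate counts — or who want to test
the whole pipeline on synthetic data with known ground truth.

## The five analysis stages

1. **Expansion census** (`metexpand.census`).  From a genome × functional-role
   copy-count matrix, a *gene expansion event* is a (group, role) pair whose
   mean copy number satisfies

   ```
   mean(group) >= mean(phylum) + SD(phylum)
   ```

   where the phylum mean and (sample) SD are taken over the per-genus means
   of that role.  Pathway-level expansion percentages are reported per
   suborder as `100 · n_flagged / (n_genera · pathway_size)`, with `NE`
   marking cells without any expansion.

2. **Duplication vs HGT** (`metexpand.phylo`).  Gene copies from a focal
   lineage are classified by explicit tree-topology rules: two (or more)
   species-congruent paralog clades ⇒ *duplication*; a copy nested inside a
   foreign lineage's clade ⇒ *HGT*; anything else ⇒ *ambiguous*.  Congruence
   between species and gene trees is scored as a normalized Robinson–Foulds
   distance on rooted clades, and a 25 % alignment-coverage filter mirrors
   the curation rule used for census candidates.

3. **Selection on duplicates** (`metexpand.selection`).  Pairwise dN/dS by
   the Nei–Gojobori counting method: fractional synonymous/nonsynonymous
   site counts per codon, pathway-averaged difference counts, Jukes–Cantor
   correction `d = -(3/4)·ln(1 - 4p/3)`, and a codon-bootstrap standard
   error on ω = dN/dS.

4. **Enzyme kinetics** (`metexpand.kinetics`).  Michaelis–Menten and Hill
   fits (`v = Vmax·Sⁿ/(S₀.₅ⁿ + Sⁿ)`) by bounded multi-start least squares,
   AICc model selection, activator dose-response fits, and derived
   quantities: turnover `kcat = Vmax·M/60000` (s⁻¹, per catalytic site),
   catalytic efficiency `kcat/S₀.₅`, and fold changes between conditions.

5. **Fitness and expression** (`metexpand.phenotype`).  Malthusian growth
   rates `m = ln(Nf/N0)/t` from competition plate counts, relative fitness
   `W = m₁/m₂` with replicate statistics and t-tests, ΔΔCt expression fold
   changes normalized to a reference gene (*hrdB*), and specific metabolite
   yields (AU/mg).

A synthetic-data module (`metexpand.synth`) generates every input with known
ground truth — planted census expansions, planted duplication/HGT events,
codon pairs evolved at a controlled ω, noisy rate tables and competition
counts — and `metexpand.pipeline` wires everything into one seeded,
reproducible run.

## Worked example

Fit cooperative phosphoenolpyruvate saturation data (simulated at the
published slow-isoform parameters, 5 % assay noise) and estimate selection
on a duplicate pair:

```python
import numpy as np
from metexpand import synth, kinetics as kin
from metexpand.selection import CodonAlignmentPair, dnds

data = synth.gen_kinetic_data(synth.KineticSimSpec(
    model="Hill", vmax=9.1, s50=8.6, hill_n=7.1,
    substrate_grid=tuple(np.linspace(1.0, 20.0, 10)),
    noise_cv=0.05, replicates=3, seed=42))
print(kin.fit_hill(data).summary())

a, b = synth.gen_codon_pair(synth.CodonPairSpec(
    n_codons=500, target_omega=0.45,
    expected_substitutions_per_codon=0.3, seed=42))
res = dnds(CodonAlignmentPair(a, b), n_bootstrap=1000, seed=0)
print(f"omega = {res.omega:.3f} +/- {res.se_omega:.3f}")
```

prints

```
Hill kinetic fit (30 observations, RSS=1.206)
  Vmax = 9.17 U/mg (SE 0.0768)
  S0.5 = 8.698 mM (SE 0.0644)
  Hill n = 6.484 (SE 0.278)
  AICc = -89.5; converged = True
omega = 0.487 +/- 0.082
```

The fitted Vmax (9.17 U/mg), half-saturation (8.70 mM) and Hill coefficient
(6.5) recover the generating truth (9.1, 8.6, 7.1) within the noise of a
triplicate assay, and the ω estimate 0.49 ± 0.08 correctly reports the
strong purifying selection built into the simulated pair (ω < 1).

The same operations are available from the shell:

```bash
metexpand demo --seed 2 --out demo_out       # synthetic end-to-end run
metexpand kinetics-fit --data rates.csv --model auto --enzyme-mass 50000
metexpand dnds --alignment pairs.fasta --bootstrap 1000 --seed 7
metexpand fitness --data competition.csv
```

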