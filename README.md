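# mazsim

Stochastic modelling and single-cell analysis of *mazEF* toxin–antitoxin
autoregulation in *Escherichia coli*.

The *mazEF* operon encodes a labile antitoxin (MazE, degraded by
ClpAP/Lon) and a stable toxin (MazF), an endoribonuclease that cleaves
single-stranded RNA at ACA sites — including its own bicistronic
transcript. The module is regulated on two levels: transcriptionally,
through conditional cooperativity (antitoxin and toxin–antitoxin complexes
repress the operator at moderate toxin:antitoxin ratios, excess toxin
de-represses it), and post-transcriptionally, through a positive feedback
loop in which free toxin destroys the transcript that encodes its own
antidote. `mazsim` is built for researchers studying how this architecture
shapes growth-rate heterogeneity in clonal populations: which cells slow
down under stress, how division times and a constitutive reporter
(mCherry-like dilution proxy) redistribute, and what changes when the
transcript is synonymously recoded free of ACA sites (ΔACA).

## What is in the box

* `mazsim.reactions` — the reaction network (operator states, complexing,
  differential transcript cleavage with 9:2 toxin-:antitoxin-region
  weighting from the per-cistron ACA counts) and an exact direct-method
  Gillespie simulator for a single cell's molecular state:
  `build_network`, `propensities`, `simulate_cell`, `apply_cleavage_outcome`.
* `mazsim.population` — cells with length, damage-coupled growth, noisy
  sizer division with stress filamentation, binomial partitioning and a
  constitutive stable reporter; numba-accelerated ensembles
  (`simulate_population`, `step_cell`) and population observables
  (`division_time_histograms`, `reporter_snapshot`, `biomass_curve`).
* `mazsim.heterogeneity` — Shannon entropy of log-scaled fluorescence,
  squared coefficient of variation, threshold tail fractions and KDE mode
  detection for uni-/bimodality calls.
* `mazsim.lineage` — mother-machine/plate-reader estimators: per-cycle
  elongation rates, 5-point maximum growth rate, recovery times and
  slopes, consecutive-division length-fluctuation slopes, normalized
  fluorescence, and two-sample comparisons (rank-sum, KS, Spearman).
* `mazsim.transcripts` — ACA-site enumeration, protein-preserving ΔACA
  recoding with backtracking, region cleavage weights, ΔΔCt relative
  abundance and mRNA half-life estimation.
* `mazsim.synthetic` — deterministic generators for every input class:
  flow-cytometry-like event mixtures, Schnitzcells-style lineage tables,
  qRT-PCR Ct tables and coding sequences with exact ACA counts.
* `mazsim.scenarios` — the canonical in-silico experiments (nutritional
  stress as 3× antitoxin proteolysis; constant mild ectopic induction;
  strong induction with a depleting inducer).
* A `mazsim` command-line interface: `simulate`, `stats`, `lineage`,
  `recode`, `halflife`, `synth`, `print-config`.

The model and its parameterization are documented in
[`docs/methods.md`](docs/methods.md).

## Worked example

Compare free-toxin dynamics with and without transcript cleavage during a
six-hour episode of three-fold antitoxin proteolysis, then compare reporter
heterogeneity between a cleavable and an ACA-free ectopic toxin gene:

```python
import numpy as np
from mazsim import KineticParams, GrowthCoupling, simulate_population, scenarios
from mazsim.population import reporter_snapshot
from mazsim.heterogeneity import shannon_entropy

params = KineticParams()
coupling = GrowthCoupling()
stress = scenarios.antitoxin_stress()

with_cleavage = simulate_population(200, params, coupling, stress,
                                    scenarios.T_END, seed=1)
without = simulate_population(200, params, coupling, stress,
                              scenarios.T_END, seed=1,
                              include_cleavage=False)

t = with_cleavage.snap_times
onset = (t >= stress.t_on) & (t <= stress.t_on + 90)
window = (t >= stress.t_on) & (t < stress.t_off)
var_on = with_cleavage.free_toxin()[:, window].var(axis=1)
var_off = without.free_toxin()[:, window].var(axis=1)
print(f"onset spike of mean free toxin, with cleavage:    "
      f"{with_cleavage.mean_free_toxin()[onset].max():.1f} molecules")
print(f"onset spike of mean free toxin, without cleavage: "
      f"{without.mean_free_toxin()[onset].max():.1f} molecules")
print(f"cells with larger toxin fluctuations under cleavage: "
      f"{(var_on > var_off).mean():.0%}")

induction = scenarios.ectopic_induction()
cleavable = simulate_population(200, params, coupling, induction,
                                scenarios.T_END, seed=1)
recoded = simulate_population(200, params.replace(cleavable_ect=False),
                              coupling, induction, scenarios.T_END, seed=1)
h_wt = shannon_entropy(reporter_snapshot(cleavable, scenarios.T_SNAPSHOT_6H))
h_re = shannon_entropy(reporter_snapshot(recoded, scenarios.T_SNAPSHOT_6H))
print(f"reporter entropy after 6 h of induction: "
      f"cleavable {h_wt:.2f} bits, ACA-free {h_re:.2f} bits")
```

Output:

```
onset spike of mean free toxin, with cleavage:    6.5 molecules
onset spike of mean free toxin, without cleavage: 2.1 molecules
cells with larger toxin fluctuations under cleavage: 82%
reporter entropy after 6 h of induction: cleavable 4.35 bits, ACA-free 4.90 bits
```

Cleavage of the module's own transcript roughly triples the
population-average toxin spike at stress onset and makes toxin levels
fluctuate more in most single cells — the positive feedback converts brief
antitoxin dips into deep toxin excursions. Under ectopic induction, the
ACA-free (cleavage-immune) construct spreads the reporter distribution
more than the wild-type construct: transcript cleavage reins in the
heterogeneity that toxin expression creates.

The same pipeline is available from the shell:

```bash
mazsim simulate --cells 200 --seed 1 --out run/
mazsim synth flow --seed 1 --out events.csv
mazsim stats --in events.csv --threshold 2000
mazsim recode --in toxin_gene.fasta --out toxin_gene_dACA.fasta
```

## Sequence tools

```python
from mazsim.transcripts import find_ACA, recode_remove_ACA, region_weights, packaged_cds

len(find_ACA(packaged_cds("mazE")))   # 2 cleavage sites (antitoxin cistron)
len(find_ACA(packaged_cds("mazF")))   # 9 cleavage sites (toxin cistron)
region_weights(2, 9)                  # 4.5: the toxin-encoding region is
                                      # 4.5x more likely to be cleaved
```

The packaged FASTA fixtures are synthetic stand-in sequences carrying the
documented per-cistron ACA counts (see the file headers); they are not the
genomic sequences.

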