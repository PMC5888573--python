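# Methods

## The model

`mazsim` simulates the *mazEF* type II toxin–antitoxin module of *E. coli*
in single cells. The antitoxin MazE is labile (degraded by ClpAP/Lon), the
toxin MazF is a stable endoribonuclease that cleaves single-stranded RNA at
ACA trinucleotides — including its own bicistronic transcript. The model
combines three regulatory layers:

1. **Direct neutralization.** Free antitoxin A binds free toxin T into an
   inert complex C (`kon`, `koff`). Proteolysis of the antitoxin *within*
   the complex releases the toxin (C → T at `delta_A`), which is the step
   that converts antitoxin loss into free-toxin gain.
2. **Conditional cooperativity at the operator.** The single chromosomal
   operator is either free (full transcription `k_tx`), bound by antitoxin
   (residual transcription `alpha_OA = 0.1`), bound by a toxin–antitoxin
   complex (`alpha_OC = 0.02`), or carries a second toxin on the bound
   complex (O_CT), which is ejected quickly (`ku_T2 = 10 /min`) together
   with the complex, restoring the free operator. Repression is therefore
   maximal at moderate toxin:antitoxin ratios and removed at high ratios.
3. **Post-transcriptional positive feedback.** Free toxin cleaves the
   full-length transcript `m_EF` at rate `k_cleave · T` per transcript.
   Cleavage falls on the toxin-encoding region with probability
   w_F/(w_E+w_F) = 9/11 (nine ACA sites) — leaving a fragment `m_E` that
   still translates antitoxin — and on the antitoxin-encoding region with
   probability 2/11 (two sites), inactivating the transcript. The fragment
   `m_E` is itself cleavable only in its antitoxin region. An ectopic
   toxin-only transcript `m_ect` (an arabinose-inducible construct) is
   cleaved at the toxin-region weight unless it represents a synonymously
   recoded, ACA-free gene (`cleavable_ect=False`).

All reactions are simulated exactly with the direct stochastic simulation
algorithm. Stress enters in one of two modes: a nutritional-stress episode
multiplies `delta_A` by 3 inside a window (up-regulated proteases), or an
induction window switches on ectopic transcription at `beta_ect`.

## Growth, damage and division

Each cell has a length L growing as dL/dt = g·L. MazF injures the
translation machinery (precursor rRNA cleavage, stress ribosomes), and the
machinery recovers slowly once the toxin is neutralized; elongation
therefore responds to a *damage* variable D, a low-pass filter of the
free-toxin count with relaxation time `tau_g = 30 min`:

    dD/dt = (T − D)/tau_g,     g(D) = g_max / (1 + (D/K_g)^h_g).

With `tau_g → 0` this reduces to an instantaneous Hill response to free
toxin. The constitutive stable reporter R (an mCherry-like protein) is
produced at `p_max / (1 + (T/K_p)^h_p)` with `K_p ≫ K_g`: production is
inhibited far more weakly than growth, so the concentration R/L rises when
growth slows — the reporter-dilution proxy for single-cell growth rate.

Division uses a noisy sizer with a damage-sensitive latency: each cycle
draws a threshold `L_div·(1 + 0.02·ξ)`; once past it the cell divides at
rate `div_rate / (1 + (D/K_d)^h_d)` with `K_d < K_g` — the division
machinery is hit harder than elongation, so stressed cells overshoot the
threshold and filament, as observed experimentally during toxin
overexpression. At division the length halves, every molecular count is
partitioned binomially (p = 1/2), and one daughter is retained per lineage
(mother-machine convention). Because dilution through growth is the main
toxin sink (δ_T ≈ 0), growth arrest and toxin accumulation reinforce each
other.

The hybrid scheme is event-driven: molecular propensities are independent
of L, so L is integrated analytically between reactions; the sizer crossing
and the stress-window bounds are event horizons; the elongation rate is
refreshed at every reaction and at least once per simulated minute while
damage is relaxing. The per-cell loop is compiled with numba; 10⁴ cells
over ~11 simulated hours take a few minutes on one core.

## Parameter choices

Defaults (all overridable via `KineticParams` / `GrowthCoupling` or a YAML
config) and why they sit where they do:

| parameter | value | rationale |
|---|---|---|
| `k_tx` | 2 /min | full-rate initiation from the free operator |
| `b_A`, `b_T` | 3.0, 0.1 /min | strong translational excess of antitoxin; see below |
| `delta_A`, `delta_T` | 0.2, 0.005 /min | fast antitoxin proteolysis, near-stable toxin |
| `delta_m` | 0.2 /min | ~3.5 min basal mRNA half-life |
| `k_cleave` | 2.0 /min per (toxin, transcript) | cleavage must outrun translation during a toxin excursion; see below |
| `w_E : w_F` | 2 : 9 | per-region ACA-site counts of the two cistrons |
| `kon`, `koff` | 100, 0.01 /min | tight, fast neutralization; the covered state carries essentially zero free toxin |
| `kb_A/kb_C`, `ku_A/ku_C` | 0.03, 1 /min | moderate operator occupancy, keeping 4–6 transcripts per cell |
| `kb_T2`, `ku_T2` | 0.1, 10 /min | efficient toxin-mediated de-repression |
| `beta_ect` | 0.85 /min | mild constant induction (chromosomal/weak-plasmid analog); the strong multicopy-plasmid scenario uses 3 /min |
| `g_max` | 0.0231 /min | 30-min doubling |
| `K_g`, `h_g` | 8, 4 | damage of ~a dozen toxins halves elongation, steeply |
| `tau_g` | 30 min | translational-capacity recovery time |
| `K_p`, `h_p` | 100, 1 | reporter production only weakly inhibited |
| `K_d`, `h_d` | 1.5, 4 | division far more damage-sensitive than elongation (filamentation) |
| `div_rate`, `div_cv` | 20 /min, 0.02 | short healthy division latency; 2% sizer noise |

The translation ratio `b_A/b_T = 30` is pinned by a coverage argument.
Total toxin and antitoxin balance when
`b_A/b_T = (m·delta_A + g)/(delta_T + g)` (with `m` the stress multiplier
on proteolysis and g the dilution rate ≈ ln2/30 min). That threshold is ≈ 8
without stress, ≈ 22 under three-fold proteolysis at full growth, and ≈ 37
once growth has halved. At 30, the module is safely covered without stress
(free toxin ≈ 0, and the cleavage-on and cleavage-off models are
indistinguishable, as they should be), marginally covered under stress, and
uncovered in slow-growing stressed cells — the band in which stochastic
antitoxin crashes can flip individual cells.

The cleavage rate is set by the requirement that the positive feedback
actually closes: during a free-toxin excursion (T of order 10–20), the
per-transcript cleavage rate `k_cleave·T` must exceed the translation
turnover, so that rescue transcripts (including the antitoxin-only
fragments) are destroyed before they can re-cover the cell; this demands
`k_cleave` of order 1 /min. Between excursions free toxin is essentially
zero (fast `kon`), so this strong rate causes no chronic transcript loss.
With the feedback closed, the cleavage-on model converts brief antitoxin
dips — which the de-repressed operator rescues within a minute or two in
the cleavage-off model — into deep, tens-of-minutes toxin excursions: the
fluctuation amplification and the higher onset spike that distinguish the
two models.

## Canonical scenarios

`mazsim.scenarios` fixes the in-silico experiments: 3 h of unstressed
growth (discarded burn-in), perturbation from t = 60 min, observation to
t = 480 min. `antitoxin_stress()` triples `delta_A` for six hours
(nutritional stress); `ectopic_induction()` applies constant mild
toxin-gene induction (comparing cleavable vs ACA-free ectopic transcripts);
`ectopic_overexpression_depleting()` applies strong induction whose
effective window ends at 270 min, modeling a host that metabolizes the
inducer — the setting in which the reporter distribution at six hours
splits into recovered (fast-dilution) and still-arrested (accumulated)
subpopulations.

## Heterogeneity statistics

Entropy is computed on log10-transformed values over 256 bins spanning at
least four decades (a coarsened 1024-channel log amplifier); SCV on linear
values with the unbiased variance; the tail fraction counts events strictly
above threshold. Mode detection builds a Gaussian KDE (Silverman bandwidth)
on log10 values, takes local maxima with topographic prominence ≥ 5% of the
global maximum, and assigns events to modes by splitting at the minima
between surviving peaks. The 5% prominence rule replaces by-eye bimodality
calls with a reproducible operation; it requires at least 50 events.

## Lineage and sequence estimators

Elongation rates are least-squares slopes of ln(length) vs time from birth
to division (exact on noiseless exponentials); the population maximum
growth rate is the best 5-point sliding-window slope of ln(biomass)
(40 min at 10-min sampling), and recovery time is the difference between
induced and control cultures in reaching that maximum, flagged as a lower
bound when the maximum sits at the series end. Length-fluctuation slopes
divide the change in pre-division length between consecutive divisions by
the time between them. Half-lives come from the slope of ln(relative
abundance) vs time, with abundances from the ΔΔCt method at an assumed
amplification efficiency of 2.0 (configurable); non-decaying series are
flagged and reported as infinite. ACA-free recoding searches synonymous
codon swaps depth-first (leftmost unresolved site first, candidates ordered
by an approximate E. coli codon-usage table), accepting a swap only if it
pushes the leftmost site rightwards and backtracking otherwise; an
infeasibility error reports stuck positions.

## Synthetic data

The generators produce the four input classes the analyses consume:
lognormal mixtures on a 4-decade clipped range (flow-cytometry events);
mother-machine-like lineage tables at 5-min frames with multiplicative
length noise (sd 2%) and a noisy sizer (5% CV), with total fluorescence =
concentration × area and concentration following the inverse-growth proxy;
qRT-PCR Ct tables with a constant reference gene, exact exponential target
decay and Gaussian Ct noise; and random in-frame coding sequences with an
exact, oracle-verified ACA count (junction-safe codon construction). All
generators are deterministic given their seed.

These fixtures emulate the statistical *structure* the estimators assume —
log-normal fluorescence, exponential elongation, first-order decay — not
instrument- or strain-specific features (autofluorescence, scatter gating,
segmentation errors, amplification-efficiency drift). Tests passing on them
show the estimators and the pipeline are correct and calibrated under the
assumed structure, not that the assumptions hold for any particular real
dataset.

## Numerical choices

Direct-method SSA with piecewise-constant propensities; stress-window
bounds are event horizons at which waiting times are redrawn (exact by
memorylessness). Sub-seeds for the statistically independent cells derive
from the master seed by counter-based splitting
(`SeedSequence(master, spawn_key=(cell_index,))`). The sizer crossing is
scheduled with a 10⁻⁷-min overshoot and the division channel activates
within a 10⁻⁹ relative band of the threshold, avoiding one-ulp stalls.
Degenerate inputs are handled explicitly: empty division windows are
flagged rather than raised; a point-mass sample is one mode; non-decaying
series report infinite half-life; lineages with fewer than two in-window
divisions are skipped with an aggregate warning.

Test and analysis problem sizes are scaled-down versions of the reference
design (10⁴ cells): ensembles of 200–1000 cells, 20 master seeds for
paired-ensemble comparisons, 200 lineages per arm for the fluctuation
analyses. At these sizes every qualitative contrast reported by the test
suite is stable across seeds except where noted below.

## Known limitations

- The model is a qualitative-regime model: rate constants were chosen by
  the coverage/feedback analysis above, not fitted to data; absolute
  molecule numbers and time constants should not be over-interpreted.
- Completed-division-time histograms under nutritional stress show the
  slow-growing subpopulation as a heavy right tail rather than a separated
  second mode: completed events weight each cell by the inverse of its
  cycle time, the damage continuum fills the region between fast and slow
  cycles, and recovering filaments divide early. The two growth states are
  nevertheless visible in the damage distribution and, in the ectopic
  scenarios, in the bimodal reporter distribution.
- Cell death and lysis are not modeled (a minority phenotype in the
  experiments), nor are inducer transport/metabolism kinetics (the
  depleting-induction scenario simply truncates the window), nor cross-talk
  with the other type II TA systems.
- One chromosomal module copy per cell; gene-copy-number variation across
  the cell cycle is ignored.
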