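# Methods notes

This note documents the models implemented in `ecdna`, the parameter
choices that matter, the numerical decisions taken where the design was
open, and what the synthetic-data tests do and do not establish.

## Birth–death population model

Each cell carries integer copy numbers (k¹, k²) of two ecDNA species.
Division occurs at rate λ_base·(1+s) with s selected by species *presence*
(copy > 0), not copy number; death, when enabled, at rate μ. The
simulation is an exact Gillespie process: the kernel tracks the total
birth propensity through the four presence-class counts, draws exponential
inter-event times, picks death cells uniformly and dividing cells by
rejection against the maximal class rate. It stops at a target cell count
or a target (global) time, whichever comes first; cells mid-waiting-time
are counted as leaves. Extinction is an explicit result, not an error.

Defaults follow the study conditions: λ_base = 0.5, s₋,₋ = 0, k_init =
(5, 5), no death, two species (more are out of scope), no copy-number cap.
The kernel is numba-compiled (~5 ms per 20,000-cell population), which is
what makes the ABC and recovery studies below tractable on one CPU. The
full lineage can be retained (reconstructed from the event log, exportable
as Newick with leaf copy states as comments) for populations up to 2·10⁵
leaves; dead branches are pruned from exports by default, with unary nodes
suppressed and edge lengths merged. Leaf states are identical whether or
not events or trees are recorded, and identical seeds give identical
populations.

An important structural property: under binomial segregation the per-cell
copy number of a species is a critical branching process (offspring mean
1), so copy numbers drift — conditioned on retention they grow roughly
linearly in the number of generations, and the fraction of low-copy cells
decays only like 1/generations. Several observable consequences (the slow
saturation of co-occurrence, the wide cross-replicate spread of ρ driven
by early founder divisions) follow from this and are discussed under
*Limitations*.

## Segregation rules

* **Element level** (default). Species 1 (the anchor; configurable)
  splits as Binomial(2N₁, ½). The coupled share of species 2 per daughter,
  γ·2N₂·n₁^(i)/(2N₁), is generally fractional: we take the floor for each
  daughter (with a 1e-9 guard against representation error) and let the
  binomially split remainder absorb the rest. This conserves copies
  exactly and converges to the proportional split in distribution.
  N₁ = 0 with N₂ > 0 would divide by zero; with no anchor signal to couple
  to, the coupled part is defined as 0 and species 2 splits binomially.
  Statistics are reported for the anchoring used.
* **Cell level.** Both species split binomially; with probability γ the
  larger halves are co-assigned. Exact half-splits make pairing a no-op,
  implemented as uniform random labelling, so ties are
  distribution-invariant. Daughters are exchangeable by a final random
  label swap.
* **Fraction coupled.** Round(φ·2N_j) copies of each species form the
  coupled pool; the shared daughter-1 ratio is drawn as
  Binomial(c_anchor, ½)/c_anchor and applied to the other species'
  coupled pool with rounding to nearest, the remainder splitting
  binomially. The ratio's law is a design choice (the binomial matches
  "randomly distributed at the same ratio" while keeping integer copies);
  an empty anchor pool falls back to a Uniform(0,1) ratio. With equal
  parent copies, φ = 1 makes daughter proportions of the two species equal
  exactly.

All three rules conserve copies per species exactly and reduce to
independent Binomial(2N, ½) splits at γ = 0 (element), γ = 0.5 (cell) and
φ = 0 (fraction-coupled); the test suite verifies the reductions by
goodness of fit at 10⁵ draws.

## Summary statistics

C is the fraction of cells with both species strictly above threshold m
(m = 1 for sweep analyses; m = 2 for ABC, matching "more than 2 copies").
ρ is the Pearson correlation of per-cell copies, computed raw for
simulation sweeps and on log1p copies when comparing against scATAC-derived
observations; it is flagged undefined (not numeric) when either species is
constant. Pure/mix/free fractions partition cells by carrying exactly one
/ both / neither species.

## ABC-SMC

Priors: s_indiv = s₋,₊ = s₊,₋ ~ U(0,1) (tied by default; an untied
four-parameter variant is available), s₊,₊ ~ U(0,2), γ ~ U(0,1).
Forward model: a population grown to `sim_cells` with λ_base = 0.5, no
death, neutral ecDNA-free cells; distance D = |C_obs − C₀| + |ρ_obs − ρ₀|,
with an infinite sentinel when ρ₀ is undefined. The SMC scheme is
standard: generation 0 keeps the first N finite-distance prior draws; each
later generation's tolerance is the 0.3 quantile of the previous accepted
distances (floored at the target ε), particles are resampled by weight and
perturbed by a component-wise Gaussian with variance twice the weighted
sample variance (out-of-support proposals redrawn), and importance weights
are prior/(mixture of kernels). The run returns a converged posterior when
the tolerance reaches ε (default 0.05), or a flagged posterior with the
achieved tolerance when the per-generation proposal budget or the
generation cap is exhausted first; a generation with zero acceptances
raises a stall error with diagnostics. Each particle stores the seed of
its accepted simulation, so any particle's statistics are exactly
reproducible post hoc.

Two tolerance schedules are used. The default 0.3 quantile decays quickly
and suits runs whose target may sit at the model's distance floor (it
reaches the stall, or the target, in few generations). For
parameter-recovery studies, where posterior calibration matters more than
speed, the median schedule with a larger particle count is the right
choice: the aggressive schedule at small particle counts concentrates
prematurely and truncates posterior tails, which measurably degrades
credible-interval coverage. `sim_cells` is a fidelity knob: 20,000 by
default here versus 500,000 at analysis scale; with fewer cells the
population has had fewer generations of selection, so the reachable
co-occurrence is slightly lower and all summary statistics are noisier.
Problem sizes used by the validation suite: 200 particles (0.3-quantile
schedule) for the cell-line targets; 128 particles, median schedule and
ε = 0.08 for the thirty parameter-recovery runs.

## Treatment schedules

Phases chain on one global clock; each phase may override selection
coefficients, λ_base, or μ, and may bottleneck the population (uniform
sampling without replacement) before it starts. Time-binned mean copy
numbers per species are averaged over event snapshots within each bin
(empty bins carry the previous value); bin widths follow the reference
choice of 5 time units before treatment and 1 after. A phase stopping "at
time T" stops at the first event time that would exceed T, leaving the
population state as of T.

The pulsed-treatment preset encodes the reference schedule: burn-in to
5,000 cells (λ_base 0.5, k_init (10,10), s₋,₋ = 0, s₋,₊ = s₊,₋ = 0.15,
s₊,₊ = 0.8), treatment with s₊,₊ = s₊,₋ = −0.1 to 100,000 cells,
a drug holiday (original selection, λ_base 0.4) to 1.2 M cells after a
25,000-cell bottleneck, and re-treatment until global time 110 after a
200,000-cell bottleneck. The stated death parameter of 2.5 is
interpreted as the *mean waiting time* to death (exponential scale, hazard
0.4): as a hazard it would make every class subcritical
(P(divide) ≈ 0.26) and the schedule's growth targets unreachable, so the
scale reading is the only one under which the stated schedule runs; the
preset exposes the stated value as `meta["death_mean_waiting_time"]`.
Presets take a `scale` factor (default 0.1) shrinking all cell-count
targets proportionally; time targets are not scaled. The validation suite
runs the pulse at scale 0.02 with 20 replicates per condition.

## Copy-number calling

Windows are BED-style 0-based half-open, 3 Mb wide with 1 Mb step; only
full-width windows are emitted so rates share a denominator. Windows
overlapping a blacklist interval by ≥ 1 bp are dropped. Neighbour sets are
the 100 windows nearest in GC content among non-overlapping windows
(overlap excluded because sliding windows within one width share
sequence), ties broken by genomic distance. Per cell, the fold change of a
window's insertions-per-bp over its neighbour-mean rate gives
CN = 2·2^{log2 FC}; the neighbour comparison is per cell (no cross-cell
averaging). Cells with a zero neighbour mean anywhere are recomputed with
a +1 insertion pseudocount per window and flagged low-coverage (an
all-zero cell then reports CN = 2 everywhere). Zero-count windows in
covered cells report CN = 0 (the −∞ log2 FC limit). Gene copy number is
the unweighted mean CN of windows overlapping the gene body; genes
overlapping no retained window yield NaN with a warning.

The amplification classifier is deliberately minimal: mean CN ≥ 4 and
variance/mean ≥ 2.5 (both inclusive, sample variance) → ecDNA-like;
mean ≥ 4 with lower dispersion → amplified-non-ecDNA; otherwise
not-amplified; fewer than 10 cells → indeterminate. Correlations between
amplicons are computed either on log CN over all cells (cell-line mode) or
on raw CN restricted to cells with both genes ≥ 4 (tumour mode), with at
least 3 qualifying cells.

## Daughter pairs and the fusion null

Per pair and species, the inherited proportion is d1/(d1+d2); pairs with
zero total signal for either species are QC-excluded and counted. The
co-segregation correlation is Pearson's R across pairs (daughter choice
affects only signs, not |R|). Fisher's z compares correlations between
conditions. The fusion null simulates, per observed pair, divisions under
the fraction-coupled rule with φ equal to that pair's observed fused
fraction; event e across pairs forms null replicate e (20 events by
default, matching the reference procedure). Because FISH intensity is not
calibrated to molecule counts, each pair's total signal is scaled to a
configurable 200 pseudo-copies split between species by their observed
share — an explicit approximation. The observed R is compared with the
null mean via Fisher's z with a (1 + 1/n_events) variance inflation for
the null mean's own Monte Carlo error; with that correction the test's
type-I error at nominal 0.05 sits in the 0.03–0.08 band (verified over
1,000 null replicates).

## Synthetic data

The count generator emulates scATAC-derived windowed insertion counts:
smoothly varying GC along one synthetic chromosome, background rates
following a quadratic log-rate GC curve (default coefficients (1.5, −6),
strong enough to make unmatched normalization fail while GC-matched
normalization recovers a diploid baseline), Poisson sampling at ~5,000
insertions per cell, and amplified window blocks scaled by per-cell CN/2
drawn from a simulator population (realistic correlated, overdispersed
copies), a constant (HSR-like), or a negative binomial with stated
variance/mean. The daughter-pair generator runs real segregation draws and
applies multiplicative lognormal measurement noise (default sd 0.1) to
each daughter/species signal; the default of 30 copies per species
reflects typical per-cell ecDNA counts in the imaged cell lines. Every
generator returns a truth sidecar (parameters, per-cell truth,
generator version) and is deterministic given its seed; validations
compare against the sidecar.

What the synthetic fixtures do **not** emulate: fragment-level read
structure, doublets, cell-cycle coverage effects, mappability variation
beyond the blacklist, chromosomal copy-number aberrations outside the
declared amplicons, or segmentation artifacts in imaging. Passing tests
therefore demonstrate correctness of the statistical machinery under the
stated generative assumptions, not robustness to every artifact of real
scATAC or FISH data.

## Limitations

* Co-occurrence saturates: because low-copy cells vanish only like
  1/generations, the model cannot produce C ≈ 0.99 (observed in the most
  strongly co-assorted cell line) at any tractable population size with
  k_init = 5 — desk-scale inference against such targets reports its
  achieved tolerance rather than converging to ε = 0.05.
* Summary statistics carry irreducible cross-replicate noise from founder
  divisions (sd of ρ ≈ 0.08 at 20,000 cells); posterior-predictive checks
  with fresh seeds inherit that floor, which is why reproducibility
  guarantees are stated with stored seeds.
* Selection acts on species presence only; copy-number-dependent fitness,
  more than two species, chromosomal integration and pharmacokinetics are
  out of scope.
* The fusion null's signal-to-copies scaling is a declared approximation;
  its absolute R level (not just its shape) depends on the assumed total
  molecule count.
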