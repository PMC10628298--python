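# Methods

## The two-state branching model

Cells are drug-susceptible (S) or primed for drug resistance (P). The
model is a continuous-time two-type branching process: a cell in state
`x ∈ {S, P}` divides at rate `r_x` and dies at rate `d_x` (both per day,
exponential waiting times, cells independent). Switching is coupled to
division: at each division, each of the two daughters independently
adopts the other state with probability `p_on` (S mothers) or `p_off`
(P mothers). Lineage identity (the founder's barcode) is inherited.

Because the field quotes switching in divisions, all interfaces use the
convention *one event per N divisions ⇔ per-daughter probability
1/(2N)* (a division offers two daughters the chance to switch). The
`switching="continuous"` mode replaces division-coupled switching with a
separate exponential event at the flux-equivalent rates `k_on = 2 p_on
r_S`, `k_off = 2 p_off r_P`; it exists for sensitivity analysis because
the biological literature does not resolve whether switching is
division-locked. The optional lineage-coupling coefficient `gamma`
implements the hypothesis that susceptible cells in partially primed
lineages switch more easily: `p_on_eff = p_on (1 + gamma · lineage primed
fraction)`, default 0.

Default parameters (`DEFAULT_PARAMS`), chosen for drug-naive melanoma:

| parameter | default | units | rationale |
|---|---|---|---|
| `r_S` | 0.2 | /day | ≈4 population doublings in 12–14 days |
| `r_P` | 0.1 | /day | primed cells divide at about half the susceptible rate |
| `d_S`, `d_P` | 0 | /day | death only enters via treatment overrides |
| `p_on` | 1/354 | per daughter | one S→P event per 177 divisions |
| `p_off` | 1/12.6 | per daughter | one P→S event per 6.3 divisions |

These switching values sit at the centres of the ranges reported for this
system (135–233 and 5–8 divisions per event) and imply a steady-state
primed fraction of ≈1% (`steady_state_fraction` solves the quadratic
fixed point of the deterministic two-type ODE; the stable root in [0, 1]
is returned and cross-checked against numerical integration to 1e-6).

The simulator core is an exact Gillespie loop (numba-compiled): event
rates depend only on state counts; the affected cell is drawn uniformly
within its state by rejection sampling; arrays are preallocated with
automatic doubling on overflow, so a run is reproducible bit-for-bit from
its seed regardless of capacity. Seeds everywhere are 32-bit; nested
randomness is derived from a single `numpy` generator per entry point.

## Synthetic data

The generator emulates the study conditions of a barcoded melanoma
experiment:

* **Barcode libraries** — unique 100-nt WSN repeats (W=A/T at positions
  ≡0 mod 3, S=G/C at ≡1, N=any at ≡2). Random WSN barcodes of this
  length have pairwise edit distances far above the clustering radius.
* **Reads** — a fixed 22-nt anchor (a configuration value; real
  constructs each have their own) followed by the barcode, with i.i.d.
  substitution errors at `read_error_rate` (default 0.005, stress tests
  use 0.01). Errors are substitutions only by default so the clustering
  oracle stays exact; an `indel_rate` knob exists for stress tests. Read
  names carry cell id and a 12-nt UMI. ~20% of cells carry a barcode
  (`infected_fraction`), matching single-integration transduction.
* **Counts** — negative binomial (mean/dispersion parameterization,
  variance `μ + μ²/θ`), base mean 3 and dispersion 3 per gene (a
  well-expressed gene with moderate overdispersion); marker genes of a
  cell's own state (primed: NT5E, EGFR, AXL, FN1, SERPINE2; susceptible:
  SOX10, MITF) have their mean multiplied by `marker_fold_change`
  (default 8). Two percent of cells are primed by default.
* **Flow intensities** — a two-component lognormal, σ=0.5 on the log
  scale, primed component shifted by `shift` log-units (default examples
  use 3, i.e. a clean 6σ separation).

Not modelled: ambient RNA, doublets, UMI collisions, read-quality
profiles, batch effects, cell-cycle structure. Passing tests on these
fixtures therefore demonstrate the correctness of the algorithms under
clean generative assumptions, not robustness to every artefact of real
droplet data.

## Barcode recovery

Extraction scans each read for the anchor allowing up to 2 substitutions
(leftmost minimal-mismatch window) and takes the following L nucleotides;
duplicates are UMI-collapsed per (cell, sequence). Error correction is
greedy sphere clustering in descending read count (ties lexicographic): a
sequence merges into the highest-count canonical within Levenshtein
distance `max_dist` whose count is at least `merge_ratio` times its own.
Defaults `max_dist=5`, `merge_ratio=5` mirror the documented defaults of
starcode-style tools for ~100-nt sequences. The greedy rule was chosen
over message passing because it is deterministic and oracle-checkable;
the map is idempotent by construction.

Lineage assignment: single-barcode cells take their barcode; cells with
several barcodes take the top one when its UMI support strictly
dominates, and otherwise fall to the combination rule (a sorted barcode
combination seen in ≥2 cells becomes a combination lineage; singletons
are ambiguous and dropped, not guessed). Under `independent_samples`
designs a lineage seen in more than one sample is impossible and removed;
`shared_split` (split-plate) designs keep sharing. Lineages with fewer
than 3 cells are dropped by default. The oversize filter removes lineages
larger than `slack · 2^doublings` observed cells (default slack 2); it is
meant for captured data — under exact exponential-time branching the raw
size distribution is long-tailed and the filter would clip ~12% of raw
lineages, but observed sizes after capture and ~60% barcode detection sit
far below the threshold. Filters only ever remove; drop reasons are
recorded per cell.

## States

Normalization is `log(1 + 10⁴ · count / column sum)` (natural log).
Signature scores are UCell-style: per cell, genes are ranked by
decreasing expression with average ranks for ties, ranks above `rmax`
(default 1500) are clipped to `rmax+1`, and the score is
`1 − U/(m·rmax)` with `U` the centred rank-sum of the `m` signature
genes — rank-based, hence invariant to monotone transforms.

State calling deliberately replaces graph clustering with thresholding of
the primed signature score, keeping the boundary reproducible and
testable: a two-component Gaussian mixture (posterior assignment,
higher-mean component = primed) or a top-`q` quantile (default q=0.02,
matching how the primed fraction is defined operationally in this
system). The method used is echoed in outputs. The mixture variant suits
clearly bimodal scores; for unimodal score distributions with a rare tail
the quantile variant is the right tool.

Differential expression is a two-sided Wilcoxon rank-sum per gene — exact
when both groups have ≤10 cells and the gene has no ties, tie-corrected
normal approximation otherwise. Fold change is log2 of group means with
pseudocount 1 (the log base of the conventional 0.25 cutoff is ambiguous
in the field; log2 is chosen and documented). Genes expressed in <10% of
cells of both groups, and genes constant across both groups, are excluded
(NA) before Bonferroni correction over the tested genes. Significance:
adjusted p < 0.05 and |log2 FC| ≥ 0.25. The primed gene set is the
significant positives with primed as group A.

Intermediate-state calling scores all cells against the crossing-lineage
gene set and relabels the top 2% of susceptible cells (global threshold;
a per-sample option exists through per-sample calls); primed labels are
never touched, and at least one cell is labelled when any susceptible
cells exist. The flow gate sets the threshold at the ⌈qN⌉-th largest
untreated intensity with `q=0.02`; events at or above the threshold are
primed (ties gate at-or-above).

## Lineage memory

Categories require a founder state per lineage — sorted-sample identity
in sorted designs, simulator truth in synthetic runs (a
lineage-majority-at-reference heuristic is available but flagged).
Intermediate cells count as susceptible throughout, because the
intermediate state is operationally a subset of the susceptible
population. The crossing-lineage DE compares susceptible cells of pure
susceptible lineages against the susceptible cells only of S→P switching
lineages.

`estimate_switch_prob_from_purity` inverts the purity of a complete
d-doubling tree (`2(2^d−1)` daughter draws): `p̂ = 1 − purity^(1/(2(2^d−1)))`,
a small-p approximation that ignores back-switching; it matches
exhaustive tree enumeration to machine precision for d ≤ 3 and is biased
<10% at p ≤ 0.02, d = 4.

`gene_memory_icc` is the one-way random-effects intraclass correlation
with lineage as the grouping factor, using the unbalanced group-size
correction, clipped to [0, 1]; zero-variance genes score 0.

Matched-lineage comparisons (split-plate designs) select lineages whose
reference-condition cells are 100% in the reference state (or all
lineages with `ref_state=None`) and report each lineage's primed fraction
per condition; `fraction_reduced` uses strict inequality, ties count as
not reduced.

## Inference

The summary vector has 21 components (population primed fraction, four
category fractions, size quartiles per founder state, 10-bin histogram of
per-lineage primed fractions) plus, for paired split-plate designs, four
matched components: primed-mass retention (treated-plate descendants per
untreated primed cell, normalized by overall growth), residual primed
fraction in formerly primed lineages, the fraction of those lineages with
strictly reduced primed fraction, and the log relative growth of
mostly-primed lineages. The matched components carry the information that
separates switching from selective killing — conversion keeps cells alive
(ex-primed cells then divide at the susceptible rate) while killing
removes them — and are the reason the paired design is used for scenario
selection; endpoint-only summaries leave those two mechanisms nearly
indistinguishable when the primed state is rare.

Grid fitting is deliberately ABC-by-grid rather than an adaptive search:
deterministic, auditable, budget-explicit. Grids are log-spaced for
probabilities and rates (death-rate scenario grids are linear from 0 so
the null is included). Distances are Euclidean after per-component
standardization; the spread is taken from observed replicates when at
least five are given, and otherwise estimated once from replicate
simulations at the geometric midpoint of the ranges (components with zero
spread are standardized by 1). Grid points whose simulations all go
extinct get infinite distance. The reported estimate is the geometric
mean over the accepted set (best 1% of points) — the usual ABC
posterior-mean estimator, smoother than the raw argmin on a 20-point
log grid whose steps are ~20%; the accepted set is a crude uncertainty
region, explicitly not a posterior.

Scenario selection fits one parameter per named scenario on its own 1-D
grid (which includes the null value) against the treated summary and
ranks scenarios by best distance, breaking exact ties toward the smallest
deviation from the null. The canonical scenario sets are: for a primed
increase — `p_on` up, `r_P` up, `d_S` up; for a primed decrease —
`p_off` up, `r_S` up, `d_P` up.

### Problem sizes

The package's standard experiment sizes are scaled-down analogues of a
full study (which would profile tens of thousands of cells across tens of
thousands of lineages): switching-rate recovery uses observed data from
1000 S + 1000 P founders over 4 susceptible doublings (4 replicate
datasets in the acceptance script) and a 20×20 grid with 10 simulations
of 1000 founders per point; scenario studies use 1176 S + 24 P founders
(2% primed), 4 expansion doublings, a 5-day treatment, paired untreated/
treated plates, two observed replicate experiments per replicate, and
10-point scenario grids with 8 simulations per point. These sizes keep
every statistic comfortably estimable while the full acceptance run
completes in minutes on one CPU.

## Known limitations

* Switching-at-division is a modelling convention; the continuous mode
  changes steady states only through the stated flux equivalence.
* The purity moment estimator assumes complete synchronous trees and no
  back-switching; use the grid fit for real estimates.
* Scenario selection distinguishes killing from switching only through
  matched-lineage information; with very rare primed populations and no
  paired design the two are weakly identified, and a few percent of
  replicate studies still pick the killing scenario at 10-fold effects.
* The mixture state-caller assumes bimodal scores; rare-tail score
  distributions should use the quantile method.
* The DE module tests one gene at a time and does not model library-size
  covariates beyond the normalization.
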