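# Methods

This note documents the models, numerical choices, and open design
decisions behind `cytopanel`. The package implements a complete
desk-scale immunophenotyping workflow for human PBMC: two declarative
multicolor panels, a ground-truth simulator, control-sample
computations, hierarchical gating, stimulation-index readouts, and a
permutation statistics layer for three-donor designs.

## Panels and gate trees

A panel couples a reagent list (marker, fluorophore, detector), a gate
tree, and population rules. Detectors follow the `Marker-Fluorophore`
naming convention (`CD3-BV570`), which makes the join between the
reagent table and the population definitions unambiguous and is used for
all event-table column headers.

**Panel 1 (lymphocyte panel)** — 12 channels (11 antibodies plus the
amine-reactive Zombie Aqua viability dye). Populations: B cells
(CD45+CD19+), T cells (CD45+CD3+), cytotoxic T (CD8a+/CD4−), naive
cytotoxic T (+CD45RA+), CD4 T (CD4+/CD8a−), regulatory T
(CD4+, CCR4+, CD25+/CD127-low), and γδ T (CD4−/CD8a−, TCRγδ+).
Activation markers CD25 (proliferation) and CD154 (co-stimulation) are
scored on B, cytotoxic T and CD4 T cells.

**Panel 2 (monocyte/DC/NK panel)** — 11 channels. After the shared
trunk, events split by scatter morphology into a monocyte branch
(CD45+CD3−CD19−CD14+) and a lymphocyte branch (pDC:
lineage−CD123+; mDC: lineage−CD11c+; NK: lineage−CD56+; NKT:
CD3+CD56+). Activation markers CD54 (adhesion) and CD69 (early
activation) on monocytes, pDC, mDC and NK.

Gate-tree conventions:

* Every gate is inclusive except the viability gate, which is
  *exclusive*: its members (dead cells) are removed from all downstream
  gating, and "live" denotes the survivors.
* We keep a single tree root. Panel 2's two morphology regions are
  sibling scatter gates placed after the shared
  main-cells/singlet/viability trunk; they are complementary halves of
  an FSC-A boundary, so they partition the live singlets exactly. An
  alternative layout puts the morphology split before singlet/viability
  gating; we chose the shared trunk so one viability gate (and one
  live-cell denominator) serves both branches.
* CD127-low is a `threshold-low` gate — keep events *at or below* an
  isotype-referenced boundary — rather than a plain negative gate. With
  the default isotype quantile the two behave identically; the distinct
  kind records the intent (Tregs are dim, not strictly negative) and
  allows a different quantile to be configured for "low" gates.
* Boundary rule everywhere: a value strictly greater than the threshold
  is positive. Events exactly at a threshold are negative.

Panels serialize to a YAML/JSON schema (both built-ins ship as fixtures
under `cytopanel/panels/`); `validate_panel` checks all structural
invariants and returns one diagnostic per violation instead of raising,
so a panel author sees every problem at once.

## Synthetic data generator

The simulator draws complete experiments — donors × conditions ×
replicates × stain types — with per-event ground truth. One sample is a
mixture of disjoint *truth populations*, each with a marker profile
(per marker: negative, low, or positive) and a scatter class
(lymphocyte or monocyte). Defaults approximate healthy-donor PBMC
composition (e.g. Panel 1: 10% B, 20% CD8 T split naive/memory, 30%
CD4 T of which 4 points are Tregs, 4% γδ T, 20% monocytes, remainder
"other live"); users can replace the population list wholesale.

* **Expression** is a two-component log-normal mixture per marker:
  background (median 100, log-scale SD 0.5) vs positive (median 8,000,
  log-scale SD 0.5), plus an intermediate "low" component (median 150)
  for CD127 on Tregs. The components are well separated: the 99.5th
  percentile of background (~360) sits far below the positive bulk, so
  gating against an isotype-derived threshold is nearly
  deterministic — deliberately, because this makes the truth-label
  oracle exact. Real data have spread, spillover-induced broadening and
  continua between negative and positive; passing the recovery tests
  therefore demonstrates correctness of the machinery, not expected
  performance on arbitrary real samples.
* **Scatter**: log-normal clusters for lymphocytes (FSC-A ~60k) and
  monocytes (~130k), a low-FSC debris cloud (5% of events), and
  doublets (2%) built by summing two singlet draws with sub-additive
  FSC-H (0.6 × sum), which is what the FSC-H/FSC-A singlet gate keys
  on. Debris + doublets + singlets account exactly for `n_events`.
* **Viability**: live cells carry dye background; dead cells (default
  25%, i.e. the 3:1 live:dead ratio used when constructing dye
  controls) carry a bright log-normal dye signal (median 20,000). The
  live/dead boundary is a fixed threshold (default 2,000) rather than
  an isotype quantile, because every stained sample — isotype controls
  included — contains a genuine dead-cell population on that channel.
* **Activation**: each activation marker has a baseline positive
  fraction of 5% in every live population. A condition adds, per
  affected population, an increment to that fraction and an optional
  log-shift of the positive component. The built-in positive-control
  conditions (LPS/PHA-M and PMA/Ionomycin for Panel 1; ODN2216/PHA-M
  for Panel 2) use increments of +0.10 to +0.40 — no quantitative
  effect sizes exist for these stimuli in the assay-qualification
  context, so these defaults were chosen once for clear separability
  and are user-configurable rather than data-derived.
* **Donor effects**: one multiplicative log-normal factor per donor
  (SD 0.15) on population fractions (renormalized) and one (SD 0.10) on
  positive expression medians, reproducing between-donor variation in
  both composition and staining intensity.
* **Determinism**: every sample's random stream is seeded by a SHA-256
  hash of (seed, donor, condition, replicate, stain type), so cohorts
  are bit-reproducible and adding samples never perturbs existing ones.
  The *cell draw* (labels, scatter, dead flags, activation states,
  viability signal) is keyed without the stain type: a fully-stained
  sample and its isotype/FMO controls see identical cells, as matched
  aliquots of one culture well should. Isotype and unstained samples
  draw only background on antibody channels; FMO samples omit exactly
  one reagent; single-stain controls are bead-style 50/50
  positive/negative mixtures on one detector.
* **Spillover** is the standard linear model: observed = true @ S, with
  S the unit-diagonal fluorophore-into-detector matrix. The default
  spec uses S = identity; tests and the acceptance script plant
  explicit matrices.
* **Intrinsic drug fluorescence** (the interference forward model) adds
  `gain × concentration × L` to listed detectors with a per-event
  log-normal loading L, emulating a formulation whose chromophore
  fluoresces into specific channels.
* `n_events` defaults to 100,000 — scaled down from the ≥500,000-event
  acquisition target of a real run to desk scale.

## Controls

**Spillover estimation** from single stains: for each stained detector,
events are split positive/negative at the 99.5th percentile of the
unstained background on that detector; `S[i, j]` is the ratio of median
shifts `(med_pos_j − med_neg_j) / (med_pos_i − med_neg_i)`. Negative
estimates are clipped to 0, the diagonal forced to 1. An inseparable
single stain (too few positives, or non-positive median shift on the
primary detector) raises an error naming the channel. **Compensation**
solves the per-event linear system; scatter and truth labels are
untouched, and compensation is linear in the event matrix.

**Stain index** uses `(median(positive) − median(negative)) /
(2 × robust-SD(negative))`, robust-SD = 1.4826 × MAD. Vendor software
computes a stain index whose exact formula is unpublished; the
median/robust-SD form is adopted because it is insensitive to the heavy
tails of cytometry distributions, and SD-vs-robust-SD and mean-vs-median
are configurable. The positive component is the stained events above the
99.5th percentile of the negative distribution; if fewer than 2% of
events land there (~0.5% is expected by chance), the sample is treated
as having no separable positive population and the whole stained sample
is used, so an unstained-like sample scores ~0. **Optimal dilution** is
the stain-index argmax with ties broken toward the larger dilution
factor (less antibody).

**Interference screen**: per detector, the robust standardized median
shift of treated unstained cells vs untreated unstained cells; a
detector is flagged at ≥3 robust SDs (configurable). The real decision
is made by eye on histogram overlays; 3 rSDs is a conservative
operational surrogate. The FMO over/under-compensation check is likewise
a visual judgment, so the package provides only an overlay-statistics
report (`fmo_overlay_report`) and never edits a compensation matrix
automatically.

## Gating

Scatter gates are reproducible surrogates for hand-drawn regions:

* main cells: per-axis percentile trimming (keep [p2, p99.5] of FSC-A
  and SSC-A) plus a fixed FSC-A floor (20,000) that removes debris;
* singlets: FSC-H/FSC-A ratio within [0.8, 1.2];
* monocyte/lymphocyte split (Panel 2): a fixed FSC-A boundary (90,000 in
  the simulator's units) chosen between the two scatter clusters; the
  two regions are complementary, hence partition live singlets. All
  boundaries are configurable via `GatingConfig`.

Marker thresholds come from *condition-matched isotype controls*: the
isotype sample is gated through scatter/singlet/viability, then each
threshold gate receives the 0.995 quantile of the isotype distribution
on its channel among those live singlets. The quantile corresponds to a
0.5% false-positive rate, standard practice for isotype gating; the
gating rule (isotype sets the negative boundary; activated samples use
activated isotype controls) is enforced by sample pairing in the
pipeline. Because an isotype sample has no specific signal anywhere,
every threshold is computed on the live-singlet pool rather than inside
recursively marker-gated parents (which would be nearly empty by
construction). Quadrant thresholds for activation markers use the same
isotype quantile on the activation channels; where a marker appears both
as a population gate and an activation axis (CD25 in Panel 1), the two
share one threshold — the data give no basis for distinct values, and
users who disagree can override the threshold set directly.

Per population the engine reports event count, percent-of-parent and
percent-of-live; populations with activation markers additionally get
the four quadrant percentages (−/−, +/−, −/+, +/+ — first sign is the
first activation marker) and each marker's whole-population gMFI.
Empty-parent percentages are reported as 0 with an explicit flag rather
than NaN, keeping downstream tables rectangular while preventing silent
misreading of rare populations.

## Readouts

gMFI is `exp(mean(log(values)))` over positive values; non-positive
events (possible after compensation) are excluded with the count
reported, and the statistic is flagged undefined when more than half the
events are non-positive. Shift-transforms were rejected because they
distort fold changes. The stimulation index divides replicate *means*
(treated over reference) rather than averaging per-replicate ratios,
matching how technical repeats are averaged before group comparison.
gMFI endpoints use the whole population per activation marker;
quadrant-restricted gMFI is available as an option but not the default,
since restricting to threshold-selected events makes the gMFI depend
discontinuously on the threshold.

The SI table contains, per (donor, treatment): one percent-of-live SI
per population, and per activation-flagged population the SI and the raw
replicate-averaged value of each quadrant percentage plus two gMFI SIs —
37 endpoints for Panel 1, 45 for Panel 2. Vehicle controls serve as the
reference where configured (e.g. Feraheme vs PBS, AmBisome vs 5%
dextrose); everything else compares to the unstimulated control. No
(donor, treatment, endpoint) cell is silently missing — absent inputs
yield flagged NaN entries.

## Statistics

**Reproducibility**: gate-percentage vectors of negative-control runs
are compared by Pearson correlation; runs are clustered by complete
linkage on the Euclidean distance matrix between rows of R. Zero-
variance runs are kept as flagged NaN rows rather than dropped.

**Paired t + exhaustive sign-flip permutation.** Each treatment is
compared to its reference by a classical paired t-test on donor-wise
differences of replicate-averaged gate percentages. With N donors there
are `2^(N−1) − 1` unique treated/control label swaps once global
negation is collapsed (a full swap negates t and leaves the two-sided p
unchanged) — three permutations at N = 3. One flip vector is applied
jointly to *all* endpoints of a treatment, preserving the strong
dependence between gate percentages in the null; per-endpoint
independent flipping was explicitly rejected because it would break
exactly the correlation structure the design is meant to keep. All
permuted p-values within a run (one panel) are pooled, and each real p
is scored as `perm_p = (b + 1) / (m + 1)` with `b` the pooled values
*strictly* below it. Strict counting follows the formula as stated for
this workflow; a `strict=False` switch provides the at-or-below variant
used in the standard permutation-p construction the approach derives
from. Degenerate permuted statistics (zero variance after flipping) are
retained in the pool with p = 1 and flagged — dropping them would shrink
m invisibly and bias perm_p downward. Tests with fewer than three
complete donor pairs are excluded entirely: they contribute nothing to
the pool and carry no permutation p-value. Whether pooling should span
treatments as well as endpoints is not fully settled; the default pools
across both within a panel (one null per run), configurable by calling
`permutation_analysis` per treatment.

Two utilities justify the design: `wilcoxon_min_p(n)` enumerates the
exact signed-rank null to show the best attainable two-sided p at
N = 3 is 0.25 (so rank tests are hopeless at this sample size), and
`value_to_beat(pooled, alpha)` returns the largest real p that still
achieves `perm_p < alpha` — with only m = 3 pooled values the answer is
"unattainable", which is precisely why pooling across endpoints is
needed. Standard multiplicity corrections (e.g. Benjamini–Hochberg) are
deliberately not provided for this analysis: they assume independence
that gate percentages do not have.

## Pipeline and I/O

Events travel as plain CSV (comma, ".", UTF-8) or FCS 3.1. No
maintained FCS library ships with the scientific stack this package
targets, so a minimal FCS 3.1 reader/writer (list-mode float data,
TEXT keywords, `$SPILLOVER` round-trip) is included; it is not a
general FCS implementation. A cohort directory holds event files plus a
`manifest.csv` (sample identity and pairing) and, for synthetic
cohorts, a ground-truth manifest. `run_pipeline` chains compensation,
condition-matched threshold fitting, gating, SI assembly and
statistics; outputs are deterministic (byte-identical CSVs on re-run)
and every unprocessed sample lands in an exclusion log with a reason.
The CLI (`cytopanel simulate / gate / run / panel`) is a thin layer over
these functions.

## Problem sizes and tolerances

Unit tests run at 20k–30k events per sample; recovery and acceptance
checks use the default 100k. At these sizes the key margins are:
spillover round-trip max relative error < 1e−6 (observed ~1e−13);
planted spillover coefficient recovered within ±0.01 (observed ~0.001
at 10k events); every population's percent-of-live within ±2 points of
the truth-label oracle (observed ≤ ~0.6); a planted two-fold activation
effect recovered as SI = 2 ± 10% (the ~5% attenuation comes from the
0.5% isotype false-positive bleed entering numerator and denominator
asymmetrically); and the pooled permutation test's type-I fraction at
α = 0.05 stays at or below 0.05 within Monte-Carlo error across 200
simulated null cohorts.

## Known limitations

* The simulator's components are cleanly separated log-normals; it does
  not model spectral spreading error, autofluorescence heterogeneity,
  time drift, or continuum marker expression, so recovery margins on
  real data will be wider than the test margins.
* Spillover estimation assumes a linear instrument response and one
  single-stain control per detector; spectral unmixing with more
  fluorophores than detectors is out of scope.
* The monocyte/lymphocyte split is a fixed boundary, appropriate for
  the simulator's well-separated clusters; real data may need the
  boundary moved or a density-based split, which the config allows only
  as a fixed value.
* Donor-specific results of any particular wet-lab study (specific
  heat-map values or pooled-null thresholds) depend on raw data and are
  not reproduced by the synthetic cohorts.
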