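# Methods

`redoxcyto` quantifies redox heterogeneity in single cells carrying the
Grx1-roGFP2 glutathione sensor, from two-channel flow cytometry, plate-reader
growth curves, time-lapse microscopy, and paired protein/transcript abundance
matrices. This note records the models, the parameters that matter, and the
design choices made where more than one reasonable implementation existed.

## Probe model and OxD

roGFP2 has two excitation maxima (405 and 488 nm) whose relative intensity
flips with the oxidation state of its engineered disulfide; the fused Grx1
equilibrates the probe with the glutathione couple. The degree of probe
oxidation of an event with intensities (I405, I488) is

    OxD = (I405·I488red − I405red·I488)
          / (I405·I488red − I405·I488ox + I405ox·I488 − I405red·I488)

with the four control anchors taken from chemically clamped populations
(40 mM DTT → fully reduced, 8 mM diamide → fully oxidized). Written in terms
of the per-event ratio R = I405/I488 and the endpoint ratios Rred, Rox it
becomes

    OxD = (R − Rred) / ((Rox − R) + (R − Rred)).

Two numerical facts about these forms, verified by the test suite:

* The ratio form's two-term denominator collapses to the constant
  Rox − Rred, so it is affine in R. It is nevertheless implemented term by
  term as written, and any nonpositive denominator flags the event's OxD as
  NaN rather than aborting a batch.
* The six-intensity form equals the ratio form exactly whenever the two 488
  anchors coincide; this identity is property-tested on random events.

OxD is **not clipped** to [0, 1] by default. Normalizing individual cells
against population-average endpoints legitimately produces values outside the
nominal scale (bright outliers can read as >100% oxidation); clipping is an
explicit opt-in so the inflation stays visible.

For imaged cells the same linear normalization is applied to the ratio of
area-mean intensities, giving OxD\* = (R̄ − Rred)/(Rox − Rred). The printed
single-channel normalization (Imean − Ired)/(Iox − Ired) is available as
`oxd_star_single_channel`, but the ratiometric form is the default because it
is independent of probe expression level, which varies with age and
treatment. A literal single-channel mode would confound oxidation with
expression.

## Calibration fitting

Controls are fit with a **zero-intercept** least-squares line i405 = s·i488
on the linear intensity scale (slope = Σxy/Σx²); the reduced and oxidized
populations separate as two lines through the origin, so a pure ratio model
is the natural parameterization (a free-intercept mode exists). R² is
computed against the mean of i405 so that a through-origin fit of
uncorrelated data scores near zero.

The stored intensity anchors are the measured 488 channel mean and the fitted
line evaluated there (i405 anchor = slope × mean488). This makes the slope
and the anchor ratio identical by construction, so the six-intensity and
ratio forms of OxD agree exactly for any event; using raw channel means for
both anchors would leave a small noise-dependent discrepancy between the two
forms. At least 50 live, probe-positive events are required per control, and
a fitted oxidized slope at or below the reduced slope raises a
calibration-inversion error (swapped controls).

## Gating and classification

Events pass a viability gate (dye signal ≤ `pi_max`, default 1000 a.u. for
the synthetic dye scale) and a probe-positive gate (both excitation channels
≥ `gfp_min`, default 25 a.u.). Classification is by ratio bands on the
linear scale: reduced if R ≤ 1.2, oxidized if R ≥ 2.5, intermediate between.
The explicit intermediate band reflects that a small group of cells falls
between the two populations; fractions are reported over live probe-positive
events and deliberately need not sum to 1 once undefined-ratio events
(i488 = 0, excluded and counted, never imputed) are accounted for. Every
gate records its exclusion count in the table attributes and the pipeline
manifest.

The ratio density uses a Gaussian KDE with Silverman's factor on the linear
ratio scale; modes are local maxima with prominence above 1% of the peak
density (suppressing sampling ripples). Per-sample summaries subsample to
10,000 events (seeded) when more are present, mirroring a fixed acquisition
count per analyzed population.

## Synthetic measurement model

The generators define the conditions under which the pipeline is tested.

**Cytometry.** Probe expression (the 488 intensity) is log-normal
(meanlog = ln 100, sdlog = 0.4 — a realistic ~40% expression CV). Control
events sit on slopes 0.6 (reduced) and 3.57 (oxidized) with 5% multiplicative
noise on the 405 channel given 488; this is the simplest model that keeps
the control fits at R² ≥ 0.97. Aging cultures are mixtures of dead,
probe-negative, reduced, intermediate, and oxidized events. The oxidized
fraction among live probe-positive cells is logistic in culture age
(midpoint 60 h, steepness 10 h, plateau 0.45), which places the largest
reduction-to-oxidation shift in the 48→72 h interval while keeping the
majority of cells reduced even at 96 h. **In-culture oxidized cells are
drawn around their own ratio mode (7.0, sdlog 0.25), not the diamide-control
slope**: untreated oxidized cells have a distinct expression pattern and sit
at ratios ≥ 6, well above the clamped control at 3.57. The intermediate
fraction defaults to 2% — the un-gated sliver between the bands, a free
parameter of the model. Dead cells carry a high viability-dye level;
probe-negative cells sit at an autofluorescence floor (~8 a.u.). A hidden
`truth_state` column supports recovery tests; end-to-end, the classified
oxidized fraction tracks the generating truth within 0.02 at n = 10⁴.

**Growth.** OD600 recovery of sorted subpopulations is lag–logistic
(od0 = 0.1, carrying capacity 1.5, 15-min sampling over 24 h, 1% log-normal
measurement noise). Configured minimal doubling times are (reduced, oxidized)
= (90, 125) min at 48 h, (95, 135) at 72 h, and (150, 155) at 96 h, with
lags ~2–2.7 h at 48/72 h and 5.5–6 h at 96 h: reduced cells recover faster at
48 and 72 h, both subpopulations converge to similar, slower doubling after
longer lags at 96 h.

**Trajectories.** Below the commitment threshold θ = 0.7, OxD\* follows a
discrete mean-reverting walk around a reduced set-point of 0.4 (reversion
0.15/frame, step noise SD 0.05, 10-min frames over 12 h) — cells transiently
oxidize toward θ and self-correct. At or above θ oxidation is absorbing:
strictly increasing drift (0.03/frame) until a death level of 1.2. Ten
percent of founders are born already above θ (0.72–0.95); 5% of tracks lose
probe signal and are truncated with fate `signal-lost`. Budding occurs at a
rate that falls linearly from 0.25/h at OxD\* = 0 to zero at θ; the daughter's
first frame copies the mother's OxD\* **exactly** — inheritance of the redox
state, not a noisy copy.

**Omics.** The design is 2 redox states × 2 ages × 3 biological replicates.
Protein log2 intensities are Gaussian around per-feature baselines
(noise SD 0.25); 150 of 1500 features carry a redox effect of |log2FC| ≈ 2
± 0.5 with random sign, consistent across age, plus a tiny age effect
(SD 0.05) — so samples cluster by redox status before age. Transcripts are
negative-binomial counts (dispersion 0.1) with the same planted effects,
except two uncoupled features (Hsp30-like and Yro2-like) whose protein is up
in the reduced cells (log2FC −2.5) while their transcript moves the opposite
way — the protein–transcript anti-correlation the coupling classifier must
recover.

**Phenotypes.** Scar counts are Poisson with a reduced-group mean of 0.7
(mostly ≤ 1 scar) and an oxidized/reduced ratio of 3.75 (inside the
3–4.5-fold band); budding flags are Bernoulli with fractions
(oxidized, reduced) = (10, 30)% at 48 h, (9, 21)% at 72 h, (6, 15)% at 96 h.

What the generators do **not** emulate: instrument spillover/compensation,
correlated multi-channel drift, doublets, cell-size effects on fluorescence,
protein-intensity missingness mechanisms beyond missing-at-random dropout,
library-size artifacts in counts, or segmentation/tracking errors in the
imaging data. Passing tests therefore demonstrate that the algorithms
recover truth under the stated statistical structure, not that they are
robust to every artifact of real instruments.

## Growth statistics

The log-phase window is the maximal contiguous run of consecutive-point
log10(OD) slopes that (a) reach at least half the global maximum slope and
(b) start below 90% of the curve maximum (excluding lag and plateau), after
an optional 3-point median filter that removes plate-reader spikes. Within
the window, MDT is derived from the steepest consecutive-pair slope s of
log10(OD): literally inverting s yields the time per *ten-fold* increase,
so the default converts via MDT = log10(2)/s — an exactly doubling culture
then returns its true doubling time (verified for a 90-min doubling series);
`literal_invert=True` retains the raw inversion for compatibility. MDT is
invariant to uniform OD rescaling and equals the brute-force minimum over
consecutive-pair doubling times (oracle-tested).

Lag is the linearly interpolated time until OD first exceeds 1.5× its
initial value (no standard formula exists for recovery lag; the factor is
configurable and lag is non-decreasing in it). A curve that never crosses is
censored at its horizon and flagged.

## Threshold estimation

Self-correction events are local maxima followed by a drop of at least
δ = 0.1 OxD\* (the default must exceed frame-to-frame noise; configurable)
before the series next exceeds the peak. The commitment threshold is
bracketed from below by `max_recovered_from`, the highest peak any cell
recovered from.

The upper bracket needs care. Reading "the lowest value from which a cell
never again dropped by δ" literally off each trajectory returns the foot of
a committed cell's final ascent — typically near the reduced set-point — or
even a transient low dip that the cell simply never revisited, and the
bracket collapses. The estimator therefore works at the level of visited
OxD\* values pooled across cells: a commitment candidate is a value that
(a) was followed by a further rise of at least δ (it lies on a genuine
rise, not flat noise), (b) was never afterwards escaped downward by δ, and
(c) lies **above** `max_recovered_from` — levels at or below the highest
recovered peak are demonstrably escapable, so a never-recovered visit there
is absence of evidence, not evidence of commitment. `min_committed_from` is
the lowest such value; θ̂ is the midpoint of the two brackets, which by
construction satisfies max_recovered_from ≤ θ̂ ≤ min_committed_from. With
only one side observed the estimate is that bound, flagged one-sided.
Uncertainty comes from a seeded bootstrap over cells (1000 resamples,
percentile 95% CI). Cells with fate `signal-lost` are excluded throughout.
On 200-cell default ensembles the estimator recovers the generating θ = 0.7
within ±0.05; whether commitment should be assessed per cell or pooled is
not settled by the data, and the pooled form was chosen because single
trajectories rarely contain both a deep recovery and a commitment.

## Trajectory clustering and inheritance

Trajectories are resampled onto a common time grid (median frame interval)
by linear interpolation; frames outside a cell's tracked span are missing
and ignored pairwise in Euclidean distances (tracks with no overlap are
assigned twice the largest finite distance). Clustering is agglomerative
with average linkage, cut at k (default 4, matching the number of
qualitative trajectory classes: stay-reduced, long self-correction, short
self-correction, born-oxidized); inputs are sorted by cell id first so the
labels are order-independent and deterministic. No algorithm is canonical
for this task; average linkage on resampled series was chosen for
determinism and robustness to unequal sampling.

Mother–daughter concordance reports |ΔOxD\*| at the separation frame and 60
minutes later, plus a flag for daughters whose OxD\* subsequently fell by δ
(self-correction of the inherited state). Against a random re-pairing null
the observed mean |Δ| at separation sits below the null's 1st percentile.

## Differential abundance and coupling

Protein intensities are compared per feature (oxidized vs reduced at fixed
age; positive log2FC = up in oxidized) with a nan-aware Welch t on the log2
scale. Features missing in more than one replicate of either group are
excluded up front; surviving missing values are handled by omission, never
imputed. Significance requires q ≤ 0.05 **and** |log2FC| ≥ 1 (two-fold).

The default multiplicity correction is permutation-based, with three
numerical safeguards that matter at n = 3 vs 3 (each one measured on null
simulations during development):

1. **Moderated ranking.** Permutations are ranked by d = Δ/(s0 + se) with
   s0 the median per-feature standard error, not by raw t: at three
   replicates a feature with freak near-zero within-group variance can reach
   |t| ≈ 10–30 with a negligible fold change, and the pooled relabeling null
   cannot reproduce such values. The reported `t` column remains the plain
   Welch statistic.
2. **Exhaustive distinct relabelings.** With 3 + 3 samples only 10 balanced
   splits exist; the observed grouping and its mirror are excluded (they
   would leak signal into the null) and the rest are enumerated exactly
   once. Resampling the same few splits hundreds of times would inflate the
   null denominator without adding evidence, pushing p-values far below the
   design's real resolution.
3. **Add-one smoothing.** p = (1 + #{null |d| ≥ |d_obs|}) / (1 + total),
   so no p-value can claim more precision than the reference set supports.

Per-feature permutation p-values are then Benjamini–Hochberg adjusted, which
equals the classical pooled E[false positives]/R estimate after the
monotonicity pass and guarantees q ≥ p. On fully null simulations the
realized false-discovery proportion averaged over 50 seeds is at or below
the nominal 0.05 (the construction is conservative); planted two-fold
effects at noise SD ≤ 0.3 are detected with sensitivity ≥ 0.9. Swapping the
group labels negates every log2FC and leaves every p unchanged (the null is
built from a canonically ordered sample matrix). `method="bh"` switches to
plain BH on parametric Welch p-values.

Transcript counts are normalized to parts-per-million per sample and tested
on log2(PPM + 1) with the same machinery. This is a substitute for a
negative-binomial count model — adequate for the two-fold/FDR screening done
here, mildly anti-conservative for very low counts — and every result table
carries a note saying so.

Coupling classification considers protein-significant genes only: same-sign
transcript log2FC → coupled, opposite sign → uncoupled, each named by the
direction of the protein change; a transcript fold change of exactly zero
counts as coupled (no opposing evidence). Everything else is `ns`.

Hierarchical clustering of normalized matrices uses the centered-correlation
distance (1 − Pearson r) with average linkage; row normalization divides by
the row median before log2 (row medians of the output are exactly zero for
odd sample counts). Dendrograms export as Newick text.

## Interfaces and reproducibility

Event tables read/write as FCS 3.1 (a self-contained list-mode float reader/
writer covering FCS 3.0/3.1 float, double, and byte-aligned integer data)
or delimited text, with a configurable channel-name mapping; growth curves,
trajectories, phenotypes, and abundance matrices travel as TSV. Every
generator and analysis entry point takes an explicit seed; identical
(config, seed) reruns are byte-identical, and the pipeline manifest records
the package version, seed, config hash, and per-stage exclusion counts.

Default problem sizes (10,000 events per cytometry sample, 200 trajectory
founders, 1500 omics features, 10,000 phenotype cells per group) match the
study design where one is stated and otherwise were chosen once as typical
for the instrument class; the full test suite runs in well under a minute.

## Known limitations

* Ratio-band gates approximate the original 2-D sector gates; the exact
  sector geometry is instrument-session-specific and not reconstructable,
  so both bounds are configurable instead.
* The threshold estimator assumes commitment is absorbing; slow recoveries
  spanning longer than the observation window would bias θ̂ upward.
* The RNA test is a log-scale substitute, not a count model.
* Organelle-targeted sensors (mitochondrial, peroxisomal) are handled by the
  same math with their own calibrations; no organelle-specific physics is
  modeled. Absolute redox potentials (Nernst conversion) are out of scope.
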