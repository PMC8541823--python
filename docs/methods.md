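# Methods

This note documents the models and procedures implemented in `synaptoquant`,
the parameter choices that matter, what the synthetic-data generators do and
do not emulate, and the package's numerical conventions.

## Quantal analysis of mEPSP amplitude histograms

### Model

Spontaneous mEPSP amplitudes are modelled as a finite Gaussian mixture whose
structure is fixed by quantal release. The quantal content *i* of an event
follows a binomial distribution with parameters *n* (releasable quanta) and
*p* (release probability):

    P(i) = C(n, i) p^i (1 - p)^(n - i)

By default the binomial is truncated to i ≥ 1 and renormalised, because a
recorded spontaneous event contains at least one quantum; the untruncated
variant is available (`truncated=False`), in which case i = 0 events are
assigned zero amplitude. The amplitude of an *i*-quantum event is Gaussian
with mean i·q and SD

    sigma_i = i^e · sigma0,      e ∈ {0.5, 1.0}

The exponent `peak_sd_exponent` is configurable because both conventions
appear in the quantal-analysis literature: e = 0.5 follows from independent
quantal variability (variances add across quanta), e = 1.0 makes the peak SD
proportional to quantal content. The default is 0.5 (variance additivity);
the choice is printed in every fit summary so it can never be silent.

Expected counts per histogram bin are computed by Gaussian CDF differences
over the bin edges — not midpoint densities — because the 0.01-mV default
bin width can be comparable to sigma_i when sigma0 is small. The sigma0 = 0
degenerate case places each peak's whole mass in the bin containing i·q
(with the package-wide convention that a value exactly on a bin edge belongs
to the right-hand bin).

### Histogram conventions

Histograms are anchored at 0 mV with uniform half-open bins [k·w, (k+1)·w),
default w = 0.01 mV. Trailing empty bins are trimmed; leading bins down to 0
are kept so bin k always spans [k·w, (k+1)·w). Counts may be non-integer so
that expected-count pseudo-histograms can serve as fit targets in
self-consistency tests.

### Fitting

The objective is the Poisson negative log-likelihood of the bin counts under
the expected counts, with the mass falling outside the histogram range
entered as a censored (zero-count) term. Because the total expected mass
over bins-plus-outside is exactly the event count, the objective reduces to
a constant minus the count-weighted log term, which makes the fit invariant
to padding the histogram with empty bins. A least-squares objective is
available for comparison (`objective="lsq"`); it does not share the padding
invariance. The choice of a count-based likelihood reflects that bin counts
are Poisson-like; no objective is canonical for this analysis, so both are
exposed.

Optimisation: an exhaustive grid over integer n ∈ [1, n_max] (default 10),
with bounded L-BFGS-B multi-start optimisation of (q, sigma0, p) inside each
n. q is initialised from the dominant spacing of histogram peaks (first
positive local maximum of the autocorrelation of the lightly smoothed,
demeaned counts), falling back to the histogram mode for single-peak data.
Start jitter is seeded; ties in the objective are broken toward smaller n
(the parsimonious model). If no start yields a finite objective the fit
raises an explicit failure — there is no silent default. Fits require at
least 30 events (configurable floor).

With a few hundred events the higher-order peaks carry little mass, so
(n, p) are weakly identified while q and sigma0 are robust; the quantal size
q is therefore the reported endpoint. Parameter-recovery behaviour is
characterised in the test suite at N = 500 events per cell (20 seeded
replicates; median relative error of q̂ is required ≤ 10%) and with a
10⁶-event Monte-Carlo histogram checked bin-wise against the analytic
expectation.

Event detection from raw voltage traces is out of scope: inputs are event
amplitude lists (CSV), matching how such recordings are exported after
manual or template-based detection.

## Larval locomotion

Per-frame tracker tables (centroid, projected area, spine length, mid-spine
width; 12.5 frames/s and 120-s recordings by default) are reduced to:

* **traveled distance** — summed Euclidean centroid displacement (mm);
* **peristaltic wave count** — the projected area oscillates once per
  peristaltic cycle, so waves are counted as peaks of the smoothed area
  curve;
* **stride size** = distance / waves (mm), **stride duration** = recording
  time / waves (s). Both identities hold exactly by construction; zero waves
  yields flagged NaN metrics rather than an exception;
* **body dimensions** — time-averaged spine length and width;
* **QC flags** — `escaped` when the centroid leaves the arena bounds;
  `burrowed` (a proxy, since the original exclusions were by eye) when the
  area stays below 50% of its median for more than 2 s.

Smoothing is Savitzky–Golay with an 11-frame window (~0.9 s at 12.5 fps) and
polynomial order 3 — short enough to preserve waves at the 1–2 Hz
peristaltic rhythm, long enough to suppress frame noise; both are
configurable since no standard values exist. A peak counts as a wave when
its prominence exceeds 0.25× the interquartile range of the smoothed series
(scale-free) **and** a noise-adaptive floor of 4× the measurement-noise SD
estimated from the smoothing residual (1.4826·MAD). The floor is what keeps
a stationary larva at zero waves: residual noise in a flat series produces
occasional peaks whose prominence can exceed any fraction of the (noise-
dominated) IQR, but stays well below 4 sigma of the residual scale, while
genuine waves exceed it by an order of magnitude.

Pixel-to-mm conversion is assumed done upstream (the tracker itself is not
reimplemented); the internal unit is mm.

## Paired-scan imaging

Both pH-probe protocols reduce to one metric. A terminal is scanned in
standard saline, the solution is exchanged (acidic saline quenches
surface-exposed probe; NH₄Cl saline collapses vesicular pH gradients and
reveals intravesicular probe), and the terminal is scanned again. Each
Z-stack is maximum-projected; a single fixed threshold is applied to both
scans of a pair; the fraction of pixels **strictly** above threshold is the
signal measure; the reported ratio is second-scan fraction over first-scan
fraction. A first-scan fraction of zero flags the ratio undefined rather
than dividing by zero.

The threshold value is acquisition-specific and is a required input — it is
never chosen automatically. An Otsu-based suggestion (`suggest_threshold`)
is provided for orientation only. Area fractions are invariant under any
strictly monotone intensity transform applied with a correspondingly
transformed threshold, and the paired ratio is scale-free; both properties
are tested.

FM-dye cycling uses intensities instead of areas: the dye signal is summed
(and averaged — both conventions are reported, since either may be meant by
a mask-restricted intensity ratio) inside a binary mask derived from a
membrane marker, and the released fraction is 1 − unloaded/loaded.

Bouton morphology enters as a list of manually measured diameters; the
endpoint is the fraction strictly greater than a 4-µm cutoff ("superior to"
is read as strict, and the same strictness is used for thresholding).
Registration between scans, bleaching correction and bouton segmentation are
out of scope.

## Co-IP enrichment chain

The chain mirrors vendor label-free quantification for a bait-vs-control
pull-down series with three independent experiments:

1. **TOP3** — protein abundance per (experiment, group) is the mean of its
   three most intense peptides; with fewer than three, the mean of those
   present (vendor behaviour; the peptide count is kept alongside so such
   cells remain identifiable).
2. **Presence filter** — keep proteins observed in ≥1 group in ≥2 distinct
   experiments; dropped proteins are logged with a reason.
3. **Imputation** — missing abundances are set to the minimum observed
   abundance of their experiment. "Minimum of the experiment" is read as
   the global minimum over all proteins and both groups of that experiment
   (vendor convention); a per-group mode is available behind a flag.
4. **Ratios** — per experiment, log₂(bait/control).
5. **Call** — enriched ⇔ log₂ R ≥ log₂(fold threshold) in *every*
   experiment. "At least 2-fold" is boundary inclusive: log₂ R = 1 passes.
6. **Annotation** — enriched proteins are checked against a bundled list of
   *Drosophila* V-ATPase subunit and accessory genes; the bait is flagged
   separately and excluded from the subunit count.

The chain is order-enforced (filter → impute → ratios → call): imputing
before filtering would manufacture presence, and ratios require complete
positive values; calling a stage out of order raises a state error rather
than silently producing shifted results. The enrichment call is invariant
under rescaling all abundances of one experiment (ratios cancel), which is
also tested.

The packaged worked example is a 12-protein log₂-ratio table from a
V5-tagged CG31030 pull-down on fly head extracts, entering the chain at the
ratio stage (whether imputed values fed any of those printed ratios is not
reconstructible, so earlier stages are exercised on synthetic tables
instead). The source table mixes '.' and ',' decimal separators in one
entry; the fixture preserves the comma verbatim (as a quoted CSV field) and
the loader normalises it. The vendor's proprietary background-based t-test
is not reimplemented; the fold-change-in-all-experiments rule is what
defines the enriched set here.

## Cross genetics

Crosses are described declaratively: per chromosome, the two alleles each
parent carries; lethal rules and progeny classes as composable predicates
(`genotype` pair, `homozygous`, `carries`, with `all`/`any`/`not`). The
engine enumerates every maternal × paternal allele combination with equal
segregation (no recombination within chromosomes — balancers suppress it —
and independent assortment between chromosomes), removes genotypes matched
by a lethal rule unless its rescue exemption holds, renormalises over
survivors, and reports per-class percentages. Fully lethal classes report
0%; a cross with no survivors raises a degenerate-cross error. Percentages
always sum to 100 over surviving classes.

The bundled rescue cross encodes: mutant/balancer mothers homozygous for an
X-linked pan-neuronal driver (so every progeny inherits it, and the rescue
predicate reduces to carrying the autosomal effector), effector/balancer
deficiency fathers, balancer homozygosity lethal, and mutant-over-deficiency
lethal unless the effector is present. Balancer lethality is an explicit
rule in the YAML, not engine logic, so other crosses need no code changes.

Observed percentages are 100·count/total, reported both raw and rounded to
one decimal (the reporting convention); comparisons should use the raw
value. Partial-penetrance rescue (observed rescue below the full-rescue
expectation, e.g. from delayed transgene expression) is deliberately not
modelled.

## Synthetic-data generators

Every generator emits its generating parameters ("truth") and is
byte-reproducible under a fixed seed (`numpy.random.default_rng`). Noise
models are the simplest structures satisfying each stage's assumptions.

* **mEPSP events**: exact sampling of the generative model (binomial content,
  Gaussian peak widths, optional baseline noise; non-positive draws redrawn);
  uniform event times over a duration set by a 2-Hz default rate. Not
  emulated: baseline drift, event overlap, detection thresholds near the
  noise floor — so recovery tests validate the estimator, not event
  detection.
* **Crawl**: sinusoidal area oscillation (one cycle per wave, amplitude 12%
  of a 4-mm² baseline area, Gaussian noise expressed as a fraction of that
  amplitude) and a centroid advancing at constant speed along a slowly
  wandering heading, so path length equals waves × stride by construction.
  Not emulated: head sweeps, pauses, turning-induced area changes; wave
  counting on real tracks may need the configurable prominence settings.
* **NMJ image pairs**: non-overlapping 2-D Gaussian puncta (placed on a
  jittered grid) over Gaussian background noise; the recorded threshold is
  3× the background SD. Quench keeps the vesicle-visible subset of puncta in
  scan 2 (expected area ratio = vesicular fraction v); collapse splits the
  punctum budget into membrane and vesicular populations at a 2:1 vesicular:
  membrane mass ratio and reveals all in scan 2 (expected ratio
  (1+r)/(1+v·r), i.e. ~3-fold for v = 0). Not emulated: punctum overlap,
  bleaching, focal drift between scans.
* **FM pairs**: the unloaded image is (1 − released fraction) times the
  loaded punctate signal plus noise; the mask is the union of punctum
  footprints.
* **Co-IP tables**: protein log₂ abundances uniform on [16, 24]; 1–8
  peptides per protein with bounded ionisation efficiencies (±0.5 log₂,
  a property of the peptide, shared across runs) and replicate noise
  (0.15 log₂ SD); bait-group fold changes for spiked proteins. Missingness
  is left-censoring at the identification level: a protein whose abundance
  in a given (experiment, group) run falls below the detection limit (the
  10% quantile of the baseline distribution) is not identified in that run,
  so all its peptides are missing together. This is the dominant missingness
  mechanism in label-free MS and keeps TOP3 comparable between groups;
  peptide-level dropout (which biases TOP3 upward in the sparser group) is
  deliberately not modelled, so the generator validates the chain's
  arithmetic, not robustness to partial peptide dropout.

Because the generators realise exactly the assumptions of their stages,
passing recovery tests demonstrates correctness of the implementations under
those assumptions — not robustness to the real-data violations listed above.

## Numerical conventions and problem sizes

* Half-open bins everywhere; values exactly on an edge belong to the
  right-hand bin (an epsilon guard covers floating-point representation of
  edge multiples).
* Strict ">" for intensity thresholds and the bouton-diameter cutoff.
* Undefined ratios (zero denominator) are flagged NaN results, never
  exceptions, wherever a zero denominator is a legitimate experimental
  outcome; genuine input errors raise typed exceptions.
* Frame spacing must be uniform within 1e-9 s; class percentages sum to 100
  within 1e-9.
* Test-suite problem sizes, chosen to characterise each stage while keeping
  the default run fast: quantal recovery at 500 events × 20 seeds plus one
  10⁶-event Monte-Carlo comparison; crawls of 1500 frames (120 s at
  12.5 fps); 256×256 images with ~100 puncta, 20 seeds per programmed
  fraction; co-IP tables of 200–300 proteins, 20 seeds.

## Known limitations

* The quantal fit assumes stationary q across the recording and a common
  sigma0 law; amplitude rundown or multimodal quantal size will bias q̂.
* (n, p) from mEPSP histograms are weakly identified at realistic event
  counts; treat them as nuisance parameters.
* The burrowing QC flag is a proxy for a by-eye exclusion and should be
  reviewed when applied to real tracks.
* The imaging ratio is threshold-dependent by design (that is the method);
  cross-study comparability requires a shared threshold protocol.
* The co-IP chain reproduces a fold-change rule, not a significance test;
  it makes no claim about false-discovery control.
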