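# Methods

## Session model

A session is one task run for one subject: subject metadata, an
electrode table (brain areas from {Hipp, Amg, dACC, preSMA, vmPFC,
other}; MNI coordinates), sorted single units (spike times in seconds
on a single session clock, optional per-spike waveforms in µV), the raw
TTL event stream, the trial table (Sternberg only), stimulus templates,
and the stimulus presentation list. Region groups used in summaries are
MTL = {Hipp, Amg} and MFC = {dACC, preSMA, vmPFC}.

Two picture-identity conventions coexist in the source data: trial
tables use 1–5 with 0 = absent, stimulus templates use 0-based indices
with index 5 reserved for the Sternberg null image (referenced when an
encoding slot is empty, timestamped 10 ms after the previous
presentation). The adapters own the mapping
(`pic_id = template_index + 1`) and everything downstream uses the 1–5
convention only.

All analysis windows are half-open `[t0, t1)`, so a spike on a shared
boundary is counted in exactly one of two adjacent windows and window
partitions conserve spike counts.

### NWB adapter

The HDF5 reader/writer targets the released files' group layout —
`general` (subject, electrodes), `acquisition/events` (TTL codes +
timestamps), `intervals/trials`, `stimulus/templates` +
`stimulus/presentation`, and `units` with jagged `spike_times` /
`spike_times_index` / `waveforms` arrays — using the exclusive
cumulative-offset convention, so unit *i* owns
`spike_times[index[i-1]:index[i]]`. The writer reproduces that
structure for synthetic sessions (round-trip tested) but does not aim
for full NWB schema compliance; unmodelled fields are ignored on read.
A plain-text fixture format (YAML metadata + CSV/whitespace tables,
floats at 17 significant digits) provides bit-faithful round trips for
tests without HDF5.

## Analysis windows and constants

| quantity | value | note |
|---|---|---|
| stimulus response window | 0.2–1.0 s post onset | encoding, screening and probe presentations |
| maintenance window | 0–2.5 s post delay onset | delay lasts 2.5–2.8 s; the common prefix is used |
| baseline window | first 0.5 s of fixation | fixation lasts 0.9–1.0 s; `baseline_last` switches to the final 0.5 s |
| α | 0.05 | per-component test, per unit; no multiple-testing correction across units |
| permutations | 1000 (default, ≥ 100 enforced) | seeded; exact enumeration available for n ≤ 10 |
| PSTH | 50 ms bins, Gaussian SD 75 ms | "smooth width" is taken as the kernel SD; a flag treats it as FWHM |
| ISI violation threshold | 3 ms | refractory-period criterion |

## Permutation tests

The ANOVA statistic is the standard one-way F; the t-type statistic is
the difference of sample means. Monte-Carlo p-values follow the add-one
convention `p = (1 + #{permuted ≥ observed}) / (n_perm + 1)`, which is
valid (never anti-conservative) and bounded below by `1/(n_perm+1)`.
Permuted statistics tying the observed one count as extreme; because a
mathematical tie can land an ulp away under a different summation
order, the comparison uses a relative guard of 1e-9. `exact=True`
enumerates all label assignments (limited to 10 observations) and
divides by the total count, observed assignment included.

Degenerate F values are defined as: 0/0 (all values identical) → F = 0,
x/0 (perfect grouping of non-identical values) → F = +∞, so a noiseless
perfectly-grouped observation still dominates its permutations.

Per-unit seeds derive from `(rng_seed, unit_id, stage)`, making
classification reproducible and invariant to the order units are
listed in.

### Classifier details

- **Concept**: responses pooled over encoding positions *and* probe
  presentations by default (`encoding_only` restricts to encoding).
  The max-vs-rest step runs a one-sided permutation t-test of the
  empirically preferred image against each other image and reports the
  worst p (an intersection-union test), so a unit with two equally
  maximal images fails; `maxvsrest_pooled` instead runs one test
  against the pooled non-preferred responses. Testing the empirically
  maximal image is selection-biased by construction; no correction is
  applied, matching the published procedure. Preference ties break to
  the lowest image id.
- **Maintenance**: one-sided maintenance > baseline across trials; a
  unit already labelled concept must additionally pass the same test on
  trials whose encoding set excludes its preferred image.
- **Probe**: one-sided probe > encoding (all encoding periods pooled)
  and probe > maintenance; both must pass. Under the null the
  conjunction rejects at ≤ α.
- **Screening image selection**: units significant in the permuted
  ANOVA contribute their preferred images ranked by F; remaining slots
  (of 5) are filled by the images with the largest across-unit peak
  mean response.
- **Persistence contrast**: per concept cell, mean delay rate over
  trials containing its preferred image vs trials that do not; paired
  one-sided t-test across cells (scipy). Requires ≥ 2 concept cells
  with both trial types.

## Sorting-quality metrics

Waveform features per spike: energy Σx², signed peak amplitude,
total area Σ|x|, and the first five principal components of the
energy-normalized waveforms, computed per electrode on all spikes
pooled across that electrode's units. The named features span eight
coordinates; all-zero waveforms are flagged and excluded from
normalization.

Isolation distance is reported as the squared Mahalanobis distance (the
convention under which the released dataset's median ≈ 31 is coherent)
of the n-th closest same-electrode non-member spike, n = cluster size;
it is undefined for units alone on their electrode, when non-member
spikes are fewer than cluster members, or when the cluster covariance
is singular. The projection test projects both clusters onto the line
joining their means and reports |Δmean| / pooled projected SD;
coincident means give 0 by convention. SNR uses the SD of waveform
residuals (spike minus mean waveform, pooled over spikes and samples)
as the noise estimate; `snr_peak` divides the mean waveform's absolute
peak by it, `snr_mean` the sample-averaged absolute mean waveform. The
session mean rate uses the task event span (first to last TTL), not
recording wall-clock.

## Behavior

RT is response minus probe onset; negative RTs are data errors. RT
medians include incorrect trials by default (`correct_only_rt`
restricts). For the dataset-level repeated-measures ANOVA, sessions are
first aggregated to subjects (mean of per-session median RTs per load),
since its error degrees of freedom, (k−1)(n−1), are defined over
subjects. The F is computed from sums of squares directly and
cross-checked against pingouin in the tests.

## Synthetic sessions

The generator emulates the task as administered: per trial a fixation
cross (0.9–1.0 s), 1–3 encoding images of 1 s separated by 1–200 ms
blanks, a 2.5–2.8 s delay, a probe answered after a shifted-lognormal
RT; 108 trials by default; TTL streams follow the task code tables, and
the stored trial table is derived from the same schedule, so the
events → parser → reconciler round trip is exact. Screening sessions
show each of 54–64 images exactly six times (1 s on, 16–200 ms ISI)
with occasional control-question responses.

Units spike as inhomogeneous Poisson processes (thinning) with a 3 ms
absolute dead time. Class rate profiles: concept units sit at
`baseline_hz` (2 Hz) and rise to `preferred_hz` (10 Hz) while their
preferred image is on screen, lagged by a 200 ms visual latency, and —
with `concept_persistence` — to `concept_maintenance_hz` (5 Hz) during
the delay of trials holding that image; maintenance units rise to 8 Hz
in every delay; probe units to 8 Hz after every probe; null units are
homogeneous at 2 Hz. Waveforms are a biphasic template scaled per unit
(≈ 60 µV) plus white noise (10 µV SD). Units are assigned in pairs to
electrodes so projection and isolation metrics are defined; concept
units sit on MTL electrodes and maintenance/probe units on MFC
electrodes, mirroring where those classes are reported.

Defaults chosen where the task description is silent, fixed once:
inter-trial interval U(1, 2) s; loads equiprobable; probe in/out
balanced 50/50; response accuracy Bernoulli(0.9); RT = 0.2 s +
lognormal with per-load medians 0.85/0.95/1.05 s and σ = 0.3 (loads
slow responses, as observed); screening control questions follow ~8
presentations on average; encoding repeats within a trial are off by
default (a flag enables them).

**What the generator does not emulate** — and hence what passing tests
do not certify about real data: spike-sorting errors and drift
(clusters are generated post-sorting and are stationary), non-Poisson
firing statistics (bursting, oscillatory locking; CV2 ≈ 1 by
construction), correlated noise across units, behavioral lapses
structured by trial content (accuracy is an independent coin), and
image-content statistics (templates are random 8×8 placeholders).

## Numerical choices and degenerate inputs

- Rates from empty windows are 0 Hz; rates for absent periods are NaN,
  never zero-filled.
- CV2 needs ≥ 3 spikes, ISI fractions ≥ 2; otherwise NaN. CV2 is
  scale-invariant; for iid exponential ISIs E[CV2] = 1 exactly.
- PSTH smoothing convolves the binned rates with a normalized Gaussian
  kernel (8 SD support); raw (unsmoothed) rates are retained and
  conserve spike counts exactly.
- The thinning simulator prunes spikes closer than the dead time to the
  previously kept spike; at the rates used the induced rate deficit is
  ≈ rate × dead_time (≤ 3%), which the recovery tests absorb in their
  Monte-Carlo tolerances.
- `validate_session` returns violations as data (type, field, index)
  rather than raising, is idempotent, and is order-insensitive.
- The end-of-encoding TTL doubles as the delay onset, so
  `ts_maintenance == ts_encLast_end` is legal; all other period
  timestamps must strictly increase.

## Problem sizes used in validation

The calibration suite classifies 1000 null units (5 sessions × 200,
108 trials each) at 1000 permutations per test; recovery uses 200
planted units per class (25 sessions × 8). Exhaustive-oracle checks run
at ≤ 10 observations (8! orderings for the ANOVA, C(10,5) assignments
for the t-test); the isolation-distance oracle at 500 points in 8
dimensions; the CV2 Poisson limit at 10⁵ ISIs. These sizes make the
binomial confidence bands around α = 0.05 and the > 90% power criterion
sharp while the whole suite completes in about a minute.

## Known limitations

- The NWB writer is layout-faithful, not schema-validating; files it
  produces are for round-trip testing, not archival deposition.
- Whether the probe-window rate should truncate at the response when
  RT < 1 s is unspecified in the task description; the fixed 0.2–1.0 s
  window is always used.
- Isolation distance depends on the noise spikes available on the same
  electrode; with exactly two similar-size clusters per electrode the
  larger cluster's value is undefined (fewer non-members than members),
  which the synthetic sessions exhibit by design.
- The dataset-level replication path (`replicate`) requires the
  released NWB files to be downloaded separately and is exercised here
  only through the layout-compatible synthetic writer.
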