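# Methods

## The annotation model

SWATH (sequential windowed acquisition of all theoretical mass spectra) is
a data-independent acquisition scheme: each cycle records one MS1 survey
scan over the full precursor range (here 50-1100 Da) followed by one MS2
scan per fixed 50 Da isolation window — 21 windows per cycle.  Every
precursor in a window is fragmented every cycle, so MS2 coverage is
complete, but the link between a precursor and its fragments is lost and
must be reconstructed.

This package reconstructs that link chromatographically, against a curated
spectral library, in four stages:

1. **Library curation** (`speclib`).  Raw MS/MS records are normalised so
   the base peak is exactly 100%, fragments below 5% relative intensity are
   discarded, survivors are tagged `D` (main daughter, > 75%) or `F`
   (secondary, 5-75%), near-duplicate m/z within 0.01 Da are collapsed
   (public repositories pool instruments, so transitions recur with slight
   mass shifts), and per-adduct precursor m/z values are computed and
   assigned to SWATH windows.  Spectra left without a `D` fragment, or with
   every adduct outside the acquisition range, are rejected with a recorded
   reason.  Both the "higher than 75%" and "lower than 5%" boundaries are
   strict inequalities: exactly 75 tags `F`, exactly 5 is retained.

2. **Precursor screening** (`screen`).  Each library precursor is sliced
   from the sample's MS1 scans at +-10 ppm and peak-detected.  Candidates
   must exceed an XIC signal-to-noise ratio of 30 and a sample:blank peak
   height ratio of 5 (strict > at this stage).  The observed m/z is the
   intensity-weighted mean of the centroids inside the extraction window at
   the apex scan.

3. **Fragment alignment** (`annotate`).  For every candidate, each library
   fragment is extracted (+-0.05 Da) from the MS2 scans of the candidate's
   own isolation window, with peak search restricted to the precursor apex
   +- 3 parent FWHM.  Two dimensionless statistics quantify co-elution:

       rt_shift    = |parent RT   - fragment RT|   / parent RT
       width_shift = |parent FWHM - fragment FWHM| / parent FWHM

4. **Filtration, scoring, redundancy** (`annotate`).  A fragment is
   retained when a peak exists, its sample:blank ratio is >= 5 (inclusive
   at this stage), rt_shift < 0.001417 (0.1417%) and width_shift <
   0.174965, and — after a second pass that rescales retained heights so
   the tallest is 100 — its observed relative intensity is >= 5%.  The
   two-pass rescaling uses only gate-passing fragments as the base-peak
   reference, so a background-dominated tall XIC cannot distort the scale.
   Identifications without a retained `D` fragment are discarded; a
   fragment XIC claimed by several compounds (same window, m/z within
   0.01 Da, apices within the RT gate) is awarded to the compound with the
   smaller precursor mass error; several adducts of one compound merge
   into a single identification listing all adducts.

### The width-shift threshold's unit

The width-shift gate value 0.174965 deserves a note: the number 17.4965 is
stated without a unit while the statistic itself is a dimensionless
fraction.  The default reads it as a percentage (fraction 0.174965), which
places it in the same regime as the RT gate and actually filters;
`FiltrationParams.width_shift_literal()` provides the literal reading
(17.4965 as a raw fraction), which no realistic chromatographic mismatch
ever exceeds — selecting it logs a warning that the gate is effectively
off.  Both readings are exposed because the intent is not recoverable; the
percentage reading is the package default.

### Scoring

The identification score is this package's own construction (the weights
are configuration, the formula is fixed):

    score = 0.5 * coverage + 0.3 * (1 - mean(rt_shift / rt_shift_max)) + 0.2 * cosine

where *coverage* is the library-relative-intensity-weighted fraction of
library fragments retained, the RT term averages over retained fragments
(clipped at 1), and *cosine* compares observed vs library relative
intensity vectors over retained fragments.  A perfect identification — all
fragments recovered at their library intensities with zero shift — scores
exactly 1.

### Threshold calibration and validation (`validate`)

The shift gates can be re-estimated from data: authentic standards are
acquired in both IDA (data-dependent) and SWATH modes, each precursor's
apex RT and FWHM are measured in both, and the gate is the population
standard deviation (ddof = 0) of the pooled per-ion shifts times a
multiplier k (default 1).  The statistic is pluggable because "the SD of
the total shift" admits several readings; the calibrate command reproduces
the mechanism, not any particular published number.

Inclusion/exclusion validation counts identified compounds against a
known-present and a known-absent list: sensitivity = TP/(TP+FN),
specificity = TN/(TN+FP), FPR = FP/(TN+FP).  Identified compounds on
neither list are reported as *unlisted* and never counted as false
positives, mirroring the two-list design.

## Adduct mass calculus (`ionization`)

All species are singly charged.  Mass deltas are sums of atomic masses of
the transferred atoms minus charge x electron mass, so `[M+H]+` adds
exactly the proton mass (1.0072765 Da).  Positive mode searches
{[M]+, [M+H]+, [M+Na]+, [M+NH4]+, [M+K]+}; negative mode
{[M-H]-, [M+Na-2H]-, [M+NH4-2H]-, [M-Cl]-, [M+K-2H]-, [M+FA-H]-,
[M+H2O-H]-}.  Two of these deserve comment: "[M-Cl]-" is chemically
anomalous as written, so the default table implements chloride attachment
(+34.9694 Da) with a strict literal-subtraction mode selectable;
"[M+FA-H]-" is the formic-acid adduct (+44.9982 Da) and "[M+H2O-H]-" the
water adduct (+17.0033 Da).  Windows are half-open [lo, hi) with the last
upper edge closed so the top of the range is assignable.

## Peak measurement (`peaks`)

The detector reports the three quantities the gates consume — height, apex
RT, FWHM — plus S/N and area:

* The trace is smoothed by a 5-point moving median then 5-point moving
  mean before apex search, so single-scan spikes cannot win; a peak exists
  only where the smoothed trace exceeds median + 5 robust SDs of the whole
  trace (SD = 1.4826 x MAD).
* Apex RT and height come from a weighted least-squares quadratic fit to
  log intensity over the contiguous region above 30% of the smoothed apex
  (Caruana's method; weights = intensity).  log of a Gaussian is exactly
  quadratic, so the estimator is unbiased at any peak width, and averaging
  over the peak top gives apex precision far below one cycle time — which
  the 0.1417% RT gate requires (at RT 5 min that gate is 0.007 min,
  roughly half a cycle).  Where the fit region is too small or not
  concave, the raw apex sample is used.
* FWHM is measured on the raw trace: walk outward from the apex to the
  first sample below half height and interpolate linearly.  If one side
  never crosses (edge peak) the available half-width is doubled and the
  peak flagged.
* S/N = height / (1.4826 x MAD of the intensities outside apex +- 2 FWHM),
  with the noise floored at 1 count so noiseless traces give S/N = height.
  The S/N estimator is necessarily this package's choice — the thresholds
  it feeds (S/N > 30) come from vendor software whose estimator is
  undocumented — hence the threshold is configuration, not hard-coded.
* With `expected_rt` given, the nearest local apex wins (ties: taller);
  `rt_halfwidth` bounds the search region.

## The synthetic-data generator (`synthdata`)

The generator is first-class, tested code providing ground truth for every
stage.  Defaults describe one fixed set of study conditions:

| parameter | default | rationale |
| --- | --- | --- |
| library size / fragments | 50 compounds, 4-12 fragments | small-molecule library scale at desk size |
| neutral masses | U(150, 900) Da | metabolite range inside the 50-1100 Da acquisition |
| intensity bands | base 100%; ~15% extra D; ~20% below 5% | exercises D/F tagging and the exclusion band |
| run length / cycle | 8 min, 0.012 min cycle (~0.7 s) | 1 MS1 + 21 MS2 scans x 30 ms per cycle |
| peak shape | Gaussian, sigma 0.05 min (FWHM 0.118 min) | typical UHPLC metabolomics peak |
| spiked apexes / heights | U(3, 7) min; log-U(1e4, 1e5) counts | well-retained, high-signal standards |
| RT jitter | multiplicative, SD 5e-4 | matches the relative RT-shift gate's regime |
| width jitter | multiplicative, SD 5% | fragment FWHM tracks its parent |
| noise | Gaussian, SD max(30, sqrt(I)); 40/25 background centroids per MS1/MS2 scan; 2 ppm mass jitter | shot-noise scaling plus chemical background |
| secondary adduct | [M+Na]+ at 30% height with prob. 0.3 | exercises cross-adduct merging |

IDA (data-dependent) mode emulates top-15 triggering above 200 counts with
a 3 s dynamic exclusion after three successive selections — enough to feed
the calibration workflow and fragment-overlap comparisons, not a full DDA
scheduler.

**What the simulator does not model** — and therefore what passing tests do
not establish about real data: isotope envelopes, chimeric/shared-fragment
interference beyond random m/z collisions, baseline drift and tailing
(peaks are pure Gaussians), retention-time drift between sample and blank,
matrix-dependent ionisation suppression, and detector saturation.  The
recovery and false-positive rates measured end-to-end characterise the
pipeline's mechanics under these idealised conditions, not instrument
performance.

## Numerical choices and degenerate inputs

* Relative intensities divide before scaling (`100 * (i / max)`) so the
  base peak is exactly 100.0 and curation is idempotent in floats.
* Near-duplicate collapse keeps the most intense representative, ties
  broken toward lower m/z; greedy by descending intensity.
* Fragment-overlap matching is greedy nearest-|delta m/z|, one-to-one,
  ties toward lower m/z — Hungarian matching would change nothing at these
  set sizes.
* XIC extraction sums centroid intensities in [mz-tol, mz+tol]; precursor
  tolerance is ppm-based (10 ppm), fragment tolerance absolute (0.05 Da),
  matching how the two stages are specified.
* All-zero spectra raise a degenerate-spectrum error; XICs shorter than 5
  points raise insufficient-data; an absent blank yields +inf blank ratios
  with a loud warning.
* Peak detection with zero-variance traces: the noise floor collapses to
  ~0 and any positive peak is found; all-zero traces return none.
* Determinism: a single integer seed drives every random draw
  (sample/blank use separate child streams); mzML output contains no
  timestamps, so regeneration is byte-identical.

## Problem sizes used in the shipped checks

The test suite and the acceptance script run 20 seeded end-to-end
repetitions of the default study conditions (50-compound library, 10
spiked, full 8-min runs, ~14,700 scans per run), a 24-cell peak-recovery
grid (heights 1e2-1e6, sigma 0.02-0.2 min, noise 0-5% of height, means
over 8 replicates per noisy cell), and desk-scale worked examples.  These
sizes are the package's own choice of a representative, reproducible
experiment.

## Known limitations

* Only singly charged species; no isotopologue scoring.
* Low-resolution library records are carried and flagged but not treated
  differently.
* The blank-ratio gate is applied to fragments as well as precursors by
  default (`fragment_blank_gate`); whether the original design re-tests
  fragments is ambiguous, so the fragment gate can be disabled.
* mzML support covers centroided spectra with the metadata this pipeline
  needs; profile data are rejected, not centroided.
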