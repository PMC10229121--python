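# Methods

## Mass model

The modelled species is the histone H3.1 N-terminal Glu-C limit peptide.
Glu-C cleaves C-terminal to glutamate and the first Glu of H3.1 is E50, so
the peptide is residues 1–50 (`ARTK…ALRE`), carried as a package constant.
This boundary is consistent with the acquisition geometry: the unmodified
[M+9H]⁹⁺ precursor computes to 594.126 Th and the heaviest quantified
proteoform (5ac + K4me3) to 622.137 Th, both inside the 585–640 Th MS1
window; no shorter or longer Glu-C fragment satisfies that constraint at 9+.

Masses are monoisotopic throughout: residue masses from the standard
residue table, water 18.010565 Da, proton 1.007276 Da, and PTM deltas
me1 = 14.015650, me2 = 28.031300, me3 = 42.046950, ac = 42.010565 Da.
Trimethyl and acetyl are near-isobaric (Δ = 0.036385 Da) and are stored as
distinct modifications, never merged. c-ions follow the ETD convention
(N-terminal residues + NH₃, protonated); printed integer m/z values use
round-half-away-from-zero.

The quantification space enumerates 4 K4 methyl states × all subsets of the
acetylatable lysines {K9, K14, K18, K23, K27} (128 proteoforms). K4ac and
N-terminal protein acetylation are representable by the `Proteoform` type
but excluded from the enumerated assay space — the readout quantifies K4
*methyl* states.

## Synthetic acquisitions

`simulate_run` emulates a targeted middle-down experiment:

* Each acetyl degree elutes as a symmetric Gaussian bell centred in its
  retention-time window (defaults 0ac 35–40, 1ac 45–55, 2ac 55–60,
  3ac 62–68, 4ac 69–73, 5ac 74–78 min). Windows are half-open `[start, end)`
  so the shared 55-min boundary deterministically assigns to 2ac.
* One MS1 + one MS2 scan per scan interval (default 2 s — the real
  instrument's duty cycle is not modelled; this default is an arbitrary,
  configurable density). Every MS2 scan carries the four C4⁺¹ sticks with
  expected intensities `abundance × π × bell(rt)`, where π is the degree's
  K4 stoichiometry vector; its precursor target is one of the degree's four
  theoretical [M+9H]⁹⁺ values, drawn with probability π to emulate the
  cycling targeted inclusion list.
* Noise: multiplicative lognormal per peak, parameterized by CV and scaled
  to unit mean (σ² = ln(1+CV²), mean-corrected), because ion-trap intensity
  noise is heteroscedastic; plus an optional uniform additive baseline of
  random off-target peaks. With CV = 0 and baseline = 0 the run is exactly
  proportional to ground truth, which the round-trip tests exploit.
* Peaks are monoisotopic sticks by default; an optional binomial ¹³C
  envelope exists for realism but is off by default and not used in
  quantification.
* Biological replicates redraw the mixture (lognormal jitter on abundances
  and stoichiometries, renormalized); technical replicates redraw only
  acquisition noise.

What the simulator does *not* emulate — chimeric spectra, retention-time
drift, dynamic exclusion, detector saturation, co-eluting background
proteoforms. Passing round-trip tests therefore demonstrates correctness of
the quantification arithmetic and its noise robustness, not robustness to
those real-data pathologies.

Runs serialize to an exact internal JSON format (primary) and to centroided
mzML (base64, 64-bit, zlib). Both the mzML writer and reader are minimal
in-package implementations of the standard spectrum/cvParam/binaryDataArray
layout.

## Targeted quantification

Scan selection is RT-window-first: the retention-time class is the primary
acetyl-degree classifier, and the precursor match (±0.05 Th default against
the degree's four theoretical 9+ values) is a coarse confirmation. This
ordering is forced by the chemistry: me3 vs ac differ by 0.0040 Th at 9+,
far below any isolation tolerance, so precursor mass cannot disambiguate
e.g. 3ac + K4me3 from 4ac + K4me0.

Manual curation of low-signal scans is replaced by a deterministic rule: a
scan is dropped when its summed intensity at the four fragment targets is
below `snr_min` (default 3) × the median off-target intensity. Surviving
scans are averaged on a fixed 0.1-Th bin grid; per-target intensity is the
maximum bin within ±0.3 Th (sum-within-tolerance available by flag); the
four intensities are normalized to 100 %.

Aggregation averages technical replicates within each biological replicate
first, then reports mean ± SEM across biological replicates (n = number of
bios). A single bio yields SEM = NaN, and empty windows propagate as NaN
cells, never zeros. Condition comparison is a two-tailed two-sample t-test,
Student pooled-variance by default (Welch by flag), raw p-values by default
(Benjamini–Hochberg by flag). Zero variance in both groups with equal means
returns p = 1 by convention.

## Kinetics

The Hill model is fitted by Levenberg–Marquardt least squares (lmfit) with
Vmax₀ = max(v), K₀ interpolated at half-max, h₀ = 1, and up to five jittered
restarts on non-convergence; the MM fit fixes h = 1. The Hill fit is started
from the MM optimum (as well as the default guesses, keeping the better), so
SS_Hill ≤ SS_MM holds by construction. Substrate enters in nM; K₀.₅ is
reported in µM, converted in exactly one place. Fits are unweighted
(a weighting hook exists); replicate points are pooled, not averaged,
before fitting.

Model comparison: F = ((SS_MM − SS_Hill)/1)/(SS_Hill/df_Hill),
p = F-survival(1, df_Hill), Hill preferred at p < 0.05. When both residual
sums are below 1e-12 × the total sum of squares (noise-free data fitted
exactly), the comparison is degenerate and reported as F = 0, p = 1 — a
ratio of rounding errors is not evidence. Calibration was checked by
simulation: fitting MM-truth data with 5 %-of-Vmax Gaussian noise in
triplicate at the 9-point titration, the test rejects at its nominal 5 %
rate within the binomial 95 % band over 1000 simulations.

The n.d. screen declares a dataset not-determinable when the one-sided
t-test of top-concentration signal against background replicates is
non-significant, or when the fitted Vmax confidence interval includes zero.
The CI is taken from a refit with Vmax unbounded: the production fit
constrains Vmax ≥ 0, which pins pure-noise data to the bound and destroys
the covariance estimate, whereas the unbounded interval legitimately
straddles zero. "n.d." propagates into reports as the literal string.

## Dose–response

The 4PL is fitted with EC50 log-parameterized (enforcing positivity and
giving a delta-method standard error), hillslope bounded to (10⁻³, 20), and
plateaus unconstrained (bottom fixable to a measured background by option).
"Relative" EC50 means the fitted inflection between the two fitted plateaus.
Q = 0 evaluates to the bottom plateau. Flat series are refused and flagged
no-binding instead of producing a meaningless EC50. Hook exclusion drops
points above the concentration of maximal mean signal whose mean falls more
than `hook_frac` (default 10 %) below the maximum. Duplicate readings stay
in the residuals individually. Fold comparisons between targets propagate
first-order uncertainty: SE(A/B) = (A/B)·√((SE_A/A)² + (SE_B/B)²).

## Default study conditions

The default mixture gives acetyl degrees steeply decreasing abundance
(100 : 30 : 10 : 3 : 1 : 0.3) with K4 me2/me3 occupancy rising with acetyl
degree, so trimethylation is essentially confined to hyperacetylated tails;
the default time course (0–120 min, six points, 3 bio × 2 tech replicates)
raises hyperacetylated abundance and me3-within-5ac monotonically, emulating
deacetylase inhibition. Kinetic defaults follow the assay design: 4 nM
enzyme, 8-point 1.5-fold titration from 400 nM plus zero. Binding defaults
use duplicate series spanning sub-nM to hundreds of nM.

Problem sizes in the test suite (e.g. 100-seed recovery at a 6-s scan
interval, 1000-simulation F-test calibration, 50-seed fold recovery) were
chosen to make the statistical assertions stable at reasonable runtime and
are stated in the tests themselves.

## Known limitations

* Acetyl-degree assignment relies entirely on the RT windows; runs with
  drifting chromatography would need alignment, which is out of scope.
* The hook model is an empirical suppression factor, not bead-binding
  chemistry; hook exclusion can leave slightly suppressed points below the
  detected maximum, biasing EC50 a few percent low in extreme hooks.
* The ESS F-test's finite-sample calibration was verified for the default
  design only; very small designs (single replicate, few points) inherit
  the usual nonlinear-regression approximations.
* The mzML I/O targets the centroided subset of the standard; profile
  spectra, indexed mzML wrappers and vendor idiosyncrasies are unsupported.
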