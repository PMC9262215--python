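# Methods

## Data model and conventions

Raw data is a table of detector readings with columns
(ms_level, frame_id, retention_time, scan, mobility, mz, intensity).
Frame and scan indices are 0-based; all intervals — m/z, scan, frame/RT
— are closed on both ends, everywhere (extraction, window membership,
descent windows). Low scan number corresponds to high 1/K0, following
the instrument convention. Stage interfaces are columnar tables
(feather preferred, CSV accepted, chosen by extension); the loaders
enforce the schema, never reorder silently (output is sorted by
frame_id, scan, mz), and reject a frame id carrying two MS levels.

The optional loader for vendor raw databases is not included; the
package consumes the columnar schema above, which mirrors what common
raw-data readers expose, and the simulator produces it directly.

## Isotope-ratio model

All envelope math flows through one contract: `ratio(M, i)` = expected
peak-height ratio I(i+1)/I(i) for a peptide of monoisotopic mass M, and
`valid_mass_range(i)`. Envelopes are cumulative products of ratios with
the monoisotopic peak normalised to 1, so the model is the single
source of truth for deconvolution scoring, saturation correction and
simulation.

The default implementation scales the averagine composition
(C4.9384 H7.7583 N1.3577 O1.4773 S0.0417 per 111.05 Da) to the target
mass, rounds C/N/O/S to integers, lets hydrogen absorb the mass
remainder, and convolves the aggregated elemental isotope distributions
(truncated binary-exponentiation convolution; 1 Da mass resolution via
an LRU cache, ample for aggregated peptide envelopes). Valid mass range
defaults to 500–5000 Da for every isotope index. Published
tryptic-peptide ratio parameterisations with index-dependent mass
ranges can be supplied as a CSV of polynomial coefficients
(`TableRatioModel`); the averagine default is deliberately swappable
because the literature models are distributed as coefficient tables,
not formulas.

Where a mass falls outside the model's domain (small MS2 fragments),
scoring uses the envelope at the nearest valid mass
(`scoring_envelope`). This is a scoring heuristic only; the saturation
corrector never clamps — out-of-range masses are flagged
uncorrectable, as are features with every isotope saturated.

## Intensity descent

The seed is the most intense remaining point; the window is
seed ± 3σ with σ = (m/z / R) / 2.35482 at R = 40,000 by default; member
points are centroided (intensity-weighted mean m/z, clamped into the
members' m/z bounds against floating-point rounding), summed, and
removed. Determinism requires a tie rule for equal intensities, and
hard detector clipping makes exact ties the norm, not the exception: a
saturated peak core is a plateau of identical values spanning the whole
m/z jitter range. Seeding at the lowest-m/z tied point would place the
window edge inside the peak and bias the centroid (measured at up to
~±17 ppm on saturated synthetic features), so the seed is the
median-m/z tied point (lower median) — equally deterministic, and the
window then straddles the plateau. The window is always derived from
the seed point's m/z, not a running centroid.

## Deconvolution

For every simplified peak as a candidate monoisotopic seed and every
charge z in range, peaks are gathered at m/z + i · 1.00335483 / z
(i = 1, 2, …, stopping at the first gap) with matching tolerance equal
to the ±3σ peak width at the target m/z; the most intense in-tolerance
peak wins. A candidate needs at least two isotopes (charge is undefined
from one peak). A seed with a credible isotopic neighbour one spacing
*below* it (intensity ≥ 0.25 × seed) is rejected as non-monoisotopic;
0.25 sits safely below the smallest I(1)/I(0) ratio (~0.38 at 700 Da)
in the supported mass range, so true monoisotopic seeds are never
suppressed by their own series.

The score is the cosine similarity between the observed intensity
series and the theoretical envelope truncated to the observed length,
times a 0.5 penalty per expected-but-missing isotope among the first
three. Candidates are ranked by (score, then m/z, then charge);
overlapping candidates are allowed and at most `max_features_per_cuboid`
(default 3) are kept per cuboid. The MS1 score threshold defaults
to 0.7. MS2 deconvolution reuses the same engine with charges 1–2 and a
0.3 threshold: a clean two-isotope fragment scores at most 0.5 by
construction (one expected isotope missing), so the MS2 threshold must
sit below that ceiling; 0.3 still rejects series whose intensity ratios
disagree grossly with the envelope. Both thresholds are configuration,
not physics.

## Extents, intensities, saturation

The monoisotopic peak's points (m/z within ±3σ) are flattened onto the
scan axis (summing per scan), smoothed with a Savitzky-Golay filter
(window = min(9, profile length made odd), polynomial order ≤ 3 —
the filter is specified by the procedure, its parameters are not, and
these are conventional choices for profiles a few dozen samples long),
and the local maximum nearest the fragmentation event's centre is the
apex; the nearest local minima on each side (or the data boundary)
bound the extent. The same procedure then runs on the RT axis with the
scan restriction applied. Profiles with fewer than three distinct
coordinates or no variation give a flagged degenerate extent.

Isotope intensity is the three-point rule: max point in the apex frame
plus max point in the neighbouring frame on each side (0 when absent),
evaluated per isotope in its own ±3σ band restricted to the feature's
extents. An isotope is saturated if any of its three contributing
points reaches the threshold (3000 counts default), so 9000 counts is
the ceiling of an unsaturated isotope. Feature intensity is the sum of
the first three isotope intensities. Saturated monoisotopic intensities
are re-inferred by chaining ratios down from the nearest unsaturated
isotope; uncorrectable states are flags on the feature, never
exceptions. Saturated points are *not* removed before centroiding —
with the median-of-ties seed the centroid stays unbiased, and dropping
the core would discard most of the weight.

A Gaussian is fit to the monoisotopic peak's m/z profile
(Levenberg-Marquardt on amplitude/mean/σ, moment-based start values)
and R² = 1 − SS_res/SS_tot, clamped to [0, 1], is reported as a peak
quality score; fit failures give 0 with a flag.

## MS2 and mass-defect windows

Each feature's MS2 points are re-extracted per feature using its scan
and RT extents (features sharing a cuboid get their own extraction),
with no m/z bounds — fragments may lie above the precursor m/z.
Windows for nominal mass N are centred at 1.00048 · N with width
0.19 + 0.0001 · N, generated over [100, 5000) Da by default: 4900
strictly ordered, pairwise disjoint windows (spacing 1.00048 Da always
exceeds the width in this range). Membership is a binary search with
closed bounds. The MGF writes fragment m/z as neutral mass
+ 1.00727647 Da, one block per feature, skipping (with a warning)
features without a charge.

## Synthetic data

The generator emulates a short-gradient DDA acquisition: 1 s cycles of
one MS1 frame plus three MS2 frames over 240 s, 300 mobility scans per
frame with a linear scan → 1/K0 map (1.30 at scan 0 down to 0.85).
Defaults: 200 peptides; tryptic-like sequences drawn uniformly over the
20 standard residues until a target mass in 800–3200 Da is reached,
with a K/R terminus; charges 1–4 with weights 5/55/30/10%; elution
σ 1.8–3.2 s; mobility σ 4–8 scans; apex intensities log-uniform over
10^2.9–10^5.4 counts so a realistic minority of monoisotopic peaks
saturates at the 3000-count clip. Per isotope, every (frame, scan) cell
above a 1-count floor emits one point with Gaussian m/z jitter
(σ = (m/z / R) / 2.35482) and 5% multiplicative intensity noise.
Isolation windows cover mono ± 2 isotope spacings in m/z and ± 2σ in
scan on the four MS2 frames nearest the elution apex. Fragments are
the full singly-charged b/y ladders (cumulative residue sums; + H2O for
y ions) with two isotopes each, scaled to 30% of the precursor's
intensity and a per-fragment relative abundance in 0.1–1.

Noise is uniform in frame, scan and m/z (intensity exponential,
scale 150 counts; 30 points per MS1 frame, 60 per MS2 frame). Half of
the MS2 noise mass values are forced into the gaps between mass-defect
windows, and 30% of noise events are emitted as two-isotope doublets:
a single random point almost never survives the two-isotope
deconvolution rule, so without structured doublets the filter would
have nothing measurable to remove downstream of deconvolution. The
noise rates themselves are placeholders — the instrument's noise
statistics are not publicly characterised.

Ground truth records, per peptide, the true monoisotopic mass/m-z,
charge, apices, and per-isotope intensities *as the three-point rule
would measure them* before clipping and noise, plus every fragment's
neutral mass and whether it falls inside a mass-defect window. That
last flag matters: ~0.7% of random-ladder fragment masses genuinely
fall in inter-window gaps, so "the filter keeps all true fragments" is
only exact when stated for in-window fragments.

What the generator does not model: chromatographic tailing, charge
coelution correlation, the instrument firmware's intensity
extrapolation under saturation (clipping only), isotope fine structure,
and realistic noise spectra. Passing recovery tests therefore
demonstrate the pipeline's correctness under its own assumptions, not
performance on real instrument data.

## Problem sizes

The reference synthetic study uses 200 peptides (~0.7M MS1 and ~1.3M
MS2 points), which exercises every code path including saturation
correction on ~20–30 features; module tests use 25–30 peptides. These
sizes keep the whole suite and the acceptance script at around half a
minute each on one CPU while leaving all measured rates stable across
seeds.

## Known limitations

- No cross-cuboid de-duplication: the same physical peptide appearing
  in two precursors' cuboids yields two features.
- No merging of overlapping cuboids; each is processed independently.
- The averagine default under-represents sulfur-rich peptides; supply a
  ratio table for sharper envelopes.
- Apex determination assumes a single dominant elution/mobility peak
  per monoisotopic band; heavily chimeric bands resolve to the peak
  nearest the event centre.
- MGF output only; no mzML, no vendor-format writing.
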