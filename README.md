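# cuboidms

Feature detection for timsTOF-style 4D LC-IMS-MS raw data: from point
clouds of detector readings (m/z, mobility scan, retention time,
intensity) to deconvolved peptide features and search-ready MGF files.

## Who this is for

Bottom-up proteomics raw data from trapped-ion-mobility TOF instruments
arrives as billions of unconnected intensity readings in four
dimensions. Before any peptide can be identified, those readings must be
grouped into isotopic peaks, resolved into features with a charge state
and a monoisotopic m/z, and reduced to fragment lists a search engine
can consume. `cuboidms` implements that front end as a set of small,
composable stages with file-based interfaces (feather/CSV tables), plus
a synthetic-data generator so every stage is testable without
instrument data.

## The four algorithms

1. **Precursor cuboid seeding.** Each precursor selected for
   fragmentation leaves isolation windows (m/z × scan regions, one per
   frame). The union of a precursor's windows is extended down 1 Th in
   m/z (the monoisotopic peak may lie below the window), by the window's
   scan breadth on both sides in mobility, and by the user-specified
   base peak width forward and back in retention time, giving a search
   cuboid in m/z × scan × RT.

2. **Intensity descent.** Within a cuboid (or an MS2 spectrum), the most
   intense remaining point seeds a window of ±3σ, where σ is derived
   from the instrument resolution R via FWHM = m/z / R and
   σ = FWHM / 2.35482. Points in the window are collapsed to an
   intensity-weighted centroid and removed; the process repeats until no
   points remain. Total intensity is conserved and every point belongs
   to exactly one peak.

3. **Envelope deconvolution and saturation correction.** Candidate
   isotopic series are assembled at spacings Δm = 1.00335483 / z and
   scored against a theoretical isotope envelope (averagine by default)
   by cosine similarity. For each feature the mobility and RT extents
   are found by flattening the monoisotopic peak's points onto each
   axis, Savitzky-Golay smoothing, and taking the apex and flanking
   valleys. Isotope intensity follows a three-point rule: the most
   intense point in the apex frame plus the most intense point in the
   frame on either side, so an unsaturated isotope is bounded by
   3 × 3000 = 9000 counts at the 3000-count detector threshold. When the
   monoisotopic isotope is saturated, its intensity is re-inferred from
   the nearest unsaturated isotope k by chaining theoretical peak-height
   ratios: I(i) = I(i+1) / r(M, i) for i = k−1 … 0.

4. **Mass-defect window filtering.** Tryptic-peptide masses cluster on
   the line M ≈ 1.00048 · N for integer N, within a window of width
   0.19 + 0.0001 · N Da. Deconvolved MS2 fragment neutral masses that
   fall in the gaps between windows are noise and are removed before the
   MGF is written (fragment m/z = neutral mass + 1.00727647 Da).

## Worked example

```
cuboidms simulate --out-dir run --n-peptides 8 --seed 5
cuboidms run --points run/points.feather --windows run/isolation_windows.feather --out-dir run/out
```

prints

```
{"cuboids": 8, "features": 11, "fragments": 1345, "fragments_kept": 935}
```

Eight simulated precursors seed eight cuboids; deconvolution proposes
11 features (cuboids may contain co-eluting candidates), and of the
1345 deconvolved fragment ions, 935 sit inside mass-defect windows and
survive into `features.filtered.mgf`. Each MGF block carries the
feature's monoisotopic m/z and intensity (PEPMASS), charge, RT apex and
a TITLE encoding the precursor id, scan apex, 1/K0 and apex frame:

```
BEGIN IONS
TITLE=precursor=0 scan=261 k0=0.9072 frame=388
PEPMASS=919.7968901601835 12318.500244140625
RTINSECONDS=97.0
CHARGE=3+
175.11856320439696 22660.046298980713
...
```

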