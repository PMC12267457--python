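# Methods

## Problem and scope

ZooMS (Zooarchaeology by Mass Spectrometry) identifies fragmentary bone by
the masses of a small panel of tryptic collagen (COL1) peptides measured on
a MALDI-TOF instrument. Each peptide "marker" — labelled by chain and
residue range, e.g. `COL1a2 757-789`, with a single panel letter — takes
taxon-specific masses, so a picked peak list constrains which taxa a bone
could belong to. `zoomsid` implements that chain for a Palaeolithic cave
assemblage (Grotta di Castelcivita, southern Italy, spanning Mousterian,
Uluzzian and Protoaurignacian cultural complexes): spectral preprocessing,
marker matching, taxonomic category resolution, replicate consensus, and
assemblage-level quantification (ZNISP tables, broad-category comparison
with morphological NISP, spatial success grids). A seeded synthetic-data
generator supplies ground-truthed assemblages so every stage is testable
without the raw spectra deposit.

## Reference library and category lattice

The library holds a 9-marker panel; each leaf taxon maps markers to one or
more expected [M+H]+ monoisotopic values (Da). No charge states beyond +1
are modelled and deamidation (~ +0.984 Da) is not expanded into extra
expected values: the 0.5 Da matching tolerance absorbs sub-Dalton shifts.

Identification is reported on a lattice of *named categories*: leaf
singletons, compound groups (`Cervid`, `Unidentified Cervid`,
`Cervid/Rupicapra`, `Bos/Bison`, `Canid`, `Felis/Lynx/Ursus`,
`Panthera/Crocuta`, `Carnivora`, ...) and a root covering every leaf.
`minimal_category` returns the smallest named category covering a candidate
set, with ties broken lexicographically so the result is deterministic.

Three published contrasts for this assemblage are fixed as `"anchor"`
values and drive the worked examples:

* `COL1a2 757-789`: 3017.5/3033.5 (red/fallow/giant deer) vs 3043.5/3059.5
  (roe deer). Without this marker the cervids cannot be split and the call
  broadens to `Unidentified Cervid`.
* `COL1a2 502-519`: 1580.8 (cervids) vs 1550.8 (caprines). Without it the
  call can broaden to `Cervid/Rupicapra`.
* `COL1a2 889-906`: 1576.8 present in *Canis*/*Cuon*, absent in *Vulpes
  lagopus* — the canid discrimination rule.

The site study's full marker table is not openly published, so the
remaining masses in `data/default_library.json` are a synthetic but
internally consistent stand-in shaped by common ZooMS compilations, tagged
`provenance="literature"`; the library is fully user-replaceable (JSON or
TSV + categories sidecar). Validation checks marker windows against the
MALDI reflector range (800–3600 Da), values against windows, category
membership, and that every leaf pair is either separable by some marker
(values > 0.5 Da apart) or grouped by a named non-root category.

## Spectral preprocessing

The chain mirrors the mMass settings used for the site's fingerprints:
baseline correction (Precision = 15, Relative offset = 25), Savitzky–Golay
smoothing (window 0.3 Da, 2 cycles), peak picking (S/N = 3.0, picking
height 75%).

* **Baseline.** The m/z axis is split into `precision` equal segments; each
  contributes an anchor at the position of its minimum, lifted by
  `relative_offset`% of a robust local spread (segment median − minimum, so
  narrow peaks do not inflate it). Anchors are joined piecewise-linearly
  with end-slope extrapolation, subtracted, and negatives clipped. Anchoring
  at the minimum's own position makes linear ramps cancel exactly; on
  noiseless input the operation is idempotent to well under 1% of total
  intensity, and planted apex heights survive within 5%.
* **Smoothing.** The 0.3 Da window is converted to an odd number of sample
  points from the median grid spacing; polynomial order is fixed at 2, so
  quadratic signal is preserved exactly; `cycles` repeats the filter.
* **Noise.** Per-point sigma = windowed MAD × 1.4826 (100 Da windows,
  interpolated, floored at machine-epsilon scale). The full chain estimates
  noise on the baseline-corrected but *unsmoothed* profile: smoothing
  deflates the apparent sigma ~2.5× and would silently turn "S/N = 3" into
  "S/N ≈ 1", flooding the peak list with noise maxima. This ordering
  (baseline → noise → smooth → pick) is a deliberate design choice.
* **Picking.** Local maxima whose height above the local background
  (windowed median) reaches `snr_threshold` × sigma are reported. The
  centroid is the midpoint of the two linearly interpolated crossings at
  75% of apex height — exact for symmetric peaks, and within 0.1 Da (in
  practice < 0.01 Da) for planted Gaussians at 10× noise on the 0.02 Da
  grid. No deisotoping is attempted; the tolerance handles the rest.

## Identification logic

Per replicate, each panel marker is matched against the peaks in its
nominal window; the peak with the smallest |Δm/z| within ±0.5 Da wins (ties
to higher intensity), and *all* in-tolerance expected values of that peak
are carried, so one peak can support several variant groups. The candidate
taxon set is the intersection over matched markers of each match's leaf
union — absent markers impose no constraint, which is exactly how missing
peptides broaden the reported category. A sample is identified only with
≥ 4 distinct markers (of the 9 maximum) and a nonempty candidate set; an
empty intersection despite enough markers is a flagged conflict and counts
as a fail, never as a root-level identification.

Triplicate spots are resolved individually, then combined. Under the
default union-consistent rule, replicates whose candidate sets are nested
(or grouped by a shared non-root category) pool their marker matches and
are re-resolved — the ≥ 4-marker criterion applies to the combined count.
Disjoint replicates are a conflict: the combiner falls back to the strict
intersection of their common markers and flags the result. A
strict-intersection-only rule is available by configuration.

## Assemblage quantification

ZNISP tables count identifications per category × stratum (layer or
cultural complex), carrying the fail row. Percentages are shares of the
stratum total *including* fails, rounded half-up to one decimal; headline
success rates (identified/total) round half-up to integers — matching the
published table conventions (e.g. 18/210 → 8.6%, 192/210 → 91%).

The packaged fixture `data/castelcivita_znisp.csv` transcribes the
published per-complex ZNISP counts; every column reconciles exactly with
the printed totals (210/840/213, fails 18/108/23). The published text
contains internal discrepancies the fixture deliberately does not
reconcile: the text's caprine (223) and Bos/Bison ("nearly 145") figures
and the Discussion's 81% Uluzzian preservation differ from what the table
columns imply (110, 156, 87%); the table is taken as authoritative. The
morphological NISP transcription is comparison-grade only — several
printed cells are typographically ambiguous and its per-complex sums do
not reconcile with the printed morphology totals — so it supports rank
association (Spearman with 10,000 seeded permutations, plus an OLS slope
on counts; the published analysis names no specific statistic, these are
this package's choices) but no exact count checks.

Spatial success grids report per-square (optionally per square × layer)
identification percentages; squares never sampled are absent, not 0%.

## Synthetic data generator

The generator defines the study conditions under which the pipeline is
validated:

* **Layers** (7, `cgr` … `rsa'`): qualitative compositions shifting from
  cervid-dominant at the bottom to equid-dominant at the top; these emulate
  the published abundance shift but are not fitted to it.
* **Squares**: twelve (E–H × 12–14-style labels) with preservation
  probabilities 0.7–1.0; the H corner is the poorly preserved one.
* **Diagenesis**: a bone is preserved with its square's probability;
  markers then drop out independently at 0.05 (preserved) or 0.9
  (degraded). With these rates a preserved bone almost always clears the
  4-marker bar and a degraded one almost never does, so the identification
  rate tracks planted preservation to within binomial error.
* **Spectra**: regular grid 800–3600 Da at 0.02 Da; surviving marker values
  become Gaussian peaks (σ = 0.08 Da) with lognormal amplitudes
  (median 50, log-sd 0.35) on a low-order polynomial baseline plus Gaussian
  noise (σ = 1), clipped at zero; three replicates per sample sharing
  marker survival (diagenesis is bone-level) but with independent
  intensities and noise. Peaks are single Gaussians without isotope
  envelopes — the classifier consumes centroids, so envelope realism would
  add nothing testable.

All sampling flows from one seeded generator; each sample's spectra use a
child generator, so ground truth is reproducible whether or not spectra are
rendered. What the generator does *not* emulate: calibration drift,
deamidation shifts, contaminant peaks at non-marker masses, detector
saturation, and isotope envelopes. Passing synthetic tests therefore shows
the logic is correct under the stated noise model, not that real Bruker
exports will match the deposit's processing.

## Numerical choices and problem sizes

Matching tolerance is inclusive (|Δ| ≤ tol), so printed integer anchors
like 3033 match the stored 3033.5 at the default 0.5 Da. Rounding is
decimal half-up throughout the tables. Test and acceptance runs use
deliberately modest sizes — 60-sample clean runs for the exactness checks,
400–500 samples for rate-tracking, 10,000 permutations for the association
p-values — chosen to keep full runs in the couple-of-minutes range while
leaving binomial error well inside the asserted bands.

## Known limitations

* The default library's non-anchor masses are plausible stand-ins, not a
  vetted compilation; real analyses should load a curated library.
* The mMass baseline/offset semantics are not published as equations; the
  segment-anchor realization here matches its observable behaviour class
  and keeps the parameter names, nothing more.
* The mzML support is a minimal profile-spectrum subset (32/64-bit float,
  zlib or none), written and read with lxml.
* Replicate consensus beyond "checked to ensure matching markers" is
  underdetermined in the source description; union-consistent with
  conflict flagging is this package's definition.
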