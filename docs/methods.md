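# Methods

This note documents the models, defaults and numerical choices behind
`guvcolocal`, and what the synthetic validation does and does not show.

## Detection

Vesicles are detected from the membrane-marker channels only: membrane
fluorescence is the one signal every vesicle is guaranteed to carry, and it
resolves hemifused and aggregated compartments that brightfield cannot.
All channels of a role are combined by pixel-wise maximum after per-channel
min–max normalization, so markers recorded at different gains contribute
equally.

The chain is: Gaussian smoothing (σ = 1 px) → contrast-limited adaptive
histogram equalization (64 px tiles, clip 0.02) → global Otsu threshold
applied with hysteresis (low threshold = 0.7 × Otsu) → morphological
closing (radius 1) → hole filling (membrane role only: rings become filled
disks) → conservative splitting of merged components → 8-connected
labelling. Design notes:

- **CLAHE** makes the threshold robust to field-to-field and
  vesicle-to-vesicle brightness variation (multilamellar objects can be
  several-fold brighter than unilamellar ones and would otherwise drag a
  global threshold up past the dim population).
- **Hysteresis** keeps dim stretches of unevenly stained (phase-separated)
  rings connected to their bright segments, so the ring still closes and
  fills. A plain threshold fragments such rings into arcs that the
  convexity filter must then discard.
- **Splitting** is deliberately conservative. Within a connected component,
  candidate centers are distance-transform maxima separated by at least
  0.8 × the component's inscribed radius and at least 30 % as deep as the
  deepest one; two or more candidates trigger a marker-based watershed.
  Components with an inscribed radius below 4 px or solidity below 0.6 are
  never split: thin structures are unclosed ring arcs or debris, and
  beading them into convex pieces would fabricate objects. Splitting is on
  by default because the hysteresis halo can bridge two *near* (not
  touching) vesicles, and a merged pair both shifts the centroid and
  destroys one detection.
- **Foreground-fraction guard** (30 %): a threshold computed on a
  signal-free, noise-only field splits the noise in half; if the binary
  mask covers more than the guard fraction the field is declared empty.
  Together with the convexity filter this yields zero detections on blank
  fields.

Objects are filtered on area (≥ 20 px), solidity (≥ 0.8) and border
contact (excluded by default), with every rejection logged with its reason.
Content-marker objects are segmented the same way (without hole filling)
and matched to membrane objects by pixel-overlap plurality; unmatched
content objects are treated as lipid-negative debris and excluded.

Per-object records carry sub-pixel centroid, area, equivalent radius
(pixel_size · √(area/π)), best-fit-ellipse aspect ratio, solidity, border
flag, and per-channel mean/min/max/integrated intensity over both the
membrane and the matched lumen region.

## Colocalization

Scores are computed on a square window (odd width) centered on the rounded
centroid. The default width is 3 × the dataset's median object diameter,
rounded odd — wide enough to contain the whole vesicle plus local context,
and adaptive to magnification. Pixels padded in when a window clips the
field border are excluded from all scores (never treated as zeros).

Methods: Pearson product-moment, Spearman (mid-ranks), Kendall τ-b (tie
corrected; R's correlation-test conventions are the reference behaviour),
and the Manders coefficient with two threshold modes (window median of the
partner channel, or the partner channel's minimum over the object's own
pixels). Because the paired markers stain equivalent structures, only one
Manders direction is reported; which channel plays numerator is fixed by
the declared pair order. Constant inputs, empty masks and zero total
intensity are flagged degenerate per object and excluded from
distributions, never aborting a batch.

Region masks (`membrane`, `lumen`, `both`) restrict the pixel vectors to
the object's own label pixels. Without a mask the score is sensitive to
neighbours inside the window — with masks it is provably invariant to any
perturbation outside the object (a property test injects a bright
neighbour and requires the masked score to move ≤ 1e−12). Unmasked Pearson
is the default: masks cut neighbour crosstalk but also shrink the
separation between positive and negative control populations.

Background is estimated per channel as the mean over detected objects of
the object's minimum pixel in that same channel, subtracted everywhere and
clamped at zero. The policy (own-channel minima) is recorded in the run's
output metadata.

## Classification and derived estimates

Fluorescence and correlation thresholds sit at the **antimode**: a Gaussian
KDE (Silverman bandwidth) is evaluated on a 512-point grid padded by three
bandwidths beyond the data range (so a mode at the data boundary is still a
peak); modes are peaks with ≥ 5 % of the maximum density as prominence; the
threshold is the density minimum between the two highest modes. Fewer than
two modes raises a typed error so callers can fall back to resampled
controls. Fluorescence intensities are thresholded on a log scale — the
negative population is a narrow spike near zero while positives are a broad
lognormal, and a linear-scale bandwidth cannot serve both; correlation
scores (bounded, comparable widths) use the linear scale. Fluorescence
thresholds default to mixed-sample provenance, correlation thresholds to
resampled synthetic mixtures whose positive fraction is chosen by
classification accuracy against the labelled control pools.

An object is positive for a channel when its background-corrected mean
(lumen mean for content channels, membrane mean for lipid channels — mean
rather than max or integrated intensity, configurable) exceeds the channel
threshold; DP means positive for both pair channels. The exchange label by
correlation (score > correlation threshold) is emitted alongside. DP
percentages are corrected by subtracting the negative control's DP
percentage, floored at zero.

Concentration = n / (imaged area × chamber thickness) × dilution, per µL;
it assumes complete sedimentation and carries a caveat flag otherwise
(real chambers equilibrate with a dynamic out-of-focus population, making
absolute counts conservative). Radius compensation inverts the
spherical-cap geometry of a sphere resting on the coverslip cut at height
h: r = √(2Rh − h²), R = (r² + h²)/2h; r = 0 maps to the tangency limit
R = h/2 and is flagged; spheres with R < h/2 never intersect the imaging
plane. Sedimentation series are fit per thickness with
N(t) = N∞(1 − e^(−t/τ)) by bounded least squares (initialized at the
maximum count and the 63 % rise time; identically zero series are flagged
unidentifiable), followed by ordinary linear regression of N∞ against
thickness with R².

## Synthetic scenes

The generator emulates sedimented vesicle fields as seen by a spinning-disc
confocal ~2 µm above the coverslip. Defaults, chosen once as realistic for
emulsion-transfer preparations: lognormal radii (median 4 µm, σ_log 0.4);
pixel size 0.4 µm/px for the validation datasets; membrane rings with a
1.5 px Gaussian radial profile; per-vesicle marker amounts lognormally
dispersed (σ_log 0.35) to emulate encapsulation variability; background
0.05, Poisson shot noise (400 counts per intensity unit) and Gaussian read
noise (σ 0.02). The dual-stained control population carries each content
marker at half the single-population amount, mirroring how such controls
are loaded; the amount dispersion is also what merges the half- and
full-amount positive modes into one broad positive mode, as in real
fluorescence histograms. Heterogeneity knobs: patchy membranes (angular
harmonic modulation, depth 0.8), multilamellar-like objects (4× gain plus
interior fill), oil-inclusion hot spots (3× Gaussian spots on the ring),
out-of-focus haze (a blurred phantom vesicle layer), and tangent clusters.
Mixture samples allocate population counts deterministically (largest
remainder) so the realized fraction equals the nominal one and recovery
error measures the pipeline, not generator sampling noise.

The content-transfer model is symmetric fractional exchange: for each
hemifused pair with transfer fraction φ ~ U(0,1), partner 1 ends with
((1−φ)A, φB) and partner 2 with (φA, (1−φ)B). Totals of each marker are
conserved exactly, and amounts among exchanged vesicles are anticorrelated
through φ — the qualitative signature seen in content-exchange dot plots.
Other parameterizations (e.g. concentration-based transfer) would share the
conservation law but differ quantitatively; this form is declared, not
derived.

What the generator does **not** emulate: realistic point-spread functions
(blur is Gaussian), pinhole crosstalk spectra, chromatic or registration
offsets between channels, vesicle motion, camera fixed-pattern noise, and
truly multilamellar optics. Passing the synthetic benchmarks therefore
demonstrates the correctness and robustness of the algorithms under
controlled heterogeneity, not instrument-level performance on any specific
microscope.

## Validation problem sizes

The mixture-recovery experiment uses five samples (negative control plus
1:1:1, 1:1:0.5, 1:1:0.1, 1:1:0.05 volumetric mixtures) of ~1000 vesicles
each across eight 1024² fields — large enough that the ±2-point agreement
band is dominated by pipeline behaviour rather than counting noise, and
small enough to run in about a minute per full series on one core.
Detection benchmarks use 512² scenes of 60 vesicles, three scenes per
condition. Both are shared verbatim by the test suite and
`scripts/acceptance.py`.

## Known limitations

- The exchange-by-correlation route can double-count aggregated neighbours
  when no mask is used; controlling vesicle density (dilution before
  imaging) or enabling masks trades this against population separation.
- Concentration estimates are uncorrected for incomplete sedimentation,
  out-of-focus losses and border exclusions; they are comparative, not
  absolute.
- The antimode needs genuinely bimodal input (n ≥ 50); heavily imbalanced
  mixtures may require the resampled-control route.
- Degraded-scene recall (~0.85 mean over seeds) is limited by heavily
  patchy rings that never close even under hysteresis; those objects are
  rejected by the convexity filter by design, since relaxing it fabricates
  objects on noisy fields.
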