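# Methods

## Model

`brainbehavior` implements regional behavioral analysis for human brain
imaging: given a database-style table of activation foci — peak coordinates
(x, y, z, mm) in Talairach space, each labelled with one of 51 behavioral
sub-domains grouped into five domains (Action, Cognition, Emotion,
Interoception, Perception) — it characterises any region of interest (ROI)
by how strongly each behavior's foci concentrate inside it.

The central object is a 4-D behavioral probability-density image. For each
sub-domain *b*, foci are binned onto an isotropic voxel grid (one count at
the voxel nearest each coordinate) and the count image is divided by the
sub-domain's whole-brain focus total N_b, giving a discrete density
PDF(x, y, z, b) that sums to one over the grid. The 51 channels are
concatenated in taxonomy order and serialized as gzip-compressed NIfTI-1
with a JSON sidecar recording channel order and N_b.

For an ROI, each sub-domain is scored by

* **observed probability** p_o = Σ_{v ∈ ROI} PDF(v, b) — the fraction of the
  behavior's foci inside the ROI;
* **expected probability** p_e = volume(ROI ∩ brain) / volume(brain) — the
  value p_o would take under a spatially uniform distribution of foci within
  the brain;
* **effect size** p_o − p_e and **relative probability** (p_o − p_e)/p_e;
* a **z-score** from the binomial model with N_b trials:

      z = (p_o − p_e) / sqrt( (p_o(1 − p_o) + p_e(1 − p_e)) / N_b )

A sub-domain is flagged significant when its effect is positive and
z ≥ 3.0; with 51 simultaneous tests this threshold acts as an approximate
Bonferroni guard at overall p ≈ 0.05. We implement the stated threshold,
not the underlying arithmetic, and expose it as a parameter. Note the
denominator adds the variances of both proportions, so under the null
(p_o ≈ p_e) the statistic is conservative by roughly √2, which our null
calibration test confirms empirically (false-positive rates far below the
nominal tail).

The modelling assumption is that the empirical distribution of reported
foci for a sub-domain approximates that behavior's true spatial probability
distribution — reasonable for large-N sub-domains, noisier for small ones;
small-N sub-domains need larger effect sizes for the same z.

### Lateralization statistic

Hemispheric asymmetry of foci (per sub-domain, or per region mask) is
scored with the one-sample proportion statistic on the left fraction
f = n_left / (n_left + n_right):

    z = (f − 0.5) / sqrt( f (1 − f) / N ),  N = n_left + n_right

This is the form that reproduces, to the printed precision, all thirteen
reference rows of the 2012 database snapshot shipped with the package
(e.g. 4232/2349 → f = 0.64, z = 24.2; 1036/1254 → f = 0.45, z = −4.6).
Foci exactly on the midline (x = 0) are excluded from both hemispheres by
default; a `midline` policy can fold them into either side. The default
significance convention is |z| ≥ 3.0; 2.0 is common for coarse anatomical
tallies and is available via the threshold parameter.

### Behavior-specific ROIs and self-consistency

To validate that the profile recovers the behavior that generated a region,
each channel can be smoothed with an isotropic 3-D Gaussian (FWHM 10 mm by
default; σ = FWHM / (2√(2 ln 2)) ≈ 4.25 mm) and thresholded at 25 % of the
smoothed maximum to form a behavior-specific ROI. Profiling every
sub-domain's own ROI yields a square rank matrix; on well-separated data
the diagonal should be all ones with large diagonal z. The 25 % threshold
is interpreted *relative to the smoothed channel maximum*; with a relative
threshold, smoothing counts or densities is immaterial (they differ by the
constant N_b). Convolution uses zero-padded boundaries: densities vanish
off-grid, so interior mass is conserved to numerical precision.

## Grids, rounding, and precision conversion

The default grid covers x ∈ [−90, 90], y ∈ [−126, 90], z ∈ [−72, 108] mm —
a generous superset of the atlas brain; extra voxels are empty and leave
probabilities unchanged. Axes follow the Talairach convention (x left−/
right+, y posterior−/anterior+, z inferior−/superior+).

* **Voxel assignment** rounds each axis to the nearest voxel center, halves
  away from zero. A coordinate exactly halfway between centers therefore
  goes to the center farther from zero, deterministically.
* **2 mm is the default spacing**, matching the effective resolution of
  functional images; 1-mm builds are supported for high-resolution ROIs.
* The 1-mm grid is defined as the *child* of the 2-mm grid (origin shifted
  by −0.5 mm per axis, shape doubled) so that every 2-mm voxel is exactly
  the union of eight 1-mm voxels. Consequently 2→1 mm mask up-conversion
  (each voxel → its 8 children) preserves volume exactly, and binning foci
  placed at 2-mm voxel centers at 1 mm then pooling 2×2×2 blocks equals the
  2-mm build integer-for-integer.
* **1→2 mm down-conversion** sets a parent voxel iff ≥ 4 of its 8 children
  are set (majority, ties set — chosen for volume stability); a stricter
  `any`-child rule is available. Up-then-down conversion is the identity;
  down-then-up removes at most a one-voxel boundary shell from solid blobs.
* Foci outside the grid are dropped, tallied per channel, and logged;
  channel normalization uses the in-grid total, so populated channels sum
  to one whenever nothing was dropped.

White matter and ventricles are *not* masked at build time: reported foci
do fall there (normalization and localisation differences across studies),
and the uniform-within-brain null absorbs this without extra assumptions.
ROIs placed where density is zero simply score non-positive z everywhere.

## Space adjustment

Internal calculations use Talairach coordinates. Data fitted to MNI space
are adjusted with an affine MNI→TAL transform; the package ships the two
pooled icbm2tal coefficient matrices (fitted on SPM- and on FSL-normalized
brains) with `spm` as the default variant, and accepts any user 4×4 matrix
as whitespace-delimited text. Binary masks are resampled by
nearest-neighbor pull mapping (output voxel centers traced through the
inverse transform), which keeps masks binary and hole-free.

## Numerical choices

* The 4-D PDF object internally stores *integer tallies* per channel and
  derives density values by division on access. Probabilities then reduce
  to exact integer ratios: a whole-brain ROI gives p_o = 1.0 and effect =
  0.0 bit-exactly instead of a floating sum ≈ 1. The serialized artifact is
  the normalized float PDF; tallies are reconstructed on read as
  rint(channel × N_b), exact for realistic counts.
* Degenerate variance in the z-score (both probabilities in {0, 1}) maps a
  zero effect to z = 0 and a nonzero effect to signed infinity; N_b = 0
  rows carry NaN and rank last. These conventions are ours; they only
  affect pathological ROIs.
* `p_e` uses voxel-count ratios (exact rationals in float), clipping the
  ROI to the brain mask so numerator and denominator stay consistent;
  out-of-brain ROI voxels are logged.
* `foci_in_roi` is reported as round(p_o · N_b), derived from the PDF-sum
  pathway rather than re-tallied.
* Profile rows are ranked by descending z with NaN last; ties break by
  sub-domain id, so ranking is deterministic.
* Statistical-map thresholding is closed (value ≥ t); non-finite voxels
  count as sub-threshold. Half-space clips keep the cutoff plane on either
  side.

## Synthetic data

Real coordinate databases are access-restricted, so the generator emulates
their structure with known ground truth: an ellipsoidal brain mask
(semi-axes 70 × 85 × 65 mm by default, volume ≈ 1.62 × 10⁶ mm³,
approximating atlas brain extent); per-sub-domain focus totals defaulting
to the 2012 snapshot tallies (51 sub-domains, ~120k foci); foci drawn from
isotropic Gaussian clusters truncated to the brain by rejection, mixed with
a uniform in-brain component; and optional hemispheric bias implemented by
reflecting each focus to the left with probability `left_bias`. All draws
come from a seeded `numpy.random.default_rng`, so fixtures are exactly
reproducible for a given seed on a given platform.

What the generator does **not** emulate: per-experiment correlation of
foci (peaks from one experiment cluster together in real data), anatomy
(gray/white contrast, cortical folding), non-Gaussian cluster shapes, and
reporting biases. Passing tests therefore demonstrate correctness of the
*method and implementation* under the stated sampling model, not empirical
claims about any real database.

Problem sizes in the shipped tests were chosen to exercise each property at
comfortable statistical resolution: the recovery fixture uses the full
51-sub-domain snapshot scales on the standard 2-mm grid; the null
calibration runs 400 replicates of 5 000 uniform foci against random ROIs
of 5 % brain volume; the grid-precision comparison uses a reduced bounding
box (±40 mm scale) so the 1-mm build stays comfortably in memory.

## Known limitations

* Forward inference only: profiles describe region→behavior evidence, not
  the reverse posterior over behaviors.
* Point-mass binning (no ALE-style uncertainty kernels) is deliberate — it
  makes ROI sums exact probabilities — but single coordinates or very small
  ROIs are not meaningful inputs; use ROIs from statistical or anatomical
  maps.
* Only axis-aligned isotropic RAS+ grids at 1 or 2 mm are supported for
  masks and PDFs; nonlinear warps and surface registration are out of
  scope.
* The behavioral taxonomy and snapshot tallies reflect the 2012 coding
  scheme; newer database releases would ship different N_b and possibly
  more sub-domains.
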