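# Methods

## The metric

For an 8-bit grayscale image and a polygonal ROI with `N` pixels, let `nᵢ`
be the number of ROI pixels with gray value `i ∈ {0, …, 255}`. The ROI's
gray-level distribution is `pᵢ = nᵢ / N` and its chromatic entropy is

    H = -Σ_{i: pᵢ>0} pᵢ log₂ pᵢ     (bits),

with the standard convention `0·log₂ 0 := 0`. H is bounded by
`log₂ 256 = 8` bits, attained only by the uniform histogram, and equals 0
only when the ROI is a single gray value. Entropy of a histogram is
**spatially blind**: it depends on the multiset of pixel values, not their
arrangement, so it measures tonal heterogeneity, not texture.

A lesion is scored against a perilesional-skin control ROI from the same
photograph:

    ΔH = H_lesion − H_control       (bits, may be negative).

This internal control absorbs baseline skin heterogeneity (age, phototype,
photodamage) that would otherwise confound comparisons across patients. ΔH
is a difference of marginal entropies — deliberately not a divergence
between the two distributions.

All entropies are computed in double precision and stored unrounded in
machine-readable (JSON) output; CSV reports display 2 decimals, matching the
convention of published lesion/control tables. Log base is 2 throughout;
there is no nats option.

## Processing conventions

**Grayscale conversion.** Two methods are provided and recorded in each
result's provenance:

* `unweighted_mean` (default): `round((r+g+b)/3)` — matches ImageJ's default
  unweighted RGB-to-gray conversion, the toolchain most users outline ROIs
  in;
* `luma_bt601`: `round(0.299r + 0.587g + 0.114b)` — the perceptual standard.

Rounding is half away from zero (`floor(x + 0.5)` on non-negative values, as
ImageJ computes it). Because the choice shifts every `pᵢ`, ΔH is only
meaningful within one convention: `relative_entropy` raises
`ProvenanceMismatchError` when the two results record different methods or
bin counts. One-channel input passes through conversion unchanged.

**Bit depth.** Only 8-bit input is accepted. 16-bit or float images raise an
error rather than being rescaled silently — rescaling would change the
histogram and hence H in ways invisible to the user. Alpha channels are
stripped; transparency does not exclude pixels from ROIs. JPEG input is
accepted as decoded; note that lossy chroma compression perturbs the
histogram and therefore H, so PNG/TIFF are preferable for quantitative work.

**Rasterization.** Polygon vertices live in continuous pixel coordinates
(origin top-left, y downward). Pixel (c, r) belongs to the ROI iff its
center `(c + 0.5, r + 0.5)` is inside the polygon under the **even-odd**
fill rule, evaluated by a horizontal-ray crossing count with half-open edge
straddling (an edge counts when one endpoint is strictly above the ray and
the other is not), so a vertex shared by two edges is never double-counted.
This rule is deterministic, orientation-independent, and checkable against a
scalar ray-casting oracle, which the test suite does exhaustively on random
polygons — including self-intersecting ones, where even-odd excludes
doubly-wound regions. Pixel centers exactly on an edge fall on the rule's
tie-break side; with integer-coordinate vertices and half-integer centers,
ties are rare and resolved consistently. Vertices may extend beyond the
image; masks are clipped to the frame, and an ROI that covers no pixel
center raises an empty-ROI error. For convex polygons the pixel count
differs from the analytic area by at most the perimeter in pixels (boundary
discretization), a bound the tests enforce.

**Validation tolerances.** A probability vector is rejected when
`|Σp − 1| > 1e-9` (no silent renormalization). Oracle-agreement tests use
1e-10 bits; exact-histogram phantom recovery uses 1e-12 bits; hard equalities
(histogram bin counts, seeded reproducibility) are asserted exactly.

## ROI file formats

ImageJ/Fiji `.roi` files are read directly (read-only): big-endian layout
with the `Iout` magic, the type byte (only polygon and freehand-as-polygon
are accepted; other types are rejected naming the type found), integer
vertex offsets relative to the bounding box, the sub-pixel float-coordinate
block when its option bit is set, and the UTF-16BE name reached through the
second header. A portable polygon-JSON dialect
(`{"name": ..., "vertices": [[x, y], ...]}`) round-trips vertices at full
float precision for users without Fiji. Writing `.roi` files and `.zip` ROI
sets are out of scope.

## Synthetic phantoms

The study conditions — a photographed lesion plus perilesional control,
scored within one image — are emulated without any clinical data by two
phantom families, both pure functions of their spec including an explicit
integer seed (numpy `default_rng`, PCG64), so fixtures are byte-reproducible
across platforms:

* **Exact-histogram phantoms**: each gray value `i` is laid out exactly
  `target_counts[i]` times and only pixel *positions* are permuted by the
  seeded generator. The histogram, and hence H, equals the spec analytically
  — not statistically — which pins down the whole
  grayscale→mask→histogram→entropy path bit-for-bit.
* **Two-region lesion phantoms**: pixels inside a lesion polygon are i.i.d.
  draws from a lesion distribution, the rest from a background distribution;
  the control ROI is the largest rectangular strip of pure background
  flanking the lesion's bounding box with one pixel of clearance. The
  default validation scene is a uniform-over-16-levels lesion (H = 4 bits)
  on a constant background (H = 0) at 256×256 px, giving ≥ 10⁴ pixels in
  each ROI so the plug-in estimator's sampling error is well below the
  0.05-bit test tolerance (for a uniform distribution over K levels the
  negative bias is ≈ (K−1)/(2N ln 2) ≈ 0.001 bits at N = 10⁴).

Pixels are i.i.d. by design: since H is spatially blind, spatial structure
(blobs, texture, illumination gradients, JPEG artifacts, camera optics)
cannot change what the phantoms test, and none is modelled. Passing phantom
tests therefore demonstrates correctness of the *computation*, not
robustness of the metric to real-world acquisition effects — lighting,
white balance and compression all move H on real photographs, and the tool
makes no attempt to correct for them. Three-channel phantoms replicate gray
into RGB so the conversion path is exercised; `r = g = b` makes both
conversion methods exact.

The plug-in (empirical-histogram) entropy estimator is negatively biased at
finite n and converges to the analytic value as n grows;
`empirical_vs_analytic_entropy` quantifies this for any distribution and is
used in the tests at n up to 10⁶ (tolerance 0.01 bits).

## Published-table arithmetic

The published lesion/control table (melanoma H = 6.94 bits over 303,369 px;
elderly perilesional skin 5.75 over 261,564; nevus 6.67 over 72,393; young
perilesional skin 4.39 over 70,137) is used as *input* to the ΔH arithmetic,
which reproduces the published +1.19 and +2.28 bits at 2-decimal display.
The absolute H values themselves cannot be recomputed because the underlying
photographs are not publicly available; whether they were rounded or
truncated to 2 decimals is also unstated, so reports display 2 decimals but
store full precision.

## Problem sizes

The validation suite uses deliberately small rasters: oracle comparisons on
200 random images up to 64×64 px (brute-force per-pixel oracles are
quadratic and meant to be read, not fast), 50 exact-histogram phantoms up to
48×48 px, and 20 seeded 256×256 lesion phantoms. These sizes already make
every failure mode observable — histogram errors are size-independent, and
sampling error at 10⁴ ROI pixels is an order of magnitude below the test
tolerance — while keeping the whole suite interactive.

## Known limitations

* Grayscale-only: per-channel RGB or Lab/HSV entropy is not computed, so
  iso-luminant color variation is invisible to the metric.
* No segmentation: ROIs are user-supplied polygons; the subjectivity of
  manual delineation propagates into H.
* No acquisition correction: lighting, white balance and JPEG compression
  all shift the histogram; comparisons are only meaningful within consistent
  imaging conditions.
* No diagnostic interpretation: the package computes H and ΔH; it does not
  classify lesions or propose thresholds.
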