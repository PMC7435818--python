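# Methods

## Model and assumptions

The monitor treats fixation state as a property of the *gray-level
distribution* of a frame, not of its spatial layout.  The working
assumptions are those of an overhead camera on a fixation line:

- the tray/background is near-white, i.e. much brighter than any leaf
  pixel, so it forms its own high-gray mass in the luma histogram;
- regions where leaves pile up are strongly shadowed and form a low-gray
  mass well below the leaf body;
- the leaf body itself occupies mid grays, green-dominant early in
  fixation, with all three channels darkening and converging as the
  process completes.

Under these assumptions the luma histogram has two interior valleys, and
everything outside the band they bound is non-informative.  All later
stages (attention peak, mapping, centroid training, distance decision)
operate on the retained band only.

A consequence worth stating: because the per-channel histograms are
sufficient statistics for the whole pipeline, the monitor is exactly
invariant to rotations, flips, and any permutation of pixels.  It is
correspondingly *blind* to spatial pathologies (e.g. a camera occlusion
that removes pixels uniformly in gray level).

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| `H` | 800 | plane units | top of the inverted mapped axis; zero energy maps to `y = H` |
| `s`, `S` | 700, 25 000 | — | mapping scale: a window average of `S` pixels spans `s` plane units |
| `n` | 2 | gray levels | attention window half-width; `n = 0` degenerates to the raw peak count |
| `alpha` | 0.2 | relative | decision half-band as a fraction of the trained `sum_S` |
| `x_scale`, `y_scale` | 1 | — | optional axis normalisation; verdicts are invariant to a common rescaling |
| `int_mode` | `round` | — | integerisation of the mapped `y` (`round` = half-up; `floor` differs by ≤ 1) |
| `window_mode` | `clipped` | — | divisor when the window is clipped by the band (`clipped` = bins used, `strict` = always `2n + 1`) |
| `distance_mode` | `euclidean` | — | plain L2 center distance; `literal` halves each distance (pure rescaling) |

The trough search splits the gray axis at 125: `T1` minimises the luma
counts over `[0, 125]`, `T2` over `[126, 255]`, and argmin/argmax ties go
to the smallest gray level.  The smallest-h rule is deterministic and, in
the lower range, keeps the retained band widest on the left; on realistic
histograms (wide zero plateaus flanking the leaf mass) it also pins `T1`
to the left edge of the shadow/leaf valley and `T2` just above the leaf
upper tail.  Bins exactly at `T1` and `T2` are discarded; the retained
band is the open interval `(T1, T2)`.

`n` is not prescribed anywhere authoritative; 2 is the default because a
5-bin average suppresses single-bin shot noise without flattening the
leaf peak (leaf channel modes are ≥ 10 bins wide in practice), and it is
exposed in `MappingConfig`.

## Numerical choices

- **Luma rounding** is half-up to the nearest integer (`floor(x + 0.5)`).
  Any fixed rule works, but it must be fixed: `T1`/`T2` are bins of this
  image, so a different rule shifts thresholds by one level.
- The mapped `y = H − int(N_ave · s / S)` is clamped at 0 so extreme
  energies cannot leave the plane; `int(·)` is half-up by default.
- **Window clipping**: when the attention window spills over a band edge
  the divisor is the number of bins actually used, preventing artificial
  deflation of `N_ave` near edges.  `window_mode="strict"` restores the
  constant `2n + 1` divisor for literal fidelity to the formula.
- **Distances** between centers are plain Euclidean.  The halved variant
  that appears in some statements of the formula is available as
  `distance_mode="literal"`; it rescales every distance by 0.5 and leaves
  all relative decisions unchanged, but the published reference distance
  table follows the plain convention (verified by recomputation).
- The decision boundary is abnormal: normal requires the *strict*
  inequality `alpha · sum_S > |sum_S − sum_M|`.  With float sums exact
  ties are measure-zero, but the convention is fixed and tested.
- Degenerate inputs fail loudly and specifically: empty images, all-zero
  or single-bin luma histograms ("degenerate histogram"), channels with
  no energy in the band ("no tea energy in band"), and models with
  non-positive `sum_S` ("untrained or degenerate model").  In batch
  monitoring, individually failing frames are skipped with a logged
  warning; only a fully failing set is an error.

## Reference data

`ieamsc.reference` freezes the published trained center coordinates and
pairwise-distance table for green tea fixed 2/4/6/8 min (the 6-min state
being the standard).  Recomputing the distances from the printed centers
reproduces 13 of the 16 printed values exactly at their two-decimal
precision; the 4-min R–B distance computes to 0.3891 where 0.38 is
printed, and the 4-min/8-min sums land within 0.016 of print.  The
printed table was evidently derived from unrounded centers, so the
package asserts exact agreement where it holds and a ≤ 0.016 bound
overall, rather than silently re-rounding.

## Synthetic data: what it does and does not emulate

`ieamsc.synthetic` renders frames with exactly the three histogram masses
the filter assumes: Gaussian white background (mean 245, sd 4), elliptical
leaf blobs covering ~50 % of the frame, and colourless shadow patches
(~8 % of the foreground, gray ≈ 10 ± 4) whose single per-pixel draw is
shared across channels — a weighted-average luma would otherwise shrink
the shadow spread and empty the lowest bins, destroying the lower valley.
Default frame size is 108 × 192; this preserves all histogram *shapes* of
a full-HD frame while scaling counts by 10⁻², and every pipeline quantity
except raw counts is size-invariant.

The fixation degree `d ∈ [0, 1]` moves the foreground channel means
linearly from (70, 102, 72) to (56, 57, 56) — endpoints taken from the
published attention gray levels at the earliest and latest reference
times — while the channel spread narrows from 18 to 8.  This yields a
strictly shrinking trained triangle across degrees {0, ⅓, ⅔, 1}
(perimeters ≈ 66 → 44 → 23 → 1 at 30 frames per batch), qualitatively
mirroring the published 1.30 → 1.04 → 0.75 → 0.45 trend; no claim of
matching absolute values is made, since the reference units are an
undocumented normalisation.

What the generator does **not** emulate: leaf shapes and texture (the
pipeline never sees them), ambient-light drift, camera optics, specular
highlights, or inter-frame correlation of a real 30 fps sequence (frames
in a batch are independent).  Passing the synthetic end-to-end tests
therefore demonstrates the *mechanism* — trough filtering, peak tracking,
triangle shrinkage, decision behaviour — not field accuracy on real tea,
which depends on lighting control the algorithm itself does not provide.

## Design choices where the design was open

- **Histogram-domain filtering**: zeroing histogram bins is equivalent to
  zeroing pixels and re-histogramming for every downstream quantity, so
  no spatial mask is kept.
- **Mapping formula reading**: the count-to-plane factor is the ratio
  `s/S` (the only reading with sane magnitudes: window averages of order
  10⁴ must land in `[0, H]`), and a self-cancelling `max/max` factor is
  dropped.
- **One label per model**: a trained model stores the centers of exactly
  one standard state; multi-time trend tables are produced by training
  one model per time.
- **Clustering reduces to means**: the SSE objective over a single
  cluster per channel is minimised by the arithmetic mean, so no
  iterative k-means is run (and k > 1 is a non-goal).
- **Exit codes** 0/3/2 (normal/abnormal/error) for the `monitor` command,
  so a PLC or shell wrapper can branch without parsing JSON.

## Limitations

- The decision uses only the triangle perimeter; two states with equal
  perimeter but different center placement are indistinguishable to it.
  (Integrating the full center table into the decision is an obvious
  extension.)
- The 0–125 / 126–255 trough split hard-codes the assumption that leaf
  grays sit below 126 and background above; very bright leaves or a gray
  tray violate it.
- `alpha` is a process-tuning constant: the default 0.2 matches the
  reference operating point but should be re-derived for a new line from
  the observed batch-to-batch spread of `sum_M` at the standard state.
- No corrective-action output (e.g. a recommended fixation time); the
  monitor only signals normal/abnormal.
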