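# Methods

## Measurement model

The quantity of interest is a neovascularization (NV) growing from the
retina into the vitreous, observed with OCTA as two registered signals:
structural reflectivity and flow decorrelation. The package treats the
NV delineations as *inputs* (manual outlines are the reference
standard; automated NV segmentation is out of scope) and computes from
them:

* **NV-angio / NV-structure area** — pixel count of the rasterized
  outline × (lateral spacing)², in mm². Rasterization uses the
  even–odd rule on pixel centers (0-based grid, centers at integer
  coordinates); centers exactly on an edge count as inside, a
  deterministic tie-break.
* **FD-angio / FD-structure** — foreground percentage of the binarized
  *angio* image inside the angio outline and the structure outline
  respectively. The structure image only ever contributes its outline;
  both FD values come from the same binary angio image. Binarization is
  computed over the full image first, the outline mask applied
  afterwards (this matters near the outline, where the local window
  sees context pixels).
* **B-scan endpoints** — the RGB B-scan's flow overlay is isolated as
  max(R − B, 0), which cancels the achromatic structural background
  exactly and ignores the green channel; the result is binarized like
  the en face angio image. Heights are the per-column maximum extent
  of (a) the outline and (b) the binarized flow above the ILM polyline,
  in µm ("toward the vitreous" = decreasing row index, row 0 at the
  top). The flow height can never exceed the structure height because
  the flow pixels counted are restricted to the outline.

## Binarization

Phansalkar local thresholding, designed for low-contrast vascular
images: with local mean m and *population* SD s over a circular window
of radius R on the [0, 1]-normalized image,

    t = m · (1 + p·e^(−q·m) + k·(s/r − 1)),  foreground ⇔ value > t.

Defaults R = 15 px, k = 0.25, r = 0.5, p = 2, q = 10 — the widely used
Fiji plugin defaults, exposed in `PhansalkarParams` because the window
radius materially affects FD on thin vessels. Normalization divides by
the declared bit-depth maximum (255/65535), so an 8-bit image and its
rescaled float twin binarize identically. Edges use mirror padding.
Ties (value = t) go to background; on an all-zero image t = 0 and
nothing is foreground. Niblack/Sauvola are available as a comparison
hook only.

## Endpoints and cohort statistics

Per NV: relative area change 100·(visit − baseline)/baseline (signed;
−100 = complete regression) and FD change reported decrease-positive
(baseline − visit, percentage points). The posttreatment visit is the
one 5 ± 1 weeks ([4, 6], nominal 5) after the last injection of the
initial treatment block; with several candidates the one closest to
the nominal week wins, ties resolving to the earlier visit. The
initial block is the leading run of injections with gaps ≤ 8 weeks
(monthly cadence with scheduling slack) — later reinjections for
recurrence or macular edema do not move the window. Series must keep a
constant pixel spacing; mixing scan patterns within one NV is refused
rather than silently rescaled.

Cohort summaries: median with range; mean with sample SD (n − 1); 95%
CI as mean ± 1.96·SD/√n. The z-multiplier (not Student-t) and the
Wilcoxon variant — zeros dropped, average ranks with tie-corrected
variance Σ(t³−t)/48, *no* continuity correction, two-sided normal p —
were identified by back-solving the published cohort report from its
per-NV table; with them, every printed CI and p-value reproduces. An
exact-enumeration p (all 2ⁿ sign assignments, n ≤ 20) is available but
not default. No multiple-testing correction is applied, matching the
original analysis. The packaged nine-NV table stores the printed
integer endpoint values plus raw-area columns derived by normalizing
each baseline to 1.0 mm², so relative changes can be recomputed from
raw values as a self-consistency check. A few published figures do not
reproduce from the integer table (documented in
`octanv.reference.KNOWN_INCONSISTENCIES`); they are excluded from the
reproduction report rather than approximated.

## Synthetic OCTA generator

What it emulates: a fan-like branching NV anchored on a flat ILM
(volume indexed [y, x, z], z increasing toward the vitreous, default
256×256×128 voxels at 11.7 µm/px lateral — a 3×3 mm pattern — and
2 µm/px axial); binary-tree branching (depth d ⇒ 2^d − 1 segments)
with lateral fan spread of 40°, decaying segment length and caliber;
capsule rasterization giving exact ground-truth voxel masks; structure
channel with retina/vitreous background and bright vessels, flow
channel nonzero only along perfused segments. Treatment response is a
perfusion schedule (fraction of non-root segments perfused per visit):
pruning is distal-tier-first — the residual perfused set is always a
connected proximal subtree, ending at the "truncated arc" at fraction
0 — and perfused sets at different fractions are nested, so monotone
schedules give monotone perfused areas. The structural scaffold is
never deleted. Recurrence raises the fraction again from a configurable
week. Noise: multiplicative Rayleigh speckle (unit-mean factor, damped
by the noise level, default 0.08) on structure, clipped additive
Gaussian on flow. One seed governs tree, schedule, and noise;
identical parameters give bit-identical exports.

Exported ground-truth outlines are convex hulls of the projected truth
masks — emulating a rater outlining the lesion envelope and
guaranteeing nested outlines under regression. The truth CSV's
"true perfused fraction" is the percentage of structure-outline pixels
overlying a perfused vessel in the noise-free rasterization, i.e. the
value FD-structure estimates.

What it does **not** emulate: physical OCT speckle statistics, eye
motion and projection artifacts, layer-segmentation errors, curved
ILM, vessel tortuosity and anastomoses, partial-volume shading.
Passing tests therefore certify the measurement chain (projection,
binarization, rasterization, counting, endpoint selection), not
robustness to real-world acquisition artifacts.

## Numerical and design choices

* Axial slab is half-open [lower, upper); a voxel strictly below the
  ILM is excluded from the projection by construction.
* Capsule rasterization includes voxel centers within one radius of
  the segment axis (point-to-segment distance, clipped parameter).
* Test and acceptance runs use a 192×192×96 grid, depth 5, noise off,
  perfusion 1.0 → 0.2 over five visits with injections at weeks
  0/4/8 — small enough for seconds-scale runs while leaving ≥ 100 px²
  outlines; the package default stays 256×256×128.
* ImageJ `.roi` I/O implements the classic integer-coordinate polygon
  record; non-polygon subtypes are rejected by name. A JSON polygon
  dialect (`{"plane": ..., "vertices": [[x, y], ...]}`) is the
  native format.
* B-scan overlays are rendered R = clip(gray + 255·flow), G = B =
  gray, so the red-blue subtraction recovers the flow plane exactly
  where unsaturated.
* Degenerate inputs raise typed errors: empty ROI masks, zero
  baselines, all-zero difference vectors, schedules missing the
  requested week, ROIs below the ILM, slabs outside the volume.

## Known limitations

* The nine NVs of the packaged cohort include fellow eyes and two NVs
  of one eye; they are summarized as independent, as in the original
  analysis — no mixed-effects correction.
* The normal-approximation Wilcoxon p is anti-conservative at n = 9;
  it is kept as the identified reporting convention, with the exact
  option one argument away.
* FD depends on the binarization parameters; values are comparable
  only at fixed `PhansalkarParams`.
* B-scan metrics are sensitive to slice selection and misalignment in
  real data; the generator always slices through the root anchor, the
  most favorable case.
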