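# Methods

This note records the models, conventions and numerical choices behind
`cortimorph`, in the order a user meets them: the measurement frame,
the Y-shape morphometry, the fiber analyses, the synthetic generator,
and the statistical reporting. Units are nanometres internally and
micrometres/degrees in every reported quantity.

## Reference frame

All heights and angles are measured against a frame fitted from the
annotation itself, so the pipeline carries no external calibration:

* **BM plane** — total least squares over all Deiters-cell (DC) root
  landmarks, rows pooled: the normal is the singular vector of the
  centred root matrix with the smallest singular value, oriented so the
  mean OHC apical landmark lies on the positive side. Degenerate input
  (< 3 roots, collinear roots) raises rather than guessing.
* **Row lines** — per row, the first principal axis of that row's
  roots; the sign is set by a required `basal_hint` vector (the
  cochlear-base direction is an anatomical datum — fibers turn toward
  it — that a local segment cannot supply by itself). The frame
  validates that the three row directions agree within 30°.
* The analysed segment (~220 μm of mid-cochlea) is treated as locally
  straight; no spiral unrolling is attempted. Rotation/translation
  equivariance of the fits is property-tested.

## Y-shape morphometry

* Lengths are Euclidean path sums along the unique tree path between
  landmarks: L_OHC basal pole → cuticular plate, L_DC DC root → PhP
  branch point, L_PhP branch point → apical insertion. The partition of
  the Y at the branch-point landmark is a convention of this package;
  the tree property guarantees path uniqueness.
* Structure axes are whole-path SVD axes (first right-singular vector
  of the centred node coordinates), signed to point from the first
  landmark to the second, i.e. BM → RL everywhere.
* α is the unclipped arccos of the two co-oriented axes: a straight
  OHC→PhP continuation reads 0°, so α is the opening angle of the Y
  (~30–52°). Whether to fold angles at 90° is therefore never an issue.
* β is reported twice: the full 3D angle (headline) and the angle after
  projecting the axis into the plane spanned by the row direction and
  the BM normal. The two differ when a structure tilts radially; both
  are kept because either convention is defensible and the choice
  matters at the several-degree level. OPCs use row 1's line (they abut
  row 1).
* **Mosaic span**: OHC apices of each row are ranked by projection onto
  that row's line (column ranks); span = |rank(nearest column to the
  PhP insertion) − rank(own OHC column)| + 1. Exact ties break toward
  the base and are flagged. Abutting partners are apices within 6 μm of
  the insertion *in the lamina projection* (perpendicular to the BM
  normal) — insertion depth is not part of abutment.
* Only complete complexes (all five landmarks) are measured; exclusions
  are counted, mirroring an intact-complexes-only census.
* QC: when both axes lie near the longitudinal plane, β_OHC − β_PhP
  should approximate α within 5°; violations are flagged, not fatal.
  In the longitudinal projection the identity |β_OHC,proj − β_PhP,proj|
  = α_proj is exact and is asserted in the tests.

## Type-2 fiber analysis

* **Turn location**: the annotated `turn` landmark is honoured when
  present. The detector otherwise maximises the angle between mean
  incoming and outgoing tangents over a 5 μm window along the fiber's
  longest path, restricted to the outer-pillar radial zone (default
  −12…−2 μm from the row-1 line) — the turn happens right after the
  fiber bypasses the pillar cells, and the restriction keeps
  collateral-junction angles out of contention. Below 45° the fiber is
  excluded from compartment analysis (signalled, logged).
* **Profiles**: one sample per main-trunk node past the turn
  (trunk = turn → `fiber_end` landmark, else the farthest node). Each
  sample carries arc length, longitudinal position (projection onto
  the row-1 direction), height above the BM, and the nearest
  supporting-cell trunk within 2 μm (DC main trunks and OPCs, densely
  resampled at 0.5 μm into a KD-tree). Negative heights are flagged.
* **Biphasic fit**: the breakpoint is the first collateral origin — the
  compartments are defined anatomically by the presence of
  OHC-innervating collaterals, not by a free change-point search (a
  change-point variant would be easy to add but is deliberately not the
  default). Each side gets an ordinary least-squares slope of height vs
  longitudinal position (dimensionless), plus a per-DC variant obtained
  by multiplying with the configured DC pitch (default 6.8 μm). OLS on
  noiseless piecewise-linear input is exact (property-tested); with the
  generator's smooth skeleton jitter the short contact region carries a
  per-fiber slope noise of a few thousandths, which is zero-mean and
  disappears in cohort means.
* **Contact heights** are pooled per (fiber, supporting cell, region)
  — one observation per pair, so long attachments do not dominate.
* **Innervation**: the fiber × OHC matrix is built strictly from the
  contact table (boutons are point annotations; proximity inference is
  never used). Denominators cover every labeled OHC including
  zero-contact ones. Row specificity: a fiber is exclusive iff all its
  contacts target one row; zero-contact fibers (e.g. truncated
  segments) are excluded from the fractions and counted separately.

## MOC classification

A tunnel-crossing is a connected stretch of the fiber inside the
radial slab between the pillar-cell rows (config: two offsets from the
row-1 line, default −22…−14 μm) that reaches both slab faces from the
modiolar side. Edges are split at the slab faces before counting, so
the count is invariant to node-resampling density (property-tested).
Branched ⇔ ≥ 2 crossings; a fiber that never traverses the slab is not
an MOC by this anatomy and is flagged. Branching *beyond* the slab
does not affect the classification (the generator deliberately gives
some unbranched fibers post-slab bifurcations to exercise this).

## Synthetic organ of Corti

The generator emulates a bounded mid-cochlear window of the sensory
epithelium; its defaults are the study conditions of the `cba1` preset
(and `cba2` for the second-animal configuration).

* **Lattice.** Rows at 10 μm radial spacing over the z = 0 BM plane,
  32 columns at 6.8 μm pitch (row 2 honeycomb-staggered by half a
  pitch), OPC row 7 μm modiolar of row 1. Per-complex lengths and
  angles are drawn from truncated Gaussians (±4 SD). The *reticular
  lamina is the regular structure*: apical columns sit on the pitch
  grid and the root positions absorb each cell's tilt variation, so the
  roots form a honeycomb with correlated ~2 μm scatter. (Independent
  apex scatter would shuffle column order and destroy the exact span
  rule, which is not what the real, crystalline RL mosaic looks like.)
* **Exact span + exact α.** For each complex the sampled L_DC/β_DC
  place the trunk and L_OHC/β_OHC the hair cell (both in the
  longitudinal plane, so β is recovered exactly). The PhP direction is
  then solved with two constraints — its longitudinal component is
  fixed by the span target (the apex column span−1 columns toward the
  base, with the tip wedging 1.5 μm apical of the target cuticular
  plate) and its angle to the OHC axis equals the sampled α — leaving
  the radial component as the free coordinate. β_PhP is therefore
  *emergent* (realized means ≈ 70/79/91° by row versus the 61/67/75°
  reference values; the ordering and inter-row trend are preserved, and
  the discrepancy is reported rather than forced). Draws in the
  infeasible small-α corner (≈ beyond −3.5 SD) resample α and L_PhP.
* **Skeleton noise.** Nodes at 1 μm spacing; perpendicular jitter is a
  smooth two-mode sinusoidal bow (amplitudes σ = 0.15 μm and σ/2) with
  exact endpoints, so axis estimates scatter realistically while path
  tortuosity stays ≈ 1 and sampled lengths are recovered to ≪ 0.1 μm.
  Coordinates are quantized to the voxel grid (11 × 11 × 40 nm).
* **Edge incompleteness.** The complexes whose span target falls
  outside the lattice (the basal span−1 columns per row) plus
  additional apical edge columns, to the configured 3/2/3, are
  generated without the PhP insertion landmark — their process leaves
  the volume — giving the 29/30/29 intact census while their apices
  still populate the RL lattice.
* **Type-2 fibers.** 40 complete fibers with home rows apportioned from
  the per-OHC contact means; climbing slope ~N(0.23, 0.07), contact
  slope ~N(0.02, 0.09), turn height ~N(13, 2) μm, plateau entry
  ~N(36.5, 3) μm. Height is linear in longitudinal position with the
  climbing slope up to the first collateral and the contact slope
  after, exactly; the first collateral leaves at the very first
  contact-region node so the anatomical breakpoint and the slope change
  coincide. Breakpoints are placed uniformly over the segment and
  climbs may begin before it (such fibers turn outside the window), as
  boundary truncation produces in a real volume. Collaterals target
  consecutive own-row OHC columns; with probability 0.125 a fiber
  splits its contacts with a neighbouring row; bouton classes are drawn
  from the per-row ribbon fractions.
* **Per-DC abundance.** A ~220 μm window cannot contain 40 fully
  resident fibers *and* 20.4/13.6/7.6 attached fibers per DC1/2/3 —
  that would need ≥ 350 μm of travel per fiber. The real counterpart of
  the missing coverage is fibers truncated by the volume boundary, so
  the generator adds contact-free *passing segments*: it first counts
  the coverage the complete fibers actually achieve (using the
  analyzer's own attachment rule), then water-fills the per-column
  deficit with through-going segments laid against the trunk positions
  at their own height. Realized counts match the configured means with
  per-cell SD ≈ 0.5–1.3. Passing segments have zero contacts and are
  excluded from innervation statistics by the ordinary zero-contact
  rule; their entry node stands in for the turn landmark.
* **MOC fibers.** Exactly round(0.243 × 70) = 17 fibers are built
  branched (2–3 pre-slab branches, each crossing the tunnel slab at a
  distinct longitudinal offset); the rest cross once, half of the
  multi-synapse unbranched fibers bifurcating after the slab. Integer
  synapse counts come from a maximum-entropy exponential-quadratic pmf
  on the printed range (3–11 branched, 1–4 unbranched) whose two
  parameters are solved at config load so the distribution has exactly
  the printed mean and SD — a plainly cut Gaussian is biased by the
  asymmetric range (e.g. 5.69 instead of 5.18). Branched fibers place
  each synapse in a modal row with probability 0.7, mirroring their
  strong row preference; unbranched fibers draw rows i.i.d.
* **Determinism.** One seed drives three independent child streams
  (lattice, afferents, efferents); identical config + seed reproduce
  the annotation byte-for-byte through NML/CSV serialization.

### What the generator does and does not emulate

It reproduces the published per-row geometry distributions, the span
rule, the biphasic trajectory statistics, innervation counts,
specificities and MOC subtype structure, with realistic annotation
noise. It does **not** model: membrane ultrastructure or image data;
cochlear curvature; the transient height *drop* a fiber shows between
the pillar cells and the first DCs (heights here are monotone from the
turn, so the on-OPC contact heights sit near the turn height rather
than the published ~21 μm — recovery tests for the height-by-support
summary therefore check against the generator ledger, not the printed
means); per-fiber variance structure beyond the printed means and SDs;
and developmental or mechanical dynamics. Passing tests demonstrate
that the *analysis* recovers known ground truth under these
conditions; they are not evidence about features of real tissue the
generator does not model.

## Statistics and reporting

Group comparisons use the classical equal-variance two-sample t test
(Welch by flag), the paired t test (one-sided variant available for
the climbing-vs-contact comparison), and one-way ANOVA, via
`scipy.stats`. Significance bands are a pure function of p
(n.s. > .05, * < .05, ** < .01, *** < .001; property-tested). No
multiple-testing correction is applied — pairwise p-values are reported
raw alongside the ANOVA — and this is deliberate and documented here.
Identical constant groups define p = 1 (no evidence of difference)
rather than NaN.

The pipeline report (`report.json`, schema version 1) keys every
summary to a figure-style panel name and includes QC: excluded
incomplete complexes, span tie-breaks, fibers without a locatable turn,
unclassifiable MOC fibers, below-plane samples.

## Test design and problem sizes

Recovery tests are coverage tests: a per-seed cohort mean should fall
within 2 SEM of the configured value (SEM from the configured SD and
the realized n) in ≈ 95% of seeds, which is checked with a one-sided
binomial non-inferiority test (p₀ = 0.95, α = 0.005) — the band's
nominal coverage is itself 95.4%, so demanding a literal ≥ 95% hit rate
would fail a perfect generator half the time. Problem sizes in the
default suite: 100 seeds on a 16-column lattice for Y-shape recovery,
30 seeds × 15-fiber cohorts for the trajectory slopes, 30 seeds ×
40-fiber cohorts for row specificity, 20 full volumes for MOC
recovery; the full CBA1 volume used by the shared fixtures has ~350
trees and ~30k nodes and generates in under a second. The acceptance
script averages each stochastic quantity over 10–12 replicate seeds
derived from its `--seed`.

## Known limitations

* The co-orientation convention makes α, β_OHC and β_PhP mutually
  consistent only in the longitudinal projection; published values
  obtained under an unknown projection convention can differ by several
  degrees from the 3D values reported here (both are emitted).
* The mosaic-span column ranking assumes an ordered apex ladder; with
  apex position noise approaching half the column pitch, rank swaps
  would make spans off-by-one (flagged via ties only when exact).
* `read_swc` carries landmarks in a sidecar table; SWC alone cannot
  round-trip them.
* The tunnel-slab bounds and the OPC turn zone are configuration, not
  inference; misplacing them on real data shifts the MOC classification
  and turn detection respectively.
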