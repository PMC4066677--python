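# Methods

## Model and procedure

The package treats a porous object as a 3D binary map: voxel value 1 is pore
(void), 0 is solid, with an isotropic physical voxel size in micrometres.
All statistics are functions of this map alone; grayscale data enter only
through segmentation.

**Gliding-box lacunarity.** For box side `r` (voxels), every axis-aligned
cubic box fully inside the volume is visited at a stride of one voxel — no
wrapping, no padding — giving `N(r) = Π(dimᵢ − r + 1)` positions. (A common
printed shorthand for cubes, `(M − r + 1)²`, is a 2D count; the 3D gliding
procedure requires the product over all three axes, which is what this
implementation uses and what its endpoint identities assume.) Box pore
counts are obtained from a zero-padded 3D summed-volume table in O(1) per
box after O(V) preprocessing, accumulated in 64-bit integers so a 256³
volume cannot overflow. LAC is the moment ratio `μ₂/μ₁² = 1 + σ²/S̄²`, with
the *population* variance over box positions, because the box set is
exhaustive rather than a sample. An empty pore phase makes the ratio
singular; the code raises rather than returning a value. An independent
brute-force enumeration (`brute_force_lacunarity`, literal triple loop,
naive counting, no shared code with the optimized path) backs the test
suite's equivalence checks.

**Relative lacunarity.** `RLF = −ln(LAC)/ln(n)` removes the porosity
dependence; it is undefined at n ∈ {0, 1} and the scalar operation rejects
those inputs. The curve builder special-cases the one reachable degenerate
input — an all-pore volume, where LAC ≡ 1 at every r — and reports its
homogeneous limit RLF = 0 instead of failing.

**Analytic identities** used as test oracles: LAC(1) = 1/n exactly (unit-box
counts are Bernoulli draws); LAC = 1 at r = side of a cubic volume (single
box, zero variance); RLF(1) = 1; for an exactly periodic lattice LAC = 1 at
every r that is a multiple of the period (each such box contains every
residue class equally often — for other r, boxes straddle period boundaries
and the variance need not vanish, so nothing is asserted there); and for an
i.i.d. Bernoulli field the marginal box count is Binomial(r³, p), giving
LAC = 1 + (1 − p)/(p·r³).

**Randomness scale.** `r*` is the smallest evaluated box size with
LAC ≤ 1 + ε. "Close to 1" is not canonically quantified, so ε is an exposed
parameter, default 0.05; a curve never reaching the threshold returns a
"beyond range" sentinel instead of extrapolating. The box size with the
largest change in slope of ln LAC vs ln r is reported as a secondary
diagnostic, and a non-monotone curve triggers a warning rather than an
error.

**Segmentation.** Slices are binarized per-slice in 2D. Local thresholds
follow Niblack, `T = m + k·s` (default window 25 px, k = −0.2), and Sauvola,
`T = m·(1 + k·(s/R − 1))` (k = 0.2, R = half the intensity dynamic range) —
standard defaults from the originating literature, all exposed in
configuration; the window computations (reflect-style edge handling) are
delegated to scikit-image. Polarity: pore = dark by default (air attenuates
X-rays less than material); an invert flag covers the opposite convention.
Strategy selection scores each candidate by the Pearson correlation at zero
lag between the wrapped Fourier phase arrays (DC term excluded) of the
grayscale slice and of the candidate rendered in the slice's own intensity
polarity — rendering matters, because an intensity inversion shifts every
non-DC phase by π and would invert the ranking. Exact ties are broken by a
fixed ordering (fixed < mean < otsu < niblack < sauvola, later preferred).
Phase correlation of the wrapped angle arrays is the simplest reading of
"correlation between Fourier phases"; a phase-only correlation peak is a
plausible alternative reading, which is why the chosen definition is stated
here and echoed in run metadata.

**Geometry.** 0-based C-order (z, y, x) indices and half-open ranges
everywhere. Micrometre slab thicknesses convert to voxels by rounding to the
nearest integer (minimum 1, realized thickness logged): e.g. a 520 μm slab
at 8.7 μm/voxel becomes 60 voxels. Non-cubic volumes are accepted
throughout; box sizes are capped by the smallest dimension.

**Subvolume heterogeneity.** Parallel slabs are each analyzed with their own
porosity, so RLF differences isolate texture. The divergence statistic is
the maximum over shared box sizes of the RLF spread (max − min) across
slabs. Because visual curve comparison is not a test, the package builds a
Monte-Carlo null: re-seeded homogeneous Bernoulli volumes of the same size
and porosity, same slab layout, 95th percentile of their divergences as the
default threshold for calling a volume regionally heterogeneous.

## Synthetic volumes: what they emulate and what they do not

The generators supply ground truth for every downstream stage. `foam_volume`
unions overlapping spheres (truncated-normal radii, voxel-center-in-sphere
voxelization) until the realized porosity first crosses the target —
overshoot of at most one sphere is accepted and the realized value recorded,
matching the statistical character of a freeze-dried foam rather than
forcing an exact fraction. Default conditions mirror the scaffold setting:
porosity targets in the 0.68–0.81 range, pore radii large against the voxel
size. `occlude_pores` emulates an inorganic filler occluding pores: when the
foam's generating sphere list is available it converts randomly selected
whole pores to solid (surviving pores keep their size, so the texture
becomes clumpier — fewer but larger pores); for arbitrary volumes it falls
back to shell-by-shell erosion. Both modes land on the target pore count
exactly via a seeded random boundary step, which makes output porosity
monotone in the occlusion fraction. `render_grayscale_stack` maps solid to
bright and pore to dark, then adds Gaussian noise and an optional linear
per-slice illumination ramp.

These are analogues, not physics: no ice-templating simulation, no CT
projection/reconstruction, no beam hardening or ring artifacts, no partial
volume effects. Passing tests therefore demonstrate correctness of the
statistics and the qualitative orderings (occlusion raises RLF; regional
texture differences raise subvolume divergence above the homogeneous band)
on controlled textures — not segmentation robustness on real scanner data.

All generators draw from per-operation `numpy.random.Generator` streams
seeded explicitly; identical parameters and seed reproduce a volume bit for
bit, and the pipeline as a whole is deterministic (re-running a config gives
byte-identical CSV/JSON; provenance carries the config echo and package
version, while timestamps go only to the log so determinism holds).

## Problem sizes and numerical choices

Tests and examples run at 32³–64³ with box sizes 1–64 (all integers by
default, any explicit list accepted); the statistics themselves handle 256³
comfortably via the integral table. The Monte-Carlo band uses 100
replicates at 64³. Internal consistency tolerances: probabilities sum to 1
within 1e−12, the `1 + σ²/S̄²` and `μ₂/μ₁²` forms agree within 1e−9,
optimized and brute-force paths within 1e−12. Natural logarithms throughout.

## Known limitations

- Lacunarity is resolution-dependent; results are comparable only between
  volumes at the same voxel size, and pores near one voxel in size are
  poorly resolved by construction.
- The box-size cap at the smallest dimension means thin slabs cannot probe
  large scales; the subvolume comparison drops such box sizes per slab and
  logs it.
- Whole-pore occlusion requires generator metadata; segmented real volumes
  always use the erosion fallback, a weaker analogue of filler deposition.
- Per-slice 2D segmentation ignores through-plane continuity; no
  machine-learned or 3D-windowed segmentation is provided.
- Fractal (box-counting) dimension estimation, anisotropic/grayscale
  lacunarity variants and pore-network graph extraction are out of scope.
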