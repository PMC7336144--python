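# Methods

## Signal model

Each voxel's b0-normalised diffusion signal is a nonnegative mixture of
three axially symmetric compartments evaluated on the acquisition scheme
(b-value `b` in s/mm², unit gradient `g`, unit fibre direction `v`):

* stick (intra-axonal): `exp(−b·d∥·(g·v)²)`
* zeppelin (extra-axonal): `exp(−b·(d⊥ + (d∥−d⊥)(g·v)²))`
* ball (isotropic): `exp(−b·d_iso)`

Diffusivities default to literature-conventional white-matter values:
`d∥ = 1.7e−3`, `d⊥ = 0.61e−3`, free-water `d_iso = 3.0e−3` mm²/s. A
hindered isotropic diffusivity (1.7e−3 mm²/s) is carried in
`TissueParams` for completeness, but the default forward model uses a
single free-water ball per voxel: with one ball the per-voxel fraction
split is identifiable at desk scale, and lesions are represented as a
free-water increase, which is the role the second ball would duplicate.

The central modelling assumption is that a streamline's intra-axonal
contribution is constant along its whole path: streamline `k` with weight
`x_k` (a signal-fraction density, units 1/mm) contributes `x_k·L_{kv}` of
stick signal in voxel `v`, where `L_{kv}` is its chord length there.
Stacking voxels × measurements gives the sparse operator `A` with column
blocks (intra | extra-axonal | isotropic), in stable order.

### Geometry

Streamlines live in scanner-mm coordinates with a diagonal voxel→mm
affine; a point belongs to voxel `i` iff its coordinate lies in
`[i·size, (i+1)·size)` (0-based). Chord lengths come from fixed-step
resampling (default step = 0.1 × min voxel size) with the original
vertices kept among the sample points, so arc length is conserved exactly
and only the voxel assignment of sub-steps is approximate (tested against
an analytic diagonal-crossing oracle at 0.5%). The per-voxel streamline
orientation is the length-weighted mean chord direction — one kernel
evaluation per (streamline, voxel), matching the resolution of the signal
model. Extra-axonal orientations are taken from the phantom's
ground-truth per-bundle mean directions (one zeppelin column per bundle
per voxel; crossing voxels get two), since fibre-orientation estimation
is out of scope.

## Phantoms

`two_bundle_phantom` builds the workhorse configuration: a 10×10×3 voxel
grid (1 mm isotropic) with two orthogonal bundles crossing at the centre,
six streamlines each. Streamlines are parallel offsets of the bundle axis
placed on a lateral lattice of one-voxel pitch with ±0.2 mm jitter: each
streamline occupies its own voxel row, which keeps the intra-axonal
columns of a bundle linearly independent — without this, per-streamline
weights are not identifiable (only bundle sums are) and recovery tests
would be meaningless. Weights are drawn uniformly from 0.04–0.10 /mm.

Per voxel the construction closes the fraction budget exactly:
`f_intra + f_extra + f_iso = 1`, with background voxels pure free water
and bundle voxels holding 5% base isotropic fraction. Lesions are
spherical and act two ways: the isotropic fraction rises inside the mask
(default +0.3, capped so the budget stays ≤ 1) and every streamline
traversing the mask has its weight scaled down (default ×0.5) along its
whole path, consistent with the constant-contribution assumption. The
extra-axonal fraction absorbs the remainder, so adding a lesion strictly
lowers `f_intra` in masked voxels while the budget still sums to one.

Spurious candidates are straight oblique chords between random interior
points: they cross voxels at orientations unmatched by any true fibre and
traverse pure-isotropic background, so their true weight is zero and a
correct fit must return zero. Noise, when requested, is Rician with scale
`1/SNR` (Gaussian available for analytic checks).

Simulated cohorts default to 24 controls vs 42 patients. Every metric
follows the linear, homoscedastic model the downstream ANCOVA assumes:
baseline + group shift (in SD units) + age/sex slopes + an optional
loading on the subject's standardized density + Gaussian noise. The
loading routes a *density-mediated* group effect (the conditional effect
given density is exactly zero); the shift injects a *direct* one. What
passing tests show is therefore calibration and behaviour under the
model's own assumptions — real cohorts add non-normality,
heteroscedasticity, covariate imbalance and measurement error that these
generators deliberately omit.

## Fitting

`fit_weights` solves `min_{x≥0} ½‖Ax−y‖²` with monotone FISTA: projected
gradient steps of size `1/‖A‖²` (power iteration), acceptance only when
the objective does not increase, momentum restart on rejection, start at
`x = 0`, convergence when the relative objective decrease falls below
`tol` (default 1e−8, `max_iter` 1000). The objective history is recorded
and non-increasing by construction. A final polish step re-solves the
least squares problem on the active support via the normal equations and
is accepted only if feasible and at least as good — on noiseless phantoms
this lands on the exact solution. No regularisation is used. The default
removal threshold for filtering is 1e−10 (signal-fraction density);
it is exposed because no canonical cutoff exists.

## Connectomes and thresholding

Endpoint assignment is exact voxel membership of the two endpoints in the
label volume (no dilation): background endpoints are unassigned,
same-node pairs are discarded as self-connections. Matrices are symmetric
with zero diagonal. The weighted entry is
`a_ij = Σ x_k l_k / (Σ l_k / N_ij)`; for a single-streamline bundle the
lengths cancel and `a_ij = x_1`. Bundles whose streamlines were all
filtered out stay zero.

Proportional thresholding is per subject over the *nonzero* edges (keep
the `⌈p·E⌉` largest, stable index tie-break). Consistency thresholding is
group-level over all `P = n(n−1)/2` *possible* edges: rank by inverse
coefficient of variation of weights across subjects (edges absent in any
subject rank last, mean weight breaks ties — identical subjects therefore
degrade to pure weight ranking), keep the top `⌈d·P⌉` as one mask applied
to every subject. With `d = 0.30` and 14 nodes the mask holds 28 of 91
edges, a common density of 30.77% — exactly 30% is unattainable because
0.30·91 is not an integer, and the implementation stays within one edge
of the target by construction.

## Graph metrics

Path-based measures use edge length `l = 1/w`; disconnected pairs
contribute zero efficiency (1/∞ = 0), not dropped. Clustering is the
Onnela geometric-mean variant with max-weight normalisation; local
efficiency is the weighted neighbourhood-subgraph efficiency with
cube-root neighbour-weight correction (nodes with < 2 neighbours score
0); assortativity is the Pearson correlation of endpoint strengths over
edges, both orientations, with an NaN flag when the endpoint-strength
variance is zero. These are conventions of the standard brain-connectivity
toolbox formulations, stated here because several inequivalent weighted
variants exist.

Modularity is weighted Newman `Q = Σ_c (e_c − γ·a_c²)` at `γ = 1`.
The optimiser is Louvain (seeded node order, multi-level aggregation)
followed by a refinement stage on the original network: single-node
moves, community merges, and a Kernighan–Lin escape pass (sequences of
best single moves with worsening steps allowed, keeping the best visited
configuration). A deterministic spectral candidate — Newman
leading-eigenvector recursive bisection — is refined the same way and the
better Q wins; the combination reaches the enumerated global optimum on
≥ 95% of random 10-node weighted graphs. Exact enumeration over set
partitions (vectorised restricted-growth strings) is available up to 12
nodes; beyond that the Bell number makes enumeration infeasible
(Bell(13) ≈ 2.8e7 partitions is the practical edge, Bell(16) ≈ 1e10 is
not reachable). The panel default reports the best of 10 seeded runs.

## Statistics

ANCOVA is OLS of `metric ~ group + covariates` with the two-sided t-test
on the group coefficient (identical to the 1-df F-test, asserted in the
suite). Group is coded HC = 0, patient = 1; sex F = 0, M = 1. A
zero-variance outcome returns β = 0, p = 1 with a flag instead of
failing; collinear designs (condition number > 1e10) raise. Partial
correlation is the Pearson correlation of covariate residuals with
`df = n − k − 2`. Stepwise regression forces block 1 (age, sex), then
forward-selects block-2 candidates by smallest partial-F p < `p_enter`
with backward removal at p > `p_remove`; defaults 0.05/0.10 are the
conventional criteria of standard statistics packages, since none are
canonical. `p_enter ≤ p_remove` is required to prevent cycling, and a
hard iteration cap guards the loop regardless. Reported betas for
selected variables are standardized. Bonferroni thresholds are exact
`α/m` for comparisons (m = 6 global, 14 nodal); display rounds to three
decimals only. The battery skips the density-adjusted model for density
itself, mirroring the analysis design.

## Reproducibility and problem sizes

All randomness flows from a single integer seed through named CRC-tagged
substreams (phantom, spurious, noise, cohort, louvain…); every generator
is a pure function of (spec, seed), and pipeline reruns with one config
reproduce all artifacts bit-identically (sha256 manifest). The test
bench runs at deliberately small sizes — 300-voxel grids, 61-measurement
schemes, ≤ 72 candidate streamlines per phantom, 10-node graphs for
enumeration, and a few hundred to a thousand cohort replicates per
calibration check — chosen so the full suite exercises every claim in
minutes while the phantom problems stay comfortably identifiable.

## Known limitations

* No realistic head geometry, motion/eddy artefacts, or tractography:
  candidate streamlines are generated, not tracked, and fibre orientations
  come from ground truth rather than spherical deconvolution.
* Weight recovery to machine precision is a noiseless, identifiable-design
  property; with noise or collinear bundle geometry only bundle-level sums
  are stable.
* The cohort generator is the ANCOVA's own data-generating process; it
  validates calibration, not robustness to assumption violations.
* The exact modularity mode is limited to 12 nodes; 14-node panels rely on
  the heuristic (best-of-10 seeded runs).
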