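# Methods

## The model

`rd5d` analyses MRI experiments in which every image is encoded jointly for
transverse relaxation and for diffusion with axially symmetric b-tensors.
Each measurement is described by five variables: echo time τE (s), b-tensor
trace b (s·m⁻²), normalized b-tensor anisotropy bΔ ∈ [−0.5, 1] (1 linear,
0 spherical, −0.5 planar), and b-tensor orientation (Θ, Φ).

A voxel is modelled as a collection of independent microscopic environments
("components"), each characterized by a transverse relaxation rate R2 and an
axially symmetric diffusion tensor with eigenvalues (D∥, D⊥) and orientation
(θ, φ).  Writing Diso = (D∥ + 2D⊥)/3 and DΔ = (D∥ − D⊥)/(3 Diso), the signal
attenuation of one component at one acquisition point is

    K = exp(−τE R2) · exp(−b Diso [1 + 2 bΔ DΔ P2(cos β)])

with P2(x) = (3x² − 1)/2 and β the arc angle between the b-tensor and
diffusion-tensor symmetry axes, cos β = cos Θ cos θ + cos(Φ − φ) sin Θ sin θ.
The voxel signal is the weight-sum of K over components; the total weight
plays the role of the unattenuated amplitude S0.  Since
1 + 2 bΔ DΔ P2(cos β) ≥ 0 over the admissible ranges, the diffusion exponent
never amplifies the signal.  Attenuations are assembled in log space and
exponentiated once, so large b·Diso products underflow gracefully.

All quantities are SI internally: b in s·m⁻² (10⁹ s·m⁻² = 1 ms·µm⁻²),
diffusivities in m²·s⁻¹, τE in s, angles in radians.  Scheme files may use
the common s·mm⁻², millisecond and degree dialects when the header says so.

## Acquisition schemes

Protocols are described as shape blocks (one b-tensor shape with its
b-shells, per-shell direction counts and echo times) and expanded to a point
table ordered by block, then τE, then b, then direction.  Per-shell gradient
directions are generated by seeded projected-gradient descent of the
antipodally symmetric electrostatic energy Σ 1/|uᵢ−uⱼ| + 1/|uᵢ+uⱼ| (best of
three restarts, ~600 iterations).  The design criterion is the attained
energy; no published direction table is reproduced.

Three presets are built in:

* `full45` — the exhaustive 852-point protocol: bΔ = 1 with 6/10/16/40
  directions at b = 0.1/0.7/1.4/2.0×10⁹ s·m⁻²; bΔ = ±0.5 with 6/10/16/32
  directions on the same shells; bΔ = 0 with one orientation repeated 6
  times over six b-values — all at τE = 80/110/150 ms — plus a linear block
  at τE = 60/80 ms.  (72+64+64+36)·3 + 72·2 = 852 points.
* `short15` — an abbreviated ~280-point variant that concentrates 87% of
  its points at two echo times (80/150 ms), which is the abbreviation's
  defining property; the exact shell table of the published short protocol
  is not public, so this is a same-generator approximation.
* `mini` — 51 points (τE = 55/95/150 ms, bΔ ∈ {1, 0, −0.5}, b up to
  2×10⁹ s·m⁻², all five variables varied) used throughout the test suite so
  that full inversions run in milliseconds.  Its echo times stay within the
  physically realizable range of the sequence family (τE ≳ 50 ms).

## Monte Carlo inversion

Recovering the component distribution from a few hundred measurements is a
severely ill-posed Laplace-type inversion.  Rather than a regularized fit on
a fixed grid, the solution space is explored stochastically, per voxel:

1. **Seeding/merging (20 rounds).**  Each round draws 200 candidate
   components log-uniformly from the sampling box
   (0 < log₁₀ R2 < 1.5, −10 < log₁₀ D∥ < −8.5, −10 < log₁₀ D⊥ < −8.5,
   uniform in 0 < cos θ < 1 and 0 < φ < 2π), merges them with the surviving
   components of the previous round, fits all weights by non-negative least
   squares (NNLS, Lawson–Hanson), and keeps the strictly positive weights.
   Because each round's dictionary contains the previous survivors, the
   residual is non-increasing by construction.
2. **Mutation (20 rounds).**  The survivors are duplicated; the copies
   receive multiplicative log-normal jitter on R2/D∥/D⊥ (0.05 decades) and
   Gaussian angular jitter (5°), clipped to the box.  Original ∪ mutated is
   refitted and the lowest-residual configuration is kept.
3. **Finalization.**  The 10 highest-weight components (stable sort; ties
   broken by earlier index) are refitted and pruned.

Nonzero means exactly nonzero: the active-set NNLS solver returns exact
zeros for inactive columns, so no epsilon culling is applied.  An empty
final component list is the "trivial solution"; such voxels can be repaired
by pooling their own components with those of their six grid neighbors
(≤ 7×10 candidates), refitting, and keeping the top 10 — an empty pool is
flagged unrecoverable (`None`).

Ensembles of N = 96 (default) independent repetitions quantify solution
uncertainty.  Each member has its own RNG stream derived from
(seed, voxel index, member index), so results are bit-identical regardless
of execution order or worker count.  By default each member additionally
sees a with-replacement resample of the measurement rows (bootstrap);
setting `bootstrap=False` gives pure random-restart ensembles.  Which of
the two mechanisms the original implementation used is not documented in
the lineage this package follows; both are provided and the choice is
explicit in the configuration.

`MonteCarloInverter` wraps the procedure as a scikit-learn estimator
(`fit(X)` over an (n_voxels, n_measurements) array, fitted attribute
`ensembles_`), composing with sklearn's parameter-management tooling.

## Ensemble statistics and binning

Every solution is reduced to weighted means, variances and covariances of
{R2, Diso, DΔ²} over its components; anisotropy enters squared because
prolate and oblate tensors of equal |DΔ| produce nearly indistinguishable
signals.  Statistics are computed per ensemble member and then condensed to
a central value ⟨x⟩ (ensemble median) and an uncertainty σ[x] (median
absolute deviation) — never on the pooled ensemble.  Members with undefined
moments (trivial solutions) are dropped from the reduction and counted.

Components are assigned to axis-aligned boxes in
(log₁₀ Diso, log₁₀ D∥/D⊥, log₁₀ R2) space:

| bin   | log₁₀ Diso (m²s⁻¹) | log₁₀ D∥/D⊥ | log₁₀ R2 (s⁻¹) | loosely captures |
|-------|--------------------|--------------|-----------------|------------------|
| big   | (−8.7, −8.0)       | (−3.5, 3.5)  | (−0.5, 2.0)     | CSF              |
| thin  | (−10, −8.7)        | (0.6, 3.5)   | (−0.5, 2.0)     | white matter     |
| thick | (−10, −8.7)        | (−3.5, 0.6)  | (−0.5, 2.0)     | gray matter      |

Intervals are half-open [lower, upper) so that binning is a deterministic
partition.  The thick bin splits along log₁₀ R2 into "low" (−0.5, 1.2),
"medium" (1.2, 1.4) and "high" (1.4, 2.0) sub-bins — in T2 units 63 ms–3.16 s,
40–63 ms and 10–40 ms.  The bins' R2 range deliberately exceeds the
inversion sampling box (upper limit 10^1.5 ≈ 31.6 s⁻¹): the printed upper
bound of 100 s⁻¹ is cosmetic, components can never populate the outer range.

Per-bin outputs are signal fractions, per-bin moment medians/MADs, and the
weight-averaged laboratory-frame tensor with its direction-encoded color
[R,G,B] = [Dxx, Dyy, Dzz]/max(Dᵢᵢ).  Per-component colors use
|[cos φ sin θ, sin φ sin θ, cos θ]| · |D∥−D⊥|/max(D∥, D⊥); the channel-wise
absolute value follows the direction-encoded-color map convention, since
RGB channels cannot be negative.

A voxel is a "mixed" thin+thick voxel when both bins hold ≥ 30% of its
signal, and "separated" when additionally the two bins' ⟨E[R2]⟩ differ by
more than the sum of their MADs (the combination rule is this package's
choice; only "greater than the estimated uncertainties" is prescribed).
Voxel collections are masked at ⟨S0⟩ > 5% of the maximum before tabulation.

## Synthetic phantoms

The generator emulates the three dominant brain constituents with one
component each, placed so that every preset falls inside its intended bin:

| preset | R2 (s⁻¹) | Diso (10⁻⁹ m²s⁻¹) | DΔ  | orientation |
|--------|----------|--------------------|-----|-------------|
| csf    | 0.4      | 3.0                | 0   | fixed       |
| gm     | 12       | 0.8                | 0   | fixed       |
| wm     | 15       | 0.8                | 0.8 | random      |

These numbers are package choices satisfying the qualitative ordering (CSF:
fast diffusion, slow relaxation; GM/WM: slower diffusion, faster relaxation;
WM distinguished by D∥/D⊥ = 13) — they are not measured constants, and they
are exposed for override.  Note that the CSF relaxation rate lies below the
sampling box's lower edge (1 s⁻¹), as real CSF does: its recovered R2 piles
up at the box boundary, while its bin assignment (driven by Diso) is
unaffected.  Mixed voxels are fraction-weighted superpositions with S0
normalized to 1.  Default noise is Rician — the magnitude of the clean
signal plus two independent Gaussian channels of standard deviation S0/SNR —
with Gaussian and noise-free variants for linear-theory tests.  Realizations
are seeded per (seed, voxel) and independent across measurements.

What the phantoms do *not* emulate: EPI readout artifacts, motion, partial
Fourier effects, spatially correlated noise, intra-tissue parameter
dispersion, or exchange.  Passing phantom tests therefore demonstrates the
correctness of the forward model, inversion machinery and statistics on the
model's own terms, not performance on scanner data.

## Numerical choices and problem sizes

* NNLS via `scipy.optimize.nnls`; squared residuals reported.
* Direction optimization: energy descent with adaptive step, 600 iterations,
  3 restarts; deterministic given the seed.
* Test-suite and validation problem sizes: the 51-point `mini` scheme,
  ensembles of 4–16 members, and 50-voxel recovery experiments — sizes at
  which a full study (50 voxels × 16 members) completes in about half a
  minute on one core while exercising every stage of the pipeline.
* Scheme serialization uses 17 significant digits (exact double round-trip).

## Known limitations

* **Positive bias of recovered means under noise.**  Unregularized
  non-negative inversion absorbs noise into heavily weighted components at
  the fast-relaxing edge of the sampling box; weight-averaged E[R2] (and,
  less severely, E[Diso]) is therefore biased upward at realistic SNR.  At
  SNR 50 on the `mini` scheme the median bias across the box is tens of
  percent for E[R2]; it shrinks with protocol size (the 852-point protocol
  roughly halves it) and would shrink further only with echo times shorter
  than the sequence family can realize.  The same mechanism produces the
  well-known pile-up of fast-relaxing weight at the R2 box edge.  Noiseless
  recovery is accurate to 1–2%.  A dense-dictionary classical NNLS fit
  shows the same bias, confirming it is a property of the inverse problem,
  not of the stochastic search.
* Ensemble members are exchangeable repetitions, not posterior samples;
  MAD spread is an uncertainty heuristic, not a credible interval.
* Only axially symmetric b-tensors and diffusion tensors are supported;
  restricted/time-dependent diffusion is outside the model.
* Gradient waveform design, concomitant-gradient compensation, motion
  correction and scanner data handling live upstream of this package.
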