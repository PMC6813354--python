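# Methods

`poresel` analyzes cation selectivity of bacterial sodium channels from two
directions that meet in one comparison table: simulation-side free-energy
profiles along the pore axis, turned into equilibrium dissociation constants;
and experiment-side whole-cell current-voltage relations, turned into
reversal potentials and relative permeabilities. Because neither raw MD
trajectories nor patch-clamp traces are distributable here, a first-class
synthetic layer generates every input from known ground truth, which makes
each estimator testable end to end.

## The simulation-side model

### Axial free-energy landscape

The 1D potential of mean force w(z) of a single cation along the pore axis is
modelled as a sum of Gaussian wells and barriers on a finite domain
(`potentials.ModelPMF`). Construction enforces that every component has
decayed below 0.01 kcal/mol at both domain edges, so w → 0 toward the bulk on
either side; the bulk phase is then the natural zero of free energy, which is
the offset convention every downstream formula assumes. The bundled
demonstration landscape has a 3 kcal/mol binding well near z = +3 Å, a
shallower outer well, and a 2 kcal/mol intracellular entrance barrier at
−4 Å — qualitatively the shape of a cation profile through a selectivity
filter, used for demonstrations and recovery tests only.

### Biased sampling surrogate

Umbrella windows are sampled by overdamped (Euler–Maruyama) Langevin dynamics
on U(z) = w(z) + ½k(z − z_c)²:

    z_{n+1} = z_n − (D/k_BT)·U′(z_n)·dt + √(2D·dt)·ξ_n,   ξ_n ~ N(0, 1)

with reflecting boundaries at the domain edges (reflection preserves the
stationary density, which is all that matters downstream). The temperature is
315 K everywhere on the simulation side (k_BT = 0.6260 kcal/mol), stored as
one central constant.

No kinetic property of the real reaction coordinate is known, so the
diffusion coefficient is an arbitrary but fixed choice, D = 100 Å²/ns; only
equilibrium statistics are ever compared. The default timestep is
dt = 2×10⁻⁵ ns. The choice is dictated by the discretization bias of the
Euler–Maruyama scheme: for a harmonic bias the discrete stationary variance
is (k_BT/k)/(1 − a·dt/2) with a = D·k/k_BT, i.e. a relative bias of about
a·dt/2. At the standard umbrella force constant k = 10 kcal/(mol·Å²) this is
1.6% at the chosen dt, versus ~19% at dt = 10⁻⁴ ns — the latter would be
visible against the analytic variance k_BT/k at the tolerances our tests use.
Two guards reject unstable configurations before sampling: the drift per step
D·dt·max|∇U|/k_BT must stay below 0.1× the narrowest landscape feature
(evaluated over the thermally accessible region, center ± 5σ of the spring),
and dt·D·k/k_BT < 0.5 for the spring itself.

Per-window RNG streams are derived from one master seed, so a batch ladder
run is sample-for-sample identical to independent single-window runs with the
same seeds, and all generators are bit-reproducible for a fixed seed.

### Hamiltonian replica exchange

`synth.run_hremd` couples adjacent windows: every `exchange_interval` steps,
neighbor pairs (alternating even/odd pairing between attempts) attempt a
coordinate swap accepted with probability min(1, exp(−βΔ)), where Δ is the
cross-bias energy difference; the landscape term cancels. Coordinates, not
Hamiltonians, are swapped, so each output series always holds configurations
of one window's bias. On the demonstration ladder (46 windows, 0.5 Å spacing,
k = 10) the mean neighbor acceptance is ≈ 0.14, consistent with the analytic
flat-landscape estimate erfc(Δz/2σ) ≈ 0.16 for σ = √(k_BT/k) = 0.25 Å. With
exchanges disabled the run reduces exactly to independent windows (verified
sample-for-sample in the tests).

### WHAM reconstruction

`wham.solve_wham` merges the biased histograms (shared 0.1 Å grid by default,
left-closed bins, out-of-range samples counted and reported) by iterating the
standard self-consistency equations over the per-window shifts f_i in log
space until max|Δf_i| ≤ 10⁻⁷ kcal/mol — the convergence metric is expressed
in kcal/mol so the printed tolerance applies directly. Non-convergence raises
an error carrying the residual history; a histogram-overlap graph that splits
into disconnected components raises an error naming the gap, and adjacent
pairs sharing no occupied bin warn. The unbiased profile w(z) = −k_BT ln p(z)
is offset so the mean over the outermost 2 Å at the extracellular (high-z)
end of the occupied grid is zero ("bulk" convention; a "min" convention is
available). Bins never visited by any window carry NaN rather than a value.

Two diagnostics accompany every solution:

* **Relative entropy.** For each window, the KL divergence
  η_i = Σ p_i^obs ln(p_i^obs / p_i^WHAM) between the observed histogram and
  the WHAM-predicted one, with 0·ln(0/q) ≡ 0. A bin observed but predicted
  impossible makes η infinite; that is reported as a boolean flag so reports
  stay serializable. Windows with η > 0.05 are flagged for resampling. The
  diagnostic is local: truncating one window's sampling flags that window
  and leaves the others' η essentially unchanged.
* **Block-averaged uncertainty.** Each window's M samples are split into
  N = 10 contiguous blocks (trailing remainder dropped with a warning); the
  variance of the window mean is var(x̄) = Σ(x̄_n − x̄)²/(N(N−1)), and the
  profile variance accumulates along the ladder as
  var[G] = (kΔr)²·Σ var(x̄_i), anchored at zero on the bulk-end window
  (the integration-constant anchor is not prescribed anywhere; the bulk end
  is the natural choice given the bulk-zero offset).

### Binding constants

With a cylindrical lateral restraint of radius R during sampling, the
single-ion dissociation constant follows from the bulk-anchored profile:

    K_D⁻¹ = πR² ∫_{z_min}^{z_max} exp(−w(z)/k_BT) dz · N_A·10⁻²⁷

integrated by composite trapezoid on the profile grid (grid-refinement
invariance is tested: halving the bin width moves K_D by < 0.1% on smooth
profiles). The N_A·10⁻²⁷ factor converts the Å³ binding volume to M⁻¹ so K_D
carries concentration units; without it the "dissociation constant" would be
a reciprocal volume. The defining integral is sometimes printed without this
factor while defining N_A alongside — the implementation always applies it.
Profiles whose designated bulk strip sits more than 0.5 kcal/mol from zero
are rejected with advice to re-offset. ΔG = RT ln(K_D/C⁰) with C⁰ = 1 M then
gives the standard-state binding free energy; both use the simulation
temperature (315 K). Defaults R = 10 Å, z ∈ [−10, 21.5] Å are exposed, not
hard-coded (the bundled demo integrates over the span its ladder actually
sampled, z ∈ [−10, +12.5]).

## The experiment-side model

Peak current-voltage relations follow a Boltzmann-activation conductance:

    I(V) = (V − V_rev)·G_max / (1 + exp((V_half − V)/V_slope))

fitted by nonlinear least squares. Default initialization: V_rev from
sign-change interpolation (an error asks for an explicit guess when the
currents never change sign), V_half at the steepest rise of the chord
conductance, V_slope = 8 mV, G_max from the limiting slope. For weakly
permeant ions — little conductance activated near reversal — V_rev comes
instead from the instantaneous tail-current I-V after a fixed activating
pre-pulse, modelled as strictly linear (ohmic open-channel conductance over
the fitted span, weighted by per-point SE when provided); its zero crossing
and standard error come from the line-fit covariance. A tail slope
indistinguishable from zero is an error, not a number.

Measured reversal potentials are corrected by per-condition liquid-junction
offsets, E_corr = E_meas − offset; offsets are always user input (an external
junction-potential predictor's job), never computed here. Relative
permeability is the bi-ionic ratio P_X/P_Na = exp((E_X − E_Na)/(RT/F)) with
RT/F = 25.4 mV at room temperature by default (overridable; the package also
computes it from R, T, F — 25.42 mV at 295 K). Group comparisons use the
unpaired two-sided Student's t test with mean ± SEM (n) summaries and the
conventional star thresholds (p < 0.05, p < 0.001); two constant equal groups
give p = 1 by convention rather than NaN. The module is unit-agnostic for
current — every output is a ratio or a zero crossing — but enforces
consistency within a record.

**Information limit of V_rev under noise.** With the default synthetic
protocol (−80…+60 mV in 10-mV steps, a standard whole-cell step family) and
Gaussian noise at 5% of the maximal current, the Fisher information of the
four-parameter fit bounds σ(V_rev) at ≈ 1.3 mV, so the median absolute
V_rev error is ≈ 0.87 mV in expectation, and a median over 50 seeds
fluctuates roughly between 0.6 and 1.1 mV depending on the seed set. Results
near 1 mV therefore reflect the protocol's information content, not fit
quality; a 5-mV step protocol would halve the variance.

## Density maps, occupancy, and sidechain states

Position snapshots are voxelized into a number density (count per frame per
Å³); the normalization Σ density·voxel volume = mean in-grid count per frame
holds exactly at any voxel size, and out-of-bounds particles are counted and
warned about, never silently dropped. The bulk density is the mean over a
designated axial slab (default: the outermost 2 Å at the upper-z edge —
must be confirmed for real data). Voxels are classified by enrichment over
bulk: ratio ≥ e¹ ≈ 2.72 marks ≥ 1 k_BT of binding preference ("weak"),
ratio ≥ e³ ≈ 20.1 marks ≥ 3 k_BT ("strong"); strong is nested inside weak by
construction. Grids are written in OpenDX text format for standard molecular
viewers, plus a TSV summary.

Selectivity-filter occupancy is the per-frame particle count inside an axial
slab with a radial cutoff about the pore axis; the default bounds
(z ∈ [0, 8] Å, r ≤ 5 Å) are a documented convention, exposed in config,
since no geometric definition is universal. The statistic reports the mean
and population SD of the per-frame counts.

The filter glutamate's rotamer is classified from (χ1, χ2), degrees wrapped
to [0, 360): upward if χ1 ∈ [60, 180] and χ2 ∈ [0, 90]; inward-facing
("dunked") if χ1 ∈ [140, 200] and χ2 ∈ [290, 330]; otherwise "other".
Intervals are closed, so boundary hits classify deterministically, and the
χ2 windows are disjoint, which disambiguates the χ1 overlap [140, 180].

## Synthetic data: what it does and does not emulate

The generators reproduce the *statistical structure* the estimators assume:
Boltzmann-distributed biased samples at 315 K, Metropolis-coupled replicas,
I-V curves obeying the activation model with iid Gaussian noise and
tail currents pinned to the pre-pulse conductance, particle clouds from an
analytically known mixture field (Poisson frame counts, Gaussian hotspots
over a uniform bulk — expected voxel densities available in closed form),
and two-state Markov dihedral chains with wrapped-Gaussian emissions and
retained ground-truth states.

They deliberately do **not** emulate: multi-ion correlations in the filter,
force-field or finite-sampling artifacts of real MD, voltage-dependent
gating kinetics, leak/capacitance artifacts of real recordings, or any 3D
channel geometry in the 1D sampler. Passing tests therefore demonstrate
estimator correctness under the stated models — not that real data meet
those models.

## Problem sizes and numerical choices

Default demonstration sizes: 46 windows × 110,000 post-equilibration samples
(WHAM recovery RMSE ≈ 0.08–0.10 kcal/mol against the generating landscape);
histogram bin width 0.1 Å; WHAM tolerance 10⁻⁷ kcal/mol (typically ~8,500
iterations on the demo ladder); 50-seed Monte-Carlo for noisy I-V recovery;
10⁵-step dihedral chains (stationary-fraction recovery to ±0.01); 3,000-frame
particle clouds in the demo pipeline. Ties and degenerate inputs are
resolved explicitly throughout: half-open histogram bins assign
edge samples rightward, classification windows are closed, empty clouds give
zero-mean occupancy, and constant equal groups give p = 1.

## Known limitations

* The 1D single-ion treatment is an idealized effective binding profile;
  multi-ion effects and kinetic barriers are outside its scope.
* Block averaging with N = 10 assumes block length exceeds the
  autocorrelation time; no autocorrelation-time estimator is provided.
* The tail-current model is strictly linear; rectifying open-channel
  behavior would bias the zero crossing.
* The DX writer targets regular scalar grids only; no MD trajectory formats
  are read.
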