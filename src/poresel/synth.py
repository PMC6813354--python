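"""Synthetic-data generators standing in for the MD engine and the rig.

Every input the analysis pipeline consumes can be generated here from a
known ground truth: biased 1D Langevin trajectories along the pore axis
(optionally coupled by Hamiltonian replica exchange), whole-cell I-V
datasets with Gaussian noise, 3D particle clouds drawn from a specified
density field, and two-state sidechain dihedral traces. Because the
truth is known analytically, every downstream estimator (WHAM, binding
constants, I-V fits, density classification) is testable end to end.

Only equilibrium properties of the Langevin surrogate are meaningful:
no kinetic parameter of the real reaction coordinate is known, so the
diffusion coefficient is an arbitrary but documented choice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .constants import SIM_TEMPERATURE_K, kBT
from .maps import DihedralTrace, ParticleCloud
from .potentials import ModelPMF

#: Default diffusion coefficient along the axis, Å²/ns (equilibrium-only surrogate).
DEFAULT_DIFFUSION = 100.0
#: Default integrator timestep, ns. Chosen so the Euler–Maruyama stationary
#: variance bias (≈ D·k·dt / 2k_BT for a harmonic bias) stays below 2% at
#: the standard umbrella force constant of 10 kcal/(mol·Å²).
DEFAULT_TIMESTEP = 2e-5

#: Drift-per-step stability margin relative to the narrowest feature width.
DRIFT_SAFETY = 0.1
#: Harmonic stability bound on dt·D·k/k_BT.
HARMONIC_SAFETY = 0.5


@dataclass(frozen=True)
class LangevinConfig:
    """Overdamped Langevin integration settings.

    ``diffusion_coefficient`` (Å²/ns) and ``timestep`` (ns) set the
    kinetics of the surrogate; only the stationary distribution matters
    downstream. Samples before ``equilibration_steps`` are discarded.
    """

    n_steps: int
    equilibration_steps: int = 20_000
    diffusion_coefficient: float = DEFAULT_DIFFUSION
    timestep: float = DEFAULT_TIMESTEP
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_steps <= self.equilibration_steps:
            raise ValueError(
                f"n_steps ({self.n_steps}) must exceed equilibration_steps "
                f"({self.equilibration_steps})")
        if self.equilibration_steps < 0:
            raise ValueError("equilibration_steps must be non-negative")
        if self.timestep <= 0 or self.diffusion_coefficient <= 0:
            raise ValueError("timestep and diffusion_coefficient must be positive")


@dataclass
class WindowSeries:
    """Biased samples from one umbrella window.

    ``samples`` are post-equilibration z positions (Å) under the total
    potential w(z) + ½k(z − center)².
    """

    window_id: int
    center: float
    force_constant: float
    samples: np.ndarray
    timestep: float
    seed: int

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).reshape(-1)
        if self.force_constant < 0:
            raise ValueError("force_constant must be non-negative")
        if len(self.samples) == 0:
            raise ValueError("a window must hold at least one sample")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")


@dataclass
class ExchangeLog:
    """Neighbor-swap bookkeeping from a replica-exchange run."""

    attempts: np.ndarray  # per neighbor pair (i, i+1)
    accepts: np.ndarray

    @property
    def acceptance_rates(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.attempts > 0, self.accepts / self.attempts, np.nan)

    @property
    def mean_acceptance(self) -> float:
        rates = self.acceptance_rates
        return float(np.nanmean(rates)) if np.isfinite(rates).any() else float("nan")


def ladder_seeds(master_seed: int, n: int) -> list[int]:
    """Deterministic per-window seeds derived from one master seed."""
    return [int(s) for s in
            np.random.SeedSequence(master_seed).generate_state(n) % (2**31)]


def _check_stability(pmf: ModelPMF, center: float, force_constant: float,
                     cfg: LangevinConfig) -> None:
    """Reject configurations whose drift per step is not small.

    Enforces D·dt·max|∇U|/k_BT < 0.1 · (narrowest feature width), with
    the gradient taken over the thermally accessible region: for a biased
    window, center ± 5σ of the spring (σ = sqrt(k_BT/k)); unbiased, the
    whole domain. A harmonic-stability guard dt·D·k/k_BT < 0.5 is applied
    as well.
    """
    kT = kBT(pmf.temperature)
    D, dt = cfg.diffusion_coefficient, cfg.timestep
    lo, hi = pmf.domain
    if force_constant > 0:
        if dt * D * force_constant / kT >= HARMONIC_SAFETY:
            raise ValueError(
                f"timestep {dt} ns is unstable for force constant "
                f"{force_constant} kcal/(mol·Å²): dt·D·k/k_BT = "
                f"{dt * D * force_constant / kT:.3g} ≥ {HARMONIC_SAFETY}")
        sigma = math.sqrt(kT / force_constant)
        bias_grad = force_constant * 5.0 * sigma
    else:
        bias_grad = 0.0
    z = np.linspace(lo, hi, 2048)
    pmf_grad = float(np.abs(np.asarray(pmf.gradient(z))).max())
    max_drift = D * dt * (pmf_grad + bias_grad) / kT
    width = pmf.min_feature_width
    if max_drift >= DRIFT_SAFETY * width:
        raise ValueError(
            f"drift per step {max_drift:.3g} Å exceeds {DRIFT_SAFETY} × the "
            f"narrowest feature width ({width:.3g} Å); reduce the timestep")


def _integrate_batch(
    pmf: ModelPMF,
    centers: np.ndarray,
    force_constants: np.ndarray,
    cfg: LangevinConfig,
    seeds: list[int],
    exchange_interval: int | None = None,
    exchange_seed: int | None = None,
) -> tuple[np.ndarray, ExchangeLog | None]:
    """Euler–Maruyama integration of a batch of walkers, one per window.

    Each walker has its own RNG stream, so a batch run with no exchanges
    is sample-for-sample identical to independent single-window runs with
    the same seeds. Reflecting boundaries at the domain edges preserve
    the stationary density. When ``exchange_interval`` is set, adjacent
    walkers attempt coordinate swaps under the Metropolis criterion with
    alternating even/odd pairing; swapping coordinates (not Hamiltonians)
    keeps row i of the output holding configurations of Hamiltonian i.
    """
    n_rep = len(centers)
    kT = kBT(pmf.temperature)
    D, dt = cfg.diffusion_coefficient, cfg.timestep
    lo, hi = pmf.domain
    noise_scale = math.sqrt(2.0 * D * dt)
    mobility = D / kT

    rngs = [np.random.default_rng(s) for s in seeds]
    z = np.array(centers, dtype=float).clip(lo, hi)
    traj = np.empty((n_rep, cfg.n_steps))

    do_exchange = exchange_interval is not None and np.isfinite(exchange_interval)
    if do_exchange and exchange_interval < 1:
        raise ValueError("exchange_interval must be ≥ 1")
    ex_rng = np.random.default_rng(exchange_seed) if do_exchange else None
    attempts = np.zeros(max(n_rep - 1, 0))
    accepts = np.zeros(max(n_rep - 1, 0))
    attempt_no = 0

    chunk = int(exchange_interval) if do_exchange else 10_000
    step = 0
    while step < cfg.n_steps:
        m = min(chunk, cfg.n_steps - step)
        noise = np.stack([rng.standard_normal(m) for rng in rngs])
        for j in range(m):
            grad = np.asarray(pmf.gradient(z)) + force_constants * (z - centers)
            z = z - mobility * grad * dt + noise_scale * noise[:, j]
            # reflecting boundaries (fold back into the domain)
            z = np.where(z < lo, 2 * lo - z, z)
            z = np.where(z > hi, 2 * hi - z, z)
            z = z.clip(lo, hi)
            traj[:, step + j] = z
        step += m
        if do_exchange and step < cfg.n_steps and n_rep > 1:
            start = attempt_no % 2
            for i in range(start, n_rep - 1, 2):
                bias = force_constants
                d_before = (0.5 * bias[i] * (z[i] - centers[i]) ** 2
                            + 0.5 * bias[i + 1] * (z[i + 1] - centers[i + 1]) ** 2)
                d_after = (0.5 * bias[i] * (z[i + 1] - centers[i]) ** 2
                           + 0.5 * bias[i + 1] * (z[i] - centers[i + 1]) ** 2)
                delta = (d_after - d_before) / kT
                attempts[i] += 1
                u = ex_rng.random()
                if delta <= 0 or u < math.exp(-delta):
                    accepts[i] += 1
                    z[i], z[i + 1] = z[i + 1], z[i]
            attempt_no += 1

    log = ExchangeLog(attempts=attempts, accepts=accepts) if do_exchange else None
    return traj[:, cfg.equilibration_steps:], log


def sample_window(pmf: ModelPMF, center: float, force_constant: float,
                  cfg: LangevinConfig, window_id: int = 0) -> WindowSeries:
    """Sample one umbrella window by overdamped Langevin dynamics.

    The walker moves on U(z) = w(z) + ½k(z − center)² with reflecting
    boundaries at the domain edges; only post-equilibration samples are
    returned. Raises a configuration error if the drift per step is not
    small against the narrowest landscape feature.
    """
    if not pmf.contains(center):
        raise ValueError(f"window center {center} outside domain {pmf.domain}")
    if force_constant < 0:
        raise ValueError("force_constant must be non-negative")
    _check_stability(pmf, center, force_constant, cfg)
    traj, _ = _integrate_batch(
        pmf, np.array([center]), np.array([float(force_constant)]), cfg,
        seeds=[cfg.seed])
    return WindowSeries(window_id=window_id, center=center,
                        force_constant=force_constant, samples=traj[0],
                        timestep=cfg.timestep, seed=cfg.seed)


def sample_ladder(pmf: ModelPMF, centers, force_constant: float,
                  cfg: LangevinConfig) -> list[WindowSeries]:
    """Independent umbrella-window runs for a whole ladder (vectorized)."""
    centers = np.asarray(centers, dtype=float)
    seeds = ladder_seeds(cfg.seed, len(centers))
    for c in centers:
        if not pmf.contains(c):
            raise ValueError(f"window center {c} outside domain {pmf.domain}")
    _check_stability(pmf, float(centers[0]), force_constant, cfg)
    traj, _ = _integrate_batch(
        pmf, centers, np.full(len(centers), float(force_constant)), cfg, seeds)
    return [
        WindowSeries(window_id=i, center=float(centers[i]),
                     force_constant=force_constant, samples=traj[i],
                     timestep=cfg.timestep, seed=seeds[i])
        for i in range(len(centers))
    ]


def run_hremd(pmf: ModelPMF, centers, force_constant: float, cfg: LangevinConfig,
              exchange_interval: int = 1000) -> tuple[list[WindowSeries], ExchangeLog]:
    """Hamiltonian replica exchange across an umbrella ladder.

    Adjacent replicas attempt coordinate swaps every ``exchange_interval``
    steps with probability min(1, exp(−βΔ)), Δ being the cross-bias energy
    difference; pairing alternates between even and odd neighbor pairs.
    Each returned :class:`WindowSeries` holds the configurations sampled
    under one Hamiltonian (one window's bias), and the log reports the
    per-pair acceptance rate.
    """
    centers = np.asarray(centers, dtype=float)
    if len(centers) > 1 and not (np.all(np.diff(centers) >= 0)
                                 or np.all(np.diff(centers) <= 0)):
        raise ValueError("window centers must be sorted by position")
    if exchange_interval < 1:
        raise ValueError("exchange_interval must be ≥ 1")
    for c in centers:
        if not pmf.contains(c):
            raise ValueError(f"window center {c} outside domain {pmf.domain}")
    _check_stability(pmf, float(centers[0]), force_constant, cfg)
    seeds = ladder_seeds(cfg.seed, len(centers))
    traj, log = _integrate_batch(
        pmf, centers, np.full(len(centers), float(force_constant)), cfg, seeds,
        exchange_interval=exchange_interval,
        exchange_seed=int(np.random.SeedSequence([cfg.seed, 0xE]).generate_state(1)[0]))
    series = [
        WindowSeries(window_id=i, center=float(centers[i]),
                     force_constant=force_constant, samples=traj[i],
                     timestep=cfg.timestep, seed=seeds[i])
        for i in range(len(centers))
    ]
    return series, log


# --------------------------------------------------------------------------
# Whole-cell I-V data

@dataclass(frozen=True)
class SyntheticIVTruth:
    """Ground-truth parameters of a Boltzmann-activation I-V relation.

    I(V) = (V − V_rev) · G_max / (1 + exp((V_half − V)/V_slope)), with
    iid Gaussian noise of SD ``noise_sd`` added per point. Instantaneous
    tail currents follow G_tail·(V − V_rev) with G_tail fixed at the
    conductance activated by the pre-pulse.
    """

    V_rev: float
    G_max: float
    V_half: float
    V_slope: float
    voltages: tuple[float, ...]
    noise_sd: float = 0.0
    pre_pulse_mV: float = -10.0
    seed: int = 0
    condition: str = "Na"

    def __post_init__(self) -> None:
        if self.V_slope == 0:
            raise ValueError("V_slope must be nonzero")
        if self.G_max < 0:
            raise ValueError("G_max must be non-negative")
        if len(self.voltages) == 0:
            raise ValueError("voltages must be non-empty")
        object.__setattr__(self, "voltages", tuple(float(v) for v in self.voltages))

    def current(self, v) -> np.ndarray:
        v = np.asarray(v, dtype=float)
        return (v - self.V_rev) * self.G_max / (
            1.0 + np.exp((self.V_half - v) / self.V_slope))

    @property
    def tail_conductance(self) -> float:
        return self.G_max / (
            1.0 + math.exp((self.V_half - self.pre_pulse_mV) / self.V_slope))


def generate_iv(truth: SyntheticIVTruth):
    """Draw one synthetic I-V record (peak + instantaneous tails) from truth."""
    from .ephys import IVRecord

    rng = np.random.default_rng(truth.seed)
    v = np.array(sorted(truth.voltages), dtype=float)
    peak = truth.current(v) + (
        rng.normal(0.0, truth.noise_sd, size=len(v)) if truth.noise_sd > 0 else 0.0)
    tails = truth.tail_conductance * (v - truth.V_rev) + (
        rng.normal(0.0, truth.noise_sd, size=len(v)) if truth.noise_sd > 0 else 0.0)
    return IVRecord(condition=truth.condition, voltages=v,
                    peak_currents=peak, tail_currents=tails)


# --------------------------------------------------------------------------
# 3D particle clouds

@dataclass(frozen=True)
class Hotspot:
    """Isotropic Gaussian binding hotspot of a density field."""

    center: tuple[float, float, float]
    sigma: float
    weight: float

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("hotspot sigma must be positive")
        if self.weight < 0:
            raise ValueError("hotspot weight must be non-negative")


@dataclass(frozen=True)
class DensityFieldSpec:
    """Mixture density: Gaussian hotspots plus a uniform bulk in a box.

    Hotspot weights plus ``bulk_weight`` must sum to 1; the expected
    number density at any point is then analytically available, which
    makes the iso-level classifier fully testable.
    """

    box_lo: tuple[float, float, float]
    box_hi: tuple[float, float, float]
    hotspots: tuple[Hotspot, ...] = ()
    bulk_weight: float = 1.0
    mean_particles_per_frame: float = 2.0

    def __post_init__(self) -> None:
        lo, hi = np.array(self.box_lo, float), np.array(self.box_hi, float)
        if not np.all(hi > lo):
            raise ValueError(f"empty domain: box_lo={self.box_lo}, box_hi={self.box_hi}")
        total = self.bulk_weight + sum(h.weight for h in self.hotspots)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"hotspot weights + bulk weight must sum to 1, got {total}")
        if self.mean_particles_per_frame < 0:
            raise ValueError("mean_particles_per_frame must be non-negative")
        object.__setattr__(self, "hotspots", tuple(self.hotspots))

    @property
    def box_volume(self) -> float:
        lo, hi = np.array(self.box_lo, float), np.array(self.box_hi, float)
        return float(np.prod(hi - lo))


def generate_particles(spec: DensityFieldSpec, n_frames: int, seed: int = 0) -> ParticleCloud:
    """Draw seeded particle snapshots from a mixture density field.

    Per-frame counts are Poisson around the specified mean; each particle
    lands in the bulk (uniform over the box) or in one hotspot (isotropic
    Gaussian, re-drawn if it falls outside the box, which is negligible
    for hotspots a few σ inside the edges).
    """
    if n_frames < 0:
        raise ValueError("n_frames must be non-negative")
    rng = np.random.default_rng(seed)
    counts = rng.poisson(spec.mean_particles_per_frame, size=n_frames)
    n_total = int(counts.sum())
    frame_index = np.repeat(np.arange(n_frames), counts)
    lo = np.array(spec.box_lo, float)
    hi = np.array(spec.box_hi, float)

    weights = [spec.bulk_weight] + [h.weight for h in spec.hotspots]
    comp = rng.choice(len(weights), size=n_total, p=weights)
    positions = np.empty((n_total, 3))
    bulk_mask = comp == 0
    positions[bulk_mask] = rng.uniform(lo, hi, size=(int(bulk_mask.sum()), 3))
    for k, hot in enumerate(spec.hotspots, start=1):
        mask = comp == k
        n_k = int(mask.sum())
        pts = rng.normal(hot.center, hot.sigma, size=(n_k, 3))
        bad = np.any((pts < lo) | (pts > hi), axis=1)
        while bad.any():
            pts[bad] = rng.normal(hot.center, hot.sigma, size=(int(bad.sum()), 3))
            bad = np.any((pts < lo) | (pts > hi), axis=1)
        positions[mask] = pts
    return ParticleCloud(positions=positions, frame_index=frame_index,
                         n_frames=n_frames)


def expected_density(spec: DensityFieldSpec,
                     edges: tuple[np.ndarray, np.ndarray, np.ndarray]) -> np.ndarray:
    """Analytic voxel-averaged expected density (particles/Å³) of a field.

    Integrates the mixture density exactly over each voxel (products of
    1D Gaussian CDF differences) — the ground-truth field the sampled
    grids converge to.
    """
    from scipy.stats import norm

    voxel_vol = float(np.prod([e[1] - e[0] for e in edges]))
    shape = tuple(len(e) - 1 for e in edges)
    mean = spec.mean_particles_per_frame
    dens = np.full(shape, mean * spec.bulk_weight / spec.box_volume)
    for hot in spec.hotspots:
        probs = []
        for ax in range(3):
            e = edges[ax]
            cdf = norm.cdf(e, loc=hot.center[ax], scale=hot.sigma)
            probs.append(np.diff(cdf))
        mass = probs[0][:, None, None] * probs[1][None, :, None] * probs[2][None, None, :]
        dens = dens + mean * hot.weight * mass / voxel_vol
    return dens


# --------------------------------------------------------------------------
# Two-state dihedral traces

@dataclass(frozen=True)
class DihedralChainSpec:
    """Two-state Markov chain emitting (χ1, χ2) dihedral pairs.

    States are the upward and dunked rotamers of the filter glutamate;
    emissions are wrapped Gaussians around each state's mean angles.
    ``p_up_to_dunked`` / ``p_dunked_to_up`` are per-step transition
    probabilities; the stationary dunked probability is their ratio
    p_ud / (p_ud + p_du).
    """

    up_mean: tuple[float, float] = (120.0, 45.0)
    dunked_mean: tuple[float, float] = (170.0, 310.0)
    emission_sd: float = 8.0
    p_up_to_dunked: float = 0.02
    p_dunked_to_up: float = 0.08
    start_state: str = "up"

    def __post_init__(self) -> None:
        for p in (self.p_up_to_dunked, self.p_dunked_to_up):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"transition probability {p} outside [0, 1]")
        if self.emission_sd < 0:
            raise ValueError("emission_sd must be non-negative")
        if self.start_state not in ("up", "dunked"):
            raise ValueError("start_state must be 'up' or 'dunked'")

    @property
    def stationary_dunked(self) -> float:
        total = self.p_up_to_dunked + self.p_dunked_to_up
        if total == 0:
            return 1.0 if self.start_state == "dunked" else 0.0
        return self.p_up_to_dunked / total


def generate_dihedrals(spec: DihedralChainSpec, n_steps: int, seed: int = 0) -> DihedralTrace:
    """Simulate the two-state chain and emit wrapped (χ1, χ2) angles.

    The ground-truth state sequence is retained on the trace so
    classifiers can be scored against it exactly.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be positive")
    rng = np.random.default_rng(seed)
    u = rng.random(n_steps)
    states = np.empty(n_steps, dtype=np.int8)  # 0 = up, 1 = dunked
    s = 0 if spec.start_state == "up" else 1
    for t in range(n_steps):
        p_leave = spec.p_up_to_dunked if s == 0 else spec.p_dunked_to_up
        if u[t] < p_leave:
            s = 1 - s
        states[t] = s
    means = np.array([spec.up_mean, spec.dunked_mean])
    mu = means[states]
    if spec.emission_sd > 0:
        angles = mu + rng.normal(0.0, spec.emission_sd, size=(n_steps, 2))
    else:
        angles = mu.astype(float)
    true_labels = np.where(states == 1, "dunked", "up").astype(object)
    return DihedralTrace(chi1=angles[:, 0] % 360.0, chi2=angles[:, 1] % 360.0,
                         true_states=true_labels)
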