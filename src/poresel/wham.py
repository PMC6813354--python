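"""Umbrella-window placement and WHAM free-energy reconstruction.

Biased samples from a ladder of harmonically restrained windows are
histogrammed on a shared axial grid and merged into one unbiased
profile w(z) by the weighted histogram analysis method: the per-window
free-energy shifts f_i are iterated to self-consistency

    p(z_l) ∝ Σ_i n_il / Σ_j N_j exp(−(u_j(z_l) − f_j)/k_BT),
    f_j = −k_BT ln Σ_l p(z_l) exp(−u_j(z_l)/k_BT),

until the largest change in any f_i falls below a tolerance in
kcal/mol (default 1e-7). The profile is offset so the bulk region sits
at zero free energy. Convergence is checked per window by the relative
entropy between observed and WHAM-predicted histograms, and the
statistical uncertainty of the profile is propagated from block-averaged
variances of the window means.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .constants import SIM_TEMPERATURE_K, kBT
from .synth import WindowSeries

logger = logging.getLogger(__name__)

#: Default WHAM self-consistency tolerance on the f_i shifts, kcal/mol.
DEFAULT_TOLERANCE = 1e-7
#: Default histogram bin width along z, Å.
DEFAULT_BIN_WIDTH = 0.1
#: Width of the bulk strip (at the extracellular end) used for the zero offset, Å.
BULK_STRIP_WIDTH = 2.0
#: Relative-entropy threshold above which a window is flagged.
DEFAULT_ETA_THRESHOLD = 0.05


@dataclass(frozen=True)
class WindowLadder:
    """An arithmetic ladder of umbrella-window centers.

    Centers may run in either direction (the experimental protocol lists
    them from the extracellular side inward) but must be strictly
    monotone with uniform spacing.
    """

    centers: tuple[float, ...]
    force_constant: float
    spacing: float

    def __post_init__(self) -> None:
        c = np.asarray(self.centers, dtype=float)
        if len(c) == 0:
            raise ValueError("ladder must contain at least one window")
        if self.force_constant < 0:
            raise ValueError("force_constant must be non-negative")
        if len(c) > 1:
            d = np.diff(c)
            if not (np.all(d > 0) or np.all(d < 0)):
                raise ValueError("centers must be strictly monotone")
            if not np.allclose(np.abs(d), self.spacing, rtol=0, atol=1e-9):
                raise ValueError("spacing must equal |difference| of consecutive centers")
        object.__setattr__(self, "centers", tuple(float(x) for x in c))

    def __len__(self) -> int:
        return len(self.centers)


@dataclass
class BiasedHistogramSet:
    """Per-window histograms of biased samples on one shared bin grid.

    Bins are left-closed, right-open. Samples falling outside the grid
    are tallied in ``n_out_of_range`` per window, never silently dropped.
    """

    bin_edges: np.ndarray
    counts: np.ndarray  # (n_windows, n_bins) integers
    n_samples: np.ndarray  # per-window totals including out-of-range
    n_out_of_range: np.ndarray

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.asarray(self.counts)
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        in_range = self.counts.sum(axis=1) + self.n_out_of_range
        if not np.array_equal(in_range, self.n_samples):
            raise ValueError("per-window counts must sum to n_samples")

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def n_windows(self) -> int:
        return self.counts.shape[0]


@dataclass
class PMFProfile:
    """Gridded free-energy profile w(z) with pointwise variance.

    ``w`` is in kcal/mol on the bin centers ``z``; bins with no samples
    anywhere carry NaN. The offset convention records how the zero of
    free energy was chosen.
    """

    z: np.ndarray
    w: np.ndarray
    var_w: np.ndarray
    offset_convention: str
    temperature: float = SIM_TEMPERATURE_K

    def occupied(self) -> np.ndarray:
        return np.isfinite(self.w)

    def interp(self, z: np.ndarray | float) -> np.ndarray | float:
        """Linear interpolation of w over occupied bins."""
        mask = self.occupied()
        return np.interp(z, self.z[mask], self.w[mask])


@dataclass
class ConvergenceReport:
    """Per-window sampling diagnostics of a converged WHAM solution."""

    eta: np.ndarray
    eta_infinite: np.ndarray  # bool flags: observed support missing from prediction
    flagged_windows: list[int]
    wham_iterations: int
    final_residual: float
    predicted_histograms: np.ndarray | None = None


class WhamConvergenceError(RuntimeError):
    """WHAM failed to reach the tolerance; carries the residual history."""

    def __init__(self, message: str, residuals: np.ndarray):
        super().__init__(message)
        self.residuals = residuals


def place_windows(z_start: float, z_end: float, spacing: float,
                  force_constant: float) -> WindowLadder:
    """Lay out an inclusive arithmetic ladder of umbrella windows.

    The span must be an integer multiple of the spacing (to 1e-9);
    otherwise an error is raised rather than silently truncating the
    ladder. Example: +12.5 to −10 Å at 0.5 Å spacing gives 46 windows.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if z_start == z_end:
        raise ValueError("z_start and z_end must differ")
    span = abs(z_end - z_start)
    n_intervals = span / spacing
    if abs(n_intervals - round(n_intervals)) > 1e-9:
        raise ValueError(
            f"span |{z_start} − {z_end}| = {span} Å is not an integer multiple "
            f"of the spacing {spacing} Å; adjust the endpoints or spacing")
    n = int(round(n_intervals)) + 1
    direction = 1.0 if z_end > z_start else -1.0
    centers = tuple(z_start + direction * spacing * i for i in range(n))
    return WindowLadder(centers=centers, force_constant=force_constant,
                        spacing=spacing)


def build_histograms(series: list[WindowSeries], bin_width: float,
                     z_range: tuple[float, float]) -> BiasedHistogramSet:
    """Histogram every window's samples on one shared half-open bin grid."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if not series:
        raise ValueError("need at least one window series")
    lo, hi = z_range
    if hi <= lo:
        raise ValueError("empty z range")
    n_bins = max(1, int(round((hi - lo) / bin_width)))
    edges = np.linspace(lo, lo + n_bins * bin_width, n_bins + 1)

    counts = np.zeros((len(series), n_bins), dtype=np.int64)
    totals = np.zeros(len(series), dtype=np.int64)
    out = np.zeros(len(series), dtype=np.int64)
    for i, s in enumerate(series):
        x = s.samples
        totals[i] = len(x)
        # np.digitize with right=False gives the left-closed convention
        idx = np.floor((x - lo) / bin_width).astype(np.int64)
        in_range = (idx >= 0) & (idx < n_bins) & (x < edges[-1]) & (x >= lo)
        out[i] = int((~in_range).sum())
        if out[i]:
            logger.warning("window %d: %d of %d samples outside histogram range",
                           s.window_id, out[i], totals[i])
        counts[i] = np.bincount(idx[in_range], minlength=n_bins)
    return BiasedHistogramSet(bin_edges=edges, counts=counts,
                              n_samples=totals, n_out_of_range=out)


def _bias_matrix(centers: np.ndarray, force_constant: float,
                 z: np.ndarray) -> np.ndarray:
    """Harmonic bias energies u_i(z_l), shape (n_windows, n_bins)."""
    return 0.5 * force_constant * (z[None, :] - centers[:, None]) ** 2


def _check_overlap(counts: np.ndarray, order: np.ndarray) -> None:
    occ = counts > 0
    for a, b in zip(order[:-1], order[1:]):
        if not np.any(occ[a] & occ[b]):
            warnings.warn(
                f"adjacent windows {a} and {b} share no occupied bin; "
                "the ladder may be disconnected there", stacklevel=3)


def _connected(counts: np.ndarray) -> None:
    """Raise if the window-overlap graph splits into disconnected groups."""
    occ = counts > 0
    n = counts.shape[0]
    seen = np.zeros(n, dtype=bool)
    stack = [0]
    seen[0] = True
    while stack:
        i = stack.pop()
        for j in range(n):
            if not seen[j] and np.any(occ[i] & occ[j]):
                seen[j] = True
                stack.append(j)
    if not seen.all():
        gap = int(np.argmin(seen))
        raise ValueError(
            f"histogram overlap graph is disconnected: window {gap} shares "
            "no occupied bins with the component containing window 0")


def solve_wham(
    hists: BiasedHistogramSet,
    ladder: WindowLadder,
    temperature: float = SIM_TEMPERATURE_K,
    tolerance: float = DEFAULT_TOLERANCE,
    max_iterations: int = 100_000,
    offset: str = "bulk",
    bulk_strip: tuple[float, float] | None = None,
    eta_threshold: float = DEFAULT_ETA_THRESHOLD,
) -> tuple[PMFProfile, ConvergenceReport]:
    """Reconstruct the unbiased PMF from biased window histograms.

    Iterates the WHAM self-consistency equations over the per-window
    shifts f_i until max|Δf_i| ≤ ``tolerance`` (kcal/mol). The unbiased
    probability gives w(z) = −k_BT ln p(z), offset per convention:
    ``"bulk"`` zeroes the mean of w over the outermost 2 Å at the
    high-z (extracellular) end of the occupied grid (or an explicit
    ``bulk_strip``), ``"min"`` zeroes the global minimum.

    Returns the profile together with a convergence report holding the
    per-window relative entropies and WHAM-predicted histograms.
    """
    if len(ladder) != hists.n_windows:
        raise ValueError("ladder and histogram set disagree on window count")
    order = np.argsort(ladder.centers)
    _check_overlap(hists.counts, order)
    _connected(hists.counts)

    kT = kBT(temperature)
    z = hists.bin_centers
    centers = np.asarray(ladder.centers, dtype=float)
    u = _bias_matrix(centers, ladder.force_constant, z)  # (W, B)
    n_il = hists.counts.astype(float)
    N_i = n_il.sum(axis=1)  # in-range totals
    total_counts = n_il.sum(axis=0)
    occupied = total_counts > 0

    log_bias = -u / kT  # (W, B)
    log_Ni = np.log(np.where(N_i > 0, N_i, 1.0))
    f = np.zeros(len(centers))  # shifts in kcal/mol
    residuals = []
    log_numer = np.log(np.where(occupied, total_counts, 1.0))

    for it in range(1, max_iterations + 1):
        # log denominator_l = logsumexp_i [ log N_i + (f_i − u_il)/kT ]
        log_den = logsumexp(log_Ni[:, None] + (f[:, None] / kT) + log_bias, axis=0)
        log_p = np.where(occupied, log_numer - log_den, -np.inf)
        # normalize p over the grid (constant shift; keeps numbers tame)
        log_p -= logsumexp(log_p[occupied])
        f_new = -kT * logsumexp(log_p[None, :] + log_bias, axis=1)
        f_new -= f_new[0]
        resid = float(np.max(np.abs(f_new - f)))
        residuals.append(resid)
        f = f_new
        if resid <= tolerance:
            break
    else:
        raise WhamConvergenceError(
            f"WHAM did not reach tolerance {tolerance} kcal/mol in "
            f"{max_iterations} iterations (last residual {residuals[-1]:.3g})",
            residuals=np.asarray(residuals))

    log_den = logsumexp(log_Ni[:, None] + (f[:, None] / kT) + log_bias, axis=0)
    log_p = np.where(occupied, log_numer - log_den, -np.inf)
    log_p -= logsumexp(log_p[occupied])

    w = np.where(occupied, -kT * log_p, np.nan)

    if offset == "bulk":
        if bulk_strip is None:
            occ_z = z[occupied]
            hi = occ_z.max()
            bulk_strip = (hi - BULK_STRIP_WIDTH, hi)
        strip = occupied & (z >= bulk_strip[0]) & (z <= bulk_strip[1])
        if not strip.any():
            raise ValueError(f"bulk strip {bulk_strip} holds no occupied bins")
        w = w - np.nanmean(w[strip])
        convention = (f"mean of w over bulk strip z ∈ [{bulk_strip[0]:.3g}, "
                      f"{bulk_strip[1]:.3g}] Å set to 0")
    elif offset == "min":
        w = w - np.nanmin(w)
        convention = "global minimum set to 0"
    else:
        raise ValueError(f"unknown offset convention {offset!r}")

    # WHAM-predicted per-window histograms for the relative-entropy check
    log_pred = log_p[None, :] + log_bias  # unnormalized per window
    log_pred_norm = logsumexp(np.where(occupied[None, :], log_pred, -np.inf), axis=1)
    pred = np.exp(log_pred - log_pred_norm[:, None])
    pred[:, ~occupied] = 0.0

    obs = np.where(n_il.sum(axis=1, keepdims=True) > 0,
                   n_il / np.maximum(n_il.sum(axis=1, keepdims=True), 1), 0.0)
    eta, inf_flags = relative_entropy(obs, pred)
    flagged = sorted(set(np.nonzero(inf_flags)[0].tolist())
                     | set(np.nonzero(eta > eta_threshold)[0].tolist()))

    profile = PMFProfile(z=z, w=w, var_w=np.zeros_like(w),
                         offset_convention=convention, temperature=temperature)
    report = ConvergenceReport(eta=eta, eta_infinite=inf_flags,
                               flagged_windows=flagged,
                               wham_iterations=it, final_residual=resid,
                               predicted_histograms=pred)
    return profile, report


def relative_entropy(obs: np.ndarray, pred: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Per-window KL divergence between observed and predicted histograms.

    Both inputs are (n_windows, n_bins) probability vectors on the same
    grid. Terms with observed probability 0 contribute 0; a bin with
    observed > 0 but predicted = 0 makes the divergence infinite, which
    is reported as a boolean flag (eta itself is set over the supported
    bins only, keeping the report serializable).
    """
    obs = np.atleast_2d(np.asarray(obs, dtype=float))
    pred = np.atleast_2d(np.asarray(pred, dtype=float))
    if obs.shape != pred.shape:
        raise ValueError(f"shape mismatch: obs {obs.shape} vs pred {pred.shape}")
    eta = np.zeros(obs.shape[0])
    inf_flags = np.zeros(obs.shape[0], dtype=bool)
    for i in range(obs.shape[0]):
        o, q = obs[i], pred[i]
        support = o > 0
        bad = support & (q <= 0)
        if bad.any():
            inf_flags[i] = True
            support = support & (q > 0)
        eta[i] = float(np.sum(o[support] * np.log(o[support] / q[support])))
    return eta, inf_flags


def block_variance(samples: np.ndarray, n_blocks: int = 10) -> float:
    """Variance of the window mean by block averaging.

    The series of M samples is split into N contiguous blocks of size
    B = M // N (trailing remainder dropped with a warning); the block
    means x̄_n give

        var(x̄) = 1/(N(N−1)) Σ_n (x̄_n − x̄)².
    """
    x = np.asarray(samples, dtype=float).reshape(-1)
    if n_blocks < 2:
        raise ValueError("need at least 2 blocks")
    if len(x) < n_blocks:
        raise ValueError(f"need at least {n_blocks} samples, got {len(x)}")
    B = len(x) // n_blocks
    dropped = len(x) - n_blocks * B
    if dropped:
        logger.warning("block_variance: dropping %d trailing samples "
                       "(M=%d not divisible by N=%d)", dropped, len(x), n_blocks)
        x = x[: n_blocks * B]
    block_means = x.reshape(n_blocks, B).mean(axis=1)
    grand = block_means.mean()
    return float(np.sum((block_means - grand) ** 2) / (n_blocks * (n_blocks - 1)))


def propagate_pmf_variance(window_mean_variances: np.ndarray,
                           force_constant: float, spacing: float) -> np.ndarray:
    """Cumulative PMF variance along the ladder from window-mean variances.

    var[G(x_m)] = (kΔr)² · Σ_{i≤m} var(x̄_i), anchored at zero variance
    on the first (bulk-end) window; the input must be ordered from the
    anchor outward. Returns one value per window position.
    """
    v = np.asarray(window_mean_variances, dtype=float).reshape(-1)
    if len(v) == 0:
        raise ValueError("need at least one window variance")
    if np.any(v < 0):
        raise ValueError("variances must be non-negative")
    prefactor = (force_constant * spacing) ** 2
    out = np.empty(len(v))
    out[0] = 0.0
    if len(v) > 1:
        out[1:] = prefactor * np.cumsum(v[1:])
    return out


def pmf_variance_profile(profile: PMFProfile, series: list[WindowSeries],
                         ladder: WindowLadder, n_blocks: int = 10,
                         anchor: str = "bulk") -> PMFProfile:
    """Attach block-averaged uncertainty to a PMF profile.

    Window-mean variances come from :func:`block_variance`; they are
    accumulated along the ladder starting from the bulk-end (highest-z)
    window and interpolated onto the profile grid.
    """
    if len(series) != len(ladder):
        raise ValueError(
            f"{len(series)} window series for a {len(ladder)}-window ladder")
    centers = np.asarray(ladder.centers, dtype=float)
    var_means = np.array([block_variance(s.samples, n_blocks) for s in series])
    order = np.argsort(centers)
    if anchor == "bulk":
        order = order[::-1]  # start from the extracellular (high-z) end
    var_g = propagate_pmf_variance(var_means[order], ladder.force_constant,
                                   ladder.spacing)
    c_sorted = centers[order]
    idx = np.argsort(c_sorted)
    var_on_grid = np.interp(profile.z, c_sorted[idx], var_g[idx])
    var_on_grid[~profile.occupied()] = np.nan
    return PMFProfile(z=profile.z, w=profile.w, var_w=var_on_grid,
                      offset_convention=profile.offset_convention,
                      temperature=profile.temperature)
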