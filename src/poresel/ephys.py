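"""Whole-cell I-V analysis: reversal potentials and relative permeability.

Peak current-voltage relations are fitted with a Boltzmann-activation
conductance model

    I(V) = (V − V_rev) · G_max / (1 + exp((V_half − V)/V_slope)),

where V_rev is the reversal potential, G_max the maximal conductance,
V_half the half-activation potential and V_slope the slope factor
(mV per e-fold). For weakly permeant ions, where little conductance is
activated near reversal, V_rev is instead read from the instantaneous
tail-current I-V after a fixed activating pre-pulse, which is linear in
voltage. Measured reversal potentials are corrected by user-supplied
liquid-junction offsets (an external predictor's job, not this
module's), and the bi-ionic permeability ratio follows from the
corrected reversal shift:

    P_X / P_Na = exp((E_X − E_Na) / (RT/F)),   RT/F ≈ 25.4 mV at room T.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .constants import THERMAL_MV_ROOM

logger = logging.getLogger(__name__)


@dataclass
class IVRecord:
    """One condition's current-voltage data (units consistent per record)."""

    condition: str
    voltages: np.ndarray
    peak_currents: np.ndarray
    tail_currents: np.ndarray | None = None
    junction_offset: float = 0.0
    n_cells: int = 1

    def __post_init__(self) -> None:
        self.voltages = np.asarray(self.voltages, dtype=float).reshape(-1)
        self.peak_currents = np.asarray(self.peak_currents, dtype=float).reshape(-1)
        if len(self.voltages) != len(self.peak_currents):
            raise ValueError("voltages and peak_currents lengths differ")
        if np.any(np.diff(self.voltages) <= 0):
            raise ValueError("voltages must be strictly increasing")
        if not np.all(np.isfinite(self.peak_currents)):
            raise ValueError("currents must be finite")
        if self.tail_currents is not None:
            self.tail_currents = np.asarray(self.tail_currents, dtype=float).reshape(-1)
            if len(self.tail_currents) != len(self.voltages):
                raise ValueError("tail_currents length differs from voltages")
            if not np.all(np.isfinite(self.tail_currents)):
                raise ValueError("currents must be finite")


@dataclass
class IVFit:
    """Fitted Boltzmann-activation I-V parameters with uncertainty."""

    V_rev: float
    G_max: float
    V_half: float
    V_slope: float
    covariance: np.ndarray
    rms_residual: float

    def __post_init__(self) -> None:
        self.covariance = np.asarray(self.covariance, dtype=float)
        if self.covariance.shape != (4, 4):
            raise ValueError("covariance must be 4×4")

    def current(self, v) -> np.ndarray:
        return boltzmann_iv(np.asarray(v, dtype=float),
                            self.V_rev, self.G_max, self.V_half, self.V_slope)


@dataclass(frozen=True)
class PermeabilityResult:
    """Relative permeability P_X/P_Na of one species vs the sodium reference."""

    species: str
    P_ratio: float
    sem: float
    n: int
    E_X: float
    E_Na: float

    def __post_init__(self) -> None:
        if self.P_ratio <= 0:
            raise ValueError("P_ratio must be positive")
        if self.n < 1:
            raise ValueError("n must be at least 1")


def boltzmann_iv(v: np.ndarray, V_rev: float, G_max: float,
                 V_half: float, V_slope: float) -> np.ndarray:
    """Boltzmann-activation current model."""
    with np.errstate(over="ignore"):  # saturates to zero current; harmless
        return (v - V_rev) * G_max / (1.0 + np.exp((V_half - v) / V_slope))


def _initial_guess(v: np.ndarray, i: np.ndarray) -> tuple[float, float, float, float]:
    """Default initialization: V_rev by sign-change interpolation, V_half at
    the steepest rise, V_slope = 8 mV, G_max from the limiting slope."""
    sign_change = np.nonzero(np.diff(np.sign(i)) != 0)[0]
    if len(sign_change) == 0:
        raise ValueError(
            "peak currents never change sign; supply an explicit initial "
            "guess or use the tail-current protocol for weakly permeant ions")
    k = sign_change[-1]
    v_rev0 = v[k] - i[k] * (v[k + 1] - v[k]) / (i[k + 1] - i[k])
    # chord conductance relative to the estimated reversal; its steepest
    # rise sits near the half-activation voltage
    safe = np.abs(v - v_rev0) > 1e-6
    g = np.zeros_like(i)
    g[safe] = i[safe] / (v[safe] - v_rev0)
    dg = np.gradient(g, v)
    v_half0 = float(v[np.argmax(dg)])
    # limiting slope: conductance once activation saturates (last points)
    tail_pts = max(2, len(v) // 4)
    g_max0 = float(np.polyfit(v[-tail_pts:], i[-tail_pts:], 1)[0])
    if g_max0 <= 0:
        g_max0 = max(np.abs(np.gradient(i, v)).max(), 1e-6)
    return float(v_rev0), g_max0, v_half0, 8.0


def fit_iv(record: IVRecord,
           init: tuple[float, float, float, float] | None = None) -> IVFit:
    """Nonlinear least-squares fit of the Boltzmann-activation I-V model.

    Requires ≥5 voltage points spanning both sides of the apparent
    reversal (or an explicit ``init`` when the currents never change
    sign). Returns parameters, their covariance and the RMS residual.
    """
    v, i = record.voltages, record.peak_currents
    if len(v) < 5:
        raise ValueError("need at least 5 voltage points to fit the I-V model")
    p0 = init if init is not None else _initial_guess(v, i)
    try:
        popt, pcov = optimize.curve_fit(
            boltzmann_iv, v, i, p0=p0, maxfev=20_000)
    except RuntimeError as err:
        resid0 = i - boltzmann_iv(v, *p0)
        raise RuntimeError(
            f"I-V fit did not converge from init {p0}; initial RMS residual "
            f"{float(np.sqrt(np.mean(resid0**2))):.4g}") from err
    resid = i - boltzmann_iv(v, *popt)
    return IVFit(V_rev=float(popt[0]), G_max=float(popt[1]),
                 V_half=float(popt[2]), V_slope=float(popt[3]),
                 covariance=pcov,
                 rms_residual=float(np.sqrt(np.mean(resid**2))))


def reversal_from_tails(record: IVRecord,
                        weights: np.ndarray | None = None) -> tuple[float, float]:
    """Reversal potential from the instantaneous tail-current I-V.

    Fits a straight line G·(V − E_rev) to the tail currents (weighted by
    1/SE² when per-point standard errors are given) and returns the zero
    crossing with its standard error. Requires ≥3 tail points that
    bracket the zero crossing.
    """
    if record.tail_currents is None:
        raise ValueError("record has no tail currents")
    v, i = record.voltages, record.tail_currents
    if len(v) < 3:
        raise ValueError("need tail currents at ≥3 voltages")
    if not (i.min() < 0 < i.max()):
        raise ValueError(
            "tail currents do not bracket zero; apply a pre-pulse protocol "
            "covering voltages on both sides of the reversal potential")
    w = None if weights is None else 1.0 / np.asarray(weights, dtype=float) ** 2
    coeffs, cov = np.polyfit(v, i, 1, w=w, cov=True)
    slope, intercept = coeffs
    if abs(slope) < 1e-12 or abs(slope) < 3 * math.sqrt(cov[0, 0]):
        raise ValueError(
            "tail-current slope indistinguishable from zero; no measurable "
            "open-channel conductance in this record")
    e_rev = -intercept / slope
    # delta method on E = −b/a
    grad = np.array([intercept / slope**2, -1.0 / slope])
    se = float(np.sqrt(grad @ cov @ grad))
    return float(e_rev), se


def apply_junction_correction(E_measured: float, offset: float) -> float:
    """Correct a measured reversal potential by a liquid-junction offset.

    The offset is supplied per condition from an external junction-
    potential predictor; E_corrected = E_measured − offset.
    """
    corrected = E_measured - offset
    logger.info("junction correction: %.6g mV − (%.6g mV) = %.6g mV",
                E_measured, offset, corrected)
    return corrected


def relative_permeability(E_X: float, E_Na: float,
                          thermal_mV: float = THERMAL_MV_ROOM) -> float:
    """Bi-ionic permeability ratio from junction-corrected reversals.

    P_X/P_Na = exp((E_X − E_Na) / (RT/F)); both potentials in mV and
    already junction-corrected.
    """
    if thermal_mV <= 0:
        raise ValueError("thermal_mV must be positive")
    return math.exp((E_X - E_Na) / thermal_mV)


def permeability_result(species: str, E_X_cells: np.ndarray, E_Na: float,
                        thermal_mV: float = THERMAL_MV_ROOM) -> PermeabilityResult:
    """Per-cell permeability ratios summarized as mean ± SEM (n)."""
    e_x = np.asarray(E_X_cells, dtype=float).reshape(-1)
    ratios = np.exp((e_x - E_Na) / thermal_mV)
    n = len(ratios)
    sem = float(ratios.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0
    return PermeabilityResult(species=species, P_ratio=float(ratios.mean()),
                              sem=sem, n=n, E_X=float(e_x.mean()), E_Na=E_Na)


def significance_stars(p: float) -> str:
    """Stars per the conventional reporting thresholds (<0.05, <0.001)."""
    if p < 0.001:
        return "***"
    if p < 0.05:
        return "*"
    return "ns"


def compare_conditions(group_a: np.ndarray, group_b: np.ndarray) -> dict:
    """Unpaired two-sided Student's t test between per-cell values.

    Returns the t statistic, p value, per-group mean ± SEM (n) and the
    significance stars. Two zero-variance groups with equal means give
    p = 1 by convention (logged) rather than NaN.
    """
    a = np.asarray(group_a, dtype=float).reshape(-1)
    b = np.asarray(group_b, dtype=float).reshape(-1)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 values per group")

    def _summary(x):
        return {"mean": float(x.mean()),
                "sem": float(x.std(ddof=1) / math.sqrt(len(x))),
                "n": len(x)}

    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            logger.info("both groups constant and equal; p = 1 by convention")
            t_stat, p = 0.0, 1.0
        else:
            t_stat, p = math.inf, 0.0
    else:
        res = stats.ttest_ind(a, b, equal_var=True)
        t_stat, p = float(res.statistic), float(res.pvalue)
    return {"t": t_stat, "p": p, "stars": significance_stars(p),
            "group_a": _summary(a), "group_b": _summary(b)}
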