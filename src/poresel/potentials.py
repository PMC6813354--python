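"""Parametric 1D model potentials along the pore axis.

A :class:`ModelPMF` is a sum of Gaussian wells (negative amplitude) and
barriers (positive amplitude) on a finite axial domain. It stands in for
the free-energy profile w(z) an ion experiences along the channel axis:
the profile decays to zero at both bulk ends, so the bulk phase is the
natural zero of free energy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constants import SIM_TEMPERATURE_K

#: Maximum |contribution| any component may have at a domain edge (kcal/mol).
EDGE_TOLERANCE_KCAL = 0.01


@dataclass(frozen=True)
class GaussianComponent:
    """One Gaussian feature of the axial free-energy landscape.

    ``amplitude`` is signed: negative for a binding well, positive for a
    barrier, in kcal/mol. ``width`` is the Gaussian sigma in Å.
    """

    center: float
    amplitude: float
    width: float

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError(f"component width must be positive, got {self.width}")

    def __call__(self, z: np.ndarray | float) -> np.ndarray | float:
        z = np.asarray(z, dtype=float)
        return self.amplitude * np.exp(-((z - self.center) ** 2) / (2.0 * self.width**2))

    def gradient(self, z: np.ndarray | float) -> np.ndarray | float:
        z = np.asarray(z, dtype=float)
        return self(z) * (-(z - self.center) / self.width**2)


@dataclass(frozen=True)
class ModelPMF:
    """Ground-truth 1D potential of mean force w(z) on a finite domain.

    Parameters
    ----------
    components
        Gaussian wells/barriers making up the landscape.
    domain
        ``(z_lo, z_hi)`` in Å. Every component must have decayed to
        |contribution| < 0.01 kcal/mol at both edges, so w(z) → 0 toward
        the bulk on either side.
    temperature
        Temperature in K at which the landscape is sampled.
    """

    components: tuple[GaussianComponent, ...]
    domain: tuple[float, float]
    temperature: float = SIM_TEMPERATURE_K

    def __post_init__(self) -> None:
        z_lo, z_hi = self.domain
        if not z_lo < z_hi:
            raise ValueError(f"domain must satisfy z_lo < z_hi, got {self.domain}")
        if self.temperature <= 0:
            raise ValueError(f"temperature must be positive, got {self.temperature}")
        object.__setattr__(self, "components", tuple(self.components))
        for comp in self.components:
            for edge in self.domain:
                contrib = abs(float(comp(edge)))
                if contrib >= EDGE_TOLERANCE_KCAL:
                    raise ValueError(
                        f"component at {comp.center} Å (width {comp.width} Å) "
                        f"contributes {contrib:.3g} kcal/mol at domain edge "
                        f"{edge} Å; the profile must vanish toward the bulk"
                    )

    @property
    def min_feature_width(self) -> float:
        """Narrowest component width; the domain span for a flat landscape."""
        if not self.components:
            return self.domain[1] - self.domain[0]
        return min(c.width for c in self.components)

    def __call__(self, z: np.ndarray | float) -> np.ndarray | float:
        z = np.asarray(z, dtype=float)
        w = np.zeros_like(z)
        for comp in self.components:
            w = w + comp(z)
        return w if w.ndim else float(w)

    def gradient(self, z: np.ndarray | float) -> np.ndarray | float:
        z = np.asarray(z, dtype=float)
        g = np.zeros_like(z)
        for comp in self.components:
            g = g + comp.gradient(z)
        return g if g.ndim else float(g)

    def contains(self, z: float) -> bool:
        return self.domain[0] <= z <= self.domain[1]


def flat_pmf(domain: tuple[float, float] = (-12.0, 14.5),
             temperature: float = SIM_TEMPERATURE_K) -> ModelPMF:
    """A featureless landscape (w ≡ 0), useful as a null model."""
    return ModelPMF(components=(), domain=domain, temperature=temperature)


def demo_two_well_pmf(temperature: float = SIM_TEMPERATURE_K) -> ModelPMF:
    """Bundled demonstration landscape for end-to-end runs.

    A main binding well near +3 Å (3 kcal/mol deep), a shallower outer
    well, and an intracellular entrance barrier (2 kcal/mol at −4 Å) —
    loosely shaped like a cation PMF through a sodium-channel selectivity
    filter. The shape is illustrative only; nothing downstream asserts it
    against any published profile.
    """
    return ModelPMF(
        components=(
            GaussianComponent(center=3.0, amplitude=-3.0, width=1.0),
            GaussianComponent(center=7.5, amplitude=-1.0, width=1.5),
            GaussianComponent(center=-4.0, amplitude=2.0, width=1.2),
        ),
        domain=(-12.0, 15.0),
        temperature=temperature,
    )


def boltzmann_density(pmf: ModelPMF, z_grid: np.ndarray) -> np.ndarray:
    """Normalized stationary density exp(−w/k_BT) on ``z_grid``.

    Normalization is by the trapezoid rule over the grid, so the result
    integrates to 1 on the grid's span.
    """
    from .constants import kBT

    w = np.asarray(pmf(z_grid), dtype=float)
    p = np.exp(-(w - w.min()) / kBT(pmf.temperature))
    norm = np.trapezoid(p, z_grid)
    return p / norm


def boltzmann_cdf(pmf: ModelPMF, n_grid: int = 4001):
    """Callable CDF of the stationary law of ``pmf`` over its domain.

    Built by cumulative trapezoid integration on a fine grid; serves as
    an independent oracle for sampled trajectories.
    """
    from scipy.integrate import cumulative_trapezoid

    z = np.linspace(pmf.domain[0], pmf.domain[1], n_grid)
    p = boltzmann_density(pmf, z)
    cdf = cumulative_trapezoid(p, z, initial=0.0)
    cdf /= cdf[-1]

    def _cdf(x):
        return np.interp(x, z, cdf)

    return _cdf


def stationary_variance(pmf: ModelPMF, force_constant: float, center: float,
                        n_grid: int = 8001) -> float:
    """Exact variance of z under the biased Boltzmann law.

    Direct numerical Boltzmann integral of the total potential
    w(z) + ½k(z−z_c)²; the analytic oracle for biased-window sampling.
    """
    from .constants import kBT

    z = np.linspace(pmf.domain[0], pmf.domain[1], n_grid)
    u = np.asarray(pmf(z), dtype=float) + 0.5 * force_constant * (z - center) ** 2
    p = np.exp(-(u - u.min()) / kBT(pmf.temperature))
    p /= np.trapezoid(p, z)
    mean = np.trapezoid(z * p, z)
    return float(np.trapezoid((z - mean) ** 2 * p, z))
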