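"""Equilibrium binding constants and free energies from 1D PMFs.

Under a cylindrical lateral restraint of radius R, the single-ion
dissociation constant follows from the axial free-energy profile w(z)
(offset to zero in the bulk):

    K_D⁻¹ = πR² ∫_{z_min}^{z_max} exp(−w(z)/k_BT) dz,

with the integral in Å³ converted to M⁻¹ through N_A·10⁻²⁷ L/Å³ so that
K_D carries concentration units. The standard-state binding free energy
is ΔG = RT ln(K_D / C⁰) with C⁰ = 1 M. Note the volume-to-molar
conversion: the printed form of the defining integral leaves N_A
implicit while defining it in the text; it is applied explicitly here,
otherwise K_D would be a reciprocal volume.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .constants import (ANGSTROM3_TO_PER_MOLAR, R_KCAL, SIM_TEMPERATURE_K, kBT)
from .wham import PMFProfile

#: |w| allowed over the designated bulk strip before refusing to integrate.
BULK_ANCHOR_TOLERANCE = 0.5


@dataclass(frozen=True)
class CylinderSpec:
    """Cylindrical restraint geometry used during the window sampling.

    ``radius`` in Å; the binding integral runs over z ∈ [z_min, z_max].
    Defaults follow the standard protocol for this channel family:
    R = 10 Å, z from −10 to +21.5 Å.
    """

    radius: float = 10.0
    z_min: float = -10.0
    z_max: float = 21.5

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.z_max <= self.z_min:
            raise ValueError("z_max must exceed z_min")

    @property
    def cross_section(self) -> float:
        return math.pi * self.radius**2


@dataclass(frozen=True)
class BindingResult:
    """K_D (mol/L) and standard-state ΔG (kcal/mol) for one species."""

    species: str
    K_D: float
    delta_G: float
    temperature: float
    cylinder: CylinderSpec

    def __post_init__(self) -> None:
        if self.K_D <= 0:
            raise ValueError("K_D must be positive")
        expected = R_KCAL * self.temperature * math.log(self.K_D)
        if abs(expected - self.delta_G) > 1e-9:
            raise ValueError(
                f"delta_G {self.delta_G} inconsistent with RT·ln(K_D): {expected}")


def compute_kd(pmf: PMFProfile, cyl: CylinderSpec | None = None,
               bulk_strip_width: float = 2.0) -> float:
    """Dissociation constant (mol/L) from a bulk-anchored 1D PMF.

    Composite-trapezoid integration of exp(−w/k_BT) over [z_min, z_max]
    on the profile's grid; the πR²·∫ volume in Å³ is converted to M⁻¹.
    The profile must already be offset to zero in the bulk: if |w|
    averaged over the outermost ``bulk_strip_width`` Å at the z_max end
    exceeds 0.5 kcal/mol, the profile is rejected with advice to
    re-offset.
    """
    cyl = cyl or CylinderSpec()
    occ = pmf.occupied()
    z_occ = pmf.z[occ]
    if len(z_occ) < 2:
        raise ValueError("PMF has fewer than two occupied bins")
    if z_occ.min() > cyl.z_min + 1e-9 or z_occ.max() < cyl.z_max - 1e-9:
        raise ValueError(
            f"PMF grid [{z_occ.min():.3g}, {z_occ.max():.3g}] Å does not cover "
            f"the integration range [{cyl.z_min}, {cyl.z_max}] Å")

    strip = occ & (pmf.z >= z_occ.max() - bulk_strip_width)
    bulk_level = float(np.nanmean(pmf.w[strip]))
    if abs(bulk_level) > BULK_ANCHOR_TOLERANCE:
        raise ValueError(
            f"PMF is not bulk-anchored: mean w over the outer "
            f"{bulk_strip_width} Å is {bulk_level:.3g} kcal/mol; re-offset the "
            "profile so the bulk sits at zero before computing K_D")

    mask = occ & (pmf.z >= cyl.z_min) & (pmf.z <= cyl.z_max)
    z = pmf.z[mask]
    integrand = np.exp(-pmf.w[mask] / kBT(pmf.temperature))
    # extend to the exact bounds by linear interpolation of w
    if z[0] > cyl.z_min:
        w_lo = pmf.interp(cyl.z_min)
        z = np.concatenate([[cyl.z_min], z])
        integrand = np.concatenate([[math.exp(-w_lo / kBT(pmf.temperature))], integrand])
    if z[-1] < cyl.z_max:
        w_hi = pmf.interp(cyl.z_max)
        z = np.concatenate([z, [cyl.z_max]])
        integrand = np.concatenate([integrand, [math.exp(-w_hi / kBT(pmf.temperature))]])

    volume_A3 = cyl.cross_section * float(np.trapezoid(integrand, z))
    kd_inv_per_molar = volume_A3 * ANGSTROM3_TO_PER_MOLAR
    return 1.0 / kd_inv_per_molar


def binding_free_energy(K_D: float, temperature: float = SIM_TEMPERATURE_K) -> float:
    """Standard-state binding free energy ΔG = RT·ln(K_D / 1 M), kcal/mol."""
    if K_D <= 0:
        raise ValueError("K_D must be positive")
    return R_KCAL * temperature * math.log(K_D)


def binding_result(pmf: PMFProfile, species: str,
                   cyl: CylinderSpec | None = None) -> BindingResult:
    """Convenience wrapper: K_D and ΔG for one species from its PMF."""
    cyl = cyl or CylinderSpec()
    kd = compute_kd(pmf, cyl)
    return BindingResult(species=species, K_D=kd,
                         delta_G=binding_free_energy(kd, pmf.temperature),
                         temperature=pmf.temperature, cylinder=cyl)


def species_table(binding_results: list[BindingResult],
                  permeabilities: list | None = None):
    """Join binding and permeability results into one comparison table.

    Returns a pandas DataFrame indexed by species with K_D, ΔG and
    P_X/P_Na columns, plus the Spearman rank correlation between K_D and
    permeability over species present in both inputs (NaN/"undefined"
    when fewer than two pairs exist). Missing pairs stay blank; nothing
    is imputed.
    """
    import pandas as pd
    from scipy.stats import spearmanr

    labels = [r.species for r in binding_results]
    if len(set(labels)) != len(labels):
        dupes = sorted({s for s in labels if labels.count(s) > 1})
        raise ValueError(f"duplicate species labels: {dupes}")
    rows = {r.species: {"K_D_molar": r.K_D, "delta_G_kcal_mol": r.delta_G}
            for r in binding_results}

    if permeabilities:
        perm_labels = [p.species for p in permeabilities]
        if len(set(perm_labels)) != len(perm_labels):
            dupes = sorted({s for s in perm_labels if perm_labels.count(s) > 1})
            raise ValueError(f"duplicate species labels: {dupes}")
        for p in permeabilities:
            rows.setdefault(p.species, {})["P_ratio"] = p.P_ratio

    table = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    table.index.name = "species"
    if "P_ratio" not in table.columns:
        table["P_ratio"] = np.nan

    paired = table.dropna(subset=["K_D_molar", "P_ratio"])
    if len(paired) >= 2:
        rho = float(spearmanr(paired["K_D_molar"], paired["P_ratio"]).statistic)
    else:
        rho = float("nan")
    table.attrs["spearman_kd_vs_permeability"] = rho
    return table
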