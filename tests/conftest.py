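"""Shared fixtures: demo umbrella-ladder sampling and an independent WHAM oracle."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.special import logsumexp

from poresel import synth, wham
from poresel.constants import kBT
from poresel.potentials import demo_two_well_pmf


@pytest.fixture(scope="session")
def demo_ladder_run():
    """46-window umbrella run on the bundled two-well landscape.

    k = 10 kcal/(mol·Å²), 0.5 Å spacing from +12.5 to −10 Å, 110k
    post-equilibration samples per window — shared across WHAM tests.
    """
    pmf = demo_two_well_pmf()
    ladder = wham.place_windows(12.5, -10.0, 0.5, 10.0)
    cfg = synth.LangevinConfig(n_steps=130_000, equilibration_steps=20_000, seed=7)
    series = synth.sample_ladder(pmf, ladder.centers, ladder.force_constant, cfg)
    return pmf, ladder, series


@pytest.fixture(scope="session")
def demo_wham_solution(demo_ladder_run):
    """Converged WHAM profile + report for the shared demo run."""
    pmf, ladder, series = demo_ladder_run
    hists = wham.build_histograms(series, 0.1, (-12.0, 14.5))
    profile, report = wham.solve_wham(hists, ladder)
    return pmf, ladder, series, hists, profile, report


def wham_oracle(hists, ladder, temperature=315.0):
    """Independent WHAM reference: direct minimization of the convex
    negative log-likelihood over the window shifts (BFGS with analytic
    gradient), a different algorithm from the package's self-consistent
    iteration. Returns w(z) (unoffset) on occupied bins, NaN elsewhere.
    """
    kT = kBT(temperature)
    z = hists.bin_centers
    centers = np.asarray(ladder.centers)
    u = 0.5 * ladder.force_constant * (z[None, :] - centers[:, None]) ** 2
    n_il = hists.counts.astype(float)
    N_i = n_il.sum(axis=1)
    M_l = n_il.sum(axis=0)
    occ = M_l > 0
    logN = np.log(np.where(N_i > 0, N_i, 1.0))

    def objective(g):
        # g = f/kT with g[0] fixed at 0
        f = np.concatenate([[0.0], g])
        a = logN[:, None] + f[:, None] - u / kT  # (W, B)
        lse = logsumexp(a[:, occ], axis=0)
        val = float(np.sum(M_l[occ] * lse) - np.sum(N_i * f))
        wgt = np.exp(a[:, occ] - lse[None, :])  # softmax over windows
        grad_full = wgt @ M_l[occ] - N_i
        return val, grad_full[1:]

    res = minimize(objective, np.zeros(len(centers) - 1), jac=True,
                   method="BFGS", options={"gtol": 1e-10, "maxiter": 2000})
    f = np.concatenate([[0.0], res.x])
    a = logN[:, None] + f[:, None] - u / kT
    log_p = np.where(occ, np.log(np.where(occ, M_l, 1.0)) - logsumexp(a, axis=0),
                     -np.inf)
    w = np.where(occ, -kT * log_p, np.nan)
    return z, w
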