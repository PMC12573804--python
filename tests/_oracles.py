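"""Independent oracles used only by tests.

The multistate-reweighting (MBAR-style) estimator here is a binless
self-consistent solver operating directly on per-sample reduced bias
energies — an entirely different computational path from the production
histogram-WHAM solver, used to cross-check it on small experiments. It is
deliberately simple (direct iteration, dense matrices) and never stands in
for the production estimator.
"""
from __future__ import annotations

import numpy as np
from scipy.special import logsumexp

from zwitterphase.constants import kbt_kj_per_mol
from zwitterphase.datatypes import UmbrellaWindow


def mbar_pmf(
    windows: list[UmbrellaWindow],
    edges: np.ndarray,
    temperature: float = 300.0,
    tol: float = 1e-10,
    max_iter: int = 100_000,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Binless multistate reweighting, then binning of the unbiased weights.

    Returns (centers, f_kbt, counts_total): the PMF on the bin centers in
    kBT (NaN on empty bins, minimum-shifted to 0 over populated bins) and
    the raw per-bin pooled counts.
    """
    kbt = kbt_kj_per_mol(temperature)
    z_all = np.concatenate([w.series for w in windows])
    n_i = np.array([w.n_samples for w in windows], dtype=float)
    # reduced bias of every sample in every window's potential
    u = np.stack([
        (0.5 * w.k_z * (z_all - w.center) ** 2 + w.bias_offset) / kbt
        for w in windows
    ])  # (W, N)
    f = np.zeros(len(windows))
    log_n = np.log(n_i)
    for _ in range(max_iter):
        log_denom = logsumexp(log_n[:, None] + f[:, None] - u, axis=0)  # (N,)
        f_new = -logsumexp(-u - log_denom[None, :], axis=1)
        f_new -= f_new[0]
        delta = np.max(np.abs(f_new - f))
        f = f_new
        if delta < tol:
            break
    else:
        raise RuntimeError(f"MBAR oracle did not converge (delta={delta:.2e})")
    log_w = -log_denom
    log_w -= logsumexp(log_w)
    # bin the unbiased sample weights onto the shared grid
    idx = np.digitize(z_all, edges) - 1
    nbins = edges.size - 1
    inside = (idx >= 0) & (idx < nbins)
    p = np.bincount(idx[inside], weights=np.exp(log_w[inside]), minlength=nbins)
    counts = np.bincount(idx[inside], minlength=nbins)
    with np.errstate(divide="ignore"):
        f_z = np.where(counts > 0, -np.log(np.where(counts > 0, p, 1.0)), np.nan)
    f_z -= np.nanmin(f_z)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, f_z, counts


def brute_force_two_state_delta_f(labels, weights, state_a, state_b) -> float:
    """-ln(p_b / p_a) from ground-truth labels and normalised frame weights."""
    p_a = float(weights[labels == state_a].sum())
    p_b = float(weights[labels == state_b].sum())
    return -np.log(p_b / p_a)
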