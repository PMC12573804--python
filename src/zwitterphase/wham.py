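"""Weighted histogram analysis method (WHAM) with Bayesian-bootstrap errors.

Per-window biased samples along the COM separation z are histogrammed on a
shared grid and combined self-consistently into an unbiased probability
p(z_b) and per-window alignment constants F_i:

    p(z_b) = sum_i n_i(z_b) / sum_i N_i exp[(F_i - V_i(z_b)) / kBT]
    F_i    = -kBT ln sum_b p(z_b) exp[-V_i(z_b) / kBT]

iterated until max_i |dF_i| < tol. The PMF is F(z) = -kBT ln p(z), shifted
so that its mean over the dissociated reference window is zero. Errors come
from a Bayesian bootstrap that treats whole window trajectories as the
exchangeable units: each replicate re-solves WHAM with flat-Dirichlet
weights applied to the window histograms, and the per-bin standard error is
the standard deviation across the ensemble.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import DEFAULT_TEMPERATURE_K, kbt_kj_per_mol
from .datatypes import UmbrellaWindow, check_unique_centers
from .errors import ConvergenceError, DataCoverageError

#: Default dissociated reference interval (nm) used to zero the PMF.
DEFAULT_REF_WINDOW: tuple[float, float] = (1.75, 2.25)


def bias_energy(z, window: UmbrellaWindow):
    """Harmonic restraint energy ½ k_z (z - z0)² (+ gauge offset), kJ/mol."""
    z = np.asarray(z, dtype=float)
    out = 0.5 * window.k_z * (z - window.center) ** 2 + window.bias_offset
    return out if out.ndim else float(out)


@dataclass
class HistogramSet:
    """Per-window counts on shared bin edges along z."""

    edges: np.ndarray          # (B+1,) nm
    counts: np.ndarray         # (W, B)
    n_i: np.ndarray            # (W,) retained samples per window

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.edges[1] - self.edges[0])


@dataclass
class PMFProfile:
    """Free-energy profile F(z) in kBT with alignment constants and errors.

    ``mask`` flags bins with zero total count (never interpolated); ``f`` is
    NaN there. ``f_i`` are the per-window alignment constants in kBT, on the
    gauge fixed by the normalisation of p. ``ensemble`` (B, nbins), when
    present, holds the Bayesian-bootstrap members, each individually
    normalised by the same reference rule, and ``se`` their per-bin standard
    deviation.
    """

    z: np.ndarray
    f: np.ndarray
    mask: np.ndarray
    f_i: np.ndarray
    n_iter: int
    delta_history: np.ndarray
    bin_width: float
    ref_window: tuple[float, float] | None
    ensemble: np.ndarray | None = None
    se: np.ndarray | None = None

    @property
    def converged_delta(self) -> float:
        return float(self.delta_history[-1])


def build_histograms(windows: list[UmbrellaWindow], bin_width: float) -> HistogramSet:
    """Histogram all window series on shared edges.

    Edges are multiples of ``bin_width`` spanning the pooled sample range
    padded by one bin on each side, so totals are conserved exactly and the
    grid is deterministic in the data.
    """
    if not windows:
        raise ValueError("need at least one umbrella window")
    if bin_width <= 0:
        raise ValueError(f"bin_width must be positive, got {bin_width}")
    for w in windows:
        if w.n_samples == 0:
            raise ValueError(f"window {w.index} has an empty series")
    check_unique_centers(windows)
    zmin = min(float(w.series.min()) for w in windows)
    zmax = max(float(w.series.max()) for w in windows)
    lo = (np.floor(zmin / bin_width) - 1.0) * bin_width
    hi = (np.ceil(zmax / bin_width) + 1.0) * bin_width
    nbins = int(round((hi - lo) / bin_width))
    edges = lo + bin_width * np.arange(nbins + 1)
    counts = np.stack([np.histogram(w.series, bins=edges)[0] for w in windows])
    return HistogramSet(edges=edges, counts=counts.astype(float),
                        n_i=counts.sum(axis=1).astype(float))


def _normalize(f_z: np.ndarray, centers: np.ndarray, mask: np.ndarray,
               ref_window: tuple[float, float] | None) -> np.ndarray:
    """Shift F so the reference-window mean (or, lacking one, the minimum) is 0."""
    ok = ~mask
    if ref_window is None:
        return f_z - np.nanmin(f_z[ok])
    lo, hi = ref_window
    in_ref = ok & (centers >= lo) & (centers <= hi)
    if not np.any(in_ref):
        raise DataCoverageError(
            f"reference window {ref_window} contains no populated bins"
        )
    return f_z - np.mean(f_z[in_ref])


def solve_wham(
    hists: HistogramSet,
    windows: list[UmbrellaWindow],
    temperature: float = DEFAULT_TEMPERATURE_K,
    tol: float = 1e-6,
    max_iter: int = 100_000,
    ref_window: tuple[float, float] | None = DEFAULT_REF_WINDOW,
    initial_f: np.ndarray | None = None,
    _weighted: tuple[np.ndarray, np.ndarray] | None = None,
) -> PMFProfile:
    """Self-consistent WHAM solution of a histogram set.

    ``tol`` is on max_i |dF_i| in kBT between successive iterations.
    ``initial_f`` warm-starts the alignment constants (used by the
    bootstrap). ``_weighted`` optionally substitutes (counts, n_i) with
    bootstrap-weighted versions while keeping the zero-count mask of the
    raw data.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    if len(windows) != hists.counts.shape[0]:
        raise ValueError("window list does not match histogram set")
    kbt = kbt_kj_per_mol(temperature)
    centers = hists.centers
    counts, n_i = (hists.counts, hists.n_i) if _weighted is None else _weighted
    total = counts.sum(axis=0)
    populated = hists.counts.sum(axis=0) > 0
    if not np.any(populated):
        raise ValueError("all histogram bins are empty")

    v = np.stack([bias_energy(centers, w) for w in windows]) / kbt  # (W, B)
    v -= v.min()                       # gauge shift for exp() range only
    expmv = np.exp(-np.minimum(v, 700.0))
    f = np.zeros(len(windows)) if initial_f is None else np.array(initial_f, float)

    deltas = []
    p = np.zeros_like(total)
    for _ in range(max_iter):
        denom = (n_i * np.exp(f)) @ expmv
        np.divide(total, denom, out=p, where=populated & (denom > 0))
        p[~populated] = 0.0
        p /= p.sum()
        z_i = expmv @ p
        f_new = -np.log(z_i)
        delta = float(np.max(np.abs(f_new - f)))
        f = f_new
        deltas.append(delta)
        if delta < tol:
            break
    else:
        raise ConvergenceError(
            f"WHAM did not converge in {max_iter} iterations "
            f"(last max|dF_i| = {deltas[-1]:.3e} kBT)",
            residual=deltas[-1],
        )

    with np.errstate(divide="ignore"):
        f_z = np.where(populated, -np.log(np.where(populated, p, 1.0)), np.nan)
    mask = ~populated
    f_z = _normalize(f_z, centers, mask, ref_window)
    return PMFProfile(
        z=centers, f=f_z, mask=mask, f_i=f, n_iter=len(deltas),
        delta_history=np.asarray(deltas), bin_width=hists.bin_width,
        ref_window=ref_window,
    )


def bootstrap_pmf(
    windows: list[UmbrellaWindow],
    bin_width: float = 0.01,
    replicates: int = 50,
    seed: int = 0,
    temperature: float = DEFAULT_TEMPERATURE_K,
    tol: float = 1e-6,
    max_iter: int = 100_000,
    ref_window: tuple[float, float] | None = DEFAULT_REF_WINDOW,
) -> PMFProfile:
    """WHAM solution plus a Bayesian-bootstrap ensemble and per-bin SE.

    Window trajectories are the exchangeable units: each of the
    ``replicates`` members re-solves WHAM with the window histograms scaled
    by flat-Dirichlet weights (times the window count, so the expected
    weight is 1). Frame-level resampling would understate the error of
    autocorrelated series. Every member obeys the same reference-window
    normalisation as the central estimate.
    """
    if replicates < 2:
        raise ValueError(f"need at least 2 bootstrap replicates, got {replicates}")
    hists = build_histograms(windows, bin_width)
    base = solve_wham(hists, windows, temperature=temperature, tol=tol,
                      max_iter=max_iter, ref_window=ref_window)
    rng = np.random.default_rng(seed)
    n_win = len(windows)
    members = np.empty((replicates, hists.centers.size))
    failures = 0
    for b in range(replicates):
        g = rng.dirichlet(np.ones(n_win)) * n_win
        try:
            sol = solve_wham(
                hists, windows, temperature=temperature, tol=tol,
                max_iter=max_iter, ref_window=ref_window, initial_f=base.f_i,
                _weighted=(hists.counts * g[:, None], hists.n_i * g),
            )
            members[b] = sol.f
        except ConvergenceError:
            members[b] = np.nan
            failures += 1
    if failures > replicates // 2:
        raise ConvergenceError(
            f"{failures}/{replicates} bootstrap replicates failed to converge"
        )
    se = np.full(members.shape[1], np.nan)
    ok = ~base.mask
    se[ok] = np.nanstd(members[:, ok], axis=0, ddof=1)
    base.ensemble = members
    base.se = se
    return base
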