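"""Reweighted conformational analysis of umbrella-sampled dimer frames.

Frames drawn under harmonic biases are restored to equilibrium with Zwanzig
unbiasing weights

    w_j ∝ exp[(V_z(z_j) + V_r(r_j) - F_i) / kBT],

where F_i is the WHAM alignment constant of the frame's source window;
frames whose total bias exceeds 4 kBT are excluded (their unbiased weight
is dominated by poorly sampled configurations). The sign convention is the
statistically consistent one: with no bias and a single window the weights
reduce to uniform.

Dimensionality reduction uses PCA on all 15 pairwise distances among the
six labelled atoms (carbonyl carbon, nitrogen, sulfur of each molecule);
weights enter only afterwards, in the kernel-density estimate of the
equilibrium distribution over (PC1, PC2), which Boltzmann inversion turns
into a free-energy surface. Minima are found by steepest descent on the
smoothed grid, de-duplicated and valued by local averaging within a 0.1
cutoff in PC space.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.stats import gaussian_kde
from sklearn.decomposition import PCA

from .constants import DEFAULT_TEMPERATURE_K, kbt_kj_per_mol
from .datatypes import FrameSet
from .errors import MappingError

#: Default bias-exclusion threshold, kBT.
DEFAULT_EXCLUSION_KBT = 4.0
#: Default local-averaging / de-duplication cutoff in raw (PC1, PC2) units.
DEFAULT_MINIMA_CUTOFF = 0.1


@dataclass
class FrameWeights:
    """Normalised unbiasing weights with the retained-frame mask."""

    weights: np.ndarray        # (n,), 0 for excluded frames, sums to 1
    retained: np.ndarray       # (n,) bool
    threshold: float           # kBT

    def __post_init__(self):
        if np.any(self.weights < 0):
            raise ValueError("weights must be non-negative")


def frame_weights(
    frames: FrameSet,
    f_i: dict,
    temperature: float = DEFAULT_TEMPERATURE_K,
    threshold: float = DEFAULT_EXCLUSION_KBT,
) -> FrameWeights:
    """Zwanzig unbiasing weights for a frame set.

    ``f_i`` maps window index -> alignment constant in kBT (from WHAM).
    A frame is retained iff (V_z + V_r) <= threshold*kBT, with the
    comparison performed on the kBT scale. Retained weights are
    w_j ∝ exp[(V_z + V_r)/kBT - F_i], normalised to sum 1.
    """
    kbt = kbt_kj_per_mol(temperature)
    unknown = set(np.unique(frames.window_index)) - set(f_i)
    if unknown:
        raise MappingError(
            f"frames reference windows with no alignment constant: {sorted(unknown)}"
        )
    v_tot_kbt = (frames.v_z + frames.v_r) / kbt
    retained = v_tot_kbt <= threshold
    if not np.any(retained):
        raise ValueError("all frames excluded by the bias threshold")
    f_of_frame = np.array([f_i[w] for w in frames.window_index], dtype=float)
    log_w = v_tot_kbt - f_of_frame
    log_w -= log_w[retained].max()          # overflow guard
    w = np.where(retained, np.exp(log_w), 0.0)
    w /= w[retained].sum()
    return FrameWeights(weights=w, retained=retained, threshold=threshold)


@dataclass
class FeatureMatrix:
    """All pairwise distances among the labelled atoms, one row per frame."""

    values: np.ndarray                 # (n, 15) nm
    labels: tuple[str, ...]            # role-pair labels


def distance_features(frames: FrameSet) -> FeatureMatrix:
    """All C(6,2)=15 Euclidean inter-atom distances per frame, fixed order."""
    pairs = list(itertools.combinations(range(len(frames.roles)), 2))
    labels = tuple(f"{frames.roles[a]}-{frames.roles[b]}" for a, b in pairs)
    a_idx = np.array([a for a, _ in pairs])
    b_idx = np.array([b for _, b in pairs])
    diff = frames.coords[:, a_idx, :] - frames.coords[:, b_idx, :]
    return FeatureMatrix(values=np.linalg.norm(diff, axis=2), labels=labels)


@dataclass
class Projection:
    """First two principal components of the distance features."""

    scores: np.ndarray                  # (n, 2)
    components: np.ndarray              # (2, n_features), orthonormal rows
    explained_variance_ratio: np.ndarray  # (2,)
    mean: np.ndarray                    # (n_features,) centering vector


def pca_project(features: FeatureMatrix) -> Projection:
    """Unweighted, mean-centred PCA onto the first two components.

    Features share nm units, so no standardisation is applied. The sign of
    each component is fixed so its largest-magnitude loading is positive.
    Raises on rank-deficient input (fewer than two directions of variance).
    """
    x = features.values
    if x.shape[0] < 2:
        raise ValueError("PCA needs at least 2 frames")
    pca = PCA(n_components=2)
    scores = pca.fit_transform(x)
    if pca.explained_variance_[1] <= np.finfo(float).eps * pca.explained_variance_[0]:
        raise ValueError("feature matrix has rank < 2; cannot build a 2-D projection")
    components = pca.components_.copy()
    for k in range(2):
        j = np.argmax(np.abs(components[k]))
        if components[k, j] < 0:
            components[k] = -components[k]
            scores[:, k] = -scores[:, k]
    return Projection(scores=scores, components=components,
                      explained_variance_ratio=pca.explained_variance_ratio_.copy(),
                      mean=pca.mean_.copy())


@dataclass
class Minimum:
    """One local free-energy minimum on the surface."""

    pc1: float
    pc2: float
    g: float                   # locally averaged free energy, kBT
    member_frames: np.ndarray  # retained frame ids within the cutoff


@dataclass
class FES2D:
    """Free-energy surface over (PC1, PC2), kBT, grid minimum at 0."""

    grid_x: np.ndarray          # (gx,)
    grid_y: np.ndarray          # (gy,)
    g: np.ndarray               # (gx, gy), NaN where masked
    mask: np.ndarray            # (gx, gy) bool, True = below density floor
    bandwidth_factor: float     # KDE covariance factor actually used
    minima: list | None = None


def build_fes(
    projection: Projection,
    weights: FrameWeights,
    bandwidth=None,
    grid_size: int = 200,
    density_floor: float = 1e-6,
    min_retained: int = 100,
) -> FES2D:
    """Weighted Gaussian-KDE free-energy surface on a (PC1, PC2) grid.

    The kernel bandwidth follows Scott's rule unless overridden; the grid
    spans the retained projections padded by three bandwidths. G = -ln(kde)
    in kBT, shifted so the grid minimum is zero; cells with density below
    ``density_floor`` of the maximum are masked.
    """
    retained = weights.retained
    if retained.sum() < min_retained:
        raise ValueError(
            f"need at least {min_retained} retained frames for a stable surface, "
            f"got {int(retained.sum())}"
        )
    pts = projection.scores[retained].T          # (2, n)
    w = weights.weights[retained]
    if w.sum() <= 0:
        raise ValueError("retained frames carry zero total weight")
    kde = gaussian_kde(pts, weights=w, bw_method=bandwidth)
    sd = np.sqrt(np.diag(kde.covariance))
    pad = 3.0 * sd
    gx = np.linspace(pts[0].min() - pad[0], pts[0].max() + pad[0], grid_size)
    gy = np.linspace(pts[1].min() - pad[1], pts[1].max() + pad[1], grid_size)
    xx, yy = np.meshgrid(gx, gy, indexing="ij")
    dens = kde(np.vstack([xx.ravel(), yy.ravel()])).reshape(grid_size, grid_size)
    mask = dens < density_floor * dens.max()
    with np.errstate(divide="ignore"):
        g = np.where(mask, np.nan, -np.log(np.where(mask, 1.0, dens)))
    g -= np.nanmin(g)
    return FES2D(grid_x=gx, grid_y=gy, g=g, mask=mask,
                 bandwidth_factor=float(kde.factor))


def _descend(g: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Steepest-descent endpoint (flat cell index) for every unmasked cell."""
    gx, gy = g.shape
    padded = np.full((gx + 2, gy + 2), np.inf)
    padded[1:-1, 1:-1] = np.where(mask, np.inf, g)
    # stack the 8 neighbours plus self; argmin picks the descent direction
    shifts = [(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1)]
    stacked = np.stack([padded[1 + di:1 + di + gx, 1 + dj:1 + dj + gy]
                        for di, dj in shifts])
    best = np.argmin(stacked, axis=0)
    di = np.array([s[0] for s in shifts])[best]
    dj = np.array([s[1] for s in shifts])[best]
    ii, jj = np.meshgrid(np.arange(gx), np.arange(gy), indexing="ij")
    nxt = (ii + di) * gy + (jj + dj)        # flat index of the descent target
    nxt[mask] = -1
    flat = nxt.ravel()
    # pointer-chase with path doubling until every chain reaches a fixed point
    for _ in range(int(np.ceil(np.log2(flat.size))) + 1):
        valid = flat >= 0
        new = flat.copy()
        new[valid] = flat[flat[valid]]
        if np.array_equal(new, flat):
            break
        flat = new
    return flat.reshape(gx, gy)


def locate_minima(fes: FES2D, averaging_cutoff: float = DEFAULT_MINIMA_CUTOFF,
                  projection: Projection | None = None,
                  weights: FrameWeights | None = None,
                  basin_mass_floor: float = 0.01) -> list[Minimum]:
    """Find, de-duplicate and value the local minima of the surface.

    Steepest descent is started at every unmasked cell; the distinct
    endpoints are candidate minima. Candidates within ``averaging_cutoff``
    of a lower one (Euclidean distance in raw PC units) are merged into it,
    and minima whose merged catchment basin carries less than
    ``basin_mass_floor`` of the total probability mass are discarded — a
    free-energy minimum is only meaningful if its basin holds real
    population, and kernel bumps around isolated outlier frames otherwise
    masquerade as minima. Each minimum's free energy is the average of G
    over the unmasked grid cells within the cutoff of its position, and
    minima are returned sorted ascending by that value. When a projection
    and weights are supplied, each minimum also records the retained frames
    within the cutoff.
    """
    if np.all(fes.mask):
        raise ValueError("free-energy surface is fully masked")
    endpoints = _descend(fes.g, fes.mask)
    cells = np.unique(endpoints[endpoints >= 0])
    gy = fes.grid_y.size
    coords = np.column_stack([fes.grid_x[cells // gy], fes.grid_y[cells % gy]])
    g_at = fes.g.ravel()[cells]
    order = np.argsort(g_at, kind="stable")

    accepted: list[tuple[float, float]] = []
    owner = np.full(cells.size, -1)       # candidate -> accepted minimum
    for k in order:
        p = coords[k]
        for a, q in enumerate(accepted):
            if np.hypot(p[0] - q[0], p[1] - q[1]) <= averaging_cutoff:
                owner[k] = a
                break
        else:
            owner[k] = len(accepted)
            accepted.append((float(p[0]), float(p[1])))

    # probability mass of each merged basin (cells draining to its minima)
    dens = np.where(fes.mask, 0.0, np.exp(-np.where(fes.mask, 0.0, fes.g)))
    cell_owner = np.full(fes.g.size, -1)
    lookup = dict(zip(cells.tolist(), owner.tolist()))
    flat_endpoints = endpoints.ravel()
    valid = flat_endpoints >= 0
    cell_owner[valid] = [lookup[e] for e in flat_endpoints[valid]]
    total = dens.sum()
    masses = np.bincount(cell_owner[valid], weights=dens.ravel()[valid],
                         minlength=len(accepted)) / total
    accepted = [p for a, p in enumerate(accepted) if masses[a] >= basin_mass_floor]
    if not accepted:
        raise ValueError("no minimum basin reaches the population floor")

    xx, yy = np.meshgrid(fes.grid_x, fes.grid_y, indexing="ij")
    minima = []
    for x0, y0 in accepted:
        near = (~fes.mask) & (np.hypot(xx - x0, yy - y0) <= averaging_cutoff)
        g_avg = float(np.mean(fes.g[near])) if np.any(near) else float(
            fes.g[np.argmin(np.abs(fes.grid_x - x0)), np.argmin(np.abs(fes.grid_y - y0))]
        )
        members = np.empty(0, dtype=int)
        if projection is not None and weights is not None:
            d = np.hypot(projection.scores[:, 0] - x0, projection.scores[:, 1] - y0)
            members = np.flatnonzero(weights.retained & (d <= averaging_cutoff))
        minima.append(Minimum(pc1=x0, pc2=y0, g=g_avg, member_frames=members))
    minima.sort(key=lambda m: m.g)
    fes.minima = minima
    return minima


def representative_frames(
    minimum: Minimum,
    projection: Projection,
    weights: FrameWeights,
    cutoff: float = DEFAULT_MINIMA_CUTOFF,
    k: int = 10,
) -> np.ndarray:
    """The k highest-weight retained frames within ``cutoff`` of a minimum.

    Returns frame indices (possibly fewer than k; empty if none qualify).
    """
    d = np.hypot(projection.scores[:, 0] - minimum.pc1,
                 projection.scores[:, 1] - minimum.pc2)
    qualifying = np.flatnonzero(weights.retained & (d <= cutoff))
    if qualifying.size == 0:
        return qualifying
    order = np.argsort(-weights.weights[qualifying], kind="stable")
    return qualifying[order[:k]]


def intramolecular_distance_distribution(
    frames: FrameSet,
    weights: FrameWeights,
    role_pair: tuple[str, str] = ("mol1:Cc", "mol1:S"),
    bins: int = 60,
    range_nm: tuple[float, float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Weighted, area-normalised histogram of an intra-molecule distance.

    Defaults to the backbone(carbonyl C)-sulfur distance of molecule 1,
    whose bimodality separates closed from open monomer conformations.
    Returns (bin_edges, density). Cross-molecule pairs are rejected.
    """
    mol_a, mol_b = (r.split(":")[0] for r in role_pair)
    if mol_a != mol_b:
        raise ValueError(
            f"role pair {role_pair} spans two molecules; this distribution is "
            "intramolecular"
        )
    ia, ib = frames.role_index(role_pair[0]), frames.role_index(role_pair[1])
    d = np.linalg.norm(frames.coords[:, ia] - frames.coords[:, ib], axis=1)
    keep = weights.retained
    counts, edges = np.histogram(
        d[keep], bins=bins, range=range_nm, weights=weights.weights[keep],
        density=True,
    )
    return edges, counts
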