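"""Ground-truth-known synthetic data emulating umbrella-sampling output.

The generators here stand in for the molecular-dynamics layer: a closed-form
potential of mean force (PMF) plays the role of the true monomer-monomer
interaction profile, a single-variable Metropolis sampler emulates biased
production sampling in each umbrella window, and a small conformer mixture
model produces labelled dimer frames with prescribed Boltzmann populations.
Everything is a pure function of (parameters, seed), so every downstream
stage — WHAM, the interaction-free-energy statistic, the reweighted
conformational analysis — can be tested against known truth without MD.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constants import DEFAULT_TEMPERATURE_K, kbt_kj_per_mol
from .datatypes import ROLES, FrameSet, UmbrellaWindow
from .errors import DomainError

_FORMS = ("flat", "gaussian_well", "double_well")


@dataclass(frozen=True)
class AnalyticPMF:
    """Closed-form PMF along the COM separation z, in units of kBT.

    ``flat`` is identically zero; ``gaussian_well`` is a single inverted
    Gaussian of depth ``well_depth`` (kBT) centred at ``well_center`` (nm)
    with standard-deviation width ``well_width`` (nm); ``double_well`` adds a
    second inverted Gaussian. All forms tend to 0 far from the wells, the
    natural reference for a dissociated monomer pair.
    """

    form: str
    well_depth: float = 0.0
    well_center: float = 0.0
    well_width: float = 0.1
    well2_depth: float = 0.0
    well2_center: float = 0.0
    well2_width: float = 0.1
    domain: tuple[float, float] = (0.0, 3.5)

    def __post_init__(self):
        if self.form not in _FORMS:
            raise ValueError(f"unknown PMF form {self.form!r}; expected one of {_FORMS}")
        if self.domain[1] <= self.domain[0]:
            raise ValueError(f"domain upper bound must exceed lower, got {self.domain}")
        if self.form != "flat" and self.well_width <= 0:
            raise ValueError("well_width must be positive")
        if self.form == "double_well" and self.well2_width <= 0:
            raise ValueError("well2_width must be positive")

    def contains(self, z) -> bool:
        z = np.asarray(z)
        return bool(np.all((z >= self.domain[0]) & (z <= self.domain[1])))


def evaluate_pmf(model: AnalyticPMF, z):
    """Evaluate the analytic PMF at z (nm); returns energy in kBT.

    Accepts scalars or arrays; raises :class:`DomainError` if any z lies
    outside the model domain.
    """
    z = np.asarray(z, dtype=float)
    if not model.contains(z):
        raise DomainError(
            f"z outside PMF domain {model.domain}: "
            f"range [{z.min():.4g}, {z.max():.4g}]"
        )
    if model.form == "flat":
        out = np.zeros_like(z)
    else:
        out = -model.well_depth * np.exp(
            -((z - model.well_center) ** 2) / (2.0 * model.well_width**2)
        )
        if model.form == "double_well":
            out = out - model.well2_depth * np.exp(
                -((z - model.well2_center) ** 2) / (2.0 * model.well2_width**2)
            )
    return out if out.ndim else float(out)


def _scalar_pmf(model: AnalyticPMF):
    """Fast scalar evaluator (math.exp) for the Metropolis inner loop."""
    if model.form == "flat":
        return lambda z: 0.0
    d1, c1, s1 = model.well_depth, model.well_center, 2.0 * model.well_width**2
    if model.form == "gaussian_well":
        return lambda z: -d1 * math.exp(-((z - c1) ** 2) / s1)
    d2, c2, s2 = model.well2_depth, model.well2_center, 2.0 * model.well2_width**2
    return lambda z: (
        -d1 * math.exp(-((z - c1) ** 2) / s1) - d2 * math.exp(-((z - c2) ** 2) / s2)
    )


def sample_window(
    model: AnalyticPMF,
    window: UmbrellaWindow,
    n: int,
    burn_in: int = 0,
    seed: int = 0,
    step: float = 0.05,
    temperature: float = DEFAULT_TEMPERATURE_K,
) -> UmbrellaWindow:
    """Metropolis Monte-Carlo sampling of one biased umbrella window.

    Draws from the stationary density ∝ exp(-[PMF(z) + V_z(z)]/kBT), where
    V_z(z) = ½ k_z (z - z0)² is the window's harmonic restraint. The first
    ``burn_in`` samples are discarded and ``n`` retained samples returned in
    a copy of ``window`` with its series filled. Perpendicular displacements
    r are drawn from the restraint's own harmonic density (|N(0, kBT/k_r)|)
    so the orthogonal bias V_r is non-trivial downstream.

    Only the stationary density matters for post-processing, so a simple
    Gaussian-proposal random walk (default step 0.05 nm) is used.
    """
    if n <= 0:
        raise ValueError(f"sample count must be positive, got {n}")
    if burn_in < 0:
        raise ValueError(f"burn_in must be non-negative, got {burn_in}")
    kbt = kbt_kj_per_mol(temperature)
    pmf = _scalar_pmf(model)
    lo, hi = model.domain
    k_z, z0 = window.k_z, window.center
    rng = np.random.default_rng(seed)
    total = n + burn_in
    steps = rng.normal(0.0, step, size=total)
    log_u = np.log(rng.random(size=total))

    z = min(max(z0, lo), hi)
    neg_logp = pmf(z) + 0.5 * k_z * (z - z0) ** 2 / kbt
    out = np.empty(total)
    for t in range(total):
        zp = z + steps[t]
        if lo <= zp <= hi:
            neg_logp_p = pmf(zp) + 0.5 * k_z * (zp - z0) ** 2 / kbt
            if log_u[t] < neg_logp - neg_logp_p:
                z, neg_logp = zp, neg_logp_p
        out[t] = z

    series = out[burn_in:]
    if window.k_r > 0:
        r = np.abs(rng.normal(0.0, math.sqrt(kbt / window.k_r), size=n))
    else:
        r = np.zeros(n)
    return UmbrellaWindow(
        index=window.index, center=window.center, k_z=window.k_z, k_r=window.k_r,
        series=series, r_series=r, bias_offset=window.bias_offset,
    )


def make_window_ladder(
    n_windows: int = 28,
    z_min: float = 0.1,
    z_max: float = 2.8,
    k_z: float = 600.0,
    k_r: float = 25_000.0,
) -> list[UmbrellaWindow]:
    """Standard umbrella ladder: equally spaced centres, shared force constants.

    Defaults mirror the production protocol: 28 windows with COM distances
    equally spaced from 0.1 to 2.8 nm, 600 kJ mol^-1 nm^-2 along z and
    25 000 kJ mol^-1 nm^-2 perpendicular.
    """
    centers = np.linspace(z_min, z_max, n_windows)
    return [UmbrellaWindow(index=i, center=float(c), k_z=k_z, k_r=k_r)
            for i, c in enumerate(centers)]


def sample_experiment(
    model: AnalyticPMF,
    windows: list[UmbrellaWindow],
    n_per_window: int,
    burn_in: int = 0,
    seed: int = 0,
    step: float = 0.05,
    temperature: float = DEFAULT_TEMPERATURE_K,
) -> list[UmbrellaWindow]:
    """Sample every window of a ladder with per-window derived seeds."""
    ss = np.random.SeedSequence(seed)
    child = ss.spawn(len(windows))
    return [
        sample_window(model, w, n_per_window, burn_in=burn_in,
                      seed=child[i], step=step, temperature=temperature)
        for i, w in enumerate(windows)
    ]


# ---------------------------------------------------------------------------
# Conformer mixture model for the conformational-analysis stage
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Conformer:
    """One dimer conformation template: label, 6 labelled-atom coordinates
    (role -> xyz in nm), and a free-energy offset in kBT relative to the
    reference conformer (Boltzmann population ∝ exp(-offset))."""

    label: str
    coords: dict = field(default_factory=dict)  # role -> (x, y, z) nm
    free_energy_offset: float = 0.0

    def template_array(self, roles: tuple[str, ...] = ROLES) -> np.ndarray:
        missing = [r for r in roles if r not in self.coords]
        if missing:
            raise ValueError(f"conformer {self.label!r} missing roles {missing}")
        return np.array([self.coords[r] for r in roles], dtype=float)


@dataclass(frozen=True)
class ConformerModel:
    """Mixture of dimer conformers with Boltzmann populations.

    ``noise`` is the isotropic Gaussian geometric jitter (nm) applied to
    every atom of a generated frame.
    """

    conformers: tuple[Conformer, ...]
    noise: float = 0.02

    def __post_init__(self):
        if len(self.conformers) < 1:
            raise ValueError("ConformerModel needs at least one conformer")
        if self.noise < 0:
            raise ValueError("geometric noise scale must be non-negative")

    def populations(self) -> np.ndarray:
        """Boltzmann populations from the free-energy offsets (sum to 1)."""
        w = np.exp(-np.array([c.free_energy_offset for c in self.conformers]))
        return w / w.sum()


def two_state_dimer_model(
    delta_f: float = 1.0,
    closed_cc_s: float = 0.5,
    open_cc_s: float = 0.9,
    com_distance: float = 0.7,
    noise: float = 0.02,
) -> ConformerModel:
    """Closed/open two-conformer dimer with a prescribed free-energy gap.

    Each molecule carries a carbonyl carbon (backbone), nitrogen and sulfur;
    the conformers differ in the backbone-sulfur distance (``closed_cc_s``
    vs ``open_cc_s``, nm), emulating the closed and open states of a
    zwitterionic monomer. The open state sits ``delta_f`` kBT above the
    closed state. The two molecules are stacked along z at ``com_distance``.
    """
    def dimer(cc_s: float) -> dict:
        # S placed in the x-y plane at the requested distance from Cc
        s = (0.6 * cc_s, 0.8 * cc_s, 0.0)
        mol1 = {"mol1:Cc": (0.0, 0.0, 0.0), "mol1:N": (0.25, 0.0, 0.0), "mol1:S": s}
        mol2 = {
            "mol2:Cc": (0.0, 0.0, com_distance),
            "mol2:N": (0.25, 0.0, com_distance),
            "mol2:S": (s[0], s[1], com_distance),
        }
        return {**mol1, **mol2}

    return ConformerModel(
        conformers=(
            Conformer("closed", dimer(closed_cc_s), 0.0),
            Conformer("open", dimer(open_cc_s), delta_f),
        ),
        noise=noise,
    )


def _sample_z_biased(
    z_pmf: AnalyticPMF | None,
    window: UmbrellaWindow,
    n: int,
    rng: np.random.Generator,
    kbt: float,
) -> np.ndarray:
    """I.i.d. draws of the COM separation from exp(-[PMF + V_z]/kBT).

    Grid inverse-CDF sampling over the window's relevant range; with
    ``z_pmf`` None the underlying PMF is flat and the draws reduce to the
    window's harmonic density.
    """
    sd = math.sqrt(kbt / window.k_z)
    lo, hi = window.center - 8 * sd, window.center + 8 * sd
    if z_pmf is not None:
        lo, hi = max(lo, z_pmf.domain[0]), min(hi, z_pmf.domain[1])
    grid = np.linspace(lo, hi, 4001)
    neg_logp = 0.5 * window.k_z * (grid - window.center) ** 2 / kbt
    if z_pmf is not None:
        neg_logp = neg_logp + evaluate_pmf(z_pmf, grid)
    logp = -neg_logp
    p = np.exp(logp - logp.max())
    cdf = np.cumsum(p)
    cdf /= cdf[-1]
    return np.interp(rng.random(n), cdf, grid)


def analytic_alignment_constants(
    z_pmf: AnalyticPMF | None,
    windows: list[UmbrellaWindow],
    temperature: float = DEFAULT_TEMPERATURE_K,
    spacing: float = 1e-3,
) -> dict:
    """Ground-truth window alignment constants F_i in kBT, by dense quadrature.

    F_i = -ln ∫ p0(z) exp(-V_i(z)/kBT) dz with p0 ∝ exp(-PMF); only
    differences between windows matter downstream, so the normalisation of
    p0 is immaterial. Serves as the sampling-free oracle for the WHAM
    alignment constants when reweighting synthetic conformer frames.
    """
    kbt = kbt_kj_per_mol(temperature)
    if z_pmf is not None:
        grid = np.arange(z_pmf.domain[0], z_pmf.domain[1] + spacing / 2, spacing)
        p0 = np.exp(-evaluate_pmf(z_pmf, grid))
    else:
        zmin = min(w.center for w in windows) - 1.0
        zmax = max(w.center for w in windows) + 1.0
        grid = np.arange(zmin, zmax + spacing / 2, spacing)
        p0 = np.ones_like(grid)
    p0 = p0 / (p0.sum() * spacing)
    out = {}
    for w in windows:
        v = 0.5 * w.k_z * (grid - w.center) ** 2 + w.bias_offset
        out[w.index] = float(-np.log(np.sum(p0 * np.exp(-v / kbt)) * spacing))
    return out


def generate_conformer_frames(
    model: ConformerModel,
    windows: list[UmbrellaWindow],
    n_per_window: int,
    seed: int = 0,
    temperature: float = DEFAULT_TEMPERATURE_K,
    z_pmf: AnalyticPMF | None = None,
) -> FrameSet:
    """Draw labelled dimer frames emulating analysed umbrella trajectories.

    For each frame a conformer is drawn with its Boltzmann probability, all
    atoms are jittered by the model's geometric noise, and the second
    molecule is translated along the COM axis so the COM separation follows
    the window's biased equilibrium density exp(-[PMF + V_z]/kBT) (harmonic
    density when ``z_pmf`` is None). Each frame is tagged with its source
    window, actual COM separation z, bias energies V_z and V_r, and the
    ground-truth conformer label (retained for recovery testing).
    """
    if n_per_window <= 0:
        raise ValueError(f"n_per_window must be positive, got {n_per_window}")
    if not windows:
        raise ValueError("empty window list")
    kbt = kbt_kj_per_mol(temperature)
    rng = np.random.default_rng(seed)
    pops = model.populations()
    templates = np.stack([c.template_array() for c in model.conformers])
    labels_by_conf = np.array([c.label for c in model.conformers])
    mol1 = slice(0, 3)
    mol2 = slice(3, 6)

    n_total = n_per_window * len(windows)
    coords = np.empty((n_total, 6, 3))
    win_idx = np.empty(n_total, dtype=int)
    z_arr = np.empty(n_total)
    vz_arr = np.empty(n_total)
    vr_arr = np.empty(n_total)
    labels = np.empty(n_total, dtype=labels_by_conf.dtype)

    pos = 0
    for w in windows:
        n = n_per_window
        conf = rng.choice(len(model.conformers), size=n, p=pops)
        frames = templates[conf].copy()
        if model.noise > 0:
            frames += rng.normal(0.0, model.noise, size=frames.shape)
        # place mol2 so the COM separation follows the biased equilibrium
        z_target = _sample_z_biased(z_pmf, w, n, rng, kbt)
        com1 = frames[:, mol1].mean(axis=1)
        com2 = frames[:, mol2].mean(axis=1)
        sep = com2 - com1
        dist = np.linalg.norm(sep, axis=1)
        unit = np.where(dist[:, None] > 0, sep / np.maximum(dist, 1e-12)[:, None],
                        np.array([0.0, 0.0, 1.0]))
        frames[:, mol2] += (z_target - dist)[:, None, None] * unit[:, None, :]
        z_actual = np.linalg.norm(
            frames[:, mol2].mean(axis=1) - frames[:, mol1].mean(axis=1), axis=1
        )
        if w.k_r > 0:
            r = np.abs(rng.normal(0.0, math.sqrt(kbt / w.k_r), size=n))
        else:
            r = np.zeros(n)
        sl = slice(pos, pos + n)
        coords[sl] = frames
        win_idx[sl] = w.index
        z_arr[sl] = z_actual
        vz_arr[sl] = 0.5 * w.k_z * (z_actual - w.center) ** 2 + w.bias_offset
        vr_arr[sl] = 0.5 * w.k_r * r**2
        labels[sl] = labels_by_conf[conf]
        pos += n

    return FrameSet(coords=coords, window_index=win_idx, z=z_arr,
                    v_z=vz_arr, v_r=vr_arr, labels=labels)


def reference_interaction_energy(
    model: AnalyticPMF,
    search_min: float = 0.4,
    ref_window: tuple[float, float] = (1.75, 2.25),
    grid_spacing: float = 1e-4,
) -> float:
    """Ground-truth interaction free energy of an analytic PMF, in kBT.

    Dense-grid evaluation (no sampling) of the same statistic the pipeline
    estimates from data: mean of the PMF over the reference window minus its
    minimum over z >= ``search_min``. Serves as the independent oracle for
    recovery tests.
    """
    lo, hi = ref_window
    if not (model.contains(lo) and model.contains(hi)) or hi <= lo:
        raise DomainError(f"reference window {ref_window} not inside domain {model.domain}")
    zmin = max(search_min, model.domain[0])
    search = np.arange(zmin, model.domain[1] + grid_spacing / 2, grid_spacing)
    ref = np.arange(lo, hi + grid_spacing / 2, grid_spacing)
    f_min = float(np.min(evaluate_pmf(model, search)))
    f_ref = float(np.mean(evaluate_pmf(model, ref)))
    return f_ref - f_min
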