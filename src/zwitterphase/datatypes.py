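"""Core in-memory containers shared between pipeline stages.

An :class:`UmbrellaWindow` is one harmonically biased simulation along the
centre-of-mass (COM) separation z of a monomer pair; a :class:`FrameSet` holds
the labelled-atom coordinates (carbonyl carbon, nitrogen, sulfur of each
molecule) of analysed frames together with the bias energies acting on them.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: Fixed role order of the six labelled atoms of a dimer frame.
ROLES: tuple[str, ...] = (
    "mol1:Cc", "mol1:N", "mol1:S",
    "mol2:Cc", "mol2:N", "mol2:S",
)


@dataclass
class UmbrellaWindow:
    """One umbrella window: harmonic bias definition plus its sampled series.

    Parameters
    ----------
    index
        Window index within the experiment (unique).
    center
        Restraint centre z0 along the COM separation, nm.
    k_z
        Harmonic force constant along z, kJ mol^-1 nm^-2 (must be > 0).
    k_r
        Force constant of the perpendicular restraint, kJ mol^-1 nm^-2.
    series
        Sampled z values, nm, in simulation order (may be empty before
        sampling/reading).
    r_series
        Optional perpendicular displacement samples, nm.
    bias_offset
        Constant added to the bias energy, kJ/mol. Physically irrelevant
        (WHAM is gauge invariant) but kept explicit so that invariance can
        be exercised.
    """

    index: int
    center: float
    k_z: float
    k_r: float = 0.0
    series: np.ndarray = field(default_factory=lambda: np.empty(0))
    r_series: np.ndarray | None = None
    bias_offset: float = 0.0

    def __post_init__(self):
        if self.k_z <= 0:
            raise ValueError(f"window {self.index}: k_z must be > 0, got {self.k_z}")
        if self.k_r < 0:
            raise ValueError(f"window {self.index}: k_r must be >= 0, got {self.k_r}")
        self.series = np.asarray(self.series, dtype=float)
        if self.r_series is not None:
            self.r_series = np.asarray(self.r_series, dtype=float)

    @property
    def n_samples(self) -> int:
        return int(self.series.size)

    def with_burn_in_removed(self, fraction: float) -> "UmbrellaWindow":
        """Drop the first `fraction` of the series (equilibration period)."""
        if not 0.0 <= fraction < 1.0:
            raise ValueError(f"burn-in fraction must be in [0, 1), got {fraction}")
        cut = int(round(fraction * self.series.size))
        if cut >= self.series.size:
            raise ValueError(f"window {self.index}: series empty after burn-in removal")
        r = self.r_series[cut:] if self.r_series is not None else None
        return replace(self, series=self.series[cut:], r_series=r)


def check_unique_centers(windows: list[UmbrellaWindow]) -> None:
    centers = [w.center for w in windows]
    if len(set(centers)) != len(centers):
        raise ValueError("umbrella window centers must be unique within an experiment")


@dataclass
class FrameSet:
    """Labelled-atom coordinates and bias energies for analysed frames.

    Structure-of-arrays layout: ``coords[j, a]`` is the (x, y, z) position in
    nm of atom role ``roles[a]`` in frame j. ``z`` is the COM separation of
    the two molecules, ``v_z``/``v_r`` the harmonic bias energies (kJ/mol,
    always >= 0) acting on the frame, ``window_index`` the source window.
    ``labels`` optionally retains the ground-truth conformer label of
    synthetic frames for recovery testing.
    """

    coords: np.ndarray           # (n, 6, 3) nm
    window_index: np.ndarray     # (n,) int
    z: np.ndarray                # (n,) nm
    v_z: np.ndarray              # (n,) kJ/mol
    v_r: np.ndarray              # (n,) kJ/mol
    labels: np.ndarray | None = None
    roles: tuple[str, ...] = ROLES
    frame_ids: np.ndarray | None = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        n = self.coords.shape[0]
        if self.coords.ndim != 3 or self.coords.shape[1:] != (len(self.roles), 3):
            raise ValueError(
                f"coords must have shape (n, {len(self.roles)}, 3), got {self.coords.shape}"
            )
        for name in ("window_index", "z", "v_z", "v_r"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != (n,):
                raise ValueError(f"{name} must have shape ({n},), got {arr.shape}")
            setattr(self, name, arr)
        if np.any(self.v_z < 0) or np.any(self.v_r < 0):
            raise ValueError("bias energies V_z, V_r must be non-negative")
        if self.frame_ids is None:
            self.frame_ids = np.arange(n)
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape != (n,):
                raise ValueError("labels must match frame count")

    def __len__(self) -> int:
        return int(self.coords.shape[0])

    def role_index(self, role: str) -> int:
        try:
            return self.roles.index(role)
        except ValueError:
            raise KeyError(f"unknown atom role {role!r}; known: {self.roles}") from None
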