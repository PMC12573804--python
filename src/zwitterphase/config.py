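"""Experiment configuration: every tunable constant of the pipeline.

Loaded from a YAML key-value file. The seed is mandatory whenever a
stochastic stage (simulation, bootstrap) will run — it is never silently
defaulted.
"""
from __future__ import annotations

from dataclasses import dataclass, field, fields

import yaml


@dataclass
class ExperimentConfig:
    """All pipeline parameters with their default values.

    Units: distances nm, energies kJ/mol except thresholds/tolerances
    expressed on the kBT scale, force constants kJ mol^-1 nm^-2.
    """

    # thermodynamic state
    temperature: float = 300.0

    # umbrella ladder / synthetic sampling
    n_windows: int = 28
    z_min: float = 0.1
    z_max: float = 2.8
    k_z: float = 600.0
    k_r: float = 25_000.0
    n_samples: int = 12_500          # raw samples per window (incl. burn-in)
    mc_step: float = 0.05            # Metropolis proposal width, nm
    pmf_form: str = "gaussian_well"
    well_depth: float = 3.0          # kBT
    well_center: float = 0.55        # nm
    well_width: float = 0.12         # nm
    well2_depth: float = 0.0
    well2_center: float = 0.0
    well2_width: float = 0.1

    # WHAM stage
    burn_in_fraction: float = 0.2
    bin_width: float = 0.01          # nm
    wham_tol: float = 1e-6           # kBT
    max_iter: int = 100_000
    bootstrap_replicates: int = 50

    # interaction-free-energy statistic
    search_min: float = 0.4
    search_max: float = 2.8          # top of the profiled interval
    ref_window: tuple = (1.75, 2.25)

    # conformational analysis
    exclusion_threshold: float = 4.0   # kBT
    fes_windows: list = field(default_factory=list)  # window indices ([] = all)
    frames_per_window: int = 5000
    kde_bandwidth: float | None = None  # None = Scott's rule
    minima_cutoff: float = 0.1
    grid_size: int = 200

    # phase-behaviour layer
    regime_thresholds: tuple = (0.8, 2.0)  # kBT

    # randomness — must be set explicitly for stochastic stages
    seed: int | None = None

    def __post_init__(self):
        positive = (
            "temperature", "n_windows", "k_z", "n_samples", "mc_step",
            "bin_width", "wham_tol", "max_iter", "bootstrap_replicates",
            "exclusion_threshold", "frames_per_window", "minima_cutoff",
            "grid_size",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"config field {name!r} must be positive")
        if not 0.0 <= self.burn_in_fraction < 1.0:
            raise ValueError("burn_in_fraction must lie in [0, 1)")
        self.ref_window = tuple(self.ref_window)
        if self.ref_window[1] <= self.ref_window[0]:
            raise ValueError(f"ref_window upper must exceed lower, got {self.ref_window}")
        self.regime_thresholds = tuple(self.regime_thresholds)
        if self.regime_thresholds[0] >= self.regime_thresholds[1]:
            raise ValueError("regime thresholds must satisfy t_low < t_high")

    def require_seed(self) -> int:
        if self.seed is None:
            raise ValueError(
                "no seed configured: stochastic stages require an explicit "
                "'seed' in the config or --seed on the command line"
            )
        return int(self.seed)


def load_config(path) -> ExperimentConfig:
    """Load an :class:`ExperimentConfig` from a YAML key-value file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    known = {f.name for f in fields(ExperimentConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return ExperimentConfig(**raw)


def dump_config(cfg: ExperimentConfig, path) -> None:
    data = {f.name: getattr(cfg, f.name) for f in fields(ExperimentConfig)}
    data["ref_window"] = list(cfg.ref_window)
    data["regime_thresholds"] = list(cfg.regime_thresholds)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
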