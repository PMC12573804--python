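"""The headline per-monomer statistic: homotypic interaction free energy.

Defined as the difference between the PMF minimum within the bound region
(COM separation >= 0.4 nm by default) and the mean PMF over the dissociated
reference window (1.75-2.25 nm). Positive values are attractive well depths
in kBT. The uncertainty applies the identical functional to every
Bayesian-bootstrap ensemble member.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataCoverageError
from .wham import PMFProfile


@dataclass(frozen=True)
class InteractionFreeEnergy:
    """Well-depth statistic (kBT) with its bootstrap SE and parameters."""

    value: float
    se: float
    search_min: float
    ref_window: tuple[float, float]
    label: str = ""
    search_max: float | None = None

    def __post_init__(self):
        if not np.isnan(self.se) and self.se < 0:
            raise ValueError("standard error must be non-negative")


def _statistic(f: np.ndarray, z: np.ndarray, mask: np.ndarray,
               search_min: float, ref_window: tuple[float, float],
               search_max: float | None) -> float:
    ok = ~mask & np.isfinite(f)
    in_ref = ok & (z >= ref_window[0]) & (z <= ref_window[1])
    in_search = ok & (z >= search_min)
    if search_max is not None:
        in_search &= z <= search_max
    if not np.any(in_ref):
        raise DataCoverageError(
            f"reference window {ref_window} has no populated PMF bins"
        )
    if not np.any(in_search):
        raise ValueError(f"no populated PMF bins with z >= {search_min}")
    # raw-bin minimum, no interpolation/smoothing: keeps the statistic free
    # of any extra bandwidth parameter
    return float(np.mean(f[in_ref]) - np.min(f[in_search]))


def interaction_free_energy(
    pmf: PMFProfile,
    search_min: float = 0.4,
    ref_window: tuple[float, float] = (1.75, 2.25),
    label: str = "",
    search_max: float | None = 2.8,
) -> InteractionFreeEnergy:
    """Compute the interaction free energy of a PMF profile, in kBT.

    value = mean(F over reference-window bins) - min(F over bins with
    search_min <= z <= search_max), both over unmasked bins only.
    ``search_max`` bounds the search to the profiled interval (the top of
    the production window ladder by default); the sparsely sampled
    histogram tail beyond the last restraint centre carries
    exp(+V/kBT)-amplified count noise and is not part of the profile.
    Pass None to search every populated bin. If the profile carries a
    bootstrap ensemble, the SE is the standard deviation of the same
    statistic across the members; otherwise SE is NaN.
    """
    if ref_window[1] <= ref_window[0]:
        raise ValueError(f"reference window must be a proper interval, got {ref_window}")
    value = _statistic(pmf.f, pmf.z, pmf.mask, search_min, ref_window, search_max)
    se = float("nan")
    if pmf.ensemble is not None:
        vals = []
        for member in pmf.ensemble:
            if np.all(np.isnan(member)):
                continue  # failed bootstrap replicate
            vals.append(_statistic(member, pmf.z, pmf.mask, search_min,
                                   ref_window, search_max))
        if len(vals) >= 2:
            se = float(np.std(vals, ddof=1))
    return InteractionFreeEnergy(value=value, se=se, search_min=search_min,
                                 ref_window=tuple(ref_window), label=label,
                                 search_max=search_max)


def rank_monomers(results: list[InteractionFreeEnergy]) -> list[InteractionFreeEnergy]:
    """Order monomers by descending interaction strength; ties by label."""
    if not results:
        raise ValueError("cannot rank an empty result list")
    return sorted(results, key=lambda r: (-r.value, r.label))


def results_table(results: list[InteractionFreeEnergy]) -> pd.DataFrame:
    """Per-monomer table (label, dG_kBT, SE_kBT, parameters) for downstream use."""
    return pd.DataFrame(
        {
            "label": [r.label for r in results],
            "dG_kBT": [r.value for r in results],
            "SE_kBT": [r.se for r in results],
            "search_min_nm": [r.search_min for r in results],
            "search_max_nm": [r.search_max for r in results],
            "ref_lo_nm": [r.ref_window[0] for r in results],
            "ref_hi_nm": [r.ref_window[1] for r in results],
        }
    )
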