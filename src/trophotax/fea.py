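"""Finite-element strain summaries.

A planar FE model solved elsewhere is reduced to two comparable
summaries: the mesh-weighted arithmetic mean (MWAM) strain, i.e. the
element-area-weighted mean of maximum in-plane principal strain, and an
interval profile giving the percentage of total model area in fixed
strain bins (a multivariate observation suitable for ordination and
discriminant analysis).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["StrainField", "IntervalProfile", "mwam_strain", "interval_profile"]


@dataclass
class StrainField:
    """Per-element area (mm^2) and maximum in-plane principal strain (microstrain)."""

    element_id: np.ndarray
    area: np.ndarray
    strain: np.ndarray

    def __post_init__(self):
        self.element_id = np.asarray(self.element_id)
        self.area = np.asarray(self.area, dtype=float)
        self.strain = np.asarray(self.strain, dtype=float)
        if not (len(self.element_id) == len(self.area) == len(self.strain)):
            raise ValueError("element_id, area and strain must have equal length")
        if len(np.unique(self.element_id)) != len(self.element_id):
            raise ValueError("element ids are not unique")
        if np.any(self.area <= 0):
            raise ValueError("element areas must be strictly positive")
        if np.any(self.strain < 0):
            raise ValueError("strains must be non-negative")

    def __len__(self) -> int:
        return len(self.area)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {"element_id": self.element_id, "area": self.area, "strain": self.strain}
        )


@dataclass
class IntervalProfile:
    """Percent of model area per strain bin; the last bin is open-ended."""

    bin_edges: np.ndarray  # length n_bins, lower edges; last bin is [upper, inf)
    area_pct: np.ndarray

    def __post_init__(self):
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.area_pct = np.asarray(self.area_pct, dtype=float)
        if np.any(self.area_pct < 0):
            raise ValueError("negative bin percentage")
        if abs(self.area_pct.sum() - 100.0) > 1e-6:
            raise ValueError("bin percentages must sum to 100")


def mwam_strain(field: StrainField) -> float:
    """Mesh-weighted arithmetic mean strain: sum(area*strain)/sum(area)."""
    if len(field) == 0:
        raise ValueError("empty strain field")
    return float(np.sum(field.area * field.strain) / np.sum(field.area))


def interval_profile(
    field: StrainField, n_bins: int = 25, upper_limit: float = 1000.0
) -> IntervalProfile:
    """Area-percentage strain histogram with equal-width half-open bins.

    Bins partition [0, upper_limit) into ``n_bins - 1`` equal [lo, hi)
    intervals plus one open-ended bin [upper_limit, inf), so the profile
    always accounts for 100% of model area.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if upper_limit <= 0:
        raise ValueError("upper_limit must be positive")
    if len(field) == 0:
        raise ValueError("empty strain field")
    width = upper_limit / (n_bins - 1)
    idx = np.floor(field.strain / width).astype(int)
    idx = np.minimum(idx, n_bins - 1)
    pct = np.zeros(n_bins)
    np.add.at(pct, idx, field.area)
    pct = 100.0 * pct / field.area.sum()
    edges = np.arange(n_bins) * width
    return IntervalProfile(bin_edges=edges, area_pct=pct)
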