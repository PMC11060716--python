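"""Jaw functional indices from 2D landmarks.

Eight dimensionless ratios summarise the lever mechanics and robusticity
of a jaw (upper or lower): anterior/posterior jaw-closing mechanical
advantage (AMA, PMA), jaw-opening mechanical advantage (OMA), relative
articular offset (AO), and relative maximum/average cranial or
mandibular height (MCH/MMH, ACH/AMH).  Levers are measured along the
jaw length axis with the quadrate articulation as the fulcrum; heights
and offsets are normalised by jaw length, so all indices are invariant
to rigid motion and uniform scaling.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = ["JawLandmarks", "JawIndices", "compute_jaw_indices", "quadrate_sensitivity"]


@dataclass
class JawLandmarks:
    """2D landmark set for one jaw (all points as (x, y) arrays).

    ``closing_muscle_attachment`` is the adductor insertion (lower jaw)
    or origin proxy (upper jaw); ``opening_muscle_attachment`` the
    retroarticular process / depressor attachment.  ``outline_heights``
    are dorsoventral depths sampled along the jaw; ``jaw_length_axis``
    is a pair of points defining the long axis and the jaw length.
    """

    jaw_joint: np.ndarray
    anterior_tip: np.ndarray
    posterior_tooth: np.ndarray
    closing_muscle_attachment: np.ndarray
    opening_muscle_attachment: np.ndarray
    tooth_row_line: tuple
    outline_heights: np.ndarray
    jaw_length_axis: tuple
    side: str = "lower"

    def __post_init__(self):
        for name in (
            "jaw_joint", "anterior_tip", "posterior_tooth",
            "closing_muscle_attachment", "opening_muscle_attachment",
        ):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValueError(f"non-finite landmark {name}")
        self.tooth_row_line = tuple(np.asarray(p, dtype=float) for p in self.tooth_row_line)
        self.jaw_length_axis = tuple(np.asarray(p, dtype=float) for p in self.jaw_length_axis)
        self.outline_heights = np.asarray(self.outline_heights, dtype=float)
        if np.any(self.outline_heights < 0):
            raise ValueError("outline heights must be non-negative")
        if self.side not in ("upper", "lower"):
            raise ValueError("side must be 'upper' or 'lower'")
        a, b = self.jaw_length_axis
        if np.allclose(a, b):
            raise ValueError("degenerate jaw length axis")

    @property
    def jaw_length(self) -> float:
        a, b = self.jaw_length_axis
        return float(np.linalg.norm(b - a))


@dataclass
class JawIndices:
    """The eight functional indices of one jaw (dimensionless)."""

    AMA: float
    PMA: float
    OMA: float
    AO: float
    max_height: float  # MCH (upper) or MMH (lower)
    mean_height: float  # ACH (upper) or AMH (lower)
    side: str = "lower"

    def as_series(self) -> pd.Series:
        tag = "C" if self.side == "upper" else "M"
        return pd.Series(
            {
                "AMA": self.AMA,
                "PMA": self.PMA,
                "OMA": self.OMA,
                "AO": self.AO,
                f"M{tag}H": self.max_height,
                f"A{tag}H": self.mean_height,
            }
        )


def _axis_coordinate(point: np.ndarray, axis: tuple) -> float:
    """Signed position of ``point`` along the unit jaw-length axis."""
    a, b = axis
    u = (b - a) / np.linalg.norm(b - a)
    return float(np.dot(point - a, u))


def _point_line_distance(point: np.ndarray, line: tuple) -> float:
    a, b = line
    d = b - a
    nrm = np.linalg.norm(d)
    if nrm == 0:
        raise ValueError("degenerate tooth row line")
    v = point - a
    return float(abs(d[0] * v[1] - d[1] * v[0]) / nrm)


def compute_jaw_indices(lm: JawLandmarks) -> JawIndices:
    """Compute AMA, PMA, OMA, AO and relative heights from landmarks.

    Out-levers are distances along the jaw length axis from the joint
    to the bite point (anterior tip or posteriormost tooth); in-levers
    are straight-line distances from the joint to the muscle attachment
    (the moment arm of a muscle whose action line is roughly normal to
    the jaw axis).  AO is the perpendicular offset of the joint from
    the tooth row over jaw length; heights are max/mean outline depth
    over jaw length.
    """
    axis = lm.jaw_length_axis
    length = lm.jaw_length
    joint = _axis_coordinate(lm.jaw_joint, axis)
    tip = _axis_coordinate(lm.anterior_tip, axis)
    tooth = _axis_coordinate(lm.posterior_tooth, axis)
    in_close = float(np.linalg.norm(lm.closing_muscle_attachment - lm.jaw_joint))
    in_open = float(np.linalg.norm(lm.opening_muscle_attachment - lm.jaw_joint))
    out_ant = abs(tip - joint)
    out_post = abs(tooth - joint)
    if out_ant == 0 or out_post == 0:
        raise ValueError("jaw joint coincides with a bite point (zero out-lever)")
    indices = JawIndices(
        AMA=in_close / out_ant,
        PMA=in_close / out_post,
        OMA=in_open / out_ant,
        AO=_point_line_distance(lm.jaw_joint, lm.tooth_row_line) / length,
        max_height=float(np.max(lm.outline_heights)) / length,
        mean_height=float(np.mean(lm.outline_heights)) / length,
        side=lm.side,
    )
    return indices


def quadrate_sensitivity(lm: JawLandmarks, shifts) -> pd.DataFrame:
    """Recompute indices with the jaw joint translated along the axis.

    ``shifts`` are signed fractions of jaw length (negative = toward the
    anterior tip).  Each shifted joint must stay on the joint's side of
    the anterior tip.  Returns a table indexed by shift with one column
    per index plus the direction of change relative to shift 0.
    """
    a, b = lm.jaw_length_axis
    u = (b - a) / np.linalg.norm(b - a)
    # orient u so that +u points from anterior tip toward the joint
    if _axis_coordinate(lm.jaw_joint, (a, b)) < _axis_coordinate(lm.anterior_tip, (a, b)):
        u = -u
    length = lm.jaw_length
    base = compute_jaw_indices(lm).as_series()
    rows = {}
    tip_coord = float(np.dot(lm.anterior_tip - a, u))
    for s in shifts:
        joint = lm.jaw_joint + s * length * u
        if float(np.dot(joint - a, u)) <= tip_coord:
            raise ValueError(f"shift {s} pushes the joint past the anterior tip")
        rows[s] = compute_jaw_indices(replace(lm, jaw_joint=joint)).as_series()
    table = pd.DataFrame(rows).T
    table.index.name = "shift"
    for col in base.index:
        table[f"{col}_direction"] = np.sign(table[col] - base[col]).astype(int)
    return table
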