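"""Pedal claw and skull morphometrics.

Claw shape is summarised by the arc angle subtended by the ungual's
dorsal curve (circle fit: algebraic Kasa solution refined by geometric
least squares) and by ungual lengths relative to digit III.  Skull shape
is summarised by the log-ratio rostral proportion and by relative skull
length — skull length normalised to the expectation for the bird's body
mass under a log-log allometric fit.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import least_squares

__all__ = [
    "ClawSet",
    "SkullMeasures",
    "AllometryFit",
    "RelativeSkullLengthFormula",
    "fit_claw_circle",
    "claw_features",
    "skull_features",
    "fit_allometry",
]

DIGITS = ("I", "II", "III", "IV")


@dataclass
class ClawSet:
    """Per-digit ungual length and arc angle (degrees), digits I-IV."""

    lengths: dict
    angles: dict

    def feature_vector(self) -> pd.Series:
        """Three length ratios over digit III plus the four arc angles."""
        if "III" not in self.lengths or self.lengths["III"] <= 0:
            raise ValueError("digit III is required as the ratio denominator")
        out = {}
        for d in ("I", "II", "IV"):
            if d in self.lengths:
                out[f"D{d}/DIII"] = self.lengths[d] / self.lengths["III"]
        for d in DIGITS:
            if d in self.angles:
                out[f"D{d} angle"] = self.angles[d]
        return pd.Series(out)


@dataclass
class SkullMeasures:
    """Skull length, rostrum length (mm) and body mass (g) for one bird."""

    skull_length: float
    rostrum_length: float
    body_mass: float

    def __post_init__(self):
        if not 0 < self.rostrum_length <= self.skull_length:
            raise ValueError("need 0 < rostrum_length <= skull_length")
        if self.body_mass <= 0:
            raise ValueError("body mass must be positive")


@dataclass
class AllometryFit:
    """log10-log10 OLS fit of body mass on skull length."""

    slope: float
    intercept: float
    r_squared: float

    def __post_init__(self):
        if not 0.0 <= self.r_squared <= 1.0:
            raise ValueError("R^2 must lie in [0, 1]")


class RelativeSkullLengthFormula(str, Enum):
    """Two readings of the relative-skull-length equation.

    ``POWER_OF_LOG`` (default): (log10 L)^slope / log10 M.
    ``LINEAR_IN_LOGS``: slope * log10 L / log10 M.
    """

    POWER_OF_LOG = "power_of_log"
    LINEAR_IN_LOGS = "linear_in_logs"


# ----------------------------------------------------------------------
# claws
# ----------------------------------------------------------------------

#: Radius/chord ratio beyond which a claw is treated as straight (angle 0).
_STRAIGHT_RATIO = 1e4


def fit_claw_circle(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Least-squares circle through 2D points: (centre, radius).

    Kasa's algebraic solution provides the start; a geometric
    (orthogonal-residual) refinement follows.  Raises
    ``np.linalg.LinAlgError`` for exactly collinear points.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
        raise ValueError("need an (n, 2) array with n >= 3")
    x, y = pts[:, 0], pts[:, 1]
    A = np.column_stack([x, y, np.ones_like(x)])
    b = x**2 + y**2
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    cx, cy = sol[0] / 2.0, sol[1] / 2.0
    r2 = sol[2] + cx**2 + cy**2
    if r2 <= 0 or not np.isfinite(r2):
        raise np.linalg.LinAlgError("degenerate circle fit")
    r = float(np.sqrt(r2))

    def resid(p):
        return np.hypot(x - p[0], y - p[1]) - p[2]

    fit = least_squares(resid, x0=[cx, cy, r], method="lm")
    cx, cy, r = fit.x
    return np.array([cx, cy]), float(abs(r))


def claw_arc_angle(points: np.ndarray) -> float:
    """Arc angle (degrees) subtended at the fitted centre from base to tip.

    Collinear (straight) claws return 0.
    """
    pts = np.asarray(points, dtype=float)
    chord = float(np.linalg.norm(pts[-1] - pts[0]))
    if chord == 0:
        raise ValueError("claw base and tip coincide")
    # collinearity check before fitting: zero perpendicular spread
    d = pts[-1] - pts[0]
    perp = (pts - pts[0]) @ np.array([-d[1], d[0]]) / chord
    if np.max(np.abs(perp)) < 1e-9 * chord:
        return 0.0
    try:
        centre, radius = fit_claw_circle(pts)
    except np.linalg.LinAlgError:
        return 0.0
    if radius / chord > _STRAIGHT_RATIO:
        return 0.0
    v0 = pts[0] - centre
    v1 = pts[-1] - centre
    cosang = np.dot(v0, v1) / (np.linalg.norm(v0) * np.linalg.norm(v1))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def claw_features(arcs: dict) -> tuple[ClawSet, pd.Series]:
    """Per-digit claw measures and the derived 7-variable feature vector.

    ``arcs`` maps digit names ('I'..'IV') either to (n, 2) point arrays
    along the dorsal curve (angle and chord length are then fitted) or
    to precomputed ``(ungual_length, arc_angle_deg)`` pairs.  Digit III
    is required.
    """
    if "III" not in arcs:
        raise ValueError("digit III is required")
    lengths, angles = {}, {}
    for digit, value in arcs.items():
        arr = np.asarray(value, dtype=float)
        if arr.ndim == 2:
            lengths[digit] = float(np.linalg.norm(arr[-1] - arr[0]))
            angles[digit] = claw_arc_angle(arr)
        else:
            length, angle = arr
            if length <= 0:
                raise ValueError(f"digit {digit}: ungual length must be positive")
            if not 0 <= angle < 180:
                raise ValueError(f"digit {digit}: angle must be in [0, 180)")
            lengths[digit] = float(length)
            angles[digit] = float(angle)
    claws = ClawSet(lengths=lengths, angles=angles)
    return claws, claws.feature_vector()


# ----------------------------------------------------------------------
# skull
# ----------------------------------------------------------------------

def skull_features(
    m: SkullMeasures,
    fit: AllometryFit,
    formula: RelativeSkullLengthFormula = RelativeSkullLengthFormula.POWER_OF_LOG,
) -> tuple[float, float]:
    """(log-ratio rostral proportion, relative skull length).

    The rostral proportion is log10(rostrum)/log10(skull).  Relative
    skull length scales skull length against the allometric expectation
    for the bird's mass; see :class:`RelativeSkullLengthFormula` for the
    two supported readings of the normalisation.
    """
    if m.skull_length <= 1.0:
        raise ValueError("skull length must exceed 1 mm (log10 must be positive)")
    if m.body_mass <= 1.0:
        raise ValueError("body mass must exceed 1 g (log10 must be positive)")
    if fit.slope <= 0:
        raise ValueError("allometric slope must be positive")
    log_l = np.log10(m.skull_length)
    log_m = np.log10(m.body_mass)
    proportion = float(np.log10(m.rostrum_length) / log_l)
    if formula is RelativeSkullLengthFormula.POWER_OF_LOG:
        rel = float(log_l**fit.slope / log_m)
    else:
        rel = float(fit.slope * log_l / log_m)
    return proportion, rel


def fit_allometry(measures) -> AllometryFit:
    """OLS of log10(body mass) on log10(skull length) over >= 3 birds."""
    ms = list(measures)
    if len(ms) < 3:
        raise ValueError("need at least 3 taxa")
    log_l = np.log10([m.skull_length for m in ms])
    log_m = np.log10([m.body_mass for m in ms])
    if np.ptp(log_l) == 0:
        raise ValueError("zero variance in skull length")
    res = sm.OLS(log_m, sm.add_constant(log_l)).fit()
    return AllometryFit(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        r_squared=float(res.rsquared),
    )
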