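"""SAR-based extinction projection under area loss.

If a reserve of area A0 holding S0 species shrinks to A1, the SAR power law
predicts S1 = S0·(A1/A0)^z remaining species.  Writing ``loss`` for the
fraction of area lost, the expected fraction of species lost is

    1 − (1 − loss)^z,

independent of A0.  The same relation inverts in closed form to give the
smallest area loss at which a single extinction becomes expectable.  The
exponent z can come from the plain SAR fit or from the area coefficient of
a multiple model (which holds latitude/elevation effects fixed while area
shrinks); results carry a provenance tag so both variants can be reported
side by side.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

Z_SOURCES = ("sar", "multiple_model")


def _check_z(z: float) -> None:
    if not z > 0:
        raise ValueError(f"z must be > 0, got {z}")


def extinction_fraction(z: float, loss) -> float | np.ndarray:
    """Expected fraction of species lost after losing ``loss`` of the area."""
    _check_z(z)
    loss_arr = np.asarray(loss, dtype=float)
    if np.any((loss_arr < 0) | (loss_arr > 1)):
        raise ValueError("loss must lie in [0, 1]")
    out = 1.0 - (1.0 - loss_arr) ** z
    return float(out) if np.isscalar(loss) else out


@dataclass(frozen=True)
class ExtinctionCurve:
    """Fraction of species lost along a grid of area-loss fractions."""

    group: str
    z: float
    z_source: str  # "sar" | "multiple_model"
    loss_grid: np.ndarray
    fraction_lost: np.ndarray


def extinction_curve(
    z: float,
    *,
    z_source: str = "sar",
    group: str = "",
    grid: Sequence[float] | None = None,
) -> ExtinctionCurve:
    """Vectorised extinction fractions over ``grid`` (default 0–1 by 0.01)."""
    if z_source not in Z_SOURCES:
        raise ValueError(f"z_source must be one of {Z_SOURCES}")
    loss = np.linspace(0.0, 1.0, 101) if grid is None else np.asarray(grid, dtype=float)
    frac = extinction_fraction(z, loss)
    return ExtinctionCurve(
        group=group, z=z, z_source=z_source, loss_grid=loss,
        fraction_lost=np.asarray(frac, dtype=float),
    )


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class ExtinctionCount:
    """Expected number of species lost from an initial richness of ``s0``."""

    s0: int
    loss: float
    z: float
    expected_real: float
    expected_rounded: int


def expected_losses(s0: int, z: float, loss: float) -> ExtinctionCount:
    """Expected species losses at one area-loss fraction.

    ``expected_real`` is s0·(1 − (1 − loss)^z); ``expected_rounded`` rounds
    half away from zero, matching how whole-species counts are reported.
    """
    if s0 < 1 or int(s0) != s0:
        raise ValueError(f"s0 must be a positive integer, got {s0}")
    frac = extinction_fraction(z, float(loss))
    real = s0 * frac
    return ExtinctionCount(
        s0=int(s0), loss=float(loss), z=z,
        expected_real=real, expected_rounded=_round_half_away(real),
    )


def min_loss_for_first_extinction(s0: int, z: float) -> float:
    """Smallest area-loss fraction at which one expected extinction occurs.

    Closed-form inverse of the projection: loss* = 1 − (1 − 1/s0)^(1/z).
    Undefined for s0 ≤ 1 (a single-species reserve "loses one species" only
    at total loss).
    """
    _check_z(z)
    if s0 <= 1:
        raise ValueError(f"s0 must exceed 1, got {s0}")
    return 1.0 - (1.0 - 1.0 / s0) ** (1.0 / z)
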