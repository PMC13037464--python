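"""Depth-resolved denitrification flux budget.

Four chained operations quantify how much of the nitrate diffusing down
into the anoxic water column the plagiopylid ciliates (via their
denitrifying endosymbionts) can remove:

1. volumetric rate at depth *i*:  ``R_P,i = N_P,i * R_SP``
   (cells l⁻¹ × pmol N d⁻¹ cell⁻¹ → pmol N l⁻¹ d⁻¹);
2. areal ciliate flux for the layer (*i*, *i*+1): trapezoidal rule,
   ``J_P = mean(R_P,i, R_P,i+1) * ΔH``, converted l→m³ (×1000) and
   pmol→µmol (×10⁻⁶) → µmol N m⁻² d⁻¹;
3. diffusive nitrate supply into the layer by Fick's first law,
   ``J_NO3 = D * ΔC/ΔH`` with the turbulent diffusivity *D*
   (default 27×10⁻⁶ m² s⁻¹) converted to m² d⁻¹; positive means downward
   transport, i.e. the gradient is taken shallow-minus-deep;
4. contribution per layer: ``100 * J_P / J_NO3`` where nitrate is
   supplied downward (``J_NO3 > 0``), undefined (NaN) otherwise.

The per-cell rate ``R_SP`` defaults to 12 pmol N d⁻¹ ciliate⁻¹.
Contributions above 100% are reported verbatim with a flag — they are
physically meaningful (other nitrate sources) and clipping would hide
model stress.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .abundance import CELLS_PER_L_TO_PER_M3
from .errors import ParameterError, ValidationError
from .profiles import DepthProfile, WaterColumnSnapshot

logger = logging.getLogger("redoxniche")

SECONDS_PER_DAY = 86400.0
LITRES_PER_M3 = 1000.0
UMOL_PER_PMOL = 1e-6
UMOL_PER_M3_PER_UM = 1000.0  # 1 µM = 1 µmol/l = 1000 µmol/m³

#: per-cell denitrification rate, pmol N per day per ciliate
DEFAULT_R_SP = 12.0
#: turbulent (eddy) diffusivity, m² per second
DEFAULT_DIFFUSIVITY = 27e-6


@dataclass
class FluxModelParams:
    """Parameters of the flux budget.

    ``r_sp`` in pmol N d⁻¹ ciliate⁻¹; ``diffusivity`` in m² s⁻¹ (treated
    as constant over depth); ``abundance_unit`` is ``cells_per_l`` or
    ``cells_per_m3`` and only rescales the input abundance.
    """

    r_sp: float = DEFAULT_R_SP
    diffusivity: float = DEFAULT_DIFFUSIVITY
    nitrate_unit: str = "uM"
    abundance_unit: str = "cells_per_l"

    def __post_init__(self) -> None:
        if self.r_sp <= 0:
            raise ParameterError("R_SP > 0 violated")
        if self.diffusivity <= 0:
            raise ParameterError("D > 0 violated")
        if self.abundance_unit not in ("cells_per_l", "cells_per_m3"):
            raise ParameterError(
                f"unknown abundance unit {self.abundance_unit!r}"
            )
        if self.nitrate_unit != "uM":
            raise ParameterError(f"unknown nitrate unit {self.nitrate_unit!r}")


@dataclass
class FluxBudget:
    """Per-depth rates and per-layer fluxes.

    ``depths`` has length *n*; the layer arrays have length *n* − 1, layer
    *j* spanning [``depths[j]``, ``depths[j+1]``).  ``contribution_pct``
    is NaN where there is no downward nitrate supply.
    """

    depths: np.ndarray
    r_p: np.ndarray  # pmol N l⁻¹ d⁻¹, per depth
    j_p: np.ndarray  # µmol N m⁻² d⁻¹, per layer
    j_no3: np.ndarray  # µmol N m⁻² d⁻¹, per layer
    contribution_pct: np.ndarray  # percent, per layer, NaN where undefined
    flags: list[str] = field(default_factory=list)

    @property
    def layer_midpoints(self) -> np.ndarray:
        return 0.5 * (self.depths[:-1] + self.depths[1:])

    def peak_layer(self) -> Optional[int]:
        """Index of the layer with the highest defined contribution."""
        if np.all(np.isnan(self.contribution_pct)):
            return None
        return int(np.nanargmax(self.contribution_pct))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "layer_top_m": self.depths[:-1],
                "layer_bottom_m": self.depths[1:],
                "R_P_top": self.r_p[:-1],
                "R_P_bottom": self.r_p[1:],
                "J_P": self.j_p,
                "J_NO3": self.j_no3,
                "contribution_pct": self.contribution_pct,
                "flags": self.flags,
            }
        )


def volumetric_rate(abundance, params: FluxModelParams = FluxModelParams()):
    """Volumetric denitrification rate ``R_P = N_P * R_SP`` in
    pmol N l⁻¹ d⁻¹.  ``abundance`` may be a scalar or array in the unit
    declared by ``params.abundance_unit``."""
    a = np.asarray(abundance, dtype=float)
    if np.any(a < 0):
        raise ValidationError("abundance must be >= 0")
    if params.abundance_unit == "cells_per_m3":
        a = a / CELLS_PER_L_TO_PER_M3
    r = a * params.r_sp
    return float(r) if np.isscalar(abundance) else r


def layer_flux(r_p_profile: DepthProfile) -> np.ndarray:
    """Per-layer areal flux from a volumetric-rate profile
    (trapezoidal rule), µmol N m⁻² d⁻¹."""
    if len(r_p_profile) < 2:
        raise ValidationError("layer flux needs >= 2 depths")
    r = r_p_profile.values
    dh = np.diff(r_p_profile.depths)
    j = 0.5 * (r[:-1] + r[1:]) * dh * LITRES_PER_M3 * UMOL_PER_PMOL
    for k, val in enumerate(j):
        logger.debug(
            "layer %.1f-%.1f m: J_P = %.6g umol N m^-2 d^-1",
            r_p_profile.depths[k], r_p_profile.depths[k + 1], val,
        )
    return j


def diffusive_flux(
    no3_profile: DepthProfile, params: FluxModelParams = FluxModelParams()
) -> np.ndarray:
    """Per-layer downward diffusive nitrate flux by Fick's first law,
    µmol N m⁻² d⁻¹.

    Positive values mean downward transport into the deeper layer: the
    gradient is taken as (C_shallow − C_deep)/ΔH, so a concentration
    decreasing with depth supplies nitrate to the consumers below.
    """
    if len(no3_profile) < 2:
        raise ValidationError("diffusive flux needs >= 2 depths")
    c = no3_profile.values
    dh = np.diff(no3_profile.depths)
    if np.any(dh == 0):
        raise ValidationError("zero-thickness layer")
    grad = (c[:-1] - c[1:]) / dh  # µM per metre, positive downward supply
    d_per_day = params.diffusivity * SECONDS_PER_DAY
    return d_per_day * grad * UMOL_PER_M3_PER_UM


def contribution(j_p: np.ndarray, j_no3: np.ndarray) -> tuple[np.ndarray, list[str]]:
    """Percent of the downward nitrate supply removed per layer.

    Returns ``(percentages, flags)``; the percentage is NaN where
    ``J_NO3 <= 0`` (flag ``no_downward_supply``) and values above 100 are
    kept verbatim (flag ``exceeds_100``).
    """
    j_p = np.asarray(j_p, dtype=float)
    j_no3 = np.asarray(j_no3, dtype=float)
    if j_p.shape != j_no3.shape:
        raise ValidationError(
            f"misaligned layers: {j_p.shape} vs {j_no3.shape}"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = np.where(j_no3 > 0, 100.0 * j_p / j_no3, np.nan)
    flags = []
    for k in range(len(pct)):
        parts = []
        if not j_no3[k] > 0:
            parts.append("no_downward_supply")
        elif pct[k] > 100:
            parts.append("exceeds_100")
        flags.append(";".join(parts))
    return pct, flags


def run_budget(
    snapshot: WaterColumnSnapshot,
    params: FluxModelParams = FluxModelParams(),
) -> FluxBudget:
    """Chain the four budget operations over a snapshot.

    Requires ``abundance`` and ``no3`` profiles; nitrate is resampled
    linearly onto the abundance grid (restricted to the overlap of the
    two profiles) when the grids differ.
    """
    for var in ("abundance", "no3"):
        if var not in snapshot:
            raise ValidationError(f"snapshot has no '{var}' profile")
    ab = snapshot["abundance"]
    no3 = snapshot["no3"]
    grid = ab.depths[(ab.depths >= no3.depths[0]) & (ab.depths <= no3.depths[-1])]
    if len(grid) < 2:
        raise ValidationError(
            "abundance and nitrate profiles overlap on fewer than 2 depths"
        )
    ab_vals = np.interp(grid, ab.depths, ab.values)
    no3_on_grid = no3.resample(grid)

    r_p = volumetric_rate(ab_vals, params)
    r_p_profile = DepthProfile("r_p", grid, r_p, units="pmol_N_per_l_per_d")
    j_p = layer_flux(r_p_profile)
    j_no3 = diffusive_flux(no3_on_grid, params)
    pct, flags = contribution(j_p, j_no3)

    budget = FluxBudget(grid, r_p, j_p, j_no3, pct, flags)
    peak = budget.peak_layer()
    if peak is None:
        warnings.warn(
            "no layer with downward nitrate supply; contributions undefined",
            UserWarning,
            stacklevel=2,
        )
    else:
        logger.info(
            "maximum contribution %.1f%% in layer %.1f-%.1f m",
            pct[peak], grid[peak], grid[peak + 1],
        )
    return budget
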