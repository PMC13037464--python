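"""Depth profiles of a stratified water column and their redox landmarks.

A *snapshot* bundles co-located depth profiles (O2, NO3-, NO2-, sulfide,
ciliate abundance) from one sampling campaign.  The operations here locate
the three landmarks that bound the niche of plagiopylid ciliates with
denitrifying endosymbionts:

* the **oxic-anoxic interface** -- the depth below which the oxygen reading
  stays at its constant lowest (sensor-floor) value,
* the **nitrate depletion depth** -- where nitrate falls below a
  detection-scale threshold and stays below it,
* the **sulfide onset depth** -- where detectable sulfide appears and
  persists downward,

and classify every depth into one of four redox regimes
(``oxic``, ``anoxic_nitrate_replete``, ``anoxic_nitrate_depleted``,
``euxinic``).  The contiguous anoxic, nitrate-replete, sulfide-free span
adjoining the interface is the *niche window*.

Depth convention: positive metres downward, profiles stored surface to
bottom.  Solutes are in µM, abundance in cells per litre.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

logger = logging.getLogger("redoxniche")

#: canonical variable names and their units
UNITS: dict[str, str] = {
    "o2": "uM",
    "no3": "uM",
    "no2": "uM",
    "h2s": "uM",
    "abundance": "cells_per_l",
}

#: file column <-> (variable, unit); the writer emits these headers
COLUMNS: dict[str, str] = {
    "depth_m": "depth",
    "o2_uM": "o2",
    "no3_uM": "no3",
    "no2_uM": "no2",
    "h2s_uM": "h2s",
    "abundance_cells_per_l": "abundance",
}

#: default detection limits, same units as the variable
DETECTION_LIMITS: dict[str, float] = {
    "o2": 0.1,
    "no3": 0.05,
    "no2": 0.05,
    "h2s": 0.1,
    "abundance": 0.0,
}

#: Clark-type sensor resolution at the oxygen floor (µM); default plateau
#: tolerance for interface detection.
O2_SENSOR_RESOLUTION = 0.1

#: default "still detectable" nitrate threshold (µM)
NO3_REPLETE_THRESHOLD = 0.1

#: default sulfide threshold for the euxinic classification (µM)
H2S_EUXINIC_THRESHOLD = 1.0


class LandmarkWarning(UserWarning):
    """A landmark was detected under a degenerate condition."""


@dataclass
class DepthProfile:
    """One measured variable on a strictly increasing depth grid.

    Parameters
    ----------
    variable :
        One of ``o2``, ``no3``, ``no2``, ``h2s``, ``abundance``.
    depths :
        Depths in metres, strictly increasing downward.
    values :
        Measurements, same length as ``depths``; non-negative.  Values
        below ``detection_limit`` are flagged in ``below_detection``.
    detection_limit :
        Smallest reliably detectable value, same units as ``values``.
    below_detection :
        Optional boolean mask; derived from ``detection_limit`` if omitted.
    """

    variable: str
    depths: np.ndarray
    values: np.ndarray
    detection_limit: float = 0.0
    below_detection: Optional[np.ndarray] = None
    units: str = ""

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.depths.ndim != 1 or self.values.ndim != 1:
            raise ValidationError("depths and values must be 1-D arrays")
        if len(self.depths) != len(self.values):
            raise ValidationError(
                f"profile '{self.variable}': {len(self.depths)} depths but "
                f"{len(self.values)} values"
            )
        if len(self.depths) == 0:
            raise ValidationError(f"profile '{self.variable}' is empty")
        d = np.diff(self.depths)
        if np.any(d <= 0):
            bad = self.depths[1:][d <= 0][0]
            raise ValidationError(
                f"profile '{self.variable}': depths not strictly increasing "
                f"at {bad} m"
            )
        if self.detection_limit < 0:
            raise ValidationError("detection_limit must be >= 0")
        if np.any(self.values < 0):
            raise ValidationError(
                f"profile '{self.variable}' contains negative values; "
                "store below-detection readings as 0 with the flag set"
            )
        if self.below_detection is None:
            self.below_detection = self.values < self.detection_limit
        else:
            self.below_detection = np.asarray(self.below_detection, dtype=bool)
            if len(self.below_detection) != len(self.values):
                raise ValidationError("below_detection mask length mismatch")
        if not self.units:
            self.units = UNITS.get(self.variable, "")

    def __len__(self) -> int:
        return len(self.depths)

    def resample(self, new_depths: np.ndarray) -> "DepthProfile":
        """Linearly interpolate onto ``new_depths`` (no extrapolation beyond
        the endpoints; edge values are held)."""
        new_depths = np.asarray(new_depths, dtype=float)
        vals = np.interp(new_depths, self.depths, self.values)
        flags = np.interp(
            new_depths, self.depths, self.below_detection.astype(float)
        ) > 0.5
        return DepthProfile(
            self.variable, new_depths, vals, self.detection_limit, flags, self.units
        )


@dataclass
class WaterColumnSnapshot:
    """A dated bundle of co-located profiles for one lake campaign.

    ``ground_truth`` carries the generating parameters of a synthetic
    snapshot for recovery tests; analysis code never reads it.
    """

    lake: str
    campaign_date: str
    profiles: dict[str, DepthProfile]
    ground_truth: object = None

    def __post_init__(self) -> None:
        if not self.profiles:
            raise ValidationError("snapshot must contain at least one profile")
        tops = [p.depths[0] for p in self.profiles.values()]
        bottoms = [p.depths[-1] for p in self.profiles.values()]
        if max(tops) > min(bottoms):
            raise ValidationError(
                "snapshot profiles do not cover overlapping depth ranges"
            )

    def __getitem__(self, variable: str) -> DepthProfile:
        return self.profiles[variable]

    def __contains__(self, variable: str) -> bool:
        return variable in self.profiles


@dataclass
class RedoxClassification:
    """Per-depth redox regime labels plus the landmark depths."""

    interface_depth: float
    no3_depletion_depth: Optional[float]
    sulfide_onset_depth: Optional[float]
    depths: np.ndarray
    per_depth_class: np.ndarray
    niche_window: Optional[tuple[float, float]]
    warnings: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"depth_m": self.depths, "redox_class": self.per_depth_class}
        )


@dataclass
class Landmarks:
    """The three landmark depths of one snapshot."""

    interface_depth: float
    no3_depletion_depth: Optional[float]
    sulfide_onset_depth: Optional[float]


# ---------------------------------------------------------------------------
# snapshot I/O (delimited text)
# ---------------------------------------------------------------------------

def read_snapshot(
    path,
    lake: str = "",
    campaign_date: str = "",
    columns: Optional[Mapping[str, str]] = None,
    detection_limits: Optional[Mapping[str, float]] = None,
    sep: Optional[str] = None,
) -> WaterColumnSnapshot:
    """Read a snapshot from a delimited text file.

    The file needs a ``depth_m`` column plus at least one variable column
    named as in :data:`COLUMNS` (or remapped via ``columns``, a mapping of
    file column name to canonical variable).  Rows are sorted by depth;
    duplicated depths are an error; missing values are retained as gaps
    (dropped per profile); negative solute readings are stored as 0 with
    the below-detection flag set.
    """
    colmap = dict(COLUMNS)
    if columns:
        colmap.update(columns)
    limits = dict(DETECTION_LIMITS)
    if detection_limits:
        limits.update(detection_limits)

    df = pd.read_csv(path, sep=sep, engine="python", comment="#")
    unknown = [c for c in df.columns if c not in colmap]
    if unknown:
        raise FormatError(
            f"unknown column/unit string(s) {unknown!r}; expected one of "
            f"{sorted(colmap)} or an explicit mapping"
        )
    df = df.rename(columns=colmap)
    if "depth" not in df.columns:
        raise FormatError("no depth column (expected 'depth_m')")
    df = df.sort_values("depth", kind="stable")
    dup = df["depth"].duplicated()
    if dup.any():
        raise ValidationError(
            f"duplicated depth row at {df['depth'][dup].iloc[0]} m"
        )

    profiles: dict[str, DepthProfile] = {}
    for var in df.columns:
        if var == "depth":
            continue
        sub = df[["depth", var]].dropna()
        if sub.empty:
            continue
        vals = sub[var].to_numpy(dtype=float)
        limit = limits.get(var, 0.0)
        flags = vals < limit
        if np.any(vals < 0):
            flags = flags | (vals < 0)
            vals = np.clip(vals, 0.0, None)
        profiles[var] = DepthProfile(
            var, sub["depth"].to_numpy(dtype=float), vals, limit, flags
        )
    name = lake or getattr(path, "stem", str(path))
    return WaterColumnSnapshot(name, campaign_date, profiles)


def write_snapshot(snapshot: WaterColumnSnapshot, path, sep: str = "\t") -> None:
    """Write a snapshot as delimited text, one row per depth, using the
    canonical column headers.  Profiles are aligned on the union of their
    depth grids; depths missing from a profile are left blank."""
    inv = {v: k for k, v in COLUMNS.items()}
    all_depths = np.unique(
        np.concatenate([p.depths for p in snapshot.profiles.values()])
    )
    data: dict[str, object] = {"depth_m": all_depths}
    for var in UNITS:
        if var not in snapshot.profiles:
            continue
        p = snapshot.profiles[var]
        col = np.full(len(all_depths), np.nan)
        idx = np.searchsorted(all_depths, p.depths)
        col[idx] = p.values
        data[inv[var]] = col
    pd.DataFrame(data).to_csv(path, sep=sep, index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# landmark detection
# ---------------------------------------------------------------------------

def _trailing_run(mask: np.ndarray) -> int:
    """Length of the run of True values at the end of ``mask``."""
    if mask.all():
        return len(mask)
    last_false = np.nonzero(~mask)[0][-1]
    return len(mask) - last_false - 1


def _interface_with_status(
    o2_profile: DepthProfile, tolerance: float
) -> tuple[float, str]:
    """Interface depth plus a status: ``ok``, ``no_plateau`` (oxygen never
    settles at a floor; deepest depth returned) or ``all_floor`` (entire
    column within tolerance of the minimum; shallowest depth returned)."""
    if len(o2_profile) < 3:
        raise ValidationError("interface detection needs >= 3 depths")
    if tolerance < 0:
        raise ValidationError("tolerance must be >= 0")
    v = o2_profile.values
    run = _trailing_run(v <= v.min() + tolerance)
    if run == len(v):
        return float(o2_profile.depths[0]), "all_floor"
    if run < 2:
        return float(o2_profile.depths[-1]), "no_plateau"
    return float(o2_profile.depths[len(v) - run]), "ok"


def detect_interface(o2_profile: DepthProfile, tolerance: float = O2_SENSOR_RESOLUTION) -> float:
    """Depth of the oxic-anoxic interface.

    Operationalises "the depth below which oxygen concentrations remained
    at a constant lowest value" as a plateau rule: the shallowest depth
    ``d*`` such that every reading at or below ``d*`` is within
    ``tolerance`` of the profile minimum.  A plateau needs at least two
    depths; otherwise the deepest depth is returned with a
    :class:`LandmarkWarning`.  An all-constant profile returns the
    shallowest depth, also with a warning (entire column at the floor).

    Parameters
    ----------
    o2_profile :
        Oxygen profile with at least three depths.
    tolerance :
        Plateau tolerance in µM (default: sensor resolution, 0.1 µM).
        For noisy data widen it to cover the noise band of the floor
        signal (see :func:`recover_landmarks`).
    """
    d, status = _interface_with_status(o2_profile, tolerance)
    if status == "all_floor":
        warnings.warn(
            "entire column within tolerance of the minimum; the whole "
            "profile is at the oxygen floor",
            LandmarkWarning,
            stacklevel=2,
        )
    elif status == "no_plateau":
        warnings.warn(
            "no oxygen plateau of length >= 2; returning the deepest depth",
            LandmarkWarning,
            stacklevel=2,
        )
    else:
        logger.info("oxic-anoxic interface detected at %.1f m", d)
    return d


def find_depletion_depth(
    profile: DepthProfile,
    threshold: float = NO3_REPLETE_THRESHOLD,
    below: Optional[float] = None,
) -> Optional[float]:
    """Shallowest depth where ``profile`` falls below ``threshold`` and
    stays below it for all deeper measured depths; ``None`` if it never
    does.  ``below`` restricts the search to depths >= that value (pass
    the interface depth to search only the anoxic column)."""
    if len(profile) == 0:
        raise ValidationError("empty profile")
    if threshold < profile.detection_limit:
        warnings.warn(
            f"threshold {threshold} below detection limit "
            f"{profile.detection_limit}; result reflects noise",
            LandmarkWarning,
            stacklevel=2,
        )
    depths, values = profile.depths, profile.values
    if below is not None:
        keep = depths >= below
        depths, values = depths[keep], values[keep]
        if len(depths) == 0:
            return None
    run = _trailing_run(values < threshold)
    if run == 0:
        return None
    d = float(depths[len(values) - run])
    logger.info("%s depletion depth at %.1f m", profile.variable, d)
    return d


def find_onset_depth(
    h2s_profile: DepthProfile, threshold: float = H2S_EUXINIC_THRESHOLD
) -> Optional[float]:
    """Shallowest depth where sulfide is at or above ``threshold`` and
    remains so for all deeper depths; ``None`` if never reached.

    A detected signal is required: readings flagged below detection (in
    particular zeros) never trigger the onset, even at ``threshold = 0``.
    """
    if len(h2s_profile) == 0:
        raise ValidationError("empty profile")
    if threshold < 0:
        raise ValidationError("threshold must be >= 0")
    v = h2s_profile.values
    detected = (v > 0) & ~h2s_profile.below_detection
    run = _trailing_run((v >= threshold) & detected)
    if run == 0:
        return None
    d = float(h2s_profile.depths[len(v) - run])
    logger.info("sulfide onset at %.1f m", d)
    return d


def recover_landmarks(
    snapshot: WaterColumnSnapshot,
    o2_resolution: float = O2_SENSOR_RESOLUTION,
    noise_sd_fraction: float = 0.0,
    no3_threshold: float = NO3_REPLETE_THRESHOLD,
    h2s_threshold: Optional[float] = None,
) -> Landmarks:
    """Detect all three landmarks with noise-aware settings.

    The interface plateau tolerance is widened to
    ``o2_resolution + 4 * noise_sd_fraction * floor`` where ``floor`` is the
    observed oxygen minimum: multiplicative sensor noise of relative
    standard deviation *f* spreads floor readings over roughly ±2*f*·floor,
    so this covers the min-to-max spread of the plateau.  Sulfide onset is
    detected at the sulfide detection limit (onset = first *detectable*
    sulfide); the 1 µM default of :func:`classify_redox` concerns the
    euxinic classification, not the landmark.
    """
    if "o2" not in snapshot:
        raise ValidationError("snapshot has no 'o2' profile")
    o2 = snapshot["o2"]
    tol = o2_resolution + 4.0 * noise_sd_fraction * float(o2.values.min())
    interface = detect_interface(o2, tol)
    depletion = None
    if "no3" in snapshot:
        depletion = find_depletion_depth(
            snapshot["no3"], no3_threshold, below=interface
        )
    onset = None
    if "h2s" in snapshot:
        h2s = snapshot["h2s"]
        thr = h2s_threshold if h2s_threshold is not None else max(
            h2s.detection_limit, 1e-12
        )
        onset = find_onset_depth(h2s, thr)
        if onset is not None:
            onset = _refine_onset(h2s, onset)
    return Landmarks(interface, depletion, onset)


def _refine_onset(h2s: DepthProfile, onset: float) -> float:
    """Back-extrapolate the near-linear sulfide rise to zero signal.

    The first detected reading sits below the true appearance depth by up
    to one sampling interval plus the detection-limit offset; the local
    slope of the rise recovers both.  The estimate is clipped to the
    sampling interval straddling the detected depth."""
    d, v = h2s.depths, h2s.values
    i = int(np.searchsorted(d, onset))
    if i + 1 >= len(d):
        return onset
    slope = (v[i + 1] - v[i]) / (d[i + 1] - d[i])
    if slope <= 0:
        return onset
    est = d[i] - v[i] / slope
    lower = d[i - 1] if i > 0 else d[0]
    return float(np.clip(est, lower, d[i]))


# ---------------------------------------------------------------------------
# redox classification
# ---------------------------------------------------------------------------

def classify_redox(
    snapshot: WaterColumnSnapshot,
    o2_tolerance: float = O2_SENSOR_RESOLUTION,
    no3_threshold: float = NO3_REPLETE_THRESHOLD,
    h2s_threshold: float = H2S_EUXINIC_THRESHOLD,
) -> RedoxClassification:
    """Label every grid depth with its redox regime and derive the niche
    window.

    Rules, applied on the oxygen profile's grid:

    * ``oxic`` above the interface;
    * ``euxinic`` at or below the sulfide onset;
    * ``anoxic_nitrate_replete`` below the interface, above the onset,
      with nitrate at or above ``no3_threshold`` (a missing nitrate
      profile counts as replete: there is no evidence of depletion);
    * ``anoxic_nitrate_depleted`` otherwise.

    The niche window is the contiguous ``anoxic_nitrate_replete`` span
    adjoining the interface, ``None`` if empty.  When oxygen never
    settles at a floor (no plateau), the column is treated as fully oxic
    and no window exists; the degenerate interface depth is still
    reported, with a warning recorded.
    """
    if "o2" not in snapshot:
        raise ValidationError("snapshot has no 'o2' profile")
    o2 = snapshot["o2"]
    warns: list[str] = []
    interface, status = _interface_with_status(o2, o2_tolerance)
    if status == "no_plateau":
        warns.append(
            "no oxygen plateau: column treated as fully oxic, no niche window"
        )
    elif status == "all_floor":
        warns.append("entire column at the oxygen floor")
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", LandmarkWarning)
        depletion = None
        if "no3" in snapshot:
            depletion = find_depletion_depth(
                snapshot["no3"], no3_threshold, below=interface
            )
        onset = None
        if "h2s" in snapshot:
            onset = find_onset_depth(snapshot["h2s"], h2s_threshold)
    warns.extend(str(w.message) for w in caught)

    grid = o2.depths
    labels = np.full(len(grid), "anoxic_nitrate_depleted", dtype=object)
    if status == "no_plateau":
        anoxic = np.zeros(len(grid), dtype=bool)
        labels[:] = "oxic"
    else:
        anoxic = grid >= interface
        labels[grid < interface] = "oxic"
    if onset is not None:
        euxinic = grid >= onset
        labels[anoxic & euxinic] = "euxinic"
        anoxic = anoxic & ~euxinic
    if "no3" in snapshot:
        no3 = snapshot["no3"].resample(grid)
        replete = (no3.values >= no3_threshold) & ~no3.below_detection
    else:
        replete = np.ones(len(grid), dtype=bool)
    labels[anoxic & replete] = "anoxic_nitrate_replete"

    niche_window = None
    first_anoxic = np.searchsorted(grid, interface)
    if first_anoxic < len(grid) and labels[first_anoxic] == "anoxic_nitrate_replete":
        i = first_anoxic
        while i + 1 < len(grid) and labels[i + 1] == "anoxic_nitrate_replete":
            i += 1
        niche_window = (float(grid[first_anoxic]), float(grid[i]))
        logger.info("niche window: %.1f-%.1f m", *niche_window)

    return RedoxClassification(
        interface_depth=interface,
        no3_depletion_depth=depletion,
        sulfide_onset_depth=onset,
        depths=grid,
        per_depth_class=np.asarray(labels),
        niche_window=niche_window,
        warnings=warns,
    )


def population_in_window(
    abundance: DepthProfile, classification: RedoxClassification
) -> Optional[float]:
    """Fraction of the depth-integrated population inside the niche window.

    Trapezoid-integrated abundance within the window divided by the
    trapezoid integral over the full profile.  Returns 0.0 when the window
    is absent and ``None`` (undefined) when the total integral is zero.
    Grids need not match: the window bounds cut the abundance profile with
    linear interpolation at the edges.
    """
    total = float(np.trapezoid(abundance.values, abundance.depths))
    if total <= 0.0:
        return None
    if classification.niche_window is None:
        return 0.0
    top, bottom = classification.niche_window
    top = max(top, float(abundance.depths[0]))
    bottom = min(bottom, float(abundance.depths[-1]))
    if bottom <= top:
        return 0.0
    inside = (abundance.depths > top) & (abundance.depths < bottom)
    d = np.concatenate(([top], abundance.depths[inside], [bottom]))
    v = np.interp(d, abundance.depths, abundance.values)
    return float(np.trapezoid(v, d) / total)
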