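"""Synthetic stratified-lake snapshots with known ground truth.

The generator emulates a single late-summer snapshot of a meromictic lake
with an anoxic, nitrate-bearing hypolimnion and (optionally) sulfidic
bottom waters — the habitat of plagiopylid ciliates carrying denitrifying
endosymbionts:

* oxygen follows a logistic decline from the surface value to a sensor
  floor; the curve is positioned so that the reading first comes within
  0.1 µM (one sensor resolution) of the floor exactly at
  ``oxycline_depth`` — the parameter *is* the oxic-anoxic interface as
  operationally defined (depth below which O2 stays at its constant
  lowest value);
* nitrate is near zero in oxygenated surface waters, ramps up to
  ``no3_at_interface`` at the interface and declines linearly to zero at
  ``no3_depletion_depth``;
* sulfide is absent above ``sulfide_onset_depth`` and increases linearly
  below it;
* host-ciliate abundance is a Gaussian peak inside the anoxic
  nitrate-replete window.

Concentrations receive multiplicative lognormal noise (mean 1, relative
standard deviation ``noise_sd_fraction``), so they stay non-negative and
the error scales with signal, as for CTD-type sensors.  The abundance
profile is left noise-free: microscopy counting noise is modelled
separately by :func:`sample_filter_counts` (Poisson counts on filter
sections).  Generating parameters travel with the snapshot in
``ground_truth`` for recovery tests and are never read by analysis code.

Defaults emulate a late-summer snapshot of a deep meromictic lake
with euxinic bottom waters: interface at
85 m, nitrate depletion and sulfide onset at 110 m, abundance peaking at
8400 cells per litre at 95 m in a 250 m column.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, replace
from typing import Optional

import numpy as np
from scipy.special import expit

from .abundance import FilterCountRecord
from .errors import ParameterError, ValidationError
from .profiles import (
    DETECTION_LIMITS,
    O2_SENSOR_RESOLUTION,
    DepthProfile,
    WaterColumnSnapshot,
    write_snapshot,
)

#: the oxygen reading reaches floor + INTERFACE_EPSILON at oxycline_depth
INTERFACE_EPSILON = O2_SENSOR_RESOLUTION


@dataclass
class SyntheticLakeParams:
    """Generative parameters of one synthetic lake snapshot.

    Units: depths and widths in metres, solutes in µM, abundance in cells
    per litre, volumes in litres, ``sulfide_slope`` in µM per metre.
    """

    max_depth: float = 250.0
    grid_step: float = 2.5
    o2_surface: float = 300.0
    oxycline_depth: float = 85.0
    oxycline_width: float = 3.0
    o2_floor: float = 0.5
    no3_at_interface: float = 5.0
    no3_depletion_depth: float = 110.0
    sulfide_onset_depth: Optional[float] = 110.0
    sulfide_slope: float = 0.086
    peak_depth: float = 95.0
    peak_abundance: float = 8400.0
    peak_width: float = 5.0
    count_volume: float = 0.5
    section_fraction: float = 1.0 / 16.0
    noise_sd_fraction: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        """Raise :class:`ParameterError` naming the violated invariant."""
        if self.grid_step <= 0:
            raise ParameterError("grid_step > 0 violated")
        if not self.oxycline_depth < self.no3_depletion_depth <= self.max_depth:
            raise ParameterError(
                "oxycline_depth < no3_depletion_depth <= max_depth violated"
            )
        if (
            self.sulfide_onset_depth is not None
            and self.sulfide_onset_depth <= self.oxycline_depth
        ):
            raise ParameterError(
                "sulfide_onset_depth > oxycline_depth violated"
            )
        if self.peak_abundance < 0:
            raise ParameterError("peak_abundance >= 0 violated")
        if not 0 < self.section_fraction <= 1:
            raise ParameterError("0 < section_fraction <= 1 violated")
        if self.count_volume <= 0:
            raise ParameterError("count_volume > 0 violated")
        if self.oxycline_width <= 0:
            raise ParameterError("oxycline_width > 0 violated")
        if self.peak_width <= 0:
            raise ParameterError("peak_width > 0 violated")
        if self.o2_floor < 0 or self.o2_surface <= self.o2_floor + INTERFACE_EPSILON:
            raise ParameterError(
                "o2_surface > o2_floor + interface epsilon violated"
            )
        if self.noise_sd_fraction < 0:
            raise ParameterError("noise_sd_fraction >= 0 violated")
        if self.sulfide_slope < 0:
            raise ParameterError("sulfide_slope >= 0 violated")

    def grid(self) -> np.ndarray:
        n = int(round(self.max_depth / self.grid_step))
        return np.round(np.arange(n + 1) * self.grid_step, 9)


# ---------------------------------------------------------------------------
# closed-form ground-truth curves
# ---------------------------------------------------------------------------

def o2_curve(z: np.ndarray, p: SyntheticLakeParams) -> np.ndarray:
    """Logistic oxygen decline; equals ``o2_floor + INTERFACE_EPSILON``
    exactly at ``oxycline_depth``."""
    span = p.o2_surface - p.o2_floor
    centre = p.oxycline_depth - p.oxycline_width * math.log(
        span / INTERFACE_EPSILON - 1.0
    )
    return p.o2_floor + span * expit(-(np.asarray(z, float) - centre) / p.oxycline_width)


def no3_curve(z: np.ndarray, p: SyntheticLakeParams) -> np.ndarray:
    """Piecewise-linear nitrate: ~0 in oxic waters, ``no3_at_interface``
    at the interface, linear decline to 0 at ``no3_depletion_depth``."""
    ramp_top = max(0.0, p.oxycline_depth - 3.0 * p.oxycline_width)
    xp = [ramp_top, p.oxycline_depth, p.no3_depletion_depth]
    fp = [0.0, p.no3_at_interface, 0.0]
    return np.interp(np.asarray(z, float), xp, fp, left=0.0, right=0.0)


def h2s_curve(z: np.ndarray, p: SyntheticLakeParams) -> np.ndarray:
    """Sulfide: zero above the onset, rising linearly below."""
    z = np.asarray(z, float)
    if p.sulfide_onset_depth is None:
        return np.zeros_like(z)
    return np.maximum(0.0, p.sulfide_slope * (z - p.sulfide_onset_depth))


def abundance_curve(z: np.ndarray, p: SyntheticLakeParams) -> np.ndarray:
    """Gaussian host-ciliate abundance peak (cells per litre)."""
    z = np.asarray(z, float)
    return p.peak_abundance * np.exp(
        -0.5 * ((z - p.peak_depth) / p.peak_width) ** 2
    )


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _lognormal_factors(rng: np.random.Generator, f: float, n: int) -> np.ndarray:
    # mean exactly 1, relative sd exactly f
    sigma2 = math.log(1.0 + f * f)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=math.sqrt(sigma2), size=n)


def generate_snapshot(params: SyntheticLakeParams) -> WaterColumnSnapshot:
    """Generate a snapshot on a regular depth grid.

    Deterministic for a given ``params.seed``; with
    ``noise_sd_fraction = 0`` every concentration equals its closed-form
    curve exactly at every grid depth.
    """
    params.validate()
    z = params.grid()
    rng = np.random.default_rng([params.seed, 0])
    profiles: dict[str, DepthProfile] = {}
    for var, curve in (("o2", o2_curve), ("no3", no3_curve), ("h2s", h2s_curve)):
        vals = curve(z, params)
        if params.noise_sd_fraction > 0:
            vals = vals * _lognormal_factors(rng, params.noise_sd_fraction, len(z))
        profiles[var] = DepthProfile(var, z, vals, DETECTION_LIMITS[var])
    profiles["abundance"] = DepthProfile(
        "abundance", z, abundance_curve(z, params), DETECTION_LIMITS["abundance"]
    )
    return WaterColumnSnapshot(
        lake="synthetic",
        campaign_date="",
        profiles=profiles,
        ground_truth=replace(params),
    )


def sample_filter_counts(
    snapshot: WaterColumnSnapshot,
    params: SyntheticLakeParams,
    rng: Optional[np.random.Generator] = None,
) -> list[FilterCountRecord]:
    """Poisson-sample microscopy counts from the snapshot's abundance.

    For each grid depth the counted cells are drawn Poisson with mean
    ``true_abundance * count_volume * section_fraction`` — the expected
    number of cells on one counted filter section.  Reproducible from
    ``params.seed`` (an independent stream from the profile noise) unless
    an explicit ``rng`` is given.
    """
    if "abundance" not in snapshot:
        raise ValidationError("snapshot has no 'abundance' profile")
    if params.count_volume <= 0:
        raise ParameterError("count_volume > 0 violated")
    if not 0 < params.section_fraction <= 1:
        raise ParameterError("0 < section_fraction <= 1 violated")
    if rng is None:
        rng = np.random.default_rng([params.seed, 1])
    prof = snapshot["abundance"]
    means = prof.values * params.count_volume * params.section_fraction
    counts = rng.poisson(means)
    return [
        FilterCountRecord(
            depth=float(d),
            counted=int(c),
            section_fraction=params.section_fraction,
            filtered_volume=params.count_volume,
        )
        for d, c in zip(prof.depths, counts)
    ]


def draw_random_params(
    rng: np.random.Generator,
    noise_sd_fraction: float = 0.0,
) -> SyntheticLakeParams:
    """Draw random but field-plausible generator parameters.

    Used by landmark-recovery checks: ranges keep the nitrate decline and
    sulfide rise steep enough that the landmark crossing sits within one
    grid step of the generating depth (see the methods note).
    """
    oxycline = rng.uniform(60.0, 150.0)
    depletion = oxycline + rng.uniform(10.0, 50.0)
    onset = rng.uniform(oxycline + 10.0, 230.0)
    return SyntheticLakeParams(
        max_depth=250.0,
        grid_step=2.5,
        o2_surface=rng.uniform(200.0, 350.0),
        oxycline_depth=oxycline,
        oxycline_width=rng.uniform(1.0, 4.0),
        o2_floor=rng.uniform(0.3, 0.8),
        no3_at_interface=rng.uniform(3.0, 6.0),
        no3_depletion_depth=depletion,
        sulfide_onset_depth=onset,
        sulfide_slope=rng.uniform(0.05, 0.5),
        peak_depth=min(depletion, onset) - 5.0,
        peak_abundance=rng.uniform(2000.0, 35000.0),
        peak_width=rng.uniform(3.0, 8.0),
        noise_sd_fraction=noise_sd_fraction,
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def write_sidecar(params: SyntheticLakeParams, path) -> None:
    """Write the generating parameters as key-value text next to a
    snapshot file."""
    with open(path, "w") as fh:
        for key, val in asdict(params).items():
            fh.write(f"{key} = {val}\n")


def write_synthetic(params: SyntheticLakeParams, path) -> WaterColumnSnapshot:
    """Generate, write the snapshot table plus its parameter sidecar, and
    return the snapshot."""
    snap = generate_snapshot(params)
    write_snapshot(snap, path)
    write_sidecar(params, f"{path}.params")
    return snap
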