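"""Synthetic cotton seasons with known phenology schedules.

The generator produces, for a configurable number of fields, (a) a
stage schedule drawn from agronomic duration ranges, (b) daily weather
with a sinusoidal annual temperature cycle, (c) Sentinel-2-like band
reflectance time series whose shape follows the schedule (double-
logistic canopy green-up/senescence plus stage-specific flowering and
boll-opening signatures), with sensor noise and cloud gaps, and (d)
two-label ground observations emulating the field-visit protocol: the
prevailing stage is always recorded, and within a band around each
stage onset the adjacent stage is recorded as secondary with a linearly
interpolated prevalence.

Stage duration ranges (days): RE 15-30, LD 35-45, S 15-30, F 20-40,
BD 25-45, BO 10-20; full cycles are resampled until the total lies in
the 150-200 day window typical for cotton in Greece.  A field-level
thermal factor couples warm fields to faster development, so calendar
date alone does not determine the stage — the within-season model must
pick the signal up from the imagery and the accumulated thermal time.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field as dc_field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .stages import Metaclass, PhenologyStage

__all__ = [
    "DURATION_RANGES",
    "SimConfig",
    "StageSchedule",
    "SeasonData",
    "simulate_schedule",
    "simulate_weather",
    "simulate_bands",
    "simulate_observations",
    "simulate_season",
    "truth_metaclasses",
]

#: Stage duration ranges in days.
DURATION_RANGES: Dict[PhenologyStage, Tuple[int, int]] = {
    PhenologyStage.RE: (15, 30),
    PhenologyStage.LD: (35, 45),
    PhenologyStage.S: (15, 30),
    PhenologyStage.F: (20, 40),
    PhenologyStage.BD: (25, 45),
    PhenologyStage.BO: (10, 20),
}

TOTAL_CYCLE_RANGE = (150, 200)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated season."""

    n_fields: int = 40
    sowing_window: Tuple[int, int] = (105, 135)
    acquisition_range: Tuple[int, int] = (100, 300)
    acquisition_cadence: int = 5
    visit_cadence: int = 10
    transition_band: int = 7  # days around an onset where both stages show
    reflectance_sd: float = 0.015
    temp_sd: float = 1.5
    cloud_gap_prob: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.cloud_gap_prob <= 1.0:
            raise ValueError("cloud_gap_prob must lie in [0, 1]")
        if self.visit_cadence < 1 or self.acquisition_cadence < 1:
            raise ValueError("cadences must be >= 1 day")
        if self.sowing_window[0] > self.sowing_window[1]:
            raise ValueError("empty sowing window")


@dataclass(frozen=True)
class StageSchedule:
    """Ground-truth phenology calendar for one field."""

    field_id: str
    sowing_doy: int
    onsets: Dict[PhenologyStage, int]  # onset DoY of each stage; RE = sowing
    harvest_doy: int

    def stage_at(self, doy: int) -> Optional[PhenologyStage]:
        """Prevailing stage at ``doy``; None outside [sowing, harvest]."""
        if doy < self.sowing_doy or doy > self.harvest_doy:
            return None
        current = PhenologyStage.RE
        for stage in PhenologyStage:
            if doy >= self.onsets[stage]:
                current = stage
        return current

    def metaclass_at(
        self, doy: int, transition_band: int = 7, min_prevalence: float = 5.0
    ) -> Optional[Metaclass]:
        """Primary(+secondary) state at ``doy`` under the visit protocol.

        Within ``transition_band`` days of an onset the adjacent stage is
        present too; its prevalence ramps linearly from 0 at the band
        edges to 100 at the onset itself, and it is reported as secondary
        when it reaches ``min_prevalence`` percent.
        """
        obs = self.observation_at(doy, transition_band, min_prevalence)
        if obs is None:
            return None
        primary, _, secondary, _ = obs
        return Metaclass(primary, secondary)

    def observation_at(
        self, doy: int, transition_band: int = 7, min_prevalence: float = 5.0
    ):
        """(primary, prevalence, secondary, prevalence) at ``doy``, or None."""
        primary = self.stage_at(doy)
        if primary is None:
            return None
        secondary = None
        sec_prev = 0.0
        for stage in list(PhenologyStage)[1:]:  # internal onsets LD..BO
            onset = self.onsets[stage]
            if abs(doy - onset) <= transition_band:
                u = (doy - (onset - transition_band)) / (2.0 * transition_band)
                prevalence = 100.0 * (1.0 - abs(2.0 * u - 1.0))
                if prevalence >= min_prevalence:
                    earlier = PhenologyStage(int(stage) - 1)
                    secondary = earlier if doy >= onset else stage
                    sec_prev = prevalence
                break
        return primary, 100.0, secondary, (sec_prev if secondary else None)


@dataclass
class SeasonData:
    """One simulated season: truth schedules plus all observable tables."""

    config: SimConfig
    schedules: List[StageSchedule]
    bands: pd.DataFrame
    weather: pd.DataFrame
    observations: pd.DataFrame
    field_offsets: Dict[str, float] = dc_field(default_factory=dict)

    def schedule(self, field_id: str) -> StageSchedule:
        return next(s for s in self.schedules if s.field_id == field_id)


def _draw_schedule(
    field_id: str, config: SimConfig, rng: np.random.Generator, thermal: float
) -> StageSchedule:
    low, high = config.sowing_window
    sowing = int(rng.integers(low, high + 1))
    scale = 1.0 - 0.04 * thermal  # warm fields (+thermal degC) develop faster
    for _ in range(200):
        durations = {}
        for stage, (dmin, dmax) in DURATION_RANGES.items():
            d = rng.uniform(dmin, dmax) * scale
            durations[stage] = int(round(min(max(d, dmin), dmax)))
        total = sum(durations.values())
        if TOTAL_CYCLE_RANGE[0] <= total <= TOTAL_CYCLE_RANGE[1]:
            break
    else:  # pragma: no cover - ranges make this unreachable in practice
        raise RuntimeError("could not sample a feasible schedule")
    onsets = {}
    t = sowing
    for stage in PhenologyStage:
        onsets[stage] = t
        t += durations[stage]
    return StageSchedule(field_id, sowing, onsets, harvest_doy=t)


def simulate_schedule(config: SimConfig) -> List[StageSchedule]:
    """Draw one stage schedule per field (see module docstring)."""
    rng = np.random.default_rng(config.seed)
    schedules = []
    for i in range(config.n_fields):
        thermal = rng.uniform(-1.5, 1.5)
        schedules.append(_draw_schedule(f"f{i:03d}", config, rng, thermal))
    return schedules


def simulate_weather(
    config: SimConfig,
    field_id: str,
    thermal_offset: float = 0.0,
    rng: Optional[np.random.Generator] = None,
    doy_range: Tuple[int, int] = (60, 310),
) -> pd.DataFrame:
    """Daily weather series for one field.

    Air temperature follows a sinusoidal annual cycle (Mediterranean
    amplitude) plus AR(1) noise and the field's thermal offset; surface
    and soil temperature are damped/lagged transforms; radiation peaks
    near the solstice; precipitation is a sparse seeded process feeding
    a decaying soil-moisture reservoir.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    doys = np.arange(doy_range[0], doy_range[1] + 1)
    n = doys.size
    seasonal = 14.0 + 13.0 * np.sin(2.0 * np.pi * (doys - 110) / 365.0)
    ar = np.zeros(n)
    eps = rng.normal(0.0, config.temp_sd, n)
    for t in range(1, n):
        ar[t] = 0.7 * ar[t - 1] + eps[t]
    t2m_mean = seasonal + thermal_offset + ar
    diurnal = np.clip(rng.normal(10.0, 1.0, n), 4.0, None)
    t2m_min = t2m_mean - diurnal / 2.0
    t2m_max = t2m_mean + diurnal / 2.0

    surf_mean = t2m_mean + 2.0
    surf_range = diurnal * 1.2
    tsurf_min, tsurf_max = surf_mean - surf_range / 2, surf_mean + surf_range / 2

    soil_mean = np.zeros(n)
    soil_mean[0] = t2m_mean[0]
    for t in range(1, n):  # soil temperature lags the air by days
        soil_mean[t] = 0.85 * soil_mean[t - 1] + 0.15 * t2m_mean[t]
    soil_range = diurnal * 0.4
    tsoil_min, tsoil_max = soil_mean - soil_range / 2, soil_mean + soil_range / 2

    wet = rng.random(n) < 0.2
    precip = np.where(wet, rng.exponential(5.0, n), 0.0)
    sm = np.zeros(n)
    sm[0] = 0.20
    for t in range(1, n):
        sm[t] = np.clip(0.97 * sm[t - 1] + 0.004 * precip[t] + 0.003, 0.05, 0.45)
    swrad = np.clip(
        190.0 + 130.0 * np.sin(2.0 * np.pi * (doys - 81) / 365.0) + rng.normal(0, 15, n),
        20.0,
        None,
    )

    return pd.DataFrame(
        {
            "field_id": field_id,
            "doy": doys,
            "t2m_min": t2m_min,
            "t2m_max": t2m_max,
            "tsurf_min": tsurf_min,
            "tsurf_max": tsurf_max,
            "tsoil_min": tsoil_min,
            "tsoil_max": tsoil_max,
            "soilmoist_min": sm - 0.01,
            "soilmoist_max": sm + 0.01,
            "precip": precip,
            "swrad": swrad,
        }
    )


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


def simulate_bands(
    schedule: StageSchedule,
    weather: pd.DataFrame,
    config: SimConfig,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Sentinel-2-like field-mean reflectances along the schedule.

    NIR follows a double-logistic canopy curve keyed to the LD onset
    (green-up) and BO onset (senescence); red mirrors it inversely and
    picks up the soil/discoloration signal.  On top of the canopy
    backbone each reproductive phase leaves its own spectral mark —
    squares, flowers, green bolls and open bolls have different
    biophysical and biochemical properties, so the signature shifts at
    every stage onset: the visible bands brighten slightly during
    flowering (creamy flowers) and markedly during boll opening (white
    open bolls), while SWIR tracks canopy water content, which rises
    from squaring to its minimum reflectance during boll development.
    Gaussian sensor noise and cloud-dropped acquisitions complete the
    series.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    lo, hi = config.acquisition_range
    doys = np.arange(lo, hi + 1, config.acquisition_cadence)

    on = schedule.onsets
    green_up = on[PhenologyStage.LD] + 12.0
    senesce = on[PhenologyStage.BO] + 6.0
    canopy = _logistic((doys - green_up) / 8.0) * (1.0 - _logistic((doys - senesce) / 6.0))

    # per-phase indicator curves, smooth-edged at the onsets
    square = _logistic((doys - on[PhenologyStage.S]) / 3.0) * (
        1.0 - _logistic((doys - on[PhenologyStage.F]) / 3.0)
    )
    flower = _logistic((doys - on[PhenologyStage.F]) / 3.0) * (
        1.0 - _logistic((doys - on[PhenologyStage.BD]) / 3.0)
    )
    boll_dev = _logistic((doys - on[PhenologyStage.BD]) / 3.0) * (
        1.0 - _logistic((doys - on[PhenologyStage.BO]) / 4.0)
    )
    boll_open = _logistic((doys - on[PhenologyStage.BO]) / 4.0)
    # canopy water content builds from squaring to boll development
    water = 0.35 * square + 0.7 * flower + 1.0 * boll_dev
    # LAI keeps building through flowering to cutout, so NIR peaks in F/BD
    maturity = _logistic((doys - (on[PhenologyStage.F] + 5.0)) / 8.0)

    b08 = 0.14 + 0.36 * canopy * (0.85 + 0.15 * maturity) - 0.06 * boll_open
    b04 = 0.11 - 0.075 * canopy + 0.015 * flower + 0.09 * boll_open
    b03 = 0.095 - 0.035 * canopy + 0.025 * flower + 0.08 * boll_open
    b02 = 0.075 - 0.02 * canopy + 0.012 * flower + 0.07 * boll_open
    b06 = 0.5 * b04 + 0.5 * b08  # red-edge approximated as a red/NIR blend
    b11 = 0.28 - 0.08 * canopy - 0.10 * water + 0.04 * boll_open
    b12 = 0.22 - 0.06 * canopy - 0.08 * water + 0.04 * boll_open

    frame = pd.DataFrame(
        {
            "field_id": schedule.field_id,
            "doy": doys,
            "B02": b02,
            "B03": b03,
            "B04": b04,
            "B06": b06,
            "B08": b08,
            "B11": b11,
            "B12": b12,
        }
    )
    for band in ("B02", "B03", "B04", "B06", "B08", "B11", "B12"):
        noisy = frame[band] + rng.normal(0.0, config.reflectance_sd, doys.size)
        frame[band] = np.clip(noisy, 0.0, 1.0)

    keep = rng.random(doys.size) >= config.cloud_gap_prob
    if keep.sum() < 2:  # always keep the series interpolatable
        keep[[0, -1]] = True
    return frame.loc[keep].reset_index(drop=True)


def simulate_observations(
    schedule: StageSchedule, config: SimConfig
) -> pd.DataFrame:
    """Field-visit records every ``visit_cadence`` days across the season."""
    rows = []
    for doy in range(schedule.sowing_doy + 5, schedule.harvest_doy + 1, config.visit_cadence):
        obs = schedule.observation_at(doy, config.transition_band)
        if obs is None:
            continue
        primary, p_prev, secondary, s_prev = obs
        rows.append(
            {
                "field_id": schedule.field_id,
                "visit_doy": doy,
                "primary_stage": primary.code,
                "primary_prevalence": p_prev,
                "secondary_stage": secondary.code if secondary else "",
                "secondary_prevalence": s_prev if secondary else "",
                "sowing_doy": schedule.sowing_doy,
                "harvest_doy": schedule.harvest_doy,
                "photo_refs": "",
            }
        )
    return pd.DataFrame(rows)


def simulate_season(config: SimConfig) -> SeasonData:
    """Generate a full season: schedules, weather, bands and observations."""
    rng = np.random.default_rng(config.seed)
    schedules = []
    offsets = {}
    for i in range(config.n_fields):
        thermal = rng.uniform(-1.5, 1.5)
        sched = _draw_schedule(f"f{i:03d}", config, rng, thermal)
        schedules.append(sched)
        offsets[sched.field_id] = thermal

    weather_frames = []
    band_frames = []
    obs_frames = []
    for sched in schedules:
        w = simulate_weather(config, sched.field_id, offsets[sched.field_id], rng)
        weather_frames.append(w)
        band_frames.append(simulate_bands(sched, w, config, rng))
        obs_frames.append(simulate_observations(sched, config))

    return SeasonData(
        config=config,
        schedules=schedules,
        bands=pd.concat(band_frames, ignore_index=True),
        weather=pd.concat(weather_frames, ignore_index=True),
        observations=pd.concat(obs_frames, ignore_index=True),
        field_offsets=offsets,
    )


def truth_metaclasses(
    season: SeasonData, index: pd.MultiIndex, transition_band: Optional[int] = None
):
    """Ground-truth metaclasses at the (field_id, doy) rows of ``index``.

    Returns (mask, metaclasses): ``mask`` marks in-season rows, and
    ``metaclasses`` holds one truth metaclass per masked row.
    """
    if transition_band is None:
        transition_band = season.config.transition_band
    by_id = {s.field_id: s for s in season.schedules}
    mask = []
    truths = []
    for fid, doy in index:
        mc = by_id[fid].metaclass_at(int(doy), transition_band)
        mask.append(mc is not None)
        if mc is not None:
            truths.append(mc)
    return np.asarray(mask, dtype=bool), truths


def schedules_frame(schedules: List[StageSchedule]) -> pd.DataFrame:
    """Truth schedules as a flat table (one row per field)."""
    rows = []
    for s in schedules:
        row = {"field_id": s.field_id, "sowing_doy": s.sowing_doy, "harvest_doy": s.harvest_doy}
        for stage in PhenologyStage:
            row[f"onset_{stage.code}"] = s.onsets[stage]
        rows.append(row)
    return pd.DataFrame(rows)
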