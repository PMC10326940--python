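"""Synthetic soaring-flight generator with known ground truth.

Emulates the data-generating process the analysis pipeline assumes: raptors
released from a fixed site alternate circling thermal climbs with straight
inter-thermal glides, occasionally flapping, while a GPS logs position at
1 (or 4) Hz and a tri-axial accelerometer samples at 25 Hz. Harness-type
effects are injectable with known magnitude — a vertical-speed offset for
leg-loop sessions during climbs and glides, and a dynamic-acceleration
(hence VeDBA) multiplier for backpack sessions — so that every downstream
stage, from behavioural segmentation to the mixed-model battery, can be
validated against a truth channel.

The default configuration mirrors the study design the pipeline targets:
10 individuals from five species, three flight sessions per day over a
week (some skipped, giving ~96 sessions), ~41 min per session, a 1.1 m/s
mean climb rate, and four flapping cycles per second.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .acc_features import AccStream, running_mean
from .gps_kinematics import GpsTrack
from .io_formats import SessionRecord

__all__ = ["SimConfig", "GroundTruth", "SimulatedSession", "StudyData",
           "simulate_session", "simulate_study", "simulate_segment_table",
           "DEFAULT_SPECIES_OF"]

#: release site: a falconry centre above a deep canyon (deg N, deg E)
RELEASE_LAT = 44.801962
RELEASE_LON = 1.612855
RELEASE_HEIGHT_M = 300.0

EARTH_RADIUS_M = 6_371_000.0

#: default individual -> species map: 4 griffon vultures, 1 Rüppell's
#: vulture, 2 Himalayan vultures, 2 tawny eagles, 1 black kite
DEFAULT_SPECIES_OF = {
    "ind01": "griffon_vulture",
    "ind02": "griffon_vulture",
    "ind03": "griffon_vulture",
    "ind04": "griffon_vulture",
    "ind05": "ruppells_vulture",
    "ind06": "himalayan_vulture",
    "ind07": "himalayan_vulture",
    "ind08": "tawny_eagle",
    "ind09": "tawny_eagle",
    "ind10": "black_kite",
}

BEHAVIOUR_CLASSES = ("passive_soaring", "passive_gliding", "active_soaring", "active_gliding")


@dataclass
class SimConfig:
    """Study-level simulation parameters.

    Defaults reproduce the target study's conditions: ~96 sessions of
    ~41 min from 10 birds of 5 species, climbs at 1.1 m/s, sinks at
    −1.2 m/s, 4 Hz flapping, hourly uniform wind.
    """

    n_individuals: int = 10
    species_of: dict = field(default_factory=lambda: dict(DEFAULT_SPECIES_OF))
    sessions_per_day: int = 3
    n_days: int = 7
    session_skip_prob: float = 0.55   # fraction of scheduled sessions not flown (~96 of 210)
    session_duration: float = 2460.0  # s (~41 min)
    climb_rate_mean: float = 1.1      # m/s while thermalling
    sink_rate_mean: float = -1.2      # m/s while gliding
    vspeed_noise_sd: float = 0.3      # m/s per-second vertical-speed noise
    thermal_circle_radius: float = 40.0  # m
    thermal_duration: float = 90.0    # s mean climb-phase length
    glide_duration: float = 60.0      # s mean glide-phase length
    soar_speed: float = 9.0           # m/s horizontal airspeed while circling
    glide_speed: float = 13.0         # m/s horizontal airspeed while gliding
    speed_noise_sd: float = 0.5       # m/s per-second horizontal-speed noise
    flap_bout_prob: float = 0.15      # probability a behavioural phase starts with flapping
    flap_freq: float = 4.0            # Hz (four flapping cycles per second)
    flap_amp: float = 0.8             # g amplitude of the flapping sinusoid
    passive_acc_noise_sd: float = 0.05  # g white noise on each dynamic axis
    wind_u: float = 2.0               # m/s eastward wind
    wind_v: float = 0.0               # m/s northward wind
    effect_vspeed_soar: float = 0.3   # m/s added to climb rate for leg-loop sessions
    effect_vspeed_glide: float = 0.15  # m/s added to sink rate (less sink) for leg-loop
    effect_vedba_factor: float = 1.1  # dynamic-acceleration multiplier for backpack
    gps_rate: int = 1                 # Hz, 1 or 4
    acc_rate: int = 25                # Hz
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gps_rate not in (1, 4):
            raise ValueError("gps_rate must be 1 or 4")
        if self.acc_rate <= 0 or self.session_duration < 0:
            raise ValueError("rates must be positive and durations non-negative")
        if not (self.climb_rate_mean > 0 > self.sink_rate_mean):
            raise ValueError("climb_rate_mean must be positive and sink_rate_mean negative")
        if not 0.0 <= self.flap_bout_prob <= 1.0:
            raise ValueError("flap_bout_prob must be a probability")


@dataclass
class GroundTruth:
    """Truth channel of one simulated session.

    ``data`` has one row per GPS second: time, true behaviour class, local
    east/north position (m), height (m a.s.l.) and the commanded per-second
    vertical rate and ground speed. ``effects`` records the harness effect
    sizes in force during the session.
    """

    data: pd.DataFrame
    effects: dict


@dataclass
class SimulatedSession:
    record: SessionRecord
    gps: GpsTrack
    acc: AccStream
    truth: GroundTruth


@dataclass
class StudyData:
    sessions: list
    config: SimConfig

    @property
    def session_records(self) -> list:
        return [s.record for s in self.sessions]


def _local_to_lonlat(x: np.ndarray, y: np.ndarray) -> tuple:
    """Flat-earth metres (east, north) around the release point to lon/lat."""
    lat = RELEASE_LAT + np.degrees(y / EARTH_RADIUS_M)
    lon = RELEASE_LON + np.degrees(x / (EARTH_RADIUS_M * np.cos(np.radians(RELEASE_LAT))))
    return lon, lat


def _phase_schedule(n: int, config: SimConfig, rng: np.random.Generator) -> list:
    """Alternating (kind, start, length, flap_len) phases covering n seconds."""
    phases = []
    t = 0
    kind = "thermal"
    while t < n:
        base = config.thermal_duration if kind == "thermal" else config.glide_duration
        length = max(5, int(round(base * rng.uniform(0.7, 1.3))))
        length = min(length, n - t)
        flap_len = 0
        if rng.random() < config.flap_bout_prob:
            flap_len = min(int(rng.integers(3, 9)), length)
        phases.append((kind, t, length, flap_len))
        t += length
        kind = "glide" if kind == "thermal" else "thermal"
    return phases


def simulate_session(config: SimConfig, session: SessionRecord, rng_seed: int):
    """Simulate one flight session.

    Returns ``(GpsTrack, AccStream, GroundTruth)``. The trajectory
    alternates circling climbs (heading rotating at constant angular rate,
    altitude rising at the climb rate plus harness offset plus noise) and
    straight glides (altitude falling at the sink rate plus noise); wind is
    added to the ground velocity; the accelerometer signal is a slowly
    rotating unit-gravity static component plus white dynamic noise, with a
    sinusoid at the flapping frequency during flapping bouts. Identical
    seeds give identical output.
    """
    rng = np.random.default_rng(rng_seed)
    n = int(round(config.session_duration))
    if n == 0:
        warnings.warn("zero-length session; returning empty outputs", stacklevel=2)
        empty_gps = GpsTrack(pd.DataFrame(columns=["time", "lon", "lat", "height"]),
                             float(config.gps_rate), session.meta)
        empty_acc = AccStream(pd.DataFrame(columns=["time", "ax", "ay", "az"]),
                              float(config.acc_rate), session.meta)
        return empty_gps, empty_acc, GroundTruth(pd.DataFrame(), {})

    legloop = session.harness == "leg-loop"
    eff_soar = config.effect_vspeed_soar if legloop else 0.0
    eff_glide = config.effect_vspeed_glide if legloop else 0.0
    acc_factor = 1.0 if legloop else config.effect_vedba_factor

    phases = _phase_schedule(n, config, rng)

    vz = np.empty(n)
    speed = np.empty(n)
    bearing = np.empty(n)
    bank = np.zeros(n)
    flapping = np.zeros(n, dtype=bool)
    soaring = np.zeros(n, dtype=bool)

    heading = rng.uniform(0.0, 2.0 * np.pi)
    for kind, start, length, flap_len in phases:
        sl = slice(start, start + length)
        if kind == "thermal":
            soaring[sl] = True
            vz[sl] = config.climb_rate_mean + eff_soar + rng.normal(0.0, config.vspeed_noise_sd, length)
            spd = config.soar_speed + rng.normal(0.0, config.speed_noise_sd, length)
            omega = (config.soar_speed / config.thermal_circle_radius) * rng.choice([-1.0, 1.0])
            bearing[sl] = (heading + omega * np.arange(length)) % (2.0 * np.pi)
            heading = bearing.flat[start + length - 1]
            bank[sl] = np.radians(25.0)
        else:
            vz[sl] = config.sink_rate_mean + eff_glide + rng.normal(0.0, config.vspeed_noise_sd, length)
            spd = config.glide_speed + rng.normal(0.0, config.speed_noise_sd, length)
            heading = rng.uniform(0.0, 2.0 * np.pi)
            bearing[sl] = heading
        speed[sl] = np.maximum(spd, 0.0)
        if flap_len:
            flapping[start:start + flap_len] = True

    true_class = np.where(
        soaring,
        np.where(flapping, "active_soaring", "passive_soaring"),
        np.where(flapping, "active_gliding", "passive_gliding"),
    )

    # integrate ground velocity (air velocity + wind) on a local ENU plane
    vx = speed * np.sin(bearing) + config.wind_u
    vy = speed * np.cos(bearing) + config.wind_v
    x = np.concatenate(([0.0], np.cumsum(vx)))[:n]
    y = np.concatenate(([0.0], np.cumsum(vy)))[:n]
    height = RELEASE_HEIGHT_M + np.concatenate(([0.0], np.cumsum(vz)))[:n]

    seconds = session.start_time + pd.to_timedelta(np.arange(n), unit="s")

    # GPS track, possibly at 4 Hz via linear interpolation of the 1 s path
    if config.gps_rate == 1:
        gx, gy, gh, gt = x, y, height, seconds
    else:
        step = 1.0 / config.gps_rate
        tt = np.arange(0.0, float(n - 1) + step / 2, step)
        gx = np.interp(tt, np.arange(n), x)
        gy = np.interp(tt, np.arange(n), y)
        gh = np.interp(tt, np.arange(n), height)
        gt = session.start_time + pd.to_timedelta(np.round(tt * 1000).astype(int), unit="ms")
    lon, lat = _local_to_lonlat(gx, gy)
    gps = GpsTrack(
        pd.DataFrame({"time": gt, "lon": lon, "lat": lat, "height": gh}),
        float(config.gps_rate),
        session.meta,
    )

    # accelerometer stream at acc_rate Hz
    m = n * config.acc_rate
    t_rel = np.arange(m) / config.acc_rate
    acc_time = session.start_time + pd.to_timedelta(np.round(t_rel * 1e6).astype(np.int64), unit="us")
    bank_hi = running_mean(np.repeat(bank, config.acc_rate), 2.0, config.acc_rate)
    static_x = np.zeros(m)
    static_y = np.sin(bank_hi)
    static_z = np.cos(bank_hi)
    noise_sd = config.passive_acc_noise_sd * acc_factor
    dyn = rng.normal(0.0, noise_sd, size=(3, m))
    flap_hi = np.repeat(flapping, config.acc_rate)
    amp = config.flap_amp * acc_factor
    dyn[2, flap_hi] += amp * np.sin(2.0 * np.pi * config.flap_freq * t_rel[flap_hi])
    acc = AccStream(
        pd.DataFrame(
            {
                "time": acc_time,
                "ax": static_x + dyn[0],
                "ay": static_y + dyn[1],
                "az": static_z + dyn[2],
            }
        ),
        float(config.acc_rate),
        session.meta,
    )

    truth = GroundTruth(
        pd.DataFrame(
            {
                "time": seconds,
                "true_class": true_class,
                "x": x,
                "y": y,
                "height": height,
                "vz": vz,
                "speed": speed,
            }
        ),
        {
            "harness": session.harness,
            "effect_vspeed_soar": eff_soar,
            "effect_vspeed_glide": eff_glide,
            "acc_amplitude_factor": acc_factor,
        },
    )
    return gps, acc, truth


def simulate_study(config: SimConfig) -> StudyData:
    """Simulate a whole multi-day study.

    Individuals fly up to ``sessions_per_day`` sessions on each of
    ``n_days`` consecutive days; each scheduled session is independently
    skipped with probability ``session_skip_prob``, and the harness type of
    each flown session is randomised (fair coin per individual per
    session), emulating a design that randomises the device/harness
    combination. The session log is consumable by the CSV writers and the
    pipeline. Fully deterministic given ``config.seed``.
    """
    root = np.random.SeedSequence(config.seed)
    assign_rng = np.random.default_rng(root.spawn(1)[0])

    individuals = sorted(config.species_of)[: config.n_individuals]
    if len(individuals) < config.n_individuals:
        raise ValueError("species_of must cover n_individuals individuals")

    start_date = pd.Timestamp("2018-06-25", tz="UTC")
    slot_hours = [8, 10, 12]  # UTC release times, three sessions per day

    sessions = []
    counter = 0
    for day in range(config.n_days):
        date = start_date + pd.Timedelta(days=day)
        for slot in range(config.sessions_per_day):
            hour = slot_hours[slot % len(slot_hours)]
            for ind in individuals:
                if assign_rng.random() < config.session_skip_prob:
                    continue
                harness = "backpack" if assign_rng.random() < 0.5 else "leg-loop"
                counter += 1
                start = date + pd.Timedelta(hours=hour)
                record = SessionRecord(
                    session_id=f"s{counter:04d}",
                    individual_id=ind,
                    species=config.species_of[ind],
                    harness=harness,
                    date=date.date(),
                    start_time=start,
                    end_time=start + pd.Timedelta(seconds=float(config.session_duration)),
                    device_id=f"dev{(counter % config.n_individuals) + 1:02d}",
                )
                child = root.spawn(1)[0]
                gps, acc, truth = simulate_session(config, record, child)
                sessions.append(SimulatedSession(record, gps, acc, truth))
    return StudyData(sessions, config)


#: plausible per-species soaring vertical-speed offsets (m/s) relative to
#: the smallest species; magnitudes typical of large-raptor comparisons
DEFAULT_SPECIES_VSPEED_OFFSET = {
    "black_kite": 0.0,
    "tawny_eagle": -0.18,
    "griffon_vulture": -0.22,
    "himalayan_vulture": -0.20,
    "ruppells_vulture": -0.50,
}


def simulate_segment_table(
    seed: int,
    effect_vspeed_soar: float = 0.3,
    interaction: dict | None = None,
    n_dates: int = 5,
    sessions_per_ind_date: int = 2,
    segments_per_session: int = 6,
    sd_individual: float = 0.1,
    sd_date: float = 0.15,
    sd_resid: float = 0.4,
    intercept: float = 0.39,
    nfix_coef: float = 0.004,
    species_of: dict | None = None,
) -> pd.DataFrame:
    """Draw a soaring-segment table directly from the mixed-model data model.

    Bypasses trajectory simulation: mean vertical speed is generated as
    intercept + harness effect (+ optional species-specific interaction
    offsets) + species offset + individual and date random intercepts +
    residual noise, with segment length as a covariate. This is the
    generator for parameter-recovery and error-rate experiments on the
    model battery, where thousands of segment tables are needed and the
    trajectory layer would only add cost, not information.
    """
    rng = np.random.default_rng(seed)
    species_of = species_of or dict(DEFAULT_SPECIES_OF)
    interaction = interaction or {}
    b_ind = {ind: rng.normal(0.0, sd_individual) for ind in species_of}
    dates = [f"2018-06-{25 + d:02d}" for d in range(n_dates)]
    b_date = {d: rng.normal(0.0, sd_date) for d in dates}

    rows = []
    sid = 0
    for date in dates:
        for ind, sp in species_of.items():
            for _ in range(sessions_per_ind_date):
                sid += 1
                harness = "leg-loop" if rng.random() < 0.5 else "backpack"
                legloop = harness == "leg-loop"
                for k in range(segments_per_session):
                    n_fixes = int(rng.integers(5, 60))
                    y = (
                        intercept
                        + (effect_vspeed_soar + interaction.get(sp, 0.0)) * legloop
                        + DEFAULT_SPECIES_VSPEED_OFFSET.get(sp, 0.0)
                        + b_ind[ind]
                        + b_date[date]
                        + nfix_coef * n_fixes
                        + rng.normal(0.0, sd_resid)
                    )
                    rows.append(
                        {
                            "session_id": f"s{sid:04d}",
                            "individual_id": ind,
                            "species": sp,
                            "harness": harness,
                            "date": date,
                            "behaviour": "passive_soaring",
                            "n_fixes": n_fixes,
                            "start": pd.Timestamp("2018-06-25", tz="UTC")
                            + pd.Timedelta(seconds=sid * 3600 + k * 60),
                            "hour_centred": rng.uniform(-2.0, 2.0),
                            "mean_vert_speed": y,
                        }
                    )
    return pd.DataFrame(rows)


def wind_table_for_study(study: StudyData) -> pd.DataFrame:
    """Hourly wind table covering the study period at the release point.

    The simulator applies a constant wind; the table exposes it in the
    format the annotation step expects (one record per hour).
    """
    config = study.config
    if not study.sessions:
        return pd.DataFrame(columns=["time", "lon", "lat", "height", "u", "v"])
    t0 = min(s.record.start_time for s in study.sessions).floor("h")
    t1 = max(s.record.end_time for s in study.sessions).ceil("h")
    times = pd.date_range(t0, t1, freq="h")
    return pd.DataFrame(
        {
            "time": times,
            "lon": RELEASE_LON,
            "lat": RELEASE_LAT,
            "height": RELEASE_HEIGHT_M,
            "u": config.wind_u,
            "v": config.wind_v,
        }
    )
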