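"""Synthetic foraging trips of a diving, krill-eating seabird.

The generator emulates the statistical structure of field bio-logger data
that the detectors assume, with known ground truth:

* dual-rate streams — tri-axial acceleration at 25 Hz, depth at 1 Hz;
* trips composed of surface intervals and dives to tens of metres, each
  regular dive with a descent / bottom / ascent trapezoid shape;
* prey-capture events (PCE) only in foraging dives, at ~2% pooled label
  prevalence, concentrated in the bottom (~83%) and ascent (~12%) phases;
* each capture annotated as an 8-sample label window (3 samples before the
  capture moment, 4 after), consecutive captures >= 8 samples apart;
* between-individual variation including individuals that forage nowhere.

Acceleration is a static gravity component rotated by the instantaneous
pitch (steeply head-down on descent, variable near horizontal at the
bottom, head-up on ascent — which makes the pitch-s.d. balancing filter
discriminative by construction), plus a flapping oscillation, Gaussian
sensor noise, and one 8-sample strike transient per capture added to the
surge and heave axes.  The 1 Hz depth is generated first and the 25 Hz
truth depth used for planting events is its linear interpolation, keeping
the generator consistent with the analysis pipeline.

The capture transient is a free signal-to-noise knob of the simulation, not
a claim about the waveform of real captures.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import AccelSeries, DepthSeries, SyncedSeries, merge_streams
from .io import write_accel, write_labels, write_tdr

logger = logging.getLogger(__name__)

#: 8-sample strike template: 3 rising samples, peak, 4 decaying samples,
#: aligned with the label window [capture-3, capture+4].
STRIKE_TEMPLATE = np.array([0.25, 0.55, 0.8, 1.0, 0.7, 0.45, 0.25, 0.1])


@dataclass
class SimConfig:
    """Parameters of the synthetic foraging-trip generator.

    Distribution parameters are (mean, sd) of truncated normals.  Defaults
    are calibrated so that the pooled PCE label prevalence of a cohort is
    ~2% of all samples and events fall (0.83, 0.12, 0.05) into bottom /
    ascent / elsewhere.
    """

    n_individuals: int = 20
    trip_duration_s: float = 1200.0
    accel_rate_hz: float = 25.0
    depth_rate_hz: float = 1.0
    dive_depth_m: tuple[float, float] = (30.0, 8.0)
    dive_duration_s: tuple[float, float] = (90.0, 15.0)
    surface_interval_s: tuple[float, float] = (40.0, 10.0)
    p_foraging_dive: float = 0.5
    pce_rate_per_foraging_dive: float = 19.0
    phase_mix: tuple[float, float, float] = (0.83, 0.12, 0.05)  # bottom, ascent, other
    p_surface_within_other: float = 0.04  # 'other' is descent or (rarely) surface
    strike_amplitude_g: float = 1.2
    noise_sd_g: float = 0.05
    flap_freq_hz: float = 2.6
    flap_amplitude_g: float = 0.25
    min_pce_separation_samples: int = 8
    p_nonforager: float = 0.1
    p_shallow_dive: float = 0.08
    descent_rate_ms: float = 1.2
    ascent_rate_ms: float = 1.2
    descent_pitch_deg: float = -70.0
    ascent_pitch_deg: float = 70.0
    bottom_pitch_sd_deg: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.accel_rate_hz <= 0 or self.depth_rate_hz <= 0:
            raise ValueError("sampling rates must be positive")
        if abs(sum(self.phase_mix) - 1.0) > 1e-9:
            raise ValueError("phase_mix must sum to 1")
        if self.min_pce_separation_samples < 8:
            raise ValueError("min_pce_separation_samples must be >= 8 "
                             "(the label-window length)")
        if self.strike_amplitude_g < 0 or self.noise_sd_g < 0:
            raise ValueError("amplitudes must be non-negative")
        for p in (self.p_foraging_dive, self.p_nonforager, self.p_shallow_dive):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")


@dataclass
class TruthEvent:
    """One planted prey-capture event (ground truth).

    ``sample_index`` is the 25 Hz index of the capture moment; the label
    window spans [sample_index - 3, sample_index + 4].
    """

    individual_id: str
    sample_index: int
    dive_id: int | None
    phase: str


@dataclass
class TrueDive:
    """Generator-side dive record (independent of the detection pipeline)."""

    dive_id: int
    start_idx: int
    end_idx: int
    descent_end_idx: int | None
    ascent_start_idx: int | None
    max_depth_m: float
    kind: str
    foraging: bool


@dataclass
class SimTrip:
    series: SyncedSeries
    events: list[TruthEvent]
    true_dives: list[TrueDive]
    depth_1hz: DepthSeries


@dataclass
class Cohort:
    config: SimConfig
    trips: list[SimTrip]

    def __iter__(self):
        return iter(self.trips)

    def __len__(self):
        return len(self.trips)

    def pooled_label_prevalence(self) -> float:
        pos = sum(int(t.series.label.sum()) for t in self.trips)
        n = sum(len(t.series) for t in self.trips)
        return pos / n

    def phase_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for t in self.trips:
            for e in t.events:
                counts[e.phase] = counts.get(e.phase, 0) + 1
        return counts


def individual_seed(master_seed: int, individual_id: str) -> np.random.SeedSequence:
    """Stable per-individual seed substream from (master seed, id)."""
    return np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF,
                                   zlib.crc32(individual_id.encode())])


def _trunc_normal(rng: np.random.Generator, mean: float, sd: float,
                  lo: float, hi: float) -> float:
    for _ in range(100):
        v = rng.normal(mean, sd)
        if lo <= v <= hi:
            return float(v)
    return float(min(max(mean, lo), hi))


def _smooth(x: np.ndarray, w: int) -> np.ndarray:
    if w <= 1 or len(x) < 2:
        return x
    return (pd.Series(x).rolling(w, center=True, min_periods=1)
            .mean().to_numpy())


def _dive_profile_1hz(rng: np.random.Generator, cfg: SimConfig
                      ) -> tuple[np.ndarray, int, int, float]:
    """One regular-dive depth excursion at 1 Hz.

    Returns (depth values, descent_end offset, ascent_start offset, max depth)
    with offsets in 1 Hz samples from the dive's first sample.
    """
    h = _trunc_normal(rng, *cfg.dive_depth_m, 4.0, 70.0)
    dur = _trunc_normal(rng, *cfg.dive_duration_s, 20.0, 240.0)
    t_desc = max(3, int(round(h / cfg.descent_rate_ms)))
    t_asc = max(3, int(round(h / cfg.ascent_rate_ms)))
    t_bot = max(16, int(round(dur)) - t_desc - t_asc)

    desc = np.linspace(0.0, h, t_desc, endpoint=False)[1:]  # exclude the 0
    wig_amp = min(1.5, 0.1 * h)
    tt = np.arange(t_bot)
    wiggle = wig_amp * np.sin(2 * np.pi * tt / max(10.0, t_bot / 2.5)
                              + rng.uniform(0, 2 * np.pi))
    bot = h + wiggle + rng.normal(0, 0.1, t_bot)
    asc = np.linspace(h, 0.0, t_asc, endpoint=False)[1:]
    depth = np.concatenate([desc, bot, asc])
    depth = np.clip(depth, 0.6, None)  # strictly submerged inside the dive
    return depth, len(desc), len(desc) + t_bot, float(depth.max())


def _shallow_profile_1hz(rng: np.random.Generator) -> np.ndarray:
    """A short, shallow 'surface dive' (0.4-2 m, a few seconds)."""
    h = rng.uniform(1.0, 1.9)
    dur = int(rng.integers(4, 9))
    half = dur // 2
    up = np.linspace(0, h, half + 1, endpoint=True)[1:]
    down = np.linspace(h, 0, dur - half, endpoint=False)[1:]
    return np.clip(np.concatenate([up, down]), 0.5, None)


def _place_events(rng: np.random.Generator, intervals: dict[str, tuple[int, int]],
                  n_events: int, cfg: SimConfig, n_total: int,
                  taken: list[int]) -> list[tuple[int, str]]:
    """Place events in phase intervals respecting the minimum separation.

    ``intervals`` maps phase name -> half-open 25 Hz index range.  Events
    whose drawn phase interval is too short are reallocated in the order
    bottom -> ascent -> descent.  Returns (sample_index, phase) pairs.
    """
    mix = np.asarray(cfg.phase_mix, dtype=float)
    placed: list[tuple[int, str]] = []
    sep = cfg.min_pce_separation_samples
    for _ in range(n_events):
        bucket = rng.choice(3, p=mix)
        if bucket == 0:
            phase = "bottom"
        elif bucket == 1:
            phase = "ascent"
        else:
            phase = ("surface" if rng.random() < cfg.p_surface_within_other
                     and "surface" in intervals else "descent")
        order = [phase] + [p for p in ("bottom", "ascent", "descent")
                           if p != phase and p in intervals]
        chosen = None
        for cand in order:
            lo, hi = intervals.get(cand, (0, 0))
            lo, hi = lo + 4, hi - 5  # keep the 8-sample window inside
            if hi - lo < 1:
                continue
            for _try in range(200):
                s = int(rng.integers(lo, hi))
                if 3 <= s <= n_total - 5 and all(abs(s - q) >= sep for q in taken):
                    chosen = (s, cand)
                    break
            if chosen:
                break
        if chosen is None:
            logger.info("event dropped: no feasible placement at separation %d", sep)
            continue
        if chosen[1] != phase:
            logger.info("event reallocated from %s to %s (interval too short)",
                        phase, chosen[1])
        taken.append(chosen[0])
        placed.append(chosen)
    return placed


def simulate_trip(config: SimConfig, individual_id: str,
                  forager: bool | None = None
                  ) -> tuple[SyncedSeries, list[TruthEvent], list[TrueDive]]:
    """Simulate one labelled foraging trip.

    Same ``config.seed`` and ``individual_id`` give bit-identical output.
    ``forager=False`` forces a zero-foraging individual (used by
    :func:`simulate_cohort`; when None the individual forages).

    Raises ``ValueError`` if the trip is too short to hold a single dive.
    """
    cfg = config
    rng = np.random.default_rng(individual_seed(cfg.seed, individual_id))
    if forager is None:
        forager = True
    rate25 = cfg.accel_rate_hz
    n1 = int(round(cfg.trip_duration_s * cfg.depth_rate_hz)) + 1
    min_needed = cfg.surface_interval_s[0] / 2 + 30
    if cfg.trip_duration_s < min_needed:
        raise ValueError(
            f"trip_duration_s={cfg.trip_duration_s} too short to hold one "
            f"dive (need >= {min_needed:.0f} s)")

    depth1 = np.zeros(n1)
    true_dives: list[TrueDive] = []
    events: list[TruthEvent] = []
    step = int(round(rate25 / cfg.depth_rate_hz))  # 1 Hz -> 25 Hz index factor
    n25 = int(round(cfg.trip_duration_s * rate25))

    pos = max(3, int(round(_trunc_normal(rng, *cfg.surface_interval_s, 8.0, 120.0) / 2)))
    dive_id = 0
    taken: list[int] = []
    pitch = np.zeros(n25)
    dive_spans: list[tuple[int, int]] = []  # 25 Hz spans for flapping

    while True:
        shallow = rng.random() < cfg.p_shallow_dive
        if shallow:
            prof = _shallow_profile_1hz(rng)
            d_end = a_start = None
            maxd = float(prof.max())
        else:
            prof, d_end, a_start, maxd = _dive_profile_1hz(rng, cfg)
        surf = max(8, int(round(_trunc_normal(rng, *cfg.surface_interval_s,
                                              8.0, 120.0))))
        if pos + len(prof) + 2 > n1 - 1:
            break
        depth1[pos:pos + len(prof)] = prof
        s25, e25 = pos * step, (pos + len(prof)) * step
        foraging = (not shallow) and forager and rng.random() < cfg.p_foraging_dive
        td = TrueDive(
            dive_id=dive_id, start_idx=s25, end_idx=e25,
            descent_end_idx=None if d_end is None else (pos + d_end) * step,
            ascent_start_idx=None if a_start is None else (pos + a_start) * step,
            max_depth_m=maxd, kind="shallow" if shallow else "regular",
            foraging=foraging)
        true_dives.append(td)
        dive_spans.append((s25, e25))

        if foraging:
            n_ev = int(rng.poisson(cfg.pce_rate_per_foraging_dive))
            # the ascent interval stops one 1 Hz step short of the dive end
            # so planted events sit strictly deeper than the 0.4 m threshold
            intervals = {
                "descent": (s25, td.descent_end_idx),
                "bottom": (td.descent_end_idx, td.ascent_start_idx),
                "ascent": (td.ascent_start_idx, e25 - step),
                "surface": (e25 + step, min((pos + len(prof) + surf) * step,
                                            n25) - step),
            }
            taken = []  # separation is enforced within a dive cycle; cycles
            # are themselves >= one surface interval apart
            for s, ph in _place_events(rng, intervals, n_ev, cfg, n25, taken):
                events.append(TruthEvent(
                    individual_id=individual_id, sample_index=s,
                    dive_id=None if ph == "surface" else dive_id, phase=ph))

        # pitch over the dive: steep descent, variable bottom, steep ascent
        if not shallow:
            de, as_ = td.descent_end_idx, td.ascent_start_idx
            pitch[s25:de] = cfg.descent_pitch_deg + rng.normal(0, 3, de - s25)
            nb = as_ - de
            wander = _smooth(rng.normal(0, 1, nb), step)
            sdw = wander.std()
            if sdw > 0:
                wander = wander / sdw * cfg.bottom_pitch_sd_deg
            pitch[de:as_] = wander
            pitch[as_:e25] = cfg.ascent_pitch_deg + rng.normal(0, 3, e25 - as_)
        else:
            pitch[s25:e25] = rng.normal(0, 5, e25 - s25)

        pos += len(prof) + surf
        dive_id += 1

    if dive_id == 0:
        raise ValueError("trip too short to hold one dive at the configured "
                         "dive/surface durations")

    # --- acceleration at 25 Hz -------------------------------------------
    t25 = np.arange(n25) / rate25
    pitch = _smooth(pitch, step)  # 1 s smoothing removes hard phase steps
    pr = np.radians(pitch)
    x = np.sin(pr)
    y = np.zeros(n25)
    z = np.cos(pr)

    flap = np.zeros(n25)
    for s25, e25 in dive_spans:
        ph0 = rng.uniform(0, 2 * np.pi)
        tt = t25[s25:e25]
        flap[s25:e25] = np.sin(2 * np.pi * cfg.flap_freq_hz * tt + ph0)
    z = z + cfg.flap_amplitude_g * flap
    x = x + 0.4 * cfg.flap_amplitude_g * flap

    x = x + rng.normal(0, cfg.noise_sd_g, n25)
    y = y + rng.normal(0, cfg.noise_sd_g, n25)
    z = z + rng.normal(0, cfg.noise_sd_g, n25)

    labels = np.zeros(n25, dtype=np.uint8)
    for ev in events:
        lo = ev.sample_index - 3
        x[lo:lo + 8] += cfg.strike_amplitude_g * STRIKE_TEMPLATE
        z[lo:lo + 8] += 0.6 * cfg.strike_amplitude_g * STRIKE_TEMPLATE
        labels[lo:lo + 8] = 1

    accel = AccelSeries(t=t25, x=x, y=y, z=z, individual_id=individual_id,
                        rate_hz=rate25)
    tdr = DepthSeries(t=np.arange(n1, dtype=float) / cfg.depth_rate_hz,
                      depth=depth1, individual_id=individual_id,
                      rate_hz=cfg.depth_rate_hz)
    series = merge_streams(accel, tdr, label=labels)
    events.sort(key=lambda e: e.sample_index)
    return series, events, true_dives


def simulate_cohort(config: SimConfig) -> Cohort:
    """Simulate ``config.n_individuals`` independent trips.

    Per-individual random substreams are derived deterministically from the
    master seed, so the same master seed reproduces the cohort bit-exactly
    and each trip is independent of cohort size or ordering.  Approximately
    ``p_nonforager`` of individuals forage nowhere.
    """
    if config.n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    rng = np.random.default_rng(
        np.random.SeedSequence([int(config.seed) & 0x7FFFFFFF, 0x0C0F00]))
    nonforager = rng.random(config.n_individuals) < config.p_nonforager
    trips = []
    for i in range(config.n_individuals):
        ind = f"ind{i:03d}"
        series, events, tds = simulate_trip(config, ind,
                                            forager=not bool(nonforager[i]))
        trips.append(SimTrip(series=series, events=events, true_dives=tds,
                             depth_1hz=_tdr_of(series, config)))
    return Cohort(config=config, trips=trips)


def _tdr_of(series: SyncedSeries, cfg: SimConfig) -> DepthSeries:
    step = int(round(series.rate_hz / cfg.depth_rate_hz))
    idx = np.arange(0, len(series), step)
    return DepthSeries(t=series.t[idx], depth=series.depth[idx],
                       individual_id=series.individual_id,
                       rate_hz=cfg.depth_rate_hz)


def write_trip(trip: SimTrip, out_dir: str | Path) -> dict[str, Path]:
    """Write one trip in the delimited formats the reader expects.

    Produces ``<id>_accel.csv``, ``<id>_tdr.csv``, ``<id>_labels.csv`` and a
    ground-truth table ``<id>_truth.csv``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ind = trip.series.individual_id
    paths = {
        "accel": out / f"{ind}_accel.csv",
        "tdr": out / f"{ind}_tdr.csv",
        "labels": out / f"{ind}_labels.csv",
        "truth": out / f"{ind}_truth.csv",
    }
    s = trip.series
    write_accel(AccelSeries(t=s.t, x=s.x, y=s.y, z=s.z, individual_id=ind),
                paths["accel"])
    write_tdr(trip.depth_1hz, paths["tdr"])
    write_labels(s.label, paths["labels"])
    pd.DataFrame([{
        "individual_id": e.individual_id,
        "sample_index": e.sample_index,
        "dive_id": -1 if e.dive_id is None else e.dive_id,
        "phase": e.phase,
    } for e in trip.events]).to_csv(paths["truth"], index=False)
    return paths
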