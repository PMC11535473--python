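"""Synthetic fed-batch dataset generator.

Emulates the statistical structure of a galactose-supplementation design of
experiments: four conditions (Control, A, B, Validation) differing in when a
25 mM galactose bolus is fed, two biological replicates per condition,
channel-specific sampling cadences, multiplicative measurement noise, and
channel-specific missingness.  Observations are sampled from a ground-truth
kinetic simulation, so the generating parameters are known exactly and every
downstream stage (estimation, OPLS, NN, comparison) can be tested against a
known answer with no external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import CSV_COLUMNS, Channel, CultureTable, logger
from .kinetics import (DEFAULT_PARAMS, FeedEvent, FeedSchedule, KineticParams,
                       ModelState, SampleEvent, simulate_fedbatch)

__all__ = ["DoECondition", "NoiseSpec", "MissingnessSpec", "default_design",
           "default_schedule", "build_feed_schedule", "generate_dataset"]

#: volume removed per sampling occasion (mL) out of a 70 mL working volume
SAMPLE_VOLUME_ML = 1.5


@dataclass(frozen=True)
class DoECondition:
    name: str
    gal_dose_mM: float
    feed_times_h: tuple
    duration_h: float

    def __post_init__(self):
        if any(t < 0 or t > self.duration_h for t in self.feed_times_h):
            raise ValueError("feed times must lie within [0, duration]")


@dataclass
class NoiseSpec:
    """Multiplicative Gaussian noise, obs = truth * (1 + CV * z).

    Glycan noise is applied to the underlying peak areas before
    renormalization to 100%.  ``truncation`` is "clip" (negatives set to 0)
    or "resample" (redraw until positive).
    """
    cv: dict = field(default_factory=dict)
    default_cv: float = 0.05
    truncation: str = "clip"

    def cv_for(self, ch: Channel) -> float:
        v = self.cv.get(ch.name, self.default_cv)
        if v < 0:
            raise ValueError("CV must be >= 0")
        return v


@dataclass
class MissingnessSpec:
    """Per-channel missing fractions (missing-completely-at-random layer on
    top of the schedule-driven sampling pattern).

    Defaults follow the study's stated incompleteness: 30% VCD, 75% titer,
    55% NSDs, 87% UDP-GlcNAc, 30-40% extracellular metabolites.
    """
    fraction: dict = field(default_factory=lambda: {
        "VCD": 0.30, "TITER": 0.75,
        "GLC": 0.30, "GLN": 0.35, "GLU": 0.40, "LAC": 0.35, "NH4": 0.40,
        "GAL": 0.30,
        "UDP_GLC": 0.55, "UDP_GAL": 0.55, "UDP_GALNAC": 0.55,
        "UDP_GLCNAC": 0.87,
        "G0F": 0.0, "G1F": 0.0, "G2F": 0.0,
    })

    def fraction_for(self, ch: Channel) -> float:
        f = self.fraction.get(ch.name, 0.0)
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"missing fraction for {ch.name} out of [0, 1]")
        return f


def default_design() -> list:
    """The four-condition galactose DoE.

    Control: no galactose, 144 h.  A: 25 mM at 72 h, 216 h.  B: 25 mM at
    120 h, 216 h.  Validation: 25 mM at both 72 and 120 h, 288 h.
    """
    return [
        DoECondition("Control", 0.0, (), 144.0),
        DoECondition("A", 25.0, (72.0,), 216.0),
        DoECondition("B", 25.0, (120.0,), 216.0),
        DoECondition("Validation", 25.0, (72.0, 120.0), 288.0),
    ]


def default_schedule(condition: DoECondition) -> dict:
    """Per-channel sampling time grids (hours) for a condition.

    Metabolites/VCD/titer follow a 12-24 h cadence from inoculation; NSDs a
    12 h cadence from 60 h; glycans a roughly 24 h cadence from 72 h;
    galactose is measured from the first feed onward.  Grids reproduce the
    published per-condition sample counts (10/13/18 metabolite points for
    the 144/216/288 h cultures, NSD counts at the top of the stated ranges,
    validation glycans at 72/96/144/168/192 h).
    """
    grids = {
        "Control": {
            "metabolite": [0, 12, 24, 48, 72, 84, 96, 120, 132, 144],
            "nsd": [60, 72, 84, 96, 108, 120, 132],
            "glycan": [72, 120, 144],
            "gal": [],
        },
        "A": {
            "metabolite": [0, 12, 24, 48, 72, 84, 96, 120, 132, 144,
                           168, 192, 216],
            "nsd": [60, 72, 84, 96, 108, 120, 132, 144, 156, 168],
            "glycan": [72, 96, 120, 144, 168],
            "gal": [72, 96, 120, 144, 156],
        },
        "B": {
            "metabolite": [0, 12, 24, 48, 72, 84, 96, 120, 132, 144,
                           168, 192, 216],
            "nsd": [60, 72, 84, 96, 108, 120, 132, 144, 156, 168],
            "glycan": [72, 96, 120, 144, 168],
            "gal": [120, 144, 156, 168, 192],
        },
        "Validation": {
            "metabolite": [0, 12, 24, 48, 72, 84, 96, 108, 120, 132, 144,
                           168, 192, 216, 240, 264, 276, 288],
            "nsd": [60, 72, 84, 96, 108, 120, 132, 144, 156, 168, 180, 192],
            "glycan": [72, 96, 144, 168, 192],
            "gal": [72, 96, 120, 132, 144, 168, 192],
        },
    }
    base = grids.get(condition.name)
    if base is None:
        # custom condition: build grids from the cadence rules
        dur = condition.duration_h
        base = {
            "metabolite": list(np.arange(0, dur + 1, 24.0)),
            "nsd": list(np.arange(60, dur + 1, 12.0)),
            "glycan": list(np.arange(72, dur + 1, 24.0)),
            "gal": (list(np.arange(min(condition.feed_times_h), dur + 1, 24.0))
                    if condition.feed_times_h else []),
        }
    met = [float(t) for t in base["metabolite"] if t <= condition.duration_h]
    nsd = [float(t) for t in base["nsd"] if t <= condition.duration_h]
    gly = [float(t) for t in base["glycan"] if t <= condition.duration_h]
    gal = [float(t) for t in base["gal"] if t <= condition.duration_h]
    sched = {
        Channel.VCD: met, Channel.TITER: met,
        Channel.GLC: met, Channel.GLN: met, Channel.GLU: met,
        Channel.LAC: met, Channel.NH4: met,
        Channel.GAL: gal,
        Channel.UDP_GLC: nsd, Channel.UDP_GAL: nsd,
        Channel.UDP_GLCNAC: nsd, Channel.UDP_GALNAC: nsd,
        Channel.G0F: gly, Channel.G1F: gly, Channel.G2F: gly,
    }
    return sched


def build_feed_schedule(condition: DoECondition,
                        initial_volume_mL: float = 70.0) -> FeedSchedule:
    """Feed events from the DoE plus sampling-volume removals at every
    distinct sampling occasion."""
    feeds = [FeedEvent(t, Channel.GAL, condition.gal_dose_mM)
             for t in condition.feed_times_h]
    sched = default_schedule(condition)
    occasions = sorted({t for times in sched.values() for t in times if t > 0})
    samples = [SampleEvent(t, SAMPLE_VOLUME_ML) for t in occasions]
    return FeedSchedule(feed_events=feeds, sample_events=samples,
                        initial_volume_mL=initial_volume_mL)


def _simulation_grid(condition: DoECondition) -> np.ndarray:
    sched = default_schedule(condition)
    pts = {t for times in sched.values() for t in times}
    pts |= set(condition.feed_times_h)
    pts |= {0.0, condition.duration_h}
    pts |= set(np.arange(0.0, condition.duration_h + 1e-9, 6.0))
    return np.array(sorted(pts))


def generate_dataset(true_params: KineticParams | None = None,
                     design=None, noise: NoiseSpec | None = None,
                     missing: MissingnessSpec | None = None,
                     n_reps: int = 2, seed: int = 0,
                     init: ModelState | None = None,
                     schedule_fn=None):
    """Generate an observed CultureTable plus its noiseless ground truth.

    Per condition x replicate: the initial viable cell density is perturbed
    uniformly within +-0.15e6 cells/mL around 0.3e6 (seeded), the kinetic
    model is simulated through the condition's feed schedule, channels are
    sampled at the schedule times, multiplicative Gaussian noise is applied
    per channel CV (glycan triplets are noised as peak areas and
    renormalized to 100%), and cells are masked missing by seeded Bernoulli
    draws at the per-channel fractions.  Bit-reproducible given the seed.

    ``schedule_fn`` (condition -> {Channel: [times]}) overrides the default
    per-channel sampling grids, e.g. for densely sampled calibration runs.

    Returns (observed, truth) CultureTables.
    """
    p = true_params if true_params is not None else DEFAULT_PARAMS
    design = design if design is not None else default_design()
    noise = noise if noise is not None else NoiseSpec()
    missing = missing if missing is not None else MissingnessSpec()
    base_init = init if init is not None else ModelState()
    rng = np.random.default_rng(seed)

    obs_rows, truth_rows = [], []
    sched_of = schedule_fn if schedule_fn is not None else default_schedule
    for cond in design:
        fs = build_feed_schedule(cond, initial_volume_mL=base_init.V)
        sched = sched_of(cond)
        pts = {t for times in sched.values() for t in times}
        pts |= set(cond.feed_times_h) | {0.0, cond.duration_h}
        grid = np.array(sorted(pts | set(np.arange(0.0, cond.duration_h + 1e-9, 6.0))))
        for rep in range(1, n_reps + 1):
            xv0 = 0.3e6 + rng.uniform(-0.15e6, 0.15e6)
            init_r = ModelState(**{**base_init.__dict__, "Xv": xv0})
            traj = simulate_fedbatch(p, init_r, fs, grid)
            batch = f"{cond.name}-r{rep}"

            # truth values on the schedule
            truth_by_ct = {}
            for ch, times in sched.items():
                if not times:
                    continue
                series = traj.channel_series(ch)
                vals = np.interp(times, traj.time_h, series)
                for t, v in zip(times, vals):
                    truth_by_ct[(ch, t)] = v
                    truth_rows.append((batch, cond.name, rep, t, ch.name, v))

            # noise: glycan triplets jointly (areas), everything else per cell
            glycan_times = sched.get(Channel.G0F, [])
            for t in glycan_times:
                areas = np.array([truth_by_ct[(Channel.G0F, t)],
                                  truth_by_ct[(Channel.G1F, t)],
                                  truth_by_ct[(Channel.G2F, t)]])
                if not np.all(np.isfinite(areas)):
                    continue
                cvs = np.array([noise.cv_for(Channel.G0F),
                                noise.cv_for(Channel.G1F),
                                noise.cv_for(Channel.G2F)])
                noisy = _noisy(areas, cvs, noise.truncation, rng)
                total = noisy.sum()
                if total <= 0:
                    noisy, total = areas, areas.sum()
                for ch, v in zip((Channel.G0F, Channel.G1F, Channel.G2F),
                                 100.0 * noisy / total):
                    obs_rows.append((batch, cond.name, rep, t, ch.name, v))
            for ch, times in sched.items():
                if ch.is_glycan:
                    continue
                for t in times:
                    v = truth_by_ct[(ch, t)]
                    if not np.isfinite(v):
                        continue
                    noisy = _noisy(np.array([v]), np.array([noise.cv_for(ch)]),
                                   noise.truncation, rng)[0]
                    obs_rows.append((batch, cond.name, rep, t, ch.name, noisy))

    obs = pd.DataFrame(obs_rows, columns=CSV_COLUMNS)
    truth = pd.DataFrame(truth_rows, columns=CSV_COLUMNS)
    # missingness layer: independent Bernoulli per cell, per channel
    drop = np.zeros(len(obs), dtype=bool)
    for name, grp in obs.groupby("channel"):
        f = missing.fraction_for(Channel[name])
        if f > 0:
            drop[grp.index] = rng.random(len(grp)) < f
    obs.loc[drop, "value"] = np.nan
    return (CultureTable(obs, validate=False),
            CultureTable(truth, validate=False))


def _noisy(values: np.ndarray, cvs: np.ndarray, truncation: str,
           rng: np.random.Generator) -> np.ndarray:
    out = values * (1.0 + cvs * rng.standard_normal(values.shape))
    if truncation == "clip":
        return np.maximum(out, 0.0)
    if truncation == "resample":
        for _ in range(100):
            bad = out < 0
            if not bad.any():
                break
            out[bad] = values[bad] * (1.0 + cvs[bad] * rng.standard_normal(bad.sum()))
        return np.maximum(out, 0.0)
    raise ValueError(f"unknown truncation policy {truncation!r}")
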