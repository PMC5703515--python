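"""Synthetic overnight SpO2 recordings and cohorts with known ground truth.

Every stage of the screening pipeline is testable without patient data by
generating 1-Hz saturation series with a controlled event rate: a baseline
(about 94 % for non-COPD-like subjects, about 91 % with slow drift and
sustained sub-90 epochs in COPD mode), superimposed trapezoidal
desaturation events arriving as a thinned Poisson process, Gaussian
measurement noise, and — separately, so the clean truth is preserved —
injected artifacts (zeros, impossible low values, >= 4 %/s jumps).

The implanted event rate plays the role of the true AHI: each trapezoidal
dip is the oximetric footprint of one respiratory event. The *achieved*
rate (after thinning to keep events non-overlapping) is reported as the
ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .io import SpO2Recording

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "simulate_recording",
    "inject_artifacts",
    "simulate_cohort",
]


@dataclass
class SimulationConfig:
    duration_hours: float = 8.0
    baseline_spo2: float = 94.0      # ~91 with high CT90 in COPD mode
    event_rate: float = 20.0         # nominal events/h, the true-AHI surrogate
    depth_mean: float = 5.0          # desaturation depth, % points
    depth_sd: float = 1.5
    desat_s: tuple[float, float] = (15.0, 35.0)  # fall time range, s
    nadir_hold_s: float = 5.0
    resat_s: float = 15.0
    noise_sd: float = 0.5            # measurement noise, % points
    artifact_rate: float = 0.0       # artifacts/h for inject_artifacts
    copd_mode: bool = False          # slow drift + sustained sub-90 epochs
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.duration_hours, self.event_rate, self.noise_sd,
               self.artifact_rate, self.depth_sd) < 0:
            raise ValueError("rates and dispersions must be non-negative")
        if not 50.0 < self.baseline_spo2 <= 100.0:
            raise ValueError("baseline saturation must lie in (50, 100]")


@dataclass
class SimulationTruth:
    event_times: list[int]          # onset sample of each implanted event
    true_rate: float                # achieved events/h
    nominal_rate: float


def _baseline_series(cfg: SimulationConfig, n: int, rng: np.random.Generator
                     ) -> np.ndarray:
    t = np.arange(n)
    base = np.full(n, cfg.baseline_spo2, float)
    if cfg.copd_mode:
        # slow respiratory drift plus sustained desaturated epochs, pushing a
        # large fraction of the night below 90 %
        base += 1.5 * np.sin(2 * np.pi * t / 5400.0 + rng.uniform(0, 2 * np.pi))
        n_epochs = max(1, int(cfg.duration_hours * rng.integers(1, 3)))
        for _ in range(n_epochs):
            start = rng.integers(0, max(n - 600, 1))
            length = int(rng.uniform(600, 2400))
            base[start : start + length] -= rng.uniform(2.0, 4.0)
    return base


def simulate_recording(cfg: SimulationConfig, subject_id: str = "sim",
                       setting: str = "lab"
                       ) -> tuple[SpO2Recording, SimulationTruth]:
    """Generate one clean recording plus its ground truth."""
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration_hours * 3600)) + 1
    x = _baseline_series(cfg, n, rng)

    event_times: list[int] = []
    min_gap = 10  # s between consecutive events, mirroring scoring practice
    if cfg.event_rate > 0:
        k = int(rng.poisson(cfg.event_rate * cfg.duration_hours))
        durations = (rng.uniform(*cfg.desat_s, size=k)
                     + cfg.nadir_hold_s + cfg.resat_s).astype(int)
        depths = np.maximum(rng.normal(cfg.depth_mean, cfg.depth_sd, size=k), 3.5)
        # thin the Poisson draw until the events fit without overlap
        k_drawn = k
        free = n - int(durations.sum()) - k * min_gap
        while free <= 0 and k > 0:
            k -= 1
            durations, depths = durations[:k], depths[:k]
            free = n - int(durations.sum()) - k * min_gap
        if k == 0 and k_drawn > 0:
            raise ValueError("infeasible config: a single event does not fit "
                             "in the recording")
        # Poisson-like irregular spacing: exponential gaps rescaled to the
        # available free time, so the achieved count equals k exactly
        gaps = rng.exponential(1.0, size=k + 1)
        gaps = np.floor(gaps / gaps.sum() * free).astype(int)
        t = 0
        for j in range(k):
            start = t + gaps[j]
            depth, desat = depths[j], durations[j] - int(cfg.nadir_hold_s + cfg.resat_s)
            shape = np.concatenate([
                np.linspace(0.0, depth, desat),
                np.full(int(cfg.nadir_hold_s), depth),
                np.linspace(depth, 0.0, int(cfg.resat_s)),
            ])
            x[start : start + len(shape)] -= shape
            event_times.append(int(start))
            t = start + durations[j] + min_gap

    if cfg.noise_sd > 0:
        x = x + rng.normal(0.0, cfg.noise_sd, n)
    x = np.clip(x, 50.0, 100.0)

    truth = SimulationTruth(
        event_times=event_times,
        true_rate=len(event_times) / cfg.duration_hours,
        nominal_rate=cfg.event_rate,
    )
    return SpO2Recording(subject_id, x, setting=setting), truth


def inject_artifacts(rec: SpO2Recording, cfg: SimulationConfig
                     ) -> SpO2Recording:
    """Corrupt a clean recording with zeros, sub-20 dips and >= 4 %/s spikes.

    The number of artifacts is ``artifact_rate * duration``; positions and
    types are drawn from the config seed (offset so they differ from the
    generation stream). ``artifact_rate == 0`` returns the recording as is.
    """
    n_art = int(round(cfg.artifact_rate * rec.duration_hours))
    if n_art == 0:
        return rec
    rng = np.random.default_rng(cfg.seed + 1_000_003)
    x = rec.samples.copy()
    n = len(x)
    positions = rng.choice(np.arange(5, n - 10), size=n_art, replace=False)
    for pos in positions:
        kind = rng.integers(0, 3)
        if kind == 0:                       # probe-off zero run
            x[pos : pos + int(rng.integers(1, 5))] = 0.0
        elif kind == 1:                     # impossible low value
            x[pos] = float(rng.uniform(5.0, 19.0))
        else:                               # transient movement spike
            x[pos] = max(x[pos] - float(rng.uniform(6.0, 15.0)), 21.0)
    return SpO2Recording(rec.subject_id, x, setting=rec.setting,
                         sample_rate=rec.sample_rate, start_time=rec.start_time)


def simulate_cohort(
    n_subjects: int,
    ahi_range: tuple[float, float] = (0.0, 60.0),
    setting_pair: bool = False,
    seed: int = 0,
    base_config: SimulationConfig | None = None,
    night_jitter_sigma: float = 0.4,
) -> list[dict]:
    """Simulate a cohort; optionally a second "home" night per subject.

    Each subject draws a nominal event rate uniformly over ``ahi_range``;
    the achieved (implanted) rate of the lab-night recording is the
    subject's true AHI. With ``setting_pair`` the home recording is
    regenerated with the rate perturbed by a lognormal factor
    (night-to-night variability) and its own noise realization.

    Returns a list of dicts with keys ``subject_id``, ``recording``,
    ``truth``, ``ahi`` and, when paired, ``recording_home``/``truth_home``.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    base = base_config or SimulationConfig()
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    sub_seeds = ss.generate_state(2 * n_subjects) % (2 ** 31)

    cohort = []
    for i in range(n_subjects):
        rate = float(rng.uniform(*ahi_range))
        cfg = replace(base, event_rate=rate, seed=int(sub_seeds[2 * i]))
        rec, truth = simulate_recording(cfg, subject_id=f"S{i:03d}")
        entry = {"subject_id": rec.subject_id, "recording": rec,
                 "truth": truth, "ahi": truth.true_rate}
        if setting_pair:
            factor = float(rng.lognormal(0.0, night_jitter_sigma))
            cfg_home = replace(base, event_rate=rate * factor,
                               seed=int(sub_seeds[2 * i + 1]))
            rec_h, truth_h = simulate_recording(cfg_home, subject_id=rec.subject_id,
                                                setting="home")
            entry["recording_home"] = rec_h
            entry["truth_home"] = truth_h
        cohort.append(entry)
    return cohort
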