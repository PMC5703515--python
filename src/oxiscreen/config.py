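"""Flat run configuration shared by the CLI subcommands.

Defaults reproduce the published processing settings: the 4 %/s and 20 %
artifact rules, 512-sample segments with a 512-point Hann window / 50 %
overlap / 1024-point FFT Welch estimate, the 0.014-0.033 Hz apnea band,
4-bin equal-frequency discretization for the correlation filter, 100
repetitions of leave-one-out model selection, and the per-setting network
presets (N_H = 12 with nu = 1 in the laboratory, nu = 4 at home).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, fields
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    # preprocessing
    delta_limit: float = 4.0
    low_limit: float = 20.0
    min_consistent_s: int = 30
    # features
    segment_len: int = 512
    sampen_m: int = 1
    sampen_r: float = 0.25
    ctm_rho: float = 0.25
    band_low: float = 0.014
    band_high: float = 0.033
    freq_moment_basis: str = "amplitude"
    # feature selection
    fcbf_bins: int = 4
    # model
    n_hidden: int = 12
    nu: float = 1.0
    reps: int = 100
    seed: int = 0
    # indices
    odi_baseline_window_s: int = 120
    odi_max_event_s: int = 300
    # evaluation
    icc_variant: str = "agreement"
    cutoffs: tuple[float, float] = (15.0, 30.0)

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "cutoffs" in data:
            data["cutoffs"] = tuple(data["cutoffs"])
        return cls(**data)

    def save(self, path: str | Path) -> None:
        d = asdict(self)
        d["cutoffs"] = list(d["cutoffs"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    def to_dict(self) -> dict:
        return asdict(self)
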