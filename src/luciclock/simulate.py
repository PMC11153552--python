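"""Seeded synthetic plate recordings with known per-well ground truth.

The generator emulates population luciferase records from ~50-worm wells:
a luciferase-accumulation onset and slow substrate/ageing decline shape a
baseline ``B(t)``, the circadian oscillation rides on it multiplicatively,
zeitgeber transitions add short masking transients during entrained epochs,
and photon-counting noise scales with the signal level:

    L(t) = background + B(t) * [1 + a(t) * cos(psi(t))] + mask(t) + eps(t)
    B(t) = baseline_counts * (1 - exp(-t/accum_tau)) * exp(-t/decay_tau)

During cyclic epochs the oscillation is phase-locked to the zeitgeber with
each well's entrained acrophase; at release into constant conditions the
phase continues from its current value and advances with the well's own
free-running period, with exponential amplitude damping thereafter.  A
truth table records every well's rhythmicity flag, drawn period, and
entrained acrophase, so every pipeline stage can be checked against known
ground truth.

Per-well random substreams are derived from ``(seed, well index)``: adding
wells to a config never perturbs existing traces.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .plate_io import (
    Epoch,
    PlateRecording,
    ProtocolSchedule,
    Regime,
    TimeSeries,
    WellMeta,
)

__all__ = [
    "GroupSimSpec",
    "SimConfig",
    "simulate_plate",
    "default_study_schedule",
    "free_run_schedule",
    "default_study_config",
    "sim_config_from_dict",
    "sim_config_to_dict",
]

PERIOD_CLIP_H = (18.0, 35.0)  # keep generator truth inside the analysis band


@dataclass
class GroupSimSpec:
    """Per-genotype simulation parameters.

    ``rhythmic_fraction`` models partial rhythmicity of populations (the
    observed range is roughly 0.4-0.65); non-rhythmic wells get amplitude 0
    but keep the baseline and noise structure.
    """

    label: str
    n_wells: int
    period_mean_h: float = 24.0
    period_sd_h: float = 1.0
    rhythmic_fraction: float = 0.6
    amplitude_rel: float = 0.3
    damping_per_day: float = 0.15
    acrophase_zt_h: float = 15.0
    masking_rel: float = 0.1

    def __post_init__(self) -> None:
        if self.n_wells < 1:
            raise ValueError("n_wells must be >= 1")
        if self.period_sd_h < 0:
            raise ValueError("period_sd_h must be >= 0")
        if not 0 <= self.rhythmic_fraction <= 1:
            raise ValueError("rhythmic_fraction must be in [0, 1]")
        if self.amplitude_rel < 0:
            raise ValueError("amplitude_rel must be >= 0")


@dataclass
class SimConfig:
    """Whole-plate simulation: groups, protocol, baseline and noise model."""

    seed: int = 0
    groups: list[GroupSimSpec] = field(default_factory=list)
    schedule: ProtocolSchedule | None = None
    sampling_h: float = 0.5
    baseline_counts: float = 5000.0
    accum_tau_h: float = 8.0
    decay_tau_h: float = 120.0
    noise_model: str = "poisson_like"  # "poisson_like" | "gaussian"
    noise_scale: float = 1.0  # 0 disables noise
    background_counts: float = 100.0
    n_blank_wells: int = 2

    def __post_init__(self) -> None:
        if self.schedule is None:
            self.schedule = default_study_schedule()
        if not self.sampling_h > 0:
            raise ValueError("sampling_h must be positive")
        if self.noise_model not in ("poisson_like", "gaussian"):
            raise ValueError('noise_model must be "poisson_like" or "gaussian"')
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be >= 0")
        if self.n_blank_wells < 0:
            raise ValueError("n_blank_wells must be >= 0")


def default_study_schedule() -> ProtocolSchedule:
    """3 days of 12:12 LD/CW entrainment followed by 4 days free run."""
    return ProtocolSchedule(
        zt0_recording_offset=0.0,
        epochs=[
            Epoch(0.0, 72.0, Regime.CYCLIC),
            Epoch(72.0, 168.0, Regime.FREE_RUN),
        ],
    )


def free_run_schedule(days: float = 7.0) -> ProtocolSchedule:
    """Constant-conditions-only protocol (e.g. 7 days DD/WW)."""
    return ProtocolSchedule(
        zt0_recording_offset=0.0,
        epochs=[Epoch(0.0, 24.0 * days, Regime.FREE_RUN)],
    )


def default_study_config(
    control_period: float = 24.4,
    mutant_period: float = 26.4,
    *,
    seed: int = 0,
) -> SimConfig:
    """Two-group study emulation: control vs long-period mutant.

    30 wells per group, well-to-well period SD 1.0 h, 60% rhythmic wells,
    the 3-day cyclic + 4-day free-run schedule, and counting noise.
    """
    return SimConfig(
        seed=seed,
        groups=[
            GroupSimSpec(label="control", n_wells=30, period_mean_h=control_period),
            GroupSimSpec(label="mutant", n_wells=30, period_mean_h=mutant_period),
        ],
        schedule=default_study_schedule(),
    )


def _phase_angle(
    times: np.ndarray, schedule: ProtocolSchedule, tau_h: float, acrophase_zt_h: float
) -> np.ndarray:
    """Unwrapped oscillation phase: zeitgeber-locked in cyclic epochs,
    advancing at the endogenous period after release (continuous at the
    transition)."""
    psi = np.zeros_like(times)
    off = schedule.zt0_recording_offset
    carry: float | None = None
    for epoch in schedule.epochs:
        zp = epoch.zeitgeber_period
        mask = (times >= epoch.start_h - 1e-9) & (times <= epoch.end_h + 1e-9)
        if epoch.regime is Regime.CYCLIC:
            psi[mask] = 2.0 * np.pi * (times[mask] - off - acrophase_zt_h) / zp
            carry = 2.0 * np.pi * (epoch.end_h - off - acrophase_zt_h) / zp
        else:
            start_psi = (
                carry
                if carry is not None
                else 2.0 * np.pi * (epoch.start_h - off - acrophase_zt_h) / zp
            )
            psi[mask] = start_psi + 2.0 * np.pi * (times[mask] - epoch.start_h) / tau_h
            carry = start_psi + 2.0 * np.pi * (epoch.end_h - epoch.start_h) / tau_h
    return psi


def _mask_indicator(times: np.ndarray, schedule: ProtocolSchedule) -> np.ndarray:
    """1 within the first hour after each lights-on/off transition (cyclic only)."""
    ind = np.zeros_like(times)
    off = schedule.zt0_recording_offset
    for epoch in schedule.epochs:
        if epoch.regime is not Regime.CYCLIC:
            continue
        zp = epoch.zeitgeber_period
        in_epoch = (times >= epoch.start_h - 1e-9) & (times <= epoch.end_h + 1e-9)
        zt = np.mod(times - off, zp)
        for transition in (epoch.lights_on_zt, epoch.lights_off_zt):
            d = np.mod(zt - transition, zp)
            ind[in_epoch & (d < 1.0 - 1e-9)] = 1.0
    return ind


def _baseline(times: np.ndarray, cfg: SimConfig) -> np.ndarray:
    return (
        cfg.baseline_counts
        * (1.0 - np.exp(-times / cfg.accum_tau_h))
        * np.exp(-times / cfg.decay_tau_h)
    )


def well_signal(
    times: np.ndarray,
    cfg: SimConfig,
    group: GroupSimSpec,
    *,
    rhythmic: bool,
    tau_h: float,
    acrophase_zt_h: float,
) -> np.ndarray:
    """Noiseless expected luminescence of one well (closed form)."""
    B = _baseline(times, cfg)
    psi = _phase_angle(times, cfg.schedule, tau_h, acrophase_zt_h)
    fr = cfg.schedule.free_run_epochs()
    release = fr[0].start_h if fr else np.inf
    days_since_release = np.maximum(times - release, 0.0) / 24.0
    a = (
        group.amplitude_rel
        * (1.0 if rhythmic else 0.0)
        * np.exp(-group.damping_per_day * days_since_release)
    )
    mask = group.masking_rel * B * _mask_indicator(times, cfg.schedule)
    return cfg.background_counts + B * (1.0 + a * np.cos(psi)) + mask


def _noise(rng: np.random.Generator, expected: np.ndarray, cfg: SimConfig) -> np.ndarray:
    if cfg.noise_scale == 0:
        return np.zeros_like(expected)
    if cfg.noise_model == "poisson_like":
        sd = cfg.noise_scale * np.sqrt(np.maximum(expected, 1.0))
    else:
        sd = np.full_like(expected, cfg.noise_scale)
    return rng.normal(0.0, 1.0, size=expected.shape) * sd


def simulate_plate(cfg: SimConfig) -> tuple[PlateRecording, pd.DataFrame]:
    """Generate a plate recording plus its ground-truth table.

    Returns ``(recording, truth)`` where ``truth`` has one row per non-blank
    well with columns ``well, group, rhythmic, true_period_h,
    true_acrophase_zt_h``.
    """
    schedule = cfg.schedule
    times = np.arange(schedule.start_h, schedule.end_h + 1e-9, cfg.sampling_h)
    series: dict[str, TimeSeries] = {}
    meta: dict[str, WellMeta] = {}
    truth_rows = []
    well_index = 0
    for group in cfg.groups:
        for i in range(group.n_wells):
            rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, well_index]))
            well_id = f"{group.label}_{i + 1:02d}"
            rhythmic = bool(rng.random() < group.rhythmic_fraction)
            tau = float(
                np.clip(
                    rng.normal(group.period_mean_h, group.period_sd_h),
                    *PERIOD_CLIP_H,
                )
            )
            phi = float(group.acrophase_zt_h + rng.uniform(-1.0, 1.0))
            expected = well_signal(
                times, cfg, group, rhythmic=rhythmic, tau_h=tau, acrophase_zt_h=phi
            )
            values = expected + _noise(rng, expected, cfg)
            series[well_id] = TimeSeries(times.copy(), values, cfg.sampling_h)
            meta[well_id] = WellMeta(
                well_id=well_id, group=group.label, n_worms=50, is_blank=False
            )
            truth_rows.append(
                {
                    "well": well_id,
                    "group": group.label,
                    "rhythmic": rhythmic,
                    "true_period_h": tau,
                    "true_acrophase_zt_h": phi,
                }
            )
            well_index += 1
    for b in range(cfg.n_blank_wells):
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, well_index]))
        well_id = f"blank_{b + 1:02d}"
        expected = np.full_like(times, float(cfg.background_counts))
        values = expected + _noise(rng, expected, cfg)
        series[well_id] = TimeSeries(times.copy(), values, cfg.sampling_h)
        meta[well_id] = WellMeta(well_id=well_id, group="blank", n_worms=0, is_blank=True)
        well_index += 1
    rec = PlateRecording(series, meta, schedule)
    truth = pd.DataFrame(
        truth_rows,
        columns=["well", "group", "rhythmic", "true_period_h", "true_acrophase_zt_h"],
    )
    return rec, truth


# ---------------------------------------------------------------------------
# JSON config plumbing

def sim_config_to_dict(cfg: SimConfig) -> dict:
    from .plate_io import schedule_to_dict

    return {
        "seed": cfg.seed,
        "groups": [vars(g).copy() for g in cfg.groups],
        "schedule": schedule_to_dict(cfg.schedule),
        "sampling_h": cfg.sampling_h,
        "baseline_counts": cfg.baseline_counts,
        "accum_tau_h": cfg.accum_tau_h,
        "decay_tau_h": cfg.decay_tau_h,
        "noise_model": cfg.noise_model,
        "noise_scale": cfg.noise_scale,
        "background_counts": cfg.background_counts,
        "n_blank_wells": cfg.n_blank_wells,
    }


def sim_config_from_dict(d: Mapping) -> SimConfig:
    from .plate_io import schedule_from_dict

    kwargs = {k: v for k, v in d.items() if k not in ("groups", "schedule")}
    groups = [GroupSimSpec(**g) for g in d.get("groups", [])]
    schedule = schedule_from_dict(d["schedule"]) if "schedule" in d else None
    return SimConfig(groups=groups, schedule=schedule, **kwargs)


def read_sim_config(path: str | Path) -> SimConfig:
    return sim_config_from_dict(json.loads(Path(path).read_text()))


def write_sim_config(cfg: SimConfig, path: str | Path) -> None:
    Path(path).write_text(json.dumps(sim_config_to_dict(cfg), indent=2) + "\n")
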