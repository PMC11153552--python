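"""End-to-end per-well analysis and group summaries.

For every non-blank well the pipeline conditions the full trace, classifies
entrainment on the cyclic epoch (24-h cosinor), estimates the endogenous
period on the free-run epoch (Lomb-Scargle) and classifies rhythmicity
there (cosinor at the Lomb-Scargle period), and extracts the peak phases
that feed the Rayleigh plots: the peak of the last entrained cycle
(expressed in Zeitgeber Time) and the first peak after release (hours after
release, modulo 24; the window extends to 26 h to catch late first peaks of
long-period genotypes).

Group summaries report the rhythmic fraction, the mean +/- SEM free-running
period over rhythmic wells only, and circular phase statistics over the
rhythmic wells of each group.  Inferential group comparisons (ANOVA,
post-hoc tests) are deliberately not included; the summary tables are
structured for direct consumption by any statistics package.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import circular, cosinor, preprocess, spectral
from .circular import CircularSummary, PhaseSet
from .cosinor import Category, CosinorFit, RhythmCall
from .plate_io import PlateRecording, TimeSeries
from .preprocess import PreprocessConfig
from .spectral import PeriodogramConfig, PeriodogramResult

__all__ = [
    "WellResult",
    "GroupSummary",
    "analyze_recording",
    "summarize_groups",
    "results_to_frame",
    "summaries_to_frame",
    "FIRST_FR_PEAK_WINDOW_H",
    "MIN_FR_SPAN_H",
]

FIRST_FR_PEAK_WINDOW_H = 26.0
MIN_FR_SPAN_H = 48.0


@dataclass
class WellResult:
    """All per-well outputs; ``status`` records preprocessing failures."""

    well_id: str
    group: str
    status: str = "ok"
    sync_call: RhythmCall | None = None
    circadian_call: RhythmCall | None = None
    fr_period_h: float | None = None
    fr_fit: CosinorFit | None = None
    phase_ldcw_h: float | None = None
    phase_fr_h: float | None = None
    periodogram: PeriodogramResult | None = None
    processed: TimeSeries | None = None


@dataclass
class GroupSummary:
    group: str
    n_total: int
    n_rhythmic: int
    percent_rhythmic: float | None
    period_mean_h: float | None
    period_sem_h: float | None
    phase_summary_ldcw: CircularSummary | None = None
    phase_summary_fr: CircularSummary | None = None


def _check_schedule(rec: PlateRecording) -> None:
    fr = rec.schedule.free_run_epochs()
    if not fr:
        raise ValueError("schedule has no FREE_RUN epoch; nothing to analyze")
    if fr[0].span_h < MIN_FR_SPAN_H - 1e-9:
        raise ValueError(
            f"free-run epoch spans {fr[0].span_h:.1f} h; need >= {MIN_FR_SPAN_H:.0f} h "
            "(2 days) for period estimation"
        )
    for well, ts in rec.series.items():
        if len(ts) and ts.times[-1] + ts.nominal_interval < fr[0].start_h + MIN_FR_SPAN_H - 1e-9:
            raise ValueError(
                f"series {well!r} ends at {ts.times[-1]:.1f} h but the schedule's "
                f"free-run analysis needs data through "
                f"{fr[0].start_h + MIN_FR_SPAN_H:.1f} h"
            )


def analyze_recording(
    rec: PlateRecording,
    pre_cfg: PreprocessConfig | None = None,
    pg_cfg: PeriodogramConfig | None = None,
) -> list[WellResult]:
    """Analyze every non-blank well of a recording.

    Wells whose preprocessing or fits fail are reported with an error
    status rather than silently dropped.
    """
    pre_cfg = pre_cfg or PreprocessConfig()
    pg_cfg = pg_cfg or PeriodogramConfig()
    _check_schedule(rec)
    schedule = rec.schedule
    bg_override: float | None = None
    if pre_cfg.background == "from_blanks":
        bg_override = preprocess.estimate_background(rec)
    cyclic = schedule.cyclic_epochs()
    fr = schedule.free_run_epochs()[0]

    results: list[WellResult] = []
    for well in rec.analysis_wells():
        meta = rec.meta[well]
        res = WellResult(well_id=well, group=meta.group)
        try:
            pp = preprocess.preprocess_well(
                rec.series[well], pre_cfg, background_override=bg_override
            )
        except ValueError as exc:
            res.status = f"error: {exc}"
            results.append(res)
            continue
        res.processed = pp

        if cyclic:
            cyc = cyclic[0]
            sub = pp.window(cyc.start_h, cyc.end_h)
            try:
                res.sync_call = cosinor.classify_synchronized(sub)
            except ValueError:
                res.sync_call = None
            # Peak of the last full entrained cycle, in Zeitgeber Time.
            zp = cyc.zeitgeber_period
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", circular.BoundaryPeakWarning)
                    res.phase_ldcw_h = circular.peak_phase(
                        pp,
                        (cyc.end_h - zp, cyc.end_h),
                        cycle_h=zp,
                        anchor=schedule.zt0_recording_offset,
                    )
            except ValueError:
                res.phase_ldcw_h = None

        sub_fr = pp.window(fr.start_h, fr.end_h)
        try:
            pg = spectral.lomb_scargle(sub_fr, pg_cfg)
            est = spectral.best_period(pg)
            res.periodogram = pg
            res.circadian_call = cosinor.classify_circadian(sub_fr, est)
            if res.circadian_call.category is Category.CIRCADIAN:
                res.fr_period_h = res.circadian_call.period_h
            res.fr_fit = res.circadian_call.fit
        except ValueError as exc:
            res.status = f"error: {exc}"
            results.append(res)
            continue
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", circular.BoundaryPeakWarning)
                res.phase_fr_h = circular.peak_phase(
                    pp,
                    (fr.start_h, fr.start_h + FIRST_FR_PEAK_WINDOW_H),
                    cycle_h=24.0,
                    anchor=fr.start_h,
                )
        except ValueError:
            res.phase_fr_h = None
        results.append(res)
    return results


def _phase_summary(phases: list[float], cycle_h: float, context: str) -> CircularSummary | None:
    phases = [p for p in phases if p is not None]
    if not phases:
        return None
    ps = PhaseSet(np.mod(np.asarray(phases), cycle_h), cycle_h=cycle_h, context=context)
    return circular.summarize_phases(ps)


def summarize_groups(results: list[WellResult], cycle_h: float = 24.0) -> list[GroupSummary]:
    """Per-group descriptive statistics over analyzable wells.

    Period mean and SEM (sample SD / sqrt(n)) are computed over wells
    classified CIRCADIAN only; SEM is undefined (absent) for a single
    rhythmic well, and period fields are absent for groups with none.
    Circular phase summaries cover the rhythmic wells of the group.
    """
    if not results:
        raise ValueError("no well results to summarize")
    order: dict[str, list[WellResult]] = {}
    for res in results:
        order.setdefault(res.group, []).append(res)
    summaries = []
    for group, wells in order.items():
        ok = [w for w in wells if w.status == "ok"]
        rhythmic = [
            w
            for w in ok
            if w.circadian_call is not None
            and w.circadian_call.category is Category.CIRCADIAN
        ]
        n_total = len(ok)
        n_rhythmic = len(rhythmic)
        percent = 100.0 * n_rhythmic / n_total if n_total else None
        periods = np.array([w.fr_period_h for w in rhythmic], dtype=float)
        mean = float(periods.mean()) if n_rhythmic else None
        sem = (
            float(periods.std(ddof=1) / math.sqrt(n_rhythmic))
            if n_rhythmic >= 2
            else None
        )
        summaries.append(
            GroupSummary(
                group=group,
                n_total=n_total,
                n_rhythmic=n_rhythmic,
                percent_rhythmic=percent,
                period_mean_h=mean,
                period_sem_h=sem,
                phase_summary_ldcw=_phase_summary(
                    [w.phase_ldcw_h for w in rhythmic], cycle_h, "entrained peak"
                ),
                phase_summary_fr=_phase_summary(
                    [w.phase_fr_h for w in rhythmic], cycle_h, "first free-run peak"
                ),
            )
        )
    return summaries


# ---------------------------------------------------------------------------
# Tabular export

def results_to_frame(results: list[WellResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        fit = r.fr_fit
        rows.append(
            {
                "well": r.well_id,
                "group": r.group,
                "status": r.status,
                "sync_category": r.sync_call.category.value if r.sync_call else "",
                "sync_r_squared": r.sync_call.r_squared if r.sync_call else np.nan,
                "circadian_category": (
                    r.circadian_call.category.value if r.circadian_call else ""
                ),
                "fr_period_h": r.fr_period_h if r.fr_period_h is not None else np.nan,
                "fr_r_squared": fit.r_squared if fit else np.nan,
                "fr_amplitude": fit.amplitude if fit else np.nan,
                "fr_acrophase_h": fit.acrophase_h if fit else np.nan,
                "fr_mesor": fit.mesor if fit else np.nan,
                "phase_ldcw_zt_h": r.phase_ldcw_h if r.phase_ldcw_h is not None else np.nan,
                "phase_fr_h": r.phase_fr_h if r.phase_fr_h is not None else np.nan,
            }
        )
    return pd.DataFrame(rows)


def summaries_to_frame(summaries: list[GroupSummary]) -> pd.DataFrame:
    def _cs(cs: CircularSummary | None, what: str):
        if cs is None:
            return {f"{what}_n": 0, f"{what}_mean_phase_h": np.nan,
                    f"{what}_R": np.nan, f"{what}_rayleigh_p": np.nan}
        return {
            f"{what}_n": cs.n,
            f"{what}_mean_phase_h": cs.mean_phase_h if cs.mean_phase_h is not None else np.nan,
            f"{what}_R": cs.resultant_R,
            f"{what}_rayleigh_p": cs.rayleigh_p if cs.rayleigh_p is not None else np.nan,
        }

    rows = []
    for s in summaries:
        row = {
            "group": s.group,
            "n_total": s.n_total,
            "n_rhythmic": s.n_rhythmic,
            "percent_rhythmic": s.percent_rhythmic if s.percent_rhythmic is not None else np.nan,
            "period_mean_h": s.period_mean_h if s.period_mean_h is not None else np.nan,
            "period_sem_h": s.period_sem_h if s.period_sem_h is not None else np.nan,
        }
        row.update(_cs(s.phase_summary_ldcw, "phase_ldcw"))
        row.update(_cs(s.phase_summary_fr, "phase_fr"))
        rows.append(row)
    return pd.DataFrame(rows)
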