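"""End-to-end analysis pipeline: events -> tables, chains, temporal and
inferential results, written as a reproducible report bundle."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from datetime import timedelta
from pathlib import Path

import pandas as pd

from .errors import UrsamarkError
from .ethogram import CLAWING, BITING, default_ethogram
from .events import (
    filter_independent_events,
    parse_event_log,
    parse_sites,
    summarize_durations,
    tabulate_behavior_frequencies,
    tabulate_class_behavior,
    tabulate_mark_heights,
    apply_merge,
)
from .inference import DebarkingModel, anova_tukey, chisq_gof_exposure
from .sequences import MarkovChain
from .solar import (
    annotate_events,
    build_actogram,
    camera_trap_days,
    compute_ric,
    period_durations_hours,
    solar_events,
    PERIODS,
)

logger = logging.getLogger(__name__)

_DURATION_BEHAVIORS = ("dorsal", "clawing", "investigation", "facial", "biting", "pedal")


@dataclass
class RunConfig:
    """Configuration of one pipeline run; defaults match the study analysis."""

    events_path: str
    sites_path: str
    out_dir: str
    window_minutes: float = 30.0
    prune_threshold: float = 0.1
    alpha: float = 0.05
    year: int | None = None
    seed: int = 0
    glm_term_sets: tuple = DebarkingModel.DEFAULT_TERM_SETS

    @classmethod
    def from_file(cls, path, **overrides):
        """Flat ``key = value`` config file; keyword overrides win."""
        kwargs = {}
        for raw in Path(path).read_text().splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, value = line.partition("=")
            kwargs[key.strip()] = value.strip()
        for k in ("window_minutes", "prune_threshold", "alpha"):
            if k in kwargs:
                kwargs[k] = float(kwargs[k])
        for k in ("year", "seed"):
            if k in kwargs:
                kwargs[k] = int(kwargs[k])
        kwargs.update(overrides)
        return cls(**kwargs)


class PipelineError(UrsamarkError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


def run_pipeline(config: RunConfig) -> dict:
    """Run the whole analysis and write the report bundle.

    Deterministic given the config; any stage error aborts the run, removes
    partial outputs, and raises :class:`PipelineError` naming the stage.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    log_lines: list[str] = []

    def note(msg):
        logger.info(msg)
        log_lines.append(msg)

    def save_csv(df: pd.DataFrame, name: str, index=True):
        path = out_dir / name
        df.to_csv(path, index=index)
        written.append(path)

    def save_json(obj, name: str):
        path = out_dir / name
        path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=str))
        written.append(path)

    def save_text(text: str, name: str):
        path = out_dir / name
        path.write_text(text)
        written.append(path)

    bundle: dict = {"config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(config).items()}}
    ethogram = default_ethogram()
    stage = "load"
    try:
        sites = parse_sites(config.sites_path)
        detections = parse_event_log(config.events_path, dialect="native_csv")
        note(f"load: {len(detections)} detections from {config.events_path}, {len(sites)} sites")

        stage = "filter"
        events = filter_independent_events(detections, config.window_minutes)
        note(f"filter: {len(detections)} detections -> {len(events)} independent events "
             f"(window {config.window_minutes} min)")
        year = config.year or min(ev.start.year for ev in events)

        stage = "tabulate"
        merged = apply_merge(events, ethogram, "visual_view")
        freq = tabulate_behavior_frequencies(merged)
        class_tab = tabulate_class_behavior(events, grouping="coarse")
        save_csv(freq, "behavior_frequencies.csv")
        save_csv(class_tab, "class_behavior.csv")
        timed = [ev for ev in events if ev.has(CLAWING, BITING)]
        durations = None
        if timed:
            durations = summarize_durations(timed, behaviors=_DURATION_BEHAVIORS)
            save_csv(durations, "durations.csv")
        heights = None
        if any(ev.mark_height for ev in events):
            heights = tabulate_mark_heights(events)
            save_json(heights, "mark_heights.json")
        note(f"tabulate: {len(events)} events, {len(timed)} with timed natural visual marks")

        stage = "sequences"
        male_marking = [ev for ev in events if ev.bear_class == "adult_male" and ev.bouts]
        chains = {}
        for preset in ("diagram", "full_chain"):
            res = MarkovChain.from_events(male_marking, preset=preset).fit(
                prune_threshold=config.prune_threshold
            )
            chains[preset] = res
            save_csv(res.counts, f"transitions_{preset}_counts.csv")
            save_csv(res.probs.round(6), f"transitions_{preset}_probs.csv")
            save_text(res.to_dot(), f"{preset}.dot")
        note(f"sequences: {len(male_marking)} adult-male sequences, "
             f"{chains['diagram'].n_transitions} transitions (diagram view)")

        stage = "temporal"
        annotations = annotate_events(events, sites)
        ric = compute_ric(events, sites, year)
        actogram = build_actogram(events, sites)
        save_csv(annotations, "annotations.csv")
        save_csv(ric, "ric.csv")
        save_csv(actogram, "actogram.csv", index=False)
        note(f"temporal: {len(annotations)} annotations, "
             f"{int(ric.camera_trap_days.sum())} camera-trap days, "
             f"{len(actogram)} actogram rows")

        stage = "gof"
        effort = camera_trap_days(sites, year)
        months = [m for m in range(1, 13) if effort.camera_trap_days[m] > 0]
        observed_m = [sum(ev.start.month == m for ev in events) for m in months]
        gof_monthly = chisq_gof_exposure(
            observed_m, [effort.camera_trap_days[m] for m in months], bins=months
        )
        period_exposure = _period_exposure_hours(sites, year)
        observed_p = [int((annotations.period == p).sum()) for p in PERIODS]
        gof_period = chisq_gof_exposure(
            observed_p, [period_exposure[p] for p in PERIODS], bins=PERIODS
        )
        save_json(gof_monthly.to_dict(), "gof_monthly.json")
        save_json(gof_period.to_dict(), "gof_period.json")
        note(f"gof: monthly chi2={gof_monthly.chi2:.1f} (df {gof_monthly.df}), "
             f"period chi2={gof_period.chi2:.1f} (df {gof_period.df})")

        stage = "glm"
        glm_payload = None
        frame = annotations.copy()
        frame["debark"] = [ev.is_visual_marking for ev in events]
        behavioral = frame[[ev.has("investigation") or ev.is_marking for ev in events]]
        try:
            fits, comparison = DebarkingModel.from_dataframe(behavioral).fit_all(
                config.glm_term_sets
            )
            glm_payload = {
                "models": [f.to_dict() for f in fits],
                "comparison": comparison.to_dict(orient="records"),
            }
            save_json(glm_payload, "glm.json")
            note(f"glm: {len(fits)} candidate models on n={len(behavioral)} events")
        except (ValueError, UrsamarkError) as exc:
            note(f"glm: skipped ({exc})")

        stage = "anova"
        anova_payload = None
        if len(timed) >= 2:
            groups, values = [], []
            for code in _DURATION_BEHAVIORS:
                for ev in timed:
                    groups.append(code)
                    values.append(sum(b.duration_s for b in ev.bouts if b.behavior == code))
            result = anova_tukey(groups, values)
            anova_payload = result.to_dict()
            save_json(anova_payload, "anova.json")
            note(f"anova: F({result.df1},{result.df2})={result.F:.2f}, p={result.p:.3g}")
        else:
            note("anova: skipped (fewer than 2 events with timed natural visual marks)")

        stage = "report"
        bundle.update(
            {
                "n_detections": len(detections),
                "n_events": len(events),
                "year": year,
                "behavior_frequencies": freq.reset_index().to_dict(orient="records"),
                "class_behavior": class_tab.reset_index(names="class").to_dict(orient="records"),
                "durations": durations.reset_index().to_dict(orient="records") if durations is not None else None,
                "mark_heights": heights,
                "ric": ric.reset_index().to_dict(orient="records"),
                "gof_monthly": gof_monthly.to_dict(),
                "gof_period": gof_period.to_dict(),
                "glm": glm_payload,
                "anova": anova_payload,
            }
        )
        save_json(bundle, "report.json")
        save_text("\n".join(log_lines) + "\n", "run.log")
    except Exception as exc:
        for path in written:
            path.unlink(missing_ok=True)
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, exc) from exc
    return bundle


def _period_exposure_hours(sites, year: int) -> dict[str, float]:
    """Summed diel-period durations (hours) over all deployed site-days."""
    totals = {p: 0.0 for p in PERIODS}
    for site in sites:
        for d0, d1 in site.deployments:
            day = d0.date() if hasattr(d0, "date") else d0
            end = d1.date() if hasattr(d1, "date") else d1
            while day <= end:
                if day.year == year:
                    for p, h in period_durations_hours(solar_events(site, day)).items():
                        totals[p] += h
                day += timedelta(days=1)
    return totals


__all__ = ["RunConfig", "PipelineError", "run_pipeline"]
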