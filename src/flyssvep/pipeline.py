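"""End-to-end pipeline: simulate (or load) -> preprocess -> score behavior ->
extract amplitudes -> contrasts -> report."""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import behavior as beh
from . import ssvep, stats
from .config import RunConfig
from .preprocess import ChannelMap, preprocess
from .synthdata import Recording, simulate_recording

__all__ = ["PipelineError", "FlyResult", "process_recording", "run_pipeline", "score_behavior"]

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class FlyResult:
    fly_id: int
    records: pd.DataFrame
    bouts: list
    segments: list
    spells: list
    channel_map: ChannelMap
    report: dict


def score_behavior(rec: Recording, cfg: RunConfig):
    """Sleep bouts, labeled segments and proboscis spells for one recording."""
    b = cfg.behavior
    active = beh.quantify_movement(rec.movement, rec.fs, bin_s=b.bin_s,
                                   threshold=b.movement_threshold)
    bouts = beh.score_bouts(active, bin_s=b.bin_s, min_sleep_s=b.min_sleep_s)
    segments = beh.segment_bouts(bouts)
    pe = beh.detect_pe_events(rec.proboscis, rec.fs, threshold=b.pe_threshold,
                              merge_gap_s=b.pe_merge_gap_s)
    _, spells = beh.classify_pe(pe, bouts=bouts, segments=segments,
                                spell_gap_s=b.spell_gap_s,
                                min_spell_events=b.min_spell_events,
                                reach_min_duration_s=b.reach_min_duration_s)
    return bouts, segments, spells


def process_recording(rec: Recording, cfg: RunConfig, fly_id: int = 0) -> FlyResult:
    """Preprocess one recording and build its labeled amplitude table."""
    try:
        rec, cmap, report = preprocess(
            rec,
            target_fs=cfg.preprocessing.target_fs,
            line_base_hz=cfg.preprocessing.line_base_hz,
            max_duration_s=cfg.preprocessing.max_duration_s,
            all_channels_mode=cfg.preprocessing.all_channels_mode,
        )
    except Exception as exc:
        raise PipelineError("preprocess", f"fly {fly_id}: {exc}") from exc
    try:
        bouts, segments, spells = score_behavior(rec, cfg)
    except Exception as exc:
        raise PipelineError("score-behavior", f"fly {fly_id}: {exc}") from exc
    try:
        records = ssvep.build_amplitude_records(
            rec, cmap, fly_id=fly_id, bouts=bouts, segments=segments, spells=spells,
            window_s=(cfg.ssvep.window_start_s, cfg.ssvep.window_end_s),
        )
    except Exception as exc:
        raise PipelineError("extract", f"fly {fly_id}: {exc}") from exc
    return FlyResult(fly_id=fly_id, records=records, bouts=bouts, segments=segments,
                     spells=spells, channel_map=cmap, report=report)


def run_pipeline(cfg: RunConfig, recordings: list[Recording] | None = None,
                 out_dir=None, figures: bool = True):
    """Run the full analysis over simulated (or supplied) flies.

    Returns ``(comparisons, records, report_dir)``.  Deterministic given
    (config, seed): per-fly seeds are spawned from ``cfg.seed``.
    """
    results: list[FlyResult] = []
    if recordings is None:
        child_seeds = np.random.SeedSequence(cfg.seed).generate_state(cfg.n_flies) % (2**31)
        for i in range(cfg.n_flies):
            rec = simulate_recording(cfg.simulator, cfg.duration_s, cfg.trial_type,
                                     seed=int(child_seeds[i]))
            results.append(process_recording(rec, cfg, fly_id=i))
    else:
        for i, rec in enumerate(recordings):
            results.append(process_recording(rec, cfg, fly_id=i))

    records = pd.concat([r.records for r in results], ignore_index=True)
    try:
        records = ssvep.normalize_amplitudes(records)
    except Exception as exc:
        raise PipelineError("normalize", str(exc)) from exc

    comparisons = []
    for spec in cfg.contrasts:
        try:
            groups = ssvep.select_contrast(records, spec.name, color=spec.color,
                                           role=spec.role, region=spec.region)
            groups = {k: v for k, v in groups.items() if len(v)}
            if len(groups) < 2:
                log.info("contrast %s: fewer than 2 non-empty groups; skipped", spec.name)
                continue
            corrected = ssvep.corrected_amplitude(groups)
            name = spec.name + (f"[{spec.role}]" if spec.role else "") \
                + (f"[{spec.color}]" if spec.color else "")
            comparisons.append(
                stats.compare_groups(corrected, name, region=spec.region,
                                     alpha=cfg.stats.alpha)
            )
        except stats.InsufficientDataError as exc:
            log.info("contrast %s skipped: %s", spec.name, exc)
        except Exception as exc:
            raise PipelineError("analyze", f"contrast {spec.name}: {exc}") from exc

    bout_rows = pd.concat(
        [beh.bouts_to_frame(r.bouts, fly_id=r.fly_id) for r in results], ignore_index=True
    )
    report_dir = None
    if out_dir is not None:
        manifest = {
            "seed": cfg.seed,
            "n_flies": cfg.n_flies,
            "config_hash": hashlib.sha256(repr(cfg).encode()).hexdigest()[:16],
        }
        try:
            report_dir = stats.build_report(comparisons, out_dir, bouts=bout_rows,
                                            manifest=manifest, figures=figures)
            records.to_csv(report_dir / "amplitudes.csv", index=False)
        except Exception as exc:
            raise PipelineError("report", str(exc)) from exc
    return comparisons, records, report_dir
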