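"""End-to-end orchestration: cohort -> labels -> markers -> behaviorome -> scores.

The marker path streams one participant-day at a time, so cohort-scale
behaviorome tables (40 subjects x 30 days of 1 Hz data) never hold full
streams in memory.  Ground-truth activity labels are used by default; the
recognizer-based path (train Home-AR / Mobile-AR on part of the cohort, then
relabel) is exercised by the CLI ``label`` stage.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import synthetic
from .assemble import assemble_behaviorome
from .markers import compute_home_markers, stack_days, watch_markers_from_arrays
from .synthetic import DAY_SECONDS, CohortConfig, RoutineProfile


def _observed_mask(date: pd.Timestamp, spans: pd.DataFrame) -> np.ndarray | None:
    """Boolean keep-mask over the day's 1 Hz grid after gap removal."""
    day_spans = spans[spans["date"] == date] if len(spans) else spans
    if len(day_spans) == 0:
        return None
    keep = np.ones(DAY_SECONDS, dtype=bool)
    for row in day_spans.itertuples(index=False):
        keep[row.start_s : row.start_s + row.n_seconds] = False
    return keep


def participant_marker_tables(
    config: CohortConfig,
    profile: RoutineProfile,
    p_idx: int,
) -> tuple[tuple[pd.DataFrame, pd.DataFrame], tuple[pd.DataFrame, pd.DataFrame]]:
    """(home, watch) (daily, hourly) marker tables for one participant,
    computed day by day from ground-truth-labeled synthetic streams."""
    dates = synthetic.cohort_dates(config)
    spans = (
        synthetic.draw_gap_spans(list(dates), config, synthetic.participant_rng(config.seed, p_idx, 2))
        if config.inject_gaps
        else pd.DataFrame(columns=["date", "start_s", "n_seconds"])
    )
    home_daily, home_hourly, watch_daily, watch_hourly = {}, {}, {}, {}
    for date, ambient, watch_arrays in synthetic.iter_participant_days(config, profile, p_idx):
        home_daily[date], home_hourly[date] = compute_home_markers(ambient, date)
        watch_daily[date], watch_hourly[date] = watch_markers_from_arrays(
            watch_arrays, _observed_mask(date, spans)
        )
    return (
        stack_days(home_daily, home_hourly),
        stack_days(watch_daily, watch_hourly),
    )


def cohort_feature_tables(
    config: CohortConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """(demographics, behaviorome, scores) tables for a synthetic cohort.

    Rows are indexed by participant id; behaviorome columns follow the fused
    schema (home block then watch block).
    """
    profiles = synthetic.cohort_profiles(config)
    demo, scores, _true = synthetic.cohort_scores(config)
    vectors = {}
    for p_idx, (pid, profile) in enumerate(profiles.items()):
        home, watch = participant_marker_tables(config, profile, p_idx)
        vectors[pid] = assemble_behaviorome(home=home, watch=watch)
    behaviorome = pd.DataFrame(vectors).T
    behaviorome.index.name = "participant_id"
    demo.index = behaviorome.index
    scores.index = behaviorome.index
    return demo, behaviorome, scores
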