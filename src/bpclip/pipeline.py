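"""End-to-end glue: sessions -> oscillograms -> screened feature table.

These helpers chain the imaging, oscillogram and screening stages so that a
cohort of recorded (or synthetic) sessions becomes the subject-by-feature
table the estimator consumes. Synthetic sessions carry their ground-truth
blood pressures, which stand in for the cuff reference a study would record.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import imaging, oscillogram
from .estimator import BPRegressionModel, _feature_columns
from .mechanics import DEFAULT_GEOMETRY, DEFAULT_SPRING
from .oscillogram import Oscillogram, ScreeningResult
from .protocol import SessionRecording


def session_oscillogram(
    session: SessionRecording,
    use_frames: bool | None = None,
    spring=DEFAULT_SPRING,
    geometry=DEFAULT_GEOMETRY,
) -> Oscillogram:
    """Raw (un-normalized) oscillogram of one session.

    Frames, when present, are pushed through the imaging pipeline; signal-
    level sessions use their stored per-level records directly.
    """
    levels = imaging.session_levels(session, use_frames=use_frames)
    return oscillogram.build_oscillogram(
        levels, session.frame_rate, spring, geometry
    )


def screen_session(
    session: SessionRecording,
    sbp_ref: float,
    dbp_ref: float,
    use_frames: bool | None = None,
    spring=DEFAULT_SPRING,
    geometry=DEFAULT_GEOMETRY,
) -> tuple[ScreeningResult, Oscillogram]:
    """Screening decision plus the raw oscillogram it was based on."""
    osc = session_oscillogram(session, use_frames, spring, geometry)
    return oscillogram.screen_subject(osc, sbp_ref, dbp_ref), osc


def cohort_table(
    sessions: list[SessionRecording],
    use_frames: bool | None = None,
    spring=DEFAULT_SPRING,
    geometry=DEFAULT_GEOMETRY,
) -> pd.DataFrame:
    """Screened cohort feature table from synthetic sessions.

    One row per subject with the 18 normalized amplitudes (NaN for excluded
    subjects), references, and the screening outcome. References come from
    each session's ground-truth subject.
    """
    rows = []
    for i, sess in enumerate(sessions):
        sub = sess.subject
        if sub is None:
            raise ValueError(f"session {i} carries no reference blood pressures")
        row = {
            "subject_id": i,
            "sbp_ref": sub.sbp_true,
            "dbp_ref": sub.dbp_true,
        }
        if not sess.complete:
            row.update(retained=False, reason="incomplete_session")
            rows.append(row)
            continue
        screening, osc = screen_session(
            sess, sub.sbp_true, sub.dbp_true, use_frames, spring, geometry
        )
        row.update(retained=screening.retained, reason=screening.reason)
        if screening.retained:
            feats = oscillogram.exclude_and_normalize(osc).amplitude
            row.update(dict(zip(_feature_columns(len(feats)), feats)))
        rows.append(row)
    df = pd.DataFrame(rows)
    return df


def retained_model(table: pd.DataFrame) -> BPRegressionModel:
    """Estimator model over the retained subjects of a cohort table."""
    kept = table[table["retained"]].reset_index(drop=True)
    cols = _feature_columns()
    return BPRegressionModel(
        kept[cols].to_numpy(),
        kept["sbp_ref"].to_numpy(),
        kept["dbp_ref"].to_numpy(),
        subject_ids=kept["subject_id"].to_numpy(),
    )
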