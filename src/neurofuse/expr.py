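"""Facial-expression features: target-expression frame counts per window.

The pipeline consumes per-frame categorical expression labels (produced
upstream by any facial-expression-recognition model; a pluggable labeler
hook is provided) and counts, in every consecutive window of 40 frames, how
many frames show the stimulus's target expression.  The resulting
per-window counts are the behavioral imitation feature vector.
"""

from __future__ import annotations

import logging
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .types import ExpressionTrack

__all__ = ["count_target_frames", "expr_feature_table", "relabel"]

logger = logging.getLogger(__name__)

#: A frame labeler maps raw per-frame observations to categorical labels.
#: Real FER models can be plugged in here; the pipeline only needs labels.
FrameLabeler = Callable[[Sequence[object]], list[str]]


def relabel(track: ExpressionTrack, labeler: FrameLabeler) -> ExpressionTrack:
    """Re-run frame labelling with a custom labeler (identity by default
    elsewhere); returns a new track with the same target label."""
    return ExpressionTrack(labels=labeler(track.labels),
                           subject_id=track.subject_id,
                           target_label=track.target_label)


def count_target_frames(track: ExpressionTrack, window: int = 40
                        ) -> np.ndarray:
    """Target-expression frame count in each full ``window``-frame block.

    Component ``w`` counts frames with the target label among frames
    ``[w*window, (w+1)*window)``.  A trailing partial window is dropped so
    every count lives on the common ``[0, window]`` scale.
    """
    if window < 1:
        raise ValueError(f"window: must be >= 1, got {window}")
    if len(track) == 0:
        raise ValueError(f"track {track.subject_id!r}: empty label track")
    n_windows = len(track) // window
    hits = np.fromiter((lab == track.target_label for lab in track.labels),
                       dtype=int, count=len(track))
    return hits[: n_windows * window].reshape(n_windows, window).sum(axis=1)


def expr_feature_table(tracks: list[ExpressionTrack], window: int = 40
                       ) -> pd.DataFrame:
    """Subjects x windows count matrix (columns ``w1..wn``).

    Tracks of unequal length are truncated to the shortest full-window
    length (with a warning); a track shorter than one window is an error.
    """
    if not tracks:
        raise ValueError("tracks: empty input")
    for t in tracks:
        if len(t) < window:
            raise ValueError(
                f"track {t.subject_id!r}: {len(t)} frames, shorter than one "
                f"{window}-frame window")
    n_windows = min(len(t) for t in tracks) // window
    lengths = {len(t) for t in tracks}
    if len(lengths) > 1:
        logger.warning(
            "expression tracks have unequal lengths %s; truncating all to "
            "%d windows", sorted(lengths), n_windows)
    rows = [count_target_frames(t, window)[:n_windows] for t in tracks]
    df = pd.DataFrame(rows, index=[t.subject_id for t in tracks],
                      columns=[f"w{w + 1}" for w in range(n_windows)])
    df.index.name = "subject_id"
    return df
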