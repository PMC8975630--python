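"""Plain-text persistence of cohorts, features and reports.

On-disk layout of a cohort directory::

    fixations.csv        subject_id,x,y           (one row per fixation)
    expressions.csv      subject_id,frame,label   (one row per frame)
    eeg/<subject_id>.csv header = channel names, one row per sample
    eeg/<subject_id>.json  {"fs": ..., "channels": [...]}
    manifest.json        subject ids, labels, target expression label
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    CHANNELS_14,
    Cohort,
    EEGRecording,
    ExpressionTrack,
    FixationSet,
    Subject,
)

__all__ = ["write_cohort", "read_cohort", "write_features", "read_features",
           "write_report"]


def write_cohort(cohort: Cohort, out_dir: str | Path) -> None:
    out = Path(out_dir)
    (out / "eeg").mkdir(parents=True, exist_ok=True)

    fix_rows = [{"subject_id": s.subject_id, "x": x, "y": y}
                for s in cohort.subjects for x, y in s.fixations.points]
    pd.DataFrame(fix_rows).to_csv(out / "fixations.csv", index=False)

    expr_rows = [{"subject_id": s.subject_id, "frame": i, "label": lab}
                 for s in cohort.subjects
                 for i, lab in enumerate(s.expressions.labels)]
    pd.DataFrame(expr_rows).to_csv(out / "expressions.csv", index=False)

    for s in cohort.subjects:
        pd.DataFrame(s.eeg.data.T, columns=list(s.eeg.channels)).to_csv(
            out / "eeg" / f"{s.subject_id}.csv", index=False,
            float_format="%.6f")
        (out / "eeg" / f"{s.subject_id}.json").write_text(json.dumps(
            {"fs": s.eeg.fs, "channels": list(s.eeg.channels)}))

    manifest = {
        "subjects": [{"subject_id": s.subject_id, "label": s.label}
                     for s in cohort.subjects],
        "target_label": cohort.subjects[0].expressions.target_label
        if cohort.subjects else None,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


def read_cohort(in_dir: str | Path) -> Cohort:
    src = Path(in_dir)
    manifest = json.loads((src / "manifest.json").read_text())
    target = manifest["target_label"]
    fixations = pd.read_csv(src / "fixations.csv")
    expressions = pd.read_csv(src / "expressions.csv")

    subjects = []
    for entry in manifest["subjects"]:
        sid, label = entry["subject_id"], entry["label"]
        pts = fixations.loc[fixations.subject_id == sid, ["x", "y"]]
        track = expressions.loc[expressions.subject_id == sid]
        track = track.sort_values("frame")["label"].tolist()
        sidecar = json.loads((src / "eeg" / f"{sid}.json").read_text())
        data = pd.read_csv(src / "eeg" / f"{sid}.csv")
        channels = tuple(sidecar.get("channels", CHANNELS_14))
        subjects.append(Subject(
            subject_id=sid, label=label,
            fixations=FixationSet(points=pts.to_numpy(), subject_id=sid),
            expressions=ExpressionTrack(labels=track, subject_id=sid,
                                        target_label=target),
            eeg=EEGRecording(data=data[list(channels)].to_numpy().T,
                             fs=sidecar["fs"], channels=channels,
                             subject_id=sid),
        ))
    return Cohort(subjects=subjects)


def write_features(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path)


def read_features(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="subject_id")


def write_report(report, out_dir: str | Path) -> None:
    """Write predictions, confusion matrix and a JSON summary of one
    evaluation run."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({
        "subject_id": report.subject_ids,
        "y_true": report.y_true,
        "y_pred": report.y_pred,
    }).to_csv(out / f"predictions_{report.modality}.csv", index=False)
    report.confusion.to_csv(out / f"confusion_{report.modality}.csv")
    (out / f"report_{report.modality}.json").write_text(report.to_json())
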