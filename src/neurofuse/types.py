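"""Core data containers for the multimodal ASD/TD pipeline.

Three per-subject modalities are carried through the pipeline:

* :class:`FixationSet` — 2-D eye-fixation coordinates on the stimulus screen,
* :class:`ExpressionTrack` — one categorical facial-expression label per
  video frame,
* :class:`EEGRecording` — a channels x samples matrix from the 14-channel
  Emotiv EPOC montage (10-20 placement).

A :class:`Cohort` bundles labelled subjects; :class:`CohortSpec` holds the
generative parameters of the synthetic cohort generator (see
:mod:`neurofuse.synth`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

#: The 14 data electrodes of the Emotiv EPOC headset, 10-20 placement.
CHANNELS_14: tuple[str, ...] = (
    "AF3", "F7", "F3", "FC5", "T7", "P7", "O1",
    "O2", "P8", "T8", "FC6", "F4", "F8", "AF4",
)

#: Scalp-region partition of the montage: left/right frontal, left/right
#: temporal, parietal, occipital.
DEFAULT_REGION_MAP: dict[str, tuple[str, ...]] = {
    "LF": ("AF3", "F3", "F7", "FC5"),
    "RF": ("AF4", "F4", "F8", "FC6"),
    "LT": ("T7",),
    "RT": ("T8",),
    "P": ("P7", "P8"),
    "O": ("O1", "O2"),
}

REGION_ORDER: tuple[str, ...] = ("LF", "RF", "LT", "RT", "P", "O")

CLASS_ASD = "ASD"
CLASS_TD = "TD"
#: Canonical class order (used for tie-breaking and report layout).
CLASSES: tuple[str, str] = (CLASS_ASD, CLASS_TD)


@dataclass(frozen=True)
class BandDefinition:
    """A frequency band, half-open interval [low, high) in Hz."""

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not (0 <= self.low < self.high):
            raise ValueError(f"band {self.name!r}: need 0 <= low < high, "
                             f"got [{self.low}, {self.high})")


#: The five analysis bands.  Adjacent intervals are half-open so a shared
#: edge frequency (6, 13, 20, 30 Hz) is never counted twice.
DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("theta", 4.0, 6.0),
    BandDefinition("alpha", 6.0, 13.0),
    BandDefinition("low_beta", 13.0, 20.0),
    BandDefinition("high_beta", 20.0, 30.0),
    BandDefinition("gamma", 30.0, 45.0),
)

BAND_ORDER: tuple[str, ...] = tuple(b.name for b in DEFAULT_BANDS)


@dataclass
class FixationSet:
    """Ordered 2-D fixation points of one subject (screen pixels)."""

    points: np.ndarray  # (n, 2) float
    subject_id: str

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError(f"points: expected (n, 2) array, got shape "
                             f"{self.points.shape}")
        if len(self.points) < 1:
            raise ValueError("points: need at least one fixation point")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("points: coordinates must be finite")

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class ExpressionTrack:
    """Per-frame categorical expression labels of one subject.

    ``target_label`` is the expression shown in the stimulus; the feature of
    interest is how often the child's face matches it.
    """

    labels: Sequence[str]
    subject_id: str
    target_label: str

    def __post_init__(self) -> None:
        self.labels = list(self.labels)

    def __len__(self) -> int:
        return len(self.labels)


@dataclass
class EEGRecording:
    """Multichannel EEG: channels x samples, with sampling rate in Hz."""

    data: np.ndarray  # (n_channels, n_samples)
    fs: float
    channels: tuple[str, ...] = CHANNELS_14
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.channels = tuple(self.channels)
        if self.data.ndim != 2:
            raise ValueError(f"data: expected 2-D (channels, samples), got "
                             f"shape {self.data.shape}")
        if self.data.shape[0] != len(self.channels):
            raise ValueError(
                f"data: {self.data.shape[0]} rows but {len(self.channels)} "
                f"channel names")
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("channels: names must be unique")
        unknown = set(self.channels) - set(CHANNELS_14)
        if unknown:
            raise ValueError(f"channels: not in the 14-channel montage: "
                             f"{sorted(unknown)}")
        # gamma extends to 45 Hz; it must be resolvable
        if self.fs <= 2 * 45.0:
            raise ValueError(f"fs: need fs > 90 Hz to resolve the gamma "
                             f"band, got {self.fs}")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class Subject:
    subject_id: str
    label: str  # ASD or TD
    fixations: FixationSet
    expressions: ExpressionTrack
    eeg: EEGRecording


@dataclass
class Cohort:
    """A labelled multimodal cohort; every subject has all three modalities."""

    subjects: list[Subject]

    def __post_init__(self) -> None:
        labels = {s.label for s in self.subjects}
        if self.subjects and not labels <= set(CLASSES):
            raise ValueError(f"labels must be in {CLASSES}, got {labels}")

    def __len__(self) -> int:
        return len(self.subjects)

    @property
    def labels(self) -> list[str]:
        return [s.label for s in self.subjects]

    @property
    def subject_ids(self) -> list[str]:
        return [s.subject_id for s in self.subjects]


# default AOI layout: four "social" centers in the face region of the frame,
# four "nonsocial" centers on peripheral background objects (1920x1080 screen)
_DEFAULT_AOI_CENTERS: tuple[tuple[float, float, bool], ...] = (
    (760.0, 390.0, True),
    (1160.0, 390.0, True),
    (760.0, 700.0, True),
    (1160.0, 700.0, True),
    (240.0, 180.0, False),
    (1680.0, 180.0, False),
    (240.0, 900.0, False),
    (1680.0, 900.0, False),
)


@dataclass
class CohortSpec:
    """Generative parameters of a synthetic cohort.

    Defaults emulate the study design: 40 children per group watching a 40 s
    video stimulus, gaze biased toward social regions in TD children and away
    from them in ASD, a higher per-frame probability of showing the target
    expression in TD, and elevated theta-band EEG amplitude in configured
    scalp regions in ASD.  Per-subject heterogeneity parameters (``*_sd``)
    control how tightly each group clusters, and hence which group each
    modality recognises more reliably.
    """

    n_asd: int = 40
    n_td: int = 40
    seed: int = 0
    screen: tuple[int, int] = (1920, 1080)
    aoi_centers: tuple[tuple[float, float, bool], ...] = _DEFAULT_AOI_CENTERS
    gaze_social_bias_td: float = 0.58
    gaze_social_bias_asd: float = 0.42
    gaze_bias_sd_td: float = 0.05
    gaze_bias_sd_asd: float = 0.14
    gaze_scatter_px: float = 60.0
    n_fixations: int = 120
    fps: float = 25.0
    video_duration_s: float = 40.0
    p_target_td: float = 0.30
    p_target_asd: float = 0.22
    p_target_sd_td: float = 0.04
    p_target_sd_asd: float = 0.10
    eeg_fs: float = 128.0
    eeg_duration_s: float = 40.0
    band_amplitudes: dict[str, float] = field(default_factory=lambda: {
        "theta": 2.0, "alpha": 2.5, "low_beta": 1.0,
        "high_beta": 0.75, "gamma": 0.5,
    })
    theta_gain_asd: float = 2.0
    theta_regions: tuple[str, ...] = ("LF", "RF", "RT", "P", "O")
    eeg_subject_sd_asd: float = 0.20
    eeg_subject_sd_td: float = 0.50
    noise_sd: float = 0.5
    target_label: str = "happy"
    nontarget_labels: tuple[str, ...] = ("neutral", "sad", "surprise")

    def __post_init__(self) -> None:
        for name in ("n_asd", "n_td"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name}: must be >= 1")
        for name in ("gaze_social_bias_td", "gaze_social_bias_asd",
                     "p_target_td", "p_target_asd"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}: probability must be in [0, 1], "
                                 f"got {v}")
        for name in ("fps", "eeg_fs", "video_duration_s", "eeg_duration_s",
                     "gaze_scatter_px"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name}: must be > 0")
        for name in ("gaze_bias_sd_td", "gaze_bias_sd_asd", "p_target_sd_td",
                     "p_target_sd_asd", "eeg_subject_sd_asd",
                     "eeg_subject_sd_td", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name}: must be >= 0")
        if self.theta_gain_asd < 1.0:
            raise ValueError(f"theta_gain_asd: must be >= 1, got "
                             f"{self.theta_gain_asd}")
        if self.n_fixations < 1:
            raise ValueError("n_fixations: must be >= 1")
        if not self.aoi_centers:
            raise ValueError("aoi_centers: need at least one AOI")
        if not any(s for _, _, s in self.aoi_centers) or \
                not any(not s for _, _, s in self.aoi_centers):
            raise ValueError("aoi_centers: need at least one social and one "
                             "nonsocial AOI")
        unknown = set(self.theta_regions) - set(REGION_ORDER)
        if unknown:
            raise ValueError(f"theta_regions: unknown regions "
                             f"{sorted(unknown)}")
        if set(self.band_amplitudes) != set(BAND_ORDER):
            raise ValueError(f"band_amplitudes: must give exactly the bands "
                             f"{BAND_ORDER}")
        if self.eeg_fs <= 2 * 45.0:
            raise ValueError(f"eeg_fs: need > 90 Hz, got {self.eeg_fs}")

    def null(self) -> "CohortSpec":
        """A copy with every group difference removed.

        Both groups share the TD/ASD-averaged gaze bias and target-expression
        probability, a common heterogeneity level, and ``theta_gain_asd`` is
        1 — the two groups' generative distributions are then identical.
        """
        bias = 0.5 * (self.gaze_social_bias_td + self.gaze_social_bias_asd)
        bias_sd = 0.5 * (self.gaze_bias_sd_td + self.gaze_bias_sd_asd)
        p = 0.5 * (self.p_target_td + self.p_target_asd)
        p_sd = 0.5 * (self.p_target_sd_td + self.p_target_sd_asd)
        amp_sd = 0.5 * (self.eeg_subject_sd_asd + self.eeg_subject_sd_td)
        return replace(
            self,
            gaze_social_bias_td=bias, gaze_social_bias_asd=bias,
            gaze_bias_sd_td=bias_sd, gaze_bias_sd_asd=bias_sd,
            p_target_td=p, p_target_asd=p,
            p_target_sd_td=p_sd, p_target_sd_asd=p_sd,
            theta_gain_asd=1.0,
            eeg_subject_sd_asd=amp_sd, eeg_subject_sd_td=amp_sd,
        )
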