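"""Synthetic multimodal cohort generator.

The study cohort (40 ASD + 40 TD children) is not publicly available, so
this module generates cohorts with the same statistical structure:

* **Gaze** — fixation points drawn from a 2-D Gaussian mixture over the AOI
  centers; a subject's mixture weight on the social AOIs equals that
  subject's social-attention bias (group mean +/- per-subject jitter, higher
  in TD).
* **Expression** — per-frame labels are independent draws; the probability
  of the target expression is the subject's imitation rate (higher in TD).
* **EEG** — each channel is a sum of five band-limited noise components
  (white noise band-pass filtered to theta/alpha/low-beta/high-beta/gamma)
  plus broadband sensor noise.  For ASD subjects the theta component in the
  configured scalp regions is multiplied by ``theta_gain_asd``.
  Per-subject, per-band log-normal factors model inter-individual
  amplitude variability.

All randomness flows from ``spec.seed`` through one ``numpy`` generator, so
identical specs give byte-identical cohorts.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from .types import (
    CHANNELS_14,
    CLASS_ASD,
    CLASS_TD,
    DEFAULT_BANDS,
    DEFAULT_REGION_MAP,
    Cohort,
    CohortSpec,
    EEGRecording,
    ExpressionTrack,
    FixationSet,
    Subject,
)

__all__ = ["generate_cohort", "group_params"]


def group_params(spec: CohortSpec, label: str) -> dict[str, float]:
    """The generative parameters a subject of ``label`` is drawn with."""
    if label == CLASS_ASD:
        return {
            "gaze_social_bias": spec.gaze_social_bias_asd,
            "gaze_bias_sd": spec.gaze_bias_sd_asd,
            "p_target": spec.p_target_asd,
            "p_target_sd": spec.p_target_sd_asd,
            "theta_gain": spec.theta_gain_asd,
            "eeg_subject_sd": spec.eeg_subject_sd_asd,
        }
    if label == CLASS_TD:
        return {
            "gaze_social_bias": spec.gaze_social_bias_td,
            "gaze_bias_sd": spec.gaze_bias_sd_td,
            "p_target": spec.p_target_td,
            "p_target_sd": spec.p_target_sd_td,
            "theta_gain": 1.0,
            "eeg_subject_sd": spec.eeg_subject_sd_td,
        }
    raise ValueError(f"label: unknown class {label!r}")


def _gen_fixations(spec: CohortSpec, params: dict, subject_id: str,
                   rng: np.random.Generator) -> FixationSet:
    centers = np.array([(x, y) for x, y, _ in spec.aoi_centers])
    social = np.array([s for _, _, s in spec.aoi_centers], dtype=bool)
    bias = float(np.clip(
        rng.normal(params["gaze_social_bias"], params["gaze_bias_sd"]),
        0.0, 1.0))
    # mixture weight `bias` spread uniformly over social AOIs, the rest
    # uniformly over nonsocial AOIs
    w = np.where(social, bias / social.sum(), (1 - bias) / (~social).sum())
    idx = rng.choice(len(centers), size=spec.n_fixations, p=w)
    pts = centers[idx] + rng.normal(0.0, spec.gaze_scatter_px,
                                    size=(spec.n_fixations, 2))
    pts[:, 0] = np.clip(pts[:, 0], 0, spec.screen[0])
    pts[:, 1] = np.clip(pts[:, 1], 0, spec.screen[1])
    return FixationSet(points=pts, subject_id=subject_id)


def _gen_expressions(spec: CohortSpec, params: dict, subject_id: str,
                     rng: np.random.Generator) -> ExpressionTrack:
    n_frames = int(round(spec.fps * spec.video_duration_s))
    p = float(np.clip(rng.normal(params["p_target"], params["p_target_sd"]),
                      0.0, 1.0))
    is_target = rng.random(n_frames) < p
    others = rng.choice(spec.nontarget_labels, size=n_frames)
    labels = np.where(is_target, spec.target_label, others)
    return ExpressionTrack(labels=labels.tolist(), subject_id=subject_id,
                           target_label=spec.target_label)


def _band_noise(rng: np.random.Generator, n_channels: int, n_samples: int,
                fs: float, low: float, high: float) -> np.ndarray:
    """Unit-RMS band-limited noise, one row per channel."""
    white = rng.standard_normal((n_channels, n_samples))
    sos = signal.butter(4, [low, high], btype="bandpass", fs=fs,
                        output="sos")
    x = signal.sosfiltfilt(sos, white, axis=-1)
    rms = np.sqrt(np.mean(x ** 2, axis=-1, keepdims=True))
    return x / np.maximum(rms, 1e-30)


def _gen_eeg(spec: CohortSpec, params: dict, subject_id: str,
             rng: np.random.Generator) -> EEGRecording:
    n_samples = int(round(spec.eeg_fs * spec.eeg_duration_s))
    n_ch = len(CHANNELS_14)
    # channels belonging to the theta-elevated regions
    theta_chans = np.zeros(n_ch, dtype=bool)
    for region in spec.theta_regions:
        for ch in DEFAULT_REGION_MAP[region]:
            theta_chans[CHANNELS_14.index(ch)] = True
    # per-subject, per-band amplitude variability (log-normal): inter-
    # individual differences in band power are band-specific, not a single
    # broadband gain
    band_scale = {b.name: float(np.exp(rng.normal(
        0.0, params["eeg_subject_sd"]))) for b in DEFAULT_BANDS}
    data = np.zeros((n_ch, n_samples))
    for band in DEFAULT_BANDS:
        comp = _band_noise(rng, n_ch, n_samples, spec.eeg_fs,
                           band.low, band.high)
        amp = spec.band_amplitudes[band.name] * band_scale[band.name]
        gain = np.ones(n_ch)
        if band.name == "theta":
            gain[theta_chans] = params["theta_gain"]
        data += comp * amp * gain[:, None]
    data += rng.normal(0.0, spec.noise_sd, size=(n_ch, n_samples))
    return EEGRecording(data=data, fs=spec.eeg_fs, channels=CHANNELS_14,
                        subject_id=subject_id)


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Generate a labelled multimodal cohort.

    Deterministic given ``spec`` (including ``spec.seed``).  ASD subjects
    are generated first, then TD, each with ids ``asd_00 ...`` /
    ``td_00 ...``.
    """
    rng = np.random.default_rng(spec.seed)
    subjects: list[Subject] = []
    for label, n, prefix in ((CLASS_ASD, spec.n_asd, "asd"),
                             (CLASS_TD, spec.n_td, "td")):
        params = group_params(spec, label)
        for i in range(n):
            sid = f"{prefix}_{i:02d}"
            subjects.append(Subject(
                subject_id=sid,
                label=label,
                fixations=_gen_fixations(spec, params, sid, rng),
                expressions=_gen_expressions(spec, params, sid, rng),
                eeg=_gen_eeg(spec, params, sid, rng),
            ))
    return Cohort(subjects=subjects)
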