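"""Generate a small synthetic multimodal cohort and inspect one subject.

The generator emulates a study in which ASD and TD children watch a 40 s
video while gaze, facial expression and 14-channel EEG are recorded.  ASD
subjects attend less to social screen regions, match the stimulus
expression less often, and show elevated theta-band EEG amplitude.
"""

from neurofuse import CohortSpec, generate_cohort

spec = CohortSpec(n_asd=5, n_td=5, seed=1)
cohort = generate_cohort(spec)

print(f"cohort of {len(cohort)} subjects: {cohort.subject_ids}")
s = cohort.subjects[0]
print(f"\nsubject {s.subject_id} ({s.label}):")
print(f"  {len(s.fixations)} fixation points, first: "
      f"{s.fixations.points[0].round(1)}")
print(f"  {len(s.expressions)} expression frames, target "
      f"{s.expressions.target_label!r}, first five: "
      f"{s.expressions.labels[:5]}")
print(f"  EEG {s.eeg.data.shape[0]} channels x {s.eeg.n_samples} samples "
      f"at {s.eeg.fs} Hz ({s.eeg.duration_s:.0f} s)")
# The printed shapes are the raw per-subject inputs every downstream
# feature extractor consumes.
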