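"""Minute-level MEWS, outcome labelling and chronological splitting.

MEWS is scored per minute from one-minute means (HR, RR) and
carried-forward intermittent observations (SBP, temperature), omitting
the neurologic component.  Outcomes are strict threshold crossings of
minute means inside 60/90/120-minute windows after the 15-minute
assessment period.
"""

from edecomp.cohort import compute_mews_series, label_outcomes, split_cohort
from edecomp.synth import SimConfig, generate_cohort

cohort = generate_cohort(SimConfig(n_visits=400, seed=11))
gt = cohort.ground_truth.set_index("visit_id")

vid = gt.index[gt["event_tachycardia"]][0]
stream = cohort.vitals[vid]
mews = compute_mews_series(stream)
labels = label_outcomes(stream, mews)
onset_cfg = gt.loc[vid, "onset_tachycardia"]
print(f"visit {vid}: configured tachycardia onset {onset_cfg:.0f} min "
      "post-assessment")
print(f"  labelled onset minute: {labels.onset_minute['tachycardia']}")
for w in (60, 90, 120):
    print(f"  tachycardia within {w:3d} min: {labels[('tachycardia', w)]}")
print(f"  max MEWS in stream: {max(m for m in mews.total if m == m):.0f}")

split = split_cohort(cohort.triage, seed=11)
counts = split.assignment.value_counts()
print(f"\nchronological patient-disjoint split of {len(cohort.visit_ids)} "
      f"visits: train={counts['train']} validation={counts['validation']} "
      f"test={counts['test']}")
print(f"test-set cutoff at {split.cutoff_time:.0f} h from study start; "
      "patients straddling the cutoff are moved entirely to train")
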