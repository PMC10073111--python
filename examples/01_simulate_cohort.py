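"""Simulate a small monitored-ED cohort and write it to disk.

Each visit gets a triage record, 1-Hz monitor channels covering a
15-minute assessment period plus 120 minutes of follow-up, a ground-truth
beat train, and hidden event/onset annotations.  Prevalences default to a
stable adult ED cohort (tachycardia 6.1 %, hypoxia 11.2 %, hypotension
2.3 %).
"""

from edecomp.io import write_cohort
from edecomp.synth import SimConfig, generate_cohort

cfg = SimConfig(n_visits=100, seed=42)
cohort = generate_cohort(cfg)

gt = cohort.ground_truth
print(f"visits: {len(cohort.visit_ids)}")
for outcome in ("tachycardia", "hypoxia", "hypotension"):
    n_ev = int(gt[f"event_{outcome}"].sum())
    print(f"  {outcome:<12s} events: {n_ev:3d}  ({100 * n_ev / len(gt):.1f} %)")

vid = cohort.visit_ids[0]
stream = cohort.vitals[vid]
print(f"\nfirst visit {vid}: {stream.duration_s} s of 1-Hz monitoring, "
      f"HR starts at {stream.hr[0]:.0f} bpm, "
      f"{len(stream.sbp_times)} intermittent BP observations")

out = write_cohort(cohort, "scratch/example_cohort", max_streams=5)
print(f"\nwrote tables and 5 example streams under {out}/")
print("(streams are regenerated lazily from the seed, so persisting all "
      "of them is rarely necessary)")
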