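"""Generate a synthetic PICU cohort and look at what it contains.

The generator emits the four tables a real extraction would provide: a long
event stream (asynchronous, multi-rate observations), demographics,
admissions, and — because this is simulation — the ground-truth injected
deterioration events that downstream stages must rediscover.
"""

from pedews import CohortSpec, generate_cohort

cohort = generate_cohort(CohortSpec(n_patients=100, seed=42))

print(f"patients:            {len(cohort.demographics)}")
print(f"event rows:          {len(cohort.events)}")
print(f"injected events:     {len(cohort.ground_truth)}"
      f"  (triggers: {cohort.ground_truth['trigger'].value_counts().to_dict()})")
print(f"deaths:              {int(cohort.admissions['died_flag'].sum())}")
print(f"median age (years):  {cohort.demographics['age_days'].median() / 365.25:.2f}")

# observation cadence of non-invasive systolic BP, the sparsest routine vital
ev = cohort.events
adm = cohort.admissions.set_index("admission_id")
los_h = ((adm["discharge_ts"] - adm["admit_ts"]).dt.total_seconds() / 3600)
nibp = ev[ev["variable"] == "nibp_sys"].groupby("admission_id").size()
print(f"NIBP obs/hour:       {(nibp / los_h).mean():.2f}  (target ~1.5/h)")

print("\nfirst event rows:")
print(cohort.events.head(5).to_string(index=False))

# Age is drawn from a paediatric mixture (median ~2.3 y); vitals are
# mean-reverting processes around age-appropriate set-points, and each
# injected event adds a MAP decline, a lactate rise, a vasoactive start and
# an observation-frequency boost in the preceding hours.
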