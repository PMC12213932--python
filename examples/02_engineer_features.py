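"""Feature engineering building blocks on hand-made inputs.

Shows the ordinal ventilation score, the vasoactive inotrope score (VIS),
device consolidation (arterial beats cuff pressure within a minute),
age-centile normalisation and the DBP back-calculation.
"""

import pandas as pd

from pedews import (VasoactiveDoses, VentilationState, VariableMap,
                    consolidate, dbp_lower_limit, ventilation_level, vis_score)
from pedews.references import ReferenceSet, centile_normalise

# --- ventilatory support collapses to a 4-level ordinal score
for desc, state in [
    ("room air, unassisted", VentilationState(room_air=True)),
    ("facemask oxygen", VentilationState(supplemental_o2=True)),
    ("high-flow nasal oxygen", VentilationState(positive_pressure=True)),
    ("endotracheal tube", VentilationState(invasive=True)),
]:
    print(f"ventilation level [{desc:24s}] = {ventilation_level(state)}")

# --- VIS: weighted sum of per-kg infusion rates
doses = VasoactiveDoses(dopamine=5.0, milrinone=0.5, epinephrine=0.1)
print(f"\nVIS(dopamine 5, milrinone 0.5, epinephrine 0.1) = {vis_score(doses):.0f}")
print("  (= 5 + 10*0.5 + 100*0.1: higher VIS = more cardiovascular support)")

# --- same-minute device conflict: the arterial line wins over the cuff
vmap = VariableMap(pd.DataFrame([
    {"alias": "abp_sys", "canonical": "sbp", "factor": 1.0, "priority": 1, "unit": "mmHg"},
    {"alias": "nibp_sys", "canonical": "sbp", "factor": 1.0, "priority": 2, "unit": "mmHg"},
]))
t = pd.Timestamp("2024-03-01 10:00:20", tz="UTC")
events = pd.DataFrame(
    [("p1", "a1", t, "nibp_sys", 96.0, "mmHg"),
     ("p1", "a1", t + pd.Timedelta(seconds=15), "abp_sys", 104.0, "mmHg")],
    columns=["patient_id", "admission_id", "timestamp", "variable", "value", "unit"])
merged = consolidate(events, vmap)
print(f"\nsame-minute SBP from cuff (96) and arterial line (104) -> kept {merged['value'].iloc[0]:.0f}")

# --- age normalisation: the same heart rate means different things at
# different ages (packaged default centile tables)
refs = ReferenceSet.load()
for age_y in (0.5, 4, 14):
    c = centile_normalise("hr", 120.0, age_y * 365.25, "M", refs.centiles)
    print(f"HR 120 bpm at age {age_y:>4} y -> centile position {c:.2f}")

# --- DBP lower limit back-calculated from MAP and SBP limits
print(f"\nDBP lower limit for MAP 65 / SBP 95: {dbp_lower_limit(65, 95):.0f} mmHg")
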