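"""Label hospitalizations for AKI by code and by KDIGO creatinine deltas.

Shows the two phenotyping routes on hand-built stays: an administrative
584.x code, a creatinine trajectory satisfying the 0.3 mg/dL / 48 h rule
against the sliding in-stay baseline, and a quiet stay that triggers
neither.
"""

import pandas as pd

import akirisk as ak

def stay(admit_id, scr, dx):
    labs = pd.DataFrame(
        [{"test_name": "serum_creatinine", "time": t, "value": v,
          "abnormal_flag": "none"} for t, v in scr]
    )
    return ak.Hospitalization(
        patient_id="P1", admit_id=admit_id, admit_time=0.0,
        discharge_time=96.0, age_at_admit=67.0,
        labs=labs if len(labs) else None,
        codes=[("ICD9-DX", c) for c in dx],
    )

cases = {
    "code only":  stay("A", scr=[(2, 1.1), (30, 1.15)], dx=["584.9", "401.9"]),
    "lab only":   stay("B", scr=[(2, 2.0), (26, 1.0), (62, 1.4)], dx=["401.9"]),
    "neither":    stay("C", scr=[(2, 1.0), (30, 1.2)], dx=["272.4"]),
}

for name, h in cases.items():
    label = ak.label_hospitalization(h)
    print(f"{name:10s} by_code={label.by_code!s:5s} by_lab={label.by_lab!s:5s} "
          f"combined={label.combined!s:5s} trigger={label.lab_trigger_time} "
          f"criterion={label.criterion}")

print("\n'lab only' fires the absolute rule: the sliding baseline is the "
      "minimum earlier value within 48 h (the 1.0 at t=26), so 1.4 - 1.0 "
      ">= 0.3 mg/dL even though both 1.5x ratios stay below threshold.")
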