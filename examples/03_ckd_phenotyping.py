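"""CKD e-phenotyping: eGFR and case/control/excluded assignment.

Cases: eGFR < 60 ml/min/1.73m2 or renal replacement therapy.  Controls:
eGFR > 90 and no CKD billing code.  The 60-90 band is excluded.
"""

import pandas as pd

from penetrax.phenotyping import (PhenotypingConfig, assign_case_control,
                                  egfr_2009, egfr_2021)

print("2009 CKD-EPI, female, age 50, creatinine 0.7 mg/dL:",
      round(egfr_2009(0.7, 50, "F"), 1), "ml/min/1.73m2")
print("2009 CKD-EPI, male, age 40, creatinine 0.9 mg/dL:",
      round(egfr_2009(0.9, 40, "M"), 1))
print("2021 race-free equation, same female:",
      round(egfr_2021(0.7, 50, "F"), 1))

pheno = pd.DataFrame({
    "participant_id": ["a", "b", "c", "d", "e"],
    "age": [60, 60, 60, 55, 70],
    "sex": ["M", "F", "M", "F", "M"],
    "creatinine_mg_dl": ["2.1", "0.6", "1.1", "", "0.8;0.9;1.0"],
    "icd9_codes": ["585.3", "", "", "", ""],
    "rrt_flag": [0, 0, 0, 1, 0],
    "batch": "b1",
})
labels = assign_case_control(pheno, PhenotypingConfig(equation="2009"))
print(labels[["participant_id", "label", "egfr"]].round(1).to_string(index=False))
# 'a' is a case (low eGFR), 'b' a control, 'c' falls in the excluded 60-90
# band, 'd' is a case by renal replacement therapy despite missing
# creatinine, and 'e' uses the median of three creatinine draws.
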