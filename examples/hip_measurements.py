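"""Hip geometric measurements and the cohort asymmetry table.

Measures head diameter, neck width, shaft width and neck-shaft angle on
both femurs of every subject, before and after positioning adjustment, and
prints the absolute-difference (AD) and absolute-percent-asymmetry (AA%)
summary.
"""

from femsym import (SyntheticConfig, generate_dataset, make_template,
                    measure_hip, summarize_cohort)
from femsym.pipeline import adjust_dataset

contours, _ = generate_dataset(SyntheticConfig(n_subjects=100, seed=0))
adjusted, excluded, *_ = adjust_dataset(contours)
_, index_map = make_template()

template, _ = make_template()
m = measure_hip(template, index_map)
print("template measurements:",
      f"head {m.head_diameter:.1f} mm, neck {m.neck_width:.1f} mm,",
      f"shaft {m.shaft_width:.1f} mm, NSA {m.neck_shaft_angle:.1f} deg")

for label, data in [("before adjustment", contours), ("after adjustment", adjusted)]:
    left = [measure_hip(c.left, index_map) for c in data]
    right = [measure_hip(c.right, index_map) for c in data]
    table = summarize_cohort(left, right)
    print(f"\n{label} (modes excluded: {excluded}):")
    cols = ["measurement", "value_mean", "value_sd", "ad_mean", "aa_pct_mean"]
    print(table[cols].to_string(index=False, float_format="%.2f"))
# AD is the per-subject |left - right| difference; AA% divides it by the
# pair mean. Positioning-sensitive measurements (neck-shaft angle) improve
# after adjustment; size measurements barely move.
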