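"""Per-predictor ROC areas from grouped counts.

The rank AUC of a categorical sign is computed in closed form from its
level counts (ties count one-half); age uses the binormal formula from
the two groups' means and SDs.  Confidence intervals are Hanley-McNeil.
"""

from scolioscreen import binormal_auc, empirical_auc, table1_contingency

for variable in (
    "shoulder_height_diff",
    "pelvic_tilt",
    "atr_thoracic",
    "atr_thoracolumbar",
    "atr_lumbar",
):
    r = empirical_auc(table1_contingency(variable))
    print(f"{variable:<22} AUC {r.auc:.2f} (95% CI {r.ci_low:.2f}-{r.ci_high:.2f})")

age = binormal_auc(13.14, 1.87, 12.67, 1.96, n_case=884, n_control=895)
print(f"{'age (binormal)':<22} AUC {age.auc:.2f} "
      f"(95% CI {age.ci_low:.2f}-{age.ci_high:.2f})")
# An AUC is the probability that a random case shows the more abnormal
# score than a random control; 0.5 means no discrimination.  Trunk
# rotation and shoulder height are the strongest single signs here.
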