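"""Score subjects with the published prediction equations.

The four published equations (plain, AOR-weighted, AUC-weighted,
AOR+AUC-weighted) ship as fixed models over twelve covariates X1..X12 in
single-score coding (0/1/2 level coding, raw years for age).  Here a
hypothetical 13-year-old girl with right scapular tilt and right thoracic
trunk rotation > 5 deg is scored with each.
"""

import numpy as np

from scolioscreen import classify, predict_probability, printed_equation

#      gender age shoulder scap lumb pelv flat tkyph lkyph atr_t atr_tl atr_l
x = np.array([1, 13.0, 0, 2, 0, 0, 0, 0, 0, 2, 0, 0])

for which in (1, 2, 3, 4):
    model = printed_equation(which)
    p = predict_probability(model, x[None])[0]
    label = classify(p)
    print(f"equation {which} ({model.scheme:<16}) "
          f"P(AIS) = {p:.3f} -> predicted label {label}")
# The four equations sit on different coefficient scales, so their
# probabilities for the same sign pattern differ markedly (here 0.13 to
# 0.63) and can disagree at the 0.5 threshold; within any one equation,
# more abnormal signs always raise the predicted risk.
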