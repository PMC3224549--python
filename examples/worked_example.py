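"""Single-gene walkthrough of cross-validated prediction error.

One paired gene with log-ratios d = (-2, 1, 3).  Each fold removes one
replicate pair, re-estimates the mean log-ratio, shrinks it by the smooth
fold-change rule, and scores the prediction against the held-out ratio.
"""

import numpy as np

import dexval as dx

data = dx.worked_example_fixture()
print("log-ratios d:", data.differences()[0])

for j in range(data.n):
    sub = data.drop_pair(j)
    dhat = dx.estimate_dhat(sub).dhat[0]
    p_de = 1 - dx.fc_shrinkage(dx.estimate_dhat(sub))[0]
    held_out = data.differences()[0, j]
    pred = p_de * dhat
    print(f"fold {j + 1}: leave-one-out dhat = {dhat:5.2f}  "
          f"P(differential) = {p_de:.2f}  prediction = {pred:6.3f}  "
          f"squared error = {(held_out - pred) ** 2:.3f}")

table = dx.loocv_paired(data, dx.get_selector("fc_shrinkage"))
print(f"\nmean cross-validated squared prediction error: {table.errors[0]:.1f}")
print("(each fold's error is (held-out ratio - shrunken estimate)^2;")
print(" the mean summarises how well the selector predicts new ratios)")
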