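"""Detection statistics from a 4-class staging confusion table.

Reproduces the summary statistics of a published 268-case keratoconus study
from its printed confusion matrix: the binary (keratoconus vs normal)
sensitivity, specificity and accuracy under the study's own literal metric
definitions, alongside the textbook variants.
"""

import numpy as np

from kerato3d import confusion, metrics

# rows = actual, cols = predicted, order mild / moderate / severe / normal
counts = np.array([
    [48, 2, 0, 8],
    [2, 66, 2, 0],
    [0, 0, 40, 0],
    [2, 2, 0, 96],
])
classes = ("mild", "moderate", "severe", "normal")
actual, predicted = [], []
for i, a in enumerate(classes):
    for j, p in enumerate(classes):
        actual += [a] * counts[i, j]
        predicted += [p] * counts[i, j]

cm = confusion(actual, predicted)
print(cm.to_frame(), "\n")
print(f"row totals: {list(cm.row_totals)} (sum {cm.counts.sum()})")
print(f"strict-diagonal TP: {list(cm.tp_diagonal)}")
print(f"row-minus-normal TP: {list(cm.tp_row_minus_normal)}")

# the study's own TP column mixes the two conventions; its summary uses
# TP=254, TN=96, FP=4 and the normal-row FN=4
m = metrics(TP=254, TN=cm.tn, FP=cm.fp, FN=4)
print(f"\nliteral sensitivity TP/(TP+FP) = {m.sensitivity:.2f}%")
print(f"literal specificity TN/(TN+FN) = {m.specificity:.2f}%")
print(f"accuracy (TP+TN)/(TP+FP+FN+TN) = {m.accuracy:.1f}%")
print(f"textbook recall TP/(TP+FN)     = {m.recall:.2f}%")
print(f"textbook specificity TN/(TN+FP)= {m.specificity_tn_fp:.2f}%")
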