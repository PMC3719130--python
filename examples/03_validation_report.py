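"""Validation statistics: confusion matrix, accuracy, precision.

Scores detections against an expert-annotated validation set.  Accuracy
is (TP+TN)/total and precision TP/(TP+FP), reported as integer percents
(half-up) the way validation tables are usually printed.
"""

from roihmm import ConfusionCounts, accuracy, confusion, precision

# an expert validated 20 recordings; the model detected 9 of them
truth = {f"rec{i:02d}": i < 12 for i in range(20)}        # 12 truly present
calls = {f"rec{i:02d}": i < 9 or i == 15 for i in range(20)}

c = confusion(truth, calls)
print(f"tp={c.tp} fp={c.fp} tn={c.tn} fn={c.fn} (n={c.n})")
acc = accuracy(c)
prec = precision(c)
print(f"accuracy  {acc.rounded}% (exact {acc.exact:.2f}%)")
print(f"precision {prec.rounded}% (exact {prec.exact:.2f}%)")
# 9 true positives, 1 false positive, 3 missed: a conservative model --
# few false alarms, more misses -- the typical operating regime for
# per-recording vocalization detectors.
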