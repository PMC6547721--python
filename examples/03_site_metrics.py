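"""The evaluation metrics on small worked examples.

F1 from precision/recall pairs, and AP/AUC on a tiny ranked score list
where the arithmetic can be followed by hand.
"""

from modcaller.metrics import auc, average_precision, f1_score

# F1 is the harmonic mean of precision and recall
for p, r in [(0.988, 0.979), (0.97, 0.93), (0.944, 0.844)]:
    print(f"precision {p:.3f}, recall {r:.3f} -> F1 = {f1_score(p, r):.3f}")

# three sites scored 0.9, 0.8, 0.7; the first and last are truly modified
scores = [0.9, 0.8, 0.7]
labels = [1, 0, 1]
print(f"\nscores {scores}, labels {labels}")
print(f"AP  = {average_precision(scores, labels):.4f}  "
      "(= 0.5*1 + 0.5*(2/3): precision at each recall step)")
print(f"AUC = {auc(scores, labels):.4f}  "
      "(one of two positive/negative pairs correctly ordered)")
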