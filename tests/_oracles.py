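"""Independent brute-force oracles shared by test modules."""

import numpy as np


def exhaustive_ap(scores, flags, n_gt):
    """Enumerate every prefix of the ranked list; at each recall level take
    the best precision at or beyond it; integrate stepwise over recall."""
    order = np.argsort(-np.asarray(scores), kind="stable")
    flags = np.asarray(flags, dtype=bool)[order]
    prefixes = []
    tp = fp = 0
    for f in flags:
        tp, fp = tp + int(f), fp + int(not f)
        prefixes.append((tp / n_gt, tp / (tp + fp)))
    ap = 0.0
    prev_r = 0.0
    for i, (r, _p) in enumerate(prefixes):
        best_p = max(p for (r2, p) in prefixes[i:])
        ap += (r - prev_r) * best_p
        prev_r = r
    return ap
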