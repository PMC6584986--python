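"""Independent reference implementations shared by the test modules.

These deliberately use direct, slow formulations (double loops, quadratic
scans) so they cannot share a defect with the FFT / grid-hashed production
code they check.
"""

import numpy as np


def brute_force_zncc(layer, template):
    """Direct double-loop Pearson correlation at every valid center."""
    H, W = layer.shape
    s = template.shape[0]
    t = template - template.mean()
    tn = np.sqrt((t * t).sum())
    out = np.full((H, W), np.nan)
    off = s // 2
    for r in range(H - s + 1):
        for c in range(W - s + 1):
            w = layer[r : r + s, c : c + s]
            wc = w - w.mean()
            wn = np.sqrt((wc * wc).sum())
            if wn < 1e-6 or tn < 1e-6:
                out[r + off, c + off] = 0.0
            else:
                out[r + off, c + off] = (wc * t).sum() / (wn * tn)
    return out


def greedy_nms_reference(candidates, nms_radius):
    """Quadratic-time greedy suppression over (col, row, score) tuples."""
    order = sorted(candidates, key=lambda t: (-t[2], t[1], t[0]))
    accepted = []
    for col, row, score in order:
        if all(
            (col - a[0]) ** 2 + (row - a[1]) ** 2 >= nms_radius**2 for a in accepted
        ):
            accepted.append((col, row, score))
    return accepted
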