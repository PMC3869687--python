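"""Brute-force reference implementations used only by tests."""

from collections import deque

import numpy as np


def flood_fill_labels(mask, connectivity):
    """BFS connected-component labelling at 6/18/26 connectivity."""
    offsets = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if (dx, dy, dz) == (0, 0, 0):
                    continue
                order = abs(dx) + abs(dy) + abs(dz)
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offsets.append((dx, dy, dz))
    labels = np.zeros(mask.shape, dtype=int)
    next_label = 0
    for start in zip(*np.nonzero(mask)):
        if labels[start]:
            continue
        next_label += 1
        queue = deque([start])
        labels[start] = next_label
        while queue:
            p = queue.popleft()
            for off in offsets:
                q = tuple(p[i] + off[i] for i in range(3))
                if any(c < 0 or c >= mask.shape[i] for i, c in enumerate(q)):
                    continue
                if mask[q] and not labels[q]:
                    labels[q] = next_label
                    queue.append(q)
    return labels, next_label


def pooled_two_sample_t(a, b):
    """Textbook pooled-variance two-sample t statistic (a minus b)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = a.size, b.size
    sp2 = ((a.var(ddof=1) * (na - 1) + b.var(ddof=1) * (nb - 1))
           / (na + nb - 2))
    return (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))


def bh_step_up(pvals, q):
    """Hand-rolled Benjamini-Hochberg step-up selection."""
    pvals = np.asarray(pvals, float)
    m = pvals.size
    order = np.argsort(pvals)
    passed = np.flatnonzero(pvals[order] <= q * (np.arange(m) + 1) / m)
    k = passed.max() + 1 if passed.size else 0
    reject = np.zeros(m, dtype=bool)
    reject[order[:k]] = True
    return reject.tolist()
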