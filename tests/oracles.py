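"""Naive brute-force reference implementations used only by the tests.

Each oracle walks explicit per-branch descendant sets or direct textbook
formulas, with no shared code with the package's vectorized
implementations.
"""

from __future__ import annotations

import numpy as np


def branch_list(tree, taxa):
    """(length, descendant-tip-set) for every branch of a rooted tree."""
    out = []
    for node in tree.postorder(include_self=False):
        tips = {t.name for t in node.tips()} if not node.is_tip() else {node.name}
        tips &= set(taxa)
        length = node.length if node.length is not None else 0.0
        out.append((length, tips))
    return out


def naive_faith_pd(counts, taxa, tree):
    observed = {t for t, c in zip(taxa, counts) if c > 0}
    return sum(l for l, tips in branch_list(tree, taxa) if tips & observed)


def naive_unweighted_unifrac(x, y, taxa, tree):
    ox = {t for t, c in zip(taxa, x) if c > 0}
    oy = {t for t, c in zip(taxa, y) if c > 0}
    unique = total = 0.0
    for l, tips in branch_list(tree, taxa):
        in_x, in_y = bool(tips & ox), bool(tips & oy)
        if in_x or in_y:
            total += l
            if in_x != in_y:
                unique += l
    return unique / total if total else 0.0


def naive_weighted_unifrac(x, y, taxa, tree, normalized=False):
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    px = dict(zip(taxa, x / x.sum()))
    py = dict(zip(taxa, y / y.sum()))
    raw = 0.0
    for l, tips in branch_list(tree, taxa):
        raw += l * abs(sum(px[t] for t in tips) - sum(py[t] for t in tips))
    if not normalized:
        return raw
    # root-to-tip distances
    depth = {}
    for tip in tree.tips():
        d, node = 0.0, tip
        while node.parent is not None:
            d += node.length or 0.0
            node = node.parent
        depth[tip.name] = d
    denom = sum(depth[t] * (px[t] + py[t]) for t in taxa)
    return raw / denom if denom else 0.0


def naive_bray_curtis(x, y):
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    return np.abs(x - y).sum() / (x + y).sum()


def naive_pielou(counts):
    counts = np.asarray(counts, float)
    q = counts[counts > 0] / counts.sum()
    h = -(q * np.log(q)).sum()
    s = (counts > 0).sum()
    return h / np.log(s) if s > 1 else np.nan


def naive_permanova_f_r2(dist, labels):
    """Direct-formula one-way PERMANOVA statistic (no permutations)."""
    dist = np.asarray(dist, float)
    labels = np.asarray(labels)
    n = len(labels)
    groups = sorted(set(labels.tolist()))
    ss_total = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            ss_total += dist[i, j] ** 2
    ss_total /= n
    ss_within = 0.0
    for g in groups:
        idx = [i for i in range(n) if labels[i] == g]
        acc = 0.0
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                acc += dist[idx[a], idx[b]] ** 2
        ss_within += acc / len(idx)
    ss_between = ss_total - ss_within
    k = len(groups)
    f = (ss_between / (k - 1)) / (ss_within / (n - k))
    return f, ss_between / ss_total
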