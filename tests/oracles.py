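"""Independent brute-force metric oracles used by the test suite.

Everything here recomputes metrics by naive enumeration (plain loops and
collections.Counter multisets) and shares no code with the package's
implementations.
"""

from collections import Counter

import numpy as np


def oracle_flat(gold, pred, codeset):
    per_label = {}
    for label in codeset:
        tp = sum(1 for g, p in zip(gold, pred) if label in g and label in p)
        fp = sum(1 for g, p in zip(gold, pred) if label not in g and label in p)
        fn = sum(1 for g, p in zip(gold, pred) if label in g and label not in p)
        per_label[label] = (tp, fp, fn)
    TP = sum(v[0] for v in per_label.values())
    FP = sum(v[1] for v in per_label.values())
    FN = sum(v[2] for v in per_label.values())

    def prf(tp, fp, fn):
        p = tp / (tp + fp) if tp + fp else 0.0
        r = tp / (tp + fn) if tp + fn else 0.0
        f = 2 * p * r / (p + r) if p + r else 0.0
        return p, r, f

    micro = prf(TP, FP, FN)
    per = [prf(*v) for v in per_label.values()]
    macro = tuple(np.mean([x[i] for x in per]) for i in range(3))
    return micro, macro


def oracle_extend(labels, families, mode):
    counts = Counter()
    for leaf in labels:
        counts[leaf] += 1
        counts[families[leaf]] += 1
    if mode == "set":
        counts = Counter({n: 1 for n in counts})
    return counts


def oracle_hier(gold, pred, families, mode):
    TP = FP = FN = 0
    for g, p in zip(gold, pred):
        gc, pc = oracle_extend(g, families, mode), oracle_extend(p, families, mode)
        for node in set(gc) | set(pc):
            TP += min(gc[node], pc[node])
            FP += max(pc[node] - gc[node], 0)
            FN += max(gc[node] - pc[node], 0)
    p = TP / (TP + FP) if TP + FP else 0.0
    r = TP / (TP + FN) if TP + FN else 0.0
    f = 2 * p * r / (p + r) if p + r else 0.0
    return p, r, f


def oracle_whcm(gold, pred, codeset, families):
    outcome = {}
    for g, p in zip(gold, pred):
        fp_fams = {families[c] for c in p if c not in g}
        for label in g:
            if label not in codeset:
                continue
            tally = outcome.setdefault(label, [0, 0, 0])
            if label in p:
                tally[0] += 1
            elif families[label] in fp_fams:
                tally[1] += 1
            else:
                tally[2] += 1
    rates = [[100 * x / sum(t) for x in t] for t in outcome.values()]
    means = [float(np.mean([r[i] for r in rates])) for i in range(3)]
    return means[2], means[1], means[0]  # oof, if, tp


def random_instance(rng):
    """Random small instance: <=5 families x <=4 leaves, <=20 documents."""
    n_fam = int(rng.integers(1, 6))
    heads = [f"{c}{i:02d}" for i, c in enumerate("ABCDE"[:n_fam])]
    leaves = []
    for head in heads:
        for j in range(int(rng.integers(1, 5))):
            leaves.append(f"{head}.{j}")
    families = {leaf: leaf[:3] for leaf in leaves}
    n_docs = int(rng.integers(1, 21))
    gold, pred = [], []
    for _ in range(n_docs):
        gold.append({l for l in leaves if rng.random() < 0.3})
        pred.append({l for l in leaves if rng.random() < 0.3})
    return leaves, families, gold, pred
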