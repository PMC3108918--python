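"""Unoptimised reference MDR used as an independent oracle in tests.

Everything here is plain Python loops over dictionaries keyed by genotype
tuples — deliberately nothing shared with the package's vectorised
implementation.  Ratio comparisons use exact rational arithmetic.
"""

from fractions import Fraction
from itertools import combinations
import math

HIGH, LOW, UNKNOWN = 1, 0, -1


def fit_cells(G, y, rows, loci):
    """Label each genotype cell high/low/unknown from the given rows."""
    counts = {}
    n_case = n_ctrl = 0
    for r in rows:
        key = tuple(int(G[r][l]) for l in loci)
        c = counts.setdefault(key, [0, 0])
        if y[r] == 1:
            c[0] += 1
            n_case += 1
        else:
            c[1] += 1
            n_ctrl += 1
    labels = {}
    for key, (ca, co) in counts.items():
        if ca + co == 0:
            continue
        if n_ctrl == 0:
            is_high = True
        else:
            is_high = Fraction(ca) >= Fraction(n_case, n_ctrl) * co
        labels[key] = HIGH if is_high else LOW
    return labels


def balanced_accuracy(labels, G, y, rows, loci):
    tp = fn = tn = fp = 0
    for r in rows:
        key = tuple(int(G[r][l]) for l in loci)
        if key not in labels:
            continue  # unknown cell: no prediction
        pred = labels[key]
        if y[r] == 1:
            if pred == HIGH:
                tp += 1
            else:
                fn += 1
        else:
            if pred == LOW:
                tn += 1
            else:
                fp += 1
    rates = []
    if tp + fn > 0:
        rates.append(tp / (tp + fn))
    if tn + fp > 0:
        rates.append(tn / (tn + fp))
    if not rates:
        return math.nan
    return sum(rates) / len(rates)


def run(G, y, assignment, n_folds, max_order=2):
    """Evaluate every 1- and 2-locus model under the given fold plan.

    Returns ``{loci: (cvc, mean_train_ba, mean_test_ba, fold_labels)}``.
    Fold wins go to the model of each order with the highest training
    balanced accuracy; ties go to the first model in enumeration order
    (single loci ascending, then pairs in lexicographic order).
    """
    n = len(y)
    L = len(G[0])
    models = [(l,) for l in range(L)]
    if max_order == 2:
        models += list(combinations(range(L), 2))
    stats = {m: {"train": [], "test": [], "labels": []} for m in models}
    for k in range(n_folds):
        test_rows = [r for r in range(n) if assignment[r] == k]
        train_rows = [r for r in range(n) if assignment[r] != k]
        fold_best = {}
        for m in models:
            labels = fit_cells(G, y, train_rows, m)
            tr = balanced_accuracy(labels, G, y, train_rows, m)
            te = balanced_accuracy(labels, G, y, test_rows, m)
            stats[m]["train"].append(tr)
            stats[m]["test"].append(te)
            stats[m]["labels"].append(labels)
            order = len(m)
            if order not in fold_best or tr > fold_best[order][1]:
                fold_best[order] = (m, tr)
        for m, _ in fold_best.values():
            stats[m].setdefault("wins", 0)
            stats[m]["wins"] += 1
    out = {}
    for m in models:
        s = stats[m]
        out[m] = (s.get("wins", 0),
                  sum(s["train"]) / n_folds,
                  sum(s["test"]) / n_folds,
                  s["labels"])
    return out
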