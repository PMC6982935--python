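"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written from the definitions with plain Python loops and
``math`` / ``collections`` only — deliberately sharing no code path with the
package — so agreement between the two is evidence, not tautology.
"""

import math
from collections import Counter
from itertools import combinations


def ac_oracle(values, lg_max):
    """Direct-summation autocovariance: property-major, lag 1..lg_max."""
    n_props = len(values)
    length = len(values[0])
    out = []
    for i in range(n_props):
        mean = sum(values[i]) / length
        for lg in range(1, lg_max + 1):
            s = 0.0
            for j in range(length - lg):
                s += (values[i][j] - mean) * (values[i][j + lg] - mean)
            out.append(s / (length - lg))
    return out


def cc_oracle(values, lg_max):
    """Direct-summation cross-covariance over ordered distinct row pairs."""
    n_props = len(values)
    length = len(values[0])
    means = [sum(row) / length for row in values]
    out = []
    for i1 in range(n_props):
        for i2 in range(n_props):
            if i1 == i2:
                continue
            for lg in range(1, lg_max + 1):
                s = 0.0
                for j in range(length - lg):
                    s += (values[i1][j] - means[i1]) * (values[i2][j + lg] - means[i2])
                out.append(s / (length - lg))
    return out


def mi_oracle(a, b):
    """Plug-in mutual information in bits from Counter-based joint counts."""
    n = len(a)
    joint = Counter(zip(a, b))
    pa = Counter(a)
    pb = Counter(b)
    total = 0.0
    for (x, y), c in joint.items():
        pxy = c / n
        total += pxy * math.log2(pxy * n * n / (pa[x] * pb[y]))
    return total


def entropy_oracle(a):
    n = len(a)
    return -sum((c / n) * math.log2(c / n) for c in Counter(a).values())


def discretize_oracle(column):
    n = len(column)
    mean = sum(column) / n
    sigma = math.sqrt(sum((x - mean) ** 2 for x in column) / n)
    if sigma == 0:
        return [1] * n
    out = []
    for x in column:
        if x <= mean - sigma:
            out.append(0)
        elif x >= mean + sigma:
            out.append(2)
        else:
            out.append(1)
    return out


def mrmr_greedy_oracle(columns, y, k):
    """Brute-force greedy mRMR on already-discretised columns.

    ``columns`` is a list of integer-state lists (one per feature).  Returns
    the list of picked indices.  First pick maximises I(x; y); later picks
    maximise I(x; y) minus the mean MI with the selected set; exact ties go
    to the lower index.
    """
    p = len(columns)
    rel = [mi_oracle(col, y) for col in columns]
    selected = []
    remaining = list(range(p))
    for _ in range(k):
        best, best_val = None, -math.inf
        for j in remaining:
            if not selected:
                v = rel[j]
            else:
                red = sum(mi_oracle(columns[j], columns[s]) for s in selected)
                v = rel[j] - red / len(selected)
            if v > best_val:
                best, best_val = j, v
        selected.append(best)
        remaining.remove(best)
    return selected


def metrics_oracle(tp, tn, fp, fn):
    """Direct evaluation of the six printed confusion-matrix formulas."""
    nan = float("nan")
    sn = tp / (tp + fn) if tp + fn else nan
    sp = tn / (tn + fp) if tn + fp else nan
    prec = tp / (tp + fp) if tp + fp else nan
    if not math.isnan(sn) and not math.isnan(prec) and (sn + prec):
        f1 = 2 * sn * prec / (sn + prec)
    else:
        f1 = nan
    acc = (tp + tn) / (tp + tn + fp + fn) if tp + tn + fp + fn else nan
    den = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(den) if den else nan
    return {"sn": sn, "sp": sp, "f1": f1, "accuracy": acc, "mcc": mcc}


def auc_oracle(truth, scores):
    """All-pairs AUC: P(score_pos > score_neg) with ties counted 1/2."""
    pos = [s for t, s in zip(truth, scores) if t == 1]
    neg = [s for t, s in zip(truth, scores) if t == 0]
    if not pos or not neg:
        return float("nan")
    wins = 0.0
    for sp_ in pos:
        for sn_ in neg:
            wins += 1.0 if sp_ > sn_ else (0.5 if sp_ == sn_ else 0.0)
    return wins / (len(pos) * len(neg))


def lse_window_oracle(seq, table, fallback):
    """Per-position mean over the values of all 4-mer windows covering it."""
    length = len(seq)
    wins = []
    for k in range(length - 3):
        kmer = seq[k : k + 4]
        wins.append(table.get(kmer, fallback))
    out = []
    for j in range(length):
        cover = [wins[k] for k in range(max(0, j - 3), min(j, length - 4) + 1)]
        out.append(sum(cover) / len(cover))
    return out


def dipeptide_oracle(seq, aa_order, gaps):
    """Brute-force gapped pair enumeration, denominator N - 1 for every gap."""
    n = len(seq)
    out = {}
    for g in gaps:
        for a in aa_order:
            for b in aa_order:
                count = sum(
                    1
                    for j in range(n - g - 1)
                    if seq[j] == a and seq[j + g + 1] == b
                )
                out[(g, a, b)] = count / (n - 1)
    return out
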