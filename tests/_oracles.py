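"""Independent reference implementations used only to cross-check the
package: naive enumeration/step-up/scan code paths deliberately written
without reusing the package's internals."""
from __future__ import annotations

import math

import numpy as np
from scipy import stats as sps


def bh_reference(p):
    """Textbook Benjamini-Hochberg step-up, O(n log n), input order."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        q[i] = running
    return q


def fisher_two_sided_enumeration(a, b, c, d):
    """Two-sided Fisher p by exhaustive enumeration at fixed margins.

    Table [[a, b], [c, d]]: sums the hypergeometric point probabilities of
    every table (same margins) whose probability does not exceed the
    observed one.
    """
    row1, row2 = a + b, c + d
    col1 = a + c
    n = row1 + row2

    def point_prob(x):
        # P(X = x) for X ~ Hypergeom(n, col1, row1)
        return (math.comb(col1, x) * math.comb(n - col1, row1 - x)
                / math.comb(n, row1))

    lo = max(0, col1 - row2)
    hi = min(col1, row1)
    observed = point_prob(a)
    total = 0.0
    for x in range(lo, hi + 1):
        px = point_prob(x)
        if px <= observed * (1 + 1e-9):
            total += px
    return min(total, 1.0)


def welch_reference(x, y):
    """Plain two-sided Welch t-test on two float samples (scipy)."""
    return float(sps.ttest_ind(y, x, equal_var=False).pvalue)


def interval_overlay_bruteforce(query, reference):
    """Overlay percent per query interval via explicit nucleotide sets."""
    ref_nucs: dict[str, set[int]] = {}
    for c, s, e in reference:
        ref_nucs.setdefault(c, set()).update(range(s, e + 1))
    out = []
    for c, s, e in query:
        covered = sum(1 for p in range(s, e + 1)
                      if p in ref_nucs.get(c, ()))
        out.append(100.0 * covered / (e - s + 1))
    return np.array(out)


def confusion_bruteforce(predicted, benchmark):
    """(tp, fp, fn) via all-pairs >= 1-nucleotide overlap checks."""
    def overlaps(i1, i2):
        return i1[0] == i2[0] and i1[1] <= i2[2] and i2[1] <= i1[2]

    tp = sum(1 for p in predicted if any(overlaps(p, b) for b in benchmark))
    fn = sum(1 for b in benchmark if not any(overlaps(b, p) for p in predicted))
    return tp, len(list(predicted)) - tp, fn


def site_qualifies_reference(meth_a, cov_a, meth_b, cov_b, crit):
    """Per-site verdict computed from first principles (scalar, scipy).

    Returns (qualifies, sign of difference).
    """
    ma, ca = np.asarray(meth_a, float), np.asarray(cov_a, float)
    mb, cb = np.asarray(meth_b, float), np.asarray(cov_b, float)
    if (ca < crit.min_coverage).any() or (cb < crit.min_coverage).any():
        return False, 0
    if ca.sum() == 0 or cb.sum() == 0:
        return False, 0
    mean_a = ma.sum() / ca.sum()
    mean_b = mb.sum() / cb.sum()
    diff = mean_b - mean_a
    if abs(diff) < crit.min_diff / 100.0:
        return False, 0
    if min(len(ma), len(mb)) == 1:
        table = [[ma.sum(), ca.sum() - ma.sum()],
                 [mb.sum(), cb.sum() - mb.sum()]]
        if np.sum(table) == 0:
            return False, 0
        p = min(float(sps.fisher_exact(np.asarray(table, dtype=np.int64))[1]),
                1.0)
    else:
        def wstats(m, c):
            mbar = m.sum() / c.sum()
            frac = np.where(c > 0, m / np.where(c > 0, c, 1), 0.0)
            return mbar, float((c * (mbar - frac) ** 2).sum() / (c.sum() - 1))
        if ca.sum() <= 1 or cb.sum() <= 1:
            return False, 0
        mu_a, va = wstats(ma, ca)
        mu_b, vb = wstats(mb, cb)
        se2 = va / len(ma) + vb / len(mb)
        if se2 == 0:
            p = 1.0 if mu_a == mu_b else 0.0
        else:
            t = (mu_b - mu_a) / math.sqrt(se2)
            df = se2 ** 2 / ((va / len(ma)) ** 2 / (len(ma) - 1)
                             + (vb / len(mb)) ** 2 / (len(mb) - 1))
            p = 2 * sps.t.sf(abs(t), df)
    if p > crit.max_p:
        return False, 0
    return True, int(np.sign(diff))


def wwe_scan_reference(pos, qual, sign, crit):
    """Naive region scan over one chromosome: list-building re-derivation
    of the expansion / gap / similar-run / shrink-back / emission rules.

    Returns emitted regions as (first_index, last_index, n_qualifying).
    """
    pos = list(map(int, pos))
    n = len(pos)
    emitted = []
    i = 0
    while i < n:
        if not qual[i]:
            i += 1
            continue
        direction = sign[i]
        included = [i]          # indices included during expansion
        last_qual_slot = 0      # position in `included` of last qualifying
        next_i = n
        j = i + 1
        while j < n:
            if pos[j] - pos[included[-1]] > crit.max_gap:
                next_i = j      # revisit j as a fresh opener
                break
            if qual[j] and sign[j] == direction:
                included.append(j)
                last_qual_slot = len(included) - 1
            elif qual[j]:
                next_i = j      # opposite direction seeds a new candidate
                break
            else:
                trailing = len(included) - 1 - last_qual_slot
                if trailing + 1 > crit.max_similar:
                    next_i = j + 1
                    break
                included.append(j)
            j += 1
        region = included[:last_qual_slot + 1]  # shrink back
        n_cpn = sum(1 for k in region if qual[k])
        span = pos[region[-1]] - pos[region[0]] + 1
        if n_cpn >= crit.min_cpn and span >= crit.min_span:
            emitted.append((region[0], region[-1], n_cpn))
        i = next_i
    return emitted
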