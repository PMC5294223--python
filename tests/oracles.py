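"""Independent reference implementations used to check the package.

These are deliberately naive (explicit loops, enumeration) and share no
code with tdgrn.
"""

from __future__ import annotations

import itertools
import math


def bruteforce_time_delayed_mi(x_series, y_series, k, n_bins, log_base=2.0):
    """Plug-in MI at lag k via an explicit contingency-table triple loop."""
    pairs = []
    for xs, ys in zip(x_series, y_series):
        for i in range(len(xs) - k):
            pairs.append((int(xs[i]), int(ys[i + k])))
    total = len(pairs)
    mi = 0.0
    for a in range(n_bins):
        for b in range(n_bins):
            nab = sum(1 for p in pairs if p == (a, b))
            if nab == 0:
                continue
            na = sum(1 for p in pairs if p[0] == a)
            nb = sum(1 for p in pairs if p[1] == b)
            pab = nab / total
            mi += pab * math.log(pab / ((na / total) * (nb / total)), log_base)
    return max(mi, 0.0)


def student_t_statistic(a, b):
    """Equal-variance two-sample t from the textbook pooled formula."""
    na, nb = len(a), len(b)
    ma = sum(a) / na
    mb = sum(b) / nb
    sa2 = sum((v - ma) ** 2 for v in a) / (na - 1)
    sb2 = sum((v - mb) ** 2 for v in b) / (nb - 1)
    sp2 = ((na - 1) * sa2 + (nb - 1) * sb2) / (na + nb - 2)
    return (ma - mb) / math.sqrt(sp2 * (1 / na + 1 / nb))


def wilcoxon_exact_p(differences):
    """Two-sided signed-rank p by enumerating all 2^n sign assignments.

    Assumes nonzero differences with distinct absolute values (no ties).
    """
    d = [v for v in differences if v != 0]
    n = len(d)
    ranked = sorted(range(n), key=lambda i: abs(d[i]))
    ranks = [0] * n
    for r, i in enumerate(ranked, start=1):
        ranks[i] = r
    w_obs = sum(ranks[i] for i in range(n) if d[i] > 0)
    le = ge = 0
    for signs in itertools.product((0, 1), repeat=n):
        w = sum(ranks[i] for i in range(n) if signs[i])
        le += w <= w_obs
        ge += w >= w_obs
    total = 2 ** n
    return min(1.0, 2 * min(le / total, ge / total))
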