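"""Independent oracles shared by the unit and acceptance suites.

These are deliberately written from scratch (scalar arithmetic, explicit
loops) and must stay decoupled from the package implementations they
check.
"""

import numpy as np

from heteropool.variant_io import MISSING


def wc_oracle(n1, p1, h1, n2, p2, h2):
    """Scalar transcription of the two-population diploid Weir-Cockerham
    variance components (a, b, c) from the published equations."""
    r = 2
    nbar = (n1 + n2) / r
    C2_num = (n1 - nbar) ** 2 + (n2 - nbar) ** 2
    nc = nbar - C2_num / (r * nbar)
    pbar = (n1 * p1 + n2 * p2) / (n1 + n2)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (n1 + n2)
    a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4)
                       / (nbar - 1))
    b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - s2 * (r - 1) / r
                               - hbar * (2 * nbar - 1) / (4 * nbar))
    c = hbar / 2
    return a, b, c


def panel_stats(dosage, idx):
    """Brute-force per-site (n_called, alt freq, het proportion) for one
    group of sample columns."""
    sub = dosage[:, idx]
    n = np.zeros(sub.shape[0])
    p = np.zeros(sub.shape[0])
    h = np.zeros(sub.shape[0])
    for i in range(sub.shape[0]):
        calls = sub[i][sub[i] != MISSING]
        n[i] = len(calls)
        if len(calls):
            p[i] = calls.sum() / (2 * len(calls))
            h[i] = (calls == 1).mean()
    return n, p, h


def pearson_chi2_oracle(table):
    """Textbook Pearson chi-squared statistic on a 2x2 table."""
    table = np.asarray(table, dtype=float)
    total = table.sum()
    chi2 = 0.0
    for i in range(2):
        for j in range(2):
            expected = table[i].sum() * table[:, j].sum() / total
            chi2 += (table[i, j] - expected) ** 2 / expected
    return chi2
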