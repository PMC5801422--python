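"""Independent reference implementations used only to check the package.

These are deliberately written in plain Python (no shared code with
src/rhythmboot) so they can serve as oracles: a step-by-step median-polish
sweep and a literal Benjamini-Hochberg step-up rule.
"""

import statistics


def median_polish_oracle(matrix, max_iter=10, tol=1e-4):
    """Row-then-column median sweeps on nested lists.

    Same sweep order and stopping rule as the package implementation but
    coded independently with ``statistics.median`` and explicit loops.
    Returns (overall, row_effects, col_effects, residuals).
    """
    resid = [list(map(float, row)) for row in matrix]
    P = len(resid)
    T = len(resid[0])
    overall = 0.0
    row_eff = [0.0] * P
    col_eff = [0.0] * T

    init_sum = sum(abs(v) for r in resid for v in r)
    prev = init_sum
    for _ in range(max_iter):
        for i in range(P):
            m = statistics.median(resid[i])
            row_eff[i] += m
            for j in range(T):
                resid[i][j] -= m
        m = statistics.median(col_eff)
        overall += m
        col_eff = [c - m for c in col_eff]

        for j in range(T):
            m = statistics.median(resid[i][j] for i in range(P))
            col_eff[j] += m
            for i in range(P):
                resid[i][j] -= m
        m = statistics.median(row_eff)
        overall += m
        row_eff = [r - m for r in row_eff]

        cur = sum(abs(v) for r in resid for v in r)
        if prev - cur < tol * (init_sum + 1e-12):
            break
        prev = cur

    m = statistics.median(row_eff)
    overall += m
    row_eff = [r - m for r in row_eff]
    m = statistics.median(col_eff)
    overall += m
    col_eff = [c - m for c in col_eff]
    return overall, row_eff, col_eff, resid


def bh_oracle(pvalues):
    """Literal BH step-up: sort, scale by m/k, cumulative min from the top."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    scaled = [pvalues[order[k]] * m / (k + 1) for k in range(m)]
    running = 1.0
    adjusted_sorted = [0.0] * m
    for k in range(m - 1, -1, -1):
        running = min(running, scaled[k])
        adjusted_sorted[k] = min(running, 1.0)
    out = [0.0] * m
    for k, idx in enumerate(order):
        out[idx] = adjusted_sorted[k]
    return out
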