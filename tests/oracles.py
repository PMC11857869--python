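"""Independent small-sample oracles, deliberately written from first
principles (no lifelines, no km2ipd internals) so they can vouch for the
implementation rather than mirror it."""

import numpy as np


def logrank_oracle(ta, ea, tb, eb):
    """Textbook two-sample log-rank statistic via hypergeometric tables."""
    ta, ea, tb, eb = map(np.asarray, (ta, ea, tb, eb))
    all_t = np.concatenate([ta, tb])
    all_e = np.concatenate([ea, eb])
    O = E = V = 0.0
    for t in np.unique(all_t[all_e == 1]):
        n1 = (ta >= t).sum()
        n2 = (tb >= t).sum()
        n = n1 + n2
        d = ((all_t == t) & (all_e == 1)).sum()
        d1 = ((ta == t) & (ea == 1)).sum()
        O += d1
        E += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    return (O - E) ** 2 / V


def cox_grid_oracle(times, events, x, lo=-5.0, hi=5.0):
    """Maximize the (no-ties) Cox partial likelihood by iterated grid refinement."""
    times, events, x = map(np.asarray, (times, events, x))

    def nll(beta):
        ll = 0.0
        for t in times[events == 1]:
            risk = times >= t
            i = np.flatnonzero((times == t) & (events == 1))[0]
            ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk])))
        return -ll

    grid = np.linspace(lo, hi, 201)
    for _ in range(6):
        grid = np.linspace(lo, hi, 201)
        vals = [nll(b) for b in grid]
        j = int(np.argmin(vals))
        lo, hi = grid[max(0, j - 2)], grid[min(200, j + 2)]
    return grid[j]
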