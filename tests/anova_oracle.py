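"""Brute-force ANOVA oracle: sequential least-squares projection onto
cell-indicator design matrices, written independently of the package's
marginal-means implementation.

For a balanced design the sum of squares of a term equals the increase in
fitted sum of squares when that term's cell indicators are added to the
model containing all lower terms in the factor lattice.
"""

from itertools import combinations

import numpy as np
from scipy import stats as sps


def _indicator(cell_ids: np.ndarray) -> np.ndarray:
    _, inv = np.unique(cell_ids, return_inverse=True, axis=0)
    k = inv.max() + 1
    X = np.zeros((len(inv), k))
    X[np.arange(len(inv)), inv] = 1.0
    return X


def anova_oracle(y: np.ndarray, within_names, groups=None, between_name="group"):
    """Return {effect: (SS, df_num, df_den, F, p)} by explicit projection."""
    y = np.asarray(y, dtype=float)
    n_subj = y.shape[0]
    k = y.ndim - 1
    shape = y.shape[1:]
    if groups is None:
        g = np.zeros(n_subj, dtype=int)
        n_groups = 1
    else:
        _, g = np.unique(np.asarray(groups), return_inverse=True)
        n_groups = g.max() + 1

    # long-format observation labels
    cells_per_subj = int(np.prod(shape)) if shape else 1
    subj_col = np.repeat(np.arange(n_subj), cells_per_subj)
    lvl_cols = []
    for i in range(k):
        before = int(np.prod(shape[:i])) if i else 1
        after = int(np.prod(shape[i + 1:])) if i + 1 < k else 1
        per_subj = np.tile(np.repeat(np.arange(shape[i]), after), before)
        lvl_cols.append(np.tile(per_subj, n_subj))
    grp_col = g[subj_col]
    yv = y.reshape(-1)

    b_levels = (0, 1, 2) if n_groups > 1 else (0, 2)
    terms = sorted(
        [
            (tuple(c), b)
            for r in range(k + 1)
            for c in combinations(range(k), r)
            for b in b_levels
        ],
        key=lambda tb: (len(tb[0]), tb[1]),
    )

    X = np.ones((len(yv), 1))
    prev_fit = X @ np.linalg.lstsq(X, yv, rcond=None)[0]
    prev_ss = float(prev_fit @ prev_fit)
    ss, dfs = {}, {}
    for t, b in terms:
        cols = [lvl_cols[i] for i in t]
        if b == 1:
            cols = cols + [grp_col]
        elif b == 2:
            cols = cols + [subj_col]
        if cols:
            cells = np.stack(cols, axis=1)
            X = np.hstack([X, _indicator(cells)])
        fit = X @ np.linalg.lstsq(X, yv, rcond=None)[0]
        cur = float(fit @ fit)
        ss[(t, b)] = cur - prev_ss
        d = 1
        for i in t:
            d *= shape[i] - 1
        if b == 1:
            d *= n_groups - 1
        elif b == 2:
            d *= (n_subj - n_groups) if n_groups > 1 else n_subj - 1
        dfs[(t, b)] = d
        prev_ss = cur

    out = {}
    for t, b in terms:
        if b == 2 or (b == 0 and not t):
            continue
        name_parts = [within_names[i] for i in t]
        if b == 1:
            name_parts.append(between_name)
        name = " × ".join(name_parts) if name_parts else between_name
        ss_e, df_e = ss[(t, 2)], dfs[(t, 2)]
        df_n = dfs[(t, b)]
        F = (ss[(t, b)] / df_n) / (ss_e / df_e)
        out[name] = (ss[(t, b)], df_n, df_e, F, float(sps.f.sf(F, df_n, df_e)))
    return out
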