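"""Independent brute-force reference implementations used as test oracles.

These deliberately follow the textbook definitions with naive loops and are
kept independent of the package's vectorized/library-backed code paths.
"""

from itertools import combinations

import numpy as np
from scipy.stats import rankdata
from sklearn.tree import DecisionTreeRegressor


def sampen_bruteforce(x, lag, m, r):
    """Sample entropy by explicit O(n^2) template comparison (Chebyshev)."""
    x = np.asarray(x, dtype=float)
    n_templates = x.size - m * lag

    def count(order):
        c = 0
        for i in range(n_templates):
            for j in range(i + 1, n_templates):
                d = max(abs(x[i + k * lag] - x[j + k * lag]) for k in range(order))
                if d <= r:
                    c += 1
        return c

    b = count(m)
    a = count(m + 1)
    if a == 0 or b == 0:
        return float("nan")
    return -np.log(a / b)


def lz76_bruteforce(bits):
    """LZ76 exhaustive-history word count by explicit substring scanning."""
    s = "".join(str(int(b)) for b in bits)
    n = len(s)
    if n <= 1:
        return n

    def reproducible(word, history_end):
        # does `word` occur starting at any position < history_end - len(word) + 1?
        hist = s[:history_end]
        for start in range(len(hist) - len(word) + 1):
            if hist[start : start + len(word)] == word:
                return True
        return False

    c = 0
    p = 0
    while p < n:
        length = 1
        while p + length <= n and reproducible(s[p : p + length], p + length - 1):
            length += 1
        if p + length > n:
            length = n - p
        c += 1
        p += length
    return c


def mwu_exact_bruteforce(x, y):
    """Two-sided exact Mann-Whitney p by full enumeration of label assignments.

    Requires tie-free pooled samples. Returns (U_x, p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    assert np.unique(pooled).size == pooled.size, "oracle requires no ties"
    n1, n2 = x.size, y.size
    ranks = rankdata(pooled)
    u1 = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2)
    u2 = n1 * n2 - u1
    u_lo, u_hi = min(u1, u2), max(u1, u2)
    total = 0
    hits = 0
    for idx in combinations(range(n1 + n2), n1):
        r = ranks[list(idx)].sum()
        u = r - n1 * (n1 + 1) / 2
        total += 1
        if u <= u_lo or u >= u_hi:
            hits += 1
    return u1, hits / total


def bh_bruteforce(p, q):
    """BH step-up by trying every threshold; returns (reject, p_adjusted)."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p)
    sorted_p = p[order]
    k_star = 0
    for k in range(1, m + 1):
        if sorted_p[k - 1] <= k * q / m:
            k_star = k
    reject = np.zeros(m, dtype=bool)
    if k_star > 0:
        reject[order[:k_star]] = True
    adj_sorted = np.minimum.accumulate((m * sorted_p / np.arange(1, m + 1))[::-1])[::-1]
    adj_sorted = np.minimum(adj_sorted, 1.0)
    adjusted = np.empty(m)
    adjusted[order] = adj_sorted
    return reject, adjusted


def stagewise_booster_predict(X_train, y_train, X_test, steps, max_depth, lr, seed=0):
    """~20-line reference gradient booster: stagewise least-squares fitting of
    depth-limited trees on the residuals of the running prediction."""
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train, dtype=float)
    X_test = np.asarray(X_test, dtype=float)
    f_train = np.full(y_train.shape, y_train.mean())
    f_test = np.full(X_test.shape[0], y_train.mean())
    for _ in range(steps):
        tree = DecisionTreeRegressor(max_depth=max_depth, random_state=seed)
        tree.fit(X_train, y_train - f_train)
        f_train = f_train + lr * tree.predict(X_train)
        f_test = f_test + lr * tree.predict(X_test)
    return f_test
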