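"""Independent brute-force oracles for the feature families and metrics.

Everything here is written as plain double loops straight from the
definitions, deliberately sharing no code with the package internals.
"""

import numpy as np

AA = "ARNDCQEGHILKMFPSTWYV"


def oracle_window_composition(ss, k):
    L = len(ss)
    out = {}
    for code in "HAP":
        total = 0.0
        for t in range(L - k + 1):
            total += ss[t:t + k].count(code) / k
        out[code] = total / (L - k + 1)
    return out


def oracle_g1(seq):
    return np.array([np.sqrt(seq.count(a) / len(seq)) for a in AA])


def oracle_g2(P):
    L = P.shape[0]
    pos = [sum(max(P[i, j], 0) for i in range(L)) / L for j in range(20)]
    neg = [sum(min(P[i, j], 0) for i in range(L)) / L for j in range(20)]
    return np.array(pos + neg)


def oracle_property_autocorr(P, prop, lags):
    L = P.shape[0]
    hpos = [sum(prop[j] * max(P[i, j], 0) for j in range(20)) for i in range(L)]
    hneg = [sum(prop[j] * min(P[i, j], 0) for j in range(20)) for i in range(L)]
    out = []
    for h in (hpos, hneg):
        for k in lags:
            if k >= L:
                out.append(0.0)
                continue
            out.append(sum(h[i] * h[i + k] for i in range(L - k)) / (L - k))
    return np.array(out)


def oracle_g5(P, lags):
    L = P.shape[0]
    out = []
    for j in range(20):
        for k in lags:
            if k >= L:
                out.append(0.0)
                continue
            out.append(sum(P[i, j] * P[i + k, j] for i in range(L - k)) / (L - k))
    return np.array(out)


def oracle_g6(P, seg_lengths):
    L = P.shape[0]
    out = []
    for clip in (lambda v: max(v, 0), lambda v: min(v, 0)):
        for k in seg_lengths:
            if k > L:
                out.extend([0.0] * 20)
                continue
            for j in range(20):
                total = 0.0
                for t in range(L - k + 1):
                    seg = sum(clip(P[i, j]) for i in range(t, t + k)) / k
                    total += seg ** 2
                out.append(total / (L - k + 1))
    return np.array(out)


def oracle_g7(P):
    L = P.shape[0]
    half = int(np.ceil(L / 2))
    out = []
    for j in range(20):
        w = [max(P[i, j], 0) for i in range(L)]
        W = sum(w)
        if W == 0:
            out.extend([0.5, 0.0, 0.0, 0.25])
            continue
        r = [(i + 1) / L for i in range(L)]
        mean = sum(wi * ri for wi, ri in zip(w, r)) / W
        spread = np.sqrt(sum(wi * (ri - mean) ** 2 for wi, ri in zip(w, r)) / W)
        bias = (sum(w[:half]) - sum(w[half:])) / W
        edge = sum(wi * abs(ri - 0.5) for wi, ri in zip(w, r)) / W
        out.extend([mean, spread, bias, edge])
    return np.array(out)


def oracle_mcc(tp, fp, tn, fn):
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / np.sqrt(denom)


def oracle_gc2(cm, k_classes=4):
    cm = np.asarray(cm, dtype=float)
    n = cm.sum()
    chi2 = 0.0
    for r in range(cm.shape[0]):
        for c in range(cm.shape[1]):
            e = cm[r].sum() * cm[:, c].sum() / n
            if e > 0:
                chi2 += (cm[r, c] - e) ** 2 / e
    return chi2 / (n * (k_classes - 1))


def oracle_normal_equations(X, t):
    return np.linalg.solve(X.T @ X, X.T @ t)


def oracle_decide(x, y1, y2, z):
    if x > 0 and y1 < 0:
        return "all-alpha"
    if x <= 0 and y2 < 0:
        return "all-beta"
    return "alpha/beta" if z > 0 else "alpha+beta"


def oracle_forward_select(X, t, m):
    """Literal refit-and-minimize-RSS selection (small problems only)."""
    n, p = X.shape
    Xc = X - X.mean(axis=0)
    tc = t - t.mean()
    selected = []
    # first: |Pearson correlation|
    best, best_score = None, -1.0
    for j in range(p):
        sx = np.linalg.norm(Xc[:, j])
        st = np.linalg.norm(tc)
        score = 0.0 if sx < 1e-12 or st < 1e-12 else abs(Xc[:, j] @ tc) / (sx * st)
        if score > best_score + 1e-12:
            best, best_score = j, score
    selected.append(best)
    while len(selected) < m:
        best, best_rss = None, np.inf
        for j in range(p):
            if j in selected:
                continue
            design = np.hstack([X[:, selected + [j]], np.ones((n, 1))])
            beta, *_ = np.linalg.lstsq(design, t, rcond=None)
            rss = float(((t - design @ beta) ** 2).sum())
            if rss < best_rss - 1e-12:
                best, best_rss = j, rss
        selected.append(best)
    return selected
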