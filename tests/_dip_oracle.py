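"""Brute-force dip oracle: LP minimisation over piecewise-linear unimodal CDFs.

Independent of the production GCM/LCM algorithm: for every candidate mode
(each data point, plus a grid of interior positions, each allowed an atom)
the sup-distance between the empirical CDF and a unimodal CDF is minimised
by linear programming over the CDF values at the data points.  Exhaustive
and exact up to the interior-mode grid; practical for n <= ~10.
"""

import numpy as np
from scipy.optimize import linprog


def dip_bruteforce(sample, n_interior: int = 7) -> float:
    x = np.sort(np.asarray(sample, float))
    n = x.size
    u = np.unique(x)
    m = u.size
    if m == 1:
        return 0.0
    counts = np.array([np.sum(x == v) for v in u])
    c = np.cumsum(counts) / n  # F(u_i)
    b = c - counts / n  # F(u_i^-)

    def solve(points_cv, points_cc, bands, mono_pairs):
        names = sorted(
            {p[0] for p in points_cv}
            | {p[0] for p in points_cc}
            | {nm for nm, _, _ in bands}
            | {a for a, _ in mono_pairs}
            | {bn for _, bn in mono_pairs}
        )
        idx = {nm: i for i, nm in enumerate(names)}
        nv = len(names) + 1
        ti = nv - 1
        A, rhs = [], []

        def band(nm, lo, hi):
            row = [0.0] * nv
            row[idx[nm]] = 1.0
            row[ti] = -1.0
            A.append(row)
            rhs.append(hi)
            row = [0.0] * nv
            row[idx[nm]] = -1.0
            row[ti] = -1.0
            A.append(row)
            rhs.append(-lo)

        for nm, lo, hi in bands:
            band(nm, lo, hi)
        for a, bn in mono_pairs:
            row = [0.0] * nv
            row[idx[a]] = 1.0
            row[idx[bn]] = -1.0
            A.append(row)
            rhs.append(0.0)
        for pts, sign in ((points_cv, 1.0), (points_cc, -1.0)):
            for (n1, x1), (n2, x2), (n3, x3) in zip(pts, pts[1:], pts[2:]):
                d1, d2 = x2 - x1, x3 - x2
                row = [0.0] * nv
                row[idx[n1]] += -sign / d1
                row[idx[n2]] += sign / d1 + sign / d2
                row[idx[n3]] += -sign / d2
                A.append(row)
                rhs.append(0.0)
        cost = [0.0] * nv
        cost[ti] = 1.0
        res = linprog(
            cost, A_ub=np.array(A), b_ub=np.array(rhs),
            bounds=[(0.0, 1.0)] * nv, method="highs",
        )
        return res.fun if res.status == 0 else np.inf

    g = [f"g{i}" for i in range(m)]
    best = np.inf

    for k in range(m):  # mode at data point u_k (atom allowed)
        bands = []
        for i in range(m):
            bands.append((g[i], c[i], c[i]))
            if i != k:
                bands.append((g[i], b[i], b[i]))
        bands.append(("gl", b[k], b[k]))
        mono = [(g[i], g[i + 1]) for i in range(m - 1)]
        if k > 0:
            mono.append((g[k - 1], "gl"))
        mono.append(("gl", g[k]))
        cv = [(g[i], u[i]) for i in range(k)] + [("gl", u[k])]
        cc = [(g[i], u[i]) for i in range(k, m)]
        best = min(best, solve(cv, cc, bands, mono))

    for j in range(m - 1):  # interior modes (atom allowed)
        for frac in np.linspace(0.05, 0.95, n_interior):
            mu = u[j] + frac * (u[j + 1] - u[j])
            bands = []
            for i in range(m):
                bands.append((g[i], c[i], c[i]))
                bands.append((g[i], b[i], b[i]))
            bands.append(("gl", c[j], c[j]))
            bands.append(("gr", c[j], c[j]))
            mono = [(g[i], g[i + 1]) for i in range(m - 1)]
            mono += [(g[j], "gl"), ("gl", "gr"), ("gr", g[j + 1])]
            cv = [(g[i], u[i]) for i in range(j + 1)] + [("gl", mu)]
            cc = [("gr", mu)] + [(g[i], u[i]) for i in range(j + 1, m)]
            best = min(best, solve(cv, cc, bands, mono))
    return float(best)
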