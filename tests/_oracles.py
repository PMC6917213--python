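"""Independent brute-force oracles used to verify the package's estimators.

Everything here is deliberately naive — direct transcription of the
defining formulas, quadratic loops, generic numerical optimization — and
shares no code with the implementation under test.
"""

import numpy as np
from scipy import optimize


def km_oracle(time, event):
    """Product-limit estimator by direct accumulation.

    Returns (times, survival) at each distinct observed time.
    """
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    ts = np.unique(time)
    s = 1.0
    out_t, out_s = [], []
    for t in ts:
        n_risk = np.sum(time >= t)
        d = np.sum((time == t) & (event == 1))
        if d > 0:
            s *= 1.0 - d / n_risk
        out_t.append(t)
        out_s.append(s)
    return np.array(out_t), np.array(out_s)


def logrank_oracle(time, event, group):
    """k-group log-rank chi-square by observed-minus-expected accumulation."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    group = np.asarray(group)
    labels = np.unique(group)
    k = len(labels)
    O = np.zeros(k)
    E = np.zeros(k)
    V = np.zeros((k, k))
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n = at_risk.sum()
        d = np.sum((time == t) & (event == 1))
        ni = np.array([np.sum(at_risk & (group == g)) for g in labels])
        di = np.array([np.sum((time == t) & (event == 1) & (group == g)) for g in labels])
        O += di
        E += d * ni / n
        if n > 1:
            for a in range(k):
                for b in range(k):
                    if a == b:
                        V[a, b] += d * (ni[a] / n) * (1 - ni[a] / n) * (n - d) / (n - 1)
                    else:
                        V[a, b] += -d * (ni[a] * ni[b] / n**2) * (n - d) / (n - 1)
    z = (O - E)[: k - 1]
    stat = float(z @ np.linalg.solve(V[: k - 1, : k - 1], z))
    return stat


def efron_loglik(beta, X, time, event):
    """Efron-corrected Cox partial log-likelihood, direct transcription."""
    beta = np.atleast_1d(np.asarray(beta, float))
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[0] != len(time):
        X = X.T
    eta = X @ beta
    w = np.exp(eta)
    ll = 0.0
    for t in np.unique(np.asarray(time)[np.asarray(event) == 1]):
        deaths = (time == t) & (event == 1)
        risk = time >= t
        d = deaths.sum()
        sum_risk = w[risk].sum()
        sum_dead = w[deaths].sum()
        ll += eta[deaths].sum()
        for ell in range(d):
            ll -= np.log(sum_risk - (ell / d) * sum_dead)
    return ll


def cox_oracle(X, time, event):
    """Maximize the Efron partial likelihood with a generic optimizer."""
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[0] != len(time):
        X = X.T
    p = X.shape[1]
    res = optimize.minimize(
        lambda b: -efron_loglik(b, X, time, event),
        x0=np.zeros(p),
        method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000},
    )
    return res.x


def cindex_oracle(risk, time, event):
    """Harrell's C by exhaustive pair enumeration.

    A pair is usable when subject i's event precedes subject j's time, or
    when the times tie and only i had the event; tied event times are not
    comparable.  Ties in risk count 1/2.
    """
    risk = np.asarray(risk, float)
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    num = den = 0.0
    n = len(time)
    for i in range(n):
        if event[i] != 1:
            continue
        for j in range(n):
            if i == j:
                continue
            usable = time[i] < time[j] or (time[i] == time[j] and event[j] == 0)
            if not usable:
                continue
            den += 1
            if risk[i] > risk[j]:
                num += 1
            elif risk[i] == risk[j]:
                num += 0.5
    return num / den


def bh_oracle(p):
    """Benjamini–Hochberg step-up by the defining min-over-tail formula."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for rank0, idx in enumerate(order):
        tail = [m * p[order[j]] / (j + 1) for j in range(rank0, m)]
        q[idx] = min(1.0, min(tail))
    return q
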