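"""Independent reference implementations used only to check the package.

Everything here is deliberately written as plain-Python direct summation,
exhaustive enumeration or brute-force optimisation, sharing no code with the
implementation under test.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def oracle_regression_metrics(y, yhat, train_mean=None, n_train=None, train_ss=None):
    """Direct-summation computation of every validation statistic."""
    y = list(map(float, y))
    yhat = list(map(float, yhat))
    n = len(y)
    ybar = math.fsum(y) / n
    yhbar = math.fsum(yhat) / n
    ss_obs = math.fsum((a - ybar) ** 2 for a in y)
    ss_pred = math.fsum((b - yhbar) ** 2 for b in yhat)
    press = math.fsum((a - b) ** 2 for a, b in zip(y, yhat))

    out = {}
    out["r2"] = 1.0 - press / ss_obs
    out["mae"] = math.fsum(abs(a - b) for a, b in zip(y, yhat)) / n
    cross = math.fsum(a * b for a, b in zip(y, yhat))
    k = cross / math.fsum(b * b for b in yhat)
    kp = cross / math.fsum(a * a for a in y)
    out["k_slope"] = k
    out["k_prime"] = kp
    out["r2_0"] = 1.0 - math.fsum((a - k * b) ** 2 for a, b in zip(y, yhat)) / ss_obs
    out["r2_0_prime"] = 1.0 - math.fsum((b - kp * a) ** 2 for a, b in zip(y, yhat)) / ss_pred
    out["ccc"] = (
        2.0 * math.fsum((a - ybar) * (b - yhbar) for a, b in zip(y, yhat))
        / (ss_obs + ss_pred + n * (ybar - yhbar) ** 2)
    )
    out["qf2"] = out["r2"]
    if train_mean is not None:
        out["qf1"] = 1.0 - press / math.fsum((a - train_mean) ** 2 for a in y)
    if train_ss is not None and n_train:
        out["qf3"] = 1.0 - (press / n) / (train_ss / n_train)
    out["rm2"] = out["r2"] * (1.0 - math.sqrt(abs(out["r2"] - out["r2_0"])))
    out["rm2_prime"] = out["r2"] * (1.0 - math.sqrt(abs(out["r2"] - out["r2_0_prime"])))
    out["rm2_bar"] = (out["rm2"] + out["rm2_prime"]) / 2.0
    return out


def pair_counting_auc(scores, labels):
    """AUC by exhaustive pair enumeration; ties count one half."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def exhaustive_cfs(bits, activity, merit_fn):
    """Maximum CFS merit over every non-empty subset of the non-constant
    columns; returns (merit, subset of original column indices)."""
    bits = np.asarray(bits, dtype=float)
    usable = [j for j in range(bits.shape[1]) if bits[:, j].std() > 0]
    y = np.asarray(activity, dtype=float)
    yc = y - y.mean()
    cols = bits[:, usable]
    xc = cols - cols.mean(axis=0)
    norms = np.sqrt((xc**2).sum(axis=0))
    cf = np.abs(xc.T @ yc) / (norms * math.sqrt(float(yc @ yc)))
    ff = np.abs((xc.T @ xc) / np.outer(norms, norms))
    np.fill_diagonal(ff, 1.0)
    best = (0.0, ())
    m = len(usable)
    for k in range(1, m + 1):
        for sub in itertools.combinations(range(m), k):
            val = merit_fn(cf, ff, sub)
            if val > best[0]:
                best = (val, tuple(usable[i] for i in sub))
    return best


def brute_force_fitted_rmsd(mobile, reference, n_starts=20, seed=0):
    """Minimal RMSD over rigid transforms via numerical optimisation of a
    rotation vector + translation (multi-start Nelder-Mead-free route using
    scipy's BFGS on the smooth objective)."""
    from scipy.optimize import minimize
    from scipy.spatial.transform import Rotation

    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)

    def objective(params):
        rot = Rotation.from_rotvec(params[:3])
        moved = rot.apply(mobile) + params[3:]
        return np.mean(np.sum((moved - reference) ** 2, axis=1))

    rng = np.random.default_rng(seed)
    best = np.inf
    for _ in range(n_starts):
        x0 = np.concatenate([rng.uniform(-np.pi, np.pi, 3), rng.normal(0, 1, 3)])
        res = minimize(objective, x0, method="BFGS")
        best = min(best, res.fun)
    return math.sqrt(max(best, 0.0))


def funnel_survivors(panel):
    """Set-difference oracle for the negative-design funnel: ``panel`` maps
    compound id -> annotation dict; a compound survives iff it is not PAINS,
    not an aggregator, and has pScore < 300."""
    excluded = set()
    for cid, ann in panel.items():
        if ann.get("pains"):
            excluded.add(cid)
        if ann.get("aggregator"):
            excluded.add(cid)
        if ann.get("pScore", 0) >= 300:
            excluded.add(cid)
    return set(panel) - excluded
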