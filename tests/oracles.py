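"""Independent oracles used by the test suite.

Each helper recomputes a quantity by a route independent of the library
implementation it checks: naive double loops, exhaustive enumeration,
generic constrained optimisation, or byte-level file construction.
"""

from __future__ import annotations

import itertools
import math
import struct
from pathlib import Path

import numpy as np
from scipy.optimize import LinearConstraint, minimize


def pearson_bruteforce(x: np.ndarray) -> np.ndarray:
    """Direct double-loop evaluation of the correlation-coefficient formula."""
    x = np.asarray(x, float)
    n = x.shape[0]
    out = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            xi = x[i] - x[i].mean()
            xj = x[j] - x[j].mean()
            out[i, j] = (xi * xj).sum() / math.sqrt((xi**2).sum() * (xj**2).sum())
    return out


def rank_sum_exact_p(a, b) -> float:
    """Two-sided exact rank-sum p by enumerating all group assignments."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    pooled = np.concatenate([a, b])
    ranks = pooled.argsort().argsort() + 1.0
    na = a.size
    w_obs = ranks[:na].sum()
    u_obs = w_obs - na * (na + 1) / 2.0
    us = []
    for comb in itertools.combinations(range(pooled.size), na):
        w = ranks[list(comb)].sum()
        us.append(w - na * (na + 1) / 2.0)
    us = np.asarray(us)
    p_low = np.mean(us <= u_obs)
    p_high = np.mean(us >= u_obs)
    return float(min(1.0, 2.0 * min(p_low, p_high)))


def nearest_corr_naive(a: np.ndarray, tol: float = 1e-10, max_iter: int = 5000) -> np.ndarray:
    """Brute-force projection: alternate PSD projection and diagonal
    restoration (no acceleration, no Dykstra correction) until the matrix is
    numerically a correlation matrix."""
    y = np.asarray(a, float).copy()
    for _ in range(max_iter):
        w, v = np.linalg.eigh(y)
        y = (v * np.clip(w, 0.0, None)) @ v.T
        y = (y + y.T) / 2.0
        np.fill_diagonal(y, 1.0)
        if np.linalg.eigvalsh(y).min() >= -tol:
            break
    return np.clip(y, -1.0, 1.0)


def svc_qp_oracle(x: np.ndarray, y, C: float) -> tuple[np.ndarray, float]:
    """Soft-margin linear SVC solved through the dual quadratic program.

    A generic constrained optimiser produces a near-solution whose active set
    is then polished by solving the KKT equations of the free variables
    exactly.  Returns (weights, offset).
    """
    x = np.asarray(x, float)
    ys = np.where(np.asarray(y, bool), 1.0, -1.0)
    n = len(x)
    Q = (ys[:, None] * ys[None, :]) * (x @ x.T)

    fun = lambda a: 0.5 * a @ Q @ a - a.sum()  # noqa: E731
    jac = lambda a: Q @ a - 1.0  # noqa: E731
    res = minimize(
        fun,
        np.full(n, min(C, 1.0) * 0.5),
        jac=jac,
        bounds=[(0.0, C)] * n,
        constraints=[LinearConstraint(ys, 0.0, 0.0)],
        method="SLSQP",
        options={"maxiter": 1000, "ftol": 1e-16},
    )
    a = np.clip(res.x, 0.0, C)

    # Polish: with the active set fixed, the free alphas solve a linear system.
    for _ in range(10):
        free = (a > 1e-7 * C) & (a < C * (1.0 - 1e-7))
        if not free.any():
            break
        nf = int(free.sum())
        A = np.zeros((nf + 1, nf + 1))
        A[:nf, :nf] = Q[np.ix_(free, free)]
        A[:nf, nf] = ys[free]
        A[nf, :nf] = ys[free]
        rhs = np.concatenate(
            [1.0 - Q[np.ix_(free, ~free)] @ a[~free], [-ys[~free] @ a[~free]]]
        )
        sol = np.linalg.lstsq(A, rhs, rcond=None)[0]
        newa = a.copy()
        newa[free] = sol[:nf]
        if np.all((newa >= -1e-9) & (newa <= C + 1e-9)):
            newa = np.clip(newa, 0.0, C)
            if np.abs(newa - a).max() < 1e-14:
                a = newa
                break
            a = newa
        else:
            break

    w = x.T @ (a * ys)
    f = x @ w
    free = (a > 1e-6 * C) & (a < C * (1.0 - 1e-6))
    if free.any():
        b = float(np.mean(ys[free] - f[free]))
    else:
        # all alphas at bounds: b lies in a KKT interval; take its midpoint
        lo, hi = -np.inf, np.inf
        for i in range(n):
            margin = ys[i] * f[i]
            if (a[i] < C / 2 and ys[i] > 0) or (a[i] > C / 2 and ys[i] < 0):
                lo = max(lo, (1.0 - margin) * ys[i])
            else:
                hi = min(hi, (1.0 - margin) * ys[i])
        b = float((lo + hi) / 2.0)
    return w, b


def write_edf(
    path: str | Path,
    data: np.ndarray,
    sampling_rates,
    labels,
    record_duration: float = 1.0,
    physical_range: float = 1000.0,
) -> Path:
    """Write a minimal synthetic EDF file (16-bit, one data record per
    ``record_duration`` seconds).  ``sampling_rates`` may differ per channel
    to fabricate mixed-rate files."""
    path = Path(path)
    data = [np.asarray(d, float) for d in data]
    ns = len(data)
    rates = list(sampling_rates)
    spr = [int(round(r * record_duration)) for r in rates]
    n_records = min(len(d) // s for d, s in zip(data, spr))

    def pad(s: str, width: int) -> bytes:
        return s.ljust(width)[:width].encode("ascii")

    header = b"".join(
        [
            pad("0", 8),
            pad("synthetic test subject", 80),
            pad("synthetic test recording", 80),
            pad("01.01.20", 8),
            pad("00.00.00", 8),
            pad(str(256 * (1 + ns)), 8),
            pad("", 44),
            pad(str(n_records), 8),
            pad(str(record_duration), 8),
            pad(str(ns), 4),
        ]
    )
    fields = [
        b"".join(pad(lab, 16) for lab in labels),
        b"".join(pad("synthetic", 80) for _ in range(ns)),
        b"".join(pad("uV", 8) for _ in range(ns)),
        b"".join(pad(str(-physical_range), 8) for _ in range(ns)),
        b"".join(pad(str(physical_range), 8) for _ in range(ns)),
        b"".join(pad("-32768", 8) for _ in range(ns)),
        b"".join(pad("32767", 8) for _ in range(ns)),
        b"".join(pad("", 80) for _ in range(ns)),
        b"".join(pad(str(s), 8) for s in spr),
        b"".join(pad("", 32) for _ in range(ns)),
    ]
    scale = 32767.0 / physical_range
    records = bytearray()
    for r in range(n_records):
        for d, s in zip(data, spr):
            chunk = np.clip(d[r * s : (r + 1) * s] * scale, -32768, 32767)
            records += struct.pack(f"<{s}h", *chunk.astype(np.int16))
    path.write_bytes(header + b"".join(fields) + bytes(records))
    return path
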