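"""Independent oracles used by the test suite.

These deliberately avoid the library code paths they check: transition
counts are tallied by direct iteration, sphere offsets by exhaustive lattice
enumeration, and the soft-margin SVM by solving the primal quadratic program
with a generic constrained optimizer.
"""

import itertools

import numpy as np
from scipy.optimize import minimize


def count_transitions_bruteforce(conditions):
    """Tally ordered condition pairs by direct iteration."""
    counts = {}
    for a, b in zip(conditions[:-1], conditions[1:]):
        counts[(a, b)] = counts.get((a, b), 0) + 1
    return counts


def lattice_ball_count(radius):
    """Exhaustively enumerate integer points with norm <= radius."""
    r = int(np.ceil(radius))
    n = 0
    for x, y, z in itertools.product(range(-r, r + 1), repeat=3):
        if x * x + y * y + z * z <= radius * radius:
            n += 1
    return n


def svm_primal_oracle(X, y, C=1.0):
    """Soft-margin linear SVM via the primal QP (SLSQP).

    minimize 0.5||w||^2 + C sum(xi)  s.t.  y_i (w.x_i + b) >= 1 - xi_i, xi >= 0

    Returns (w, b).  y must be +/-1.  Only suitable for tiny problems.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, d = X.shape

    def objective(p):
        w = p[:d]
        xi = p[d + 1 :]
        return 0.5 * w @ w + C * xi.sum()

    def margin(p):
        w, b, xi = p[:d], p[d], p[d + 1 :]
        return y * (X @ w + b) - 1 + xi

    cons = [
        {"type": "ineq", "fun": margin},
        {"type": "ineq", "fun": lambda p: p[d + 1 :]},
    ]
    best = None
    for trial in range(3):  # multistart for SLSQP robustness
        p0 = np.zeros(n + d + 1)
        if trial:
            rng = np.random.default_rng(trial)
            p0[: d + 1] = rng.normal(scale=0.1, size=d + 1)
        p0[d + 1 :] = 1.0
        res = minimize(objective, p0, constraints=cons, method="SLSQP",
                       options={"maxiter": 500, "ftol": 1e-12})
        if res.success and (best is None or res.fun < best.fun):
            best = res
    assert best is not None, "oracle QP failed to converge"
    return best.x[:d], best.x[d]


def svm_oracle_predict(X_train, y_train, X_test, C=1.0):
    """Labels (+/-1) predicted by the primal-QP SVM oracle."""
    w, b = svm_primal_oracle(X_train, y_train, C=C)
    dec = X_test @ w + b
    return np.where(dec > 0, 1, -1)
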