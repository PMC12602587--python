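"""Independent brute-force oracles used to check the exact-enumeration code.

Everything here is deliberately written with plain Python loops over
itertools-generated patterns, independent of the package's vectorised
log-space implementation.
"""

import itertools
import math

import numpy as np


def brute_potential(tau, omega, y):
    e = sum(tau[i] * y[i] for i in range(len(y)))
    for i in range(len(y)):
        for j in range(i + 1, len(y)):
            e += omega[i][j] * y[i] * y[j]
    return math.exp(e)


def brute_partition(tau, omega, k=0):
    m = len(tau)
    return sum(
        brute_potential(tau, omega, y)
        for y in itertools.product((0, 1), repeat=m)
        if sum(y) >= k
    )


def brute_conditional(tau, omega, y, k=0):
    if sum(y) < k:
        return 0.0
    return brute_potential(tau, omega, y) / brute_partition(tau, omega, k)


def brute_neg_log_likelihood(tau, omega, rows, k=0):
    Zk = brute_partition(tau, omega, k)
    return -sum(
        math.log(brute_potential(tau, omega, row) / Zk) for row in rows
    )


def random_model_params(rng, m, scale=1.0):
    """Random symmetric zero-diagonal parameters for property tests."""
    tau = rng.normal(0.0, scale, m)
    omega = np.triu(rng.normal(0.0, scale, (m, m)), 1)
    return tau, omega + omega.T
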