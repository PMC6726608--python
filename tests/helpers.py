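"""Independent oracles used by the test suite.

Everything here is deliberately written from the definitions rather than
by calling the library's own code paths: a naive penalized log-likelihood
with a zoom-in grid maximizer, a transcription of the consensus rules, and
an exact enumeration of the submitter-call multinomial.
"""

from __future__ import annotations

import math
from itertools import product

import numpy as np


def penalized_loglik_naive(x, y, b0: float, b1: float) -> float:
    """Jeffreys-penalized logistic log-likelihood, written out longhand."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    eta = b0 + b1 * x
    p = np.clip(1.0 / (1.0 + np.exp(-eta)), 1e-12, 1.0 - 1e-12)
    ll = float(np.sum(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))
    w = p * (1.0 - p)
    # information of the design [1, x]: 2x2 determinant by hand
    a = w.sum()
    b = (w * x).sum()
    c = (w * x * x).sum()
    det = a * c - b * b
    if det <= 0:
        return -math.inf
    return ll + 0.5 * math.log(det)


def grid_maximize_penalized(x, y, half: float = 10.0, stages: int = 5, pts: int = 41):
    """Coarse-to-fine grid argmax of the penalized likelihood over (b0, b1).

    Starts on [-half, half]^2 and zooms; final resolution ~1e-4 with the
    defaults, enough to check solver output to 3 decimals.
    """
    c0 = c1 = 0.0
    best = (-math.inf, 0.0, 0.0)
    for _ in range(stages):
        g0 = np.linspace(c0 - half, c0 + half, pts)
        g1 = np.linspace(c1 - half, c1 + half, pts)
        best = (-math.inf, c0, c1)
        for b0 in g0:
            for b1 in g1:
                ll = penalized_loglik_naive(x, y, b0, b1)
                if ll > best[0]:
                    best = (ll, b0, b1)
        _, c0, c1 = best
        spacing = 2.0 * half / (pts - 1)
        half = 2.0 * spacing
    return best[1], best[2], best[0]


def consensus_rule_oracle(n_blb: int, n_plp: int, n_vus: int) -> str:
    """Direct transcription of the inclusion/exclusion formulas."""
    if n_plp >= 1 and n_blb >= 1:
        return "EXCLUDED_CONFLICT"
    if n_vus > max(n_blb, n_plp):
        return "EXCLUDED_VUS"
    if n_plp >= max(n_vus, 1) and n_blb == 0:
        return "PLP"
    if n_blb >= max(n_vus, 1) and n_plp == 0:
        return "BLB"
    return "EXCLUDED_EMPTY"


def exact_consensus_recovery_rate(n_submitters: int, noise: float) -> float:
    """P(consensus == truth) under the submitter-call model, by enumeration.

    Each call is truth-consistent w.p. 1 - noise, VUS w.p. noise/2 and
    opposing w.p. noise/2; the consensus recovers the truth when the
    consistent side wins under the rules (no opposing call and consistent
    count >= max(VUS count, 1)).  Enumerates the (consistent, vus,
    opposing) multinomial exactly.
    """
    p = (1.0 - noise, noise / 2.0, noise / 2.0)
    total = 0.0
    for counts in product(range(n_submitters + 1), repeat=3):
        if sum(counts) != n_submitters:
            continue
        k_cons, k_vus, k_opp = counts
        prob = (
            math.factorial(n_submitters)
            / (math.factorial(k_cons) * math.factorial(k_vus) * math.factorial(k_opp))
            * p[0] ** k_cons
            * p[1] ** k_vus
            * p[2] ** k_opp
        )
        verdict = consensus_rule_oracle(
            n_blb=k_opp, n_plp=k_cons, n_vus=k_vus
        )  # orient truth as PLP; symmetric for BLB truth
        if verdict == "PLP":
            total += prob
    return total
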