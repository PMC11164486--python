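"""Shared fixtures and independent oracle implementations.

The oracles here are deliberately written as literal, per-position /
per-pair enumerations so they stay independent of the vectorized library
code they check.
"""

import numpy as np
import pandas as pd
import pytest

from mpps import SurvivalData


def ssgsea_oracle(expr_col: pd.Series, set_genes, alpha: float) -> float:
    """Literal per-position running-sum ssGSEA score for one sample.

    Genes are ranked by expression, largest value = largest rank, ties
    broken by gene ID (lexicographically smaller ID ranks higher). Walking
    in descending rank order, accumulate the rank^alpha-weighted in-set
    fraction minus the uniform out-of-set fraction.
    """
    items = sorted(expr_col.items(), key=lambda kv: (-kv[1], kv[0]))
    n = len(items)
    in_set = [g in set(set_genes) for g, _ in items]
    m = sum(in_set)
    assert 0 < m < n
    ranks = [n - k for k in range(n)]  # rank at walk position k
    denom_in = sum(r**alpha for r, flag in zip(ranks, in_set) if flag)
    score = 0.0
    cum_in = 0.0
    cum_out = 0
    for k in range(n):
        if in_set[k]:
            cum_in += ranks[k] ** alpha
        else:
            cum_out += 1
        score += cum_in / denom_in - cum_out / (n - m)
    return score


def cindex_oracle(scores, time, event) -> float:
    """Brute-force Harrell's C: enumerate all permissible pairs.

    A pair is permissible when the shorter observed time is an event;
    higher score on the shorter-lived subject is concordant, score ties
    count one half.
    """
    scores = np.asarray(scores, float)
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    num = den = 0.0
    n = len(time)
    for i in range(n):
        for j in range(n):
            if time[i] < time[j] and event[i] == 1:
                den += 1
                if scores[i] > scores[j]:
                    num += 1
                elif scores[i] == scores[j]:
                    num += 0.5
            elif time[i] == time[j] and i < j and event[i] != event[j]:
                # equal times, one event: event subject must have higher score
                den += 1
                ev, other = (i, j) if event[i] == 1 else (j, i)
                if scores[ev] > scores[other]:
                    num += 1
                elif scores[ev] == scores[other]:
                    num += 0.5
    assert den > 0
    return num / den


def mann_whitney_auc(pos, neg) -> float:
    """Empirical AUC by pairwise enumeration (ties count one half)."""
    pos = np.asarray(pos, float)
    neg = np.asarray(neg, float)
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(pos) * len(neg))


def random_survival(rng, n, log_hr=0.0, x=None, censor_frac=0.2, rate=0.5):
    """Tiny exponential proportional-hazards world for unit tests."""
    if x is None:
        x = (rng.random(n) < 0.5).astype(float)
    T = rng.exponential(1.0, n) / (rate * np.exp(log_hr * x))
    if censor_frac > 0:
        C = rng.exponential(1.0, n) / (rate * censor_frac / (1 - censor_frac))
    else:
        C = np.full(n, np.inf)
    time = np.minimum(T, C)
    event = (T <= C).astype(int)
    ids = [f"s{i}" for i in range(n)]
    return SurvivalData.from_arrays(ids, np.maximum(time, 1e-9), event), pd.Series(x, index=ids)


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def small_cohort():
    """One small synthetic cohort shared across tests (session-scoped for speed)."""
    from mpps import SimulationConfig, simulate_cohort

    cfg = SimulationConfig(seed=7, n_samples=200)
    return cfg, simulate_cohort(cfg, cohort_seed=1)
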