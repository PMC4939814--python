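"""Shared fixtures and independent oracle implementations.

The oracles deliberately re-derive each quantity from its definition with
plain Python loops (O(N) or O(N^2)), independent of the vectorized code
paths they check.
"""

import numpy as np
import pandas as pd
import pytest

from finprot.survey import SurveyDataset, build_dataset


def make_dataset(total, food, oop, size=None, weight=None, **optional) -> SurveyDataset:
    """Build a strict-validated dataset from plain sequences."""
    total = np.asarray(total, dtype=float)
    n = total.size
    frame = pd.DataFrame(
        {
            "total_expenditure": total,
            "food_expenditure": np.asarray(food, dtype=float),
            "oop_health": np.asarray(oop, dtype=float),
            "size": np.ones(n, dtype=int) if size is None else np.asarray(size),
            "weight": np.ones(n) if weight is None else np.asarray(weight, dtype=float),
        }
    )
    for name, values in optional.items():
        frame[name] = values
    return build_dataset(frame, "strict", source_label="fixture")


def random_dataset(rng: np.random.Generator, n: int, zero_oop_prob=0.3) -> SurveyDataset:
    """A random valid survey: log-normal expenditure, food and OOP within budget."""
    size = 1 + rng.poisson(2.0, n)
    total = rng.lognormal(12.0, 0.6, n) * size
    food = rng.uniform(0.1, 0.7, n) * total
    oop = rng.uniform(0.0, 1.0, n) * (total - food)
    oop[rng.random(n) < zero_oop_prob] = 0.0
    return make_dataset(total, food, oop, size=size)


def oracle_fractional_rank(values, weights):
    """Loop re-derivation of the weighted fractional rank (stable tie order)."""
    n = len(values)
    order = sorted(range(n), key=lambda i: (values[i], i))
    total = float(sum(weights))
    r = [0.0] * n
    cum = 0.0
    for i in order:
        r[i] = (cum + weights[i] / 2.0) / total
        cum += weights[i]
    return np.asarray(r)


def oracle_concentration_index(outcome, rank_variable, weights=None):
    """O(N^2) definitional double-sum concentration index.

    C = sum_ij w_i w_j (y_i - y_j)(r_i - r_j) / (2 W^2 mu), with r the
    weighted fractional rank — the pairwise form of 2 cov_w(y, r) / mu.
    """
    y = list(map(float, outcome))
    n = len(y)
    w = [1.0] * n if weights is None else list(map(float, weights))
    r = oracle_fractional_rank(list(map(float, rank_variable)), w)
    total = sum(w)
    mu = sum(wi * yi for wi, yi in zip(w, y)) / total
    acc = 0.0
    for i in range(n):
        for j in range(n):
            acc += w[i] * w[j] * (y[i] - y[j]) * (r[i] - r[j])
    return acc / (2.0 * total * total) * 2.0 / mu


def expand_to_persons(dataset: SurveyDataset):
    """Replicate each household into `size` identical individuals (weight 1)."""
    y_gross, y_net = [], []
    for rec in dataset.records:
        for _ in range(rec.size):
            y_gross.append(rec.total_expenditure / rec.size)
            y_net.append((rec.total_expenditure - rec.oop_health) / rec.size)
    return np.asarray(y_gross), np.asarray(y_net)


@pytest.fixture
def rng():
    return np.random.default_rng(20160711)


@pytest.fixture
def toy_dataset():
    """Five households with hand-checkable OOP shares 0.02/0.08/0.12/0.30/0.05."""
    total = [100.0, 200.0, 300.0, 400.0, 500.0]
    oop = [2.0, 16.0, 36.0, 120.0, 25.0]
    food = [40.0, 80.0, 120.0, 160.0, 200.0]
    return make_dataset(total, food, oop)
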