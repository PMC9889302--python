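import math

import numpy as np
import pytest

from growthshape.simulate import generate_lms_reference

#: canonical follow-up ages in months (birth .. 11 y)
VISIT_AGES_MONTHS = np.array([0.0, 3.0, 11.9, 23.9, 49.5, 81.6, 132.0])


@pytest.fixture(scope="session")
def lms_ref():
    return generate_lms_reference()


@pytest.fixture(scope="session")
def band_maker():
    """Factory for 'band' trajectories: constant z offsets plus iid noise,
    with lightly jittered visit ages — the simplest latent-class structure."""

    def make(n_per, offsets, noise_sd, seed, age_jitter=0.1):
        rng = np.random.default_rng(seed)
        trajs, labels = [], []
        for ci, off in enumerate(offsets):
            for _ in range(n_per):
                t = VISIT_AGES_MONTHS + rng.normal(0, age_jitter, VISIT_AGES_MONTHS.size)
                t[0] = 0.0
                t.sort()
                z = off + rng.normal(0, noise_sd, VISIT_AGES_MONTHS.size)
                trajs.append((t, z))
                labels.append(ci)
        return trajs, np.array(labels)

    return make


def frechet_bruteforce(a, b, time_scale=0.1, aggregation="max"):
    """Exhaustive minimax/min-sum over every monotone coupling of two vertex
    sequences. Exponential — only for tiny inputs; independent of the DP."""
    ta, za = [list(map(float, v)) for v in a]
    tb, zb = [list(map(float, v)) for v in b]
    n, m = len(ta), len(tb)

    def cost(i, j):
        return math.hypot(time_scale * (ta[i] - tb[j]), za[i] - zb[j])

    best = math.inf

    def rec(i, j, acc_max, acc_sum):
        nonlocal best
        c = cost(i, j)
        acc_max = max(acc_max, c)
        acc_sum += c
        if i == n - 1 and j == m - 1:
            val = acc_max if aggregation == "max" else acc_sum
            best = min(best, val)
            return
        for di, dj in ((1, 0), (0, 1), (1, 1)):
            ni, nj = i + di, j + dj
            if ni < n and nj < m:
                rec(ni, nj, acc_max, acc_sum)

    rec(0, 0, 0.0, 0.0)
    return best


@pytest.fixture(scope="session")
def frechet_oracle():
    return frechet_bruteforce
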