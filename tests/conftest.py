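import numpy as np
import pytest

from groupknock import CorrelationModel, regularize
from groupknock.covmodels import cov_to_corr
from groupknock.grouping import GroupPartition, KeySelection, partition_from_labels


def random_correlation(rng: np.random.Generator, p: int, strength: float = 0.5) -> np.ndarray:
    """A generic well-conditioned random correlation matrix."""
    A = rng.standard_normal((p, 2 * p))
    return cov_to_corr(A @ A.T / (2 * p) + strength * np.eye(p))


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def make_ci_model(rng, group_sizes, n_keys):
    """Build a correlation model that satisfies group-key conditional
    independence exactly: non-key members are linear functions of their own
    group's keys plus independent noise.

    Returns (model, partition, keys) with keys the exact generating key sets.
    """
    sizes = list(group_sizes)
    p = sum(sizes)
    starts = np.cumsum([0] + sizes[:-1])
    key_idx, star, dagger, labels = [], [], [], []
    for g, (s0, sz, nk) in enumerate(zip(starts, sizes, n_keys)):
        members = np.arange(s0, s0 + sz)
        star.append(members[:nk])
        dagger.append(members[nk:])
        key_idx.extend(members[:nk])
        labels.extend([g] * sz)
    key_idx = np.array(key_idx)
    K = key_idx.size

    sigma_star = random_correlation(rng, K, strength=1.0)
    sigma = np.zeros((p, p))
    # map each variable to its expression in terms of the keys, plus noise
    pos = {j: t for t, j in enumerate(key_idx)}
    M = np.zeros((p, K))
    noise = np.zeros((p, p))
    for s, d in zip(star, dagger):
        for j in s:
            M[j, pos[j]] = 1.0
        if d.size:
            B = rng.uniform(-0.6, 0.6, size=(d.size, s.size))
            M[d, :] = 0.0
            for r, j in enumerate(d):
                for c, key in enumerate(s):
                    M[j, pos[key]] = B[r, c]
            A = rng.standard_normal((d.size, 2 * d.size))
            R = A @ A.T / (2 * d.size) + 0.4 * np.eye(d.size)
            noise[np.ix_(d, d)] = R
    sigma = M @ sigma_star @ M.T + noise
    # PD by construction (keys carry sigma_star, non-keys their own noise);
    # no identity shift is applied, which would break the exact CI structure
    model = CorrelationModel(sigma=cov_to_corr(sigma))
    partition = partition_from_labels(labels)
    keys = KeySelection(partition=partition, star=star, dagger=dagger, c=0.5)
    return model, partition, keys
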