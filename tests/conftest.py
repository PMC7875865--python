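import itertools

import numpy as np
import pytest

from gazehmm import (
    AOIRegion,
    AOISet,
    FixationRecord,
    FixationSequence,
    GaussianHMM,
)


def square(cx, cy, half):
    return np.array(
        [[cx - half, cy - half], [cx + half, cy - half],
         [cx + half, cy + half], [cx - half, cy + half]]
    )


def make_sequence(xy, subject="s1", group="expert", image="img1", durations=None):
    """Wrap a (T, 2) array into a FixationSequence with synthetic timing."""
    xy = np.asarray(xy, dtype=float)
    if durations is None:
        durations = np.full(len(xy), 250.0)
    onsets = np.concatenate([[0.0], np.cumsum(durations)[:-1]])
    records = [
        FixationRecord(
            subject_id=subject, group=group, image_id=image, fixation_index=t,
            onset_ms=float(onsets[t]), duration_ms=float(durations[t]),
            x=float(xy[t, 0]), y=float(xy[t, 1]),
        )
        for t in range(len(xy))
    ]
    return FixationSequence(subject_id=subject, group=group, image_id=image, records=records)


def random_model(rng, n_states, scale=500.0):
    pi = rng.dirichlet(np.ones(n_states))
    A = rng.dirichlet(np.ones(n_states), size=n_states)
    means = rng.uniform(0, scale, (n_states, 2))
    covars = rng.uniform(1.0, (scale / 10) ** 2, (n_states, 2))
    return GaussianHMM(pi=pi, A=A, means=means, covars=covars)


# ---------------------------------------------------------------------------
# independent brute-force oracles (path enumeration)
# ---------------------------------------------------------------------------

def enumerate_paths_loglik(model, xy):
    """log sum over all state paths of path-probability x emission-probability."""
    T = len(xy)
    logB = model.emission_logprob(xy)
    total = -np.inf
    for path in itertools.product(range(model.n_states), repeat=T):
        lp = np.log(model.pi[path[0]]) + logB[0, path[0]]
        for t in range(1, T):
            lp += np.log(model.A[path[t - 1], path[t]]) + logB[t, path[t]]
        total = np.logaddexp(total, lp)
    return total


def enumerate_paths_argmax(model, xy):
    """Best path by exhaustive search; ties resolved toward the lexicographically
    smaller path, matching the lower-state-index rule."""
    T = len(xy)
    logB = model.emission_logprob(xy)
    best_lp, best_path = -np.inf, None
    for path in itertools.product(range(model.n_states), repeat=T):
        lp = np.log(model.pi[path[0]]) + logB[0, path[0]]
        for t in range(1, T):
            lp += np.log(model.A[path[t - 1], path[t]]) + logB[t, path[t]]
        if lp > best_lp + 1e-12:
            best_lp, best_path = lp, path
    return np.array(best_path), best_lp


def enumerate_posteriors(model, xy):
    """Smoothed state posteriors by exhaustive path enumeration."""
    T = len(xy)
    N = model.n_states
    logB = model.emission_logprob(xy)
    post = np.zeros((T, N))
    total = -np.inf
    weights = []
    paths = list(itertools.product(range(N), repeat=T))
    for path in paths:
        lp = np.log(model.pi[path[0]]) + logB[0, path[0]]
        for t in range(1, T):
            lp += np.log(model.A[path[t - 1], path[t]]) + logB[t, path[t]]
        weights.append(lp)
        total = np.logaddexp(total, lp)
    for path, lp in zip(paths, weights):
        w = np.exp(lp - total)
        for t, s in enumerate(path):
            post[t, s] += w
    return post


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_aoiset():
    """Six 100x100 AOIs on a 1000x600 canvas: primes stacked right, targets left."""
    regions = [
        AOIRegion("P1", square(900, 100, 50)),
        AOIRegion("P2", square(900, 300, 50)),
        AOIRegion("P3", square(900, 500, 50)),
        AOIRegion("T1", square(200, 100, 50)),
        AOIRegion("T2", square(200, 300, 50)),
        AOIRegion("T3", square(500, 450, 50)),
    ]
    return AOISet(image_id="toy", canvas_width=1000, canvas_height=600, regions=regions)


@pytest.fixture
def separated_3state():
    """A 3-state model whose means are >= 8 SD apart (SD 10 px), self-transition 0.9."""
    A = np.full((3, 3), 0.05)
    np.fill_diagonal(A, 0.9)
    return GaussianHMM(
        pi=np.ones(3) / 3,
        A=A,
        means=np.array([[100.0, 100.0], [400.0, 100.0], [250.0, 400.0]]),
        covars=np.full((3, 2), 100.0),
    )


def simulate_from(model, n_sequences, length, seed):
    from gazehmm import simulate_subject

    rng = np.random.default_rng(seed)
    return [
        simulate_subject(
            model, length, canvas=(1e9, 1e9), seed=int(rng.integers(2**31 - 1)),
            subject_id=f"s{i}",
        )
        for i in range(n_sequences)
    ]
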