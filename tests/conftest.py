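import numpy as np
import pytest

from nucstates.hmm_core import HmmModel


def sample_sequences(model: HmmModel, n_seq: int, T: int, rng: np.random.Generator):
    """Test-local Markov sampler, independent of the package's generators."""
    S, V = model.n_states, model.n_symbols
    seqs = []
    for _ in range(n_seq):
        states = np.empty(T, dtype=np.int64)
        states[0] = rng.choice(S, p=model.pi)
        for t in range(1, T):
            states[t] = rng.choice(S, p=model.A[states[t - 1]])
        obs = np.array([rng.choice(V, p=model.B[s]) for s in states], dtype=np.int64)
        seqs.append(obs)
    return seqs


def anchored_model(S: int, V: int, seed: int, self_loop: float = 0.85, anchor_mass: float = 0.7) -> HmmModel:
    """Well-separated ground-truth model: each state anchors on its own symbol."""
    rng = np.random.default_rng(seed)
    if S == 1:
        A = np.ones((1, 1))
    else:
        off = (1 - self_loop) / (S - 1)
        A = np.full((S, S), off)
        np.fill_diagonal(A, self_loop)
    anchors = rng.permutation(V)[:S]
    B = rng.dirichlet(np.ones(V), size=S) * (1 - anchor_mass)
    for s in range(S):
        B[s, anchors[s]] += anchor_mass
    return HmmModel(np.full(S, 1.0 / S), A, B)


def random_stochastic_model(S: int, V: int, rng: np.random.Generator) -> HmmModel:
    return HmmModel(
        rng.dirichlet(np.ones(S)),
        rng.dirichlet(np.ones(S), size=S),
        rng.dirichlet(np.ones(V), size=S),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
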