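"""Discrete first-order HMM training with BIC selection and state pruning.

Implements the two-round training scheme: (1) Baum-Welch over a grid of
state counts with several random restarts each, selecting the model with
the lowest BIC; (2) removal of states holding fewer than a cutoff fraction
of Viterbi-assigned nucleosomes, with the aborted states' outgoing
transition mass evenly redistributed over the survivors, followed by a
shorter retraining round.  Decoding is Viterbi in log space; per-mark
probabilities are obtained by marginalizing emission rows over all symbols
carrying the mark's bit.

The forward-backward recursions are batched over equal-length sequences
(sequences are bucketed by length), which keeps training on tens of
thousands of nucleosomes interactive in pure numpy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .obs_encoding import ObservationSequence

_ROW_TOL = 1e-9
_EMISSION_FLOOR = 1e-10


@dataclass
class HmmModel:
    """A discrete HMM: initial (pi), transition (A) and emission (B) rows."""

    pi: np.ndarray  # (S,)
    A: np.ndarray  # (S, S)
    B: np.ndarray  # (S, V)

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        self.A = np.asarray(self.A, dtype=float)
        self.B = np.asarray(self.B, dtype=float)
        S = self.pi.shape[0]
        if self.A.shape != (S, S):
            raise ValueError(f"A must be ({S},{S}), got {self.A.shape}")
        if self.B.shape[0] != S:
            raise ValueError(f"B must have {S} rows, got {self.B.shape}")
        self.validate()

    @property
    def n_states(self) -> int:
        return self.pi.shape[0]

    @property
    def n_symbols(self) -> int:
        return self.B.shape[1]

    def validate(self) -> None:
        if (self.pi < 0).any() or (self.A < 0).any() or (self.B < 0).any():
            raise ValueError("probabilities must be nonnegative")
        if abs(self.pi.sum() - 1.0) > _ROW_TOL:
            raise ValueError(f"pi sums to {self.pi.sum()}, not 1")
        for name, M in (("A", self.A), ("B", self.B)):
            bad = np.abs(M.sum(axis=1) - 1.0) > _ROW_TOL
            if bad.any():
                raise ValueError(f"rows {np.flatnonzero(bad)} of {name} do not sum to 1")

    def copy(self) -> "HmmModel":
        return HmmModel(self.pi.copy(), self.A.copy(), self.B.copy())


@dataclass
class TrainingResult:
    model: HmmModel
    log_likelihood_trace: list[float]
    bic: float
    state_occupancy: np.ndarray
    n_obs: int = 0
    seed: int | None = None


@dataclass
class MarkStateMatrix:
    """Per-state marginal probability of each individual mark."""

    probs: np.ndarray  # (S, n_marks)
    mark_order: tuple[str, ...] | None = None


def _as_symbol_arrays(sequences: Iterable) -> list[np.ndarray]:
    arrays = []
    for seq in sequences:
        symbols = seq.symbols if isinstance(seq, ObservationSequence) else seq
        arr = np.asarray(symbols, dtype=np.int64)
        if arr.size:
            arrays.append(arr)
    if not arrays:
        raise ValueError("no non-empty observation sequences provided")
    return arrays


def _bucket_by_length(arrays: list[np.ndarray]) -> list[np.ndarray]:
    """Stack equal-length sequences into (n_seq, T) batches."""
    buckets: dict[int, list[np.ndarray]] = {}
    for arr in arrays:
        buckets.setdefault(arr.size, []).append(arr)
    return [np.stack(group) for _, group in sorted(buckets.items())]


def random_model(n_states: int, n_symbols: int, rng: np.random.Generator) -> HmmModel:
    """Dirichlet(1)-random row-stochastic initialization."""
    pi = rng.dirichlet(np.ones(n_states))
    A = rng.dirichlet(np.ones(n_states), size=n_states)
    B = rng.dirichlet(np.ones(n_symbols), size=n_states)
    return HmmModel(pi, A, B)


def empirical_model(
    sequences: Iterable,
    n_states: int,
    n_symbols: int,
    rng: np.random.Generator,
    noise_scale: float = 0.5,
    self_loop: float = 0.6,
) -> HmmModel:
    """Data-driven initialization: emission rows are the empirical symbol
    frequencies perturbed per-state by log-normal noise; transitions are
    sticky.  Far less prone to poor EM local optima than fully random rows
    on sparse alphabets (most of the 2**n symbols are rare).
    """
    allobs = np.concatenate(_as_symbol_arrays(sequences))
    freq = np.bincount(allobs, minlength=n_symbols).astype(float)
    freq = np.maximum(freq / allobs.size, 1e-6)
    B = freq[None, :] * np.exp(rng.normal(0.0, noise_scale, size=(n_states, n_symbols)))
    B = np.maximum(B, _EMISSION_FLOOR)
    B /= B.sum(axis=1, keepdims=True)
    if n_states == 1:
        A = np.ones((1, 1))
    else:
        A = np.full((n_states, n_states), (1.0 - self_loop) / (n_states - 1))
        np.fill_diagonal(A, self_loop)
    pi = np.full(n_states, 1.0 / n_states)
    return HmmModel(pi, A, B)


def _forward_batch(
    obs: np.ndarray, pi: np.ndarray, A: np.ndarray, B: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Scaled forward pass over an (n, T) batch.

    Returns (alpha_hat (n,T,S), scale c (n,T), lik (n,T,S)).
    """
    n, T = obs.shape
    S = pi.shape[0]
    lik = B.T[obs]  # (n, T, S)
    alpha = np.empty((n, T, S))
    c = np.empty((n, T))
    a = pi[None, :] * lik[:, 0]
    c[:, 0] = a.sum(axis=1)
    if (c[:, 0] <= 0).any():
        raise FloatingPointError("zero-probability prefix in forward pass")
    alpha[:, 0] = a / c[:, 0, None]
    for t in range(1, T):
        a = (alpha[:, t - 1] @ A) * lik[:, t]
        c[:, t] = a.sum(axis=1)
        if (c[:, t] <= 0).any():
            raise FloatingPointError("zero-probability prefix in forward pass")
        alpha[:, t] = a / c[:, t, None]
    return alpha, c, lik


def log_likelihood(sequences: Iterable, model: HmmModel) -> float:
    """Total log-likelihood of the sequences under the model."""
    total = 0.0
    for obs in _bucket_by_length(_as_symbol_arrays(sequences)):
        _, c, _ = _forward_batch(obs, model.pi, model.A, model.B)
        total += float(np.log(c).sum())
    return total


def baum_welch(
    sequences: Iterable,
    model0: HmmModel,
    max_iter: int = 300,
    tol: float = 1e-4,
    emission_floor: float = _EMISSION_FLOOR,
) -> TrainingResult:
    """EM re-estimation of pi, A, B from independent observation sequences.

    Stops after ``max_iter`` iterations or when the log-likelihood improves
    by less than ``tol``.  Emission rows are floored at ``emission_floor``
    after each M-step (then renormalized) so unseen symbols on a large
    alphabet cannot lock states out.  The trace is non-decreasing up to
    floating-point slack.
    """
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    arrays = _as_symbol_arrays(sequences)
    V = model0.n_symbols
    maxsym = max(int(arr.max()) for arr in arrays)
    if maxsym >= V:
        raise ValueError(f"symbol {maxsym} >= alphabet size {V}")
    batches = _bucket_by_length(arrays)
    n_obs = sum(arr.size for arr in arrays)

    pi, A, B = model0.pi.copy(), model0.A.copy(), model0.B.copy()
    S = pi.shape[0]
    trace: list[float] = []
    prev = -np.inf
    for _ in range(max_iter):
        logL = 0.0
        pi_acc = np.zeros(S)
        A_acc = np.zeros((S, S))
        B_acc = np.zeros((S, V))
        n_seq = 0
        for obs in batches:
            n, T = obs.shape
            alpha, c, lik = _forward_batch(obs, pi, A, B)
            logL += float(np.log(c).sum())
            beta = np.empty_like(alpha)
            beta[:, T - 1] = 1.0
            for t in range(T - 2, -1, -1):
                beta[:, t] = ((lik[:, t + 1] * beta[:, t + 1]) / c[:, t + 1, None]) @ A.T
            gamma = alpha * beta
            gamma /= gamma.sum(axis=2, keepdims=True)
            pi_acc += gamma[:, 0].sum(axis=0)
            n_seq += n
            for t in range(T - 1):
                A_acc += np.einsum(
                    "ni,nj->ij",
                    alpha[:, t],
                    (lik[:, t + 1] * beta[:, t + 1]) / c[:, t + 1, None],
                ) * A
            BT_acc = B_acc.T  # (V, S) view
            for t in range(T):
                np.add.at(BT_acc, obs[:, t], gamma[:, t])
        trace.append(logL)
        if logL - prev < tol and np.isfinite(prev):
            break
        prev = logL
        pi = pi_acc / n_seq
        A_rows = A_acc.sum(axis=1, keepdims=True)
        A = np.where(A_rows > 0, A_acc / np.maximum(A_rows, 1e-300), 1.0 / S)
        B_rows = B_acc.sum(axis=1, keepdims=True)
        B = np.where(B_rows > 0, B_acc / np.maximum(B_rows, 1e-300), 1.0 / V)
        B = np.maximum(B, emission_floor)
        B /= B.sum(axis=1, keepdims=True)
        pi = np.maximum(pi, 0)
        pi /= pi.sum()
        A = np.maximum(A, 0)
        A /= A.sum(axis=1, keepdims=True)

    model = HmmModel(pi, A, B)
    final_logL = log_likelihood(arrays, model)
    trace.append(final_logL)
    occ = state_occupancy(arrays, model)
    return TrainingResult(
        model=model,
        log_likelihood_trace=trace,
        bic=bic(model, final_logL, n_obs),
        state_occupancy=occ,
        n_obs=n_obs,
    )


def bic(model: HmmModel, logL: float, n_obs: int) -> float:
    """``k * ln(n_obs) - 2 * logL`` with k = (S-1) + S(S-1) + S(V-1)."""
    if n_obs < 1:
        raise ValueError("n_obs must be >= 1")
    S, V = model.n_states, model.n_symbols
    k = (S - 1) + S * (S - 1) + S * (V - 1)
    return k * np.log(n_obs) - 2.0 * logL


def select_best(
    sequences: Sequence,
    n_symbols: int,
    state_range: Iterable[int] = range(15, 26),
    replicates: int = 5,
    max_iter: int = 300,
    tol: float = 1e-4,
    seed: int = 0,
) -> TrainingResult:
    """Train ``replicates`` seeded restarts per state count and return the
    minimum-BIC model (ties: fewer states, then lower replicate index).

    Restarts use :func:`empirical_model` initialization with per-replicate
    perturbation seeds.
    """
    state_range = list(state_range)
    if not state_range:
        raise ValueError("state_range must be nonempty")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    arrays = _as_symbol_arrays(sequences)
    best: TrainingResult | None = None
    best_key: tuple | None = None
    for n_states in state_range:
        for rep in range(replicates):
            rng = np.random.default_rng(np.random.SeedSequence([seed, n_states, rep]))
            result = baum_welch(arrays, empirical_model(arrays, n_states, n_symbols, rng), max_iter, tol)
            result.seed = rep
            key = (result.bic, n_states, rep)
            if best_key is None or key < best_key:
                best, best_key = result, key
    assert best is not None
    return best


def prune_states(
    model: HmmModel, occupancy: np.ndarray, cutoff: float = 0.005
) -> HmmModel:
    """Drop states whose occupancy is below ``cutoff``.

    For every surviving row of A (and for pi) the probability mass that
    pointed at removed states is redistributed evenly over the survivors,
    so all rows re-sum to 1.
    """
    occupancy = np.asarray(occupancy, dtype=float)
    if occupancy.shape[0] != model.n_states:
        raise ValueError("occupancy length must match n_states")
    keep = occupancy >= cutoff
    n_keep = int(keep.sum())
    if n_keep == 0:
        raise ValueError("all states fall below the occupancy cutoff")
    if n_keep == model.n_states:
        return model.copy()
    pi = model.pi[keep]
    pi = pi + (1.0 - pi.sum()) / n_keep
    A = model.A[np.ix_(keep, keep)]
    A = A + (1.0 - A.sum(axis=1, keepdims=True)) / n_keep
    B = model.B[keep]
    return HmmModel(pi, A, B)


def retrain(
    sequences: Iterable,
    pruned: HmmModel,
    max_iter: int = 200,
    tol: float = 1e-4,
) -> TrainingResult:
    """Second training round seeded from the pruned model."""
    return baum_welch(sequences, pruned, max_iter=max_iter, tol=tol)


def viterbi(sequence, model: HmmModel) -> np.ndarray:
    """Maximum-probability state path (log-space; ties -> lower state index)."""
    symbols = sequence.symbols if isinstance(sequence, ObservationSequence) else sequence
    obs = np.asarray(symbols, dtype=np.int64)
    if obs.size == 0:
        return np.array([], dtype=np.int64)
    if obs.max() >= model.n_symbols:
        raise ValueError("symbol out of alphabet range")
    with np.errstate(divide="ignore"):
        log_pi = np.log(model.pi)
        log_A = np.log(model.A)
        log_B = np.log(model.B)
    T = obs.size
    S = model.n_states
    delta = log_pi + log_B[:, obs[0]]
    psi = np.zeros((T, S), dtype=np.int64)
    for t in range(1, T):
        scores = delta[:, None] + log_A  # (from, to)
        psi[t] = np.argmax(scores, axis=0)  # first max -> lowest index
        delta = scores[psi[t], np.arange(S)] + log_B[:, obs[t]]
    if not np.isfinite(delta.max()):
        raise ValueError("sequence has zero probability under the model")
    path = np.empty(T, dtype=np.int64)
    path[T - 1] = int(np.argmax(delta))
    for t in range(T - 1, 0, -1):
        path[t - 1] = psi[t, path[t]]
    return path


def decode_all(sequences: Iterable, model: HmmModel) -> list[np.ndarray]:
    return [viterbi(seq, model) for seq in sequences]


def state_occupancy(sequences: Iterable, model: HmmModel) -> np.ndarray:
    """Fraction of observations Viterbi-assigned to each state."""
    counts = np.zeros(model.n_states)
    for path in decode_all(sequences, model):
        if path.size:
            counts += np.bincount(path, minlength=model.n_states)
    total = counts.sum()
    if total == 0:
        raise ValueError("no observations to decode")
    return counts / total


def mark_state_matrix(
    model: HmmModel, n_marks: int, mark_order: tuple[str, ...] | None = None
) -> MarkStateMatrix:
    """Marginal mark probabilities: sum of B over symbols carrying each bit."""
    V = model.n_symbols
    if V != (1 << n_marks):
        raise ValueError(f"alphabet size {V} is not 2**{n_marks}")
    symbols = np.arange(V)
    probs = np.empty((model.n_states, n_marks))
    for bit in range(n_marks):
        has_bit = (symbols & (1 << bit)) > 0
        probs[:, bit] = model.B[:, has_bit].sum(axis=1)
    return MarkStateMatrix(probs=probs, mark_order=mark_order)


def two_round_train(
    sequences: Sequence,
    n_symbols: int,
    state_range: Iterable[int] = range(15, 26),
    replicates: int = 5,
    first_iters: int = 300,
    second_iters: int = 200,
    tol: float = 1e-4,
    prune_cutoff: float = 0.005,
    seed: int = 0,
) -> tuple[TrainingResult, TrainingResult]:
    """Full pipeline: select-by-BIC, prune low-occupancy states, retrain.

    Returns (first_round_result, final_result).
    """
    first = select_best(
        sequences, n_symbols, state_range, replicates, first_iters, tol, seed
    )
    pruned = prune_states(first.model, first.state_occupancy, prune_cutoff)
    final = retrain(sequences, pruned, max_iter=second_iters, tol=tol)
    return first, final
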