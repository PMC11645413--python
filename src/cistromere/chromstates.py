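"""Chromatin-state segmentation with a multi-track Bernoulli-emission HMM.

Mark peak calls are binarized into fixed-width bins; states are learned
by Baum-Welch EM (scaled forward-backward), decoded by Viterbi or
posterior argmax, and ordered E1..EK by an active-minus-repressive
emission score so the numeric transform 1..K tracks regulatory activity.
"""
from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple
import warnings

import numpy as np

from .intervals import PeakSet

__all__ = [
    "BinarizedMarkMatrix",
    "ChromatinStateModel",
    "StateAnnotation",
    "binarize_from_peaks",
    "fit_model",
    "decode",
    "order_states",
    "state_frequencies_at",
]

_EPS = 1e-6  # emission/transition floor keeping log-likelihoods finite


@dataclass
class BinarizedMarkMatrix:
    """Per-chromosome boolean matrices (bins x marks) at a fixed bin size."""

    data: Dict[str, np.ndarray]
    mark_names: List[str]
    bin_size: int = 200

    def __post_init__(self):
        if len(set(self.mark_names)) != len(self.mark_names):
            raise ValueError("mark names must be unique")
        if self.bin_size < 1:
            raise ValueError("bin size must be >= 1")
        for chrom, arr in self.data.items():
            arr = np.asarray(arr, dtype=bool)
            if arr.ndim != 2 or arr.shape[1] != len(self.mark_names):
                raise ValueError(
                    f"{chrom}: matrix must be bins x {len(self.mark_names)} marks"
                )
            self.data[chrom] = arr

    @property
    def n_marks(self) -> int:
        return len(self.mark_names)

    @property
    def n_bins(self) -> int:
        return sum(arr.shape[0] for arr in self.data.values())

    def sequences(self) -> List[np.ndarray]:
        """One observation sequence per chromosome, in sorted chrom order."""
        return [self.data[c] for c in sorted(self.data)]


def binarize_from_peaks(
    mark_peaks: Dict[str, PeakSet],
    chrom_lengths: Dict[str, int],
    bin_size: int = 200,
) -> BinarizedMarkMatrix:
    """A bin is true for a mark iff any peak of that mark overlaps it by
    >= 1 bp."""
    if bin_size < 1:
        raise ValueError("bin size must be >= 1")
    marks = list(mark_peaks)
    data: Dict[str, np.ndarray] = {}
    for chrom, length in chrom_lengths.items():
        n_bins = -(-length // bin_size)
        mat = np.zeros((n_bins, len(marks)), dtype=bool)
        for m, mark in enumerate(marks):
            for iv in mark_peaks[mark].by_chrom().get(chrom, []):
                b0 = iv.start // bin_size
                b1 = -(-min(iv.end, length) // bin_size)
                mat[b0:b1, m] = True
        data[chrom] = mat
    return BinarizedMarkMatrix(data, marks, bin_size)


@dataclass
class ChromatinStateModel:
    """K-state HMM with conditionally independent Bernoulli emissions."""

    initial: np.ndarray  # (K,)
    transitions: np.ndarray  # (K, K), rows sum to 1
    emissions: np.ndarray  # (K, M) per-mark Bernoulli probabilities
    mark_names: List[str]
    loglik_trace: List[float] = field(default_factory=list)

    def __post_init__(self):
        self.initial = np.asarray(self.initial, dtype=float)
        self.transitions = np.asarray(self.transitions, dtype=float)
        self.emissions = np.asarray(self.emissions, dtype=float)
        if not np.isclose(self.initial.sum(), 1.0, atol=1e-9):
            raise ValueError("initial distribution must sum to 1")
        if not np.allclose(self.transitions.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("transition rows must sum to 1")
        if np.any(self.emissions < 0) or np.any(self.emissions > 1):
            raise ValueError("emissions must lie in [0,1]")

    @property
    def n_states(self) -> int:
        return len(self.initial)

    def log_emission(self, obs: np.ndarray) -> np.ndarray:
        """(T, K) log probability of each observation row under each state."""
        e = np.clip(self.emissions, _EPS, 1 - _EPS)
        x = obs.astype(float)
        return x @ np.log(e).T + (1 - x) @ np.log(1 - e).T

    def to_json(self, path: str | os.PathLike) -> None:
        payload = {
            "initial": self.initial.tolist(),
            "transitions": self.transitions.tolist(),
            "emissions": self.emissions.tolist(),
            "mark_names": self.mark_names,
            "loglik_trace": self.loglik_trace,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "ChromatinStateModel":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            np.array(payload["initial"]),
            np.array(payload["transitions"]),
            np.array(payload["emissions"]),
            payload["mark_names"],
            payload.get("loglik_trace", []),
        )


# ---------------------------------------------------------------------------
# EM fitting
# ---------------------------------------------------------------------------

def _forward_backward(
    logb: np.ndarray, initial: np.ndarray, trans: np.ndarray
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Scaled forward-backward. Returns (alpha, beta, scales, loglik)."""
    T, K = logb.shape
    # shift log emissions rowwise for numerical stability before exp
    shift = logb.max(axis=1, keepdims=True)
    b = np.exp(logb - shift)
    alpha = np.zeros((T, K))
    scales = np.zeros(T)
    a = initial * b[0]
    scales[0] = a.sum()
    alpha[0] = a / scales[0]
    for t in range(1, T):
        a = (alpha[t - 1] @ trans) * b[t]
        scales[t] = a.sum()
        alpha[t] = a / scales[t]
    beta = np.zeros((T, K))
    beta[-1] = 1.0
    for t in range(T - 2, -1, -1):
        beta[t] = (trans @ (b[t + 1] * beta[t + 1])) / scales[t + 1]
    loglik = float(np.log(scales).sum() + shift.sum())
    return alpha, beta, scales, loglik


def _em_once(
    seqs: List[np.ndarray],
    K: int,
    rng: np.random.Generator,
    max_iter: int,
    tol: float,
) -> ChromatinStateModel:
    M = seqs[0].shape[1]
    # uniform-plus-jitter initialization around the data's column means
    colmeans = np.concatenate(seqs).mean(axis=0)
    initial = np.full(K, 1.0 / K) + 0.01 * rng.random(K)
    initial /= initial.sum()
    trans = np.full((K, K), 1.0 / K) + 0.01 * rng.random((K, K))
    trans /= trans.sum(axis=1, keepdims=True)
    emis = np.clip(
        colmeans[None, :] + 0.25 * (rng.random((K, M)) - 0.5), 0.05, 0.95
    )
    trace: List[float] = []
    model = ChromatinStateModel(initial, trans, emis, [f"m{i}" for i in range(M)])
    for _ in range(max_iter):
        loglik = 0.0
        init_acc = np.zeros(K)
        trans_num = np.zeros((K, K))
        gamma_sum = np.zeros(K)
        emis_num = np.zeros((K, M))
        for obs in seqs:
            logb = model.log_emission(obs)
            shift = logb.max(axis=1, keepdims=True)
            b = np.exp(logb - shift)
            alpha, beta, scales, ll = _forward_backward(
                logb, model.initial, model.transitions
            )
            loglik += ll
            gamma = alpha * beta
            gamma /= gamma.sum(axis=1, keepdims=True)
            init_acc += gamma[0]
            # xi summed over t, fully vectorized
            w = (b[1:] * beta[1:]) / scales[1:, None]
            trans_num += model.transitions * (alpha[:-1].T @ w)
            gamma_sum += gamma.sum(axis=0)
            emis_num += gamma.T @ obs.astype(float)
        trace.append(loglik)
        new_initial = init_acc / init_acc.sum()
        new_trans = trans_num / np.clip(
            trans_num.sum(axis=1, keepdims=True), _EPS, None
        )
        new_emis = np.clip(emis_num / gamma_sum[:, None], _EPS, 1 - _EPS)
        model = ChromatinStateModel(
            new_initial, new_trans, new_emis, model.mark_names, trace
        )
        if len(trace) >= 2 and trace[-1] - trace[-2] < tol:
            break
    return model


def fit_model(
    matrix: BinarizedMarkMatrix | np.ndarray,
    K: int = 6,
    seed: int = 0,
    n_restarts: int = 5,
    max_iter: int = 500,
    tol: float = 1e-4,
) -> ChromatinStateModel:
    """Baum-Welch EM; best of ``n_restarts`` by final log-likelihood.

    K=1 collapses to the closed form (emissions = column means) with a
    warning. Each chromosome is treated as an independent sequence.
    """
    if isinstance(matrix, np.ndarray):
        matrix = BinarizedMarkMatrix(
            {"seq": np.asarray(matrix, dtype=bool)},
            [f"m{i}" for i in range(np.asarray(matrix).shape[1])],
        )
    seqs = matrix.sequences()
    total = sum(len(s) for s in seqs)
    stacked = np.concatenate(seqs)
    if not stacked.any():
        raise ValueError("degenerate all-false matrix: nothing to segment")
    if K < 2:
        warnings.warn("K < 2: returning the closed-form single-state model")
        emis = stacked.mean(axis=0, keepdims=True)
        model = ChromatinStateModel(
            np.array([1.0]), np.array([[1.0]]), emis, matrix.mark_names
        )
        return model
    if total < 10 * K:
        raise ValueError(f"need at least {10 * K} bins to fit K={K} states")
    rng = np.random.default_rng(seed)
    best: Optional[ChromatinStateModel] = None
    for _ in range(n_restarts):
        model = _em_once(seqs, K, rng, max_iter, tol)
        if best is None or model.loglik_trace[-1] > best.loglik_trace[-1]:
            best = model
    assert best is not None
    best.mark_names = list(matrix.mark_names)
    return best


# ---------------------------------------------------------------------------
# Decoding and state ordering
# ---------------------------------------------------------------------------

@dataclass
class StateAnnotation:
    """Per-bin state indices with optional ordered labels/numeric values."""

    states: Dict[str, np.ndarray]  # raw model-state index per bin
    bin_size: int
    labels: Optional[List[str]] = None  # label per raw state index
    numeric: Optional[Dict[str, np.ndarray]] = None  # ordered index 1..K

    @property
    def n_bins(self) -> int:
        return sum(len(v) for v in self.states.values())

    def apply_ordering(self, order: np.ndarray) -> None:
        """Attach E1..EK labels given ``order`` (state indices sorted
        ascending by activity); numeric value = ordered rank 1..K."""
        K = len(order)
        rank = np.empty(K, dtype=int)
        rank[np.asarray(order)] = np.arange(1, K + 1)
        self.labels = [f"E{rank[s]}" for s in range(K)]
        self.numeric = {c: rank[v] for c, v in self.states.items()}


def _viterbi(
    logb: np.ndarray, initial: np.ndarray, trans: np.ndarray
) -> np.ndarray:
    T, K = logb.shape
    with np.errstate(divide="ignore"):
        log_init = np.log(np.clip(initial, _EPS, None))
        log_trans = np.log(np.clip(trans, _EPS, None))
    delta = log_init + logb[0]
    back = np.zeros((T, K), dtype=int)
    for t in range(1, T):
        cand = delta[:, None] + log_trans
        back[t] = cand.argmax(axis=0)
        delta = cand.max(axis=0) + logb[t]
    path = np.zeros(T, dtype=int)
    path[-1] = int(delta.argmax())
    for t in range(T - 2, -1, -1):
        path[t] = back[t + 1, path[t + 1]]
    return path


def decode(
    model: ChromatinStateModel,
    matrix: BinarizedMarkMatrix,
    method: str = "viterbi",
) -> StateAnnotation:
    """Viterbi path (default) or per-bin posterior argmax."""
    if list(matrix.mark_names) != list(model.mark_names):
        raise ValueError(
            f"mark order mismatch: model {model.mark_names} vs "
            f"matrix {matrix.mark_names}"
        )
    if method not in ("viterbi", "posterior"):
        raise ValueError(f"unknown decode method {method!r}")
    states: Dict[str, np.ndarray] = {}
    for chrom in sorted(matrix.data):
        obs = matrix.data[chrom]
        logb = model.log_emission(obs)
        if method == "viterbi":
            states[chrom] = _viterbi(logb, model.initial, model.transitions)
        else:
            alpha, beta, _, _ = _forward_backward(
                logb, model.initial, model.transitions
            )
            gamma = alpha * beta
            gamma /= gamma.sum(axis=1, keepdims=True)
            states[chrom] = gamma.argmax(axis=1)
    return StateAnnotation(states, matrix.bin_size)


def posterior(
    model: ChromatinStateModel, matrix: BinarizedMarkMatrix
) -> Dict[str, np.ndarray]:
    """Per-bin posterior state probabilities (rows sum to 1)."""
    out: Dict[str, np.ndarray] = {}
    for chrom in sorted(matrix.data):
        logb = model.log_emission(matrix.data[chrom])
        alpha, beta, _, _ = _forward_backward(
            logb, model.initial, model.transitions
        )
        gamma = alpha * beta
        gamma /= gamma.sum(axis=1, keepdims=True)
        out[chrom] = gamma
    return out


def order_states(
    model: ChromatinStateModel,
    active_marks: Sequence[str],
    repressive_marks: Sequence[str] = (),
) -> Tuple[np.ndarray, List[str]]:
    """Sort states ascending by (sum of active-mark emissions - sum of
    repressive-mark emissions), ties broken by total emission mass.

    Returns (order, labels): ``order[i]`` is the raw state index labeled
    ``E{i+1}``; ``labels[s]`` is the label of raw state ``s``.
    """
    marks = list(model.mark_names)
    for m in list(active_marks) + list(repressive_marks):
        if m not in marks:
            raise ValueError(f"mark {m!r} not in model marks {marks}")
    act_idx = [marks.index(m) for m in active_marks]
    rep_idx = [marks.index(m) for m in repressive_marks]
    score = (
        model.emissions[:, act_idx].sum(axis=1)
        - model.emissions[:, rep_idx].sum(axis=1)
    )
    total = model.emissions.sum(axis=1)
    order = np.lexsort((total, score))
    labels = [""] * model.n_states
    for pos, s in enumerate(order):
        labels[s] = f"E{pos + 1}"
    return order, labels


def state_frequencies_at(
    annotation: StateAnnotation,
    peaks: PeakSet,
    n_states: Optional[int] = None,
) -> np.ndarray:
    """Fraction of peak-overlapped bins in each state (sums to 1)."""
    bin_size = annotation.bin_size
    K = n_states or int(max(v.max() for v in annotation.states.values())) + 1
    counts = np.zeros(K)
    for chrom, states in annotation.states.items():
        covered = np.zeros(len(states), dtype=bool)
        for iv in peaks.by_chrom().get(chrom, []):
            b0 = iv.start // bin_size
            b1 = -(-iv.end // bin_size)
            covered[b0:min(b1, len(states))] = True
        if covered.any():
            counts += np.bincount(states[covered], minlength=K)
    if counts.sum() == 0:
        raise ValueError("peaks overlap no annotated bins")
    return counts / counts.sum()
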