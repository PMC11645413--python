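"""Synthetic input generators with planted ground truth.

Every generator is deterministic under a fixed seed and plants a known
quantity (motif fractions, emission model, expression effects, hazard
coefficient) that the corresponding analysis stage should recover.
Ground truth is serialized as a JSON sidecar so tests never re-derive it.
"""
from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .chromstates import BinarizedMarkMatrix, ChromatinStateModel
from .genome import Genome
from .intervals import GenomicInterval, PeakSet
from .motifs import PositionWeightMatrix, scan

__all__ = [
    "SimulationTruth",
    "make_genome",
    "make_peak_sets",
    "make_matched_cohort",
    "make_mark_tracks",
    "make_expression_cohort",
    "make_survival",
]

BASES = "ACGT"


@dataclass
class SimulationTruth:
    """Planted ground truth accompanying a synthetic dataset."""

    seed: int
    planted_are_fraction_per_set: Dict[str, float] = field(default_factory=dict)
    true_state_sequence: Optional[List[int]] = None
    true_model: Optional[ChromatinStateModel] = None
    signature_genes: Dict[str, Dict[str, float]] = field(default_factory=dict)
    survival_beta: Optional[float] = None

    def __post_init__(self):
        for name, frac in self.planted_are_fraction_per_set.items():
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"fraction for {name!r} outside [0,1]")
        for direction, genes in self.signature_genes.items():
            for g, eff in genes.items():
                if not np.isfinite(eff):
                    raise ValueError(f"non-finite effect for {g}")

    def to_json(self, path: str | os.PathLike) -> None:
        payload = {
            "seed": self.seed,
            "planted_are_fraction_per_set": self.planted_are_fraction_per_set,
            "true_state_sequence": self.true_state_sequence,
            "signature_genes": self.signature_genes,
            "survival_beta": self.survival_beta,
        }
        if self.true_model is not None:
            payload["true_model"] = {
                "initial": self.true_model.initial.tolist(),
                "transitions": self.true_model.transitions.tolist(),
                "emissions": self.true_model.emissions.tolist(),
                "mark_names": self.true_model.mark_names,
            }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> str:
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list(BASES))[rng.choice(4, size=n, p=probs)])


def make_genome(
    seed: int, chrom_lengths: Dict[str, int], gc: float = 0.41
) -> Genome:
    """I.i.d. random genome with the stated GC content."""
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc must lie in [0,1]")
    for name, length in chrom_lengths.items():
        if length < 1000:
            raise ValueError(f"{name}: chromosome length must be >= 1000")
    rng = np.random.default_rng(seed)
    return Genome(
        {name: _random_bases(rng, length, gc) for name, length in chrom_lengths.items()}
    )


def make_peak_sets(
    genome: Genome,
    n_peaks: int,
    width: int,
    are_fraction: float,
    pwm: PositionWeightMatrix,
    seed: int,
    threshold: Optional[float] = None,
    gc: float = 0.41,
    sample_id: str = "synthetic",
    condition: str = "",
    max_tries: int = 1000,
) -> Tuple[PeakSet, SimulationTruth]:
    """Non-overlapping peaks with exactly round(n * fraction) planted
    max-score motif sites at peak centers.

    Motif-negative peaks are rejection-sampled against the scan
    threshold, so scanning at that threshold recovers the planted
    fraction exactly. The genome is edited in place.
    """
    if not 0.0 <= are_fraction <= 1.0:
        raise ValueError("are_fraction must lie in [0,1]")
    if width < pwm.length:
        raise ValueError("peak width must accommodate the motif")
    if threshold is None:
        threshold = pwm.threshold_for_fpr()
    rng = np.random.default_rng(seed)
    gap = 20
    slot = width + gap
    # lattice placement guarantees non-overlap; jitter stays inside the slot
    slots: List[Tuple[str, int]] = []
    for chrom, length in genome.chrom_lengths.items():
        for k in range(length // slot):
            slots.append((chrom, k * slot))
    if len(slots) < n_peaks:
        raise ValueError(
            f"genome too small: {len(slots)} slots for {n_peaks} peaks"
        )
    chosen = [slots[i] for i in rng.choice(len(slots), n_peaks, replace=False)]
    chosen.sort()
    n_pos = round(n_peaks * are_fraction)
    positive = np.zeros(n_peaks, dtype=bool)
    positive[rng.choice(n_peaks, n_pos, replace=False)] = True
    consensus = pwm.consensus()
    intervals: List[GenomicInterval] = []
    for i, (chrom, base) in enumerate(chosen):
        start = base + int(rng.integers(0, gap + 1))
        # rejection-sample a motif-free background for the peak body
        for attempt in range(max_tries):
            seq = _random_bases(rng, width, gc)
            if not scan(pwm, seq, threshold):
                break
        else:
            raise RuntimeError("rejection sampling failed; threshold too low?")
        genome.set_sequence(chrom, start, seq)
        if positive[i]:
            center = start + width // 2
            genome.set_sequence(chrom, center - pwm.length // 2, consensus)
        intervals.append(
            GenomicInterval(chrom, start, start + width, name=f"peak{i}")
        )
    peaks = PeakSet(intervals, sample_id=sample_id, condition=condition)
    truth = SimulationTruth(
        seed=seed,
        planted_are_fraction_per_set={sample_id: n_pos / n_peaks},
    )
    return peaks, truth


def make_matched_cohort(
    n_patients: int,
    normal_mean: float,
    depletion: float,
    noise_sd: float,
    seed: int,
) -> pd.DataFrame:
    """Paired (normal, tumor) ARE-fraction table with tumor depleted by a
    fixed amount plus noise; values clipped to [0,1]."""
    if n_patients < 2:
        raise ValueError("need at least 2 patients")
    if not 0.0 < depletion < normal_mean:
        raise ValueError("require 0 < depletion < normal_mean")
    rng = np.random.default_rng(seed)
    normal = np.clip(
        normal_mean + noise_sd * rng.standard_normal(n_patients), 0.0, 1.0
    )
    tumor = np.clip(
        normal - depletion + noise_sd * rng.standard_normal(n_patients),
        0.0,
        1.0,
    )
    return pd.DataFrame(
        {
            "patient": [f"P{i + 1}" for i in range(n_patients)],
            "normal": normal,
            "tumor": tumor,
        }
    )


def make_mark_tracks(
    true_model: ChromatinStateModel,
    n_bins: int,
    bin_size: int,
    seed: int,
    chrom: str = "chr1",
) -> Tuple[BinarizedMarkMatrix, np.ndarray]:
    """Sample a state path from the Markov chain and mark calls from the
    per-state Bernoulli emissions. Returns the binarized matrix and the
    true state sequence."""
    K = true_model.n_states
    if n_bins < 10 * K:
        raise ValueError(f"n_bins must be >= {10 * K} for K={K}")
    if not np.allclose(true_model.transitions.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("transition rows must sum to 1")
    rng = np.random.default_rng(seed)
    states = np.zeros(n_bins, dtype=int)
    states[0] = rng.choice(K, p=true_model.initial)
    for t in range(1, n_bins):
        states[t] = rng.choice(K, p=true_model.transitions[states[t - 1]])
    probs = true_model.emissions[states]  # (n_bins, M)
    marks = rng.random(probs.shape) < probs
    matrix = BinarizedMarkMatrix(
        {chrom: marks}, list(true_model.mark_names), bin_size
    )
    return matrix, states


def mark_tracks_to_bedgraph(
    matrix: BinarizedMarkMatrix, out_dir: str | os.PathLike
) -> List[str]:
    """Write each mark's 0/1 bin calls as a bedGraph track."""
    from .signal import SignalTrack, write_bedgraph

    os.makedirs(out_dir, exist_ok=True)
    paths = []
    for m, mark in enumerate(matrix.mark_names):
        track = SignalTrack(
            {c: arr[:, m].astype(float) for c, arr in matrix.data.items()},
            matrix.bin_size,
            sample_id=mark,
        )
        path = os.path.join(out_dir, f"{mark}.bedgraph")
        write_bedgraph(track, path)
        paths.append(path)
    return paths


def make_expression_cohort(
    n_genes: int,
    n_samples: int,
    up_genes: int | Sequence[str],
    down_genes: int | Sequence[str],
    group_labels: Optional[Sequence[str]] = None,
    effect: float = 2.0,
    noise_sd: float = 1.0,
    seed: int = 0,
    baseline_mean: float = 8.0,
    baseline_sd: float = 2.0,
) -> Tuple[pd.DataFrame, List[str], SimulationTruth]:
    """Log2 expression cohort with planted up/down genes shifted by
    +/- ``effect`` in the treated group.

    ``up_genes``/``down_genes`` may be counts (names auto-assigned) or
    explicit gene-name lists. ``group_labels`` defaults to half control /
    half treated.
    """
    rng = np.random.default_rng(seed)
    genes = [f"g{i + 1:05d}" for i in range(n_genes)]
    if isinstance(up_genes, int):
        up = genes[:up_genes]
    else:
        up = list(up_genes)
    if isinstance(down_genes, int):
        down = genes[len(up):len(up) + down_genes]
    else:
        down = list(down_genes)
    if set(up) & set(down):
        raise ValueError("up and down gene sets overlap")
    unknown = (set(up) | set(down)) - set(genes)
    if unknown:
        raise ValueError(f"planted genes not in gene universe: {sorted(unknown)[:5]}")
    if group_labels is None:
        group_labels = ["control"] * (n_samples // 2) + ["treated"] * (
            n_samples - n_samples // 2
        )
    group_labels = list(group_labels)
    if len(group_labels) != n_samples:
        raise ValueError("group_labels length must equal n_samples")
    samples = [f"s{i + 1:03d}" for i in range(n_samples)]
    base = baseline_mean + baseline_sd * rng.standard_normal(n_genes)
    values = base[:, None] + noise_sd * rng.standard_normal((n_genes, n_samples))
    treated = np.array([lab == "treated" for lab in group_labels])
    gene_idx = {g: i for i, g in enumerate(genes)}
    for g in up:
        values[gene_idx[g], treated] += effect
    for g in down:
        values[gene_idx[g], treated] -= effect
    expr = pd.DataFrame(values, index=genes, columns=samples)
    truth = SimulationTruth(
        seed=seed,
        signature_genes={
            "up": {g: effect for g in up},
            "down": {g: -effect for g in down},
        },
    )
    return expr, group_labels, truth


def make_survival(
    scores: pd.Series | Sequence[float],
    beta: float,
    baseline_hazard: float = 0.02,
    censor_rate: float = 0.2,
    seed: int = 0,
) -> Tuple[pd.DataFrame, SimulationTruth]:
    """Exponential survival times with hazard
    baseline * exp(beta * standardized score) and independent exponential
    censoring tuned so roughly ``censor_rate`` of records are censored."""
    if not 0.0 <= censor_rate < 1.0:
        raise ValueError("censor_rate must lie in [0, 1)")
    if baseline_hazard <= 0:
        raise ValueError("baseline hazard must be positive")
    vals = np.asarray(
        scores.values if isinstance(scores, pd.Series) else scores, dtype=float
    )
    sd = vals.std(ddof=1)
    z = (vals - vals.mean()) / sd if sd > 0 else np.zeros_like(vals)
    rng = np.random.default_rng(seed)
    hazard = baseline_hazard * np.exp(beta * z)
    event_times = rng.exponential(1.0 / hazard)
    if censor_rate > 0:
        censor_hazard = baseline_hazard * censor_rate / (1 - censor_rate)
        censor_times = rng.exponential(1.0 / censor_hazard, size=len(vals))
    else:
        censor_times = np.full(len(vals), np.inf)
    time = np.minimum(event_times, censor_times)
    event = (event_times <= censor_times).astype(int)
    table = pd.DataFrame(
        {
            "id": [f"pt{i + 1:04d}" for i in range(len(vals))],
            "time": time,
            "event": event,
            "score": vals,
            "score_z": z,
        }
    )
    truth = SimulationTruth(seed=seed, survival_beta=beta)
    return table, truth
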