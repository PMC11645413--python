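"""PWM motif model, scanning, fraction-with-motif statistics, density
profiles, differential profiles, and background-matched enrichment.

Scores are log-odds in bits: sum over positions of
``log2(p_base / bg_base)``. Scanning covers both strands; a hit is any
window whose score reaches the threshold. The default threshold is
calibrated so that a random background window scores as a hit with
probability ``1e-4`` per position per strand (the per-motif cutoffs of
common scanners are not portable, so we pin an explicit false-positive
rate instead).
"""
from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats
from scipy.signal import savgol_filter

from .genome import Genome
from .intervals import GenomicInterval, PeakSet, peak_center

__all__ = [
    "PositionWeightMatrix",
    "MotifHit",
    "DensityProfile",
    "load_motif",
    "canonical_are_pwm",
    "scan",
    "peak_has_motif",
    "fraction_with_motif",
    "compare_fractions",
    "motif_density_profile",
    "differential_density",
    "motif_enrichment",
]

BASES = "ACGT"
_COMPLEMENT = {0: 3, 1: 2, 2: 1, 3: 0}

# byte -> base code lookup (A=0 C=1 G=2 T=3, everything else -1)
_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

DEFAULT_SCAN_FPR = 1e-4


def encode_sequence(seq: str) -> np.ndarray:
    """Map a DNA string to integer codes; N and unknowns become -1."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


class PositionWeightMatrix:
    """Probabilistic motif model over A,C,G,T with a background model."""

    def __init__(
        self,
        probs: np.ndarray,
        background: Optional[Sequence[float]] = None,
        name: str = "motif",
        pseudocount: float = 0.0,
    ):
        probs = np.asarray(probs, dtype=float)
        if probs.ndim != 2 or probs.shape[1] != 4:
            raise ValueError("probs must be L x 4")
        if probs.shape[0] < 4:
            raise ValueError("motif length must be >= 4")
        if np.any(probs < 0):
            raise ValueError("probabilities must be non-negative")
        rowsums = probs.sum(axis=1)
        if not np.allclose(rowsums, 1.0, atol=1e-9):
            raise ValueError("each position's probabilities must sum to 1")
        bg = np.asarray(
            background if background is not None else [0.25] * 4, dtype=float
        )
        if bg.shape != (4,) or not np.isclose(bg.sum(), 1.0, atol=1e-9):
            raise ValueError("background must be 4 probabilities summing to 1")
        if np.any(bg <= 0):
            raise ValueError("background probabilities must be positive")
        self.probs = probs
        self.background = bg
        self.name = name
        self.pseudocount = pseudocount
        self._threshold_cache: Dict[float, float] = {}

    # -- basic properties --------------------------------------------------
    @property
    def length(self) -> int:
        return self.probs.shape[0]

    def __len__(self) -> int:
        return self.length

    @property
    def log_odds(self) -> np.ndarray:
        """L x 4 matrix of log2(p/bg); zero-probability cells are -inf."""
        with np.errstate(divide="ignore"):
            return np.log2(self.probs / self.background)

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.probs.argmax(axis=1))

    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())

    def min_score(self) -> float:
        return float(self.log_odds.min(axis=1).sum())

    def reverse_complement(self) -> "PositionWeightMatrix":
        rc = self.probs[::-1, ::-1].copy()
        bg = self.background[::-1].copy()
        return PositionWeightMatrix(
            rc, bg, name=self.name + "_rc", pseudocount=self.pseudocount
        )

    @classmethod
    def from_counts(
        cls,
        counts: np.ndarray,
        background: Optional[Sequence[float]] = None,
        name: str = "motif",
        pseudocount: float = 0.25,
    ) -> "PositionWeightMatrix":
        counts = np.asarray(counts, dtype=float)
        if counts.ndim != 2 or counts.shape[1] != 4:
            raise ValueError("counts must be L x 4")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        padded = counts + pseudocount
        probs = padded / padded.sum(axis=1, keepdims=True)
        return cls(probs, background, name=name, pseudocount=pseudocount)

    # -- threshold calibration --------------------------------------------
    def score_distribution(
        self, grid: float = 1e-3
    ) -> Tuple[np.ndarray, np.ndarray]:
        """Exact distribution of the forward-strand window score under the
        background model, by per-position convolution on a discretized
        score grid (bin width ``grid`` bits)."""
        lo = self.log_odds
        finite = np.where(np.isfinite(lo), lo, 0.0)
        idx = np.round(finite / grid).astype(int)
        offset = 0
        dist = np.array([1.0])
        for pos in range(self.length):
            lows = idx[pos].min()
            span = idx[pos].max() - lows
            new = np.zeros(len(dist) + span)
            for base in range(4):
                p = self.background[base]
                if not np.isfinite(lo[pos, base]):
                    continue  # -inf contributions never reach any threshold
                shift = idx[pos, base] - lows
                new[shift:shift + len(dist)] += p * dist
            dist = new
            offset += lows
        scores = (offset + np.arange(len(dist))) * grid
        return scores, dist

    def threshold_for_fpr(self, fpr: float = DEFAULT_SCAN_FPR) -> float:
        """Smallest score t with P(window score >= t | background) <= fpr."""
        if fpr in self._threshold_cache:
            return self._threshold_cache[fpr]
        scores, dist = self.score_distribution()
        tail = np.cumsum(dist[::-1])[::-1]
        ok = np.nonzero(tail <= fpr)[0]
        if len(ok) == 0:
            thr = float(scores[-1]) + 1e-9  # only the max score qualifies
        else:
            thr = float(scores[ok[0]]) - 1e-9  # guard against grid rounding
        self._threshold_cache[fpr] = thr
        return thr


@dataclass(frozen=True)
class MotifHit:
    position: int  # 0-based offset of the hit start within the scanned sequence
    strand: str  # '+' or '-'
    score: float


def load_motif(
    path: str | os.PathLike,
    background: Optional[Sequence[float]] = None,
    pseudocount: float = 0.25,
) -> PositionWeightMatrix:
    """Read a JASPAR-style PFM: an optional '>' header then four rows
    (A, C, G, T) of counts, with or without the ``A [ ... ]`` brackets."""
    name = "motif"
    rows: List[List[float]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                parts = line[1:].split()
                name = parts[-1] if parts else "motif"
                continue
            cleaned = line.replace("[", " ").replace("]", " ")
            fields = cleaned.split()
            if fields and fields[0].upper() in ("A", "C", "G", "T"):
                fields = fields[1:]
            try:
                rows.append([float(x) for x in fields])
            except ValueError as exc:
                raise ValueError(f"{path}: malformed PFM row {line!r}") from exc
    if len(rows) != 4:
        raise ValueError(f"{path}: expected 4 base rows, found {len(rows)}")
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise ValueError(f"{path}: ragged PFM (row lengths {sorted(lengths)})")
    counts = np.array(rows).T  # rows are per-base; transpose to L x 4
    if np.any(counts < 0):
        raise ValueError(f"{path}: negative counts")
    return PositionWeightMatrix.from_counts(
        counts, background, name=name, pseudocount=pseudocount
    )


def canonical_are_pwm(pseudocount: float = 0.25) -> PositionWeightMatrix:
    """A canonical full-site ARE model: two strong inverted half-sites
    (AGAACA ... TGTTCT) around a 3-bp uniform spacer. Palindromic by
    construction (equal to its own reverse complement)."""
    consensus = "AGAACANNNTGTTCT"
    counts = np.zeros((len(consensus), 4))
    for i, base in enumerate(consensus):
        if base == "N":
            counts[i] = 25.0
        else:
            counts[i] = 5.0
            counts[i, BASES.index(base)] = 85.0
    return PositionWeightMatrix.from_counts(
        counts, name="ARE", pseudocount=pseudocount
    )


# ---------------------------------------------------------------------------
# Scanning
# ---------------------------------------------------------------------------

def _window_scores(codes: np.ndarray, log_odds: np.ndarray) -> np.ndarray:
    """Score every window start for one strand; windows containing an
    unknown base (code -1) score -inf."""
    L = log_odds.shape[0]
    n = len(codes) - L + 1
    if n <= 0:
        return np.empty(0)
    scores = np.zeros(n)
    valid = np.ones(n, dtype=bool)
    safe = np.where(codes >= 0, codes, 0)
    for j in range(L):
        col = log_odds[j, safe[j:j + n]]
        scores += col
        valid &= codes[j:j + n] >= 0
    scores[~valid] = -np.inf
    return scores


def scan(
    pwm: PositionWeightMatrix,
    sequence: str,
    threshold: Optional[float] = None,
) -> List[MotifHit]:
    """All motif hits on both strands with score >= threshold.

    Hit positions are the 0-based start of the L-bp window on the forward
    strand. When both strands hit at the same position only the higher
    scoring one is kept (tie broken toward '+').
    """
    if threshold is None:
        threshold = pwm.threshold_for_fpr()
    codes = encode_sequence(sequence)
    if len(codes) < pwm.length:
        return []
    fwd = _window_scores(codes, pwm.log_odds)
    rev = _window_scores(codes, pwm.reverse_complement().log_odds)
    best = np.maximum(fwd, rev)
    minus = rev > fwd  # tie broken toward '+'
    hits = [
        MotifHit(int(pos), "-" if minus[pos] else "+", float(best[pos]))
        for pos in np.nonzero(best >= threshold)[0]
    ]
    return hits


def peak_has_motif(
    peak: GenomicInterval,
    genome: Genome,
    pwm: PositionWeightMatrix,
    window: int = 100,
    threshold: Optional[float] = None,
) -> bool:
    """True iff the window (total width, centered on the peak center)
    contains at least one hit. Clipped at chromosome edges."""
    if peak.chrom not in genome:
        raise KeyError(f"chromosome {peak.chrom!r} absent from genome")
    center = peak_center(peak)
    seq = genome.fetch(peak.chrom, center - window // 2, center + window // 2)
    return len(scan(pwm, seq, threshold)) > 0


def fraction_with_motif(
    peakset: PeakSet,
    genome: Genome,
    pwm: PositionWeightMatrix,
    window: int = 100,
    threshold: Optional[float] = None,
) -> float:
    """Fraction of peaks whose central window contains a motif hit."""
    if len(peakset) == 0:
        raise ValueError("empty peak set")
    if threshold is None:
        threshold = pwm.threshold_for_fpr()
    positives = sum(
        peak_has_motif(iv, genome, pwm, window, threshold) for iv in peakset
    )
    return positives / len(peakset)


def compare_fractions(
    group_a: Sequence[float],
    group_b: Sequence[float],
    paired: bool = False,
) -> Dict[str, float]:
    """Two-sided rank test between two groups of per-sample fractions.

    Unpaired: Mann-Whitney U (exact when both samples are small and
    untied). Paired: Wilcoxon signed-rank on differences, zeros dropped;
    all-zero differences return p = 1 by convention.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if paired:
        if len(a) != len(b):
            raise ValueError("paired comparison requires equal lengths")
        diffs = a - b
        diffs = diffs[diffs != 0]
        if len(diffs) == 0:
            return {"statistic": 0.0, "pvalue": 1.0}
        n = len(diffs)
        if n <= 15:
            # full 2^n sign-vector enumeration (valid with tied magnitudes)
            ranks = stats.rankdata(np.abs(diffs))
            w_obs = float(ranks[diffs > 0].sum())
            total = float(ranks.sum())
            signs = (
                np.arange(2**n)[:, None] >> np.arange(n)[None, :]
            ) & 1
            w_all = signs @ ranks
            lo = min(w_obs, total - w_obs)
            hi = max(w_obs, total - w_obs)
            p = float(np.mean((w_all >= hi - 1e-12) | (w_all <= lo + 1e-12)))
            return {"statistic": min(w_obs, total - w_obs), "pvalue": p}
        exact = n <= 25 and len(np.unique(np.abs(diffs))) == n
        res = stats.wilcoxon(
            diffs, alternative="two-sided",
            method="exact" if exact else "approx",
        )
        return {"statistic": float(res.statistic), "pvalue": float(res.pvalue)}
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    exact = len(pooled) <= 25 and len(np.unique(pooled)) == len(pooled)
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided",
        method="exact" if exact else "asymptotic",
    )
    return {"statistic": float(res.statistic), "pvalue": float(res.pvalue)}


# ---------------------------------------------------------------------------
# Density profiles
# ---------------------------------------------------------------------------

@dataclass
class DensityProfile:
    """Per-bin motif frequency per bp per peak around peak centers."""

    values: np.ndarray
    window: int
    bin_size: int
    n_peaks: int
    name: str = ""
    metadata: Dict[str, str] = None  # type: ignore[assignment]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.metadata is None:
            self.metadata = {}
        if self.window % self.bin_size != 0:
            raise ValueError("bin size must divide the window")
        if len(self.values) != self.window // self.bin_size:
            raise ValueError("value count must equal window / bin size")

    @property
    def n_bins(self) -> int:
        return len(self.values)

    def bin_offsets(self) -> np.ndarray:
        """Offset of each bin's left edge relative to the peak center."""
        return np.arange(self.n_bins) * self.bin_size - self.window // 2

    def same_geometry(self, other: "DensityProfile") -> bool:
        return self.window == other.window and self.bin_size == other.bin_size


def motif_density_profile(
    peaks: PeakSet,
    genome: Genome,
    pwm: PositionWeightMatrix,
    window: int = 2400,
    bin_size: int = 10,
    threshold: Optional[float] = None,
) -> DensityProfile:
    """Motif-hit density around peak centers.

    Hits are assigned to bins by hit-start offset relative to the center;
    values are hits / (bin_size * n_peaks), i.e. frequency/bp/peak.
    """
    if len(peaks) == 0:
        raise ValueError("empty peak set")
    if window % bin_size != 0:
        raise ValueError("bin size must divide the window")
    if threshold is None:
        threshold = pwm.threshold_for_fpr()
    half = window // 2
    counts = np.zeros(window // bin_size)
    for iv in peaks:
        center = peak_center(iv)
        # extend right so hit *starts* can cover the full [-half, half) range
        lo = center - half
        seq = genome.fetch(iv.chrom, lo, center + half + pwm.length - 1)
        clip_left = max(0, -lo)  # bases lost to the chromosome edge
        for hit in scan(pwm, seq, threshold):
            offset = hit.position + clip_left - half
            if -half <= offset < half:
                counts[(offset + half) // bin_size] += 1
    values = counts / (bin_size * len(peaks))
    return DensityProfile(values, window, bin_size, len(peaks), name=pwm.name)


def differential_density(
    a: DensityProfile, b: DensityProfile, smooth: bool = False
) -> DensityProfile:
    """Signed differential profile a - b; positive bins mark enrichment,
    negative depletion. Optional local-quadratic (Savitzky-Golay order 2,
    5-bin window) smoothing."""
    if not a.same_geometry(b):
        raise ValueError("profiles have mismatched window/bin geometry")
    diff = a.values - b.values
    meta = {"smoothing": "none"}
    if smooth:
        if len(diff) < 5:
            raise ValueError("smoothing requires at least 5 bins")
        diff = savgol_filter(diff, window_length=5, polyorder=2, mode="interp")
        meta["smoothing"] = "savgol(window=5, order=2)"
    return DensityProfile(
        diff, a.window, a.bin_size, a.n_peaks,
        name=f"{a.name}-diff", metadata=meta,
    )


# ---------------------------------------------------------------------------
# Enrichment
# ---------------------------------------------------------------------------

def motif_enrichment(
    foreground: PeakSet,
    background: PeakSet,
    genome: Genome,
    pwm: PositionWeightMatrix,
    window: int = 100,
    threshold: Optional[float] = None,
    p_cutoff: float = 1e-20,
) -> Dict[str, float]:
    """Background-matched motif enrichment via a one-sided Fisher exact
    test on motif-positive counts; significant iff p <= ``p_cutoff``
    (default 1e-20)."""
    if len(foreground) == 0 or len(background) == 0:
        raise ValueError("both peak sets must be non-empty")
    if threshold is None:
        threshold = pwm.threshold_for_fpr()

    def _counts(ps: PeakSet) -> Tuple[int, int]:
        pos = sum(
            peak_has_motif(iv, genome, pwm, window, threshold) for iv in ps
        )
        return pos, len(ps) - pos

    fg_pos, fg_neg = _counts(foreground)
    bg_pos, bg_neg = _counts(background)
    table = [[fg_pos, fg_neg], [bg_pos, bg_neg]]
    odds, p = stats.fisher_exact(table, alternative="greater")
    return {
        "odds_ratio": float(odds),
        "pvalue": float(p),
        "significant": bool(p <= p_cutoff),
        "fg_positive": fg_pos,
        "fg_total": len(foreground),
        "bg_positive": bg_pos,
        "bg_total": len(background),
    }
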