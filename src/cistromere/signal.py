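"""Binned signal tracks, anchored signal matrices, aggregate profiles,
RPKM normalization, and sample PCA over consensus regions.

Tracks are exchanged as bedGraph (bigWig conversion is left to external
utilities). Window edges that fall off a chromosome are treated as
missing (NaN) and excluded from means, never zero-filled.
"""
from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .intervals import PeakSet, peak_center

__all__ = [
    "SignalTrack",
    "SignalMatrix",
    "read_bedgraph",
    "write_bedgraph",
    "rpkm",
    "signal_matrix",
    "mean_profile",
    "sample_pca",
]


@dataclass
class SignalTrack:
    """Per-chromosome arrays of values at a fixed bin resolution."""

    data: Dict[str, np.ndarray]
    bin_size: int
    sample_id: str = ""
    normalization: str = "raw"

    def __post_init__(self):
        if self.bin_size < 1:
            raise ValueError("bin size must be >= 1")
        for chrom, arr in self.data.items():
            arr = np.asarray(arr, dtype=float)
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"non-finite values on {chrom}")
            self.data[chrom] = arr

    def value_at(self, chrom: str, pos: int) -> float:
        """Track value at a base position; NaN outside the track."""
        arr = self.data.get(chrom)
        if arr is None:
            return float("nan")
        idx = pos // self.bin_size
        if pos < 0 or idx >= len(arr):
            return float("nan")
        return float(arr[idx])


def read_bedgraph(
    path: str | os.PathLike,
    bin_size: int,
    chrom_lengths: Optional[Dict[str, int]] = None,
    sample_id: str = "",
) -> SignalTrack:
    """Read a bedGraph onto a fixed bin grid by length-weighted mean
    (uncovered stretches count as zero). Overlapping records are an error.
    """
    if bin_size < 1:
        raise ValueError("bin size must be >= 1")
    records: Dict[str, List[Tuple[int, int, float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise ValueError(f"{path}: line {lineno}: need 4 columns")
            chrom, start, end, value = (
                fields[0], int(fields[1]), int(fields[2]), float(fields[3])
            )
            if start < 0 or start >= end:
                raise ValueError(f"{path}: line {lineno}: bad interval")
            records.setdefault(chrom, []).append((start, end, value))
    data: Dict[str, np.ndarray] = {}
    for chrom, recs in records.items():
        recs.sort()
        for (s1, e1, _), (s2, _, _) in zip(recs, recs[1:]):
            if s2 < e1:
                raise ValueError(f"overlapping bedGraph records on {chrom}")
        extent = recs[-1][1]
        if chrom_lengths and chrom in chrom_lengths:
            extent = max(extent, chrom_lengths[chrom])
        n_bins = -(-extent // bin_size)
        acc = np.zeros(n_bins)
        for start, end, value in recs:
            b0, b1 = start // bin_size, -(-end // bin_size)
            for b in range(b0, b1):
                lo = max(start, b * bin_size)
                hi = min(end, (b + 1) * bin_size)
                acc[b] += value * (hi - lo)
        data[chrom] = acc / bin_size
    return SignalTrack(data, bin_size, sample_id=sample_id)


def write_bedgraph(track: SignalTrack, path: str | os.PathLike) -> None:
    """Write non-zero runs as bedGraph records (run-length compressed)."""
    with open(path, "w") as fh:
        for chrom in sorted(track.data):
            arr = track.data[chrom]
            i = 0
            while i < len(arr):
                j = i
                while j < len(arr) and arr[j] == arr[i]:
                    j += 1
                if arr[i] != 0:
                    fh.write(
                        f"{chrom}\t{i * track.bin_size}\t"
                        f"{j * track.bin_size}\t{arr[i]:g}\n"
                    )
                i = j


def rpkm(
    counts_per_bin: Dict[str, np.ndarray] | SignalTrack,
    bin_size: int,
    total_mapped_reads: float,
    sample_id: str = "",
) -> SignalTrack:
    """Reads-per-kilobase-per-million normalization:
    value = count / ((bin_size/1000) * (total/1e6))."""
    if total_mapped_reads <= 0:
        raise ValueError("total mapped reads must be positive")
    if isinstance(counts_per_bin, SignalTrack):
        data = counts_per_bin.data
        bin_size = counts_per_bin.bin_size
        sample_id = sample_id or counts_per_bin.sample_id
    else:
        data = counts_per_bin
    denom = (bin_size / 1000.0) * (total_mapped_reads / 1e6)
    out = {c: np.asarray(v, dtype=float) / denom for c, v in data.items()}
    return SignalTrack(out, bin_size, sample_id=sample_id, normalization="RPKM")


@dataclass
class SignalMatrix:
    """Rows = peaks, columns = position bins relative to the peak center."""

    values: np.ndarray  # may contain NaN where windows ran off a chromosome
    window: int
    bin_size: int
    peak_ids: List[str] = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[1] != self.window // self.bin_size:
            raise ValueError("column count must equal window / bin size")


def signal_matrix(
    track: SignalTrack,
    peaks: PeakSet,
    window: int = 4000,
    bin_size: int = 50,
) -> SignalMatrix:
    """Signal in ``window`` bp around each peak center, averaged in
    ``bin_size`` bp columns. Off-chromosome positions are NaN."""
    if window % bin_size != 0:
        raise ValueError("bin size must divide the window")
    usable = [iv for iv in peaks if iv.chrom in track.data]
    if not usable:
        raise ValueError("no peak lies on a chromosome present in the track")
    n_cols = window // bin_size
    half = window // 2
    rows = np.full((len(usable), n_cols), np.nan)
    ids = []
    for r, iv in enumerate(usable):
        arr = track.data[iv.chrom]
        extent = len(arr) * track.bin_size
        positions = np.arange(peak_center(iv) - half, peak_center(iv) + half)
        valid = (positions >= 0) & (positions < extent)
        per_bp = np.full(window, np.nan)
        per_bp[valid] = arr[positions[valid] // track.bin_size]
        with warnings.catch_warnings():
            # all-NaN columns (off-chromosome) stay NaN by design
            warnings.simplefilter("ignore", RuntimeWarning)
            rows[r] = np.nanmean(per_bp.reshape(n_cols, bin_size), axis=1)
        ids.append(iv.name or f"{iv.chrom}:{iv.start}-{iv.end}")
    return SignalMatrix(rows, window, bin_size, peak_ids=ids)


def mean_profile(matrix: SignalMatrix) -> np.ndarray:
    """Per-column mean over peaks, excluding missing values."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(matrix.values, axis=0)


def sample_pca(
    tracks: Sequence[SignalTrack],
    regions: PeakSet,
    n_components: Optional[int] = None,
) -> Dict[str, np.ndarray]:
    """PCA of samples using mean signal per region as features.

    Deterministic up to sign; sign is fixed by making each component's
    largest-magnitude loading positive. Returns coordinates, explained
    variance (and ratio), and region loadings.
    """
    if len(tracks) < 2:
        raise ValueError("need at least 2 tracks")
    if len(regions) < 2:
        raise ValueError("need at least 2 regions")
    feats = np.zeros((len(tracks), len(regions)))
    for s, track in enumerate(tracks):
        for r, iv in enumerate(regions):
            vals = [
                track.value_at(iv.chrom, p) for p in range(iv.start, iv.end)
            ]
            vals = [v for v in vals if not np.isnan(v)]
            feats[s, r] = float(np.mean(vals)) if vals else 0.0
    centered = feats - feats.mean(axis=0, keepdims=True)
    u, svals, vt = np.linalg.svd(centered, full_matrices=False)
    k = min(
        n_components or len(svals), len(svals)
    )
    u, svals, vt = u[:, :k], svals[:k], vt[:k]
    for comp in range(k):
        j = np.argmax(np.abs(vt[comp]))
        if vt[comp, j] < 0:
            vt[comp] *= -1
            u[:, comp] *= -1
    coords = u * svals
    n = feats.shape[0]
    explained = svals**2 / (n - 1)
    total_var = centered.var(axis=0, ddof=1).sum()
    ratio = explained / total_var if total_var > 0 else np.zeros_like(explained)
    return {
        "coordinates": coords,
        "explained_variance": explained,
        "explained_variance_ratio": ratio,
        "loadings": vt,
        "sample_ids": [t.sample_id for t in tracks],
    }
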