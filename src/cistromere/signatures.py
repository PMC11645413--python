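"""Gene signatures: surrogate differential expression, signature
derivation, z-score signature scoring, over-representation testing, and
quartile stratification.

Scoring implements score_s = sum(z[up, s]) - sum(z[down, s]) with
z-scores computed gene-wise across the scored cohort using the sample
standard deviation (n-1 divisor). The surrogate DE test (Welch t +
Benjamini-Hochberg) is an explicit stand-in for external DE tools and is
meant for synthetic testing only.
"""
from __future__ import annotations

import logging
import os
from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Set

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GeneSignature",
    "surrogate_de",
    "derive_signature",
    "score_signature",
    "ora_fisher",
    "quartile_stratify",
    "read_gmt",
    "write_gmt",
]

logger = logging.getLogger(__name__)


@dataclass
class GeneSignature:
    name: str
    up_genes: Set[str]
    down_genes: Set[str]

    def __post_init__(self):
        self.up_genes = set(self.up_genes)
        self.down_genes = set(self.down_genes)
        if self.up_genes & self.down_genes:
            raise ValueError(
                f"{self.name}: up and down sets overlap: "
                f"{sorted(self.up_genes & self.down_genes)[:5]}"
            )
        if not self.up_genes and not self.down_genes:
            raise ValueError(f"{self.name}: both gene sets are empty")


def surrogate_de(
    expr: pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
) -> pd.DataFrame:
    """Per-gene Welch t-test on log2 values between two sample groups.

    log2FC = mean(B) - mean(A); p-values BH-adjusted. Columns: gene,
    log2fc, pvalue, padj.
    """
    group_a, group_b = list(group_a), list(group_b)
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least 2 samples")
    a = expr[group_a].to_numpy(dtype=float)
    b = expr[group_b].to_numpy(dtype=float)
    log2fc = b.mean(axis=1) - a.mean(axis=1)
    res = stats.ttest_ind(b, a, axis=1, equal_var=False)
    pvals = np.where(np.isnan(res.pvalue), 1.0, res.pvalue)
    padj = multipletests(pvals, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "gene": expr.index,
            "log2fc": log2fc,
            "pvalue": pvals,
            "padj": padj,
        }
    ).set_index("gene", drop=False)


def derive_signature(
    de: pd.DataFrame,
    lfc_cut: float = 1.0,
    padj_cut: float = 0.05,
    name: str = "signature",
) -> GeneSignature:
    """Threshold a DE table into up/down signature gene sets."""
    sig = de[de["padj"] <= padj_cut]
    up = set(sig.loc[sig["log2fc"] >= lfc_cut, "gene"])
    down = set(sig.loc[sig["log2fc"] <= -lfc_cut, "gene"])
    if not up and not down:
        raise ValueError(
            f"no genes pass padj <= {padj_cut} and |log2fc| >= {lfc_cut}; "
            "relax the thresholds or check the DE input"
        )
    return GeneSignature(name, up, down)


def score_signature(
    expr: pd.DataFrame,
    signature: GeneSignature,
    method: str = "zscore",
) -> pd.Series:
    """Per-sample signature score over the cohort in ``expr``
    (genes x samples, log2 scale).

    method='zscore' (default): sum of gene-wise z-scores (sample sd,
    ddof=1) over up-genes minus down-genes. method='raw': sums raw log2
    values instead (summed-fold-change style variant). Genes absent from
    the cohort or with zero variance are dropped (count logged).
    """
    if expr.shape[1] < 3:
        raise ValueError("scoring needs at least 3 samples")
    if method not in ("zscore", "raw"):
        raise ValueError(f"unknown scoring method {method!r}")
    wanted = signature.up_genes | signature.down_genes
    present = wanted & set(expr.index)
    missing = len(wanted) - len(present)
    if missing:
        logger.info(
            "%s: %d/%d signature genes absent from cohort; dropped",
            signature.name, missing, len(wanted),
        )
    if not present:
        raise ValueError(
            f"{signature.name}: no signature gene present in the cohort"
        )
    sub = expr.loc[sorted(present)].astype(float)
    if method == "zscore":
        sd = sub.std(axis=1, ddof=1)
        keep = sd > 0
        if (~keep).any():
            logger.info(
                "%s: dropped %d zero-variance genes",
                signature.name, int((~keep).sum()),
            )
        sub = sub[keep]
        if sub.empty:
            raise ValueError(
                f"{signature.name}: all signature genes have zero variance"
            )
        z = sub.sub(sub.mean(axis=1), axis=0).div(sd[keep], axis=0)
    else:
        z = sub
    up = [g for g in z.index if g in signature.up_genes]
    down = [g for g in z.index if g in signature.down_genes]
    scores = z.loc[up].sum(axis=0) - z.loc[down].sum(axis=0)
    scores.name = signature.name
    return scores


def ora_fisher(
    de_hits: Iterable[str],
    pathway: Iterable[str],
    universe: Iterable[str],
) -> Dict[str, float]:
    """Over-representation of ``de_hits`` in ``pathway`` within
    ``universe``: two-sided Fisher exact test on the 2x2 table, sample
    odds ratio."""
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    hits = set(de_hits) & universe
    path = set(pathway) & universe
    a = len(hits & path)
    b = len(hits - path)
    c = len(path - hits)
    d = len(universe) - a - b - c
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    odds = (a * d) / (b * c) if b * c > 0 else float("inf")
    return {
        "odds_ratio": float(odds),
        "pvalue": float(p),
        "table": [[a, b], [c, d]],
    }


def quartile_stratify(scores: pd.Series | Sequence[float]) -> List[str]:
    """Label each sample Q1 (lowest) .. Q4 (highest) by quartile breaks at
    the 25/50/75th percentiles (linear interpolation); ties go to the
    lower quartile."""
    vals = np.asarray(
        scores.values if isinstance(scores, pd.Series) else scores, dtype=float
    )
    if len(vals) < 4:
        raise ValueError("need at least 4 samples to stratify")
    if np.all(vals == vals[0]):
        raise ValueError("all scores identical: cannot stratify")
    q25, q50, q75 = np.quantile(vals, [0.25, 0.5, 0.75])
    idx = 1 + (vals > q25).astype(int) + (vals > q50) + (vals > q75)
    return [f"Q{i}" for i in idx]


# ---------------------------------------------------------------------------
# GMT I/O (two entries per signature: NAME_UP, NAME_DN)
# ---------------------------------------------------------------------------

def write_gmt(
    signatures: Sequence[GeneSignature], path: str | os.PathLike
) -> None:
    with open(path, "w") as fh:
        for sig in signatures:
            fh.write(
                "\t".join([f"{sig.name}_UP", "na", *sorted(sig.up_genes)]) + "\n"
            )
            fh.write(
                "\t".join([f"{sig.name}_DN", "na", *sorted(sig.down_genes)])
                + "\n"
            )


def read_gmt(path: str | os.PathLike) -> List[GeneSignature]:
    halves: Dict[str, Dict[str, Set[str]]] = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 2 or not fields[0]:
                continue
            entry, genes = fields[0], set(g for g in fields[2:] if g)
            if entry.endswith("_UP"):
                halves.setdefault(entry[:-3], {})["up"] = genes
            elif entry.endswith("_DN"):
                halves.setdefault(entry[:-3], {})["down"] = genes
            else:
                halves.setdefault(entry, {})["up"] = genes
    return [
        GeneSignature(name, parts.get("up", set()), parts.get("down", set()))
        for name, parts in halves.items()
    ]
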