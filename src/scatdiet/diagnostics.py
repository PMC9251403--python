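"""Artifact diagnostics: sequence distances and read-count structure.

If apparent diet detections were sequencing artifacts of the host's own
DNA, the offending MOTU sequences would sit a mutation or two away from the
host's, and their read counts would track host read counts.  Two checks
address this: pairwise edit distances between host-assigned and diet-
assigned MOTU sequences, and the joint distribution of per-PCR host vs
target read counts (quadrant occupancy on a log10(reads+1) scale, with an
upper-quantile regression over the target-positive component).
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib
import numpy as np
import pandas as pd
from scipy import sparse
from scipy.optimize import linprog
from scipy.stats import spearmanr

from .tables import MOTUTable


def log10p1(counts) -> np.ndarray:
    """log10(reads + 1), the transform used for all read-count plots."""
    return np.log10(np.asarray(counts, float) + 1.0)


def edit_distance_matrix(
    seqs_a: list[str], seqs_b: list[str]
) -> tuple[np.ndarray, dict[str, float]]:
    """Levenshtein distances (unit costs) for every A x B pair, with summary."""
    if not seqs_a or not seqs_b:
        raise ValueError("sequence sets must be non-empty")
    mat = np.zeros((len(seqs_a), len(seqs_b)), dtype=int)
    for i, a in enumerate(seqs_a):
        for j, b in enumerate(seqs_b):
            mat[i, j] = edlib.align(a, b, mode="NW")["editDistance"]
    flat = mat.ravel().astype(float)
    summary = {
        "mean": float(flat.mean()),
        "sd": float(flat.std(ddof=1)) if flat.size > 1 else 0.0,
        "min": float(flat.min()),
        "max": float(flat.max()),
    }
    return mat, summary


@dataclass(frozen=True)
class ReadPairSet:
    """Per-PCR (host reads, target reads) pairs for one target taxon."""

    host_reads: np.ndarray
    target_reads: np.ndarray

    def __post_init__(self) -> None:
        if len(self.host_reads) != len(self.target_reads):
            raise ValueError("host and target vectors differ in length")
        if (self.host_reads < 0).any() or (self.target_reads < 0).any():
            raise ValueError("read counts must be non-negative")


def read_pairs(
    table: MOTUTable, host_taxon: str, target_taxon: str,
    samples: list[str] | None = None,
) -> ReadPairSet:
    """Extract per-PCR host/target read pairs from a merged taxon table."""
    from .host_diet import taxon_counts

    counts = taxon_counts(table)
    cols = list(counts.columns)
    if samples is not None:
        keep = set(samples)
        cols = [c for c in cols if table.pcr_index.loc[c, "sample_id"] in keep]
    host = counts.loc[host_taxon, cols].to_numpy() if host_taxon in counts.index \
        else np.zeros(len(cols), dtype=int)
    target = counts.loc[target_taxon, cols].to_numpy() if target_taxon in counts.index \
        else np.zeros(len(cols), dtype=int)
    return ReadPairSet(host_reads=host, target_reads=target)


def quadrant_summary(pairs: ReadPairSet) -> dict[str, float]:
    """Fractions of PCRs in the four zero/nonzero quadrants (sum to 1)."""
    h = pairs.host_reads > 0
    t = pairs.target_reads > 0
    n = len(h)
    if n == 0:
        raise ValueError("need at least one PCR")
    return {
        "both_zero": float((~h & ~t).sum()) / n,
        "target_only": float((~h & t).sum()) / n,
        "host_only": float((h & ~t).sum()) / n,
        "both_positive": float((h & t).sum()) / n,
    }


@dataclass(frozen=True)
class QuantileFit:
    tau: float
    intercept: float
    slope: float
    fraction_above: float
    n_points: int


def fit_quantile_regression(
    pairs: ReadPairSet, tau: float = 0.90, nonzero: str = "target",
) -> QuantileFit:
    """Quantile regression of log10(target+1) on log10(host+1).

    Restricted to the nonzero component: ``nonzero='target'`` keeps PCRs
    with target reads > 0 (the host may be zero); ``'both'`` additionally
    requires host reads > 0.  The pinball-loss minimizer is solved exactly
    as a linear program.
    """
    if not 0.0 < tau < 1.0:
        raise ValueError("tau must be in (0, 1)")
    mask = pairs.target_reads > 0
    if nonzero == "both":
        mask &= pairs.host_reads > 0
    elif nonzero != "target":
        raise ValueError("nonzero must be 'target' or 'both'")
    x = log10p1(pairs.host_reads[mask])
    y = log10p1(pairs.target_reads[mask])
    n = len(x)
    if n < 10:
        raise ValueError("need at least 10 nonzero points")
    if np.allclose(x, x[0]):
        raise ValueError("all host read counts identical: slope undefined")
    # variables: a+, a-, b+, b-, u_1..u_n, v_1..v_n  (all >= 0)
    c = np.concatenate([np.zeros(4), np.full(n, tau), np.full(n, 1.0 - tau)])
    A = sparse.hstack([
        sparse.csc_matrix(np.column_stack([np.ones(n), -np.ones(n), x, -x])),
        sparse.eye(n, format="csc"),
        -sparse.eye(n, format="csc"),
    ], format="csc")
    res = linprog(c, A_eq=A, b_eq=y, method="highs")
    if not res.success:
        raise RuntimeError(f"quantile LP failed: {res.message}")
    a = res.x[0] - res.x[1]
    b = res.x[2] - res.x[3]
    above = float(np.mean(y > a + b * x + 1e-9))
    return QuantileFit(tau=tau, intercept=float(a), slope=float(b),
                       fraction_above=above, n_points=n)


def max_read_share_curve(table: MOTUTable) -> pd.DataFrame:
    """Per PCR: total reads and the maximum single-row read count.

    On a curated (taxon-merged) table this is the max single-taxon count,
    the quantity whose dependence on total depth explains why strong hosts
    drag the ceiling of every taxon's counts upward.
    """
    totals = table.counts.sum(axis=0)
    maxima = table.counts.max(axis=0) if table.n_motus else totals * 0
    return pd.DataFrame({"pcr_id": table.counts.columns,
                         "total_reads": totals.to_numpy(int),
                         "max_taxon_reads": np.asarray(maxima, int)})


def max_share_correlation(table: MOTUTable) -> float:
    """Spearman correlation between per-PCR total and max taxon reads."""
    curve = max_read_share_curve(table)
    rho, _ = spearmanr(curve["total_reads"], curve["max_taxon_reads"])
    return float(rho)
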