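"""Host assignment by replicate voting, diet detection, and occurrence summaries.

A scat's depositor is identified from its three PCR replicates by a voting
rule: in each replicate the candidate host (from a configured host list) with
the strictly largest read count gets a vote, provided it holds at least 1% of
that replicate's reads; a host is assigned iff it collects two or more votes.

Diet items are then taken from the non-host taxa: a taxon is detected in a
sample when its mean relative read frequency across (non-empty) replicates
reaches the detection threshold (default 1%).  Per predator x prey, the
summary reports frequency of occurrence (%FO, share of positive samples) and
a modified relative read abundance (RRA, mean read percentage across positive
samples only).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .tables import MOTUTable

UNASSIGNED = "UNASSIGNED"


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding, matching conventional table formatting."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class HostAssignment:
    sample_id: str
    host_taxon: str                       # taxon name or UNASSIGNED
    votes: tuple[tuple[str, float], ...]  # per voting replicate: (host, share of PCR reads)


@dataclass(frozen=True)
class DietOccurrence:
    sample_id: str
    taxon: str
    mean_rel_freq: float  # percent, averaged across non-empty replicates
    detected: bool


@dataclass(frozen=True)
class DietSummary:
    predator: str
    prey: str
    n_occurrences: int
    n_samples: int
    fo_pct: float   # 100 * n_occurrences / n_samples, half-up to 2 dp
    rra_pct: float  # mean read % across positive samples, half-up to 2 dp


def taxon_counts(table: MOTUTable) -> pd.DataFrame:
    """Taxon x PCR read counts from an annotated (ideally merged) table."""
    if table.annotation is None:
        raise ValueError("table must be annotated")
    df = table.counts.copy()
    df.index = table.annotation["best_taxon"].values
    return df.groupby(level=0).sum()


def assign_host(
    sample_counts: pd.DataFrame,
    host_list: list[str],
    min_share: float = 0.01,
) -> HostAssignment:
    """Vote over PCR replicates; assign the host winning >= 2 votes.

    ``sample_counts``: taxa x replicate columns for one sample. In each
    replicate with nonzero reads, candidate hosts are compared by read count;
    a strict maximum holding >= ``min_share`` of the replicate's total reads
    earns one vote (ties or sub-threshold maxima earn none).
    """
    if sample_counts.shape[1] == 0:
        raise ValueError("sample has no PCR columns")
    if not host_list:
        raise ValueError("host list is empty")
    sample_id = sample_counts.columns[0].rsplit(".R", 1)[0]
    hosts_present = [h for h in host_list if h in sample_counts.index]
    votes: list[tuple[str, float]] = []
    for pcr in sample_counts.columns:
        total = int(sample_counts[pcr].sum())
        if total == 0 or not hosts_present:
            continue
        host_reads = sample_counts.loc[hosts_present, pcr]
        top = int(host_reads.max())
        winners = host_reads.index[host_reads == top]
        if top == 0 or len(winners) > 1:
            continue  # tie or no host reads: no vote
        share = top / total
        if share >= min_share:
            votes.append((winners[0], share))
    tally: dict[str, int] = {}
    for host, _ in votes:
        tally[host] = tally.get(host, 0) + 1
    winner = max(tally, key=tally.get) if tally else None
    host_taxon = winner if winner is not None and tally[winner] >= 2 else UNASSIGNED
    return HostAssignment(sample_id=sample_id, host_taxon=host_taxon, votes=tuple(votes))


def assign_all_hosts(
    table: MOTUTable, host_list: list[str], min_share: float = 0.01
) -> pd.DataFrame:
    """Apply the voting rule to every sample; one row per sample."""
    counts = taxon_counts(table)
    rows = []
    for sample in table.sample_ids():
        pcrs = table.pcrs_of_sample(sample)
        a = assign_host(counts[pcrs], host_list, min_share)
        rows.append({"sample_id": sample, "host": a.host_taxon, "votes": len(a.votes)})
    return pd.DataFrame(rows).set_index("sample_id")


def detect_diet_items(
    sample_counts: pd.DataFrame,
    host_taxon: str,
    detection_threshold: float = 1.0,
    denominator: str = "total",
) -> list[DietOccurrence]:
    """Per-taxon mean relative read frequency across replicates.

    Replicates with zero total reads are treated as failed amplifications
    and excluded from the average (missing data, not absence).  The
    ``denominator`` is either ``"total"`` (all reads of the PCR, host
    included) or ``"diet"`` (non-host reads only).
    """
    if denominator not in ("total", "diet"):
        raise ValueError("denominator must be 'total' or 'diet'")
    sample_id = sample_counts.columns[0].rsplit(".R", 1)[0]
    diet_taxa = [t for t in sample_counts.index if t != host_taxon]
    shares = {t: [] for t in diet_taxa}
    for pcr in sample_counts.columns:
        col = sample_counts[pcr]
        denom = int(col.sum()) if denominator == "total" else int(col[diet_taxa].sum())
        if int(col.sum()) == 0:
            continue  # failed PCR: excluded from the average
        for t in diet_taxa:
            shares[t].append(100.0 * col[t] / denom if denom > 0 else 0.0)
    out = []
    for t in diet_taxa:
        mean = float(np.mean(shares[t])) if shares[t] else 0.0
        out.append(DietOccurrence(
            sample_id=sample_id, taxon=t, mean_rel_freq=mean,
            detected=mean >= detection_threshold,
        ))
    return out


def detect_all_diet_items(
    table: MOTUTable,
    assignments: pd.DataFrame,
    detection_threshold: float = 1.0,
    denominator: str = "total",
) -> pd.DataFrame:
    """Occurrence matrix for all host-assigned samples.

    Returns a long DataFrame [sample_id, taxon, mean_rel_freq, detected]
    covering every assigned sample x non-host taxon pair.
    """
    counts = taxon_counts(table)
    rows = []
    for sample, rec in assignments.iterrows():
        if rec["host"] == UNASSIGNED:
            continue
        pcrs = [p for p in table.pcrs_of_sample(sample) if p in counts.columns]
        for occ in detect_diet_items(counts[pcrs], rec["host"],
                                     detection_threshold, denominator):
            rows.append({
                "sample_id": occ.sample_id, "taxon": occ.taxon,
                "mean_rel_freq": occ.mean_rel_freq, "detected": occ.detected,
            })
    return pd.DataFrame(rows, columns=["sample_id", "taxon", "mean_rel_freq", "detected"])


def summarize_diet(
    occurrences: pd.DataFrame,
    assignments: pd.DataFrame,
    predator: str,
    prey: str,
) -> DietSummary:
    """%FO and modified RRA for one predator x prey pair."""
    pred_samples = assignments.index[assignments["host"] == predator]
    n_samples = len(pred_samples)
    if n_samples == 0:
        raise ValueError(f"no samples assigned to predator {predator!r}")
    sub = occurrences[
        occurrences["sample_id"].isin(pred_samples) & (occurrences["taxon"] == prey)
    ]
    positives = sub[sub["detected"]]
    n_occ = len(positives)
    fo = round_half_up(100.0 * n_occ / n_samples)
    rra = round_half_up(float(positives["mean_rel_freq"].mean())) if n_occ else 0.0
    return DietSummary(predator=predator, prey=prey, n_occurrences=n_occ,
                       n_samples=n_samples, fo_pct=fo, rra_pct=rra)


def diet_summary_table(
    occurrences: pd.DataFrame, assignments: pd.DataFrame
) -> pd.DataFrame:
    """Occurrence summary for every observed predator x prey combination."""
    rows = []
    predators = sorted(set(assignments["host"]) - {UNASSIGNED})
    for predator in predators:
        pred_samples = assignments.index[assignments["host"] == predator]
        taxa = sorted(set(occurrences.loc[
            occurrences["sample_id"].isin(pred_samples), "taxon"]))
        for prey in taxa:
            s = summarize_diet(occurrences, assignments, predator, prey)
            rows.append({
                "Predator": predator, "Prey": prey,
                "No_of_occurrences": s.n_occurrences, "N": s.n_samples,
                "FO_pct": s.fo_pct, "RRA_pct": s.rra_pct,
            })
    return pd.DataFrame(rows, columns=[
        "Predator", "Prey", "No_of_occurrences", "N", "FO_pct", "RRA_pct"])


def crosscheck_field_id(
    assignments: pd.DataFrame, metadata: pd.DataFrame
) -> tuple[pd.DataFrame, float]:
    """Contingency of field species guess vs genetic host, with agreement rate."""
    meta = metadata.set_index("sample_id")
    joined = assignments.join(meta["field_species_guess"], how="inner")
    joined = joined[joined["host"] != UNASSIGNED]
    if joined.empty:
        import warnings
        warnings.warn("no overlap between assignments and metadata")
        return pd.DataFrame(), float("nan")
    ct = pd.crosstab(joined["field_species_guess"], joined["host"])
    agreement = float((joined["field_species_guess"] == joined["host"]).mean())
    return ct, agreement
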