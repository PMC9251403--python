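"""MOTU curation cascade for metabarcoding read tables.

The raw MOTU x PCR table is cleaned by a fixed sequence of stages:

1. drop sequences seen only once in the whole dataset (singletons),
2. drop sequences with degenerate (non-ACGT) bases,
3. drop sequences outside the expected marker length (60-130 bp inclusive),
4. drop MOTUs that never reach 10 reads in any single PCR,
5. annotate each MOTU against a reference database, keeping hits with
   >= 95% global-alignment identity,
6. remove MOTUs annotated to known contaminant taxa (mostly primate DNA),
7. zero out trace counts attributable to tag jumps (cells below a small
   fraction of the sequence's dataset-wide total),
8. merge MOTUs annotated to the same taxon, folding redundant genus-level
   annotations into their single species-level representative.

Each stage only removes rows, zeroes cells, or merges rows, so MOTU and
read counts are non-increasing along the cascade (merging conserves reads
exactly); ``run_curation`` records a per-stage attrition log.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import edlib
import pandas as pd

from .tables import DNA_ALPHABET, IUPAC_ALPHABET, MOTUTable, ReferenceDB


@dataclass(frozen=True)
class FilterParams:
    """Thresholds of the curation cascade (units as named)."""

    min_len: int = 60                   # bp, inclusive
    max_len: int = 130                  # bp, inclusive
    min_reads_one_pcr: int = 10         # reads in the MOTU's best PCR
    min_identity: float = 95.0          # percent global-alignment identity
    contaminant_taxa: frozenset[str] = frozenset({"Homo sapiens"})
    # Tag-jump cut, as a fraction of the sequence's dataset-wide total.
    # Must sit between the expected trace share of a jumped read
    # (jump rate / number of PCRs) and the smallest genuine per-PCR share
    # (~1 / number of PCRs for a taxon present throughout); 1e-4 separates
    # the two across dataset sizes from tens to thousands of PCRs.
    tagjump_fraction: float = 1e-4
    detection_threshold: float = 1.0    # percent, consumed by diet detection

    def __post_init__(self) -> None:
        if not 0 < self.min_len <= self.max_len:
            raise ValueError("need 0 < min_len <= max_len")
        if self.min_reads_one_pcr < 1:
            raise ValueError("min_reads_one_pcr must be >= 1")
        if not 0.0 <= self.min_identity <= 100.0:
            raise ValueError("min_identity is a percentage")
        if not 0.0 <= self.tagjump_fraction < 1.0:
            raise ValueError("tagjump_fraction must be in [0, 1)")


def remove_singletons(table: MOTUTable) -> MOTUTable:
    """Drop MOTUs whose dataset-wide read total is 1 (true singletons)."""
    keep = table.counts.sum(axis=1) >= 2
    return table.subset(table.counts.index[keep])


def remove_degenerate(table: MOTUTable) -> MOTUTable:
    """Drop MOTUs whose sequence contains IUPAC ambiguity codes."""
    keep = []
    for motu_id, seq in table.sequences.items():
        chars = set(seq.upper())
        if not chars <= IUPAC_ALPHABET:
            raise ValueError(f"MOTU {motu_id} has non-IUPAC characters")
        keep.append(chars <= DNA_ALPHABET)
    return table.subset(table.sequences.index[keep])


def filter_length(table: MOTUTable, params: FilterParams) -> MOTUTable:
    """Keep MOTUs with min_len <= length <= max_len (bounds inclusive)."""
    lengths = table.sequences.str.len()
    keep = (lengths >= params.min_len) & (lengths <= params.max_len)
    return table.subset(table.sequences.index[keep])


def filter_min_reads(table: MOTUTable, params: FilterParams) -> MOTUTable:
    """Keep MOTUs that reach ``min_reads_one_pcr`` reads in >= 1 PCR."""
    if table.counts.shape[1] == 0:
        return table.subset([])
    keep = table.counts.max(axis=1) >= params.min_reads_one_pcr
    return table.subset(table.counts.index[keep])


# -- taxonomic annotation ---------------------------------------------------

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


def alignment_identity(query: str, reference: str) -> float:
    """Percent identity under global (end-to-end) alignment, unit costs.

    Identity is matches / alignment columns, i.e. ``100 * (1 - d / L)``
    with ``d`` the Levenshtein distance and ``L`` the number of columns of
    an optimal global alignment.
    """
    res = edlib.align(query, reference, mode="NW", task="path")
    matches = 0
    length = 0
    for num, op in _CIGAR_RE.findall(res["cigar"]):
        num = int(num)
        length += num
        if op == "=":
            matches += num
    return 100.0 * matches / length


def _best_hit(seq: str, db: ReferenceDB) -> tuple[str | None, float]:
    """Best reference taxon and identity; ties resolved by shared genus."""
    best: list[str] = []
    best_id = -1.0
    for taxon, ref in db.sequences.items():
        ident = alignment_identity(seq, ref)
        if ident > best_id + 1e-12:
            best, best_id = [taxon], ident
        elif abs(ident - best_id) <= 1e-12:
            best.append(taxon)
    if len(best) == 1:
        return best[0], best_id
    genera = {t.split()[0] for t in best}
    if len(genera) == 1:
        # lowest common ancestor of same-genus ties is the genus itself
        return genera.pop(), best_id
    return None, best_id  # ambiguous across genera: drop


def annotate_taxonomy(
    table: MOTUTable, reference_db: ReferenceDB, params: FilterParams
) -> MOTUTable:
    """Assign each MOTU its best reference taxon; drop weak or ambiguous hits."""
    if len(reference_db) == 0:
        raise ValueError("reference database is empty")
    taxa, idents, keep = [], [], []
    for motu_id, seq in table.sequences.items():
        taxon, ident = _best_hit(seq, reference_db)
        ok = taxon is not None and ident >= params.min_identity
        keep.append(ok)
        if ok:
            taxa.append(taxon)
            idents.append(ident)
    kept_ids = table.sequences.index[keep]
    out = table.subset(kept_ids)
    out.annotation = pd.DataFrame(
        {"best_taxon": taxa, "identity": idents}, index=kept_ids
    )
    return out


def remove_contaminants(table: MOTUTable, params: FilterParams) -> MOTUTable:
    """Drop MOTUs annotated to contaminant taxa (e.g. human DNA)."""
    if table.annotation is None:
        raise ValueError("table must be annotated before contaminant removal")
    keep = ~table.annotation["best_taxon"].isin(params.contaminant_taxa)
    return table.subset(table.annotation.index[keep])


def remove_tag_jumps(table: MOTUTable, params: FilterParams) -> MOTUTable:
    """Zero per-PCR counts below ``tagjump_fraction`` of the MOTU's total.

    Trace counts of a sequence outside its true PCRs are the signature of
    tag jumping during multiplexed sequencing; the conventional cure is a
    per-sequence relative-abundance cut. Rows reduced to all zeros are
    dropped.
    """
    counts = table.counts.copy()
    totals = counts.sum(axis=1)
    cutoff = params.tagjump_fraction * totals
    zero_mask = counts.lt(cutoff, axis=0)
    counts[zero_mask] = 0
    out = MOTUTable(
        sequences=table.sequences.copy(),
        counts=counts,
        annotation=table.annotation.copy() if table.annotation is not None else None,
        pcr_index=table.pcr_index,
    )
    # drop only rows the rule itself reduced to zero
    keep = (counts.sum(axis=1) > 0) | (table.counts.sum(axis=1) == 0)
    return out.subset(counts.index[keep])


def merge_taxa(table: MOTUTable) -> MOTUTable:
    """Collapse to one row per taxon, summing per-PCR counts.

    A genus-level annotation (single-word taxon) is folded into its species
    when exactly one species of that genus is present in the table;
    otherwise it stays at genus. The representative sequence of a merged
    row is the member MOTU with the highest dataset-wide read total; its
    identity is the read-weighted best among members.
    """
    if table.annotation is None:
        raise ValueError("table must be annotated before merging")
    taxon_of = table.annotation["best_taxon"].copy()
    names = set(taxon_of)
    for name in sorted(names):
        if " " not in name:  # genus-level
            descendants = {t for t in names if t != name and t.split()[0] == name}
            if len(descendants) == 1:
                taxon_of[taxon_of == name] = descendants.pop()
    merged_rows = {}
    for taxon in sorted(set(taxon_of)):
        members = taxon_of.index[taxon_of == taxon]
        counts = table.counts.loc[members].sum(axis=0)
        rep = table.counts.loc[members].sum(axis=1).idxmax()
        merged_rows[taxon] = (counts, table.sequences[rep],
                              float(table.annotation.loc[rep, "identity"]))
    index = list(merged_rows)
    return MOTUTable(
        sequences=pd.Series([merged_rows[t][1] for t in index], index=index, name="sequence"),
        counts=pd.DataFrame([merged_rows[t][0] for t in index], index=index).astype(int),
        annotation=pd.DataFrame(
            {"best_taxon": index, "identity": [merged_rows[t][2] for t in index]},
            index=index,
        ),
        pcr_index=table.pcr_index,
    ) if index else MOTUTable(
        sequences=pd.Series([], dtype=str, name="sequence"),
        counts=pd.DataFrame(index=pd.Index([]), columns=table.counts.columns, dtype=int),
        annotation=pd.DataFrame(columns=["best_taxon", "identity"]),
        pcr_index=table.pcr_index,
    )


STAGES = (
    "remove_singletons",
    "remove_degenerate",
    "filter_length",
    "filter_min_reads",
    "annotate_taxonomy",
    "remove_contaminants",
    "remove_tag_jumps",
    "merge_taxa",
)


def run_curation(
    table: MOTUTable,
    reference_db: ReferenceDB,
    params: FilterParams | None = None,
) -> tuple[MOTUTable, pd.DataFrame]:
    """Run the full cascade; return the curated table and the attrition log.

    The log has one row per stage: MOTUs and total reads before and after.
    """
    params = params or FilterParams()
    stage_funcs = {
        "remove_singletons": lambda t: remove_singletons(t),
        "remove_degenerate": lambda t: remove_degenerate(t),
        "filter_length": lambda t: filter_length(t, params),
        "filter_min_reads": lambda t: filter_min_reads(t, params),
        "annotate_taxonomy": lambda t: annotate_taxonomy(t, reference_db, params),
        "remove_contaminants": lambda t: remove_contaminants(t, params),
        "remove_tag_jumps": lambda t: remove_tag_jumps(t, params),
        "merge_taxa": lambda t: merge_taxa(t),
    }
    log_rows = []
    current = table
    for stage in STAGES:
        motus_in, reads_in = current.n_motus, current.total_reads
        current = stage_funcs[stage](current)
        log_rows.append({
            "stage": stage,
            "motus_in": motus_in, "motus_out": current.n_motus,
            "reads_in": reads_in, "reads_out": current.total_reads,
        })
    return current, pd.DataFrame(log_rows)
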