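"""Core data containers and text-format I/O.

The central object is :class:`MOTUTable`: one row per molecular operational
taxonomic unit (MOTU, a dereplicated unique sequence), one integer read-count
column per PCR amplification.  PCR column names follow the convention
``"<sample_id>.R<k>"`` with ``k`` the replicate number (1-3), from which the
sample/replicate index is derived.

All on-disk formats are plain text: TSV for tables, FASTA for sequences
(reference headers are ``>taxon_name|rank``).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_PCR_RE = re.compile(r"^(?P<sample>.+)\.R(?P<rep>[0-9]+)$")

DNA_ALPHABET = frozenset("ACGT")
IUPAC_ALPHABET = frozenset("ACGTRYSWKMBDHVN")


def parse_pcr_id(pcr_id: str) -> tuple[str, int]:
    """Split a PCR column name into (sample_id, replicate number)."""
    m = _PCR_RE.match(pcr_id)
    if m is None:
        raise ValueError(f"malformed PCR id {pcr_id!r}; expected '<sample>.R<k>'")
    return m.group("sample"), int(m.group("rep"))


def build_pcr_index(pcr_ids) -> pd.DataFrame:
    """Build the PCR -> (sample, replicate) index from column names."""
    rows = [parse_pcr_id(p) for p in pcr_ids]
    idx = pd.DataFrame(rows, index=list(pcr_ids), columns=["sample_id", "replicate"])
    dup = idx.duplicated(subset=["sample_id", "replicate"])
    if dup.any():
        raise ValueError(f"duplicate sample/replicate pairs: {list(idx.index[dup])}")
    return idx


@dataclass
class MOTUTable:
    """MOTU sequences with per-PCR read counts and optional taxonomy.

    Parameters
    ----------
    sequences
        Series of IUPAC DNA strings indexed by motu_id.
    counts
        Integer DataFrame, rows = motu_id, columns = PCR ids.
    annotation
        Optional DataFrame indexed like ``sequences`` with columns
        ``best_taxon`` and ``identity`` (percent, 0-100); present only
        after taxonomic annotation.
    """

    sequences: pd.Series
    counts: pd.DataFrame
    annotation: pd.DataFrame | None = None
    pcr_index: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not self.sequences.index.equals(self.counts.index):
            raise ValueError("sequences and counts must share the same MOTU index")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("read counts must be non-negative")
        if self.pcr_index is None:
            self.pcr_index = build_pcr_index(self.counts.columns)
        for seq in self.sequences:
            if not seq:
                raise ValueError("empty MOTU sequence")

    # -- basic accessors ---------------------------------------------------
    @property
    def n_motus(self) -> int:
        return len(self.sequences)

    @property
    def total_reads(self) -> int:
        return int(self.counts.to_numpy().sum())

    def sample_ids(self) -> list[str]:
        return list(dict.fromkeys(self.pcr_index["sample_id"]))

    def pcrs_of_sample(self, sample_id: str) -> list[str]:
        mask = self.pcr_index["sample_id"] == sample_id
        return list(self.pcr_index.index[mask])

    def subset(self, motu_ids) -> "MOTUTable":
        ann = self.annotation.loc[motu_ids] if self.annotation is not None else None
        return MOTUTable(
            sequences=self.sequences.loc[motu_ids].copy(),
            counts=self.counts.loc[motu_ids].copy(),
            annotation=ann.copy() if ann is not None else None,
            pcr_index=self.pcr_index,
        )

    # -- I/O ---------------------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame({"motu_id": self.sequences.index, "sequence": self.sequences.values})
        df = pd.concat([df.set_index("motu_id"), self.counts], axis=1)
        if self.annotation is not None:
            df = pd.concat([df, self.annotation], axis=1)
        df.to_csv(path, sep="\t", index_label="motu_id")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "MOTUTable":
        df = pd.read_csv(path, sep="\t", index_col="motu_id")
        ann_cols = [c for c in ("best_taxon", "identity") if c in df.columns]
        count_cols = [c for c in df.columns if c != "sequence" and c not in ann_cols]
        annotation = df[ann_cols] if ann_cols else None
        return cls(
            sequences=df["sequence"].astype(str),
            counts=df[count_cols].astype(int),
            annotation=annotation,
        )


# -- reference database ----------------------------------------------------

@dataclass(frozen=True)
class ReferenceDB:
    """Reference sequences keyed by taxon name, with a rank per taxon."""

    sequences: dict[str, str]
    ranks: dict[str, str]

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ValueError("reference database is empty")
        for name, seq in self.sequences.items():
            bad = set(seq) - DNA_ALPHABET
            if bad:
                raise ValueError(
                    f"reference sequence for {name!r} contains non-ACGT characters {sorted(bad)}; "
                    "ambiguity codes are not accepted in references"
                )

    def __len__(self) -> int:
        return len(self.sequences)

    def to_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(Seq(seq), id=f"{name.replace(' ', '_')}|{self.ranks[name]}", description="")
            for name, seq in self.sequences.items()
        ]
        with open(path, "w") as fh:
            SeqIO.write(records, fh, "fasta")

    @classmethod
    def from_fasta(cls, path: str | Path) -> "ReferenceDB":
        sequences: dict[str, str] = {}
        ranks: dict[str, str] = {}
        for rec in SeqIO.parse(str(path), "fasta"):
            name, _, rank = rec.id.partition("|")
            name = name.replace("_", " ")
            sequences[name] = str(rec.seq).upper()
            ranks[name] = rank or ("species" if " " in name else "genus")
        return cls(sequences=sequences, ranks=ranks)
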