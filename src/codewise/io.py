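"""Readers and writers for the formats the framework consumes.

Transcript sequences travel as FASTA with ``gene=`` / ``class_code=``
header tokens; conserved-domain hits as the tab-separated "hits" dialect
of Batch CD-Search; expression matrices and annotation tables as plain
tab-separated files.  Sequences are stored in the DNA alphabet (U is
normalised to T on ingest) and every transcript carries a
Cuffcompare-style class code, from which the sense/antisense orientation
is derived (codes ``x`` and ``s`` are antisense).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: Cuffcompare-style transcript class codes used throughout.
CLASS_CODES = frozenset({"=", "j", "o", "c", "x", "s", "u", "-"})

#: Class codes denoting antisense orientation.
ANTISENSE_CODES = frozenset({"x", "s"})

_DNA_ALPHABET = frozenset("ACGTN")


@dataclass
class TranscriptRecord:
    """A stranded transcript sequence with its class code and gene of origin."""

    transcript_id: str
    gene_id: str = ""
    sequence: str = ""
    class_code: str = "="

    def __post_init__(self) -> None:
        seq = self.sequence.upper().replace("U", "T")
        if len(seq) < 1:
            raise ValueError(
                f"transcript {self.transcript_id!r}: sequence must be non-empty"
            )
        bad = set(seq) - _DNA_ALPHABET
        if bad:
            raise ValueError(
                f"transcript {self.transcript_id!r}: invalid sequence "
                f"characters {sorted(bad)}"
            )
        self.sequence = seq
        if self.class_code not in CLASS_CODES:
            warnings.warn(
                f"transcript {self.transcript_id!r}: unknown class code "
                f"{self.class_code!r} (known: {sorted(CLASS_CODES)}); keeping it",
                stacklevel=2,
            )

    @property
    def strand_note(self) -> str:
        """``"antisense"`` for class codes x/s, else ``"sense"``."""
        return "antisense" if self.class_code in ANTISENSE_CODES else "sense"

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class DomainHit:
    """One conserved-domain hit for a transcript's translated protein."""

    transcript_id: str
    domain_accession: str
    domain_name: str
    is_truncated: bool


def read_fasta(path: str | Path) -> list[TranscriptRecord]:
    """Read transcripts from FASTA.

    ``gene=`` and ``class_code=`` tokens in the description are parsed into
    the record; the class code defaults to ``"="`` when absent.  An empty
    file yields an empty list with a warning.
    """
    records: list[TranscriptRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        gene_id = ""
        class_code = "="
        for token in rec.description.split()[1:]:
            if token.startswith("gene="):
                gene_id = token[len("gene="):]
            elif token.startswith("class_code="):
                class_code = token[len("class_code="):]
        try:
            records.append(
                TranscriptRecord(rec.id, gene_id, str(rec.seq), class_code)
            )
        except ValueError as exc:
            raise ValueError(f"malformed FASTA record {rec.id!r}: {exc}") from exc
    if not records:
        warnings.warn(f"{path}: no FASTA records found", stacklevel=2)
    return records


def write_fasta(records: Iterable[TranscriptRecord], path: str | Path) -> None:
    """Write transcripts as FASTA, preserving gene/class-code header tokens."""
    seqs = []
    for r in records:
        desc = []
        if r.gene_id:
            desc.append(f"gene={r.gene_id}")
        desc.append(f"class_code={r.class_code}")
        seqs.append(SeqRecord(Seq(r.sequence), id=r.transcript_id,
                              description=" ".join(desc)))
    SeqIO.write(seqs, str(path), "fasta")


# Batch CD-Search "hits" dialect column names (matched case-insensitively,
# after stripping whitespace) -> canonical name.
_HIT_COLUMNS = {
    "query": "transcript_id",
    "accession": "domain_accession",
    "short name": "domain_name",
    "incomplete": "incomplete",
}

_TRUNCATION_TOKENS = {"n", "c", "nc", "cn", "incomplete", "partial"}


def _parse_query_id(value: str) -> str:
    # Batch CD-Search writes queries as e.g. "Q#1 - >transcript_id".
    value = str(value).strip()
    if ">" in value:
        value = value.rsplit(">", 1)[1]
    return value.split()[0] if value else value


def read_domain_hits(path: str | Path) -> list[DomainHit]:
    """Read a Batch CD-Search-style tab-separated hits table.

    The truncation column maps "N", "C", "NC", "incomplete" or "partial"
    (case-insensitive) to ``is_truncated=True``; "-" or empty to ``False``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment=None)
    lower = {c.strip().lower(): c for c in df.columns}
    missing = [k for k in _HIT_COLUMNS if k not in lower]
    if missing:
        raise ValueError(
            f"{path}: missing mandatory column(s) {missing}; "
            f"found columns {list(df.columns)}"
        )
    hits: list[DomainHit] = []
    for _, row in df.iterrows():
        trunc_raw = row[lower["incomplete"]]
        trunc = (
            str(trunc_raw).strip().lower() in _TRUNCATION_TOKENS
            if pd.notna(trunc_raw)
            else False
        )
        hits.append(
            DomainHit(
                transcript_id=_parse_query_id(row[lower["query"]]),
                domain_accession=str(row[lower["accession"]]).strip(),
                domain_name=str(row[lower["short name"]]).strip(),
                is_truncated=trunc,
            )
        )
    return hits


def write_domain_hits(hits: Iterable[DomainHit], path: str | Path) -> None:
    """Write hits back out in the same tab-separated dialect."""
    rows = [
        {
            "Query": h.transcript_id,
            "Accession": h.domain_accession,
            "Short name": h.domain_name,
            "Incomplete": "C" if h.is_truncated else "-",
        }
        for h in hits
    ]
    pd.DataFrame(rows, columns=["Query", "Accession", "Short name", "Incomplete"]
                 ).to_csv(path, sep="\t", index=False)


def hits_by_transcript(hits: Iterable[DomainHit]) -> dict[str, list[DomainHit]]:
    """Group a flat hit list by transcript id (order preserved)."""
    grouped: dict[str, list[DomainHit]] = {}
    for h in hits:
        grouped.setdefault(h.transcript_id, []).append(h)
    return grouped


def read_expression_matrix(path: str | Path) -> pd.DataFrame:
    """Read a transcripts x time-points FPKM matrix.

    First column holds transcript ids; remaining columns are time-point
    labels.  Values must be non-negative.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df = df.astype(float)
    if (df.values < 0).any():
        raise ValueError(f"{path}: negative FPKM values are not allowed")
    return df


def write_expression_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", index_label="transcript_id")


def filter_expressed(matrix: pd.DataFrame, threshold: float = 1.0) -> pd.DataFrame:
    """Keep transcripts whose FPKM sum across the time course exceeds ``threshold``.

    The inequality is strict: a row summing exactly to the threshold is
    dropped.  Row order is preserved; the operation is idempotent.
    """
    return matrix.loc[matrix.sum(axis=1) > threshold]


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Read the annotation table: transcript_id, in_mapman_bin (0/1), cpc_score.

    ``cpc_score`` may be NA; an absent score is kept as NaN so it stays
    distinguishable from 0.
    """
    df = pd.read_csv(path, sep="\t", index_col=0,
                     na_values=["NA", "na", ""], keep_default_na=True)
    if "in_mapman_bin" in df.columns:
        df["in_mapman_bin"] = df["in_mapman_bin"].fillna(0).astype(int)
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate transcript ids {dupes}")
    return df


def write_annotation(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index_label="transcript_id", na_rep="NA")
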