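"""Batch translation: longest AUG-to-stop open reading frame per transcript.

An ORF is a span that begins at an ATG and ends at the first in-frame
stop codon (TAA/TAG/TGA) downstream of that ATG, stop included.  Run-off
spans with no in-frame stop do not count, and a codon containing an
ambiguous base (N) encountered before any stop invalidates the
candidate.  Among all valid spans the longest wins; ties go to the
5'-most start.  Scanning is on the given strand only — transcripts are
assumed to be already stranded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from Bio.Seq import Seq

from .io import TranscriptRecord

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

#: Column order of the translation-statistics table.
STATS_COLUMNS = [
    "transcript_id",
    "transcript_len",
    "utr5_len",
    "orf_len",
    "orf_ratio",
    "utr5_ratio",
    "protein_len",
]


@dataclass(frozen=True)
class TranslationStats:
    """Translation statistics for one transcript.

    ``orf_len`` counts ATG through the stop codon inclusive, so a
    transcript that is exactly one ORF has ``orf_ratio == 1.0``;
    ``protein_len`` excludes the stop (``orf_len/3 - 1``).  A transcript
    with no valid ORF has all ORF fields zero and an empty protein.
    """

    transcript_id: str
    transcript_len: int
    utr5_len: int
    orf_len: int
    orf_ratio: float
    utr5_ratio: float
    protein_len: int
    protein_seq: str


def _zero_stats(transcript_id: str, n: int) -> TranslationStats:
    return TranslationStats(transcript_id, n, 0, 0, 0.0, 0.0, 0, "")


def find_longest_orf(record: TranscriptRecord | str,
                     transcript_id: str = "") -> TranslationStats:
    """Locate the longest ATG..stop ORF and report translation statistics.

    Accepts a :class:`TranscriptRecord` or a raw sequence string.
    """
    if isinstance(record, TranscriptRecord):
        seq, tid = record.sequence, record.transcript_id
    else:
        seq = str(record).upper().replace("U", "T")
        tid = transcript_id
    n = len(seq)

    # Per frame, walk codons once; for every codon index note the position
    # of the next terminating event (stop codon, or an N-containing codon
    # which invalidates any ORF that reaches it).
    best_start = -1
    best_len = 0
    for frame in range(3):
        # next_event[i] for codon starting at position i (same frame):
        # (pos, is_stop) or None if the frame runs off the end cleanly.
        starts = range(frame, n - 2, 3)
        events: dict[int, tuple[int, bool] | None] = {}
        nxt: tuple[int, bool] | None = None
        for i in reversed(starts):
            codon = seq[i:i + 3]
            if codon in STOP_CODONS:
                nxt = (i, True)
            elif "N" in codon:
                nxt = (i, False)
            events[i] = nxt
        for i in starts:
            if seq[i:i + 3] != "ATG":
                continue
            ev = events[i]
            if ev is None or not ev[1]:
                continue  # no in-frame stop, or blocked by an ambiguous codon
            orf_len = ev[0] + 3 - i
            if orf_len > best_len or (orf_len == best_len and i < best_start):
                best_len = orf_len
                best_start = i

    if best_len == 0:
        return _zero_stats(tid, n)
    protein = str(Seq(seq[best_start:best_start + best_len - 3]).translate())
    return TranslationStats(
        transcript_id=tid,
        transcript_len=n,
        utr5_len=best_start,
        orf_len=best_len,
        orf_ratio=best_len / n,
        utr5_ratio=best_start / n,
        protein_len=best_len // 3 - 1,
        protein_seq=protein,
    )


def batch_translate(
    records: Sequence[TranscriptRecord],
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Translate a batch of transcripts.

    Returns ``(proteins, stats)`` where ``proteins`` is a list of
    ``(transcript_id, protein_seq)`` pairs for every transcript with a
    nonzero-length protein (suitable for FASTA output) and ``stats`` is a
    table with one row per input transcript, zero-ORF rows included, in
    input order with exactly the columns of :data:`STATS_COLUMNS`.
    """
    if not records:
        raise ValueError("batch_translate requires a non-empty record list")
    all_stats = [find_longest_orf(r) for r in records]
    proteins = [(s.transcript_id, s.protein_seq) for s in all_stats
                if s.protein_seq]
    stats = pd.DataFrame(
        [{c: getattr(s, c) for c in STATS_COLUMNS} for s in all_stats],
        columns=STATS_COLUMNS,
    )
    return proteins, stats


def write_protein_fasta(proteins: Iterable[tuple[str, str]],
                        path) -> None:
    """Write (id, protein) pairs as FASTA."""
    with open(path, "w") as fh:
        for tid, prot in proteins:
            fh.write(f">{tid}\n{prot}\n")


def stats_by_transcript(stats: Iterable[TranslationStats]
                        ) -> dict[str, TranslationStats]:
    return {s.transcript_id: s for s in stats}
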