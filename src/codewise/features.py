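"""Assembly of the 12-slot coding-potential feature vector.

Per transcript the classifier consumes: sequence length, ORF ratio,
5'-UTR ratio, potential protein length, GC content, T/A and G/C ratios,
conserved-domain count, domain truncation ratio, minimum free energy of
the predicted secondary structure, and (optionally) a MapMan-bin
presence flag and a CPC score.

Structure energy is a pluggable backend: an adapter to ViennaRNA when
its Python binding is importable, otherwise a built-in base-pair
maximisation dynamic program that returns a pseudo-energy.  Both
backends preserve the discriminative ordering the classifier relies on
(more stable structure => lower energy); MFE values are treated as
opaque model units.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Protocol, Sequence

import pandas as pd

from .io import DomainHit, TranscriptRecord
from .orf import TranslationStats

#: Fixed column order of the feature table.  The last two are optional.
FEATURE_COLUMNS = [
    "transcript_len",
    "orf_ratio",
    "utr5_ratio",
    "protein_len",
    "gc_content",
    "ta_ratio",
    "gc_ratio",
    "n_domains",
    "truncation_ratio",
    "mfe",
    "in_mapman_bin",
    "cpc_score",
]

OPTIONAL_FEATURES = ["in_mapman_bin", "cpc_score"]


@dataclass(frozen=True)
class SequenceContent:
    """Nucleotide-content features for one sequence.

    When a ratio's denominator is zero it is clamped to 1 (the ratio then
    equals the numerator count) and the corresponding flag is set, so
    downstream scaling never sees non-finite values.
    """

    gc_content: float
    ta_ratio: float
    gc_ratio: float
    ta_clamped: bool = False
    gc_clamped: bool = False


def sequence_content(sequence: str) -> SequenceContent:
    """GC content (over non-N bases), T/A ratio and G/C ratio."""
    if not sequence:
        raise ValueError("sequence_content requires a non-empty sequence")
    seq = sequence.upper().replace("U", "T")
    a, c, g, t = (seq.count(b) for b in "ACGT")
    non_n = a + c + g + t
    gc_content = (g + c) / non_n if non_n else 0.0
    ta_clamped = a == 0
    gc_clamped = c == 0
    return SequenceContent(
        gc_content=gc_content,
        ta_ratio=t / max(a, 1),
        gc_ratio=g / max(c, 1),
        ta_clamped=ta_clamped,
        gc_clamped=gc_clamped,
    )


def domain_features(hits: Sequence[DomainHit],
                    dedupe: bool = False) -> tuple[int, float]:
    """Domain count and truncation ratio (truncated hits / total hits).

    With ``dedupe=True`` hits are collapsed to distinct accessions (an
    accession counts as truncated if any of its hits is).
    """
    ids = {h.transcript_id for h in hits}
    if len(ids) > 1:
        raise ValueError(f"hits span multiple transcripts: {sorted(ids)}")
    if dedupe:
        by_acc: dict[str, bool] = {}
        for h in hits:
            by_acc[h.domain_accession] = by_acc.get(h.domain_accession, False) or h.is_truncated
        n = len(by_acc)
        trunc = sum(by_acc.values())
    else:
        n = len(hits)
        trunc = sum(h.is_truncated for h in hits)
    return n, (trunc / n if n else 0.0)


class FoldingBackend(Protocol):
    """Deterministic, strand-specific folding energy oracle."""

    name: str

    def fold(self, sequence: str) -> float:
        """Return a single energy value <= 0 for the sequence."""
        ...


# Pseudo-energy contributions per closed base pair.
_PAIR_SCORES = {
    ("G", "C"): -3.0, ("C", "G"): -3.0,
    ("A", "T"): -2.0, ("T", "A"): -2.0,
    ("G", "T"): -1.0, ("T", "G"): -1.0,
}

#: Minimum number of unpaired bases enclosed by a hairpin-closing pair.
MIN_HAIRPIN_LOOP = 3


class NussinovBackend:
    """Base-pair maximisation pseudo-energy (O(n^3) dynamic program).

    Maximises the total (negative) pair score with pair contributions
    GC=-3, AU=-2, GU=-1 and a minimum hairpin loop of 3 unpaired bases.
    Intended for short sequences; long transcripts should use the
    ViennaRNA backend.
    """

    name = "builtin"

    def fold(self, sequence: str) -> float:
        if not sequence:
            raise ValueError("cannot fold an empty sequence")
        seq = sequence.upper().replace("U", "T")
        n = len(seq)
        if n <= MIN_HAIRPIN_LOOP + 1:
            return 0.0
        # E[i][j]: minimum pseudo-energy of subsequence i..j inclusive.
        E = [[0.0] * n for _ in range(n)]
        for span in range(MIN_HAIRPIN_LOOP + 1, n):
            for i in range(n - span):
                j = i + span
                best = E[i][j - 1]  # j unpaired
                for k in range(i, j - MIN_HAIRPIN_LOOP):
                    score = _PAIR_SCORES.get((seq[k], seq[j]))
                    if score is None:
                        continue
                    left = E[i][k - 1] if k > i else 0.0
                    inner = E[k + 1][j - 1] if k + 1 <= j - 1 else 0.0
                    cand = left + score + inner
                    if cand < best:
                        best = cand
                E[i][j] = best
        return E[0][n - 1]


class ViennaRNABackend:
    """Adapter to the ViennaRNA thermodynamic folder (kcal/mol)."""

    name = "viennarna"

    def __init__(self) -> None:
        import RNA  # noqa: F401 — deferred so the backend is optional
        self._rna = RNA

    def fold(self, sequence: str) -> float:
        if not sequence:
            raise ValueError("cannot fold an empty sequence")
        _, mfe = self._rna.fold(sequence.upper().replace("T", "U"))
        return min(float(mfe), 0.0)


def get_backend(name: str = "external") -> FoldingBackend:
    """Resolve a folding backend.

    ``"external"``/``"viennarna"`` selects ViennaRNA when importable
    (falling back to the built-in DP with a warning for plain
    ``"external"``); ``"builtin"`` always selects the DP.
    """
    if name == "builtin":
        return NussinovBackend()
    if name in ("external", "viennarna"):
        try:
            return ViennaRNABackend()
        except ImportError:
            if name == "viennarna":
                raise
            warnings.warn(
                "ViennaRNA binding not importable; using the built-in "
                "base-pair maximisation backend",
                stacklevel=2,
            )
            return NussinovBackend()
    raise ValueError(f"unknown folding backend {name!r}")


def compute_mfe(sequence: str, backend: FoldingBackend,
                transcript_id: str = "") -> float:
    """Fold one sequence with the given backend, surfacing failures clearly."""
    if not sequence:
        raise ValueError(
            f"transcript {transcript_id!r}: cannot fold an empty sequence"
        )
    try:
        return backend.fold(sequence)
    except ValueError:
        raise
    except Exception as exc:  # pragma: no cover - backend-specific failures
        raise RuntimeError(
            f"folding backend {backend.name!r} failed on transcript "
            f"{transcript_id!r}: {exc}"
        ) from exc


def build_feature_table(
    records: Sequence[TranscriptRecord],
    stats: Mapping[str, TranslationStats] | Iterable[TranslationStats],
    hits: Mapping[str, Sequence[DomainHit]] | None = None,
    annotations: pd.DataFrame | None = None,
    backend: FoldingBackend | None = None,
    dedupe_domains: bool = False,
) -> pd.DataFrame:
    """Assemble one feature row per transcript, indexed by transcript id.

    ``stats`` must cover every record (missing stats are an error);
    ``hits`` and ``annotations`` may be partial — a transcript absent
    from the hit table gets (0, 0) domain features, and one absent from
    the annotation table gets ``in_mapman_bin=0`` and a missing
    ``cpc_score``.
    """
    if not isinstance(stats, Mapping):
        stats = {s.transcript_id: s for s in stats}
    hits = hits or {}
    if backend is None:
        backend = get_backend("external")
    rows = []
    for rec in records:
        tid = rec.transcript_id
        if tid not in stats:
            raise ValueError(f"no translation stats for transcript {tid!r}")
        st = stats[tid]
        content = sequence_content(rec.sequence)
        n_dom, trunc = domain_features(hits.get(tid, []), dedupe=dedupe_domains)
        mapman = 0
        cpc = float("nan")
        if annotations is not None and tid in annotations.index:
            row = annotations.loc[tid]
            mapman = int(row.get("in_mapman_bin", 0))
            cpc = float(row.get("cpc_score", float("nan")))
        rows.append({
            "transcript_id": tid,
            "transcript_len": st.transcript_len,
            "orf_ratio": st.orf_ratio,
            "utr5_ratio": st.utr5_ratio,
            "protein_len": st.protein_len,
            "gc_content": content.gc_content,
            "ta_ratio": content.ta_ratio,
            "gc_ratio": content.gc_ratio,
            "n_domains": n_dom,
            "truncation_ratio": trunc,
            "mfe": compute_mfe(rec.sequence, backend, tid),
            "in_mapman_bin": mapman,
            "cpc_score": cpc,
        })
    return pd.DataFrame(rows, columns=["transcript_id", *FEATURE_COLUMNS]
                        ).set_index("transcript_id")


def read_feature_table(path) -> pd.DataFrame:
    """Read a tab-separated feature table indexed by transcript id."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_feature_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index_label="transcript_id", na_rep="NA")
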