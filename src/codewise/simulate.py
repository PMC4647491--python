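"""Synthetic transcripts, feature tables, domain hits and expression matrices.

The generator emulates the statistical structure the classifier and the
network analyses assume, so the whole framework can be exercised without
external downloads:

* coding transcripts are longer (length lognormal, median ~1,500 nt),
  carry a dominant ORF (ORF ratio near 0.7, short 5'-UTR), conserved
  domains (1-4 hits, each truncated with probability 0.1), more stable
  secondary structure (mean energy -371 model units vs -134 for
  noncoding) and a higher CPC-like score;
* noncoding transcripts are shorter (median ~600 nt), have short
  spurious ORFs (ratio near 0.2), long 5'-UTRs (~0.45), almost never a
  domain, and weaker structure;
* nucleotide content (GC content, T/A and G/C ratios) is deliberately
  drawn from the same distribution for both classes, so the classifier
  cannot lean on it;
* expression profiles follow three temporal archetypes over a 10-point
  developmental time course — an early-maturation decline, a mid-to-late
  plateau, and a final-day desiccation spike — with multiplicative
  lognormal noise and designated correlated sense–antisense pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import TranscriptRecord, DomainHit
from .orf import find_longest_orf
from .features import FEATURE_COLUMNS

ARCHETYPES = ("early", "mid_late", "dt")

# Base temporal profiles over 10 developmental time points, in relative
# units: early-maturation decline, mid-to-late plateau, day-55 spike.
_BASE_PROFILES = {
    "early": np.array([1.0, 0.85, 0.6, 0.35, 0.2, 0.12, 0.1, 0.1, 0.1, 0.1]),
    "mid_late": np.array([0.08, 0.1, 0.2, 0.45, 0.75, 0.95, 1.0, 1.0, 1.0, 1.0]),
    "dt": np.array([0.05, 0.05, 0.05, 0.05, 0.05, 0.05, 0.05, 0.05, 0.1, 1.0]),
}

# No-ATG stop cassette providing an in-frame stop in all three frames
# within the first 12 bases of a 3'-UTR.
_STOP_CASSETTE = "TAGATAGATAGA"

_STOPS = ("TAA", "TAG", "TGA")
_NON_STOP_CODONS = tuple(
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in _STOPS
)


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic generator, in one auditable place.

    Defaults encode the study conditions: a 3:1 coding:noncoding class
    ratio, per-class mean structure energies of -371 and -134 model
    units, the qualitative feature separations between classes, and a
    10-point time course.
    """

    n_coding: int = 3000
    n_noncoding: int = 1000
    seed: int = 42

    # structure energy (model units)
    coding_mfe_mean: float = -371.0
    coding_mfe_sd: float = 80.0
    noncoding_mfe_mean: float = -134.0
    noncoding_mfe_sd: float = 50.0

    # length distributions (lognormal, nt)
    coding_len_median: float = 1500.0
    coding_len_sigma: float = 0.45
    noncoding_len_median: float = 600.0
    noncoding_len_sigma: float = 0.5

    # ORF / 5'-UTR ratio Beta distributions
    coding_orf_beta: tuple[float, float] = (14.0, 6.0)      # mean 0.7
    noncoding_orf_beta: tuple[float, float] = (4.0, 16.0)   # mean 0.2
    coding_utr5_beta: tuple[float, float] = (2.0, 18.0)     # mean 0.1
    noncoding_utr5_beta: tuple[float, float] = (9.0, 11.0)  # mean 0.45

    # conserved domains
    coding_domain_range: tuple[int, int] = (1, 4)
    domain_truncation_prob: float = 0.1
    noncoding_no_domain_prob: float = 0.95

    # nucleotide content — identical for both classes by design
    gc_mean: float = 0.42
    gc_sd: float = 0.04
    base_ratio_sd: float = 0.15

    # annotation / CPC-like score
    coding_mapman_prob: float = 0.9
    noncoding_mapman_prob: float = 0.05
    cpc_like_noise_sd: float = 0.5

    # expression matrix
    timepoints: int = 10
    n_expression_transcripts: int = 300
    archetype_mix: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    expression_noise_sd: float = 0.25
    amplitude_log_mean: float = 3.0
    amplitude_log_sd: float = 1.0
    n_antisense_pairs: int = 30
    antisense_corr_sign: int = 1
    antisense_noise_sd: float = 0.1

    def __post_init__(self) -> None:
        if self.n_coding <= 0 or self.n_noncoding <= 0:
            raise ValueError("class counts must be positive")
        if self.timepoints < 3:
            raise ValueError("need at least 3 time points")
        if self.antisense_corr_sign not in (-1, 1):
            raise ValueError("antisense_corr_sign must be +1 or -1")


def benchmark_config(seed: int = 42, **overrides) -> GeneratorConfig:
    """The `benchmark` preset: 3,000 coding + 1,000 noncoding rows."""
    return GeneratorConfig(n_coding=3000, n_noncoding=1000, seed=seed,
                           **overrides)


def _cpc_like(orf_ratio: np.ndarray, protein_len: np.ndarray,
              noise: np.ndarray) -> np.ndarray:
    # Noisy monotone function of ORF ratio and protein length, mimicking
    # a coding-potential score that is largely redundant with those two.
    return -4.5 + 4.0 * orf_ratio + 1.8 * np.log10(protein_len + 1.0) + noise


def generate_feature_table(
    config: GeneratorConfig,
) -> tuple[pd.DataFrame, pd.Series]:
    """Sample a labelled feature table.

    Returns ``(features, labels)`` with coding rows first (ids ``C...``,
    label +1) followed by noncoding rows (ids ``N...``, label -1).
    Internal consistency constraints of the feature vector hold by
    construction: protein length follows from ORF ratio and length,
    ``utr5_ratio + orf_ratio <= 1``, truncation ratio is 0 without
    domains, and energies are clipped at 0.
    """
    rng = np.random.default_rng(config.seed)
    frames = []
    for label, n in ((1, config.n_coding), (-1, config.n_noncoding)):
        coding = label == 1
        length = rng.lognormal(
            np.log(config.coding_len_median if coding
                   else config.noncoding_len_median),
            config.coding_len_sigma if coding else config.noncoding_len_sigma,
            n)
        length = np.clip(np.round(length), 200, None).astype(int)
        a, b = config.coding_orf_beta if coding else config.noncoding_orf_beta
        orf_ratio = rng.beta(a, b, n)
        a, b = config.coding_utr5_beta if coding else config.noncoding_utr5_beta
        utr5_ratio = np.minimum(rng.beta(a, b, n), 1.0 - orf_ratio)
        orf_len = 3 * np.round(orf_ratio * length / 3).astype(int)
        orf_len = np.clip(orf_len, 6, length)
        orf_ratio = orf_len / length
        utr5_ratio = np.minimum(utr5_ratio, 1.0 - orf_ratio)
        protein_len = orf_len // 3 - 1

        if coding:
            lo, hi = config.coding_domain_range
            n_domains = rng.integers(lo, hi + 1, n)
        else:
            has = rng.random(n) >= config.noncoding_no_domain_prob
            n_domains = has.astype(int)
        n_trunc = rng.binomial(n_domains, config.domain_truncation_prob)
        truncation_ratio = np.where(n_domains > 0,
                                    n_trunc / np.maximum(n_domains, 1), 0.0)

        mfe_mean = config.coding_mfe_mean if coding else config.noncoding_mfe_mean
        mfe_sd = config.coding_mfe_sd if coding else config.noncoding_mfe_sd
        mfe = np.minimum(rng.normal(mfe_mean, mfe_sd, n), 0.0)

        gc = np.clip(rng.normal(config.gc_mean, config.gc_sd, n), 0.2, 0.7)
        ta = np.clip(rng.normal(1.0, config.base_ratio_sd, n), 0.3, None)
        gc_ratio = np.clip(rng.normal(1.0, config.base_ratio_sd, n), 0.3, None)

        mapman_p = (config.coding_mapman_prob if coding
                    else config.noncoding_mapman_prob)
        in_bin = (rng.random(n) < mapman_p).astype(int)
        cpc = _cpc_like(orf_ratio, protein_len.astype(float),
                        rng.normal(0.0, config.cpc_like_noise_sd, n))

        prefix = "C" if coding else "N"
        frames.append(pd.DataFrame({
            "transcript_len": length,
            "orf_ratio": orf_ratio,
            "utr5_ratio": utr5_ratio,
            "protein_len": protein_len,
            "gc_content": gc,
            "ta_ratio": ta,
            "gc_ratio": gc_ratio,
            "n_domains": n_domains,
            "truncation_ratio": truncation_ratio,
            "mfe": mfe,
            "in_mapman_bin": in_bin,
            "cpc_score": cpc,
        }, index=[f"{prefix}{i:05d}" for i in range(n)])[FEATURE_COLUMNS])
    features = pd.concat(frames)
    features.index.name = "transcript_id"
    labels = pd.Series(
        [1] * config.n_coding + [-1] * config.n_noncoding,
        index=features.index, name="label")
    return features, labels


def _random_no_atg(rng: np.random.Generator, n: int) -> str:
    """A random DNA string of length n guaranteed free of 'ATG'."""
    if n <= 0:
        return ""
    bases = rng.choice(list("ACGT"), size=n)
    s = list("".join(bases))
    for i in range(len(s) - 2):
        if s[i] == "A" and s[i + 1] == "T" and s[i + 2] == "G":
            s[i + 2] = "C"
    return "".join(s)


def _designed_transcript(rng: np.random.Generator, length: int,
                         orf_len: int, utr5_len: int) -> str:
    """Assemble UTR5 + designed ORF + stop-cassette-prefixed UTR3."""
    n_codons = orf_len // 3
    interior = "".join(
        _NON_STOP_CODONS[i]
        for i in rng.integers(0, len(_NON_STOP_CODONS), n_codons - 2))
    stop = _STOPS[rng.integers(0, 3)]
    orf = "ATG" + interior + stop
    utr3_len = length - utr5_len - orf_len
    if utr3_len >= len(_STOP_CASSETTE):
        utr3 = _STOP_CASSETTE + _random_no_atg(rng, utr3_len - len(_STOP_CASSETTE))
    else:
        utr3 = _random_no_atg(rng, utr3_len)
    return _random_no_atg(rng, utr5_len) + orf + utr3


def generate_transcript_fasta(
    config: GeneratorConfig,
) -> tuple[list[TranscriptRecord], list[DomainHit], pd.DataFrame]:
    """Generate sequences realising the per-class ORF geometry.

    Coding sequences embed a designed ATG..stop ORF of target length
    inside ATG-free UTRs (verified: the realised longest ORF is the
    designed one); noncoding sequences get a short designed ORF the same
    way, capping their realised ORF ratio.  Also emits a matching
    synthetic domain-hit list and a truth table of designed values.
    """
    rng = np.random.default_rng(config.seed + 1)
    records: list[TranscriptRecord] = []
    hits: list[DomainHit] = []
    truth_rows = []
    specs = [("C", 1, config.n_coding), ("N", -1, config.n_noncoding)]
    for prefix, label, count in specs:
        coding = label == 1
        for i in range(count):
            tid = f"{prefix}{i:05d}"
            gene = f"g{prefix}{i:05d}"
            for _attempt in range(50):
                median = (config.coding_len_median if coding
                          else config.noncoding_len_median)
                sigma = (config.coding_len_sigma if coding
                         else config.noncoding_len_sigma)
                length = int(np.clip(round(rng.lognormal(np.log(median), sigma)),
                                     300, 6000))
                a, b = (config.coding_orf_beta if coding
                        else config.noncoding_orf_beta)
                target_orf = rng.beta(a, b)
                a, b = (config.coding_utr5_beta if coding
                        else config.noncoding_utr5_beta)
                target_utr5 = min(rng.beta(a, b), 1.0 - target_orf)
                orf_len = int(np.clip(3 * round(target_orf * length / 3),
                                      9, 3 * (length // 3)))
                utr5_len = min(int(round(target_utr5 * length)),
                               length - orf_len)
                seq = _designed_transcript(rng, length, orf_len, utr5_len)
                realized = find_longest_orf(seq, tid)
                if realized.orf_len == orf_len and realized.utr5_len == utr5_len:
                    break
            else:  # pragma: no cover - vanishingly rare
                raise RuntimeError(f"could not realise designed ORF for {tid}")
            class_code = "=" if coding else ("u" if rng.random() < 0.5 else "x")
            records.append(TranscriptRecord(tid, gene, seq, class_code))
            truth_rows.append({
                "transcript_id": tid, "label": label,
                "designed_orf_len": orf_len, "designed_utr5_len": utr5_len,
                "transcript_len": length,
            })
            if coding:
                lo, hi = config.coding_domain_range
                n_dom = int(rng.integers(lo, hi + 1))
            else:
                n_dom = int(rng.random() >= config.noncoding_no_domain_prob)
            for d in range(n_dom):
                hits.append(DomainHit(
                    tid, f"pfam{rng.integers(0, 2000):05d}", f"dom{d}",
                    bool(rng.random() < config.domain_truncation_prob)))
    truth = pd.DataFrame(truth_rows).set_index("transcript_id")
    return records, hits, truth


def _profile(archetype: str, timepoints: int) -> np.ndarray:
    base = _BASE_PROFILES[archetype]
    if timepoints == base.size:
        return base.copy()
    x = np.linspace(0, 1, timepoints)
    return np.interp(x, np.linspace(0, 1, base.size), base)


def generate_expression_matrix(
    config: GeneratorConfig,
) -> tuple[pd.DataFrame, pd.Series, list[tuple[str, str]]]:
    """Sample an FPKM matrix of temporal archetypes.

    Returns ``(matrix, archetype_labels, antisense_pairs)``.  Each
    transcript follows one archetype profile scaled by a lognormal
    amplitude with multiplicative lognormal noise; the first
    ``n_antisense_pairs`` transcripts get a paired antisense partner that
    shares (sign +1) or mirrors (sign -1) the sense profile at high
    correlation.  With zero noise the curves are exact, so normalised
    profiles within an archetype are identical.
    """
    rng = np.random.default_rng(config.seed + 2)
    n = config.n_expression_transcripts
    t = config.timepoints
    mix = np.asarray(config.archetype_mix, dtype=float)
    mix = mix / mix.sum()
    counts = np.floor(mix * n).astype(int)
    counts[0] += n - counts.sum()
    labels = np.repeat(ARCHETYPES, counts)
    timecols = [f"day{d:02d}" for d in
                np.linspace(5, 55, t).round().astype(int)]

    rows, ids = [], []
    for i, arch in enumerate(labels):
        base = _profile(arch, t)
        amp = rng.lognormal(config.amplitude_log_mean, config.amplitude_log_sd)
        noise = np.exp(rng.normal(0.0, config.expression_noise_sd, t))
        rows.append(base * amp * noise)
        ids.append(f"T{i:05d}.1")
    label_map = dict(zip(ids, labels))

    pairs: list[tuple[str, str]] = []
    n_pairs = min(config.n_antisense_pairs, n)
    for i in range(n_pairs):
        sense_id = ids[i]
        anti_id = f"T{i:05d}.AS"
        sense_vals = rows[i]
        if config.antisense_corr_sign > 0:
            base_vals = sense_vals
        else:
            base_vals = sense_vals.max() + sense_vals.min() - sense_vals
        scale = rng.lognormal(0.0, 0.3)
        noise = np.exp(rng.normal(0.0, config.antisense_noise_sd, t))
        rows.append(base_vals * scale * noise)
        ids.append(anti_id)
        label_map[anti_id] = label_map[sense_id]
        pairs.append((sense_id, anti_id))

    matrix = pd.DataFrame(rows, index=ids, columns=timecols)
    matrix.index.name = "transcript_id"
    archetypes = pd.Series(label_map, name="archetype").loc[matrix.index]
    return matrix, archetypes, pairs


def write_benchmark(config: GeneratorConfig, outdir,
                    with_sequences: bool = True) -> dict[str, str]:
    """Write the full synthetic benchmark to ``outdir``.

    Emits features.tsv, labels.tsv, expression.tsv, truth.tsv and — when
    ``with_sequences`` — transcripts.fasta and domains.tsv.  Returns a
    mapping of artifact names to paths.
    """
    from .io import write_fasta, write_domain_hits, write_expression_matrix
    from .features import write_feature_table

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}

    features, labels = generate_feature_table(config)
    write_feature_table(features, outdir / "features.tsv")
    labels.to_frame().to_csv(outdir / "labels.tsv", sep="\t")
    artifacts["features"] = str(outdir / "features.tsv")
    artifacts["labels"] = str(outdir / "labels.tsv")

    matrix, archetypes, pairs = generate_expression_matrix(config)
    write_expression_matrix(matrix, outdir / "expression.tsv")
    artifacts["expression"] = str(outdir / "expression.tsv")

    truth = archetypes.to_frame()
    truth["antisense_partner"] = ""
    for sense, anti in pairs:
        truth.loc[sense, "antisense_partner"] = anti
    truth.to_csv(outdir / "truth.tsv", sep="\t")
    artifacts["truth"] = str(outdir / "truth.tsv")

    if with_sequences:
        records, hits, seq_truth = generate_transcript_fasta(config)
        write_fasta(records, outdir / "transcripts.fasta")
        write_domain_hits(hits, outdir / "domains.tsv")
        seq_truth.to_csv(outdir / "sequence_truth.tsv", sep="\t")
        artifacts["transcripts"] = str(outdir / "transcripts.fasta")
        artifacts["domains"] = str(outdir / "domains.tsv")
    return artifacts
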