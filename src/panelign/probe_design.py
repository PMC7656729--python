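"""Probe-pair design for hybridization panels.

A transcript is scanned in 100-nt windows.  Each window is profiled for
sequence pathologies (non-canonical bases, homopolymer runs, direct and
inverted repeats) and the survivors are split in half; each half is
thermodynamically tuned to the probe length (35–50 nt, anchored at the
half's 5' end) whose predicted melting temperature is closest to the target.
Candidates are then ranked by splice-isoform coverage (more isoforms hit is
better), cross-hybridization risk against the rest of the transcriptome
(lower is better), thermodynamic fit, and finally window position; the best
candidate wins.

Cross-hybridization is scored with exact 12-mer seeds plus ungapped
extension: for every seed shared with a transcript of another gene, the
best-scoring contiguous segment on that diagonal (match +1, mismatch −2) is
found and the score is the segment's match count divided by probe length —
0 with no shared seeds, 1.0 for a verbatim off-target copy.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

from .errors import ContractError, FormatError, NoCandidateError
from .thermo import (DEFAULT_NA_MOLAR, DEFAULT_STRAND_CONC_MOLAR,
                     is_canonical, melting_temperature, reverse_complement)

CANONICAL = set("ACGT")


@dataclass(frozen=True)
class TranscriptRecord:
    transcript_id: str
    gene: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ContractError(f"transcript {self.transcript_id!r}: empty sequence")


@dataclass(frozen=True)
class WindowProfile:
    start: int
    length: int
    gc_fraction: float
    noncanonical_count: int
    max_homopolymer_run: int
    has_direct_repeat: bool
    has_inverted_repeat: bool
    window_tm: float  # NaN when the window has non-canonical bases


@dataclass(frozen=True)
class Probe:
    sequence: str
    start: int   # 0-based offset on the transcript
    length: int
    tm: float


@dataclass(frozen=True)
class ProbePair:
    transcript_id: str
    gene: str
    probe_a: Probe
    probe_b: Probe
    window_start: int
    crosshyb_score: float
    isoform_coverage: float
    composite_rank_key: tuple

    @property
    def sequence(self) -> str:
        """Concatenated pair sequence (the probed target region)."""
        return self.probe_a.sequence + self.probe_b.sequence


@dataclass(frozen=True)
class ProbeDesignConfig:
    window_length: int = 100
    step: int = 1
    probe_min: int = 35
    probe_max: int = 50
    tm_target: float = 78.0
    seed_k: int = 12
    k_rep: int = 8
    run_max: int = 6
    na_molar: float = DEFAULT_NA_MOLAR
    strand_conc_molar: float = DEFAULT_STRAND_CONC_MOLAR


DEFAULT_CONFIG = ProbeDesignConfig()


# ---------------------------------------------------------------------------
# FASTA I/O
# ---------------------------------------------------------------------------

def read_transcripts(path: str | Path) -> list[TranscriptRecord]:
    """Read transcripts from FASTA; header format ``>transcript_id gene=GENE``."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        gene = None
        for token in rec.description.split():
            if token.startswith("gene="):
                gene = token[5:]
        if gene is None:
            raise FormatError(
                f"{path}: transcript {rec.id!r} lacks a gene=... header token")
        records.append(TranscriptRecord(transcript_id=rec.id, gene=gene,
                                        sequence=str(rec.seq).upper()))
    return records


def isoforms_of(transcriptome: Sequence[TranscriptRecord],
                gene: str) -> list[TranscriptRecord]:
    return [t for t in transcriptome if t.gene == gene]


# ---------------------------------------------------------------------------
# windowing and profiling
# ---------------------------------------------------------------------------

def enumerate_windows(t: TranscriptRecord, window_length: int = 100,
                      step: int = 1) -> list[int]:
    """Window start offsets: 0, step, 2*step, ... while the window fits."""
    if window_length > len(t.sequence):
        raise NoCandidateError(
            f"transcript {t.transcript_id!r}: length {len(t.sequence)} "
            f"< window {window_length}")
    return list(range(0, len(t.sequence) - window_length + 1, step))


def _max_run(seq: str) -> int:
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def _has_direct_repeat(seq: str, k: int) -> bool:
    # a >=k repeat occurring twice disjointly implies its length-k prefix does
    first: dict[str, int] = {}
    for i in range(len(seq) - k + 1):
        kmer = seq[i:i + k]
        if kmer in first:
            if i - first[kmer] >= k:
                return True
        else:
            first[kmer] = i
    return False


def _has_inverted_repeat(seq: str, k: int) -> bool:
    kmers = {seq[i:i + k] for i in range(len(seq) - k + 1)}
    return any(reverse_complement(km) in kmers for km in kmers
               if is_canonical(km))


def profile_window(window_sequence: str,
                   config: ProbeDesignConfig = DEFAULT_CONFIG,
                   start: int = 0) -> WindowProfile:
    """Profile one window's intrinsic sequence makeup."""
    seq = window_sequence
    canonical = [b for b in seq if b in CANONICAL]
    gc = (sum(b in "GC" for b in canonical) / len(canonical)) if canonical else 0.0
    noncanon = len(seq) - len(canonical)
    tm = float("nan")
    if noncanon == 0:
        tm = melting_temperature(seq, config.na_molar, config.strand_conc_molar)
    return WindowProfile(
        start=start,
        length=len(seq),
        gc_fraction=gc,
        noncanonical_count=noncanon,
        max_homopolymer_run=_max_run(seq) if seq else 0,
        has_direct_repeat=_has_direct_repeat(seq, config.k_rep),
        has_inverted_repeat=_has_inverted_repeat(seq, config.k_rep),
        window_tm=tm,
    )


def window_admissible(profile: WindowProfile,
                      config: ProbeDesignConfig = DEFAULT_CONFIG) -> bool:
    return (profile.noncanonical_count == 0
            and profile.max_homopolymer_run < config.run_max
            and not profile.has_direct_repeat
            and not profile.has_inverted_repeat)


# ---------------------------------------------------------------------------
# thermodynamic tuning
# ---------------------------------------------------------------------------

def tune_probe(region: str, tm_target: float,
               config: ProbeDesignConfig = DEFAULT_CONFIG) -> Probe:
    """Pick the 5'-anchored probe length whose Tm is closest to target.

    Candidate lengths run from ``probe_min`` to ``min(probe_max, len(region))``;
    ties break toward the shorter probe.
    """
    if len(region) < config.probe_min:
        raise NoCandidateError(
            f"region of {len(region)} nt shorter than minimum probe length "
            f"{config.probe_min}")
    best: Probe | None = None
    best_err = float("inf")
    for length in range(config.probe_min,
                        min(config.probe_max, len(region)) + 1):
        seq = region[:length]
        tm = melting_temperature(seq, config.na_molar, config.strand_conc_molar)
        err = abs(tm - tm_target)
        if err < best_err - 1e-12:
            best = Probe(sequence=seq, start=0, length=length, tm=tm)
            best_err = err
    assert best is not None
    return best


# ---------------------------------------------------------------------------
# cross-hybridization and isoform coverage
# ---------------------------------------------------------------------------

def _best_segment_matches(probe: str, target: str, diag: int) -> int:
    """Best contiguous segment match count on one diagonal.

    ``diag`` is the target offset of probe position 0 (may be negative).
    Scoring: match +1, mismatch −2 (Kadane over the aligned overlap); the
    returned value is the number of matches inside the best-scoring segment.
    """
    lo = max(0, -diag)
    hi = min(len(probe), len(target) - diag)
    best_matches = 0
    best_score = 0
    score = 0
    matches = 0
    for i in range(lo, hi):
        contrib = 1 if probe[i] == target[diag + i] else -2
        if score <= 0:
            score = 0
            matches = 0
        score += contrib
        matches = matches + 1 if contrib > 0 else matches
        if score > best_score:
            best_score = score
            best_matches = matches
        elif score <= 0:
            matches = 0
    return best_matches


def crosshyb_score(probe_sequence: str,
                   transcriptome: Sequence[TranscriptRecord],
                   target_gene: str,
                   config: ProbeDesignConfig = DEFAULT_CONFIG) -> float:
    """Max off-target identity fraction found by seeded ungapped extension."""
    if not (config.probe_min <= len(probe_sequence) <= config.probe_max):
        raise ContractError(
            f"probe length {len(probe_sequence)} outside "
            f"[{config.probe_min},{config.probe_max}]")
    k = config.seed_k
    seeds: dict[str, list[int]] = {}
    for i in range(len(probe_sequence) - k + 1):
        seeds.setdefault(probe_sequence[i:i + k], []).append(i)
    best = 0.0
    for t in transcriptome:
        if t.gene == target_gene:
            continue
        seen_diags: set[int] = set()
        for j in range(len(t.sequence) - k + 1):
            kmer = t.sequence[j:j + k]
            if kmer not in seeds:
                continue
            for i in seeds[kmer]:
                diag = j - i
                if diag in seen_diags:
                    continue
                seen_diags.add(diag)
                m = _best_segment_matches(probe_sequence, t.sequence, diag)
                best = max(best, m / len(probe_sequence))
    return best


def isoform_coverage(probe_sequence: str,
                     isoforms: Sequence[TranscriptRecord]) -> float:
    """Fraction of a gene's isoforms containing the probe subsequence exactly."""
    if not isoforms:
        return 0.0
    return sum(probe_sequence in t.sequence for t in isoforms) / len(isoforms)


def _pair_coverage(pair_a: Probe, pair_b: Probe,
                   isoforms: Sequence[TranscriptRecord]) -> float:
    if not isoforms:
        return 0.0
    hits = sum(1 for t in isoforms
               if pair_a.sequence in t.sequence and pair_b.sequence in t.sequence)
    return hits / len(isoforms)


# ---------------------------------------------------------------------------
# pair design
# ---------------------------------------------------------------------------

def design_probe_candidates(t: TranscriptRecord,
                            transcriptome: Sequence[TranscriptRecord],
                            config: ProbeDesignConfig = DEFAULT_CONFIG
                            ) -> list[ProbePair]:
    """All admissible probe-pair candidates for a transcript, best first.

    Raises NoCandidateError (with per-filter tallies) when no window passes
    the hard filters or admits two tuned half-probes.
    """
    starts = enumerate_windows(t, config.window_length, config.step)
    half = config.window_length // 2
    isoforms = isoforms_of(transcriptome, t.gene) or [t]
    tallies = {"noncanonical": 0, "homopolymer": 0, "direct_repeat": 0,
               "inverted_repeat": 0, "too_short": 0}
    candidates: list[ProbePair] = []
    for start in starts:
        window = t.sequence[start:start + config.window_length]
        prof = profile_window(window, config, start=start)
        if prof.noncanonical_count > 0:
            tallies["noncanonical"] += 1
            continue
        if prof.max_homopolymer_run >= config.run_max:
            tallies["homopolymer"] += 1
            continue
        if prof.has_direct_repeat:
            tallies["direct_repeat"] += 1
            continue
        if prof.has_inverted_repeat:
            tallies["inverted_repeat"] += 1
            continue
        try:
            pa = tune_probe(window[:half], config.tm_target, config)
            pb = tune_probe(window[half:], config.tm_target, config)
        except NoCandidateError:
            tallies["too_short"] += 1
            continue
        pa = replace(pa, start=start)
        pb = replace(pb, start=start + half)
        ch = max(crosshyb_score(pa.sequence, transcriptome, t.gene, config),
                 crosshyb_score(pb.sequence, transcriptome, t.gene, config))
        cov = _pair_coverage(pa, pb, isoforms)
        tm_err = max(abs(pa.tm - config.tm_target),
                     abs(pb.tm - config.tm_target))
        key = (-cov, ch, tm_err, start)
        candidates.append(ProbePair(
            transcript_id=t.transcript_id, gene=t.gene,
            probe_a=pa, probe_b=pb, window_start=start,
            crosshyb_score=ch, isoform_coverage=cov,
            composite_rank_key=key))
    if not candidates:
        raise NoCandidateError(
            f"transcript {t.transcript_id!r}: no admissible window "
            f"(filter tallies: {tallies})")
    candidates.sort(key=lambda c: c.composite_rank_key)
    return candidates


def design_probe_pair(t: TranscriptRecord,
                      transcriptome: Sequence[TranscriptRecord],
                      config: ProbeDesignConfig = DEFAULT_CONFIG) -> ProbePair:
    """The best-ranked probe pair for a transcript."""
    return design_probe_candidates(t, transcriptome, config)[0]
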