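"""Windowing, profiling, thermodynamic tuning, cross-hyb and pair design."""

import numpy as np
import pytest
from Bio.SeqUtils import MeltingTemp as mt

from panelign import probe_design as pdx
from panelign import synthetic_data as sd
from panelign import thermo
from panelign.errors import ContractError, NoCandidateError
from panelign.probe_design import (DEFAULT_CONFIG, ProbeDesignConfig,
                                   TranscriptRecord)


def _t(seq, tid="t1", gene="g1"):
    return TranscriptRecord(transcript_id=tid, gene=gene, sequence=seq)


def _random_seq(rng, n, gc=0.5):
    p = [gc / 2, gc / 2, (1 - gc) / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("GCAT"), size=n, p=p))


# ---------------------------------------------------------------------------
# windows
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("length,window,step,expected", [
    (100, 100, 1, 1),
    (109, 100, 1, 10),
    (250, 100, 50, 4),
])
def test_enumerate_windows_counts(length, window, step, expected):
    rng = np.random.default_rng(0)
    starts = pdx.enumerate_windows(_t(_random_seq(rng, length)), window, step)
    assert len(starts) == expected
    assert starts[0] == 0
    assert all(s + window <= length for s in starts)


def test_enumerate_windows_too_short():
    rng = np.random.default_rng(0)
    with pytest.raises(NoCandidateError):
        pdx.enumerate_windows(_t(_random_seq(rng, 99)), 100, 1)


# ---------------------------------------------------------------------------
# window profiling
# ---------------------------------------------------------------------------

def test_profile_alternating_acgt():
    prof = pdx.profile_window("ACGT" * 25)
    assert prof.gc_fraction == pytest.approx(0.5)
    assert prof.noncanonical_count == 0
    assert prof.max_homopolymer_run == 1


def test_profile_homopolymer_run():
    rng = np.random.default_rng(1)
    win = _random_seq(rng, 46) + "AAAAAAA" + _random_seq(rng, 47)
    prof = pdx.profile_window(win)
    assert prof.max_homopolymer_run >= 7


def test_profile_direct_repeat_by_construction():
    rng = np.random.default_rng(2)
    s = _random_seq(rng, 50)
    prof = pdx.profile_window(s + s)
    assert prof.has_direct_repeat


def test_profile_inverted_repeat_by_construction():
    rng = np.random.default_rng(3)
    arm = _random_seq(rng, 10)
    mid = _random_seq(rng, 30)
    win = arm + mid + thermo.reverse_complement(arm)
    win = win + _random_seq(rng, 100 - len(win))
    assert pdx.profile_window(win).has_inverted_repeat


def test_profile_counts_noncanonical():
    prof = pdx.profile_window("ACGTN" * 20)
    assert prof.noncanonical_count == 20
    assert prof.gc_fraction == pytest.approx(0.5)


# ---------------------------------------------------------------------------
# melting temperature
# ---------------------------------------------------------------------------

def test_tm_matches_independent_nearest_neighbor_oracle():
    """Tm equals the published-parameter oracle summation (via Biopython)."""
    rng = np.random.default_rng(12)
    for _ in range(10):
        seq = _random_seq(rng, int(rng.integers(15, 51)))
        mine = thermo.melting_temperature(seq, na_molar=0.05,
                                          strand_conc_molar=0.25e-6)
        oracle = mt.Tm_NN(seq, nn_table=mt.DNA_NN3, Na=50,
                          dnac1=125, dnac2=125, saltcorr=5)
        assert mine == pytest.approx(oracle, abs=0.1)


def test_tm_duplex_symmetry():
    rng = np.random.default_rng(13)
    for _ in range(5):
        seq = _random_seq(rng, 30)
        assert thermo.melting_temperature(seq) == pytest.approx(
            thermo.melting_temperature(thermo.reverse_complement(seq)),
            abs=1e-9)


def test_tm_contract_errors():
    with pytest.raises(ContractError):
        thermo.melting_temperature("ACGTAC")  # 6-mer too short
    with pytest.raises(ContractError):
        thermo.melting_temperature("ACGTACGTN")


# ---------------------------------------------------------------------------
# probe tuning
# ---------------------------------------------------------------------------

def test_tune_probe_matches_exhaustive_oracle():
    rng = np.random.default_rng(21)
    region = _random_seq(rng, 50)
    probe = pdx.tune_probe(region, 78.0)
    best_len, best_err = None, float("inf")
    for length in range(35, 51):
        tm = thermo.melting_temperature(region[:length])
        if abs(tm - 78.0) < best_err:
            best_len, best_err = length, abs(tm - 78.0)
    assert probe.length == best_len
    assert probe.sequence == region[:probe.length]


def test_tune_probe_tie_breaks_shorter(monkeypatch):
    # force an exact tie across all candidate lengths: shortest must win
    monkeypatch.setattr(pdx, "melting_temperature",
                        lambda seq, *a, **k: 78.0)
    rng = np.random.default_rng(22)
    region = _random_seq(rng, 50)
    assert pdx.tune_probe(region, 78.0).length == 35


def test_tune_probe_too_short():
    with pytest.raises(NoCandidateError):
        pdx.tune_probe("ACGT" * 7, 78.0)  # 28 nt < 35


# ---------------------------------------------------------------------------
# cross-hybridization
# ---------------------------------------------------------------------------

def test_crosshyb_zero_without_shared_kmers():
    rng = np.random.default_rng(31)
    probe = "AC" * 20
    other = _t("GT" * 400, "o1", "g2")
    assert pdx.crosshyb_score(probe, [other], "g1") == 0.0


def test_crosshyb_one_for_verbatim_off_target():
    rng = np.random.default_rng(32)
    probe = _random_seq(rng, 40)
    other = _t(_random_seq(rng, 100) + probe + _random_seq(rng, 100),
               "o1", "g2")
    assert pdx.crosshyb_score(probe, [other], "g1") == 1.0


def test_crosshyb_ignores_same_gene_isoforms():
    rng = np.random.default_rng(33)
    probe = _random_seq(rng, 40)
    iso = _t(probe + _random_seq(rng, 60), "t1.2", "g1")
    assert pdx.crosshyb_score(probe, [iso], "g1") == 0.0


def _brute_force_matches(probe, target):
    """Oracle: best match count over every diagonal and every sub-interval
    with alignment score (match +1, mismatch -2) maximal."""
    best = 0
    for diag in range(-(len(probe) - 1), len(target)):
        lo, hi = max(0, -diag), min(len(probe), len(target) - diag)
        hits = [1 if probe[i] == target[diag + i] else -2
                for i in range(lo, hi)]
        for a in range(len(hits)):
            score = matches = 0
            best_here = (0, 0)
            for b in range(a, len(hits)):
                score += hits[b]
                if hits[b] > 0:
                    matches += 1
                if score > best_here[0]:
                    best_here = (score, matches)
            if best_here[0] > 0:
                best = max(best, best_here[1])
    return best


def test_crosshyb_planted_island_matches_alignment_oracle():
    rng = np.random.default_rng(34)
    probe = _random_seq(rng, 40)
    island = probe[:30]
    # flanks built base-by-base to never match the probe on that diagonal
    target = ("G" * 50) + island + ("G" * 50)
    target = target.replace("GG" + island, "CT" + island)  # guard boundary
    other = _t(target, "o1", "g2")
    score = pdx.crosshyb_score(probe, [other], "g1")
    oracle = _brute_force_matches(probe, target) / len(probe)
    assert score == pytest.approx(oracle)
    assert score >= 30 / 40  # at least the planted island


def test_crosshyb_random_fixture_equals_oracle():
    rng = np.random.default_rng(35)
    probe = _random_seq(rng, 40)
    # embed a mutated copy: 37 matching positions, runs long enough to seed
    copy = list(probe)
    for pos in (5, 20, 33):
        copy[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[copy[pos]]
    target = _random_seq(rng, 80) + "".join(copy) + _random_seq(rng, 80)
    other = _t(target, "o1", "g2")
    score = pdx.crosshyb_score(probe, [other], "g1")
    oracle = _brute_force_matches(probe, target) / len(probe)
    assert score == pytest.approx(oracle)


def test_crosshyb_monotone_under_added_duplicate():
    rng = np.random.default_rng(36)
    probe = _random_seq(rng, 40)
    base = [_t(_random_seq(rng, 300), "o1", "g2")]
    before = pdx.crosshyb_score(probe, base, "g1")
    extra = base + [_t(probe, "o2", "g3")]
    assert pdx.crosshyb_score(probe, extra, "g1") >= before


# ---------------------------------------------------------------------------
# isoform coverage
# ---------------------------------------------------------------------------

def test_isoform_coverage_fractions():
    rng = np.random.default_rng(41)
    probe = _random_seq(rng, 40)
    hit = _t(_random_seq(rng, 30) + probe, "t1", "g1")
    misses = [_t(_random_seq(rng, 100), f"t{i}", "g1") for i in (2, 3, 4)]
    assert pdx.isoform_coverage(probe, [hit]) == 1.0
    assert pdx.isoform_coverage(probe, [hit] + misses) == 0.25
    assert pdx.isoform_coverage(probe, [hit] * 4) == 1.0


# ---------------------------------------------------------------------------
# pair design
# ---------------------------------------------------------------------------

def test_design_clean_transcript_yields_clean_pair():
    cfg = sd.SimulationConfig(seed=7, transcript_length_range=(200, 200))
    recs = sd.simulate_transcriptome(["gA"], cfg, max_isoforms=1)
    pair = pdx.design_probe_pair(recs[0], recs)
    assert pair.crosshyb_score == 0.0
    assert pair.isoform_coverage == 1.0
    assert 35 <= pair.probe_a.length <= 50
    assert 35 <= pair.probe_b.length <= 50
    # adjacency: probe B starts at the window midpoint
    assert pair.probe_b.start == pair.window_start + 50
    assert pair.probe_a.start == pair.window_start


def test_design_all_a_transcript_fails_homopolymer_filter():
    with pytest.raises(NoCandidateError, match="homopolymer"):
        pdx.design_probe_pair(_t("A" * 300), [_t("A" * 300)])


def test_design_matches_exhaustive_oracle():
    """Winner equals brute force over all windows x tuning lengths."""
    cfg = sd.SimulationConfig(seed=8, transcript_length_range=(400, 400))
    recs = sd.simulate_transcriptome(["gA", "gB"], cfg, max_isoforms=2)
    t0 = recs[0]
    config = ProbeDesignConfig(step=3)
    pair = pdx.design_probe_pair(t0, recs, config)

    best_key = None
    isoforms = [r for r in recs if r.gene == t0.gene]
    for start in range(0, len(t0.sequence) - 100 + 1, 3):
        window = t0.sequence[start:start + 100]
        prof = pdx.profile_window(window, config, start=start)
        if not pdx.window_admissible(prof, config):
            continue
        pa = pdx.tune_probe(window[:50], config.tm_target, config)
        pb = pdx.tune_probe(window[50:], config.tm_target, config)
        ch = max(pdx.crosshyb_score(pa.sequence, recs, t0.gene, config),
                 pdx.crosshyb_score(pb.sequence, recs, t0.gene, config))
        cov = sum(1 for r in isoforms if pa.sequence in r.sequence
                  and pb.sequence in r.sequence) / len(isoforms)
        key = (-cov, ch, max(abs(pa.tm - 78.0), abs(pb.tm - 78.0)), start)
        if best_key is None or key < best_key:
            best_key = key
    assert pair.composite_rank_key == best_key


def test_design_determinism():
    cfg = sd.SimulationConfig(seed=9, transcript_length_range=(300, 300))
    recs = sd.simulate_transcriptome(["gA", "gB"], cfg)
    p1 = pdx.design_probe_pair(recs[0], recs)
    p2 = pdx.design_probe_pair(recs[0], recs)
    assert p1 == p2


def test_fasta_reader_round_trip(tmp_path):
    cfg = sd.SimulationConfig(seed=10, transcript_length_range=(150, 250))
    recs = sd.simulate_transcriptome(["gA", "gB"], cfg)
    path = tmp_path / "tx.fa"
    sd.write_transcripts(recs, path)
    back = pdx.read_transcripts(path)
    assert back == recs
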