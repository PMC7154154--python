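import itertools
import math

import numpy as np
import pandas as pd
import pytest

from varepi.core_io import ExpressionTable, PFM, Variant
from varepi.motif_scan import (AlleleDelta, AlleleWindows, ReferenceMismatchError,
                               allele_delta, differential_tfs, encode,
                               expressed_tfs, extract_allele_windows,
                               genome_background, pfm_to_pwm, scan_best_hit,
                               strong_hit_counts, top_k_tfs)
from varepi.synthetic_data import generate_expression

RC = str.maketrans("ACGT", "TGCA")


def revcomp(s: str) -> str:
    return s.translate(RC)[::-1]


def oracle_best_hit(pwm, seq):
    """Independent enumeration of every offset and strand.

    Scores within 1e-9 count as tied (summation-order float noise); ties go
    to the smaller offset, then the + strand.
    """
    w = pwm.width
    idx = {b: i for i, b in enumerate("ACGT")}
    cands = []
    for j in range(len(seq) - w + 1):
        for strand in "+-":
            sub = seq[j:j + w] if strand == "+" else revcomp(seq[j:j + w])
            score = sum(pwm.weights[idx[b], i] if b in idx else 0.0
                        for i, b in enumerate(sub))
            cands.append((j, strand, score))
    if not cands:
        return None
    top = max(c[2] for c in cands)
    tied = [c for c in cands if c[2] >= top - 1e-9]
    return min(tied, key=lambda c: (c[0], c[1] == "-"))


def _sharp_pfm(consensus: str, name="TFX", hi=97.0) -> PFM:
    counts = np.ones((4, len(consensus)))
    for j, b in enumerate(consensus):
        counts["ACGT".index(b), j] = hi
    return PFM(name, counts)


# ---------------------------------------------------------------------------
# PWM construction
# ---------------------------------------------------------------------------

def test_uniform_column_gives_zero_weights():
    pwm = pfm_to_pwm(PFM("U", np.ones((4, 1))))
    assert np.allclose(pwm.weights, 0.0)


def test_pwm_hand_arithmetic():
    pwm = pfm_to_pwm(PFM("H", np.array([[10.0], [0.0], [0.0], [0.0]])),
                     pseudocount=0.5)
    assert pwm.weights[0, 0] == pytest.approx(math.log((10.5 / 12) / 0.25), abs=1e-4)
    assert pwm.weights[0, 0] == pytest.approx(1.2528, abs=1e-4)
    assert np.allclose(pwm.weights[1:, 0], math.log((0.5 / 12) / 0.25), atol=1e-4)


def test_pwm_stable_under_count_doubling():
    rng = np.random.default_rng(2)
    counts = rng.integers(1, 50, size=(4, 6)).astype(float)
    a = pfm_to_pwm(PFM("A", counts))
    b = pfm_to_pwm(PFM("B", counts * 2))
    assert np.abs(a.weights - b.weights).max() < 0.2
    assert (a.weights.argmax(axis=0) == b.weights.argmax(axis=0)).all()


def test_pwm_rejects_zero_background():
    with pytest.raises(ValueError):
        pfm_to_pwm(PFM("Z", np.ones((4, 2))), background=[0.5, 0.5, 0.0, 0.0])


def test_genome_background_frequencies():
    bg = genome_background({"c": "AACG", "d": "TTNN"})
    assert bg == pytest.approx([2 / 6, 1 / 6, 1 / 6, 2 / 6])


# ---------------------------------------------------------------------------
# scanning
# ---------------------------------------------------------------------------

def test_consensus_scores_maximum_at_offset_zero():
    pwm = pfm_to_pwm(_sharp_pfm("ACGTAC"))
    hit = scan_best_hit(pwm, "ACGTAC")
    assert hit.offset == 0 and hit.strand == "+"
    assert hit.score == pytest.approx(pwm.max_score)


def test_sequence_shorter_than_motif_gives_none():
    pwm = pfm_to_pwm(_sharp_pfm("ACGTACGT"))
    assert scan_best_hit(pwm, "ACGT") is None


def test_palindromic_motif_tie_goes_to_plus():
    pwm = pfm_to_pwm(_sharp_pfm("ACGT"))   # reverse complement of itself
    hit = scan_best_hit(pwm, "ACGT")
    assert hit.strand == "+" and hit.score == pytest.approx(pwm.max_score)


def test_scan_matches_exhaustive_enumeration():
    rng = np.random.default_rng(5)
    for _ in range(100):
        w = int(rng.integers(3, 9))
        counts = rng.integers(0, 30, size=(4, w)).astype(float) + 0.1
        pwm = pfm_to_pwm(PFM("R", counts))
        seq = "".join(rng.choice(list("ACGT"), size=int(rng.integers(w, 40))))
        got = scan_best_hit(pwm, seq)
        j, strand, score = oracle_best_hit(pwm, seq)
        assert (got.offset, got.strand) == (j, strand)
        assert got.score == pytest.approx(score, abs=1e-9)


def test_scan_strand_symmetric_score():
    rng = np.random.default_rng(6)
    pwm = pfm_to_pwm(PFM("S", rng.integers(1, 20, size=(4, 5)).astype(float)))
    for _ in range(20):
        seq = "".join(rng.choice(list("ACGT"), size=25))
        assert scan_best_hit(pwm, seq).score == \
            pytest.approx(scan_best_hit(pwm, revcomp(seq)).score, abs=1e-9)


def test_consensus_attains_global_maximum_exhaustively():
    rng = np.random.default_rng(7)
    pwm = pfm_to_pwm(PFM("G", rng.integers(0, 40, size=(4, 5)).astype(float) + 0.2))
    idx = {b: i for i, b in enumerate("ACGT")}
    best = max(sum(pwm.weights[idx[b], i] for i, b in enumerate(s))
               for s in map("".join, itertools.product("ACGT", repeat=5)))
    assert pwm.max_score == pytest.approx(best, abs=1e-12)
    assert scan_best_hit(pwm, pwm.consensus).score == pytest.approx(best, abs=1e-12)


def test_pwm_agrees_with_biopython_pssm():
    """Independent route: Bio.motifs log-odds (log2) equals ours up to ln 2."""
    from Bio import motifs as bio_motifs
    rng = np.random.default_rng(19)
    counts = rng.integers(0, 40, size=(4, 7)).astype(float)
    m = bio_motifs.Motif(counts={b: list(counts[i]) for i, b in enumerate("ACGT")})
    pssm = m.counts.normalize(pseudocounts=0.5).log_odds()
    ours = pfm_to_pwm(PFM("X", counts), pseudocount=0.5)
    for i, b in enumerate("ACGT"):
        assert np.allclose(ours.weights[i] / math.log(2), list(pssm[b]),
                           atol=1e-9)
    seq = "".join(rng.choice(list("ACGT"), size=7))
    theirs = float(pssm.calculate(seq))
    idx = {b: i for i, b in enumerate("ACGT")}
    mine = sum(ours.weights[idx[b], i] for i, b in enumerate(seq))
    assert mine / math.log(2) == pytest.approx(theirs, abs=1e-5)


def test_scan_with_n_bases_is_background_neutral():
    pwm = pfm_to_pwm(_sharp_pfm("ACG"))
    hit = scan_best_hit(pwm, "NNN")
    assert hit.score == pytest.approx(0.0)


# ---------------------------------------------------------------------------
# allele windows
# ---------------------------------------------------------------------------

GENOME = {"chr1": "ACGTACGTACGTACGTACGTACGTACGT"}


def test_snv_windows_differ_only_at_center():
    v = Variant("chr1", 10, "C", "T")      # base 10 is C
    win = extract_allele_windows(GENOME, v, 4)
    assert len(win.ref_window) == 9
    assert win.ref_window[4] == "C" and win.alt_window[4] == "T"
    assert win.ref_window[:4] == win.alt_window[:4]
    assert win.ref_window[5:] == win.alt_window[5:]
    assert not win.truncated


def test_deletion_alt_window_shorter():
    v = Variant("chr1", 9, "ACG", "A")     # pos 9..11 = "ACG"
    win = extract_allele_windows(GENOME, v, 5)
    assert len(win.ref_window) - len(win.alt_window) == 2
    assert win.ref_window[5:8] == "ACG" and win.alt_window[5] == "A"


def test_deletion_alt_window_padding():
    v = Variant("chr1", 9, "ACG", "A")
    win = extract_allele_windows(GENOME, v, 5, pad_to_nominal=True)
    assert len(win.alt_window) == len(win.ref_window)
    assert win.alt_padded


def test_reference_mismatch_raises():
    with pytest.raises(ReferenceMismatchError):
        extract_allele_windows(GENOME, Variant("chr1", 10, "G", "A"), 4)


def test_window_truncated_at_contig_edge():
    win = extract_allele_windows(GENOME, Variant("chr1", 2, "C", "A"), 5)
    assert win.truncated and win.ref_window.startswith("AC")


def test_allele_delta_degenerate_and_antisymmetry():
    pwm = pfm_to_pwm(_sharp_pfm("ACGTA"))
    v = Variant("chr1", 10, "C", "T")
    same = AlleleWindows(v, "ACGTACGTA", "ACGTACGTA")
    assert allele_delta(pwm, same).diff == 0.0
    win = extract_allele_windows(GENOME, v, 6)
    fwd = allele_delta(pwm, win)
    swapped = AlleleWindows(v, win.alt_window, win.ref_window)
    assert allele_delta(pwm, swapped).diff == pytest.approx(-fwd.diff)


def test_planted_gain_restores_consensus_score():
    consensus = "ACGTACGTT"
    pwm = pfm_to_pwm(_sharp_pfm(consensus))
    broken = consensus[:4] + "G" + consensus[5:]      # A at column 4 -> G? no: ref breaks
    genome = {"c": "TTTT" + broken + "TTTT"}
    v = Variant("c", 9, "G", consensus[4])            # alt restores the consensus
    win = extract_allele_windows(genome, v, 8)
    d = allele_delta(pwm, win)
    assert d.diff > 0
    assert d.score_alt == pytest.approx(pwm.max_score)


# ---------------------------------------------------------------------------
# expression gate, counts, ranking
# ---------------------------------------------------------------------------

def _expr(tf_tpm: dict[str, float], condition="stem") -> ExpressionTable:
    rows = [(g, condition, "r1", v) for g, v in tf_tpm.items()]
    return ExpressionTable(pd.DataFrame(
        rows, columns=["gene_id", "condition", "replicate", "tpm"]))


def test_expressed_tfs_inclusive_boundary():
    expr = _expr({"gA": 3.0, "gB": 2.99})
    got = expressed_tfs(expr, "stem", {"A": "gA", "B": "gB", "C": "gC"})
    assert got == {"A"}


def test_expressed_tf_counts_with_planted_plan():
    """154 TFs in cond1, 193 in cond2, 135 shared, per the planted plan."""
    both = {f"tf{i:03d}": (True, True) for i in range(135)}
    only1 = {f"tf{i:03d}": (True, False) for i in range(135, 154)}
    only2 = {f"tf{i:03d}": (False, True) for i in range(154, 212)}
    plan = {**both, **only1, **only2}
    expr, _ = generate_expression([], tf_plan=plan, seed=33, reps=3)
    tf_map = {g: g for g in plan}
    e1 = expressed_tfs(expr, "stem", tf_map)
    e2 = expressed_tfs(expr, "induced", tf_map)
    assert (len(e1), len(e2), len(e1 & e2)) == (154, 193, 135)


def test_strong_hit_counts_planted_sites():
    consensus = "ACGTACGTT"
    pwm = pfm_to_pwm(_sharp_pfm(consensus))
    assert pwm.max_score >= 10
    rng = np.random.default_rng(12)
    chunks, anchors = [], []
    pos = 0
    for i in range(9):
        filler = "".join(rng.choice(list("ACGT"), 150))
        site = consensus if i < 7 else "".join(rng.choice(list("ACGT"), 9))
        chunks += [filler, site]
        pos += 150
        anchors.append(pos + 5)            # inside the planted site
        pos += 9
    genome = {"c": "".join(chunks) + "A" * 200}
    variants = [Variant("c", a, genome["c"][a - 1],
                        "A" if genome["c"][a - 1] != "A" else "C")
                for a in anchors]
    counts = strong_hit_counts(variants, genome, [pwm], "ref", half_width=75)
    assert counts["TFX"] >= 7              # all 7 planted sites found


def test_strong_hit_counts_zero_and_monotone_in_cutoff():
    pwm = pfm_to_pwm(_sharp_pfm("ACGTACGTT"))
    genome = {"c": "A" * 400}
    variants = [Variant("c", 200, "A", "G")]
    assert strong_hit_counts(variants, genome, [pwm], "ref") == {"TFX": 0}
    lo = strong_hit_counts(variants, genome, [pwm], "ref", score_cutoff=-100.0)
    assert lo["TFX"] == 1


def test_differential_tfs_rules():
    assert differential_tfs({"A": 5}, {"A": 5}, {"A"}) == []
    got = differential_tfs({"A": 25, "B": 3}, {"A": 10, "B": 30},
                           expressed_set={"A"}, min_count_diff=10)
    assert got == [("A", -15)]             # B exceeds the diff but is not expressed


def test_top_k_tfs_ranking():
    counts = {"B": 5, "A": 5, "C": 9, "D": 1}
    assert top_k_tfs(counts, {"A", "B", "C", "D"}, k=3) == \
        [("C", 9), ("A", 5), ("B", 5)]
    assert top_k_tfs(counts, {"A"}, k=20) == [("A", 5)]
    assert top_k_tfs(counts, {"A", "B"}, k=0) == []
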