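"""PWM construction and scanning, and allele-aware rescoring of variant windows.

A position frequency matrix (base counts per motif column) is turned into a
natural-log log-odds PWM:

    p_hat[b, i] = (count[b, i] + pc) / (colsum[i] + 4 pc)
    weight[b, i] = ln(p_hat[b, i] / background[b])

with pseudocount pc = 0.5 and a flat background by default (optionally
estimated from a supplied genome).  A sequence window is scored at every
offset on both strands; the best hit is the maximum score, ties going to the
smaller offset and then the + strand.  The allele delta of a variant is the
best-hit score of the alternate-allele window minus that of the
reference-allele window: positive values mean the alternate allele gains
predicted binding affinity.

Bases outside ACGT (N) contribute weight 0 (background-neutral) at any
column they occupy.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from varepi.core_io import BASES, ExpressionTable, PFM, PWM, Variant

log = logging.getLogger(__name__)

_CODE = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT_IDX = np.array([3, 2, 1, 0, 4])  # A<->T, C<->G, N->N


class ReferenceMismatchError(ValueError):
    """The genome base at the variant position does not equal the ref allele."""


@dataclass(frozen=True)
class MotifHit:
    tf_name: str
    offset: int          # 0-based start of the match within the window
    strand: str          # + / -
    score: float


@dataclass(frozen=True)
class AlleleWindows:
    variant: Variant
    ref_window: str
    alt_window: str
    truncated: bool = False
    alt_padded: bool = False


@dataclass(frozen=True)
class AlleleDelta:
    tf_name: str
    score_ref: float
    score_alt: float
    hit_ref: MotifHit | None = None
    hit_alt: MotifHit | None = None

    @property
    def diff(self) -> float:
        return self.score_alt - self.score_ref


# ---------------------------------------------------------------------------
# PWM construction
# ---------------------------------------------------------------------------

def genome_background(seqs: Mapping[str, str] | Iterable[str]) -> np.ndarray:
    """ACGT frequencies of the supplied sequences (N ignored)."""
    if isinstance(seqs, Mapping):
        seqs = seqs.values()
    counts = Counter()
    for s in seqs:
        counts.update(s)
    total = sum(counts[b] for b in BASES)
    if total == 0:
        raise ValueError("no ACGT bases in the supplied sequences")
    return np.array([counts[b] / total for b in BASES])


def pfm_to_pwm(pfm: PFM, pseudocount: float = 0.5,
               background: Sequence[float] | None = None) -> PWM:
    """Natural-log log-odds weights from a count matrix."""
    bg = np.full(4, 0.25) if background is None \
        else np.asarray(background, dtype=float)
    if (bg <= 0).any():
        raise ValueError("background must be strictly positive")
    bg = bg / bg.sum()
    colsum = pfm.counts.sum(axis=0)
    p_hat = (pfm.counts + pseudocount) / (colsum + 4.0 * pseudocount)
    weights = np.log(p_hat / bg[:, None])
    return PWM(tf_name=pfm.tf_name, weights=weights, background=bg,
               pseudocount=pseudocount)


# ---------------------------------------------------------------------------
# scanning
# ---------------------------------------------------------------------------

def encode(sequence: str) -> np.ndarray:
    return np.fromiter((_CODE.get(c, 4) for c in sequence.upper()),
                       dtype=np.int8, count=len(sequence))


def _padded(weights: np.ndarray) -> np.ndarray:
    return np.vstack([weights, np.zeros(weights.shape[1])])  # row 4 = N


def _strand_scores(weights: np.ndarray, codes: np.ndarray) -> np.ndarray:
    w = weights.shape[1]
    windows = np.lib.stride_tricks.sliding_window_view(codes, w)
    return _padded(weights)[windows, np.arange(w)].sum(axis=1)


def scan_best_hit(pwm: PWM, sequence: str) -> MotifHit | None:
    """Best-scoring match of the motif in the sequence over both strands.

    A '-' strand hit at offset j means the reverse complement of
    ``sequence[j:j+w]`` matches the motif.  Returns None when the sequence is
    shorter than the motif.
    """
    w = pwm.width
    if len(sequence) < w:
        return None
    codes = encode(sequence)
    plus = _strand_scores(pwm.weights, codes)
    rc_weights = pwm.weights[[3, 2, 1, 0], ::-1]
    minus = _strand_scores(rc_weights, codes)
    # tie order: score desc, offset asc, '+' before '-'; scores within 1e-9
    # are ties (vectorized summation order can differ by an ulp)
    top = max(plus.max(), minus.max())
    best = None
    for strand, scores in (("+", plus), ("-", minus)):
        for j in np.flatnonzero(scores >= top - 1e-9):
            cand = (int(j), 0 if strand == "+" else 1)
            if best is None or cand < best[0]:
                best = (cand, MotifHit(pwm.tf_name, int(j), strand,
                                       float(scores[j])))
    return best[1]


# ---------------------------------------------------------------------------
# allele windows
# ---------------------------------------------------------------------------

def extract_allele_windows(genome: Mapping[str, str], variant: Variant,
                           half_width: int,
                           pad_to_nominal: bool = False) -> AlleleWindows:
    """Reference- and alternate-allele windows centered on a variant.

    The reference window spans ``half_width`` bases either side of the ref
    allele; the alternate window is the same flanks with ref spliced to alt
    (so indel windows differ in length unless ``pad_to_nominal`` extends the
    right flank from the genome).  Windows are truncated at contig edges with
    a flag; a genome/ref mismatch raises :class:`ReferenceMismatchError`.
    """
    try:
        seq = genome[variant.chrom]
    except KeyError:
        raise KeyError(f"contig {variant.chrom!r} not in the genome") from None
    i = variant.pos - 1
    if seq[i:i + len(variant.ref)] != variant.ref:
        raise ReferenceMismatchError(
            f"{variant.key}: genome has {seq[i:i + len(variant.ref)]!r}, "
            f"expected {variant.ref!r}")
    left = seq[max(0, i - half_width):i]
    right = seq[i + len(variant.ref):i + len(variant.ref) + half_width]
    truncated = len(left) < half_width or len(right) < half_width
    alt_right = right
    padded = False
    if pad_to_nominal and len(variant.alt) < len(variant.ref):
        deficit = len(variant.ref) - len(variant.alt)
        extra = seq[i + len(variant.ref) + half_width:
                    i + len(variant.ref) + half_width + deficit]
        alt_right = right + extra
        padded = deficit > 0 and len(extra) == deficit
    return AlleleWindows(variant=variant,
                         ref_window=left + variant.ref + right,
                         alt_window=left + variant.alt + alt_right,
                         truncated=truncated, alt_padded=padded)


def allele_delta(pwm: PWM, windows: AlleleWindows) -> AlleleDelta:
    """Best-hit score per allele window and their difference (alt - ref).

    A window shorter than the motif scores -inf.
    """
    hit_ref = scan_best_hit(pwm, windows.ref_window)
    hit_alt = scan_best_hit(pwm, windows.alt_window)
    score_ref = hit_ref.score if hit_ref is not None else -math.inf
    score_alt = hit_alt.score if hit_alt is not None else -math.inf
    return AlleleDelta(pwm.tf_name, score_ref, score_alt, hit_ref, hit_alt)


# ---------------------------------------------------------------------------
# expression gating, counting, ranking
# ---------------------------------------------------------------------------

def expressed_tfs(expr: ExpressionTable, condition: str,
                  tf_gene_map: Mapping[str, str],
                  tpm_cutoff: float = 3.0) -> set[str]:
    """TF names whose encoding gene's mean TPM in the condition is >= cutoff.

    ``tf_gene_map`` maps motif/TF names to gene ids; TFs whose gene is absent
    from the table are excluded with a log message.
    """
    means = expr.mean_tpm(condition)
    out = set()
    missing = []
    for tf, gene in tf_gene_map.items():
        if gene not in means.index:
            missing.append(tf)
            continue
        if means[gene] >= tpm_cutoff:
            out.add(tf)
    if missing:
        log.info("expressed_tfs: %d TFs absent from the expression table: %s",
                 len(missing), ", ".join(sorted(missing)[:5]))
    return out


def strong_hit_counts(variants: Sequence[Variant], genome: Mapping[str, str],
                      pwms: Sequence[PWM], allele: str = "ref",
                      half_width: int = 75,
                      score_cutoff: float = 10.0) -> dict[str, int]:
    """Per TF, the number of variant windows whose best hit reaches the cutoff.

    ``allele`` selects which allele is applied to the window ("ref" scores
    the stem genome, "alt" the induced one).  Deletion alt windows are
    re-padded from the genome to the nominal width so counts are comparable
    across alleles.
    """
    if allele not in ("ref", "alt"):
        raise ValueError("allele must be 'ref' or 'alt'")
    counts = {pwm.tf_name: 0 for pwm in pwms}
    for v in variants:
        win = extract_allele_windows(genome, v, half_width, pad_to_nominal=True)
        seq = win.ref_window if allele == "ref" else win.alt_window
        for pwm in pwms:
            hit = scan_best_hit(pwm, seq)
            if hit is not None and hit.score >= score_cutoff:
                counts[pwm.tf_name] += 1
    return counts


def differential_tfs(counts_ref: Mapping[str, int], counts_alt: Mapping[str, int],
                     expressed_set: Iterable[str],
                     min_count_diff: int = 10) -> list[tuple[str, int]]:
    """Expressed TFs whose strong-hit counts differ by at least the cutoff.

    Returns (tf, diff) with diff = count_alt - count_ref (induced minus
    stem), sorted by |diff| descending, ties by name.
    """
    universe = set(counts_ref) | set(counts_alt)
    expressed = set(expressed_set)
    rows = []
    for tf in universe:
        diff = counts_alt.get(tf, 0) - counts_ref.get(tf, 0)
        if tf in expressed and abs(diff) >= min_count_diff:
            rows.append((tf, diff))
    return sorted(rows, key=lambda r: (-abs(r[1]), r[0]))


def top_k_tfs(counts: Mapping[str, int], expressed_set: Iterable[str],
              k: int = 20) -> list[tuple[str, int]]:
    """Top-k expressed TFs by strong-hit count (ties by name)."""
    if k < 0:
        raise ValueError("k must be non-negative")
    expressed = set(expressed_set)
    rows = [(tf, n) for tf, n in counts.items() if tf in expressed]
    return sorted(rows, key=lambda r: (-r[1], r[0]))[:k]
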