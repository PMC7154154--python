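"""Classify variants into genomic region categories and relate them to TSSs.

Each variant receives exactly one category from a closed vocabulary using a
fixed precedence (exonic > UTR5 > UTR3 > intronic > ncRNA_intronic >
upstream > downstream > intergenic).  UTR bases of one transcript that are
coding-exonic in another transcript are called exonic; "exonic" here means
an exon base not annotated as UTR in that transcript.  Indels are classified
by their anchor position.

Also provides the per-category fold-enrichment ratio, the 12-way / 6-way
substitution spectrum, TSS-distance profiles, and nearest-TSS gene
assignment.
"""

from __future__ import annotations

import logging
import warnings
from bisect import bisect_left
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from varepi.core_io import BASES, GeneModel, Variant

log = logging.getLogger(__name__)

CATEGORIES = ("exonic", "UTR5", "UTR3", "intronic", "ncRNA_intronic",
              "upstream", "downstream", "intergenic")
_RANK = {c: i for i, c in enumerate(CATEGORIES)}

SUBSTITUTIONS_12 = tuple(f"{r}>{a}" for r in BASES for a in BASES if r != a)
#: strand-collapsed classes keyed by pyrimidine reference
SUBSTITUTIONS_6 = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class RegionCall:
    variant_key: str
    category: str
    gene_id: str | None = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown region category {self.category!r}")


@dataclass(frozen=True)
class GeneAssignment:
    variant_key: str
    gene_id: str
    distance: int  # signed, gene-orientation-aware; negative = upstream of TSS


class GeneIndex:
    """Per-chromosome interval and TSS indexes over a set of gene models."""

    def __init__(self, models: Sequence[GeneModel]):
        self.models = tuple(models)
        self._trees: dict[str, IntervalTree] = {}
        self._tss: dict[str, list[tuple[int, str, str]]] = {}
        by_chrom: dict[str, list[GeneModel]] = {}
        for m in models:
            by_chrom.setdefault(m.chrom, []).append(m)
        self._by_chrom = by_chrom
        for chrom, ms in by_chrom.items():
            tree = IntervalTree()
            for m in ms:
                # flanked span so one query finds every transcript that could
                # label the position (max flank handled at query time)
                tree.addi(m.start, m.end + 1, m)
            self._trees[chrom] = tree
            self._tss[chrom] = sorted((m.tss, m.gene_id, m.strand) for m in ms)

    def models_near(self, chrom: str, pos: int, flank: int) -> list[GeneModel]:
        if chrom not in self._trees:
            return []
        hits = {iv.data for iv in self._trees[chrom].overlap(pos - flank, pos + flank + 1)}
        return sorted(hits, key=lambda m: (m.gene_id, m.transcript_id))

    def models_on(self, chrom: str) -> list[GeneModel]:
        return self._by_chrom.get(chrom, [])

    def tss_list(self, chrom: str) -> list[tuple[int, str, str]]:
        return self._tss.get(chrom, [])

    @property
    def chroms(self) -> list[str]:
        return sorted(self._by_chrom)


def _as_index(gene_models: Sequence[GeneModel] | GeneIndex) -> GeneIndex:
    if isinstance(gene_models, GeneIndex):
        return gene_models
    return GeneIndex(gene_models)


def _in_intervals(pos: int, intervals: Iterable[tuple[int, int]]) -> bool:
    return any(s <= pos <= e for s, e in intervals)


def transcript_category(model: GeneModel, pos: int, flank: int) -> str | None:
    """Category of ``pos`` with respect to one transcript, or None if outside."""
    if model.start <= pos <= model.end:
        if _in_intervals(pos, model.utr5):
            return "UTR5"
        if _in_intervals(pos, model.utr3):
            return "UTR3"
        if _in_intervals(pos, model.exons):
            return "exonic"
        return "intronic" if model.biotype == "coding" else "ncRNA_intronic"
    if model.strand == "+":
        if model.tss - flank <= pos < model.start:
            return "upstream"
        if model.end < pos <= model.tes + flank:
            return "downstream"
    else:
        if model.end < pos <= model.tss + flank:
            return "upstream"
        if model.tes - flank <= pos < model.start:
            return "downstream"
    return None


def classify_variant_region(variant: Variant,
                            gene_models: Sequence[GeneModel] | GeneIndex,
                            flank: int = 1000) -> RegionCall:
    """Single region category for a variant's anchor position.

    The highest-precedence category over all transcripts wins; a chromosome
    with no gene model yields intergenic with a warning.
    """
    index = _as_index(gene_models)
    pos = variant.pos
    if variant.chrom not in index.chroms:
        warnings.warn(f"no gene models on {variant.chrom}; calling intergenic",
                      stacklevel=2)
        return RegionCall(variant.key, "intergenic")
    best: tuple[int, str, str | None] | None = None
    for m in index.models_near(variant.chrom, pos, flank):
        cat = transcript_category(m, pos, flank)
        if cat is None:
            continue
        cand = (_RANK[cat], cat, m.gene_id)
        if best is None or cand < best:
            best = cand
    if best is None:
        return RegionCall(variant.key, "intergenic")
    return RegionCall(variant.key, best[1], best[2])


def fold_enrichment(category_variant_counts: Mapping[str, int],
                    category_genome_lengths: Mapping[str, int],
                    total_variants: int | None = None,
                    total_genome_length: int | None = None) -> dict[str, float]:
    """Per-category ratio (n_c / N) / (L_c / L); zero-variant categories give 0."""
    N = total_variants if total_variants is not None \
        else sum(category_variant_counts.values())
    L = total_genome_length if total_genome_length is not None \
        else sum(category_genome_lengths.values())
    if N <= 0 or L <= 0:
        raise ValueError("totals must be positive")
    ratios: dict[str, float] = {}
    for cat, n in category_variant_counts.items():
        if n == 0:
            ratios[cat] = 0.0
            continue
        L_c = category_genome_lengths[cat]
        if L_c <= 0:
            raise ValueError(f"category {cat!r} has non-positive genome length")
        ratios[cat] = (n / N) / (L_c / L)
    return ratios


def substitution_spectrum(variants: Iterable[Variant],
                          collapse: bool = False) -> dict[str, int]:
    """Counts over the 12 ordered substitutions (SNVs only; indels logged).

    ``collapse=True`` returns the 6-class strand-collapsed view keyed by the
    pyrimidine reference (C>T counts both C>T and G>A, etc.).
    """
    counts = dict.fromkeys(SUBSTITUTIONS_12, 0)
    n_skipped = 0
    for v in variants:
        if v.vclass != "SNV":
            n_skipped += 1
            continue
        counts[f"{v.ref}>{v.alt}"] += 1
    if n_skipped:
        log.info("substitution_spectrum: ignored %d non-SNV variants", n_skipped)
    if not collapse:
        return counts
    collapsed = dict.fromkeys(SUBSTITUTIONS_6, 0)
    for sub, n in counts.items():
        ref, alt = sub.split(">")
        if ref in "AG":
            ref, alt = ref.translate(_COMPLEMENT), alt.translate(_COMPLEMENT)
        collapsed[f"{ref}>{alt}"] += n
    return collapsed


def assign_nearest_tss(variant: Variant,
                       gene_models: Sequence[GeneModel] | GeneIndex
                       ) -> GeneAssignment | None:
    """Assign a variant to the gene with the nearest TSS on its chromosome.

    The signed distance is gene-orientation-aware (negative means the variant
    lies upstream of the TSS).  Ties on |distance| go to the lexicographically
    smaller gene_id.  Returns None (logged) when the chromosome has no gene.
    """
    index = _as_index(gene_models)
    tss_list = index.tss_list(variant.chrom)
    if not tss_list:
        log.warning("no gene models on %s; variant %s unassigned",
                    variant.chrom, variant.key)
        return None
    positions = [t[0] for t in tss_list]
    pos = variant.pos
    i = bisect_left(positions, pos)
    nearby = tss_list[max(0, i - 1):i + 1]
    best_dist = min(abs(pos - t[0]) for t in nearby)
    # several genes can share the minimal distance (including duplicated TSSs)
    ties = [t for t in tss_list if abs(pos - t[0]) == best_dist]
    tss, gene_id, strand = min(ties, key=lambda t: t[1])
    if len(ties) > 1:
        log.info("nearest-TSS tie for %s resolved to %s", variant.key, gene_id)
    distance = pos - tss if strand == "+" else tss - pos
    return GeneAssignment(variant.key, gene_id, distance)


def tss_distance_profile(variants: Iterable[Variant],
                         gene_models: Sequence[GeneModel] | GeneIndex,
                         half_window: int = 2500,
                         bin_width: int = 50) -> pd.Series:
    """Binned counts of signed distances to the nearest TSS.

    Only variants with |distance| <= half_window contribute; bins are
    half-open ``[left, left + bin_width)`` and indexed by left edge, covering
    [-half_window, +half_window).
    """
    index = _as_index(gene_models)
    dists = []
    for v in variants:
        a = assign_nearest_tss(v, index)
        if a is not None and abs(a.distance) <= half_window:
            dists.append(a.distance)
    edges = np.arange(-half_window, half_window + bin_width, bin_width)
    # clip +half_window into the last bin rather than letting histogram's
    # closed right edge create an off-by-one class
    d = np.clip(np.asarray(dists, dtype=float), -half_window, half_window - 0.5)
    counts, _ = np.histogram(d, bins=edges)
    return pd.Series(counts, index=edges[:-1], name="n_variants")


def classify_all(variants: Sequence[Variant],
                 gene_models: Sequence[GeneModel] | GeneIndex,
                 flank: int = 1000) -> dict[str, RegionCall]:
    index = _as_index(gene_models)
    return {v.key: classify_variant_region(v, index, flank) for v in variants}


def assign_all(variants: Sequence[Variant],
               gene_models: Sequence[GeneModel] | GeneIndex
               ) -> dict[str, GeneAssignment]:
    index = _as_index(gene_models)
    out: dict[str, GeneAssignment] = {}
    for v in variants:
        a = assign_nearest_tss(v, index)
        if a is not None:
            out[v.key] = a
    return out


def _subtract_intervals(intervals: Iterable[tuple[int, int]],
                        holes: Sequence[tuple[int, int]]
                        ) -> list[tuple[int, int]]:
    """1-based inclusive interval subtraction."""
    out: list[tuple[int, int]] = []
    for s, e in intervals:
        pieces = [(s, e)]
        for hs, he in sorted(holes):
            nxt: list[tuple[int, int]] = []
            for ps, pe in pieces:
                if he < ps or hs > pe:
                    nxt.append((ps, pe))
                    continue
                if ps < hs:
                    nxt.append((ps, hs - 1))
                if he < pe:
                    nxt.append((he + 1, pe))
            pieces = nxt
        out.extend(pieces)
    return out


def paint_chromosome(length: int,
                     gene_models: Sequence[GeneModel] | GeneIndex,
                     chrom: str, flank: int = 1000) -> np.ndarray:
    """Category rank (index into CATEGORIES) per 1-based position.

    Vectorized painting in reverse precedence order; index 0 of the returned
    array is unused.  Agrees with :func:`classify_variant_region` at every
    base.
    """
    index = _as_index(gene_models)
    paint = np.full(length + 1, _RANK["intergenic"], dtype=np.int8)
    layers: dict[str, list[tuple[int, int]]] = {c: [] for c in CATEGORIES}
    for m in index.models_on(chrom):
        if m.strand == "+":
            layers["upstream"].append((m.tss - flank, m.start - 1))
            layers["downstream"].append((m.end + 1, m.tes + flank))
        else:
            layers["upstream"].append((m.end + 1, m.tss + flank))
            layers["downstream"].append((m.tes - flank, m.start - 1))
        intron_cat = "intronic" if m.biotype == "coding" else "ncRNA_intronic"
        layers[intron_cat].append((m.start, m.end))
        # per transcript, an exon base annotated as UTR is UTR, so the
        # exonic layer is exon minus UTR (matching transcript_category)
        layers["exonic"].extend(_subtract_intervals(m.exons, m.utr5 + m.utr3))
        for s, e in m.utr3:
            layers["UTR3"].append((s, e))
        for s, e in m.utr5:
            layers["UTR5"].append((s, e))
    for cat in reversed(CATEGORIES[:-1]):          # low precedence painted first
        for s, e in layers[cat]:
            s, e = max(1, s), min(length, e)
            if s <= e:
                paint[s:e + 1] = _RANK[cat]
    return paint


def category_genome_lengths(genome_lengths: Mapping[str, int],
                            gene_models: Sequence[GeneModel] | GeneIndex,
                            flank: int = 1000) -> dict[str, int]:
    """Bases of the genome painted with each category (same precedence).

    Used as the fold-enrichment denominator.
    """
    index = _as_index(gene_models)
    totals = dict.fromkeys(CATEGORIES, 0)
    for chrom, L in genome_lengths.items():
        paint = paint_chromosome(L, index, chrom, flank)
        vals, counts = np.unique(paint[1:], return_counts=True)
        for rank, n in zip(vals, counts):
            totals[CATEGORIES[rank]] += int(n)
    return totals
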