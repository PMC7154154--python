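"""Epigenetic-state calls at variant sites and state-switch classification.

For activating marks (H3K4me3 promoter, H3K27ac enhancer) a site is Active
("A") when it falls inside a peak and Inactive ("I") otherwise.  For
repressive signals (H3K27me3, DNA methylation) a peak means Inhibited
("In"), otherwise permissive ("T").  A variant whose promoter or enhancer
state is active in both conditions ("A->A") is *epigenetically stable*: an
expression change at its gene cannot be attributed to a local epigenetic
switch.

Site overlap convention: a variant's position is compared directly against
the half-open peak interval, ``start <= pos < end``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from varepi.core_io import ACTIVATING_MARKS, REPRESSIVE_MARKS, Peak, Variant

log = logging.getLogger(__name__)

ACTIVATING_STATES = ("A", "I")
REPRESSIVE_STATES = ("In", "T")


@dataclass(frozen=True)
class StateCall:
    variant_key: str
    mark: str
    state1: str
    state2: str

    def __post_init__(self) -> None:
        vocab = ACTIVATING_STATES if self.mark in ACTIVATING_MARKS else REPRESSIVE_STATES
        for s in (self.state1, self.state2):
            if s not in vocab:
                raise ValueError(
                    f"state {s!r} not in the {self.mark} vocabulary {vocab}")

    @property
    def switch(self) -> str:
        return f"{self.state1}->{self.state2}"


@dataclass(frozen=True)
class StableCall:
    """A variant that qualified as epigenetically stable."""

    variant_key: str
    via: str            # promoter | enhancer | both
    mark: str           # H3K4me3 for promoter-stable, else H3K27ac


class PeakSet:
    """Interval index over peaks, keyed by (mark, condition)."""

    def __init__(self, peaks: Iterable[Peak]):
        self.peaks = list(peaks)
        self._trees: dict[tuple[str, str, str], IntervalTree] = {}
        for p in self.peaks:
            key = (p.mark, p.condition, p.chrom)
            self._trees.setdefault(key, IntervalTree()).addi(p.start, p.end, p)

    def covers(self, chrom: str, pos: int, mark: str, condition: str) -> bool:
        tree = self._trees.get((mark, condition, chrom))
        return bool(tree is not None and tree.at(pos))

    def subset(self, mark: str, condition: str) -> list[Peak]:
        return [p for p in self.peaks if p.mark == mark and p.condition == condition]


def _as_peakset(peaks: Iterable[Peak] | PeakSet) -> PeakSet:
    return peaks if isinstance(peaks, PeakSet) else PeakSet(peaks)


def mark_state(variant: Variant, peaks: Iterable[Peak] | PeakSet,
               mark: str, condition: str) -> str:
    """State of the variant's anchor position for one mark in one condition."""
    ps = _as_peakset(peaks)
    inside = ps.covers(variant.chrom, variant.pos, mark, condition)
    if mark in REPRESSIVE_MARKS:
        return "In" if inside else "T"
    return "A" if inside else "I"


def classify_switch(state1: str, state2: str) -> str:
    """Render a pair of per-condition states as a switch label like "A->A"."""
    for vocab in (ACTIVATING_STATES, REPRESSIVE_STATES):
        if state1 in vocab and state2 in vocab:
            return f"{state1}->{state2}"
    raise ValueError(
        f"states {state1!r}, {state2!r} do not share a vocabulary")


def call_states(variants: Sequence[Variant], peaks: Iterable[Peak] | PeakSet,
                marks: Iterable[str], cond1: str, cond2: str
                ) -> dict[str, dict[str, StateCall]]:
    """StateCall per variant per mark: ``{variant_key: {mark: StateCall}}``."""
    ps = _as_peakset(peaks)
    out: dict[str, dict[str, StateCall]] = {}
    for v in variants:
        out[v.key] = {}
        for mark in marks:
            s1 = mark_state(v, ps, mark, cond1)
            s2 = mark_state(v, ps, mark, cond2)
            out[v.key][mark] = StateCall(v.key, mark, s1, s2)
    return out


def switch_class_counts(statecalls: Mapping[str, Mapping[str, StateCall]],
                        mark: str) -> dict[str, int]:
    counts: dict[str, int] = {}
    for calls in statecalls.values():
        if mark in calls:
            sw = calls[mark].switch
            counts[sw] = counts.get(sw, 0) + 1
    return counts


def select_epigenetically_stable(
        statecalls: Mapping[str, Mapping[str, StateCall]],
        require_repressive_stable: bool = False) -> list[StableCall]:
    """Variants whose H3K4me3 (promoter) or H3K27ac (enhancer) state is A->A.

    A variant qualifying under both marks is returned once, flagged
    ``via="both"`` (counted as promoter-stable for the primary mark).  With
    ``require_repressive_stable``, any repressive call present must also be
    unchanged (In->In or T->T).
    """
    out: list[StableCall] = []
    for key in sorted(statecalls):
        calls = statecalls[key]
        if "H3K4me3" not in calls or "H3K27ac" not in calls:
            raise ValueError(
                f"variant {key}: H3K4me3 and H3K27ac calls are both required")
        promoter = calls["H3K4me3"].switch == "A->A"
        enhancer = calls["H3K27ac"].switch == "A->A"
        if not (promoter or enhancer):
            continue
        if require_repressive_stable:
            repressive = [c for m, c in calls.items() if m in REPRESSIVE_MARKS]
            if any(c.state1 != c.state2 for c in repressive):
                continue
        via = "both" if (promoter and enhancer) else (
            "promoter" if promoter else "enhancer")
        mark = "H3K4me3" if promoter else "H3K27ac"
        out.append(StableCall(key, via, mark))
    n_both = sum(1 for s in out if s.via == "both")
    if n_both:
        log.info("%d variants stable under both marks (counted once)", n_both)
    return out


def peak_count_profile(variants_by_class: Mapping[str, Sequence[Variant]],
                       peaks: Iterable[Peak] | PeakSet,
                       half_window: int = 2000,
                       bin_width: int = 100) -> pd.DataFrame:
    """Per switch class, (variant, peak) overlap counts in bins around sites.

    Bin ``b`` of a variant covers genomic ``[pos + b, pos + b + bin_width)``
    in the site-overlap frame; a cell counts the (variant, peak) pairs whose
    intervals intersect.  Rows are labeled "class (n)" with the class's
    variant count.
    """
    peaks = list(peaks.peaks if isinstance(peaks, PeakSet) else peaks)
    offsets = np.arange(-half_window, half_window, bin_width)
    by_chrom: dict[str, list[Peak]] = {}
    for p in peaks:
        by_chrom.setdefault(p.chrom, []).append(p)
    rows = {}
    for cls, variants in variants_by_class.items():
        counts = np.zeros(len(offsets), dtype=int)
        for v in variants:
            for p in by_chrom.get(v.chrom, []):
                starts = v.pos + offsets
                ends = starts + bin_width
                counts += (p.start < ends) & (starts < p.end)
        rows[f"{cls} ({len(variants)})"] = counts
    return pd.DataFrame(rows, index=offsets).T


def methylation_regions_from_cpg(cpg_calls: Sequence[tuple[str, int, float]],
                                 condition: str,
                                 threshold: float = 0.5,
                                 window: int = 200) -> list[Peak]:
    """Call methylated regions from per-CpG levels.

    ``cpg_calls`` are (chrom, 1-based position, methylation level in [0, 1])
    records.  Non-overlapping windows whose mean level over covered CpGs is
    >= threshold become DNAme peaks (the "inhibited" input to state calling).
    """
    by_chrom: dict[str, list[tuple[int, float]]] = {}
    for chrom, pos, level in cpg_calls:
        if not 0.0 <= level <= 1.0:
            raise ValueError(f"methylation level {level} outside [0, 1]")
        by_chrom.setdefault(chrom, []).append((pos, level))
    peaks: list[Peak] = []
    for chrom, calls in by_chrom.items():
        bins: dict[int, list[float]] = {}
        for pos, level in calls:
            bins.setdefault((pos - 1) // window, []).append(level)
        meth_bins = sorted(b for b, levels in bins.items()
                           if float(np.mean(levels)) >= threshold)
        # merge runs of adjacent methylated windows into single regions
        i = 0
        while i < len(meth_bins):
            j = i
            while j + 1 < len(meth_bins) and meth_bins[j + 1] == meth_bins[j] + 1:
                j += 1
            peaks.append(Peak(chrom, meth_bins[i] * window,
                              (meth_bins[j] + 1) * window, "DNAme", condition))
            i = j + 1
    return peaks
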