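"""Differential expression from the TPM table and target-set statistics.

Per gene, a two-sample t-test on log2(TPM + 1) compares the two conditions;
p-values are Benjamini-Hochberg adjusted across tested genes.  The default
statistic is Student's pooled-variance t: like limma's linear model it
assumes a common within-condition variance, which keeps the full
n1 + n2 - 2 degrees of freedom at the small replicate counts typical of
these designs (Welch's effective df collapses toward min(n)-1 there and
loses considerable power; pass ``equal_var=False`` for Welch).  Two calling
presets are available:

``default``
    |fold change| > 2 and BH-adjusted p < 0.05 (the standard DE criteria).
``strict``
    |fold change| >= 4 and raw p <= 1e-5 (the stricter candidate-level
    criteria).

Fold change is computed on the log2(TPM + 1) scale, so FC > 2 means
|log2FC| > 1.  Genes with zero TPM in every sample are reported as ``ns``
and excluded from testing (and from the BH family).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from varepi.core_io import ExpressionTable

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DEPreset:
    name: str
    fc: float                 # fold-change threshold (linear scale)
    alpha: float              # p-value threshold
    use_fdr: bool             # threshold on BH-adjusted (True) or raw p
    inclusive: bool = False   # thresholds compared with >= / <= instead of > / <


PRESETS: dict[str, DEPreset] = {
    "default": DEPreset("default", fc=2.0, alpha=0.05, use_fdr=True),
    "strict": DEPreset("strict", fc=4.0, alpha=1e-5, use_fdr=False, inclusive=True),
}


@dataclass(frozen=True)
class DEResult:
    gene_id: str
    mean_tpm1: float
    mean_tpm2: float
    log2fc: float             # condition 2 over condition 1, log2(TPM+1) scale
    pvalue: float             # NaN when untestable (single replicate, all-zero)
    fdr: float
    direction: str            # up | down | ns


@dataclass(frozen=True)
class OverlapSummary:
    n_a: int
    n_b: int
    n_overlap: int
    denominator: int
    percentage: float

    def __post_init__(self) -> None:
        if self.n_overlap > min(self.n_a, self.n_b):
            raise ValueError("overlap exceeds set size")


@dataclass(frozen=True)
class TargetShiftResult:
    statistic: float
    pvalue: float
    mean_shift: float
    n_genes: int


def bh_adjust(pvalues: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def differential_expression(expr: ExpressionTable, cond1: str, cond2: str,
                            preset: str | DEPreset = "default",
                            fc_threshold: float | None = None,
                            fdr_threshold: float | None = None,
                            equal_var: bool = True) -> list[DEResult]:
    """Per-gene t-test DE calls of cond2 versus cond1 on log2(TPM + 1).

    ``equal_var=True`` (default) uses Student's pooled-variance t;
    ``equal_var=False`` uses Welch's.  Explicit ``fc_threshold``/
    ``fdr_threshold`` override the preset's values (the override threshold is
    applied on the same p-value column the preset uses).  With a single
    replicate per condition no p-values exist and calling is
    fold-change-only (logged prominently).
    """
    ps = PRESETS[preset] if isinstance(preset, str) else preset
    fc = fc_threshold if fc_threshold is not None else ps.fc
    alpha = fdr_threshold if fdr_threshold is not None else ps.alpha

    m1 = expr.matrix(cond1)
    m2 = expr.matrix(cond2)
    genes = sorted(set(m1.index) & set(m2.index))
    a = np.log2(m1.loc[genes].to_numpy(dtype=float) + 1.0)
    b = np.log2(m2.loc[genes].to_numpy(dtype=float) + 1.0)
    mean_tpm1 = m1.loc[genes].mean(axis=1).to_numpy()
    mean_tpm2 = m2.loc[genes].mean(axis=1).to_numpy()
    log2fc = b.mean(axis=1) - a.mean(axis=1)
    all_zero = (mean_tpm1 == 0) & (mean_tpm2 == 0)

    single_rep = a.shape[1] < 2 or b.shape[1] < 2
    if single_rep:
        log.warning("single replicate per condition: p-values unavailable, "
                    "DE calling is fold-change-only")
        pvals = np.full(len(genes), np.nan)
    else:
        import warnings
        with np.errstate(divide="ignore", invalid="ignore"), \
                warnings.catch_warnings():
            # zero-variance genes trigger a precision warning; handled below
            warnings.simplefilter("ignore", RuntimeWarning)
            _, pvals = stats.ttest_ind(b, a, axis=1, equal_var=equal_var)
        # degenerate zero-variance genes: identical data -> null, else extreme
        nan_mask = np.isnan(pvals)
        pvals[nan_mask & (log2fc == 0)] = 1.0
        pvals[nan_mask & (log2fc != 0)] = 0.0

    tested = ~all_zero & ~np.isnan(pvals)
    fdr = np.full(len(genes), np.nan)
    if tested.any():
        fdr[tested] = bh_adjust(pvals[tested])

    log2_fc_cut = np.log2(fc)
    results = []
    for i, g in enumerate(genes):
        direction = "ns"
        if not all_zero[i]:
            fc_ok = (abs(log2fc[i]) >= log2_fc_cut if ps.inclusive
                     else abs(log2fc[i]) > log2_fc_cut)
            if single_rep:
                p_ok = True
            else:
                p = fdr[i] if ps.use_fdr else pvals[i]
                p_ok = (p <= alpha) if ps.inclusive else (p < alpha)
            if fc_ok and p_ok:
                direction = "up" if log2fc[i] > 0 else "down"
        results.append(DEResult(g, float(mean_tpm1[i]), float(mean_tpm2[i]),
                                float(log2fc[i]), float(pvals[i]),
                                float(fdr[i]), direction))
    return results


def de_results_frame(results: Iterable[DEResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results]).set_index("gene_id")


def _round_half_up(x: float, digits: int = 2) -> float:
    q = Decimal(10) ** -digits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def target_set_overlap(set_a: Iterable[str], set_b: Iterable[str],
                       denominator: int) -> OverlapSummary:
    """Overlap of two gene-id sets with a percentage of a declared denominator.

    The percentage is 100 * |A ∩ B| / denominator, rounded half-up to two
    decimals (the printed-table convention).
    """
    A, B = set(set_a), set(set_b)
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    n = len(A & B)
    return OverlapSummary(len(A), len(B), n, denominator,
                          _round_half_up(100.0 * n / denominator))


def paired_target_shift_test(target_genes: Iterable[str], expr: ExpressionTable,
                             cond1: str, cond2: str) -> TargetShiftResult:
    """Paired t-test of per-gene mean log2(TPM+1) shift across a target set.

    Each target gene contributes one paired observation
    (mean log2(TPM+1) in cond2) - (mean log2(TPM+1) in cond1); genes absent
    from the table are skipped with a log message.
    """
    m1, m2 = expr.matrix(cond1), expr.matrix(cond2)
    targets = sorted(set(target_genes))
    present = [g for g in targets if g in m1.index and g in m2.index]
    if len(present) < len(targets):
        log.info("paired_target_shift_test: %d of %d target genes absent "
                 "from the expression table", len(targets) - len(present),
                 len(targets))
    if len(present) < 2:
        raise ValueError("need >= 2 target genes with expression in both conditions")
    x1 = np.log2(m1.loc[present].to_numpy(dtype=float) + 1.0).mean(axis=1)
    x2 = np.log2(m2.loc[present].to_numpy(dtype=float) + 1.0).mean(axis=1)
    d = x2 - x1
    if np.allclose(d.std(ddof=1), 0.0) and np.allclose(d.mean(), 0.0):
        return TargetShiftResult(0.0, 1.0, 0.0, len(present))
    t, p = stats.ttest_rel(x2, x1)
    return TargetShiftResult(float(t), float(p), float(d.mean()), len(present))
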