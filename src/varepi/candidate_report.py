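"""Integrate all stages into the candidate list and the final report.

A *candidate* is a variant that (i) is epigenetically stable — its promoter
(H3K4me3) or enhancer (H3K27ac) state is active in both conditions — and
(ii) is assigned (nearest TSS) to a differentially expressed gene.  For each
candidate, allele-aware motif rescoring over the expressed TFs records which
factors gain a strong binding site on the alternate allele.

``run_pipeline`` orchestrates annotate -> epigenetic states -> DE -> motif
rescoring -> report over a bundle directory and returns a
:class:`PipelineResult` with all intermediate tables and a ``summary()``.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from varepi import core_io
from varepi.core_io import ExpressionTable, PFM, PWM, Peak, Variant, tsv_header_comment
from varepi.epi_state import (PeakSet, StableCall, call_states,
                              select_epigenetically_stable, switch_class_counts)
from varepi.expression_de import DEResult, differential_expression
from varepi.motif_scan import (AlleleDelta, expressed_tfs, extract_allele_windows,
                               allele_delta, pfm_to_pwm)
from varepi.region_annotation import (GeneAssignment, GeneIndex, RegionCall,
                                      assign_all, classify_all)

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All thresholds of the pipeline in one place."""

    cond1: str = "stem"
    cond2: str = "induced"
    flank: int = 1000                 # upstream/downstream region width (bp)
    scan_half_width: int = 75         # cohort scan: 150-bp windows
    rescore_half_width: int = 6       # candidate rescoring: 12-bp windows
    score_cutoff: float = 10.0        # strong motif-hit threshold (log-odds)
    tpm_cutoff: float = 3.0           # TF presence gate
    min_count_diff: int = 10          # differential-TF count threshold
    de_preset: str = "default"
    pseudocount: float = 0.5
    require_repressive_stable: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class CandidateVariant:
    variant: Variant
    region: RegionCall | None
    assignment: GeneAssignment
    mark: str                       # qualifying mark (H3K4me3 / H3K27ac)
    via: str                        # promoter | enhancer | both
    de: DEResult
    tf_gains: list[AlleleDelta] = field(default_factory=list)
    no_tf_gain: bool = False


def select_candidates(stable_variants: Sequence[StableCall],
                      gene_assignments: Mapping[str, GeneAssignment],
                      de_results: Mapping[str, DEResult] | Sequence[DEResult],
                      variants: Mapping[str, Variant],
                      regions: Mapping[str, RegionCall] | None = None
                      ) -> list[CandidateVariant]:
    """Stable variants whose assigned gene is differentially expressed."""
    if not isinstance(de_results, Mapping):
        de_results = {r.gene_id: r for r in de_results}
    out = []
    for stable in stable_variants:
        assignment = gene_assignments.get(stable.variant_key)
        if assignment is None:
            continue
        de = de_results.get(assignment.gene_id)
        if de is None or de.direction == "ns":
            continue
        out.append(CandidateVariant(
            variant=variants[stable.variant_key],
            region=regions.get(stable.variant_key) if regions else None,
            assignment=assignment, mark=stable.mark, via=stable.via, de=de))
    return out


def annotate_tf_gains(candidate: CandidateVariant, genome: Mapping[str, str],
                      pwms: Sequence[PWM], expr: ExpressionTable,
                      tf_gene_map: Mapping[str, str], cond2: str,
                      rescore_half_width: int = 6,
                      score_cutoff: float = 10.0,
                      tpm_cutoff: float = 3.0) -> CandidateVariant:
    """Allele rescoring for one candidate over the expressed TFs.

    The expression gate uses the induced condition (``cond2``), where the
    gained site would act; a TF is retained iff its alternate-allele best
    score reaches the cutoff.  Deltas are sorted by diff descending.  A
    candidate with no qualifying TF is kept but flagged.
    """
    expressed = expressed_tfs(expr, cond2, tf_gene_map, tpm_cutoff)
    windows = extract_allele_windows(genome, candidate.variant, rescore_half_width)
    gains = []
    for pwm in pwms:
        if pwm.tf_name not in expressed:
            continue
        delta = allele_delta(pwm, windows)
        if delta.score_alt >= score_cutoff:
            gains.append(delta)
    candidate.tf_gains = sorted(gains, key=lambda d: (-d.diff, d.tf_name))
    candidate.no_tf_gain = not gains
    return candidate


# ---------------------------------------------------------------------------
# report writing
# ---------------------------------------------------------------------------

CANDIDATE_COLUMNS = ["chrom", "pos", "ref", "alt", "location", "gene",
                     "modification_type", "tss_distance", "log2fc", "fdr",
                     "direction"]
TF_GAIN_COLUMNS = ["variant", "tf", "expr_cond1", "expr_cond2", "score_alt",
                   "score_ref", "diff"]


def write_report(candidates: Sequence[CandidateVariant], out_dir: str | Path,
                 expr: ExpressionTable | None = None,
                 tf_gene_map: Mapping[str, str] | None = None,
                 cond1: str = "stem", cond2: str = "induced",
                 config_hash: str = "", seed: int | None = None) -> dict[str, Path]:
    """Write candidates.tsv, tf_gains.tsv and a JSON run manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    header = tsv_header_comment(config_hash)

    cand_rows = []
    gain_rows = []
    mean1 = expr.mean_tpm(cond1) if expr is not None else None
    mean2 = expr.mean_tpm(cond2) if expr is not None else None
    for c in candidates:
        cand_rows.append({
            "chrom": c.variant.chrom, "pos": c.variant.pos,
            "ref": c.variant.ref, "alt": c.variant.alt,
            "location": c.region.category if c.region else "",
            "gene": c.assignment.gene_id, "modification_type": c.mark,
            "tss_distance": c.assignment.distance,
            "log2fc": round(c.de.log2fc, 4), "fdr": c.de.fdr,
            "direction": c.de.direction})
        for d in sorted(c.tf_gains, key=lambda d: (-d.diff, d.tf_name)):
            gene = tf_gene_map.get(d.tf_name) if tf_gene_map else None
            gain_rows.append({
                "variant": c.variant.key, "tf": d.tf_name,
                "expr_cond1": round(float(mean1.get(gene, float("nan"))), 4)
                              if mean1 is not None and gene else "",
                "expr_cond2": round(float(mean2.get(gene, float("nan"))), 4)
                              if mean2 is not None and gene else "",
                "score_alt": round(d.score_alt, 4),
                "score_ref": round(d.score_ref, 4),
                "diff": round(d.diff, 4)})

    paths = {"candidates": out_dir / "candidates.tsv",
             "tf_gains": out_dir / "tf_gains.tsv",
             "manifest": out_dir / "run_manifest.json"}
    for name, rows, cols in (("candidates", cand_rows, CANDIDATE_COLUMNS),
                             ("tf_gains", gain_rows, TF_GAIN_COLUMNS)):
        with open(paths[name], "w") as fh:
            fh.write(header + "\n")
            pd.DataFrame(rows, columns=cols).to_csv(fh, sep="\t", index=False)
    with open(paths["manifest"], "w") as fh:
        json.dump({"tool": "varepi", "version": __import__("varepi").__version__,
                   "config_hash": config_hash, "seed": seed,
                   "n_candidates": len(candidates)}, fh, indent=2)
        fh.write("\n")
    return paths


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

@dataclass
class PipelineResult:
    config: PipelineConfig
    candidates: list[CandidateVariant]
    stable: list[StableCall]
    regions: dict[str, RegionCall]
    assignments: dict[str, GeneAssignment]
    state_calls: dict[str, dict]
    de_results: list[DEResult]
    n_variants: int

    @property
    def candidate_keys(self) -> set[str]:
        return {c.variant.key for c in self.candidates}

    def switch_counts(self, mark: str) -> dict[str, int]:
        return switch_class_counts(self.state_calls, mark)

    def summary(self) -> str:
        n_de = sum(1 for r in self.de_results if r.direction != "ns")
        lines = [
            f"varepi pipeline summary (config {self.config.hash()})",
            f"  variants analysed:        {self.n_variants}",
            f"  epigenetically stable:    {len(self.stable)}"
            f" (promoter {sum(1 for s in self.stable if s.mark == 'H3K4me3')},"
            f" enhancer {sum(1 for s in self.stable if s.mark == 'H3K27ac')})",
            f"  DE genes ({self.config.de_preset} preset): {n_de}",
            f"  candidate variants:       {len(self.candidates)}",
        ]
        for c in self.candidates:
            gains = ", ".join(f"{d.tf_name} (+{d.diff:.2f})" for d in c.tf_gains[:3])
            lines.append(f"    {c.variant.key}  {c.region.category if c.region else '?'}"
                         f"  {c.assignment.gene_id}  {c.mark}"
                         f"  log2FC={c.de.log2fc:+.2f}"
                         f"  gains: {gains or 'none'}")
        return "\n".join(lines)


def run_pipeline(bundle_dir: str | Path,
                 config: PipelineConfig | None = None,
                 out_dir: str | Path | None = None,
                 seed: int | None = None) -> PipelineResult:
    """Run every stage over a bundle directory.

    Expects the layout written by :func:`varepi.synthetic_data.generate_bundle`:
    genome.fa, genes.gtf, variants.vcf, peaks/<mark>_<condition>.narrowPeak,
    expression.tsv, motifs.jaspar, tf_gene_map.tsv.
    """
    cfg = config or PipelineConfig()
    bundle = Path(bundle_dir)

    genome = core_io.read_fasta(bundle / "genome.fa")
    models = core_io.read_gene_models(bundle / "genes.gtf")
    variants = core_io.read_variants(bundle / "variants.vcf")
    expr = core_io.read_expression(bundle / "expression.tsv")
    pfms = core_io.read_jaspar(bundle / "motifs.jaspar")
    tf_gene_map = read_tf_gene_map(bundle / "tf_gene_map.tsv")
    peaks: list[Peak] = []
    for path in sorted((bundle / "peaks").glob("*.narrowPeak")):
        mark, condition = path.stem.rsplit("_", 1)
        peaks.extend(core_io.read_peaks(path, mark, condition))

    index = GeneIndex(models)
    vmap = {v.key: v for v in variants}
    regions = classify_all(variants, index, cfg.flank)
    assignments = assign_all(variants, index)

    peakset = PeakSet(peaks)
    marks = sorted({p.mark for p in peaks})
    states = call_states(variants, peakset, marks, cfg.cond1, cfg.cond2)
    stable = select_epigenetically_stable(
        states, require_repressive_stable=cfg.require_repressive_stable)

    de_results = differential_expression(expr, cfg.cond1, cfg.cond2,
                                         preset=cfg.de_preset)
    de_map = {r.gene_id: r for r in de_results}

    candidates = select_candidates(stable, assignments, de_map, vmap, regions)
    pwms = [pfm_to_pwm(p, cfg.pseudocount) for p in pfms]
    for c in candidates:
        annotate_tf_gains(c, genome, pwms, expr, tf_gene_map, cfg.cond2,
                          cfg.rescore_half_width, cfg.score_cutoff,
                          cfg.tpm_cutoff)

    result = PipelineResult(cfg, candidates, stable, regions, assignments,
                            states, de_results, len(variants))
    if out_dir is not None:
        write_report(candidates, out_dir, expr, tf_gene_map,
                     cfg.cond1, cfg.cond2, cfg.hash(), seed)
    return result


def read_tf_gene_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV mapping TF/motif name -> gene id (no fuzzy matching)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["tf", "gene_id"], dtype=str)
    if df["tf"].duplicated().any():
        raise ValueError(f"{path}: duplicate TF names")
    return dict(zip(df["tf"], df["gene_id"]))


def write_tf_gene_map(mapping: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for tf, gene in sorted(mapping.items()):
            fh.write(f"{tf}\t{gene}\n")
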