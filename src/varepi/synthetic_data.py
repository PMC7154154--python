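"""Self-contained toy dataset generator with a known ground-truth manifest.

The generator emulates the study design end to end on a small scale: a
single-contig genome, non-overlapping multi-exon gene models, variants
placed by region category with a C>T-dominated substitution spectrum and a
~55% indel fraction, per-mark/condition peak sets realizing a configurable
state-switch plan (46 promoter-stable + 20 enhancer-stable by default),
lognormal TPM expression with planted fold changes, and causal variants
planted inside motif matches so that the alternate allele completes the
consensus and crosses the strong-hit score threshold while the reference
allele breaks it.

Every planted label is recorded in a :class:`TruthManifest`, which suffices
to score pipeline recovery without re-reading generator internals.  All
randomness flows through one seeded ``numpy.random.Generator``; re-runs with
the same seed are byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from varepi import core_io
from varepi.core_io import (BASES, ExpressionTable, GeneModel, PFM, PWM, Peak,
                            Variant)
from varepi.motif_scan import allele_delta, extract_allele_windows, pfm_to_pwm
from varepi.region_annotation import (CATEGORIES, GeneIndex, _RANK, assign_all,
                                      paint_chromosome)

log = logging.getLogger(__name__)

DEFAULT_SPECTRUM: dict[str, float] = {
    # C>T transitions dominate, G>C is rarest (the observed SNV spectrum shape)
    "C>T": 0.21, "G>A": 0.17, "A>G": 0.10, "T>C": 0.10,
    "C>A": 0.07, "G>T": 0.07, "A>C": 0.05, "T>G": 0.05,
    "A>T": 0.05, "T>A": 0.05, "C>G": 0.05, "G>C": 0.03,
}

DEFAULT_REGION_WEIGHTS: dict[str, float] = {
    "intronic": 0.34, "intergenic": 0.28, "exonic": 0.10,
    "ncRNA_intronic": 0.08, "upstream": 0.06, "downstream": 0.06,
    "UTR5": 0.03, "UTR3": 0.05,
}

#: per-mark switch-class counts (remaining variants get the null class)
DEFAULT_SWITCH_PLAN: dict[str, dict[str, int]] = {
    "H3K4me3": {"A->A": 46, "I->A": 30, "A->I": 30},
    "H3K27ac": {"A->A": 20, "I->A": 18, "A->I": 12},
    "H3K27me3": {},
    "DNAme": {},
}


@dataclass
class SimConfig:
    """Study-condition defaults for the synthetic bundle."""

    genome_length: int = 500_000
    gc: float = 0.41
    chrom: str = "chr1"
    n_genes: int = 50
    n_variants: int = 1000
    indel_fraction: float = 0.55
    indel_max_len: int = 5
    flank: int = 1000
    region_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_REGION_WEIGHTS))
    spectrum: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SPECTRUM))
    switch_plan: dict[str, dict[str, int]] = field(
        default_factory=lambda: {m: dict(p) for m, p in DEFAULT_SWITCH_PLAN.items()})
    n_background_peaks: int = 80
    de_fraction: float = 0.2
    effect_log2: float = 2.0
    reps: int = 5
    sigma_log2: float = 0.3
    n_causal: int = 6                 # planted candidate variants
    n_causal_enhancer: int = 1        # of which enhancer-stable (H3K27ac)
    score_cutoff: float = 10.0
    cond1: str = "stem"
    cond2: str = "induced"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        import yaml
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown simulation config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class TruthManifest:
    """Planted ground truth for every generated entity."""

    seed: int
    region_categories: dict[str, str] = field(default_factory=dict)
    substitutions: dict[str, str] = field(default_factory=dict)  # SNVs only
    switch_classes: dict[str, dict[str, str]] = field(default_factory=dict)
    stable: dict[str, str] = field(default_factory=dict)   # key -> qualifying mark
    de_genes: dict[str, dict] = field(default_factory=dict)
    expressed_tfs: dict[str, list] = field(default_factory=dict)
    causal: list[dict] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthManifest":
        with open(path) as fh:
            return cls(**json.load(fh))

    @property
    def causal_keys(self) -> set[str]:
        return {c["variant_key"] for c in self.causal}


def _rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# genome and gene models
# ---------------------------------------------------------------------------

def generate_genome(length: int = 500_000, gc: float = 0.41,
                    seed: int | np.random.Generator = 0) -> str:
    """I.i.d. random sequence with the given GC content."""
    if length < 10_000:
        raise ValueError("genome length must be >= 10 kb")
    rng = _rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codes = rng.choice(4, size=length, p=p)
    return "".join(BASES[c] for c in codes)


def generate_gene_models(genome_length: int = 500_000, n_genes: int = 50,
                         seed: int | np.random.Generator = 0,
                         chrom: str = "chr1",
                         noncoding_fraction: float = 0.2,
                         min_gap: int = 2000) -> list[GeneModel]:
    """Non-overlapping multi-exon genes on both strands, ~20% noncoding.

    The TSS-adjacent exon is kept short (150-300 bp) so that first introns
    start close to the TSS.
    """
    rng = _rng(seed)
    models: list[GeneModel] = []
    cursor = min_gap + 1000   # leave room for upstream flanks
    for i in range(n_genes):
        n_exons = int(rng.integers(2, 5))
        first_exon = int(rng.integers(150, 301))
        exon_lens = [first_exon] + [int(rng.integers(100, 301))
                                    for _ in range(n_exons - 1)]
        intron_lens = [int(rng.integers(400, 1201)) for _ in range(n_exons - 1)]
        gene_len = sum(exon_lens) + sum(intron_lens)
        start = cursor + int(rng.integers(0, 1001))
        end = start + gene_len - 1
        if end + min_gap > genome_length - 1000:
            log.warning("genome full after %d genes", i)
            break
        strand = "+" if rng.random() < 0.5 else "-"
        # exon order along the genome; TSS-adjacent exon is the short one
        lens = exon_lens if strand == "+" else exon_lens[::-1]
        ilens = intron_lens if strand == "+" else intron_lens[::-1]
        exons = []
        s = start
        for j, el in enumerate(lens):
            exons.append((s, s + el - 1))
            if j < len(ilens):
                s = s + el + ilens[j]
        noncoding = rng.random() < noncoding_fraction
        utr5: tuple = ()
        utr3: tuple = ()
        if not noncoding:
            # UTRs inside the terminal exons
            u5 = int(rng.integers(30, min(100, first_exon - 30)))
            if strand == "+":
                utr5 = ((exons[0][0], exons[0][0] + u5 - 1),)
                last = exons[-1]
            else:
                utr5 = ((exons[-1][1] - u5 + 1, exons[-1][1]),)
                last = exons[0]
            u3 = int(rng.integers(30, min(100, last[1] - last[0] - 20)))
            utr3 = ((last[0], last[0] + u3 - 1),) if strand == "-" \
                else ((last[1] - u3 + 1, last[1]),)
        gid = f"gene{i + 1:04d}"
        models.append(GeneModel(
            gene_id=gid, gene_name=gid.upper(), chrom=chrom, strand=strand,
            tss=start if strand == "+" else end,
            tes=end if strand == "+" else start,
            exons=tuple(exons), utr5=utr5, utr3=utr3,
            biotype="noncoding" if noncoding else "coding",
            transcript_id=gid + ".1"))
        cursor = end + min_gap
    return models


# ---------------------------------------------------------------------------
# variants
# ---------------------------------------------------------------------------

def generate_variants(genome: str, models: Sequence[GeneModel],
                      n: int = 1000,
                      region_weights: Mapping[str, float] | None = None,
                      spectrum: Mapping[str, float] | None = None,
                      seed: int | np.random.Generator = 0,
                      chrom: str = "chr1",
                      indel_fraction: float = 0.55,
                      indel_max_len: int = 5,
                      flank: int = 1000,
                      reserved: set[int] | None = None
                      ) -> tuple[list[Variant], dict[str, str], dict[str, str]]:
    """Variants placed per category weights with a planted SNV spectrum.

    Returns (variants, planted category per key, planted substitution per
    SNV key).  ``reserved`` positions (1-based) are never touched; each
    generated variant reserves its own footprint.
    """
    rng = _rng(seed)
    weights = dict(region_weights or DEFAULT_REGION_WEIGHTS)
    spec = dict(spectrum or DEFAULT_SPECTRUM)
    L = len(genome)
    paint = paint_chromosome(L, list(models), chrom, flank)
    codes = np.frombuffer(genome.encode(), dtype=np.uint8)
    base_code = {b: ord(b) for b in BASES}

    # positions per (category, base), 1-based; keep 100 bp off the contig ends
    usable = np.zeros(L + 1, dtype=bool)
    usable[101:L - 100] = True
    pos_by_cat: dict[str, dict[str, np.ndarray]] = {}
    for cat in weights:
        mask = (paint == _RANK[cat]) & usable
        positions = np.flatnonzero(mask)
        pos_by_cat[cat] = {
            b: positions[codes[positions - 1] == base_code[b]] for b in BASES}

    cats = [c for c in weights if weights[c] > 0]
    cat_p = np.array([weights[c] for c in cats], dtype=float)
    cat_p /= cat_p.sum()
    subs = sorted(spec)
    sub_p = np.array([spec[s] for s in subs], dtype=float)
    sub_p /= sub_p.sum()

    taken = set(reserved or ())
    variants: list[Variant] = []
    truth_cat: dict[str, str] = {}
    truth_sub: dict[str, str] = {}
    max_tries = 50 * n
    tries = 0
    while len(variants) < n and tries < max_tries:
        tries += 1
        cat = cats[rng.choice(len(cats), p=cat_p)]
        if rng.random() < indel_fraction:
            pool = np.concatenate([pos_by_cat[cat][b] for b in BASES])
            if pool.size == 0:
                continue
            pos = int(pool[rng.integers(pool.size)])
            length = int(rng.integers(1, indel_max_len + 1))
            if rng.random() < 0.5 and pos + length <= L:       # deletion
                ref = genome[pos - 1:pos - 1 + 1 + length]
                alt = ref[0]
            else:                                               # insertion
                ref = genome[pos - 1]
                ins = "".join(BASES[c] for c in rng.integers(0, 4, size=length))
                alt = ref + ins
            sub = None
        else:
            sub = subs[rng.choice(len(subs), p=sub_p)]
            ref_base = sub[0]
            pool = pos_by_cat[cat][ref_base]
            if pool.size == 0:
                continue
            pos = int(pool[rng.integers(pool.size)])
            ref, alt = ref_base, sub[2]
        footprint = range(pos - 1, pos + len(ref) + 1)
        if any(p in taken for p in footprint):
            continue
        taken.update(footprint)
        v = Variant(chrom=chrom, pos=pos, ref=ref, alt=alt)
        variants.append(v)
        truth_cat[v.key] = cat
        if sub is not None:
            truth_sub[v.key] = sub
    if len(variants) < n:
        raise RuntimeError(f"could only place {len(variants)} of {n} variants")
    return variants, truth_cat, truth_sub


# ---------------------------------------------------------------------------
# peaks realizing a switch plan
# ---------------------------------------------------------------------------

def plan_switch_classes(variants: Sequence[Variant],
                        switch_plan: Mapping[str, Mapping[str, int]],
                        seed: int | np.random.Generator = 0,
                        forced: Mapping[str, Mapping[str, str]] | None = None,
                        stable_pool: set[str] | None = None
                        ) -> dict[str, dict[str, str]]:
    """Assign a switch class per variant per mark so the plan counts are met.

    ``forced`` pins specific variants to specific classes (consuming plan
    slots); ``stable_pool`` restricts which unpinned variants may receive an
    activating A->A class.  The H3K4me3 and H3K27ac A->A sets are disjoint.
    """
    rng = _rng(seed)
    forced = {k: dict(v) for k, v in (forced or {}).items()}
    keys = [v.key for v in variants]
    if len(set(keys)) != len(keys):
        raise ValueError("duplicate variant keys")
    pool = set(stable_pool) if stable_pool is not None else set(keys)
    assignment: dict[str, dict[str, str]] = {k: {} for k in keys}
    for k, per_mark in forced.items():
        for mark, label in per_mark.items():
            assignment[k][mark] = label

    stable_taken: set[str] = set()
    for mark in ("H3K4me3", "H3K27ac"):        # A->A sets first, disjointly
        plan = dict(switch_plan.get(mark, {}))
        want = plan.get("A->A", 0)
        have = [k for k in keys if assignment[k].get(mark) == "A->A"]
        need = want - len(have)
        if need < 0:
            raise ValueError(f"{mark}: more forced A->A than planned")
        eligible = [k for k in keys
                    if k in pool and k not in stable_taken
                    and mark not in assignment[k]]
        if need > len(eligible):
            raise ValueError(f"{mark}: stable pool too small for the plan")
        chosen = list(rng.choice(eligible, size=need, replace=False)) if need else []
        for k in chosen:
            assignment[k][mark] = "A->A"
        stable_taken.update(chosen + have)

    for mark, plan in switch_plan.items():
        null = "T->T" if mark in core_io.REPRESSIVE_MARKS else "I->I"
        todo: list[str] = []
        for label, count in plan.items():
            if label == "A->A" and mark in ("H3K4me3", "H3K27ac"):
                continue
            have = sum(1 for k in keys if assignment[k].get(mark) == label)
            todo.extend([label] * (count - have))
        free = [k for k in keys if mark not in assignment[k]]
        if len(todo) > len(free):
            raise ValueError(f"{mark}: plan exceeds the number of variants")
        chosen = list(rng.choice(free, size=len(todo), replace=False)) if todo else []
        for k, label in zip(chosen, todo):
            assignment[k][mark] = label
        for k in keys:
            assignment[k].setdefault(mark, null)
    return assignment


def generate_peaks(variants: Sequence[Variant],
                   switch_plan: Mapping[str, Mapping[str, int]] | None = None,
                   seed: int | np.random.Generator = 0,
                   genome_length: int = 500_000,
                   conditions: tuple[str, str] = ("stem", "induced"),
                   forced: Mapping[str, Mapping[str, str]] | None = None,
                   stable_pool: set[str] | None = None,
                   n_background: int = 80,
                   assignment: Mapping[str, Mapping[str, str]] | None = None,
                   half_width: int = 150
                   ) -> tuple[list[Peak], dict[str, dict[str, str]]]:
    """Peaks such that state calling reproduces the planned class exactly.

    A peak is placed over a variant's position for every (mark, condition)
    whose planned state is active/inhibited, clipped so it covers no other
    variant; background peaks are added away from every variant.
    """
    rng = _rng(seed)
    if assignment is None:
        assignment = plan_switch_classes(
            variants, switch_plan or DEFAULT_SWITCH_PLAN, rng, forced, stable_pool)
    pos_of = {v.key: v.pos for v in variants}
    positions = np.array(sorted(pos_of.values()))
    peaks: list[Peak] = []
    for key, per_mark in sorted(assignment.items()):
        pos = pos_of[key]
        i = np.searchsorted(positions, pos)
        prev = int(positions[i - 1]) if i > 0 else None
        nxt = int(positions[i + 1]) if i + 1 < len(positions) else None
        start = max(pos - half_width, 0 if prev is None else prev + 1)
        end = min(pos + half_width, genome_length if nxt is None else nxt)
        for mark, label in per_mark.items():
            s1, s2 = label.split("->")
            for state, cond in zip((s1, s2), conditions):
                if state in ("A", "In"):
                    peaks.append(Peak(variants[0].chrom, start, end, mark, cond,
                                      score=float(rng.uniform(5, 50))))
    # background peaks clear of every variant position
    occupied = set(int(p) for p in positions)
    for mark in (switch_plan or DEFAULT_SWITCH_PLAN):
        for cond in conditions:
            placed = 0
            tries = 0
            while placed < n_background and tries < n_background * 50:
                tries += 1
                length = int(rng.integers(200, 801))
                start = int(rng.integers(0, genome_length - length))
                if any(start <= p < start + length for p in occupied):
                    continue
                peaks.append(Peak(variants[0].chrom, start, start + length,
                                  mark, cond, score=float(rng.uniform(5, 50))))
                placed += 1
    return peaks, {k: dict(v) for k, v in assignment.items()}


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def generate_expression(gene_ids: Sequence[str],
                        de_plan: Mapping[str, float] | None = None,
                        de_fraction: float = 0.0,
                        effect_log2: float = 2.0,
                        reps: int = 3,
                        sigma_log2: float = 0.3,
                        seed: int | np.random.Generator = 0,
                        conditions: tuple[str, str] = ("stem", "induced"),
                        tf_plan: Mapping[str, tuple[bool, bool]] | None = None
                        ) -> tuple[ExpressionTable, dict[str, dict]]:
    """Lognormal TPM table with planted fold changes.

    Baseline log2(TPM+1) means are Normal(3, 2) truncated at 0 (differential
    genes draw from Uniform(4, 6) so down-shifts stay positive); condition-2
    means are shifted by the planted signed effect.  ``de_plan`` maps gene id
    to a signed log2 effect; alternatively ``de_fraction`` picks genes at
    random with alternating sign.  ``tf_plan`` maps TF gene ids to
    (expressed in cond1, expressed in cond2) targets straddling the TPM >= 3
    presence gate.

    Returns the table and the DE truth ``{gene: {direction, effect_log2}}``.
    """
    rng = _rng(seed)
    cond1, cond2 = conditions
    plan = dict(de_plan) if de_plan is not None else {}
    if de_plan is None and de_fraction > 0:
        n_de = int(round(de_fraction * len(gene_ids)))
        chosen = rng.choice(np.asarray(gene_ids, dtype=object), size=n_de,
                            replace=False)
        for i, g in enumerate(chosen):
            plan[str(g)] = effect_log2 if i % 2 == 0 else -effect_log2

    rows = []
    truth: dict[str, dict] = {}
    for g in gene_ids:
        if g in plan:
            mu1 = float(rng.uniform(4, 6))
            mu2 = mu1 + plan[g]
            truth[g] = {"direction": "up" if plan[g] > 0 else "down",
                        "effect_log2": float(plan[g])}
        else:
            mu1 = mu2 = max(0.0, float(rng.normal(3, 2)))
        for cond, mu in ((cond1, mu1), (cond2, mu2)):
            for r in range(1, reps + 1):
                x = max(0.0, float(rng.normal(mu, sigma_log2)))
                rows.append((g, cond, f"r{r}", 2.0 ** x - 1.0))
    for g, (on1, on2) in (tf_plan or {}).items():
        for cond, on in ((cond1, on1), (cond2, on2)):
            mu = float(rng.uniform(3.2, 5.3)) if on else float(rng.uniform(0.3, 1.3))
            for r in range(1, reps + 1):
                x = max(0.0, float(rng.normal(mu, sigma_log2)))
                rows.append((g, cond, f"r{r}", 2.0 ** x - 1.0))
    table = ExpressionTable(pd.DataFrame(
        rows, columns=["gene_id", "condition", "replicate", "tpm"]))
    return table, truth


# ---------------------------------------------------------------------------
# motif library and regulatory plants
# ---------------------------------------------------------------------------

def toy_pfm_library() -> list[PFM]:
    """Ten fixed toy PFMs, widths 6-15, mostly sharp columns.

    The library is deterministic (internal fixed seed) and independent of the
    bundle seed, playing the role of the motif database.
    """
    rng = np.random.default_rng(20180101)
    pfms = []
    for i, width in enumerate(range(6, 16), start=1):
        consensus = rng.integers(0, 4, size=width)
        counts = np.full((4, width), 1.0)
        for j, b in enumerate(consensus):
            counts[b, j] = 97.0
        # one softer, degenerate column in the wider motifs
        if width >= 10:
            j = width // 3
            counts[:, j] = 10.0
            counts[consensus[j], j] = 70.0
        pfms.append(PFM(tf_name=f"TF{i:02d}", counts=counts))
    return pfms


def plant_regulatory_variant(genome: str, pwm: PWM, site_pos: int,
                             mode: str = "gain",
                             score_cutoff: float = 10.0
                             ) -> tuple[str, Variant]:
    """Write a motif match around ``site_pos`` and return the edited genome.

    In ``gain`` mode the consensus is written with the variant column broken
    by the reference allele, so the alternate allele completes the motif:
    score_alt >= cutoff > score_ref under the shipped PWM set.  ``loss`` is
    the mirror image.  The variant column is the motif's middle column.
    """
    if mode not in ("gain", "loss"):
        raise ValueError("mode must be 'gain' or 'loss'")
    w = pwm.width
    col = w // 2
    consensus = pwm.consensus
    strong = consensus[col]
    weak = BASES[int(np.argmin(pwm.weights[:, col]))]
    motif_start = site_pos - 1 - col            # 0-based
    if motif_start < 0 or motif_start + w > len(genome):
        raise ValueError("site too close to the contig edge for the motif")
    site = consensus[:col] + (weak if mode == "gain" else strong) + consensus[col + 1:]
    edited = genome[:motif_start] + site + genome[motif_start + w:]
    ref, alt = (weak, strong) if mode == "gain" else (strong, weak)
    return edited, (ref, alt)


# ---------------------------------------------------------------------------
# the full bundle
# ---------------------------------------------------------------------------

@dataclass
class Bundle:
    config: SimConfig
    genome: dict[str, str]
    models: list[GeneModel]
    variants: list[Variant]
    peaks: list[Peak]
    expression: ExpressionTable
    pfms: list[PFM]
    tf_gene_map: dict[str, str]
    truth: TruthManifest


def _pick_causal_sites(models: Sequence[GeneModel], causal_genes: Sequence[GeneModel],
                       rng: np.random.Generator) -> list[int]:
    """One intron position near the TSS per causal gene (1-based)."""
    sites = []
    for m in causal_genes:
        # the intron adjacent to the TSS-side exon
        if m.strand == "+":
            intron = (m.exons[0][1] + 1, m.exons[1][0] - 1)
        else:
            intron = (m.exons[-2][1] + 1, m.exons[-1][0] - 1)
        lo, hi = intron[0] + 20, intron[1] - 20
        # stay within 900 bp of the TSS so the nearest-TSS gene is this gene
        if m.strand == "+":
            hi = min(hi, m.tss + 900)
        else:
            lo = max(lo, m.tss - 900)
        if lo > hi:
            raise RuntimeError(f"gene {m.gene_id}: no room for a causal site")
        sites.append(int(rng.integers(lo, hi + 1)))
    return sites


def generate_bundle(config: SimConfig | None = None,
                    seed: int = 17,
                    out_dir: str | Path | None = None) -> Bundle:
    """Generate the complete toy dataset and its truth manifest.

    With ``out_dir`` the bundle is written in the layout ``run_pipeline``
    expects (FASTA, GTF, VCF, narrowPeak files, expression TSV, JASPAR
    motifs, TF-gene map, truth manifest as JSON + TSV).
    """
    cfg = config or SimConfig()
    rng = np.random.default_rng(seed)
    chrom = cfg.chrom

    genome = generate_genome(cfg.genome_length, cfg.gc, rng)
    models = generate_gene_models(cfg.genome_length, cfg.n_genes, rng, chrom)
    pfms = toy_pfm_library()
    pwms = {p.tf_name: pfm_to_pwm(p) for p in pfms}
    tf_gene_map = {p.tf_name: f"tfgene_{p.tf_name}" for p in pfms}
    expressed = [p.tf_name for p in pfms[:7]]
    tf_plan = {tf_gene_map[p.tf_name]: (p.tf_name in expressed,
                                        p.tf_name in expressed) for p in pfms}

    # causal genes: prefer one noncoding among them, all with >= 2 exons
    noncoding = [m for m in models if m.biotype == "noncoding"]
    coding = [m for m in models if m.biotype == "coding"]
    causal_genes = (noncoding[:1] + coding)[:cfg.n_causal]
    if len(causal_genes) < cfg.n_causal:
        raise RuntimeError("not enough genes for the causal plan")

    # plant the causal variants: consensus written with the ref allele broken.
    # Only motifs whose maximum score sits within one broken column of the
    # cutoff can realize score_alt >= cutoff > score_ref; in this library
    # that is the width-9/10 sharp motifs.
    plant_tfs = [tf for tf in expressed
                 if 9 <= pwms[tf].width <= 10
                 and pwms[tf].max_score >= cfg.score_cutoff]
    sites = _pick_causal_sites(models, causal_genes, rng)
    causal_variants: list[Variant] = []
    causal_records: list[dict] = []
    reserved: set[int] = set()
    for idx, (gene, site) in enumerate(zip(causal_genes, sites)):
        tf = plant_tfs[idx % len(plant_tfs)]
        pwm = pwms[tf]
        genome, (ref, alt) = plant_regulatory_variant(genome, pwm, site, "gain",
                                                      cfg.score_cutoff)
        v = Variant(chrom=chrom, pos=site, ref=ref, alt=alt)
        win = extract_allele_windows({chrom: genome}, v, 6)
        delta = allele_delta(pwm, win)
        if not (delta.score_alt >= cfg.score_cutoff > delta.score_ref):
            raise RuntimeError(
                f"planted site at {v.key} violates the score relation "
                f"(ref {delta.score_ref:.2f}, alt {delta.score_alt:.2f})")
        causal_variants.append(v)
        causal_records.append({"variant_key": v.key, "gene_id": gene.gene_id,
                               "tf": tf, "site": site})
        reserved.update(range(site - pwm.width - 2, site + pwm.width + 3))

    background, truth_cat, truth_sub = generate_variants(
        genome, models, cfg.n_variants - len(causal_variants),
        cfg.region_weights, cfg.spectrum, rng, chrom,
        cfg.indel_fraction, cfg.indel_max_len, cfg.flank, reserved)
    variants = causal_variants + background
    index = GeneIndex(models)
    for v, rec in zip(causal_variants, causal_records):
        gene = next(m for m in models if m.gene_id == rec["gene_id"])
        truth_cat[v.key] = ("intronic" if gene.biotype == "coding"
                            else "ncRNA_intronic")
        truth_sub[v.key] = f"{v.ref}>{v.alt}"

    # expression: causal genes up, extra DE genes to reach the fraction
    de_plan = {m.gene_id: cfg.effect_log2 for m in causal_genes}
    n_extra = max(0, int(round(cfg.de_fraction * cfg.n_genes)) - len(causal_genes))
    causal_ids = set(de_plan)
    others = [m.gene_id for m in models if m.gene_id not in causal_ids]
    extra = list(rng.choice(others, size=min(n_extra, len(others)), replace=False))
    for i, g in enumerate(extra):
        de_plan[g] = cfg.effect_log2 if i % 2 == 0 else -cfg.effect_log2
    gene_ids = [m.gene_id for m in models]
    expr, de_truth = generate_expression(
        gene_ids, de_plan=de_plan, reps=cfg.reps, sigma_log2=cfg.sigma_log2,
        seed=rng, conditions=(cfg.cond1, cfg.cond2), tf_plan=tf_plan)

    # stable pool: only variants whose nearest gene is not differentially
    # expressed may receive an (unforced) A->A class
    assignments = assign_all(variants, index)
    de_gene_set = set(de_plan)
    stable_pool = {k for k, a in assignments.items()
                   if a.gene_id not in de_gene_set}
    forced: dict[str, dict[str, str]] = {}
    n_enh = cfg.n_causal_enhancer
    for i, v in enumerate(causal_variants):
        if i < len(causal_variants) - n_enh:
            forced[v.key] = {"H3K4me3": "A->A", "H3K27ac": "I->I"}
            causal_records[i]["mark"] = "H3K4me3"
        else:
            forced[v.key] = {"H3K4me3": "I->I", "H3K27ac": "A->A"}
            causal_records[i]["mark"] = "H3K27ac"
    peaks, switch_assignment = generate_peaks(
        variants, cfg.switch_plan, rng, len(genome), (cfg.cond1, cfg.cond2),
        forced, stable_pool, cfg.n_background_peaks)

    stable_truth = {}
    for k, per_mark in switch_assignment.items():
        if per_mark.get("H3K4me3") == "A->A":
            stable_truth[k] = "H3K4me3"
        elif per_mark.get("H3K27ac") == "A->A":
            stable_truth[k] = "H3K27ac"

    truth = TruthManifest(
        seed=seed, region_categories=truth_cat, substitutions=truth_sub,
        switch_classes=switch_assignment, stable=stable_truth,
        de_genes=de_truth,
        expressed_tfs={cfg.cond1: sorted(expressed), cfg.cond2: sorted(expressed)},
        causal=causal_records)

    bundle = Bundle(cfg, {chrom: genome}, models, variants, peaks, expr,
                    pfms, tf_gene_map, truth)
    if out_dir is not None:
        write_bundle(bundle, out_dir)
    return bundle


def write_bundle(bundle: Bundle, out_dir: str | Path) -> None:
    out = Path(out_dir)
    (out / "peaks").mkdir(parents=True, exist_ok=True)
    core_io.write_fasta(bundle.genome, out / "genome.fa")
    core_io.write_gene_models(bundle.models, out / "genes.gtf")
    contigs = {name: len(seq) for name, seq in bundle.genome.items()}
    core_io.write_variants(bundle.variants, out / "variants.vcf", contigs)
    by_file: dict[tuple[str, str], list[Peak]] = {}
    for p in bundle.peaks:
        by_file.setdefault((p.mark, p.condition), []).append(p)
    for (mark, cond), peaks in sorted(by_file.items()):
        core_io.write_peaks(peaks, out / "peaks" / f"{mark}_{cond}.narrowPeak")
    core_io.write_expression(bundle.expression, out / "expression.tsv")
    core_io.write_jaspar(bundle.pfms, out / "motifs.jaspar")
    from varepi.candidate_report import write_tf_gene_map
    write_tf_gene_map(bundle.tf_gene_map, out / "tf_gene_map.tsv")
    bundle.truth.to_json(out / "truth.json")
    pd.DataFrame(
        [{"variant": k, "category": c} for k, c in
         sorted(bundle.truth.region_categories.items())]
    ).to_csv(out / "truth_variants.tsv", sep="\t", index=False)
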