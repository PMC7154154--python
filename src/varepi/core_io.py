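"""Domain types and readers/writers for the standard formats the pipeline touches.

Coordinate conventions
----------------------
VCF and GTF are 1-based inclusive; BED/narrowPeak are 0-based half-open.
All internal arithmetic uses 1-based inclusive positions and converts at the
I/O boundary.  The BED interval of a variant is ``(pos - 1, pos - 1 + |ref|)``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

BASES = "ACGT"
_BASE_SET = frozenset("ACGTN")

#: activating histone marks: a peak means the site is Active ("A"), else Inactive ("I")
ACTIVATING_MARKS = frozenset({"H3K4me3", "H3K27ac"})
#: repressive signals: a peak means the site is Inhibited ("In"), else permissive ("T")
REPRESSIVE_MARKS = frozenset({"H3K27me3", "DNAme"})
DEFAULT_MARKS = ACTIVATING_MARKS | REPRESSIVE_MARKS


class FormatError(ValueError):
    """A file violated the expectations of its format."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Variant:
    """One called difference between the stem and the induced genome.

    ``pos`` is the 1-based position of the first (anchor) base of ``ref``.
    Indels are VCF-style: ref and alt share the anchor base.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    vclass: str = ""          # derived: SNV / INS / DEL
    pair_id: str = ""

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        for allele in (self.ref, self.alt):
            if not allele or set(allele) - set(BASES):
                raise ValueError(
                    f"allele {allele!r} at {self.chrom}:{self.pos} not over ACGT")
        vclass = _variant_class(self.ref, self.alt)
        if vclass != "SNV" and self.ref[0] != self.alt[0]:
            raise ValueError(
                f"indel at {self.chrom}:{self.pos} must share the anchor base "
                f"({self.ref}>{self.alt})")
        if self.vclass and self.vclass != vclass:
            raise ValueError(f"vclass {self.vclass!r} inconsistent with alleles")
        object.__setattr__(self, "vclass", vclass)

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"

    def bed_interval(self) -> tuple[int, int]:
        """0-based half-open interval covered by the reference allele."""
        return self.pos - 1, self.pos - 1 + len(self.ref)


def _variant_class(ref: str, alt: str) -> str:
    if len(ref) == 1 and len(alt) == 1:
        return "SNV"
    return "INS" if len(alt) > len(ref) else "DEL"


@dataclass(frozen=True)
class GeneModel:
    """Transcript structure; intervals are 1-based inclusive ``(start, end)``."""

    gene_id: str
    gene_name: str
    chrom: str
    strand: str
    tss: int
    tes: int
    exons: tuple[tuple[int, int], ...]
    utr5: tuple[tuple[int, int], ...] = ()
    utr3: tuple[tuple[int, int], ...] = ()
    biotype: str = "coding"           # coding | noncoding
    transcript_id: str = ""

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.biotype not in ("coding", "noncoding"):
            raise ValueError(f"biotype must be coding|noncoding, got {self.biotype!r}")
        exons = tuple(sorted(tuple(e) for e in self.exons))
        if not exons:
            raise ValueError(f"{self.gene_id}: transcript without exons")
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 <= e1:
                raise ValueError(f"{self.gene_id}: overlapping exons")
        object.__setattr__(self, "exons", exons)
        span = (exons[0][0], exons[-1][1])
        expect_tss = span[0] if self.strand == "+" else span[1]
        if self.tss != expect_tss:
            raise ValueError(
                f"{self.gene_id}: tss {self.tss} inconsistent with strand/span {span}")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]


@dataclass(frozen=True)
class Peak:
    """One enriched interval for a named mark in a named condition (0-based, half-open)."""

    chrom: str
    start: int
    end: int
    mark: str
    condition: str
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"peak {self.chrom}:{self.start}-{self.end}: start >= end")
        if self.score < 0:
            raise ValueError("peak score must be non-negative")


@dataclass
class ExpressionTable:
    """Long-form per-gene TPM with replicates.

    Wraps a DataFrame with columns ``gene_id, condition, replicate, tpm``.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["gene_id", "condition", "replicate", "tpm"]
        missing = set(required) - set(self.data.columns)
        if missing:
            raise ValueError(f"expression table missing columns {sorted(missing)}")
        self.data = self.data[required].copy()
        if (self.data["tpm"] < 0).any():
            bad = self.data.loc[self.data["tpm"] < 0, "gene_id"].iloc[0]
            raise ValueError(f"negative TPM for gene {bad}")
        if self.data.duplicated(["gene_id", "condition", "replicate"]).any():
            raise ValueError("duplicate (gene, condition, replicate) record")

    @property
    def conditions(self) -> list[str]:
        return sorted(self.data["condition"].unique())

    @property
    def genes(self) -> list[str]:
        return sorted(self.data["gene_id"].unique())

    def mean_tpm(self, condition: str) -> pd.Series:
        sub = self.data[self.data["condition"] == condition]
        return sub.groupby("gene_id")["tpm"].mean()

    def matrix(self, condition: str) -> pd.DataFrame:
        """genes x replicates TPM matrix for one condition."""
        sub = self.data[self.data["condition"] == condition]
        return sub.pivot(index="gene_id", columns="replicate", values="tpm")


@dataclass(frozen=True)
class PFM:
    """Position frequency matrix: raw base counts, rows in A,C,G,T order."""

    tf_name: str
    counts: np.ndarray  # (4, w)

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        if counts.ndim != 2 or counts.shape[0] != 4 or counts.shape[1] < 1:
            raise ValueError(f"{self.tf_name}: counts must be 4 x w with w >= 1")
        if (counts < 0).any():
            raise ValueError(f"{self.tf_name}: negative counts")
        if (counts.sum(axis=0) <= 0).any():
            raise ValueError(f"{self.tf_name}: column with zero total count")
        object.__setattr__(self, "counts", counts)

    @property
    def width(self) -> int:
        return self.counts.shape[1]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.counts.argmax(axis=0))


@dataclass(frozen=True)
class PWM:
    """Log-odds motif matrix (natural log), with background and pseudocount."""

    tf_name: str
    weights: np.ndarray       # (4, w)
    background: np.ndarray    # (4,)
    pseudocount: float

    def __post_init__(self) -> None:
        weights = np.asarray(self.weights, dtype=float)
        background = np.asarray(self.background, dtype=float)
        if not np.isfinite(weights).all():
            raise ValueError(f"{self.tf_name}: non-finite weights")
        if abs(background.sum() - 1.0) > 1e-9 or (background <= 0).any():
            raise ValueError(f"{self.tf_name}: background must be positive, sum 1")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")
        object.__setattr__(self, "weights", weights)
        object.__setattr__(self, "background", background)

    @property
    def width(self) -> int:
        return self.weights.shape[1]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.weights.argmax(axis=0))

    @property
    def max_score(self) -> float:
        return float(self.weights.max(axis=0).sum())


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def normalize_chrom(chrom: str, style: str = "chr") -> str:
    """Normalize chromosome-name dialects ('chr5' vs '5').

    style='chr' adds the prefix where absent; style='plain' strips it.
    """
    has = chrom.startswith("chr")
    if style == "chr":
        return chrom if has else "chr" + chrom
    if style == "plain":
        return chrom[3:] if has else chrom
    raise ValueError(f"unknown chromosome style {style!r}")


def tsv_header_comment(config_hash: str = "") -> str:
    from varepi import __version__
    extra = f" config={config_hash}" if config_hash else ""
    return f"# varepi v{__version__}{extra}"


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into ``{name: uppercased sequence}``.

    Names are taken up to the first whitespace.  Characters outside ACGTN
    raise ``FormatError`` naming the offending record.
    """
    from Bio import SeqIO

    seqs: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        seq = str(record.seq).upper()
        bad = set(seq) - _BASE_SET
        if bad:
            raise FormatError(
                f"record {record.id!r} in {path} contains non-ACGTN characters "
                f"{sorted(bad)}")
        seqs[record.id] = seq
    if not seqs:
        warnings.warn(f"FASTA file {path} contains no records", stacklevel=2)
    return seqs


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_variants(path: str | Path, pair_id: str = "") -> list[Variant]:
    """Read biallelic SNV/indel records from a VCF.

    Records whose FILTER is anything but PASS or '.' are dropped (their count
    is logged); multiallelic ALT fields raise ``FormatError``.
    """
    from cyvcf2 import VCF

    variants: list[Variant] = []
    n_filtered = 0
    for rec in VCF(str(path)):
        if len(rec.ALT) != 1:
            raise FormatError(
                f"multiallelic record at {rec.CHROM}:{rec.POS} "
                f"(ALT={','.join(rec.ALT)}); split or remove it first")
        if rec.FILTER is not None:      # cyvcf2: None means PASS or '.'
            n_filtered += 1
            continue
        variants.append(Variant(chrom=rec.CHROM, pos=rec.POS, ref=rec.REF,
                                alt=rec.ALT[0], pair_id=pair_id))
    if n_filtered:
        log.info("dropped %d non-PASS records from %s", n_filtered, path)
    return variants


def write_variants(variants: Sequence[Variant], path: str | Path,
                   contigs: Mapping[str, int] | None = None) -> None:
    """Write a minimal well-formed VCF (all records PASS)."""
    if contigs is None:
        contigs = {}
        for v in variants:
            end = v.pos + len(v.ref)
            contigs[v.chrom] = max(contigs.get(v.chrom, 0), end + 1)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=varepi\n")
        for name, length in contigs.items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in sorted(variants, key=lambda v: (v.chrom, v.pos)):
            fh.write(f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t.\n")


# ---------------------------------------------------------------------------
# BED / narrowPeak
# ---------------------------------------------------------------------------

def read_peaks(path: str | Path, mark: str, condition: str) -> list[Peak]:
    """Read BED3+/narrowPeak intervals as peaks for one (mark, condition).

    narrowPeak column 7 (signalValue) is used as the score when present,
    otherwise the score is 0.
    """
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise FormatError(f"{path}:{lineno}: fewer than 3 columns")
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            score = float(cols[6]) if len(cols) >= 7 else 0.0
            peaks.append(Peak(chrom=cols[0], start=start, end=end, mark=mark,
                              condition=condition, score=score))
    return peaks


def write_peaks(peaks: Sequence[Peak], path: str | Path) -> None:
    """Write peaks as 10-column narrowPeak (score round-trips via signalValue)."""
    with open(path, "w") as fh:
        for i, p in enumerate(sorted(peaks, key=lambda p: (p.chrom, p.start))):
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\tpeak{i}\t0\t.\t"
                     f"{p.score:g}\t-1\t-1\t-1\n")


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

_CODING_BIOTYPES = {"protein_coding"}


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read one GeneModel per transcript from a GTF.

    Requires explicit ``transcript`` and ``exon`` features;
    ``five_prime_utr``/``three_prime_utr`` features populate the UTR lists.
    Transcripts without exons are skipped with a warning.
    """
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", keep_order=True,
                            merge_strategy="create_unique",
                            disable_infer_genes=True,
                            disable_infer_transcripts=True)
    models: list[GeneModel] = []
    for t in db.features_of_type("transcript"):
        exons = tuple((e.start, e.end)
                      for e in db.children(t, featuretype="exon", order_by="start"))
        if not exons:
            warnings.warn(f"transcript {t.id} has no exons; skipped", stacklevel=2)
            continue
        utr5 = tuple((u.start, u.end)
                     for u in db.children(t, featuretype="five_prime_utr",
                                          order_by="start"))
        utr3 = tuple((u.start, u.end)
                     for u in db.children(t, featuretype="three_prime_utr",
                                          order_by="start"))
        attrs = t.attributes
        biotype_raw = (attrs.get("gene_biotype") or attrs.get("gene_type")
                       or ["protein_coding"])[0]
        gene_id = (attrs.get("gene_id") or [t.id])[0]
        span = (exons[0][0], exons[-1][1])
        tss, tes = (span[0], span[1]) if t.strand == "+" else (span[1], span[0])
        models.append(GeneModel(
            gene_id=gene_id,
            gene_name=(attrs.get("gene_name") or [gene_id])[0],
            chrom=t.seqid, strand=t.strand, tss=tss, tes=tes,
            exons=exons, utr5=utr5, utr3=utr3,
            biotype="coding" if biotype_raw in _CODING_BIOTYPES else "noncoding",
            transcript_id=(attrs.get("transcript_id") or [t.id])[0]))
    return models


def write_gene_models(models: Sequence[GeneModel], path: str | Path,
                      source: str = "varepi") -> None:
    def attrs(m: GeneModel) -> str:
        biotype = "protein_coding" if m.biotype == "coding" else "lncRNA"
        return (f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id or m.gene_id + ".1"}"; '
                f'gene_name "{m.gene_name}"; gene_biotype "{biotype}";')

    with open(path, "w") as fh:
        for m in sorted(models, key=lambda m: (m.chrom, m.start)):
            a = attrs(m)
            rows = [("gene", m.start, m.end), ("transcript", m.start, m.end)]
            rows += [("exon", s, e) for s, e in m.exons]
            rows += [("five_prime_utr", s, e) for s, e in m.utr5]
            rows += [("three_prime_utr", s, e) for s, e in m.utr3]
            for feat, s, e in rows:
                fh.write(f"{m.chrom}\t{source}\t{feat}\t{s}\t{e}\t.\t{m.strand}\t.\t{a}\n")


# ---------------------------------------------------------------------------
# expression table
# ---------------------------------------------------------------------------

def read_expression(path: str | Path) -> ExpressionTable:
    """Read a wide TSV: gene_id column plus one ``condition:replicate`` column each."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if df.columns[0] != "gene_id":
        raise FormatError(f"{path}: first column must be 'gene_id'")
    long = df.melt(id_vars="gene_id", var_name="sample", value_name="tpm")
    parts = long["sample"].str.split(":", n=1, expand=True)
    if parts.isna().any().any():
        raise FormatError(f"{path}: sample columns must be named 'condition:replicate'")
    long["condition"] = parts[0]
    long["replicate"] = parts[1]
    return ExpressionTable(long[["gene_id", "condition", "replicate", "tpm"]])


def write_expression(expr: ExpressionTable, path: str | Path) -> None:
    wide = expr.data.assign(
        sample=expr.data["condition"] + ":" + expr.data["replicate"].astype(str)
    ).pivot(index="gene_id", columns="sample", values="tpm")
    wide.round(6).to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# JASPAR PFM text
# ---------------------------------------------------------------------------

def read_jaspar(path: str | Path) -> list[PFM]:
    """Read JASPAR-text PFMs (">ID NAME" header, 'A [ ... ]' rows, any row order)."""
    from Bio import motifs

    with open(path) as fh:
        parsed = motifs.parse(fh, "jaspar")
    pfms = []
    for m in parsed:
        counts = np.array([m.counts[b] for b in BASES], dtype=float)
        pfms.append(PFM(tf_name=m.name or m.matrix_id, counts=counts))
    return pfms


def write_jaspar(pfms: Sequence[PFM], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, p in enumerate(pfms, start=1):
            fh.write(f">M{i:04d} {p.tf_name}\n")
            for b, row in zip(BASES, p.counts):
                vals = " ".join(f"{v:g}" for v in row)
                fh.write(f"{b} [ {vals} ]\n")
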