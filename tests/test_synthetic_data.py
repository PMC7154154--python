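import json

import numpy as np
import pytest
from scipy import stats

from varepi import core_io
from varepi.epi_state import PeakSet, classify_switch, mark_state
from varepi.expression_de import differential_expression
from varepi.motif_scan import allele_delta, extract_allele_windows, pfm_to_pwm
from varepi.region_annotation import classify_all, substitution_spectrum
from varepi.synthetic_data import (DEFAULT_SPECTRUM, SimConfig, generate_bundle,
                                   generate_expression, generate_gene_models,
                                   generate_genome, generate_peaks,
                                   generate_variants,
                                   plant_regulatory_variant, toy_pfm_library)


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

def test_genome_gc_zero_is_all_at():
    seq = generate_genome(10_000, gc=0.0, seed=1)
    assert set(seq) <= {"A", "T"}


def test_genome_deterministic_per_seed():
    assert generate_genome(12_000, seed=5) == generate_genome(12_000, seed=5)
    assert generate_genome(12_000, seed=5) != generate_genome(12_000, seed=6)


def test_genome_base_frequencies_within_ci():
    L, gc = 500_000, 0.41
    seq = generate_genome(L, gc=gc, seed=2)
    n_gc = seq.count("G") + seq.count("C")
    sd = np.sqrt(gc * (1 - gc) * L)
    assert abs(n_gc - gc * L) < 4 * sd


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------

def test_gene_models_disjoint_and_in_bounds(tmp_path):
    models = generate_gene_models(200_000, 20, seed=4)
    assert len(models) == 20
    spans = sorted((m.start, m.end) for m in models)
    assert all(e < s2 for (_, e), (s2, _) in zip(spans, spans[1:]))
    assert spans[0][0] >= 1 and spans[-1][1] <= 200_000
    assert {"+", "-"} == {m.strand for m in models}
    assert any(m.biotype == "noncoding" for m in models)
    # round trip through the GTF reader loses nothing
    path = tmp_path / "g.gtf"
    core_io.write_gene_models(models, path)
    back = {m.gene_id: m for m in core_io.read_gene_models(path)}
    for m in models:
        assert back[m.gene_id].exons == m.exons
        assert back[m.gene_id].biotype == m.biotype


# ---------------------------------------------------------------------------
# variants
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def small_world():
    genome = generate_genome(150_000, seed=10)
    models = generate_gene_models(150_000, 15, seed=10)
    return genome, models


def test_variants_ref_matches_genome(small_world):
    genome, models = small_world
    variants, _, _ = generate_variants(genome, models, n=300, seed=11)
    for v in variants:
        assert genome[v.pos - 1:v.pos - 1 + len(v.ref)] == v.ref


def test_variants_all_intergenic_weights(small_world):
    genome, models = small_world
    weights = {c: 0.0 for c in DEFAULT_SPECTRUM}  # irrelevant keys ignored
    variants, truth, _ = generate_variants(
        genome, models, n=200, region_weights={"intergenic": 1.0}, seed=12)
    calls = classify_all(variants, models)
    assert all(c.category == "intergenic" for c in calls.values())
    assert set(truth.values()) == {"intergenic"}


def test_variant_categories_match_plan(small_world):
    genome, models = small_world
    variants, truth, _ = generate_variants(genome, models, n=400, seed=13)
    calls = classify_all(variants, models)
    mismatches = [k for k, c in calls.items() if c.category != truth[k]]
    assert mismatches == []


def test_planted_spectrum_recovered_within_ci(small_world):
    genome, models = small_world
    n = 5000
    variants, _, truth_sub = generate_variants(
        genome, models, n=n, seed=14, indel_fraction=0.0)
    spec = substitution_spectrum(variants)
    total = sum(spec.values())
    assert total == n
    for sub, p in DEFAULT_SPECTRUM.items():
        sd = np.sqrt(p * (1 - p) * n)
        assert abs(spec[sub] - p * n) < 4 * sd, sub
    assert max(spec, key=spec.get) == "C>T"


def test_indel_fraction_and_lengths(small_world):
    genome, models = small_world
    variants, _, _ = generate_variants(genome, models, n=800, seed=15,
                                       indel_fraction=0.55)
    n_indel = sum(1 for v in variants if v.vclass != "SNV")
    assert abs(n_indel / 800 - 0.55) < 0.06
    for v in variants:
        if v.vclass != "SNV":
            assert 1 <= abs(len(v.ref) - len(v.alt)) <= 5


# ---------------------------------------------------------------------------
# peaks and switch plans
# ---------------------------------------------------------------------------

def test_peaks_realize_planned_switches(small_world):
    genome, models = small_world
    variants, _, _ = generate_variants(genome, models, n=300, seed=16)
    peaks, assignment = generate_peaks(variants, seed=16,
                                       genome_length=len(genome))
    ps = PeakSet(peaks)
    for v in variants:
        for mark, label in assignment[v.key].items():
            s1 = mark_state(v, ps, mark, "stem")
            s2 = mark_state(v, ps, mark, "induced")
            assert classify_switch(s1, s2) == label, (v.key, mark)


def test_planned_null_class_has_no_overlap(small_world):
    genome, models = small_world
    variants, _, _ = generate_variants(genome, models, n=300, seed=17)
    peaks, assignment = generate_peaks(variants, seed=17,
                                       genome_length=len(genome))
    ps = PeakSet(peaks)
    for v in variants:
        if assignment[v.key]["H3K4me3"] == "I->I":
            for cond in ("stem", "induced"):
                assert not ps.covers(v.chrom, v.pos, "H3K4me3", cond)


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def test_expression_null_type_one_error_near_alpha():
    genes = [f"g{i}" for i in range(2000)]
    expr, truth = generate_expression(genes, de_fraction=0.0, seed=20, reps=3)
    assert truth == {}
    results = differential_expression(expr, "stem", "induced")
    pvals = np.array([r.pvalue for r in results if not np.isnan(r.pvalue)])
    fpr = (pvals < 0.05).mean()
    assert abs(fpr - 0.05) < 0.02


def test_expression_planted_up_gene_ratio():
    expr, truth = generate_expression(["g1", "g2"], de_plan={"g1": 2.0},
                                      seed=21, reps=4, sigma_log2=0.05)
    m1 = np.log2(expr.mean_tpm("stem") + 1)
    m2 = np.log2(expr.mean_tpm("induced") + 1)
    assert (m2["g1"] - m1["g1"]) == pytest.approx(2.0, abs=0.3)
    assert truth["g1"]["direction"] == "up"


def test_expression_deterministic_per_seed():
    a, _ = generate_expression(["g1", "g2"], de_fraction=0.5, seed=22)
    b, _ = generate_expression(["g1", "g2"], de_fraction=0.5, seed=22)
    assert a.data.equals(b.data)


# ---------------------------------------------------------------------------
# regulatory plants
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("mode,sign", [("gain", 1), ("loss", -1)])
def test_plant_modes_produce_signed_deltas(mode, sign):
    genome = generate_genome(20_000, seed=30)
    pwm = pfm_to_pwm([p for p in toy_pfm_library() if p.width == 9][0])
    site = 10_000
    edited, (ref, alt) = plant_regulatory_variant(genome, pwm, site, mode)
    v = core_io.Variant("chr1", site, ref, alt)
    win = extract_allele_windows({"chr1": edited}, v, 6)
    d = allele_delta(pwm, win)
    assert np.sign(d.diff) == sign
    if mode == "gain":
        assert d.score_alt == pytest.approx(pwm.max_score)
        assert d.score_alt >= 10.0 > d.score_ref


def test_toy_library_shape():
    pfms = toy_pfm_library()
    assert len(pfms) == 10
    assert sorted(p.width for p in pfms) == list(range(6, 16))
    assert toy_pfm_library()[3].counts.tolist() == pfms[3].counts.tolist()


# ---------------------------------------------------------------------------
# the bundle
# ---------------------------------------------------------------------------

def test_bundle_parses_through_every_reader(bundle_dir):
    genome = core_io.read_fasta(bundle_dir / "genome.fa")
    models = core_io.read_gene_models(bundle_dir / "genes.gtf")
    variants = core_io.read_variants(bundle_dir / "variants.vcf")
    expr = core_io.read_expression(bundle_dir / "expression.tsv")
    pfms = core_io.read_jaspar(bundle_dir / "motifs.jaspar")
    peak_files = sorted((bundle_dir / "peaks").glob("*.narrowPeak"))
    assert len(genome) == 1 and len(models) == 50
    assert len(variants) == 1000 and len(pfms) == 10
    assert len(peak_files) == 8            # 4 marks x 2 conditions
    assert len(expr.genes) == 60           # 50 genes + 10 TF genes
    truth = json.loads((bundle_dir / "truth.json").read_text())
    assert len(truth["stable"]) == 66


def test_bundle_truth_matches_written_variants(bundle, bundle_dir):
    written = core_io.read_variants(bundle_dir / "variants.vcf")
    assert {v.key for v in written} == {v.key for v in bundle.variants}
    assert bundle.truth.causal_keys <= {v.key for v in written}


def test_bundle_seeds_differ_but_schema_stable():
    a = generate_bundle(SimConfig(), seed=1)
    b = generate_bundle(SimConfig(), seed=2)
    assert {v.key for v in a.variants} != {v.key for v in b.variants}
    assert len(a.truth.stable) == len(b.truth.stable) == 66
    assert len(a.truth.causal) == len(b.truth.causal) == 6


def test_bundle_byte_identical_across_reruns(tmp_path):
    cfg = SimConfig(genome_length=60_000, n_genes=6, n_variants=80,
                    n_causal=2, n_causal_enhancer=1,
                    switch_plan={"H3K4me3": {"A->A": 5, "I->A": 3, "A->I": 3},
                                 "H3K27ac": {"A->A": 4, "I->A": 2, "A->I": 2},
                                 "H3K27me3": {}, "DNAme": {}})
    d1, d2 = tmp_path / "a", tmp_path / "b"
    generate_bundle(cfg, seed=9, out_dir=d1)
    generate_bundle(cfg, seed=9, out_dir=d2)
    for f in sorted(p.relative_to(d1) for p in d1.rglob("*") if p.is_file()):
        assert (d1 / f).read_bytes() == (d2 / f).read_bytes(), f
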