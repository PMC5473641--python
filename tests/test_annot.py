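import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cladecons.annot import (
    GeneModel,
    associate_genes,
    classify_region,
    rank_associated_genes,
    read_gff3,
    snp_density_test,
    write_gff3,
)
from cladecons.hmm import ConservedElement
from cladecons.intervals import IntervalSet


def el(start, end, score=1.0, chrom="chr1"):
    return ConservedElement(chrom, start, end, score)


@pytest.fixture
def gene_plus():
    # + strand; CDS from 13,000 to 20,000; transcript 12,000-21,000
    return GeneModel("gA", "chr1", "+", 12_000, 21_000,
                     [(13_000, 15_000), (18_000, 20_000)])


@pytest.fixture
def gene_minus():
    return GeneModel("gB", "chr1", "-", 50_000, 60_000,
                     [(52_000, 54_000), (57_000, 59_000)])


def test_classify_coding_priority(gene_plus):
    assert classify_region(el(13_500, 13_530), [gene_plus]) == "coding"
    # overlapping both CDS and the 5' window: coding wins
    assert classify_region(el(12_990, 13_010), [gene_plus]) == "coding"


def test_classify_five_prime_window(gene_plus):
    # translation start at 13,000: window [3000, 13000)
    assert classify_region(el(12_500, 12_530), [gene_plus]) == "five_prime_10kb"
    assert classify_region(el(2_500, 2_530), [gene_plus]) == "intergenic"
    assert classify_region(el(3_000, 3_010), [gene_plus]) == "five_prime_10kb"


def test_classify_three_prime_and_intron(gene_plus):
    # stop at 19,999 (+): 3' window [20000, 30000)
    assert classify_region(el(22_000, 22_100), [gene_plus]) == "three_prime_10kb"
    # between the two CDS chunks, inside the transcript
    assert classify_region(el(16_000, 16_050), [gene_plus]) == "intronic"


def test_classify_strand_aware(gene_minus):
    # - strand: translation start at 58,999; 5' window [59000, 69000)
    assert classify_region(el(61_000, 61_050), [gene_minus]) == "five_prime_10kb"
    # 3' side is below 52,000
    assert classify_region(el(45_000, 45_050), [gene_minus]) == "three_prime_10kb"


def test_classify_no_genes():
    assert classify_region(el(100, 200), []) == "intergenic"


def test_classes_partition(gene_plus, gene_minus):
    rng = np.random.default_rng(0)
    genes = [gene_plus, gene_minus]
    for _ in range(200):
        s = int(rng.integers(0, 80_000))
        cls = classify_region(el(s, s + 30), genes)
        assert cls in ("coding", "five_prime_10kb", "three_prime_10kb",
                       "intronic", "intergenic")


# --------------------------------------------------------------------- #
def test_associate_inside_gene(gene_plus):
    assoc = associate_genes([el(16_000, 16_030)], [gene_plus])
    assert assoc == {0: "gA"}


def test_associate_window_boundary(gene_plus):
    # transcript starts at 12,000; element ending 10,000 bp before it
    exactly = el(12_000 - 10_000 - 30, 12_000 - 10_000)
    beyond = el(12_000 - 10_001 - 30, 12_000 - 10_001)
    assert associate_genes([exactly], [gene_plus]) == {0: "gA"}
    assert associate_genes([beyond], [gene_plus]) == {}


def test_associate_tie_breaks_lexicographic():
    g1 = GeneModel("gZ", "chr1", "+", 0, 1000, [(100, 900)])
    g2 = GeneModel("gA", "chr1", "+", 2000, 3000, [(2100, 2900)])
    e = el(1_450, 1_550)  # 450 bp from gZ end, 450 bp from gA start
    assoc = associate_genes([e], [g1, g2])
    assert assoc == {0: "gA"}


def test_rank_genes_max_score_and_order():
    els = [el(0, 10, 3.2), el(20, 30, 7.1), el(40, 50, 5.0), el(60, 70, 5.0)]
    assoc = {0: "g1", 1: "g1", 2: "g2", 3: "g3"}
    df = rank_associated_genes(els, assoc)
    assert df.loc[0, "gene"] == "g1" and df.loc[0, "score"] == pytest.approx(7.1)
    # tie at 5.0 broken by gene id
    assert list(df["gene"]) == ["g1", "g2", "g3"]
    assert len(rank_associated_genes(els, assoc, top_n=100)) == 3


def test_rank_matches_sort_oracle():
    rng = np.random.default_rng(1)
    els = [el(i * 10, i * 10 + 5, float(s)) for i, s in
           enumerate(rng.normal(0, 5, 1000))]
    assoc = {i: f"g{i % 300:03d}" for i in range(1000)}
    df = rank_associated_genes(els, assoc, top_n=100)
    # oracle: best score per gene, python sort
    best = {}
    for i, g in assoc.items():
        best[g] = max(best.get(g, -np.inf), els[i].score)
    want = sorted(best.items(), key=lambda kv: (-kv[1], kv[0]))[:100]
    assert list(df["gene"]) == [g for g, _ in want]


# --------------------------------------------------------------------- #
def test_gff3_round_trip(tmp_path, gene_plus, gene_minus):
    p = tmp_path / "g.gff3"
    write_gff3([gene_plus, gene_minus], p)
    back = read_gff3(p)
    assert {g.gene_id for g in back} == {"gA", "gB"}
    ga = next(g for g in back if g.gene_id == "gA")
    assert (ga.tx_start, ga.tx_end) == (12_000, 21_000)
    assert ga.cds == [(13_000, 15_000), (18_000, 20_000)]
    assert ga.strand == "+"


# --------------------------------------------------------------------- #
def test_snp_density_proportional_gives_chi2_zero():
    target = IntervalSet([("chr1", 0, 1000)])
    # 10 in 1 kb, 90 in the remaining 9 kb: identical densities
    snps = np.concatenate([np.arange(0, 1000, 100), np.arange(1000, 10_000, 100)])
    res = snp_density_test(snps, target, 10_000)
    assert res["chi2"] == pytest.approx(0.0, abs=1e-9)
    assert res["p"] == pytest.approx(1.0)


def test_snp_density_hand_oracle():
    # expected counts all >= 5 here, so the plain Pearson formula applies
    target = IntervalSet([("chr1", 0, 1000)])
    snps = np.unique(np.concatenate(
        [np.arange(0, 1000, 20), np.arange(1000, 1_000_000, 100)]
    ))
    res = snp_density_test(snps, target, 1_000_000)
    assert not res["yates"]
    a, b = res["n_in"], 1000 - res["n_in"]
    c, d = res["n_out"], 999_000 - res["n_out"]
    n = a + b + c + d
    chi2 = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
    assert res["chi2"] == pytest.approx(chi2, rel=1e-9)
    assert res["density_in"] == pytest.approx(50.0)


def test_snp_density_errors():
    target = IntervalSet([("chr1", 0, 1000)])
    with pytest.raises(ValueError, match="no variants"):
        snp_density_test(np.array([]), target, 10_000)
    with pytest.raises(ValueError):
        snp_density_test(np.array([5]), target, 1000)


# --------------------------------------------------------------------- #
@given(st.integers(0, 5000), st.integers(1, 30))
@settings(max_examples=60, deadline=None, derandomize=True)
def test_interval_ops_match_bitmap_oracle(seed, n):
    """Merge/intersect agree with a per-base bitmap on small chromosomes."""
    rng = np.random.default_rng(seed)
    L = 500
    def rand_set():
        ivs, bitmap = [], np.zeros(L, bool)
        for _ in range(n):
            a = int(rng.integers(0, L - 1))
            b = int(rng.integers(a + 1, min(a + 60, L) + 1))
            ivs.append(("c", a, b))
            bitmap[a:b] = True
        return IntervalSet(ivs), bitmap
    s1, b1 = rand_set()
    s2, b2 = rand_set()
    assert s1.total_length == int(b1.sum())
    inter = s1.intersect(s2)
    assert inter.total_length == int((b1 & b2).sum())
    got = np.zeros(L, bool)
    for _, a, b in inter:
        got[a:b] = True
    assert np.array_equal(got, b1 & b2)
    pts = rng.integers(0, L, 40)
    assert np.array_equal(s1.contains_points("c", pts), b1[pts])
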