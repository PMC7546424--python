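"""Motif models, consensus rendering, and exact score p-values."""

import itertools
import math

import numpy as np
import pytest

from cyanolim.motifs import (
    BASES,
    MotifModel,
    SiteCollection,
    build_motif,
    parse_consensus,
    read_sites_fasta,
    logo_table,
    reverse_complement,
)
from cyanolim.simulate import (
    FUR_BOX_CONSENSUS,
    NTCA_BOX_CONSENSUS,
    SimConfig,
    consensus_pfm,
    sample_sites,
)


def enumerate_tail(model):
    """Independent brute-force oracle: tail of the lattice score over all
    4^w words, using the same per-column rounding as the package DP."""
    dist = model.score_distribution()
    k = np.rint(model.pwm_ / dist.bin_width).astype(int)
    bg = model.background_
    word_scores = {}
    for word in itertools.product(range(4), repeat=model.width_):
        s = sum(int(k[j, b]) for j, b in enumerate(word))
        p = 1.0
        for b in word:
            p *= bg[b]
        word_scores[s] = word_scores.get(s, 0.0) + p
    out = {}
    for s in word_scores:
        out[s] = sum(p for s2, p in word_scores.items() if s2 >= s)
    return out, dist


class TestBuildMotif:
    def test_pure_sites_give_certain_pfm(self):
        m = MotifModel(pseudocount=1e-9).fit(["ACGT"] * 4)
        assert m.width_ == 4
        assert np.allclose(m.pfm_.sum(axis=1), 1.0)
        for j, base in enumerate("ACGT"):
            assert m.pfm_[j, BASES.index(base)] == 1.0
        assert np.allclose(m.info_content_, 2.0, atol=1e-6)

    def test_pwm_log_odds_identity(self):
        m = MotifModel(pseudocount=0.5).fit(["ACGT", "AAGT", "ACGA"])
        expected = np.log2(
            ((m.counts_ + 0.5 * m.background_) / (3 + 0.5)) / m.background_
        )
        assert np.allclose(m.pwm_, expected)

    def test_n_bases_spread_fractionally(self):
        m = MotifModel().fit(["AN", "AN"])
        assert np.allclose(m.counts_[1], [0.5, 0.5, 0.5, 0.5])
        assert m.counts_[0, 0] == 2.0

    def test_info_content_bounds_and_pseudocount_monotonicity(self):
        sites = ["ACGT", "ACGA", "ACTT", "ACGT", "TCGT"]
        total = None
        for pc in (0.0, 0.5, 2.0, 10.0):
            m = MotifModel(pseudocount=pc).fit(sites)
            assert np.all(m.info_content_ >= -1e-12)
            assert np.all(m.info_content_ <= 2.0 + 1e-12)
            t = m.info_content_.sum()
            if total is not None:
                assert t <= total + 1e-12
            total = t

    def test_pfm_reconstruction_from_samples(self):
        pfm = consensus_pfm(FUR_BOX_CONSENSUS, 0.9)
        rng = np.random.default_rng(3)
        m200 = MotifModel().fit(sample_sites(pfm, 200, rng))
        assert np.max(np.abs(m200.pfm_ - pfm)) < 0.08
        m2000 = MotifModel().fit(sample_sites(pfm, 2000, rng))
        assert np.max(np.abs(m2000.pfm_ - pfm)) < 0.03

    def test_variable_length_trimming(self):
        core = ["TTGACA"] * 6
        padded = ["AC" + "TTGACA", "TTGACA" + "GG", "A" + "TTGACA" + "C"]
        m = MotifModel().fit(core + padded)
        assert m.width_ == 6
        assert all(s == "TTGACA" for s in m.aligned_sites_)

    def test_sites_shorter_than_modal_width_error(self):
        with pytest.raises(ValueError, match="shorter than the modal width"):
            MotifModel().fit(["ACGTAC", "ACGTAC", "ACG"])

    def test_site_collection_validation(self):
        with pytest.raises(ValueError):
            SiteCollection("x", ("ACGT",))
        with pytest.raises(ValueError):
            SiteCollection("x", ("ACGT", "ACXT"))


class TestConsensus:
    def test_uniform_column_renders_n(self):
        m = MotifModel().fit(["A" + b for b in "ACGT"])
        assert m.consensus()[1] == "N"

    def test_fifty_fifty_column_brackets(self):
        m = MotifModel(pseudocount=1e-6).fit(["AT", "AC"] * 10)
        cons = m.consensus()
        assert cons[0] == "A"
        assert cons[1:] in ("[C/T]", "[T/C]")

    def test_ntca_box_pattern(self):
        # conserved GTA at positions 2-4 and TAC at 13-15 around an
        # uninformative 8-bp spacer
        pfm = consensus_pfm(NTCA_BOX_CONSENSUS, 0.9)
        sites = sample_sites(pfm, 400, np.random.default_rng(5))
        cons = MotifModel().fit(sites).consensus()
        assert len(cons) == 16
        assert cons[1:4] == "GTA"
        assert cons[12:15] == "TAC"
        assert set(cons[4:12]) == {"N"}

    def test_fur_box_width_from_consensus_matching_sites(self):
        cols = parse_consensus(FUR_BOX_CONSENSUS)
        assert len(cols) == 19
        rng = np.random.default_rng(7)
        sites = [
            "".join(allowed[rng.integers(len(allowed))] for allowed in cols)
            for _ in range(60)
        ]
        m = build_motif(SiteCollection("fur", tuple(sites)))
        assert m.width_ == 19


class TestParseConsensus:
    def test_brackets_and_n(self):
        cols = parse_consensus("A[T/C]NG")
        assert cols == [("A",), ("T", "C"), ("A", "C", "G", "T"), ("G",)]

    def test_bad_characters_rejected(self):
        with pytest.raises(ValueError):
            parse_consensus("AC?T")
        with pytest.raises(ValueError):
            parse_consensus("A[]T")


class TestScoreDistribution:
    def test_width_one_uniform_background(self):
        m = MotifModel(pseudocount=1e-9).fit(["A", "A", "A", "C"])
        dist = m.score_distribution()
        assert dist.pvalue(m.score("A")) == pytest.approx(0.25, abs=1e-12)
        assert dist.tail[0] == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_dp_equals_enumeration_width6(self, seed):
        rng = np.random.default_rng(seed)
        pfm = rng.dirichlet(np.full(4, 0.8), size=6)
        sites = sample_sites(pfm, 40, rng)
        bg = rng.dirichlet(np.full(4, 12.0))
        m = MotifModel(background=bg).fit(sites)
        oracle, dist = enumerate_tail(m)
        lattice = np.rint(dist.scores / dist.bin_width).astype(int)
        for s, p in oracle.items():
            idx = int(np.searchsorted(lattice, s))
            assert dist.tail[idx] == pytest.approx(p, abs=1e-12)

    def test_tail_monotone_nonincreasing(self):
        m = MotifModel().fit(["ACGTAC", "ACGTAC", "ACGTTT", "AGGTAC"])
        dist = m.score_distribution()
        assert np.all(np.diff(dist.tail) <= 1e-15)
        assert dist.pmf.sum() == pytest.approx(1.0, abs=1e-12)

    def test_threshold_for_pvalue_consistency(self):
        m = MotifModel().fit(["ACGTAC", "ACGTAC", "ACGTTT", "AGGTAC"])
        dist = m.score_distribution()
        for p in (0.5, 1e-2, 1e-3):
            thr = dist.threshold_for_pvalue(p)
            if thr <= dist.scores[-1]:
                assert dist.pvalue(thr) <= p + 1e-15
            else:
                # cutoff below the motif's best attainable tail: nothing passes
                assert dist.tail[-1] > p

    def test_lattice_guard(self):
        m = MotifModel().fit(["A" * 33, "A" * 33])
        with pytest.raises(ValueError, match="width"):
            m.score_distribution()


def test_fasta_reader_and_logo_table(tmp_path):
    path = tmp_path / "sites.fa"
    path.write_text(">s1\nACGT\n>s2\nACGA\n>s3\nACGT\n")
    sc = read_sites_fasta(path, regulator="toy")
    assert sc.regulator == "toy" and len(sc.sites) == 3
    m = MotifModel().fit(sc)
    table = logo_table(m)
    assert list(table.columns[:2]) == ["position", "info_content_bits"]
    assert len(table) == 4
    freqs = table[[f"freq_{b}" for b in BASES]].to_numpy()
    assert np.allclose(freqs.sum(axis=1), 1.0)


def test_reverse_complement():
    assert reverse_complement("ACGTN") == "NACGT"
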