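"""Genome scanning, promoter-window gene assignment, regulon summaries."""

import numpy as np
import pytest
from scipy import stats

from cyanolim.motifs import MotifModel, reverse_complement
from cyanolim.regulon import (
    GeneAnnotation,
    MotifHit,
    assign_hits,
    genome_background,
    read_cog_map,
    read_genome_fasta,
    read_gff_genes,
    relative_position,
    scan_genome,
    summarize_regulon,
    write_hits_bed,
    write_regulon_tsv,
)
from cyanolim.simulate import (
    FUR_BOX_CONSENSUS,
    SimConfig,
    consensus_pfm,
    gen_genome,
    sample_sites,
    write_genome_files,
)


def fur_model(seed=0, background=None):
    sites = sample_sites(
        consensus_pfm(FUR_BOX_CONSENSUS, 0.9), 200, np.random.default_rng(seed)
    )
    return MotifModel(background=background).fit(sites, regulator="fur")


class TestScanGenome:
    def test_planted_consensus_recovered(self):
        rng = np.random.default_rng(11)
        genome = "".join(rng.choice(list("ACGT"), size=50_000))
        consensus = "ATTGAAAATTATTTTTAAT"
        positions = [5_000, 17_345, 33_000]
        for p in positions:
            genome = genome[:p] + consensus + genome[p + 19 :]
        model = fur_model()
        hits = scan_genome(model, {"chr": genome}, pvalue_cutoff=1e-5)
        found = {h.pos for h in hits}
        assert set(positions) <= found
        # false positives bounded by the Poisson band around 2*L*p
        extra = len(found - set(positions))
        assert extra <= stats.poisson.ppf(0.999, 2 * 50_000 * 1e-5)

    def test_empty_genome(self):
        assert scan_genome(fur_model(), {}) == []

    def test_hits_sorted_with_pvalues_in_unit_interval(self):
        rng = np.random.default_rng(2)
        genome = {"c1": "".join(rng.choice(list("ACGT"), size=20_000))}
        hits = scan_genome(fur_model(), genome, pvalue_cutoff=1e-2)
        assert hits == sorted(hits, key=lambda h: (h.contig, h.pos, h.strand))
        assert all(0 < h.pvalue <= 1 for h in hits)

    def test_reverse_complement_symmetry(self):
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list("ACGT"), size=30_000))
        model = fur_model()
        fwd = scan_genome(model, {"chr": seq}, pvalue_cutoff=1e-3)
        rev = scan_genome(model, {"chr": reverse_complement(seq)}, pvalue_cutoff=1e-3)
        L, w = len(seq), model.width_
        mirrored = {(L - h.pos - w, "-" if h.strand == "+" else "+") for h in fwd}
        assert mirrored == {(h.pos, h.strand) for h in rev}

    def test_zero_information_motif_matches_everywhere(self):
        # a uniform motif scores 0 at every position: with cutoff p=1,
        # every window on both strands is a hit (the analytic 2*L*p)
        m = MotifModel(pseudocount=1e9).fit(["ACGT", "TGCA"])
        rng = np.random.default_rng(4)
        genome = {"c": "".join(rng.choice(list("ACGT"), size=500))}
        hits = scan_genome(m, genome, pvalue_cutoff=1.0)
        assert len(hits) == 2 * (500 - 4 + 1)

    def test_ambiguous_bases_scored_not_crashing(self):
        model = fur_model()
        genome = {"c": "ATTGAAAATTATTTTTAATNNNNN" + "ACGT" * 30}
        hits = scan_genome(model, genome, pvalue_cutoff=1e-5)
        assert any(h.pos == 0 for h in hits)


class TestAssignHits:
    def hit(self, pos, width=30, strand="+"):
        return MotifHit("chr", pos, strand, 10.0, 1e-6, "A" * width)

    def test_plus_strand_upstream_arithmetic(self):
        gene = GeneAnnotation("g1", "chr", 1000, 1900, "+")
        out = assign_hits([self.hit(400)], [gene])
        assert out[0].assigned_genes == (("g1", -600),)

    def test_window_boundaries_inclusive(self):
        gene = GeneAnnotation("g1", "chr", 1000, 1900, "+")
        at = lambda rel: assign_hits([self.hit(1000 + rel, width=10)], [gene])[0]
        assert at(-801).assigned_genes == ()
        assert at(-800).assigned_genes == (("g1", -800),)
        assert at(40).assigned_genes == (("g1", 40),)
        assert at(41).assigned_genes == ()

    def test_minus_strand_relative_position(self):
        # translation start of a minus-strand gene is its end coordinate;
        # upstream extends to higher forward coordinates
        gene = GeneAnnotation("g1", "chr", 5000, 5900, "-")
        w = 19
        pos = 5900 + 100 - w  # 5'-most base 100 bp upstream on the coding strand
        assert relative_position(pos, w, gene) == -100
        out = assign_hits([self.hit(pos, width=w)], [gene])
        assert out[0].assigned_genes == (("g1", -100),)

    def test_divergent_gene_pair_shares_hit(self):
        left = GeneAnnotation("gL", "chr", 1000, 2000, "-")  # upstream rightwards
        right = GeneAnnotation("gR", "chr", 2500, 3500, "+")  # upstream leftwards
        hit = self.hit(2200, width=20)
        out = assign_hits([hit], [left, right])
        assigned = dict(out[0].assigned_genes)
        assert assigned == {"gL": 1999 - 2219, "gR": 2200 - 2500}

    def test_unassigned_hits_retained(self):
        gene = GeneAnnotation("g1", "chr", 50_000, 51_000, "+")
        out = assign_hits([self.hit(10)], [gene])
        assert len(out) == 1 and out[0].assigned_genes == ()


class TestSummarizeRegulon:
    def test_empty(self):
        reg = summarize_regulon([], [], regulator="fur")
        assert reg.genes == frozenset() and reg.cog_fractions == {}

    def test_single_letter_histogram(self):
        genes = [GeneAnnotation(f"g{i}", "c", 10 * i + 1, 10 * i + 5, "+",
                                cog_letters={"P"}) for i in range(10)]
        hits = [
            MotifHit("c", 0, "+", 5.0, 1e-5, "AAAA",
                     assigned_genes=tuple((g.gene_id, -10) for g in genes))
        ]
        reg = summarize_regulon(hits, genes)
        assert reg.cog_fractions == {"P": 1.0}
        assert reg.cog_counts == {"P": 10.0}

    def test_multi_letter_split_and_renormalisation(self):
        # 2 genes P, 1 gene PL (1/2 each), 1 gene unannotated
        genes = [
            GeneAnnotation("a", "c", 1, 5, "+", cog_letters={"P"}),
            GeneAnnotation("b", "c", 11, 15, "+", cog_letters={"P"}),
            GeneAnnotation("d", "c", 21, 25, "+", cog_letters={"P", "L"}),
            GeneAnnotation("e", "c", 31, 35, "+"),
        ]
        hits = [MotifHit("c", 0, "+", 5.0, 1e-5, "AA",
                         assigned_genes=(("a", 0), ("b", 0), ("d", 0), ("e", 0)))]
        reg = summarize_regulon(hits, genes)
        assert reg.cog_counts == pytest.approx({"P": 2.5, "L": 0.5})
        assert reg.cog_fractions == pytest.approx({"P": 2.5 / 3, "L": 0.5 / 3})
        assert sum(reg.cog_fractions.values()) == pytest.approx(1.0)
        assert reg.genes == {"a", "b", "d", "e"}

    def test_gene_level_deduplication(self):
        genes = [GeneAnnotation("a", "c", 1, 5, "+", cog_letters={"T"})]
        hits = [
            MotifHit("c", p, "+", 5.0, 1e-5, "AA", assigned_genes=(("a", p),))
            for p in (0, 1, 2)
        ]
        reg = summarize_regulon(hits, genes)
        assert reg.genes == {"a"} and len(reg.hits) == 3


class TestIO:
    def test_genome_files_round_trip(self, tmp_path):
        cfg = SimConfig(seed=9, planted_sites=(("fur", 2, -120),))
        sg = gen_genome(cfg)
        outdir = write_genome_files(sg, tmp_path / "fx")
        genome = read_genome_fasta(tmp_path / "fx" / "genome.fa")
        assert genome["chr"] == sg.genome["chr"]
        cogs = read_cog_map(tmp_path / "fx" / "cog_map.tsv")
        genes = read_gff_genes(tmp_path / "fx" / "genes.gff3", cog_map=cogs)
        assert len(genes) == len(sg.genes)
        byid = {g.gene_id: g for g in genes}
        for g in sg.genes:
            r = byid[g.gene_id]
            assert (r.start, r.end, r.strand) == (g.start, g.end, g.strand)
            assert r.cog_letters == sg.cog_map.get(g.gene_id, frozenset())

    def test_bed_and_regulon_writers(self, tmp_path):
        hits = [
            MotifHit("chr", 100, "-", 12.345, 2.5e-6, "ACGTACGT", "fur",
                     (("g1", -50),))
        ]
        genes = [GeneAnnotation("g1", "chr", 150, 900, "+", cog_letters={"P"})]
        bed = tmp_path / "hits.bed"
        write_hits_bed(hits, bed)
        fields = bed.read_text().strip().split("\t")
        assert fields[:6] == ["chr", "100", "108", "fur", "12.345", "-"]
        assert fields[8] == "g1:-50"
        reg = summarize_regulon(hits, genes)
        out = tmp_path / "reg.tsv"
        write_regulon_tsv(reg, out)
        assert "g1\t1" in out.read_text()

    def test_genome_background_composition(self):
        bg = genome_background({"c": "AAAACCGGTTTT"})
        assert bg == pytest.approx([4 / 12, 2 / 12, 2 / 12, 4 / 12])


def test_full_roundtrip_recovers_planted_regulons():
    """scan -> assign -> summarize reproduces the planted gene sets: the
    high-information PHO/Fur boxes exactly at a stringent cutoff, the
    low-information NtcA box with full recall at its feasible cutoff."""
    from cyanolim import benchmarks

    out = benchmarks.regulon_roundtrip(5)
    assert out["pho"]["exact"]
    assert out["fur"]["exact"]
    assert out["ntca"]["full_recall"]
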