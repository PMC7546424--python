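"""Synthetic fixtures: growth curves, factorial designs, and genomes
with planted regulatory motifs.

The generators emulate the study conditions the package targets:
duplicate batch cultures read as optical density every two days, 2x2
nutrient-addition designs with a planted limitation category, and a
desk-scale bacterial genome (100 kb, 80 genes on alternating strands)
whose intergenic regions carry binding-site instances planted at known
offsets from gene starts.  Every generator is a pure function of a
:class:`SimConfig`; each one draws from its own stream seeded from the
master seed, so adding a generator never perturbs existing fixtures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .colimitation import CATEGORIES, FactorialResponse, _PATTERN_MAP
from .growth import GrowthSeries
from .motifs import BASES, MotifModel, parse_consensus
from .regulon import GeneAnnotation

__all__ = [
    "SimConfig",
    "gen_growth",
    "gen_factorial",
    "gen_genome",
    "gen_monod_curve",
    "consensus_pfm",
    "sample_sites",
    "DEFAULT_MOTIFS",
    "PHO_BOX_CONSENSUS",
    "FUR_BOX_CONSENSUS",
    "NTCA_BOX_CONSENSUS",
]

# Consensus boxes of the three regulators modelled here: the PHO box is
# three tandem ATTTAAAT repeats separated by 3-bp spacers, the Fur box a
# 19-bp AT-rich palindrome-like element, the NtcA box the canonical
# TGTA-N8-TACA palindrome.
PHO_BOX_CONSENSUS = "ATTTAAATNNNATTTAAATNNNATTTAAAT"
FUR_BOX_CONSENSUS = "ATTGAAAATTATTTT[T/C]AAT"
NTCA_BOX_CONSENSUS = "TGTANNNNNNNNTACA"

DEFAULT_MOTIFS = {
    "pho": PHO_BOX_CONSENSUS,
    "fur": FUR_BOX_CONSENSUS,
    "ntca": NTCA_BOX_CONSENSUS,
}

_SIGN_OF = {v: k for k, v in _PATTERN_MAP.items()}

COG_LETTERS = "PLMHTECJKO"


@dataclass(frozen=True)
class SimConfig:
    """Configuration shared by all generators; seed-fixed => identical
    outputs byte for byte."""

    seed: int = 0
    # growth curves
    planted_mu: float = 0.33
    noise_sd: float = 0.02  # lognormal sd of multiplicative OD noise
    n_timepoints: int = 6
    dt_days: float = 2.0
    od0: float = 0.2
    carrying_capacity: float = 20.0
    n_replicates: int = 2
    treatments: tuple = ("T1",)
    # factorial designs
    planted_category: str = "no_response"
    effect_size: float = 0.3
    base_mu: float = 0.2
    factorial_noise_sd: float = 0.05  # log-scale replicate noise
    # genomes
    genome_length: int = 100_000
    n_genes: int = 80
    gene_length: int = 900
    intergenic_mean: float = 350.0
    gc_content: float = 0.45
    planted_sites: tuple = ()  # (regulator, gene_index, rel_pos)
    sites_per_collection: int = 200
    consensus_concentration: float = 0.9
    plant_exact_consensus: bool = True

    def __post_init__(self):
        for reg, idx, rel in self.planted_sites:
            if not (-800 <= rel <= 40):
                raise ValueError(
                    f"planted site ({reg}, {idx}, {rel}): rel_pos outside [-800, 40]"
                )

    def rng(self, stream: str) -> np.random.Generator:
        """Independent stream derived from the master seed."""
        return np.random.default_rng(
            np.random.SeedSequence((self.seed, hash_stream(stream)))
        )


def hash_stream(name: str) -> int:
    """Stable small integer id of a stream name (process-independent)."""
    h = 0
    for ch in name:
        h = (h * 131 + ord(ch)) % (2**31 - 1)
    return h


# ---------------------------------------------------------------------------
# growth


def gen_growth(cfg: SimConfig) -> list:
    """Duplicate OD time series per treatment.

    OD follows a logistic curve K*OD0*e^(mu t) / (K + OD0*(e^(mu t)-1)):
    exponential with the planted mu while OD << K, saturating beyond.
    Multiplicative lognormal noise models read-to-read variation.
    """
    rng = cfg.rng("growth")
    t = np.arange(cfg.n_timepoints) * cfg.dt_days
    out = []
    for trt in cfg.treatments:
        for rep in range(1, cfg.n_replicates + 1):
            raw = cfg.od0 * np.exp(cfg.planted_mu * t)
            od = cfg.carrying_capacity * raw / (cfg.carrying_capacity + raw - cfg.od0)
            if cfg.noise_sd > 0:
                od = od * rng.lognormal(0.0, cfg.noise_sd, size=t.size)
            out.append(
                GrowthSeries(
                    treatment_id=str(trt),
                    replicate_id=f"r{rep}",
                    times=tuple(t),
                    od=tuple(od),
                )
            )
    return out


def gen_monod_curve(cfg: SimConfig, mu_max: float, q_min: float, q_values=None,
                    noise_sd: float = 0.02):
    """(Q, mu) points from the quota-Monod curve with Gaussian noise."""
    rng = cfg.rng("monod")
    if q_values is None:
        q_values = q_min * np.geomspace(1.1, 16.0, 9)
    q = np.asarray(q_values, dtype=float)
    mu = mu_max * (q - q_min) / q
    if noise_sd > 0:
        mu = mu + rng.normal(0.0, noise_sd, size=q.size)
    return q, mu


# ---------------------------------------------------------------------------
# factorial designs


def gen_factorial(cfg: SimConfig) -> FactorialResponse:
    """A 2x2 design whose cell means realise the planted category's sign
    pattern with log-scale margins equal to ``effect_size``; replicates
    get multiplicative lognormal noise."""
    if cfg.planted_category not in _SIGN_OF:
        raise ValueError(
            f"planted_category must be one of {sorted(_SIGN_OF)}, "
            f"got {cfg.planted_category!r}"
        )
    rng = cfg.rng("factorial")
    signs = _SIGN_OF[cfg.planted_category]
    shift = {"+": cfg.effect_size, "-": -cfg.effect_size, "0": 0.0}
    means = {
        "00": cfg.base_mu,
        "10": cfg.base_mu * math.exp(shift[signs[0]]),
        "01": cfg.base_mu * math.exp(shift[signs[1]]),
        "11": cfg.base_mu * math.exp(shift[signs[2]]),
    }
    cells = {
        code: tuple(
            m * rng.lognormal(0.0, cfg.factorial_noise_sd, size=cfg.n_replicates)
        )
        for code, m in means.items()
    }
    return FactorialResponse(
        label_a="A", label_b="B",
        mu_00=cells["00"], mu_10=cells["10"],
        mu_01=cells["01"], mu_11=cells["11"],
    )


# ---------------------------------------------------------------------------
# motifs and genomes


def consensus_pfm(consensus: str, concentration: float = 0.9) -> np.ndarray:
    """PFM realising a consensus string: each column puts
    ``concentration`` total mass on its allowed bases (split evenly) and
    the rest evenly on the others; N columns are uniform."""
    cols = parse_consensus(consensus)
    pfm = np.empty((len(cols), 4))
    for j, allowed in enumerate(cols):
        if len(allowed) == 4:
            pfm[j] = 0.25
            continue
        idx = [BASES.index(b) for b in allowed]
        pfm[j] = (1.0 - concentration) / (4 - len(idx))
        pfm[j, idx] = concentration / len(idx)
    return pfm


def sample_sites(pfm: np.ndarray, n: int, rng: np.random.Generator):
    """n sites drawn column-wise from a PFM."""
    w = pfm.shape[0]
    out = []
    for _ in range(n):
        idx = [rng.choice(4, p=pfm[j]) for j in range(w)]
        out.append("".join(BASES[i] for i in idx))
    return out


def _consensus_word(consensus: str, rng) -> str:
    """One exact realisation of a consensus (random choice within
    brackets and at N columns)."""
    return "".join(
        allowed[rng.integers(len(allowed))] for allowed in parse_consensus(consensus)
    )


@dataclass(frozen=True)
class SyntheticGenome:
    """gen_genome output bundle with ground truth."""

    genome: dict
    genes: tuple
    site_collections: dict  # regulator -> list of sampled sites
    cog_map: dict
    truth: pd.DataFrame  # planted placements
    truth_regulons: dict  # regulator -> frozenset of gene ids in window reach
    motif_consensus: dict


def gen_genome(cfg: SimConfig) -> SyntheticGenome:
    """A synthetic annotated genome with planted motif instances.

    Background sequence is i.i.d. with the configured GC content; genes
    of fixed length sit on alternating strands separated by
    exponential(intergenic_mean) spacers (>= 60 bp so promoters exist).
    Each planted site (regulator, gene_index, rel_pos) is written so
    that the motif's 5'-most base lies at rel_pos from that gene's
    translation start on its coding strand; minus-strand genes receive
    the reverse complement on the forward strand.  Overlapping planted
    placements raise with the colliding entries listed.
    """
    rng = cfg.rng("genome")
    p = np.array(
        [(1 - cfg.gc_content) / 2, cfg.gc_content / 2, cfg.gc_content / 2,
         (1 - cfg.gc_content) / 2]
    )
    seq = rng.choice(list(BASES), size=cfg.genome_length, p=p)

    # gene placement
    genes = []
    cursor = 900  # room for upstream windows of the first gene
    for i in range(cfg.n_genes):
        gap = 60.0 + rng.exponential(max(cfg.intergenic_mean - 60.0, 1.0))
        start = cursor + int(gap)
        end = start + cfg.gene_length
        if end > cfg.genome_length - 900:
            break
        genes.append(
            GeneAnnotation(
                gene_id=f"gene{i:04d}",
                contig="chr",
                start=start,
                end=end,
                strand="+" if i % 2 == 0 else "-",
            )
        )
        cursor = end
    genes = tuple(genes)

    # COG letters: most genes one letter, some two, some none
    cog_rng = cfg.rng("cogs")
    cog_map = {}
    for g in genes:
        r = cog_rng.random()
        if r < 0.15:
            continue  # unannotated
        k = 2 if r > 0.85 else 1
        letters = cog_rng.choice(list(COG_LETTERS), size=k, replace=False)
        cog_map[g.gene_id] = frozenset(str(x) for x in letters)

    # site collections for model building
    site_rng = cfg.rng("sites")
    collections_ = {
        reg: sample_sites(
            consensus_pfm(cons, cfg.consensus_concentration),
            cfg.sites_per_collection,
            site_rng,
        )
        for reg, cons in DEFAULT_MOTIFS.items()
    }

    # plant motif instances
    plant_rng = cfg.rng("plant")
    placements, rows = [], []
    for reg, gene_index, rel in cfg.planted_sites:
        cons = DEFAULT_MOTIFS.get(reg, reg)  # unknown regulator: literal consensus
        if gene_index >= len(genes):
            raise ValueError(f"planted site gene_index {gene_index} out of range")
        gene = genes[gene_index]
        if cfg.plant_exact_consensus:
            word = _consensus_word(cons, plant_rng)
        else:
            pfm = consensus_pfm(cons, cfg.consensus_concentration)
            word = sample_sites(pfm, 1, plant_rng)[0]
        w = len(word)
        if gene.strand == "+":
            pos = gene.start + rel
            fwd = word
        else:
            pos = gene.end - rel - w
            fwd = "".join(
                {"A": "T", "C": "G", "G": "C", "T": "A"}[c] for c in reversed(word)
            )
        if pos < 0 or pos + w > cfg.genome_length:
            raise ValueError(f"planted site ({reg}, {gene_index}, {rel}) leaves genome")
        placements.append((pos, pos + w, reg, gene_index, rel))
        rows.append(
            {
                "regulator": reg,
                "gene_id": gene.gene_id,
                "rel_pos": rel,
                "contig": "chr",
                "pos": pos,
                "strand": gene.strand,
                "site_seq": word,
            }
        )
        seq[pos : pos + w] = list(fwd)

    placements.sort()
    collisions = [
        (placements[i], placements[i + 1])
        for i in range(len(placements) - 1)
        if placements[i + 1][0] < placements[i][1]
    ]
    if collisions:
        raise ValueError(f"planted placements collide: {collisions}")

    # ground-truth regulons by direct coordinate arithmetic: every gene
    # whose [-800, +40] window (on its coding strand) contains a planted
    # site's 5'-most base, including divergent neighbours of the target
    truth_regulons: dict = {}
    for row in rows:
        w = len(row["site_seq"])
        members = truth_regulons.setdefault(row["regulator"], set())
        for g in genes:
            if g.strand == "+":
                rel = row["pos"] - g.start
            else:
                rel = (g.end - 1) - (row["pos"] + w - 1)
            if -800 <= rel <= 40:
                members.add(g.gene_id)
    truth_regulons = {k: frozenset(v) for k, v in truth_regulons.items()}

    return SyntheticGenome(
        genome={"chr": "".join(seq)},
        genes=genes,
        site_collections=collections_,
        cog_map=cog_map,
        truth=pd.DataFrame(
            rows,
            columns=["regulator", "gene_id", "rel_pos", "contig", "pos", "strand",
                     "site_seq"],
        ),
        truth_regulons=truth_regulons,
        motif_consensus=dict(DEFAULT_MOTIFS),
    )


# ---------------------------------------------------------------------------
# file emission


def write_genome_files(sg: SyntheticGenome, outdir):
    """Write FASTA + GFF3 + per-regulator site multifasta + COG TSV +
    ground-truth table under ``outdir``."""
    import os

    os.makedirs(outdir, exist_ok=True)
    fa = os.path.join(outdir, "genome.fa")
    with open(fa, "w") as fh:
        for contig, seq in sg.genome.items():
            fh.write(f">{contig}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
    gff = os.path.join(outdir, "genes.gff3")
    with open(gff, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sg.genes:
            fh.write(
                f"{g.contig}\tcyanolim\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )
    for reg, sites in sg.site_collections.items():
        with open(os.path.join(outdir, f"{reg}_sites.fa"), "w") as fh:
            for i, s in enumerate(sites):
                fh.write(f">{reg}_site_{i}\n{s}\n")
    with open(os.path.join(outdir, "cog_map.tsv"), "w") as fh:
        fh.write("gene_id\tcog_letters\n")
        for gid in sorted(sg.cog_map):
            fh.write(f"{gid}\t{''.join(sorted(sg.cog_map[gid]))}\n")
    sg.truth.to_csv(os.path.join(outdir, "planted_sites.tsv"), sep="\t", index=False)
    return outdir
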