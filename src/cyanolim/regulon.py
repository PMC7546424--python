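"""Genome scanning with motif models and promoter-window regulon calls.

The scan slides a PWM over both strands of every contig and keeps
positions whose exact background p-value clears a cutoff (default 1e-4;
a p-value cutoff is comparable across motifs of different widths, a raw
score is not).  Hits are then assigned to genes whose translation start
lies within a promoter window of the hit — by default from 800 bp
upstream to 40 bp downstream, inclusive at both ends — measured on the
gene's coding strand from the motif's 5'-most base.  The per-regulator
gene set with its COG functional-category breakdown is the predicted
regulon.

Coordinates are 0-based half-open internally; GFF3 I/O converts from the
1-based inclusive convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .motifs import BASES, MotifModel, reverse_complement

__all__ = [
    "GeneAnnotation",
    "MotifHit",
    "Regulon",
    "PROMOTER_WINDOW",
    "scan_genome",
    "assign_hits",
    "summarize_regulon",
    "genome_background",
    "read_genome_fasta",
    "read_gff_genes",
    "read_cog_map",
    "write_hits_bed",
    "write_regulon_tsv",
]

PROMOTER_WINDOW = (-800, 40)

_CODES = {b: i for i, b in enumerate(BASES)}


@dataclass(frozen=True)
class GeneAnnotation:
    """A coding span on a contig (0-based half-open) with optional COGs."""

    gene_id: str
    contig: str
    start: int
    end: int
    strand: str
    cog_letters: frozenset = frozenset()

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"gene {self.gene_id}: need 0 <= start < end")
        if self.strand not in "+-":
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        object.__setattr__(self, "cog_letters", frozenset(self.cog_letters))

    @property
    def translation_start(self) -> int:
        """Forward-strand index of the first coding base (end-1 on -)."""
        return self.start if self.strand == "+" else self.end - 1


@dataclass(frozen=True)
class MotifHit:
    """A scored PWM match; pos is the forward-strand start of the match."""

    contig: str
    pos: int
    strand: str
    score: float
    pvalue: float
    matched_seq: str
    regulator: str = ""
    assigned_genes: tuple = ()  # (gene_id, rel_pos) pairs

    @property
    def width(self) -> int:
        return len(self.matched_seq)


@dataclass(frozen=True)
class Regulon:
    """Predicted gene set of one regulator with its COG histogram."""

    regulator: str
    genes: frozenset
    hits: tuple
    cog_counts: dict = field(default_factory=dict)
    cog_fractions: dict = field(default_factory=dict)


def genome_background(genome: dict) -> np.ndarray:
    """Mononucleotide composition of a genome (ambiguous bases ignored)."""
    counts = np.zeros(4)
    for seq in genome.values():
        arr = _encode(seq)
        counts += np.bincount(arr[arr < 4], minlength=4)
    if counts.sum() == 0:
        return np.full(4, 0.25)
    return counts / counts.sum()


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.size, 4, dtype=np.int8)  # 4 = ambiguous
    for b, i in _CODES.items():
        out[arr == ord(b)] = i
    return out


def _column_scores(pwm_int: np.ndarray, background: np.ndarray, bin_width: float):
    """Integer lattice column scores extended with an ambiguity column
    (background-weighted average score)."""
    ambig = np.rint((pwm_int * background).sum(axis=1)).astype(np.int64)
    return np.concatenate([pwm_int, ambig[:, None]], axis=1)


def _window_scores(codes: np.ndarray, cols: np.ndarray) -> np.ndarray:
    w = cols.shape[0]
    n = codes.size - w + 1
    if n <= 0:
        return np.zeros(0, dtype=np.int64)
    acc = np.zeros(n, dtype=np.int64)
    for j in range(w):
        acc += cols[j, codes[j : j + n]]
    return acc


def scan_genome(model: MotifModel, genome: dict, pvalue_cutoff: float = 1e-4):
    """All PWM matches on both strands at exact p-value <= cutoff.

    ``genome`` maps contig name -> sequence.  Hits are sorted by
    (contig, pos); a reverse-strand hit reports the forward-strand
    position of its leftmost base and its matched sequence in motif
    orientation.  Ambiguous bases score as the background-weighted
    average of the column.  An empty genome yields an empty list.
    """
    dist = model.score_distribution()
    thr_score = dist.threshold_for_pvalue(pvalue_cutoff)
    thr_int = int(np.rint(thr_score / dist.bin_width))
    k = dist.int_offsets
    w = model.width_
    k_rc = k[::-1, ::-1].copy()  # reverse-complement PWM on the lattice
    bg = model.background_
    hits = []
    for contig in sorted(genome):
        seq = genome[contig].upper()
        codes = _encode(seq)
        for strand, cols in (
            ("+", _column_scores(k, bg, dist.bin_width)),
            ("-", _column_scores(k_rc, bg, dist.bin_width)),
        ):
            scores = _window_scores(codes, cols)
            for pos in np.nonzero(scores >= thr_int)[0]:
                word = seq[pos : pos + w]
                matched = word if strand == "+" else reverse_complement(word)
                score_int = int(scores[pos])
                hits.append(
                    MotifHit(
                        contig=contig,
                        pos=int(pos),
                        strand=strand,
                        score=score_int * dist.bin_width,
                        pvalue=dist.pvalue(score_int * dist.bin_width),
                        matched_seq=matched,
                        regulator=model.regulator_,
                    )
                )
    hits.sort(key=lambda h: (h.contig, h.pos, h.strand))
    return hits


def relative_position(hit_pos: int, width: int, gene: GeneAnnotation) -> int:
    """Offset of the motif's 5'-most base from the gene's translation
    start, measured along the gene's coding strand (negative = upstream)."""
    if gene.strand == "+":
        return hit_pos - gene.start
    return (gene.end - 1) - (hit_pos + width - 1)


def assign_hits(hits, genes, window=PROMOTER_WINDOW):
    """Assign each hit to every gene whose promoter window contains it.

    Window bounds are inclusive at both ends.  A hit near divergently
    transcribed genes can be assigned to both; hits with no gene in
    range are retained unassigned.
    """
    lo, hi = window
    by_contig = {}
    for g in genes:
        by_contig.setdefault(g.contig, []).append(g)
    out = []
    for h in hits:
        assigned = []
        for g in by_contig.get(h.contig, ()):
            rel = relative_position(h.pos, h.width, g)
            if lo <= rel <= hi:
                assigned.append((g.gene_id, rel))
        assigned.sort(key=lambda x: x[0])
        out.append(replace(h, assigned_genes=tuple(assigned)))
    return out


def summarize_regulon(hits, genes, cog_map=None, regulator: str = "") -> Regulon:
    """Collapse assigned hits to a unique gene set with COG breakdown.

    A gene annotated with k COG letters contributes 1/k to each letter;
    fractions are renormalised over the genes that carry letters, so they
    sum to 1 whenever any annotated gene is present.
    """
    regulator = regulator or (hits[0].regulator if hits else "")
    gene_ids = set()
    for h in hits:
        gene_ids.update(g for g, _ in h.assigned_genes)
    letters_of = {}
    if cog_map is not None:
        letters_of.update(cog_map)
    else:
        letters_of.update({g.gene_id: g.cog_letters for g in genes})
    counts: dict = {}
    for gid in gene_ids:
        letters = sorted(letters_of.get(gid, ()))
        if not letters:
            continue
        for letter in letters:
            counts[letter] = counts.get(letter, 0.0) + 1.0 / len(letters)
    total = sum(counts.values())
    fractions = {k: v / total for k, v in counts.items()} if total else {}
    return Regulon(
        regulator=regulator,
        genes=frozenset(gene_ids),
        hits=tuple(hits),
        cog_counts=counts,
        cog_fractions=fractions,
    )


# ---------------------------------------------------------------------------
# I/O


def read_genome_fasta(path) -> dict:
    """Contig name -> uppercase sequence from a FASTA file."""
    from Bio import SeqIO

    return {r.id: str(r.seq).upper() for r in SeqIO.parse(str(path), "fasta")}


def read_gff_genes(path, cog_map=None):
    """Genes from a GFF3 file (1-based inclusive -> 0-based half-open)."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True, merge_strategy="warning"
    )
    gene_feats = list(db.features_of_type("gene"))
    if not gene_feats:  # annotations that only carry CDS records
        gene_feats = list(db.features_of_type("CDS"))
    genes = []
    for feat in gene_feats:
        gid = feat.attributes.get("ID", [feat.id])[0]
        genes.append(
            GeneAnnotation(
                gene_id=gid,
                contig=feat.seqid,
                start=feat.start - 1,
                end=feat.end,
                strand=feat.strand,
                cog_letters=frozenset((cog_map or {}).get(gid, ())),
            )
        )
    return genes


def read_cog_map(path) -> dict:
    """gene_id -> set of COG letters from a two-column TSV."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    cols = list(df.columns)
    if len(cols) < 2:
        raise ValueError("COG map TSV needs gene id and letter columns")
    return {
        str(row[cols[0]]): frozenset(str(row[cols[1]]).strip())
        for _, row in df.iterrows()
        if str(row[cols[1]]).strip()
    }


def write_hits_bed(hits, path):
    """Hits as BED6+ (chrom, start, end, regulator, score bits, strand,
    pvalue, matched_seq, semicolon-joined gene:rel_pos assignments)."""
    with open(path, "w") as fh:
        for h in hits:
            assigned = ";".join(f"{g}:{rel}" for g, rel in h.assigned_genes)
            fh.write(
                f"{h.contig}\t{h.pos}\t{h.pos + h.width}\t{h.regulator}\t"
                f"{h.score:.3f}\t{h.strand}\t{h.pvalue:.3e}\t{h.matched_seq}\t"
                f"{assigned}\n"
            )


def write_regulon_tsv(regulon: Regulon, path):
    rows = [
        {
            "regulator": regulon.regulator,
            "gene_id": gid,
            "n_hits": sum(
                1 for h in regulon.hits if gid in {g for g, _ in h.assigned_genes}
            ),
        }
        for gid in sorted(regulon.genes)
    ]
    pd.DataFrame(rows, columns=["regulator", "gene_id", "n_hits"]).to_csv(
        path, sep="\t", index=False
    )
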