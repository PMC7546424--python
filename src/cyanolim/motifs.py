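"""Position weight matrices from aligned binding-site collections.

A motif model is built from a collection of aligned transcription-factor
binding sites (e.g. PHO, Fur or NtcA boxes pooled across cyanobacterial
genera): a count matrix, a position frequency matrix (PFM), a log2-odds
PWM against a background composition, and per-column information content

    IC_i = 2 + sum_b p_ib log2 p_ib          (bits, in [0, 2])

which is the quantity sequence logos draw.  Sites of unequal length are
reduced to a common width by a deterministic best-window procedure.  An
exact null distribution of the PWM score of a background-random word is
computed by dynamic programming over a discretised score lattice, giving
exact p-values for genome scan hits.
"""

from __future__ import annotations

import collections
import math
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

__all__ = [
    "SiteCollection",
    "MotifModel",
    "ScoreDistribution",
    "build_motif",
    "consensus",
    "score_pvalue_table",
    "parse_consensus",
    "read_sites_fasta",
    "logo_table",
]

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

UNIFORM_BACKGROUND = np.full(4, 0.25)

MAX_EXACT_WIDTH = 32  # hard DP width cap; lattice size is checked too


@dataclass(frozen=True)
class SiteCollection:
    """Aligned binding sites for one regulator (alphabet A/C/G/T/N)."""

    regulator: str
    sites: tuple
    source_organisms: tuple = ()

    def __post_init__(self):
        sites = tuple(s.upper() for s in self.sites)
        if len(sites) < 2:
            raise ValueError("a site collection needs at least 2 sites")
        for s in sites:
            if not s or set(s) - set("ACGTN"):
                raise ValueError(f"site {s!r} has characters outside A/C/G/T/N")
        object.__setattr__(self, "sites", sites)


def _site_counts(sites, width):
    """Count matrix over aligned equal-width sites; N spreads 0.25/base."""
    counts = np.zeros((width, 4))
    for s in sites:
        for j, ch in enumerate(s):
            if ch == "N":
                counts[j] += 0.25
            else:
                counts[j, _BASE_INDEX[ch]] += 1.0
    return counts


def _score_site(site, pwm, background):
    total = 0.0
    for j, ch in enumerate(site):
        if ch == "N":
            total += float(background @ pwm[j])
        else:
            total += pwm[j, _BASE_INDEX[ch]]
    return total


class MotifModel(BaseEstimator):
    """PFM/PWM motif model fitted from a site collection.

    Parameters
    ----------
    pseudocount : float
        Total pseudocount, distributed across bases by the background
        frequencies (default 0.5).
    background : array-like of 4 frequencies, optional
        Base composition of the null model; uniform by default.  For
        genome scanning, pass the genome's mononucleotide composition.
    score_bin : float
        Score discretisation (bits) of the exact null distribution.

    Fitted attributes: ``width_``, ``counts_``, ``pfm_``, ``pwm_``,
    ``probs_`` (pseudocounted frequencies behind the PWM),
    ``info_content_``, ``n_sites_``, ``regulator_``.
    """

    def __init__(self, pseudocount: float = 0.5, background=None, score_bin: float = 0.01):
        self.pseudocount = pseudocount
        self.background = background
        self.score_bin = score_bin

    # -- fitting ----------------------------------------------------------

    def fit(self, sites, regulator: str = ""):
        if isinstance(sites, SiteCollection):
            regulator = regulator or sites.regulator
            sites = sites.sites
        sc = SiteCollection(regulator or "motif", tuple(sites))
        bg = (
            UNIFORM_BACKGROUND.copy()
            if self.background is None
            else np.asarray(self.background, dtype=float)
        )
        if bg.shape != (4,) or not math.isclose(bg.sum(), 1.0, abs_tol=1e-6) or bg.min() <= 0:
            raise ValueError("background must be 4 positive frequencies summing to 1")
        bg = bg / bg.sum()
        aligned = self._align_sites(sc.sites, bg)
        self._finalize(_site_counts(aligned, len(aligned[0])), len(aligned), bg)
        self.regulator_ = sc.regulator
        self.aligned_sites_ = tuple(aligned)
        return self

    def _finalize(self, counts, n_sites, bg):
        probs = (counts + self.pseudocount * bg) / (n_sites + self.pseudocount)
        self.counts_ = counts
        self.n_sites_ = n_sites
        self.background_ = bg
        self.pfm_ = counts / counts.sum(axis=1, keepdims=True)
        self.probs_ = probs
        with np.errstate(divide="ignore"):  # zero pseudocount => -inf odds
            self.pwm_ = np.log2(probs / bg)
        plogp = np.where(probs > 0, probs * np.log2(np.where(probs > 0, probs, 1.0)), 0.0)
        self.info_content_ = 2.0 + plogp.sum(axis=1)
        self.width_ = counts.shape[0]

    def _align_sites(self, sites, bg):
        """Reduce variable-length sites to the modal width.

        The model is seeded from the modal-length sites; each longer site
        then contributes its best-scoring window (leftmost on ties), the
        model is rebuilt, and the window choice is repeated once against
        the rebuilt model.  Sites shorter than the modal width cannot be
        aligned and raise.
        """
        lengths = collections.Counter(len(s) for s in sites)
        top = max(lengths.values())
        width = min(l for l, c in lengths.items() if c == top)
        short = [s for s in sites if len(s) < width]
        if short:
            raise ValueError(
                f"{len(short)} site(s) shorter than the modal width {width}: "
                f"{short[:3]}..."
            )
        if all(len(s) == width for s in sites):
            return list(sites)

        modal = [s for s in sites if len(s) == width]
        model = MotifModel(pseudocount=self.pseudocount)
        model._finalize(_site_counts(modal, width), len(modal), bg)
        aligned = self._pick_windows(sites, width, model.pwm_, bg)
        model._finalize(_site_counts(aligned, width), len(aligned), bg)
        return self._pick_windows(sites, width, model.pwm_, bg)

    @staticmethod
    def _pick_windows(sites, width, pwm, bg):
        out = []
        for s in sites:
            if len(s) == width:
                out.append(s)
                continue
            best, best_score = None, -math.inf
            for k in range(len(s) - width + 1):
                window = s[k : k + width]
                score = _score_site(window, pwm, bg)
                if score > best_score:
                    best, best_score = window, score
            out.append(best)
        return out

    # -- derived quantities ----------------------------------------------

    def consensus(self, tie_fraction: float = 0.1, min_info: float = 0.25) -> str:
        """Majority-base consensus string.

        Columns with information content below ``min_info`` bits render
        as ``N``; columns whose two most frequent bases are within
        ``tie_fraction`` of each other render as ``[X/Y]``.
        """
        out = []
        for j in range(self.width_):
            if self.info_content_[j] < min_info:
                out.append("N")
                continue
            order = np.argsort(self.pfm_[j])[::-1]
            p1, p2 = self.pfm_[j, order[0]], self.pfm_[j, order[1]]
            if p1 - p2 <= tie_fraction:
                out.append(f"[{BASES[order[0]]}/{BASES[order[1]]}]")
            else:
                out.append(BASES[order[0]])
        return "".join(out)

    def score_distribution(self) -> "ScoreDistribution":
        """Exact null distribution of the PWM score (see module docstring)."""
        if self.width_ > MAX_EXACT_WIDTH:
            raise ValueError(
                f"exact score distribution supports width <= {MAX_EXACT_WIDTH}; "
                "use a coarser score_bin for wider motifs"
            )
        return ScoreDistribution.from_pwm(self.pwm_, self.background_, self.score_bin)

    def score(self, word: str) -> float:
        """Log2-odds score of one word of motif width."""
        word = word.upper()
        if len(word) != self.width_:
            raise ValueError(f"word length {len(word)} != motif width {self.width_}")
        return _score_site(word, self.pwm_, self.background_)


@dataclass(frozen=True)
class ScoreDistribution:
    """Exact PWM score null distribution on a discrete score lattice.

    ``scores`` is the ascending lattice (bits), ``pmf`` the probability of
    each lattice score for a background-random word, ``tail[i]`` the
    probability of scoring >= scores[i].  Column scores are rounded to
    the lattice once, so the DP is an exact enumeration-by-convolution of
    the rounded score; for small widths it agrees with brute-force
    enumeration to float accumulation error.
    """

    scores: np.ndarray
    pmf: np.ndarray
    tail: np.ndarray
    bin_width: float
    int_offsets: np.ndarray  # (width, 4) integer lattice scores per column

    @classmethod
    def from_pwm(cls, pwm, background, bin_width: float = 0.01):
        if bin_width <= 0 or bin_width > 0.01:
            raise ValueError("bin_width must be in (0, 0.01]")
        k = np.rint(np.asarray(pwm) / bin_width).astype(np.int64)
        lo, hi = int(k.min(axis=1).sum()), int(k.max(axis=1).sum())
        if hi - lo > 5_000_000:
            raise ValueError(
                f"score lattice of {hi - lo} bins is too large; "
                "use a coarser score_bin"
            )
        pmf = np.zeros(hi - lo + 1)
        pmf[0] = 1.0  # score lattice starts at lo
        width = k.shape[0]
        cur_lo = 0
        for j in range(width):
            nxt = np.zeros_like(pmf)
            base_lo = int(k[j].min())
            for b in range(4):
                shift = int(k[j, b]) - base_lo
                if shift == 0:
                    nxt[: pmf.size] += background[b] * pmf
                else:
                    nxt[shift:] += background[b] * pmf[: pmf.size - shift]
            # re-anchor: lattice origin advances by this column's min
            pmf = nxt
            cur_lo += base_lo
        # cur_lo == lo by construction
        tail = np.cumsum(pmf[::-1])[::-1]
        scores = (lo + np.arange(pmf.size)) * bin_width
        return cls(
            scores=scores,
            pmf=pmf,
            tail=np.minimum(tail, 1.0),
            bin_width=bin_width,
            int_offsets=k,
        )

    def pvalue(self, score: float) -> float:
        """P(null score >= score), evaluated on the lattice.

        Un-rounded word scores can exceed the lattice maximum by up to
        half a bin per column; such scores map to the top of the tail.
        """
        idx = int(np.searchsorted(self.scores, score - self.bin_width / 2.0))
        if idx >= self.scores.size:
            slack = (self.int_offsets.shape[0] + 1) * self.bin_width / 2.0
            return float(self.tail[-1]) if score <= self.scores[-1] + slack else 0.0
        return float(self.tail[idx])

    def threshold_for_pvalue(self, pvalue: float) -> float:
        """Smallest lattice score whose tail probability is <= pvalue.

        When even the maximum score cannot reach the requested tail
        probability (a low-information motif), the returned threshold
        lies one bin above the lattice maximum, so nothing passes.
        """
        if not (0 < pvalue <= 1):
            raise ValueError("pvalue must be in (0, 1]")
        if self.tail[-1] > pvalue:
            return float(self.scores[-1] + self.bin_width)
        idx = int(np.searchsorted(-self.tail, -pvalue))
        return float(self.scores[idx])


# ---------------------------------------------------------------------------
# functional wrappers


def build_motif(sc, pseudocount: float = 0.5, background=None) -> MotifModel:
    """Build a :class:`MotifModel` from a site collection."""
    return MotifModel(pseudocount=pseudocount, background=background).fit(sc)


def consensus(model: MotifModel, tie_fraction: float = 0.1) -> str:
    return model.consensus(tie_fraction=tie_fraction)


def score_pvalue_table(model: MotifModel) -> dict:
    """Map lattice score -> P(score >= s) under the background null."""
    dist = model.score_distribution()
    return dict(zip(dist.scores.tolist(), dist.tail.tolist()))


def parse_consensus(text: str):
    """Parse a consensus string like ``ATTGAAAATTATTTT[T/C]AAT`` into a
    list of per-column allowed-base sets; ``N`` means any base.  The
    string's width is the list length."""
    cols, i = [], 0
    while i < len(text):
        ch = text[i].upper()
        if ch == "[":
            j = text.index("]", i)
            group = [c for c in text[i + 1 : j].upper() if c in BASES]
            if not group:
                raise ValueError(f"empty bracket group in {text!r}")
            cols.append(tuple(group))
            i = j + 1
        elif ch == "N":
            cols.append(tuple(BASES))
            i += 1
        elif ch in BASES:
            cols.append((ch,))
            i += 1
        else:
            raise ValueError(f"unexpected character {text[i]!r} in consensus")
    return cols


def read_sites_fasta(path, regulator: str = "") -> SiteCollection:
    """Read a binding-site multifasta into a :class:`SiteCollection`."""
    from Bio import SeqIO

    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no sequences in {path}")
    return SiteCollection(
        regulator=regulator or "motif",
        sites=tuple(str(r.seq).upper() for r in records),
        source_organisms=tuple(r.id for r in records),
    )


def logo_table(model: MotifModel):
    """Per-column logo data (position, information content, base
    frequencies) as a DataFrame, consumable by any logo renderer."""
    import pandas as pd

    return pd.DataFrame(
        {
            "position": np.arange(1, model.width_ + 1),
            "info_content_bits": model.info_content_,
            **{f"freq_{b}": model.pfm_[:, i] for i, b in enumerate(BASES)},
        }
    )


def reverse_complement(seq: str) -> str:
    return "".join(_COMPLEMENT.get(c, "N") for c in reversed(seq.upper()))
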