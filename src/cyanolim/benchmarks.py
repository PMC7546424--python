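"""Self-contained recovery experiments on synthetic data.

Each function generates its own fixtures from a seed, runs the relevant
pipeline end to end, and reports recovery statistics.  They are the
package's calibration battery: exactness of the PWM score null, planted
motif recovery on a synthetic genome, co-limitation category recovery,
and Monod/growth-rate parameter recovery at realistic noise.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy import stats

from .colimitation import CATEGORIES, ColimitationClassifier
from .growth import MonodModel, fit_exponential
from .motifs import BASES, MotifModel
from .regulon import assign_hits, scan_genome, summarize_regulon, genome_background
from .simulate import (
    SimConfig,
    gen_factorial,
    gen_genome,
    gen_growth,
    gen_monod_curve,
    hash_stream,
)

__all__ = [
    "enumerated_score_tail",
    "dp_vs_enumeration",
    "planted_motif_roundtrip",
    "colimitation_recovery",
    "null_false_positive_rate",
    "monod_recovery",
    "growth_rate_recovery",
]


def enumerated_score_tail(model: MotifModel):
    """Brute-force tail of the lattice PWM score over all 4^w words.

    Uses the same per-column score rounding as the dynamic program, so
    for small widths the two must agree to float accumulation error.
    """
    dist = model.score_distribution()
    k = dist.int_offsets
    w = k.shape[0]
    bg = model.background_
    probs: dict = {}
    for word in itertools.product(range(4), repeat=w):
        s = int(sum(k[j, b] for j, b in enumerate(word)))
        p = math.prod(bg[b] for b in word)
        probs[s] = probs.get(s, 0.0) + p
    lattice = np.rint(dist.scores / dist.bin_width).astype(np.int64)
    tail = np.zeros(lattice.size)
    for s, p in probs.items():
        tail[: int(np.searchsorted(lattice, s)) + 1] += p
    return dist.scores, tail


def dp_vs_enumeration(seed: int, width: int = 6, n_sites: int = 30) -> dict:
    """Max |DP tail - enumerated tail| for a random motif of given width."""
    rng = np.random.default_rng(seed)
    pfm = rng.dirichlet(np.full(4, 0.7), size=width)
    sites = [
        "".join(BASES[rng.choice(4, p=pfm[j])] for j in range(width))
        for _ in range(n_sites)
    ]
    bg = rng.dirichlet(np.full(4, 10.0))
    model = MotifModel(background=bg).fit(sites)
    dist = model.score_distribution()
    _, tail = enumerated_score_tail(model)
    return {
        "max_abs_diff": float(np.max(np.abs(dist.tail - tail))),
        "n_words": 4**width,
    }


def planted_motif_roundtrip(
    seed: int,
    regulator: str = "fur",
    n_planted: int = 10,
    pvalue_cutoff: float = 1e-5,
    fp_quantile: float = 0.999,
) -> dict:
    """Plant consensus sites in a synthetic genome, scan, and tally.

    Reports the fraction of planted positions recovered at the cutoff,
    the number of background (non-planted) hits, and the Poisson bound
    on that number implied by the expectation 2*L*p.
    """
    rel_positions = [-700, -550, -420, -300, -180, -90, -45, 0, 20, 40]
    planted = tuple(
        (regulator, 3 * i + 1, rel_positions[i % len(rel_positions)])
        for i in range(n_planted)
    )
    cfg = SimConfig(seed=seed, planted_sites=planted)
    sg = gen_genome(cfg)
    bg = genome_background(sg.genome)
    model = MotifModel(background=bg).fit(
        sg.site_collections[regulator], regulator=regulator
    )
    hits = scan_genome(model, sg.genome, pvalue_cutoff=pvalue_cutoff)
    planted_pos = set(sg.truth["pos"])
    recovered = planted_pos & {h.pos for h in hits}
    false_pos = sum(1 for h in hits if h.pos not in planted_pos)
    genome_len = sum(len(s) for s in sg.genome.values())
    expectation = 2.0 * genome_len * pvalue_cutoff
    return {
        "recovered": len(recovered),
        "planted": len(planted_pos),
        "recovery_pct": 100.0 * len(recovered) / len(planted_pos),
        "false_positives": false_pos,
        "fp_expectation": expectation,
        "fp_bound": int(stats.poisson.ppf(fp_quantile, expectation)),
    }


def regulon_roundtrip(seed: int, cutoffs: dict | None = None) -> dict:
    """Full scan -> assign -> summarize round trip against ground truth.

    Default cutoffs respect each motif's information budget: the 30-bp
    PHO and 19-bp Fur boxes support stringent cutoffs with essentially
    no background hits, so their regulons are recovered exactly; the
    16-bp NtcA box carries only ~8 informative columns (best attainable
    p-value ~3e-5), so it is scanned at 1e-4 where full recall holds but
    background hits are expected.
    """
    cutoffs = cutoffs or {"pho": 1e-8, "fur": 1e-8, "ntca": 1e-4}
    planted = tuple(
        (reg, 4 * i + k, (-60, -250, -500)[k])
        for k, reg in enumerate(cutoffs)
        for i in range(6)
    )
    sg = gen_genome(SimConfig(seed=seed, planted_sites=planted))
    bg = genome_background(sg.genome)
    out = {}
    for reg, cutoff in cutoffs.items():
        model = MotifModel(background=bg).fit(sg.site_collections[reg], regulator=reg)
        hits = scan_genome(model, sg.genome, pvalue_cutoff=cutoff)
        hits = assign_hits(hits, sg.genes)
        r = summarize_regulon(hits, sg.genes, cog_map=sg.cog_map, regulator=reg)
        out[reg] = {
            "genes": r.genes,
            "truth": sg.truth_regulons[reg],
            "exact": r.genes == sg.truth_regulons[reg],
            "full_recall": sg.truth_regulons[reg] <= r.genes,
        }
    return out


def _design_threshold(cfg: SimConfig, alpha: float = 0.05) -> float:
    """Population critical threshold of a synthetic factorial design:
    t_{1-alpha/2, df} times the known delta-method SE of a log ratio
    (log-scale noise sd sigma, n replicates per cell, 4 cells)."""
    n = cfg.n_replicates
    df = 4 * n - 4
    se = cfg.factorial_noise_sd * math.sqrt(2.0 / n)
    return float(stats.t.ppf(1.0 - alpha / 2.0, df) * se)


def colimitation_recovery(
    seed: int,
    n_seeds: int = 500,
    effect_multiple: float = 3.0,
    alpha: float = 0.05,
) -> dict:
    """Planted-category recovery at effect = effect_multiple x threshold.

    The classifier is given the design's known population threshold
    (the effect size is defined relative to it), so the experiment
    isolates the sign-pattern mapping from threshold estimation noise.
    """
    base = SimConfig(seed=seed)
    thr = _design_threshold(base, alpha)
    per_category = {}
    for category in CATEGORIES:
        correct = 0
        for i in range(n_seeds):
            cfg = SimConfig(
                seed=(seed * 100003 + i * 1009 + hash_stream(category) % 997) % (2**31),
                planted_category=category,
                effect_size=effect_multiple * thr,
            )
            fr = gen_factorial(cfg)
            clf = ColimitationClassifier(alpha=alpha, threshold=thr).fit(fr)
            correct += clf.category_ == category
        per_category[category] = 100.0 * correct / n_seeds
    return {
        "per_category_pct": per_category,
        "min_pct": min(per_category.values()),
        "mean_pct": float(np.mean(list(per_category.values()))),
        "threshold": thr,
    }


def null_false_positive_rate(seed: int, n_seeds: int = 2000, alpha: float = 0.05) -> float:
    """Fraction of effect-0 designs called anything but no_response."""
    base = SimConfig(seed=seed)
    thr = _design_threshold(base, alpha)
    fp = 0
    for i in range(n_seeds):
        cfg = SimConfig(
            seed=(seed * 99991 + i) % (2**31),
            planted_category="no_response",
            effect_size=0.0,
        )
        clf = ColimitationClassifier(alpha=alpha, threshold=thr).fit(gen_factorial(cfg))
        fp += clf.category_ != "no_response"
    return fp / n_seeds


def monod_recovery(
    seed: int,
    n_seeds: int = 200,
    mu_max: float = 0.83,
    q_min: float = 12.58,
    noise_sd: float = 0.02,
    n_points: int = 9,
) -> dict:
    """Quota-Monod parameter recovery.

    Noiseless inversion must be exact to numerical tolerance; with
    Gaussian noise on mu the median relative error of mu'_max over
    n_seeds simulated curves is reported.
    """
    q, mu = gen_monod_curve(SimConfig(seed=seed), mu_max, q_min, noise_sd=0.0)
    clean = MonodModel().fit(q, mu)
    noiseless_err = max(
        abs(clean.mu_max_ - mu_max) / mu_max, abs(clean.q_min_ - q_min) / q_min
    )
    errs = []
    for i in range(n_seeds):
        cfg = SimConfig(seed=(seed * 7919 + i) % (2**31))
        q, mu = gen_monod_curve(cfg, mu_max, q_min, noise_sd=noise_sd)
        try:
            fit = MonodModel().fit(q, mu)
        except Exception:
            continue
        errs.append(abs(fit.mu_max_ - mu_max) / mu_max)
    return {
        "noiseless_max_rel_err": noiseless_err,
        "median_mu_max_rel_err_pct": 100.0 * float(np.median(errs)),
        "n_converged": len(errs),
    }


def growth_rate_recovery(
    seed: int, n_seeds: int = 20, planted_mu: float = 0.33, noise_sd: float = 0.02
) -> dict:
    """Recovered exponential mu from noisy synthetic OD curves."""
    errs = []
    for i in range(n_seeds):
        cfg = SimConfig(
            seed=(seed * 6007 + i) % (2**31), planted_mu=planted_mu, noise_sd=noise_sd
        )
        for series in gen_growth(cfg):
            fit = fit_exponential(series)
            errs.append(abs(fit.mu_per_day - planted_mu))
    return {
        "max_abs_err": float(np.max(errs)),
        "median_abs_err": float(np.median(errs)),
        "n_curves": len(errs),
    }
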