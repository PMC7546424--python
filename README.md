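# cyanolim

Growth kinetics, nutrient co-limitation classification and PWM-based
regulon prediction for N2-fixing cyanobacteria.

Diazotrophic cyanobacteria are frequently limited by phosphorus, iron
and combined nitrogen, singly or together, and they respond through the
PhoB (P), Fur (Fe) and NtcA (N) master regulators. `cyanolim` packages
the quantitative chain such studies run, for microbial ecologists and
regulatory genomicists:

* **Growth kinetics** — exponential growth rates from optical-density
  time series, mu = (ln OD_f − ln OD_i)/(T_f − T_i) and Tg = ln 2/mu,
  plus the quota-Monod model mu(Q) = mu′max (Q − Qmin)/Q with the
  half-velocity concentration K_mu.
* **Co-limitation classification** — log response ratios
  ln(mu_treatment/mu_control) for 2×2 nutrient-addition designs, a
  critical significance threshold at p = 0.05, and a categorical call
  (single, serial, independent or simultaneous (co-)limitation).
* **Regulon prediction** — position weight matrices built from aligned
  binding-site collections (PHO, Fur, NtcA boxes), genome scanning on
  both strands with *exact* score p-values (dynamic programming over
  the score lattice), gene assignment by a promoter window from −800 bp
  upstream to +40 bp downstream of the translation start, and regulon
  summaries with COG functional breakdowns.
* **Assay conversions** — acetylene-reduction (ARA) readouts to
  N2-fixation rates via the 4:1 molar factor, and ROS production rates
  as blank-corrected fluorescence slopes per cell.
* **Synthetic data** — seed-deterministic generators for growth curves
  with known mu, factorial designs with planted limitation categories,
  and annotated genomes with motif instances planted at known offsets,
  used throughout the test suite as ground truth.

The main classes follow scikit-learn conventions (`fit`, `predict`,
fitted attributes with trailing underscores) and compose with sklearn
tooling; every operation is also available as a plain function.

## Worked example

```python
import numpy as np
from cyanolim import (ColimitationClassifier, FactorialResponse, MotifModel)
from cyanolim.growth import fit_replicates, summarize_treatments
from cyanolim.regulon import (assign_hits, genome_background, scan_genome,
                              summarize_regulon)
from cyanolim.simulate import SimConfig, gen_genome, gen_growth

# 1. growth: duplicate OD series at a planted mu of 0.33/day
series = gen_growth(SimConfig(seed=7, planted_mu=0.33))
print(summarize_treatments(fit_replicates(series)).to_string(index=False))
#  treatment  mu_mean  mu_spanning_range  n_replicates  tg_days
#         T1 0.329213           0.001034             2 2.105465

# 2. co-limitation: N and P additions on a severely N-limited control
fr = FactorialResponse("NO3", "PO4", (0.05, 0.05), (0.19, 0.20),
                       (0.05, 0.06), (0.21, 0.20))
p = ColimitationClassifier(alpha=0.05).fit(fr).profile_
print(f"resp_N={p.resp_a:.3f} resp_P={p.resp_b:.3f} resp_NP={p.resp_ab:.3f} "
      f"threshold={p.threshold:.3f} -> {p.category}")
# resp_N=1.361 resp_P=0.095 resp_NP=1.411 threshold=0.340
#   -> serial_limitation_A_then_B

# 3. regulon: scan a synthetic genome with three planted Fur boxes
sg = gen_genome(SimConfig(seed=7, planted_sites=(
    ("fur", 2, -120), ("fur", 9, -340), ("fur", 20, 15))))
model = MotifModel(background=genome_background(sg.genome)).fit(
    sg.site_collections["fur"], regulator="fur")
print("consensus:", model.consensus())
# consensus: ATTGAAAATTATTTT[C/T]AAT
hits = assign_hits(scan_genome(model, sg.genome, pvalue_cutoff=1e-8), sg.genes)
reg = summarize_regulon(hits, sg.genes, cog_map=sg.cog_map)
print(f"{len(hits)} hits -> genes {sorted(reg.genes)}")
# 5 hits -> genes ['gene0001', 'gene0002', 'gene0009', 'gene0010',
#                  'gene0019', 'gene0020']
print({k: round(v, 2) for k, v in sorted(reg.cog_fractions.items())})
# {'E': 0.25, 'H': 0.25, 'P': 0.5}
```

Reading the output: the recovered growth rate (0.3292/day over
duplicates, spanning range 0.001) matches the planted 0.33 within noise,
and Tg = ln 2/mu. The factorial design responds to N alone and to N+P
but not to P alone — the serial-limitation signature (first N, then P).
The genome scan reports the 19-bp Fur-box consensus it rebuilt from the
site collection (the bracket marks a near-tie column); the palindromic
box yields hits on both strands at each planted locus, and one site sits
in a shared divergent promoter, so 5 hits map to 6 genes, with the COG
histogram over the annotated members.

A `cyanolim` CLI wraps the same functions
(`cyanolim growth|colim|scan|assay|simulate`, see `--help`).

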