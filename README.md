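# mirtarget

Prediction of miRNA target **repression strength** in 3′-UTRs.

miRNAs guide the RNA-induced silencing complex (RISC) to mRNAs through
Watson–Crick pairing of the miRNA *seed* (positions 2–7/8 from the 5′
end) with the 3′-UTR.  Seed matches are abundant, so the practical
question is not *whether* a transcript carries a match but *how
strongly* it will be repressed.  `mirtarget` evaluates each seed match
with eleven features spanning four complementary views of the
interaction and combines them into a single linear predictor:

| Category | Feature | Meaning |
|---|---|---|
| thermodynamic | `dg_duplex` | MFE of the joint miRNA:site structure (kcal/mol) |
| | `dg_binding` | ensemble association energy: G(pair) − G(miRNA) − G(site) |
| | `dg_open` | cost of forcing the site single-stranded (accessibility, ≥ 0) |
| | `dg_total` | `dg_duplex + dg_open` |
| probabilistic | `p_over_binomial` | P(≥ n seed matches) under an order-1 Markov background, binomial approximation |
| | `p_over_exact` | the same tail from the exact occurrence-count law (automaton–chain embedding) |
| evolutionary | `bls` | branch length score: total length of the species subtree retaining the site, on a tree ML-fitted to the UTR alignment |
| | `phylop` | −log10 P of a branch-scaling likelihood-ratio test for locally shortened branches (negative selection) |
| | `phastcons` | mean per-base conservation score over the seed (optional track) |
| sequence | `au_content` | 1/d-weighted A/U fraction of the site flanks |
| | `pairing3` | 3′-supplementary pairing of miRNA positions ≥ 9 (13–16 core) |
| | `utr_position` | distance to the nearest UTR end (capped) |

Feature values feed an OLS model whose explained variance is
decomposed per feature with the CAR method, ω = (R^{−1/2} r)², where
R is the feature correlation matrix and r the marginal
feature–response correlations; Σω equals the model R² exactly.
Multi-site transcripts are aggregated with best / sum / log-sum-exp.

The folding backend is an in-repo reduced nearest-neighbour model
(stacking terms plus affine loop costs, G:U wobbles, no dangling
ends) with exact minimum-free-energy and McCaskill-style
partition-function dynamic programming, verified against brute-force
structure enumeration.  An adapter implementing `BackendContract` can
drop in another folding engine.

## Worked example

```python
import numpy as np
from mirtarget import MiRNA, Utr, SeedSpec, find_seed_matches, evaluate_site
from mirtarget.core import FeatureContext

rng = np.random.default_rng(7)
mir = MiRNA("miR-ex", "UGGAAUGUAAAGAAGUAUGUAU")
seq = "".join(rng.choice(list("ACGU"), size=200))
seq = seq[:90] + "ACAUUCC" + seq[97:]          # plant one seed match
utr = Utr("utr-ex", seq)

ctx = FeatureContext(mirnas={"miR-ex": mir}, utrs={"utr-ex": utr})
sites = find_seed_matches(mir, utr, SeedSpec())     # [(90, 97)]
site = evaluate_site(sites[0], ctx, ["dg_duplex", "dg_open", "dg_total",
                                     "p_over_exact", "au_content",
                                     "utr_position", "pairing3"])
for k, v in site.features.items():
    print(f"{k}: {v:.3f}")
```

prints

```
dg_duplex: -7.900
dg_open: 14.243
dg_total: 6.343
p_over_exact: 0.006
au_content: 0.306
pairing3: 3.000
utr_position: 90.000
```

The duplex gains −7.9 kcal/mol but opening the structured site costs
14.2, a net unfavourable engagement (`dg_total` > 0); the single
planted match is nevertheless rare under this UTR's composition
(`p_over_exact` ≈ 0.006).  Conservation features additionally need a
per-UTR alignment (MAF) and a species topology (Newick):

```sh
mirtarget simulate --seed 7 --outdir bundle          # synthetic fixtures
mirtarget scan --mirna-fasta bundle/mirnas.fa --utr-fasta bundle/utrs.fa \
    --maf bundle/alignment.maf --tree bundle/tree.nwk --out report.tsv
mirtarget train --table features.tsv --out model.txt
mirtarget aggregate --scores scores.tsv --sign -1 --out per_transcript.tsv
```

## Layout

- `src/mirtarget/core.py` — sequence types, seed scanning, feature dispatch
- `src/mirtarget/thermo.py`, `_fold.py` — energy features and the folding engine
- `src/mirtarget/probabilistic.py` — Markov background, exact count law
- `src/mirtarget/conservation.py` — alignments, trees, BLS, selection LRT
- `src/mirtarget/seqfeatures.py` — AU content, 3′ pairing, UTR position
- `src/mirtarget/model.py` — OLS, CAR importances, aggregation
- `src/mirtarget/simulate.py` — seeded synthetic-data generators
- `src/mirtarget/io.py`, `cli.py` — formats and the `mirtarget` command
- `docs/methods.md` — models, assumptions, parameter choices, limitations
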