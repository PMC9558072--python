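# reoscore

Rank-based immune gene-pair signatures for bulk expression cohorts: discovery,
scoring and survival/response evaluation.

## The problem

Expression-based prognostic signatures usually require normalisation that is
fragile across microarray platforms, sequencing pipelines and batches. A
signature built on **within-sample relative expression orderings (REO)**
avoids this entirely: for an ordered gene pair (G<sub>a</sub>, G<sub>b</sub>),
a sample scores

&nbsp;&nbsp;&nbsp;&nbsp;s(pair, sample) = 1 if expr[G<sub>a</sub>] > expr[G<sub>b</sub>] else 0

and a patient's signature score is the plain sum over the pairs,
S = Σ<sub>k</sub> 1[G<sub>a<sub>k</sub></sub> > G<sub>b<sub>k</sub></sub>] ∈ {0, …, K}.
Because only the ordering of two genes inside one sample enters, S is
invariant under any strictly increasing per-sample transform — it needs no
normalisation and transfers across platforms.

`reoscore` implements, for cohorts of locally advanced rectal cancer (LARC)
patients treated with neoadjuvant chemoradiotherapy (nCRT) and for any
comparable expression + survival cohort:

- **Discovery** of an immune-related gene-pair (IRGP) signature in seven
  stages: k-means patient clustering; differential expression between the
  clusters (BH-FDR); intersection with an immune-gene list (IRDEGs); pairing
  of every IRDEG with every other gene; REO pair scoring; a per-pair log-rank
  survival screen; and a *diversity filter* retaining pairs whose score is
  concentrated in one cluster (fraction ≥ α scoring 1 in one cluster and ≥ α
  scoring 0 in the other, either orientation), with α escalated in 0.05 steps
  to keep the signature below a size cap.
- **Scoring** of any cohort with a signature, including the bundled 18-pair /
  24-gene immuno-score signature (IPS), with median or fixed-threshold
  (score > 9 → high) stratification.
- **Evaluation statistics**: Mantel–Haenszel log-rank (also vectorised over
  tens of thousands of candidate pairs), Kaplan–Meier curves, 2×2 response
  odds ratios with Woolf intervals, Wilcoxon–Mann–Whitney rank-sum (exact for
  small samples), multivariate Cox regression (Newton–Raphson, Breslow ties),
  cross-platform pair-score concordance, and score–marker rank correlations.
- A **synthetic-cohort generator** that plants known discriminative pairs,
  ties survival hazard and response to the planted pair score, and emulates
  platform changes with monotone or noisy per-sample distortions — so every
  pipeline stage is testable end to end without any external download.

## Worked example

```python
import reoscore as rs

expr, clinical, truth = rs.simulate_cohort(rs.SimulationConfig(n_samples=300, seed=42))
signature, report = rs.discover_signature(
    expr, clinical, list(truth.immune_genes), rs.DiscoveryConfig(seed=42)
)
```

Running `python examples/02_discover_signature.py` (exactly this cohort) prints:

```
stage counts:
  cluster_sizes: {'A': 150, 'B': 150}
  n_deg: 488
  n_irdeg: 60
  n_irgp: 34170
  n_candidates: 8002
  n_final: 10
diversity factor used: 0.8
recall of planted pairs: 1.00; precision: 1.00
```

34,170 candidate pairs shrink to 8,002 prognostic candidates (log-rank
p < 0.05) and the diversity filter at α = 0.8 isolates exactly the 10 planted
pairs. Scoring and response evaluation with the bundled signature
(`examples/03`, `examples/04`) print, among others:

```
cohort 1 (111 patients): OR 5.23 (95% CI 2.24-12.22), 80.70% of responders are high-score
```

i.e. on the first published validation response table the odds of responding
to nCRT are ≈5.2× higher in the high-score group. The other examples
demonstrate cohort simulation, score invariance under monotone platform
distortion, and cross-platform concordance.

## Layout

```
src/reoscore/
  core.py       domain types + TSV/JSON I/O (expression, clinical, signatures)
  simulate.py   synthetic cohorts with planted pair structure
  discovery.py  the seven-stage signature discovery pipeline
  scoring.py    signature scoring and patient stratification
  stats.py      log-rank, KM, odds ratio, rank-sum, Cox, concordance
  cli.py        thin CLI: reoscore simulate|discover|score|evaluate
  data/         the bundled 18-pair signature
examples/       one short narrative script per capability
docs/methods.md model, parameters, numerical choices, limitations
```
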