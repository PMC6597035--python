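# mtvlmm

Linear mixed models for the temporal dynamics of longitudinal microbiome
data.

Given taxa-by-time relative-abundance tables from one or more hosts,
`mtvlmm` asks: *how much of a taxon's abundance at time t is explained
by the composition of the whole community at earlier times?* It answers
with a variance-component model borrowed from statistical genetics,
identifies the taxa with a significant temporal (autoregressive)
component, predicts held-out time points, and estimates which taxa drive
which. It is aimed at researchers analysing longitudinal 16S/shotgun
cohorts (daily adult sampling, infant development series, and the like)
who want a scalable, testable alternative to per-taxon autoregression.

## The model

For focal taxon *j*, stack its relative abundances over hosts and time
points into `y` and model

```
y = X β + W̃ u + H r + ε,     u ~ N(0, σ²_u I),  r ~ N(0, σ²_r I),  ε ~ N(0, σ²_ε I)
```

- `X`: intercept plus the taxon's own `p` raw lags (fixed effects);
- `W̃`: the whole community's quantile-binned abundances (low/medium/
  high per-taxon) at the previous `q` time points (random effects);
- `H`: `W̃` with rows scrambled within each host — it keeps host
  identity but destroys temporal order, guarding against host effects
  posing as dynamics.

Marginally `y ~ N(Xβ, σ²_AR K1 + σ²_ind K2 + σ²_ε I)` with the
*temporal kinship matrix* `K1 = W̃W̃'/c` (`c` = community columns), the
analogue of a genetic relationship matrix. Variance components are
estimated by average-information REML; the headline statistic is the
**time-explainability**

```
χ = σ²_AR / (σ²_AR + σ²_ind + σ²_ε)
```

— the taxon's variance share attributable to the lagged community —
with a delta-method CI and a boundary likelihood-ratio test
(`½χ²₀ + ½χ²₁`), BH-adjusted across taxa. Held-out time points are
predicted by BLUP (conditional-normal) prediction; model order (p, q)
is chosen per taxon on a chronological train/validation/test split; an
AR(1) least-squares baseline and a Wilcoxon comparison are built in.
See `docs/methods.md` for the full account.

## Worked example

```python
import mtvlmm

# simulate a cohort: 10 hosts, 70 samples each, 200 taxa, 20% of them
# driven by the previous community state (ground truth recorded)
dataset, truth = mtvlmm.simulate_community(seed=11)
screened, retained = mtvlmm.screen_taxa(dataset)
print(f"{len(retained)} of {dataset.n_taxa} taxa pass the 10% presence screen")

table = mtvlmm.fit_all_taxa(screened, p=0, q=1, rng_seed=11)
ar = table[table["autoregressive"]]
print(f"{len(ar)} taxa called autoregressive (BH q < 0.05)")
print(f"mean time-explainability among them: {ar['chi'].mean():.2f}")

flags = dict(zip(table["taxon_id"], table["autoregressive"]))
taxonomy = {t: screened.taxonomy[t] for t in retained}
p, n_empty = mtvlmm.order_permutation_test(flags, taxonomy, seed=11)
print(f"orders with zero autoregressive taxa: {n_empty}; permutation p = {p:.2g}")
```

prints

```
185 of 200 taxa pass the 10% presence screen
38 taxa called autoregressive (BH q < 0.05)
mean time-explainability among them: 0.52
orders with zero autoregressive taxa: 8; permutation p = 1e-05
```

The simulator planted 40 autoregressive taxa (38 survive the presence
screen) concentrated in two taxonomic orders; the fit recovers exactly
those, each with roughly half its temporal variance explained by the
previous community state, and the permutation test confirms that eight
orders containing no autoregressive taxon is far more concentration
than random labelling would produce.

The same pipeline is available from the shell on TSV/CSV tables:

```
mtvlmm validate  -a abundance.tsv -m metadata.tsv
mtvlmm fit       -a abundance.tsv -m metadata.tsv --p 0 --q 1 -o chi.tsv
mtvlmm predict   -a abundance.tsv -m metadata.tsv --p 1 --q 1 -o pred.tsv
mtvlmm select    -a abundance.tsv -m metadata.tsv -o models.tsv
mtvlmm associations -a abundance.tsv -m metadata.tsv -o U.tsv
mtvlmm downstream --te-table chi.tsv --taxonomy tax.tsv -o out/
mtvlmm simulate  --mode community --seed 1 -o sim/
```

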