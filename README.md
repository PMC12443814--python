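# mutualnet

Quantitative analysis of weighted bipartite mutualistic networks, built around
the kind of plant–frugivore visitation data collected in year-round transect
surveys (here modeled on a subtropical karst bird–plant community: 18
frugivorous birds × 14 fruiting plants, 4446 foraging visits). The package
covers the full analysis chain for such a study:

- **Network-level metrics** on the weighted visit matrix `w` (plants as rows,
  birds as columns, `m = Σ w_ij` events, `L` realized links):
  - connectance `C = L / (A_p·A_b)`;
  - weighted nestedness **wNODF** (overlap with decreasing fill, 0–100);
  - specialization **H2′** — the two-dimensional Shannon entropy
    `H2 = −Σ p_ij ln p_ij` rescaled between the entropy extremes attainable
    under the observed marginals, `H2′ = (H2max − H2)/(H2max − H2min)`;
  - **Barber bipartite modularity** `Q = (1/m) Σ_ij [w_ij − r_i c_j/m]·δ(g_i, g_j)`
    maximized by seeded label propagation plus exhaustive module merging.
- **Species-level metrics**: degree `k`, species strength
  `s_j = Σ_i w_ij / r_i` (partner dependencies; strengths on one side sum to
  the other side's richness), and standardized Kullback–Leibler
  specialization `d′`.
- **Fixed-marginal null models**: uniform draws from integer matrices with
  the observed row/column totals (the r2dtable distribution), z-scores
  `z = (obs − mean_null)/sd_null` and empirical tail p-values.
- **Extinction robustness**: sequential removal of one side (hubs first, hubs
  last, or random), secondary extinction of partners left with no
  interactions, and robustness `R` = area under the attack-tolerance curve.
- **Sample coverage**: Chao's estimator
  `Ĉ = 1 − (f1/n)·(n−1)f1 / ((n−1)f1 + 2f2)` for links and for each side.
- **Trait → role regression**: log10 transformation, all-subsets Gaussian
  linear models, AIC model averaging (Akaike weights, full averaging,
  unconditional standard errors) linking bird/plant traits to degree,
  strength and d′.
- **Synthetic data**: a generator of visit matrices and trait tables with
  heterogeneous species propensities, niche-matching structure, planted
  modules, seasonal tags and causal trait couplings, so the whole pipeline is
  testable without any field download.

## Worked example

The numbered scripts under `analysis/` run the full study on a simulated
survey (seed 42) and write their tables under `results/`:

```bash
python analysis/01_simulate_network.py
python analysis/02_network_metrics.py
python analysis/03_null_models.py
```

which prints:

```
wrote synthetic web: 14 plants x 18 birds, m=4446, L=206, rainy share 51.7%
richness: 18 birds, 14 plants, L=206, m=4446
C=0.817  wNODF=69.0  H2'=0.096  Q=0.171
connectance  obs=   0.817 z=  -12.30 p_up=1.000 p_lo=0.000 (significant tail: lower)
wnodf        obs=  68.991 z=  -19.29 p_up=1.000 p_lo=0.000 (significant tail: lower)
H2prime      obs=   0.096 z=   75.30 p_up=0.000 p_lo=1.000 (significant tail: upper)
Q            obs=   0.171 z=   39.11 p_up=0.000 p_lo=1.000 (significant tail: upper)
```

Read: the simulated web realizes 206 of 252 possible links; against 1000
fixed-marginal randomizations it is *less* connected (z = −12.3) but far
*more* specialized (H2′ z = +75.3) and modular (Q z = +39.1) than chance —
the characteristic signature of a specialized mutualistic web. Because the
null conserves marginals, a metric can only be judged in the tail where it
actually lies; the report always prints both tails. Steps `04`–`07` add the
extinction-robustness table (hubs-first removal is always the most damaging
scenario), per-season Chao coverage, the model-averaged trait coefficients,
and a single `report.json` covering every stage per season.

The same machinery is available as a CLI (`mutualnet simulate|metrics|null|
extinct|coverage|traits|run-all`) for use on real matrices or edge lists; see
`mutualnet --help`.

Published reference tables from the karst frugivory survey (species-level
degree/strength/specialization, per-season network summaries, robustness and
coverage values) ship as CSV under `src/mutualnet/data/` and load via
`mutualnet.reference`.

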