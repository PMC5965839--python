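# vegnet

Signed species-association networks from vegetation-plot data, and a test of
whether community structure improves species distribution models (SDMs).

## The problem

Relevé databases record, for thousands of vegetation plots, the percent cover
of every species on an ordered cover-class scale, together with the plot's
environment (climate, geology, land use, orientation, dominant growth form)
and its grid-cell coordinates. The relative abundance of co-occurring species
("community structure") reflects local assembly processes — micro-environmental
filtering and biotic interactions — that coarse environmental layers cannot
see. `vegnet` implements a pipeline for Mediterranean woody-plant communities
that:

1. learns a **directed association network** over species abundances and
   environmental variables with score-based Bayesian-network structure
   learning (multinomial BIC, greedy hill climbing with restarts), under
   ecological constraints (species never influence the environment; exogenous
   drivers — warmest-quarter temperature `Twarm`, annual precipitation
   `anualP`, geology, orientation — accept no parents);
2. makes the network robust by **bootstrap consensus**: the structure is
   learned on many bootstrap resamples of the plots; an arc's *strength* is
   the fraction of runs containing it, its orientation is kept only when one
   direction appears in > 50% of those runs, and a data-driven threshold
   (the cut minimising the L1 distance between the strength ECDF and the
   ideal 0/1 CDF) flags *significant* arcs;
3. gives each significant link a **sign** with the Jonckheere–Terpstra trend
   test over ordered parent levels (`+` / `−` / unsigned; exact permutation
   p-value for small samples);
4. fits per-species **binomial additive SDMs** (logit link, penalized
   thin-plate-type smooth of lon×lat with GCV-selected λ) whose predictors
   are the species' parent nodes in either the overall network (**Env+Bio**)
   or its environment-only network (**Env**), plus a random-predictor
   baseline;
5. **evaluates** both model families on a held-out third of the plots:
   Spearman ρ of observed vs predicted abundance per species, AIC and
   deviance explained, Bray–Curtis similarity `1 − Σ|xᵢ−yᵢ|/Σ(xᵢ+yᵢ)` of
   predicted vs observed community structure per plot, all compared with
   paired t-tests;
6. asks whether species-species links concentrate within **trait syndromes**
   (Tertiary vs Quaternary lineages) with χ² goodness-of-fit tests.

Because real survey extracts are not redistributable, the package ships a
first-class **synthetic community generator**: it samples a ground-truth DAG
with known conditional probability tables (proportional-odds construction,
95% positive signs, same-syndrome bias) and simulates relevé tables by
ancestral sampling, so every stage of the pipeline is benchmarked against a
known truth.

## Worked example

```bash
python analysis/01_simulate_communities.py
python analysis/02_infer_networks.py
python analysis/03_sign_links.py
python analysis/04_fit_and_evaluate_sdms.py
python analysis/05_syndrome_analysis.py
python analysis/06_figures.py
```

Output of the chain on the default configuration (24 species, 1000 plots,
100 consensus runs):

```
simulated 1000 plots x 24 species
ground truth: 40 arcs, 29/30 signed arcs positive
overall network: 63 consensus arcs, 34 significant (strength threshold 0.270)
recovery vs ground truth: precision 1.00, recall 0.85, SHD 9
34 significant links, 19 species-species
positive fraction among signed species-species links: 94.74%
true '+' arcs recovered: 28, of which signed '+': 100.00%
evaluated 24 species on 334 validation plots
  bc_env_bio_vs_env: mean delta +0.04649, t = 26.83, df = 333, p = 3.09e-85
  dev_expl_env_bio_vs_env: mean delta +10.4, t = 5.86, df = 23, p = 5.75e-06
  dev_expl_env_bio_vs_random: mean delta +13.03, t = 8.69, df = 23, p = 1.01e-08
  rho_env_bio_vs_env: mean delta +0.1756, t = 5.58, df = 19, p = 2.2e-05
```

Reading: the consensus network recovers the generating structure almost
exactly (every significant arc is true, 85% of true arcs found); recovered
positive arcs are signed `+`; and because the generating process really does
couple species, the Env+Bio models explain on average 10.4 percentage points
more deviance than the Env models, predict abundances that rank-correlate
better with the observed ones (Δρ ≈ +0.18), and reconstruct community
structure more faithfully (ΔBray–Curtis ≈ +0.046 per plot). On communities
simulated *without* species-species arcs the same comparison is null — the
pipeline does not invent biotic signal (see `tests/test_acceptance.py`).

The same stages are available as a CLI (`vegnet simulate | infer | sign |
sdm | evaluate | syndromes | full-run`) and as library calls
(`vegnet.run_full_pipeline`).

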