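# punctevo

Punctuational-evolution analysis of single-cell lineage-tracing
phylogenies.

## The problem

CRISPR-Cas9 lineage tracing reconstructs the clonal history of a tumour
as a rooted bifurcating tree over thousands of individual cells, with
branch lengths in expected nucleotide substitutions at the engineered
target sites.  A basic question about such trees is *how* molecular
change accumulates: gradually, clock-like along branches, or in bursts
concentrated at diversification events — the appearance of new cellular
subpopulations.  The second pattern, punctuational evolution, is
expected wherever founder effects or niche invasion accompany
diversification, and metastatic colonization (a handful of cells
seeding a new organ site) is a textbook candidate.

`punctevo` implements the complete statistical battery for this
question, aimed at computational cancer-evolution researchers working
with posterior samples of reconstructed single-cell trees:

- **Punctuation test.** For each tree, each cell's root-to-tip
  divergence *LD* is regressed on its diversification count *DE* by
  phylogenetic generalized least squares, `LD = β·DE + g`, with Pagel's
  λ profiled by maximum likelihood.  β > 0 is the punctuational signal;
  the gradual contribution *g* is absorbed by the intercept and the
  tree-structured residual.
- **Node-density artefact screen.** Reconstruction underestimates
  branch lengths in sparsely sampled regions, which fakes a positive
  β.  The curvilinear model `LD = β·DE^(1/δ) + g` detects this: a
  significant β with δ > 1 in a posterior majority flags the lineage as
  artefactual rather than punctuational.
- **Punctuational contribution.** `PC = 2(c−1)·β/T` — the share of a
  c-tip tree's total length T attributable to per-node bursts — and the
  deviation-from-gradualism correlation
  `ρ = β·σₙ / sqrt(β²·σₙ² + σ_g²)`.
- **Location partition.** A two-state continuous-time Markov model over
  {primary, metastasis} with κ-transformed branches and the root fixed
  in the primary state reconstructs ancestral locations; branches are
  categorized (P, M, transition, undefined) and the per-location
  contributions `PC_P = N_P·β/T_P`, `PC_M = N_M·β/T_M` are compared by
  paired Wilcoxon tests with Bonferroni correction across lineages.
- **Metastatic complexity.** Fritz–Purvis phylogenetic dispersion D of
  the metastatic tip labels (≈1 random scatter, ≈0 single clumped
  seeding clade).
- **Synthetic cohorts.** A generator producing Yule trees whose branch
  lengths mix a gradual clock with gamma-distributed per-branch jumps,
  CTMC tip locations, CNV counts, pseudo-posterior samples, and full
  ground-truth records for every experiment above.

## Worked example

Simulate one metastatic lineage of 300 cells in which the metastatic
clade diversifies faster and jumps three times harder (true
punctuational share 0.101), then run the full per-lineage analysis:

```python
from punctevo import SimulationConfig, make_lineage, PipelineConfig, run_lineage

cfg = SimulationConfig(
    n_tips=300, target_pc=0.10, seeding_mode="monophyletic",
    met_branch_scale=1/3, met_jump_scale=3.0,
    n_posterior=25, rng_seed=7,
)
lin = make_lineage(cfg)
report = run_lineage(lin.posterior, lin.meta,
                     PipelineConfig(d_n_perm=500, d_n_bm=500))
```

which prints (via the report fields):

```
verdict            : punctuational
PC (posterior mean): 0.102
rho                : 0.421
D (complexity)     : -0.72
PC_P / PC_M        : 0.092 / 0.219
paired Wilcoxon p  : 5.96e-08  direction: M>P
```

Read: the lineage shows punctuational evolution (significant β with
δ ≤ 1 in a posterior majority); bursts account for ~10% of its total
molecular diversity, matching the generating truth; the punctuational
share is 2.4× higher on metastatic branches than on primary branches
and the paired posterior contrast is decisive; D = −0.72 says the
metastatic cells sit in one clumped clade (a single seeding event), as
simulated.

## Analysis scripts

`analysis/` contains numbered drivers that run the same machinery over
a full 26-lineage synthetic cohort (11 metastatic, 15 non-metastatic,
three mouse-model backgrounds):

```bash
python analysis/01_simulate_cohort.py      # trees + metadata -> scratch/, manifest -> results/
python analysis/02_test_punctuation.py     # per-lineage verdicts -> results/
python analysis/03_partition_locations.py  # PC_P vs PC_M contrasts -> results/
python analysis/04_metastatic_complexity.py# dispersion D -> results/
python analysis/05_cohort_statistics.py    # cohort tests -> results/
```

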