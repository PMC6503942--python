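# hiercomplex

Hierarchical complexity analysis of structural brain connectomes.

Structural connectomes — whole-brain networks whose nodes are atlas
parcels (ROIs) and whose edges are white-matter connections inferred from
diffusion MRI — have a topology that standard indices (clustering,
assortativity, degree variance) describe only partially.  *Hierarchical
complexity* targets a different property: how **variable** the
connectivity patterns of *hierarchically equivalent* nodes (nodes sharing
a degree) are.  This package implements the full analysis around that
statistic for cohorts of connectome-like networks: the statistic itself
and its degree-restricted variants, three matched random-graph null
models, degree-based tier decomposition with regional consistency,
neighbourhood/tier connectivity profiling, cohort statistics, and a
synthetic connectome cohort generator that stands in for MRI data.

It is intended for network-neuroscience researchers and methodologists
who want a tested, reproducible implementation of the statistic and its
surrounding pipeline.

## The statistic

Let `K_p` be the set of nodes of degree `p` and, for node `i` of degree
`p`, let `s_i = (s_i(1) ≤ … ≤ s_i(p))` be its ordered neighbourhood
degree sequence.  With `μ_p(j)` the mean of the `j`-th entries over
`K_p`, the mean positional variance of the class is

    W_p = (1/p) Σ_j  (1/(|K_p|−1)) Σ_{i∈K_p} (s_i(j) − μ_p(j))²

and the hierarchical complexity of the network is the average over the
`D` distinct degrees of the slot-normalised class terms

    R = (1/D) Σ_{p : |K_p|>1}  W_p / (p·|K_p|)

(`R = (1/D) Σ W_p`, without the slot normalisation, is available as
`scaled=False`; see `docs/methods.md` for the two conventions).  `R = 0`
for every regular, vertex-transitive or star graph — any graph whose
same-degree nodes look alike — and grows when nodes of equal degree
connect to systematically different parts of the degree hierarchy.

Around `R` the package computes degree variance `V`, assortativity `r`,
global clustering `C`, density-normalised clustering `γ = C/P`,
characteristic path length `L` and the mean rich-club coefficient, and
compares each cohort against three node- and edge-matched null models:
Erdős–Rényi graphs, 3D random geometric graphs (RGGs), and
degree-preserving configuration rewirings.

## Worked example

```python
import numpy as np
from hiercomplex import (SyntheticParams, simulate_cohort, group_threshold,
                         hierarchical_complexity, configuration_rewire,
                         compare_groups)

cohort = group_threshold(simulate_cohort(SyntheticParams(subjects=79, seed=0)))
R = [hierarchical_complexity(b) for b in cohort]
Rc = [hierarchical_complexity(configuration_rewire(b, seed=i))
      for i, b in enumerate(cohort)]
print(f"cohort R = {np.mean(R):.3f}, rewired R = {np.mean(Rc):.3f}, "
      f"d = {compare_groups(R, Rc).d:.2f}")
```

prints

```
cohort R = 0.565, rewired R = 0.152, d = 2.60
```

i.e. the synthetic connectomes are far more hierarchically complex than
degree-matched random rewirings of themselves — same-degree regions make
systematically more diverse connections than degree structure alone
explains — with a very large effect size across the 79 subjects.

The full analysis is organised as numbered drivers:

```bash
python analysis/01_simulate_cohort.py    # cohort -> scratch/, summary -> results/
python analysis/02_null_ensembles.py     # matched ER/RGG index statistics
python analysis/03_run_pipeline.py       # thresholds, indices, nulls, tiers, profiles
python analysis/04_summary_tables.py     # headline index table + correlation ranking
```

`03` reports, among other things, the per-tier effect sizes showing that
the complexity difference concentrates in the middle degree tiers rather
than in the hubs, and the regional tier-consistency table (74 of 85 ROIs
consistently tiered at the default seed).

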