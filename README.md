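# ccdyn — consensus connectome dynamics

`ccdyn` is a Python library (with a thin `ccd` command-line wrapper) for
studying how a population-level brain network grows as its consensus
threshold is relaxed, and for simulating that growth with a small random
graph model. It is aimed at researchers working with ensembles of structural
connectomes — one undirected braingraph per subject, all over a shared
anatomical atlas — who want to quantify which connections are common, how
reproducible their order of appearance is, and whether a simple growth rule
accounts for it.

## The objects and the model

Given `n` subject graphs over `N` atlas nodes, an edge is **k-frequent** if
at least `k` subjects have it; the **k-consensus connectome** contains all
k-frequent edges. Lowering `k` from `n` to 1 yields a nested, growing graph
sequence (step `i` ↔ the `(n+1−i)`-consensus connectome) whose striking
feature is that new edges overwhelmingly attach to edges already present:
**isolated** new edges — sharing no endpoint with any other consensus edge —
are rare.

Robustness of the appearance order is measured by splitting the subjects
into 4 balanced groups and estimating the **discordance probability**: for
random distinct groups X, Y and random common edges e, f, the probability
that e appears strictly before f in X while f appears strictly before e in
Y (or vice versa). Random orders give 1/2; reproducible dynamics give much
less.

The growth itself is modeled by **doubly-preferential attachment**: starting
from a small random seed graph, each step adds every absent edge `uv`
independently with probability

    p_uv = B/(2(N−1)) · (deg u + deg v) + C

so the expected number of new edges per step is `B·|E|` (exponential growth
at rate `B`), and the constant `C` lets edges occasionally appear between
isolated nodes. `A` and `B` come from a log-linear fit of the observed edge
counts (`A·e^{Bk}`); the seed graph has `⌊A − binom(N,2)·C/B + 0.5⌋` edges to
offset the extra edges `C` injects; `C` is calibrated by ratio scaling
against a target cumulative isolated-edge total. A synthetic-data module
generates ensembles with a planted developmental order (and an exchangeable
null) so the whole pipeline is testable without any data download.

## Worked example

```python
from ccdyn import (planted_model, sample_ensemble, edge_frequencies,
                   ccd_trajectory)

model = planted_model(N=100, n_edges=600, coupling=1.0,
                      q_max=0.95, q_min=0.05, seed=21)
ensemble = sample_ensemble(model, n_subjects=400, seed=22)
traj = ccd_trajectory(edge_frequencies(ensemble))
print(traj.edge_count[-1], traj.cumulative_isolated[-1])
```

The scripts in `examples/` walk each capability; `examples/quarter_robustness.py`
prints

```
planted order     : discordance = 0.061 ± 0.000 (599 common edges)
exchangeable null : discordance = 0.443 ± 0.001 (600 common edges)
```

— the planted-order ensemble's appearance order barely depends on which
quarter of the subjects built it (0.061, far below the 1/2 random-order
level), while the null ensemble sits at the random-order level (just under
1/2 because tied appearance steps count as concordant).

`examples/dpa_simulation.py` runs the model at the reference parameters
(`N=1015`, `A=46.37`, `B=0.014`, `C=7.6e−7`, 418 steps) and prints the
exponential edge-count curve alongside the cumulative isolated-edge total,
which rises while many nodes still have degree zero and then plateaus near
51 — the model's quantitative signature of structured growth.

The same operations are available from the shell, e.g.:

```bash
ccd synth --N 100 --edges 600 --subjects 400 --coupling 0.9 --seed 1 --out ens/
ccd trajectory --graphs ens/ --out traj.tsv
ccd robustness --graphs ens/ --kind edge --samples 1000000 --seed 1
ccd simulate --N 1015 --A 46.37 --B 0.014 --C 7.6e-7 --steps 418 --runs 10 \
    --seed 1 --out sim.tsv
ccd calibrate-c --target 52 --c0 2e-6 --seed 1
```

Pointing `ccd trajectory` / `ccd robustness` / `ccd fit-exp` at a directory
of real per-subject GraphML files reproduces the real-data analyses; no test
or shipped result depends on downloaded data.

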