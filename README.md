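# ibclust — individual-based clustering of movement data

`ibclust` clusters the *individuals* in a movement dataset — animals resighted
across wetlands, people geolocated across counties — by the locations they
visit, instead of clustering the locations themselves. Because each individual
keeps its own membership, locations can be used by one group or by several, so
the method identifies **mixed-membership sites** (critical connectivity sites),
tracks **how each group's space use changes between time periods** with full
posterior uncertainty, and relates group membership to individual traits
(birth cohort, origin) that were never part of the fit.

It is aimed at movement ecologists and anyone analysing visitation matrices
(mark–resight records, geotagged social-media counts, cell-tower logs).

## Model

The input is a matrix `w` whose entry `w_jl` counts how often individual
`j = 1..J` was observed at location `l = 1..L`. The generative model is a
Bayesian multinomial mixture:

- `z_j ~ Categorical(β)` — individual `j` belongs to group `z_j`;
- `w_j ~ Multinomial(n_j, ψ_k)` given `z_j = k`, where `n_j` is the total
  number of observations of `j` and `ψ_k` is group `k`'s visitation-rate
  vector (a point on the `L`-simplex);
- `β` has a truncated stick-breaking prior,
  `β_k = V_k ∏_{m<k} (1 − V_m)` with `V_k ~ Beta(1, α)` for `k < K` and
  `V_K = 1`, which favours few occupied groups — only the maximum `K` is
  pre-specified and the *effective* number of groups emerges from the data;
- `ψ_k ~ Dirichlet(ε, …, ε)`.

Defaults are `K = 25`, `α = 0.1`, `ε = 0.1`. All conditionals are conjugate
and the model is fit by a blocked Gibbs sampler (`ψ | z, w`, then `V | z`,
then `z | β, ψ`), followed by a relabeling pass that resolves label
switching. Temporal change is analysed by a **conditional refit**: group
memberships from an earlier window are frozen while `ψ` (and `β`) are
re-estimated on a later window, and per-site differences `Δψ = ψ^t2 − ψ^t1`
are declared significant when their 95% equal-tailed credible interval
excludes zero.

## Worked example

Simulate the low-overlap benchmark (4 groups, 50 locations, 9 of them shared
between groups), fit, and summarize:

```python
import ibclust as ib

spec = ib.scenario_preset("scenario1")          # 400 individuals, n_j = 20
sim = ib.simulate_counts(spec, seed=1)

fit = ib.run_gibbs(sim.counts, n_iter=3000, burnin=1500, thin=5, seed=2)
fit = ib.relabel_samples(fit)

groups, coverage = ib.effective_groups(fit, min_share=0.01)
print(f"{len(groups)} effective groups covering {coverage:.1%} of individuals")
for g in groups:
    print(f"  group {g.group}: occupancy {g.occupancy:.3f}, "
          f"beta {g.beta_mean:.3f}, {len(g.members)} members at the mode")

sites = ib.mixed_membership_sites(fit.psi_mean(), groups, cutoff=0.02,
                                  col_labels=fit.col_labels)
print(sites["classification"].value_counts().to_dict())
edges = ib.group_edges(fit.psi_mean(), group=1, cutoff=0.05,
                       col_labels=fit.col_labels)
print(f"group 1 network: {len(edges)} links between above-cutoff sites")
```

Output:

```
4 effective groups covering 100.0% of individuals
  group 1: occupancy 0.250, beta 0.252, 100 members at the mode
  group 2: occupancy 0.250, beta 0.248, 100 members at the mode
  group 3: occupancy 0.250, beta 0.250, 100 members at the mode
  group 4: occupancy 0.250, beta 0.236, 100 members at the mode
{'single': 41, 'mixed': 9}
group 1 network: 105 links between above-cutoff sites
```

Although the sampler was given up to `K = 25` groups, exactly the four
designed groups carry posterior mass, every individual lands in its true
group, and the 9 designed mixed-membership sites are recovered at the 0.02
visitation-rate cutoff. The 105 links are the clique over group 1's 15
above-cutoff sites.

The same workflow is available from the shell:

```bash
ibc simulate --scenario scenario1 --seed 1 --out-prefix sim1
ibc fit --counts sim1_counts.csv --out-dir fit1 --n-iter 3000 --burnin 1500 --thin 5
ibc summarize --fit-dir fit1 --out-dir summary1
ibc pipeline --counts period1.csv --counts-t2 period2.csv --out-dir run1  # incl. Δψ table
```

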