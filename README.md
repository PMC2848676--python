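# flumeflux

Analysis toolkit for experiments linking **fine-scale flow heterogeneity**
in stream mesocosms to **biofilm bacterial biodiversity** and to the rate
and **molecular diversity of dissolved-organic-carbon (DOC) uptake**.

Streams process a globally significant share of terrestrial carbon, and the
benthic biofilms that do the work live in a physically structured world:
bedforms create microhabitats that differ in velocity, turbulence and mass
transfer.  This package implements the full quantitative chain needed to
ask whether that physical heterogeneity begets biological diversity and
broader resource use:

* **hydro** — velocimetry grids to node statistics (time-mean 3-D speed
  `R_xyz`, turbulent kinetic energy, turbulence intensity) and the
  flume-level heterogeneity measure `SD_Rxyz`;
* **diversity** — T-RFLP fingerprints to OTU tables; Hill-number diversity
  `D_q = (Σ pᵢ^q)^(1/(1−q))`; multiplicative partitioning γ = α·β where β
  is the effective number of distinct microhabitat communities; evenness;
  Bray-Curtis dissimilarity;
* **uptake** — first-order loss rates from recirculating decay curves by
  log-linear fit, converted to depth-independent uptake velocities
  `v_f = k·h̄` (cm h⁻¹);
* **ftms** — FTICR-MS peak lists to CHONS molecular formulas (exhaustive
  search under C≤100, O≤80, N≤5, S≤1 with DBE/H:C/O:C validity filters),
  Van Krevelen descriptors, compound-specific mass transfer
  `v_f = (h̄/T)·ln(I_in/I_res)` and DOC-pool diversity;
* **regstats** — OLS, hierarchical partitioning of R², z-scores, bootstrap
  CIs for coefficients of variation;
* **matstats** — Mantel and partial Mantel tests with exact 6! = 720
  permutation enumeration, path coefficients over a causal DAG on the
  Mantel correlation structure, UPGMA clustering, Bonferroni control;
* **synth** — a synthetic six-flume experiment with known ground truth, so
  every estimator is testable end to end;
* **pipeline** — config-driven orchestration with tidy TSV outputs and a
  JSON manifest, plus a thin `flumeflux` CLI (`simulate` / `run` /
  `report`).

## Worked example

```python
from flumeflux.pipeline import RunConfig, run, report

result = run(RunConfig(seed=0, outdir="flumeflux_out"))
print(report(result))
```

The summary table printed for the default seeded design:

```
|   flume |   mean_Rxyz |   SD_Rxyz |   mean_depth |   residence_time_min |   n_nodes |   beta |   vf_DOC |   slope_rI |
|--------:|------------:|----------:|-------------:|---------------------:|----------:|-------:|---------:|-----------:|
|       0 |         7.6 |      1.6  |        6.724 |                8.772 |        80 |  1.034 |    0.431 |    129.976 |
|       1 |         7.6 |      2.54 |        6.69  |                8.772 |        80 |  1.057 |    0.466 |    113.618 |
|       2 |         7.6 |      3.48 |        6.702 |                8.772 |        80 |  1.099 |    0.541 |     95.363 |
|       3 |         7.6 |      4.42 |        6.671 |                8.772 |        80 |  1.152 |    0.583 |     79.401 |
|       4 |         7.6 |      5.36 |        6.704 |                8.772 |        80 |  1.192 |    0.701 |     62.559 |
|       5 |         7.6 |      6.3  |        6.727 |                8.772 |        80 |  1.241 |    0.746 |     44.663 |
```

Reading it: all six flumes share the mean velocity (7.6 cm s⁻¹, an 8.8-min
residence time) and depth, while `SD_Rxyz` — spatial flow heterogeneity —
rises 1.6 → 6.3 cm s⁻¹.  Along that gradient bacterial beta diversity
(`beta`, effective number of distinct microhabitat communities at q = 1)
and bulk DOC uptake velocity (`vf_DOC`, cm h⁻¹) increase, while `slope_rI`
— the strength with which a compound's inflow availability predicts its
individual uptake — decreases: biofilms in heterogeneous flow draw on a
wider, less availability-driven slice of the DOC pool.  The run directory
additionally contains the per-date diversity partitions, all uptake fits,
the 361-compound table with assigned formulas and per-flume v_f, the
Mantel/partial-Mantel table (exact 720-permutation P values), the fitted
path model (edge list + DOT) and a UPGMA tree of resource-use similarity.

The `examples/` directory holds one short narrative script per capability;
each builds or generates a small input, runs one method and explains the
numbers it prints.

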