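# hollownet

Bipartite network analysis of tree hollow–saproxylic insect communities.

Saproxylic insects — species that depend on dead or decaying wood during
some life stage — breed inside tree hollows, and the emergence counts of
each species from each hollow form a bipartite species × microhabitat
matrix.  `hollownet` implements the statistics ecologists use to describe
the architecture of such networks and its consequences for persistence:

* **Nestedness** — NODF (binary) and WNODF (quantitative), the estimators
  based on overlap and decreasing fills, with Monte-Carlo significance
  against the **CE** null (cell probability = mean of row and column
  occupancy proportions) and the **RC** null (individuals re-placed
  proportionally to row/column totals until every margin is reproduced
  exactly).
* **Modularity** — Barber's bipartite modularity
  `M = Σ_m [L_m/L − K_m^A K_m^B / L²]`, maximized by simulated annealing,
  with a budget-matched CE randomization test.
* **Core/periphery** — the categorical model (correlation with the ideal
  core pattern, mixed blocks excluded), repeated from 25 random starts;
  nodes in the core in ≥80% of runs are tier-a core, in 65–79% tier-b.
* **Descriptors** — links per species L/S, connectance C, quantitative
  linkage density LD (effective partners `2^H` weighted by marginal
  totals), Schluter's variance ratio, and per-node degree/strength from
  the dependency matrix `d_ij = a_ij / row_total_i`.
* **Robustness** — secondary-extinction curves as hollows are removed
  (randomly, least-connected-first, most-connected-first, or
  least-abundant-first); R is the area under the survivor curve, 1 =
  tolerant, 0 = immediate collapse.
* **Synthetic matrices** — seeded generators for nested, modular
  (planted-partition) and random incidence structure with a lognormal
  abundance overlay, including presets sized like three Mediterranean
  woodland communities (137×30 / 2343 individuals, 114×27 / 1219,
  85×30 / 825).

## Worked example

```python
import hollownet as hn

m = hn.site_preset("SO", seed=11)          # sclerophyllous-oak-sized preset
print("matrix:", m.n_rows, "species x", m.n_cols, "hollows,",
      m.links, "links,", m.individuals, "individuals")

report = hn.analyze(m, hn.AnalysisConfig(site_name="SO", nulls=1000, seed=11))
for key, val in report["table2"].items():
    print(f"{key:10s} {val:10.4f}")
sig = report["significance"]
print("NODF p =", sig["NODF"]["p"], " WNODF p =", sig["WNODF"]["p"], " M p =", sig["M"]["p"])
```

prints (about 25 s on one CPU):

```
matrix: 85 species x 30 hollows, 280 links, 825 individuals
N (NODF)      51.9337
WNODF         24.0846
M (SA)         0.3411
L/S            2.4348
C              0.1098
LD            16.6066
V-ratio       14.9043
R RE           0.7262
R DE1          0.9622
R DE2          0.3108
NODF p = 0.000999  WNODF p = 0.829171  M p = 0.984016
```

Reading the numbers: the synthetic community is significantly nested
(NODF far above all 1000 CE draws, p = 1/1001) but not significantly
modular (most CE matrices optimize to a higher M), the same qualitative
pattern reported for real tree-hollow networks.  The robustness rows show
the characteristic ordering: removing the most connected hollows first
(R DE2 ≈ 0.31) collapses the community quickly, random loss is
intermediate (R RE ≈ 0.73), and losing the least connected hollows first
is almost harmless until the end (R DE1 ≈ 0.96).

The same pipeline runs from the shell:

```sh
hollownet synth --preset SO --seed 11 --out so.csv
hollownet analyze so.csv --nulls 1000 --seed 11 --out report.json
hollownet robustness so.csv --runs 100 --seed 11
hollownet coreper so.csv --runs 25 --seed 11 --out nodes.csv
```

See `docs/methods.md` for the statistical conventions (tie handling in
NODF/WNODF, the add-one p-value rule, the annealing schedule, what the
synthetic presets do and do not emulate).

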