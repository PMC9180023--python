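# equipanel

Equity analysis of healthcare-resource allocation across the regions of a
tiered facility system. The motivating setting is China's rural three-tier
network — county-level medical and health institutions (CMHIs), township
hospitals (THs) and village clinics (VCs) — where institutions, beds and
personnel are tracked per province per year, but the machinery applies to
any balanced region × year resource panel with a zone partition.

The package is for health-services researchers and statisticians who need
the standard equity toolkit over such panels, reproducibly and with tested
numerics:

- **Gini coefficient** on grouped data, under a *population* or *geography*
  calibre: regions sorted by resource density eᵢ/mᵢ, trapezoid rule on the
  Lorenz curve, G = 1 − Σᵢ (Xᵢ−Xᵢ₋₁)(Yᵢ+Yᵢ₋₁), with the conventional
  fairness bands (G < 0.3 optimal … G ≥ 0.6 danger).
- **Health resource density index**, HRDI = HR/√(A·P), the geometric-mean
  density that avoids the biases of purely per-capita or per-area measures;
  aggregated by summing totals before applying the formula.
- **Theil index** T = Σᵢ (mᵢ/M) ln((mᵢ/M)/(eᵢ/E)) with its exact
  decomposition T_total = T_inter + T_intra into between-zone and
  within-zone parts and the contribution rates T_intra/T_total,
  T_inter/T_total.
- **Mann–Kendall trend test** with tie-corrected variance, continuity
  correction, two-sided p and the *** / ** / * ladder at α = 0.01/0.05/0.1,
  plus the exact small-n permutation null as an oracle.
- A **synthetic panel generator** (lognormal sizes and densities, zone
  offsets, controllable dispersion growth and level drift) so the full
  pipeline is testable end-to-end without any external data, and a **CLI**
  (`equipanel simulate | run | mk`) that writes every result table as CSV
  with a JSON manifest.

## Worked example

```python
import equipanel as ep

panel = ep.generate_panel(ep.GeneratorConfig(seed=1))   # 31 regions x 2003-2020

# Gini of county-institution beds in 2020, both calibres
a = panel.slice_allocation(2020, ep.Tier.CMHI, ep.ResourceKind.BED,
                           ep.Calibre.POPULATION)
print(ep.gini(a).G, ep.gini(a).band)

g = panel.slice_allocation(2020, ep.Tier.CMHI, ep.ResourceKind.BED,
                           ep.Calibre.GEOGRAPHY)
print(ep.gini(g).G, ep.gini(g).band)

# Theil decomposition of the same cross-section
d = ep.theil_decompose(a)
print(d.T_total, d.T_inter, d.T_intra, 100 * d.contrib_intra)

# inject inequality growth, then test the Gini series for trend
trended = ep.inject_trend(panel, "gini", +1, seed=1)
series = [r.G for r in ep.gini_series(trended, ep.Tier.CMHI,
                                      ep.ResourceKind.BED,
                                      ep.Calibre.POPULATION)]
print(ep.mk_test(series).cell)
```

prints (rounded)

```
0.188 optimal
0.671 danger
0.0641 0.0281 0.036 56.15
2.197 ** (+)
```

Read: by population the 2020 bed allocation is comfortably equitable
(G = 0.188, "optimal" band), but against land area it is deeply unequal
(G = 0.671, "danger") — the generator's dense-east/sparse-west gradient
reproduces the familiar gap between the two calibres. Of the total Theil
inequity 0.064, 56 % sits *within* zones (0.036) and 44 % between them.
After injecting dispersion growth, the Mann–Kendall test flags the Gini
series as significantly increasing (Z = 2.197, p < 0.05, "(+)").

The same analysis end-to-end from a shell:

```bash
equipanel simulate --seed 1 --out panel.csv
equipanel run --panel panel.csv --out results/
equipanel mk --series results/gini_series.csv --column gini
```

`results/` then contains `status_quo.csv` (growth rates), `gini_series.csv`,
`hrdi_series.csv`, `hrdi_cross_section.csv`, `theil_series.csv`,
`contribution_table.csv`, three Mann–Kendall tables and `manifest.json`
with file hashes; re-running on the same panel reproduces identical bytes.

A packaged reference table of within-zone contribution rates for the
three-tier system (2003–2020) ships in `equipanel.datasets` as a worked
validation fixture for the contribution-table formatter.

## Documentation

`docs/methods.md` documents the formulas, conventions (sorting, banding,
log base, continuity correction), the generator's assumptions and
limitations, and every numerically consequential design choice.
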