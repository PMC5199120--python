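# carousel

Steady-state analysis of the *carousel* model of GPCR / G-protein / RGS
coupling — the mechanism by which the yeast pheromone pathway responds to
the **fraction** of occupied receptors rather than their absolute number.

Classical receptor theory predicts that the effect of an agonist scales
with the amount of agonist–receptor complex, E/Em = f(ε·[R₀]·[L]/(K_d+[L])),
so changing receptor abundance R₀ should shift the dose-response. The yeast
pheromone system instead shows **robustness to receptor abundance** and
**dose-response alignment (DoRA)**: free-Gβγ output tracks fractional
occupancy, with the output EC₅₀ pinned near the ligand K_d. The carousel
model explains this by composing the ternary-complex model (L + R ⇌ LR,
R + G ⇌ RG, …) with a three-state G-protein cycle

```
Gαβγ(GDP)  --kE-->  Gα(GTP) + Gβγ  --kH-->  Gα(GDP)  --kA·[Gβγ]-->  Gαβγ(GDP)
```

in which both exchange (GEF) and hydrolysis (GAP, via the receptor-bound
RGS) are catalyzed *on the receptor*: ligand-occupied receptor–RGS
complexes activate the Gα they carry (kE_LRG ≫ kH_LRGt is irrelevant — the
exchange wins), while unoccupied complexes deactivate it (kH_RGt ≫ kE_RG).
A Gα that hops from receptor to receptor therefore ends up reflecting the
occupancy state of the last receptor it met, and the free-Gβγ level reads
out the occupied fraction — a ratiometric, push-pull measurement.

The package provides:

* the reaction network (12 species, 19 mass-action reactions; an extended
  variant with explicit RGS–receptor binding; a two-receptor-pool variant
  for dominant-negative non-binder alleles), with exact conservation laws;
* a steady-state solver robust across 8-decade parameter ranges (Newton on
  the conservation-augmented system, pseudo-transient fallback, LSODA
  oracle path);
* dose-response simulation with amplitude, interpolated EC₅₀ and DoRA;
* Latin-hypercube sampling of the 12 kinetic parameters (log-uniform,
  8 decades around the reference values);
* robustness classification (robust amplitude / robust EC₅₀ / robust
  response / DoRA) against 10-fold receptor-abundance changes, 2D-histogram
  matrices, and pairwise parameter-restriction mining;
* a `carousel` CLI (`dor`, `classify`, `scan`, `restrictions`, `baseline`).

Intended users: quantitative biologists modeling GPCR signaling who want a
reproducible, scriptable implementation of fraction-measurement analysis.

## Worked example

Reference parameters (yeast pheromone response: K_d(L·R) = 5.6 nM,
koff(R·G) = 0.1 s⁻¹, localized GAP kH_RGt = 0.11 s⁻¹ ≫ kH_Gt = 0.002 s⁻¹;
R_tot = 1400 nM, G_tot = 860 nM):

```bash
$ carousel dor --rtot-mult 0.1,1,10
R_tot x0.1: amplitude=0.8029 EC50=3.42 nM (occupancy 5.619 nM) basal=0.0510
R_tot x1: amplitude=0.9241 EC50=3.119 nM (occupancy 5.619 nM) basal=0.0075
R_tot x10: amplitude=0.9244 EC50=3.116 nM (occupancy 5.619 nM) basal=0.0072
```

A 100-fold receptor-abundance range leaves the curve nearly unchanged: the
amplitude moves by ≤ 13% and the EC₅₀ stays within 10%, pinned a factor
~1.8 below the occupancy EC₅₀ (= the ligand K_d, 5.6 nM, by construction).
Classifying the same point:

```bash
$ carousel classify
{ "normal_amplitude": true, "robust_amplitude": true, "robust_ec50": true,
  "robust_response": true, "dora": true, "any_failure": false,
  "dora_ratio": 0.556 }
```

Setting `koff_RG = 0.001` (precoupled/ternary regime) or raising the
uncoupled hydrolysis rate to the receptor-coupled one (`kH_Gt = 0.11`,
delocalized RGS) breaks robustness to receptor *decrease* — the behaviors
the model predicts for RGS mutants. In Python:

```python
from carousel import KineticParameters, Abundances, build_network, simulate_dor, summarize

net = build_network("simplified", KineticParameters(koff_RG=10.0))
print(summarize(simulate_dor(net, Abundances())).dora_ratio)  # 0.079: sensitized
```

A global scan with restriction mining:

```bash
carousel scan --n 2000 --seed 1 --out scan_out/
```

writes `draws.csv`, `labels.csv`, `fractions.json`, `restrictions.json` and
per-pair histogram tables, all with embedded seed and config hash.

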