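# rootarch

Deep phenotyping of 3D-digitized coarse root system architecture.

Tree seedlings anchor themselves and forage with a structural root
system whose form — a gravitropic taproot, shallow laterals tracking the
soil surface, branching between herringbone and dichotomous extremes —
responds plastically to slope and to mechanical perturbation of the
shoot.  Quantifying that plasticity requires more than a handful of
summary numbers: it takes the *full* architectural battery measured on
each digitized root system.  `rootarch` is that battery as a reusable
Python library, for root ecologists and biomechanics groups working with
3D-digitized (or CT-extracted) coarse root systems of container-grown
plants.

It provides:

* **I/O** — a documented MTG-dialect text format for digitized segments
  (topology codes, XYZ, basal diameter, fine-root counts; see
  `docs/mtg_dialect.md`) and a portable CSV segment table, both with
  lossless round trips and structural validation.
* **Geometry** — axis lengths (with the mother-radius correction), the
  cylinder-equivalent mean diameter `2*sqrt(V/(pi*L))`, proximal tapers,
  10 mm virtual segmentation with exact frustum volumes, container-wall
  artefact correction, taproot angle, azimuths, root directional
  deviation (RDD) and winding.
* **Classification** — the eight architectural compartments (stump,
  taproot, ZRT, shallow-beyond-ZRT, sinkers, deep, intermediate,
  oblique, with the standard pooling to six), and slope-oriented
  circular sectors (us = 0 +/- 45 deg, ds = 180 +/- 45 deg, pp the rest)
  with sector shares and reinforcement = (share - 25%)/25%.
* **Topology & fractal branching** — the topological index
  `qb = (Pe - Pe_min)/(Pe_max - Pe_min)` on collar-to-tip path lengths
  (0 = dichotomous, 1 = herringbone), mean branching order, and the
  branch-event parameters `p_branch` (CSA before / CSA after, > 1 under
  tapering), `q` (largest daughter's CSA share, 0.5 for an equal
  dichotomy) and `p_within` (% CSA per cm between branches), including
  the 2 cm continuing-CSA interpolation rule.
* **Synthetic seedlings** — a seeded generator of container-grown root
  systems with tunable herringbone weight, azimuth anisotropy
  (von Mises), taper targets and wall deflection, retaining hidden
  ground truth for parameter-recovery testing.
* **Statistics** — per-trait three-way ANOVA (Slope, Flexing, Block,
  interaction) with a Shapiro-driven none -> log -> rank transformation
  ladder; the per-compartment sector mixed model (sector fixed, tree
  random, perpendicular sector halved for additive quantities) with
  compact letter displays; and PCA of a 17-trait selection.

## Worked example

```python
from rootarch import synthetic as syn, compartments as comp, topology as topo
from rootarch.stats import plant_traits

rs = syn.generate(syn.GeneratorConfig(seed=1))       # one seedling
traits = plant_traits(rs)
print(round(traits["total_volume_cm3"], 2))           # 7.48
print(round(traits["root_density_g_cm3"], 3))         # 0.5
print(round(traits["qb_total_iafr"], 3))              # 0.204
print(round(traits["taproot_angle_deg"], 1))          # -88.2

labeled = comp.classify_system(rs)
print({k: round(v, 1) for k, v in comp.sector_shares(labeled).items()})
# {'us': 5.1, 'pp': 70.3, 'ds': 24.7}
```

`total_volume_cm3` is the root volume with the stump (first 45 mm of the
first-order root) excluded; `root_density_g_cm3` recovers the
generator's configured tissue density exactly; `qb_total_iafr` says this
system branches far on the dichotomous side of the herringbone scale;
the taproot descends at 88 deg to the soil surface; and the sector
shares are the upslope / perpendicular / downslope split of lateral root
volume (25/50/25 would be perfectly even).

The numbered scripts under `analysis/` run the whole study-shaped
analysis on a simulated cohort (4 treatment groups x 8 plants):

```bash
python analysis/01_simulate_cohort.py --seed 1   # 32 MTG files
python analysis/02_extract_traits.py             # 74 traits per plant
python analysis/03_treatment_anova.py            # Slope/Flexing effects
python analysis/04_sector_models.py              # circular heterogeneity
python analysis/05_pca.py                        # PC1 48.8 %, PC2 16.4 %
```

All tables land in `results/`.  The same pipeline runs on real digitized
MTG files via the `rootarch` CLI (`rootarch run --config cfg.json`) or
`rootarch.pipeline.run_pipeline`.

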