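# nucleoprofile

Quantification and classification of nuclear marker foci in two-channel
fluorescence images of isolated plant root-meristem nuclei, plus a
DNA-content cell-cycle fitter and a synthetic image generator that provides
ground truth for every analysis stage.

The package is aimed at plant cell-cycle and chromatin researchers who
image isolated interphase nuclei with a DNA stain (DAPI) in one channel and
an immunofluorescence marker — here modelled on phosphorylated
retinoblastoma-like protein (pRb, RbS807/811ph) — in the other, and who
want the manual ImageJ-style measurements (areas, thresholded
heterochromatin, focus counts, labeling index, activity-profile types)
as a reproducible, scriptable pipeline.

## What it computes

Per nucleus, from the chromatin channel:

* nucleus area `A_nuc` and nucleolus area (pixel counts),
* heterochromatin (HC) mask by an inter-class-variance (Otsu) split of the
  intra-nucleus intensity histogram, and
  `HC% = 100 · A_HC / A_nuc`.

From the marker channel:

* foci as 8-connected components above
  `median + max(k · 1.4826 · MAD, Δ_min)` (defaults `k = 3`, `Δ_min = 40`),
* per-nucleus count, total/mean focus area, nucleus coverage %, focus
  intensities, and the population labeling index
  `LI = 100 · (#nuclei with ≥1 focus) / N`,
* a rule-based assignment of one of five activity profiles:
  * **Type 1** — foci only inside the nucleolus,
  * **Type 2** — foci outside a dark (unlabeled) nucleolus,
  * **Type 2a** — Type 2 plus a perinucleolar ring of brighter foci,
  * **Type 2b** — foci across the whole nucleus including the nucleolus,
  * **Type 3** — focus area dominated by large merged clusters.

From a gated univariate DNA-content sample (one fluorescence value per
cell), phase fractions by an EM fit of a Dean–Jett–Fox-style mixture:
Gaussian G1 peak `N(μ, (cv·μ)²)`, Gaussian G2/M peak `N(rμ, (cv·rμ)²)`
with `r ≈ 2`, and an S compartment modelled as ten equal-weight Gaussians
tiling `(μ, rμ)`.  Mixture weights are the G1/S/G2M fractions (M cannot be
separated from G2 by DNA content alone).

Across treatment conditions (control, hydroxyurea replication arrest "HU",
HU + caffeine checkpoint override "PCC"), the reporting layer computes
mean ± SD summaries, Pearson `r`/`r²` correlations, and one-way ANOVA with
Tukey HSD post-hoc tests at α = 0.05.

Because real specimens of this kind deposit no public images, the
`synthetic` module generates two-channel nuclei with planted geometry,
heterochromatin fraction, focus positions/sizes/intensities and profile
type — so every stage is validated by parameter recovery against known
ground truth.

## Worked example

Simulate 40 nuclei per condition, analyze them end-to-end and fit the
cell-cycle model:

```python
import nucleoprofile as npf
from nucleoprofile.config import PipelineConfig, SimulationParams, CellCycleParams

config = PipelineConfig(
    simulate=SimulationParams(conditions={"CONTROL": 40, "HU": 40, "PCC": 40}),
    cellcycle=CellCycleParams(),
)
npf.run_pipeline(config, "demo_run", seed=11)
```

`demo_run/condition_summary.csv` then contains (abridged):

```
condition  n_nuclei  labeling_index_percent  foci_count_mean  coverage_percent_mean  hc_percent_mean  nucleus_area_px_mean
  CONTROL        40                   90.00            22.15                   3.21            19.57              17355.50
       HU        40                   35.00             3.70                   0.27            11.53              21772.50
      PCC        40                   60.00            10.28                   1.14            18.57              18061.50
```

Reading across a row: 90% of control nuclei carry detectable foci, an
average nucleus has ~22 foci covering 3.2% of its area, and ~19.6% of the
nucleus is heterochromatin.  Replication arrest (HU) collapses the
labeling index to 35%, thins and dims the foci (coverage 0.27%), shrinks
heterochromatin occupancy and swells the nucleus; checkpoint override
(PCC) sits between the two.  The profile-type table
(`type_distribution.csv`) shows the ring profile Type 2a rising from 8.3%
of labeled control nuclei to 20.8% after PCC while the cluster profile
Type 3 drops from 19.4% to 0%, and `cellcycle.json` reports the fitted
phase percentages:

```
CONTROL  G1 66.02%  S 25.59%  G2M 8.40%
HU       G1 56.70%  S 40.19%  G2M 3.11%
PCC      G1 49.42%  S 38.32%  G2M 12.26%
```

recovering the simulated S-phase accumulation under HU (planted S
fractions 26.17% / 41.06% / 38.51%).

A command-line interface wraps the same pipeline:

```sh
nucleoprofile simulate --out nuclei/ --seed 1 --n 30
nucleoprofile analyze --images nuclei/CONTROL --out results/ --seed 1
nucleoprofile cellcycle --events events.csv --out results/
nucleoprofile report --results results/
```

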