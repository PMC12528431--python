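# seasonccm

Seasonal trophic-control inference from survey time series: who is eating
whom, and in which season?

Long-running plankton and trawl surveys produce annual, season-resolved
abundance series for a prey taxon (here, by convention, a *Calanus*-type
copepod, `calfin`) and its candidate predators. `seasonccm` turns
station-level records into analysis-ready seasonal series and asks two
directional questions per predator:

* **bottom-up** — does spring prey abundance drive the predator's
  spring–summer abundance?
* **top-down** — does the predator's spring–summer abundance drive down
  the prey's fall (overwintering) abundance?

Three complementary tools answer them:

1. **Spearman rank correlations** (sign and strength per directed season
   pairing);
2. **Convergent cross mapping (CCM)** — the driver X is estimated from the
   time-delay embedding of the putative effect Y (E + 1 nearest neighbors,
   exponential weights); skill ρ(L) rising with library size L is the
   signature of dynamic coupling. Significance comes from a **seasonal
   surrogate null**: surrogates preserve the series' mean cycle over a
   fixed period (default 12 years) and permute the residuals (500
   surrogates; add-one p-value; `**` for p ≤ 0.05, `*` for p ≤ 0.10);
3. **Boosted regression trees (BRTs)** — cross-validated gradient-boosted
   ensembles rank predators by relative influence (%) on the prey's spring
   and fall series, with partial dependence curves for effect shape.

Because real survey archives are external, the package ships a first-class
synthetic generator — a seasonally forced Ricker predator–prey model with
a survey observation layer (sparse months, lognormal tow noise, missing
years) — with known coupling labels, so the whole chain is validated
against planted truth. See `docs/methods.md` for models, defaults and
limitations.

## Worked example

Simulate a 60-year, five-predator community in which only euphausiids are
trophically coupled to the prey, observe it with survey noise, and run the
full study:

```python
import pandas as pd
from seasonccm import (SimulationConfig, simulate_community, observe_survey,
                       run_full_study, StudyConfig, SurrogateConfig, BRTConfig)

cfg = SimulationConfig(model="seasonal_pp", n_years=60, seed=11,
                       obs_noise_sd=0.2, missing_year_prob=0.15, region="A")
latent, truth = simulate_community(cfg, coupled_predator="euphausiids")
records = observe_survey(latent, cfg)          # year,month,region,taxon,abundance_m3

study = StudyConfig(surrogate=SurrogateConfig(n_surrogates=500),
                    brt=BRTConfig(learning_rates=(0.01, 0.05),
                                  tree_complexities=(1, 2),
                                  max_trees=500, k_folds=5),
                    n_subsamples=30, seed=3)
report = run_full_study(records, ["A"], "calfin",
                        sorted(set(latent) - {"calfin"}), study)
print(report.table[["driver", "effect", "mode", "rho", "ccm_skill",
                    "ccm_p", "asterisks"]].to_string(index=False))
```

Output (abridged):

```
       driver        effect           mode       rho  ccm_skill    ccm_p asterisks
       calfin        calfin spring_to_fall -0.643234   0.588974 0.001996        **
       calfin   euphausiids      bottom_up  0.511698   0.499865 0.001996        **
  euphausiids        calfin       top_down -0.718588   0.670506 0.001996        **
 chaetognaths        calfin       top_down  0.077499  -0.299923 0.960080
 paraeuchaeta        calfin       top_down -0.128758  -0.256801 0.850299
siphonophores        calfin       top_down -0.207280  -0.121066 0.660679
      herring        calfin       top_down  0.095471  -0.098128 0.658683
```

Reading it: the planted mechanism is recovered — spring prey anticorrelates
with fall prey (ρ = −0.64, with significant CCM self-coupling), the coupled
predator shows the expected positive bottom-up (ρ = +0.51, `**`) and
negative top-down (ρ = −0.72, cross-map skill 0.67, `**`) signals, and all
four decoy predators are silent. The fall-response BRT puts the largest
selection-frequency influence on euphausiids:

```python
report.brt[("A", "top_down")].influence_selection
# {'euphausiids': 42.9, 'chaetognaths': 32.1, 'herring': 25.0, ...}
```

(With only ~40 common years the two influence measures can disagree on a
single realization; the repeated-seed validation in the test suite scores
the ranking across 30 independent communities.)

The same workflow is scriptable from the shell:

```sh
seasonccm simulate --config sim.yaml --out records.csv
seasonccm prep --records records.csv --taxon calfin --region A --season spring --out spring.csv
seasonccm ccm --driver spring.csv --effect fall.csv --surrogates 500 --seed 1 --out ccm.json
seasonccm run --records records.csv --config study.yaml --out report/
```

`report/` then holds `fig4_table.csv` (the hypothesis-by-hypothesis
correlation/CCM table), `fig3_influence.csv` (BRT influences),
`partial_dependence.csv` and `ccm_curves.json` (skill-vs-library curves).

Real survey extracts are accepted as the same CSV dialect
(`year,month,region,taxon,abundance_m3`); the package does not download
archives.

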