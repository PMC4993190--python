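# seedgerm

Estimation of seed-germination response to temperature and water potential,
and classification of species into functional germination groups.

Choosing which cover crop to sow in late summer hinges on whether its seeds
can germinate in a hot, dry seedbed. `seedgerm` implements the laboratory
analysis pipeline behind that decision for agronomists and seed
ecophysiologists: from raw cumulative germination counts it derives, per
species, the cardinal temperatures (T<sub>0</sub>, T<sub>opt</sub>,
T<sub>max</sub>), the base temperature T<sub>b</sub> used for thermal-time
accumulation, and the base water potential Ψ<sub>b</sub>, then groups
species with similar germination envelopes by Ward clustering. A synthetic
seed-lot generator with known ground truth makes every stage testable.

## The models

**Time courses.** Cumulative germination of a lot (percent of sown seeds)
follows the Gompertz sigmoid

    G(t) = Gmax · exp[ −(b/c) · exp(−c·t) ]

fitted by bounded nonlinear least squares. Inverting the fitted curve gives
the time t(G) to reach a population percentile G ∈ {20, 30, 40, 50} % of
*sown* seeds, and the germination rate 1/t(G). Percentiles a
low-germinability lot never reaches (e.g. the 40th/50th when Gmax < 50 %)
are skipped, not zero-filled.

**Thermal response.** Across temperatures the rate of each percentile
follows a beta-shaped function

    1/t(G) = exp(μ) · (T − T0)^α · (Tmax − T)^β,   T0 < T < Tmax

whose fitted T0 and Tmax are the thermal limits and whose analytic argmax

    Topt = (α·Tmax + β·T0) / (α + β)

is the optimum. One fit per percentile; cardinal temperatures are reported
as mean ± SD across percentiles. T<sub>b</sub> is the x-intercept of an OLS
line through the *linear* sub-optimal phase of rate vs temperature
(window selected automatically by R², shared across percentiles).

**Water response.** At 20 °C the rate declines linearly with water
potential; Ψ<sub>b</sub> is the x-intercept of rate vs Ψ (20th/30th
percentiles). PEG-8000 concentration ↔ water potential conversion uses the
printed calibration anchors (−0.1 MPa ↔ 73.7 g/L, −0.5 ↔ 195, −0.75 ↔ 250,
−1.5 ↔ 376).

**Functional groups.** Species are clustered on (T0, Topt, Tmax, Ψb) with
the Ward criterion in squared-Euclidean geometry (merge heights are
within-cluster variance increases), cut at k = 5 by default.

## Worked example

```python
from seedgerm import SpeciesGerminationModel, SimulationConfig, TrueSpecies, simulate_experiment

sp = TrueSpecies(species_id="Brassica-like", family="Brassicaceae",
                 t0=0.5, tmax=39.0, alpha=2.0, beta=0.8, mu=-11.0,
                 psi_b=-1.4, g_max_plateau=95.0)
cfg = SimulationConfig(species=[sp], rng_seed=7)   # 25 seeds x 4 reps, 9 temps + 4 psi
courses, truth = simulate_experiment(cfg)
res = SpeciesGerminationModel.from_time_courses(courses).fit()
print(res.summary())
```

prints

```
Germination profile: Brassica-like (Brassicaceae)
  final germination (best)       99.0 %
  T0   (degC)                     0.0  +/- 0.0
  Topt (degC)                    27.8  +/- 0.0
  Tmax (degC)                    39.0  +/- 0.0
  Tb   (degC)                     4.8
  Psi_b (MPa)                   -1.46
  mean thermal-fit R^2          0.999
  linear window (degC)       11.5, 15, 20
```

The species was generated with true Topt = 28.0 °C and Ψb = −1.4 MPa; the
pipeline recovers them from the noisy 25-seed counts to 0.2 °C and
0.06 MPa. T0 is reported as 0.0 ± 0.0 because the beta-function fit pins it
at its physiological lower bound of 0 °C for every percentile — exactly the
behaviour seen for many real chilling-tolerant species. Tb (4.8 °C) differs
from T0 by construction: it extrapolates the linear mid-range rates, not
the curved toe of the response.

The same pipeline runs from the shell:

```bash
seedgerm simulate --n-species 5 --seed 1 --out data.csv
seedgerm profile data.csv --out profiles.csv
seedgerm classify profiles.csv --k 5 --out groups.csv --newick-out tree.nwk
seedgerm summarize profiles.csv --by family --out families.csv
```

A packaged reference table (`seedgerm.load_table1_fixture()`) carries seed
mass, cardinal temperatures and base temperature for 36 cover-crop taxa
from 6 botanical families, for summary statistics and as clustering input.

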