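# Methods

## Scope and data model

The package estimates per-species germination traits from replicated
cumulative-count time courses observed under controlled conditions, and
groups species by those traits. The canonical input is a tidy CSV with one
row per observation time per replicate (cumulative counts, not increments,
because cumulative dynamics are what laboratories report and plot); columns
are `species_id, family, replicate_id, temperature_C, water_potential_MPa,
time_h, cum_germinated, n_seeds`. Files are UTF-8 with decimal points; a
missing water-potential column means pure water (0 MPa). All percentages
are percent of *sown* seeds.

## Time-course fitting

Replicates sharing a condition and an observation grid are averaged into
one curve: percentages are step-interpolated (last observation carried
forward, zero before the first observation, since lots are sown
ungerminated) onto the union time grid and averaged. Same-condition runs
observed on *different* grids — e.g. a 2-hour imaging run and an 8-hour
incubator run of the control — are deliberately kept as separate runs:
pooling them through carried-forward steps lags the mean curve of the
denser run and biases downstream rates by several percent.

The Gompertz curve G(t) = Gmax·exp[−(b/c)·exp(−c·t)] is fitted to each
curve by bounded least squares (Gmax ∈ (0, 100], b, c > 0) minimising the
residual sum of squares, with a deterministic five-point multi-start: Gmax
starts at the observed maximum, the time-scale parameter c at 2/(t_last −
t_first) scaled by {1, 0.3, 3, 0.1, 10}, and b tied to c through the
observed half-maximum time via the median relation (b/c)·e^(−c·t_half) =
ln 2. Observations before first germination are retained (the zeros inform
b and c). Lots with no germination raise an error; curves with fewer than
two distinct positive levels (a single observed jump) are returned flagged
`converged=False` rather than dropped, because b and c are then not
identifiable.

Times to percentile use the closed form t(G) = −(1/c)·ln[−(c/b)·ln(G/Gmax)]
and invert the curve to 1e−9. Rates are 1/t(G) for G ∈ {20, 30, 40, 50} %
of sown seeds. A percentile is skipped (never zero-filled) when it is at or
above the fitted Gmax **or** above the maximum the observed curve actually
reached — the second guard prevents rates being extrapolated from the toe
of an experiment truncated by its horizon. Percentiles are on the
sown-seed scale, not relative to Gmax: that is the only scale on which
skipping the 40th/50th percentiles of a 37 %-germination lot is coherent.

## Thermal response and cardinal temperatures

For each percentile with rates at ≥ 5 temperatures, the beta-function model
1/t(G) = exp(μ)·(T − T0)^α·(Tmax − T)^β is fitted by bounded least squares.
Only temperatures with an observed rate enter the residuals; the tested
grid bounds the cardinal parameters (T0 ∈ [0, lowest T with a rate], Tmax ∈
[highest T with a rate, 50 °C], α, β ∈ [0.05, 12]). Multi-starts cover
combinations of T0/Tmax/shape starts with μ solved from the observed peak
rate. T0's lower bound of 0 °C reflects that many chilling-tolerant species
pin the fit at exactly 0.0 ± 0.0; a `t0_lower=-5` flag relaxes it. Fits
whose shape parameters end on a bound, or fitted to rate sets with no
variance, are flagged non-converged.

The optimum is the analytic argmax of the fitted response,
Topt = (α·Tmax + β·T0)/(α + β), which always lies strictly inside
(T0, Tmax); it is verified against a dense-grid argmax in the tests.
Cardinal temperatures are reported as mean ± sample SD (ddof = 1; 0 for a
single percentile) across the per-percentile fits, per species.

The base temperature extrapolates the linear sub-optimal phase instead:
among contiguous windows of ≥ 3 tested temperatures with positive rates
strictly below Topt, the window maximising OLS R² is selected (ties broken
by longer window, then lower starting temperature); the window is chosen
once per species on the 50th-percentile rates (or the highest percentile
available) and shared across percentiles. Tb is the mean of the
per-percentile x-intercepts (−intercept/slope), with SD across percentiles;
percentiles with non-positive slopes are excluded with a note. Tb is *not*
clamped at zero — negative base temperatures are physically meaningful for
extrapolated thermal time — which is deliberately asymmetric with the
beta-fit T0 bound.

## Water response

At the osmotic-test temperature (20 °C) rates decline linearly with water
potential; Ψb is the x-intercept of OLS lines of rate on Ψ for the 20th and
30th percentiles (higher percentiles are usually unreachable under osmotic
stress), averaged. The 0 MPa control is an ordinary regression point. Two
potentials suffice for a (then exact) line — species with shallow Ψb
physically cannot yield more than two informative potentials on the
standard grid — but fewer exclude the percentile. Slopes must be positive
(rate increasing toward pure water); if no percentile qualifies the
estimation fails with an explicit error.

The PEG-8000 calibration interpolates the printed anchor pairs
{(0, 0), (−0.1, 73.7), (−0.5, 195), (−0.75, 250), (−1.5, 376)} (MPa, g/L)
piecewise-linearly, exactly at anchors and with an exact inverse; it is
valid at 20 °C only, and no extrapolation outside [−1.5, 0] MPa is
permitted. The full temperature-dependent PEG equation is intentionally
not implemented.

## Functional grouping

Ward agglomerative clustering on the feature vector (T0, Topt, Tmax, Ψb):
at each step the pair of clusters minimising the increase in total
within-cluster variance, Δ(A,B) = |A||B|/(|A|+|B|)·‖c_A − c_B‖², is merged,
and Δ is recorded as the merge height. T0 represents the cold limit rather
than Tb because it is estimated more precisely. Features are raw °C/MPa by
default — group summary tables are on raw scales — though mixing units
unscaled is statistically questionable, so a z-score flag exists. Ties are
broken by the lowest pair of cluster ids, making the linkage deterministic.
k defaults to 5. The implementation is authored here because the required
height semantics (variance increase on squared-Euclidean geometry) and
deterministic tie-break are part of the contract; scipy's Ward linkage
(heights h with h²/2 = Δ) serves as an independent cross-check in the
tests, alongside an exhaustive greedy oracle for n ≤ 7. Summary tables
report mean ± sample SD per group and per family (singletons report SD 0
with a flag), and trait correlations are Pearson r, r², and the two-sided
p-value, with a multiple-R² helper for one-trait-on-three regressions.

## Synthetic experiments

The generator emulates the laboratory design so that every stage can be
tested against known truth:

- **Design.** 4 replicates of 25 seeds per condition; temperature grid
  {4.5, 11.5, 15, 20, 26.7, 31, 36, 39.5, 43} °C in pure water; water
  potentials {0, −0.1, −0.5, −0.75} MPa at 20 °C, extended by −0.9 and
  −1.5 MPa for species whose germination remains substantial at −0.75
  (hydro factor > 0.25) when the adaptive option is on, as an
  osmotic-stress protocol would. Imaging-table temperatures (11.5–36 °C)
  are observed every 2 h; extreme temperatures and all osmotic runs every
  8 h (incubators with manual counts). Observation horizon 1000 h.
- **Species truth.** Each virtual species carries beta-function thermal
  parameters, a base water potential acting as the linear rate factor
  max(0, 1 − Ψ/Ψb), a final-germination profile over temperature (plateau
  collapsing linearly between 0.9·Tmax and Tmax; optionally also ramping
  from half plateau at T0 to full plateau by T0 + 5 °C, emulating the two
  qualitative final-germination shapes seen in real lots), and a
  germination-time dispersion parameter `spread`.
- **Sampling.** A seed germinates with probability g_max(T)/100; its
  germination time is drawn by inverting the normalised Gompertz CDF
  F(τ) = exp(−ln2·e^(spread·(1−τ))) scaled so the median equals
  1/rate(T, Ψ). The expected cumulative curve is therefore exactly
  Gompertz — the estimation model is well-specified — and `spread` (default
  5, i.e. lots rise from onset to plateau over roughly one median-time
  unit, matching the look of real imaging curves) controls synchrony. The
  paper-scale data give no way to calibrate within-lot dispersion, so the
  default is an order-of-magnitude choice. Noiseless mode replaces the
  binomial lot by its expectation with a 10⁶-seed virtual lot.
- **Reproducibility.** One root seed; each time course uses an independent
  stream derived by CRC-hashing (species, condition, replicate), so any
  subset of an experiment reproduces bit-identically.
- **Trait ranges for recovery studies.** Virtual species are drawn with
  T0 ~ U[0, 11] °C, Tmax ~ U[max(29, T0+25), 43] °C (every species in the
  packaged reference table keeps ≥ ~25 °C between its thermal limits),
  α ~ U[1.3, 3], β ~ U[0.4, 1.2] (gradual sub-optimal rise, sharp
  supra-optimal fall), peak rate U[0.02, 0.07] h⁻¹, Ψb ~ U[−2.6, −0.15]
  MPa, plateau U[70, 100] %.

What the generator does **not** emulate: hard-seededness and dormancy,
seed-lot aging, spatial or imaging artifacts, water-potential effects on
final germination percentage (stress slows germination but does not lower
the plateau in the simulator), and non-linear hydrotime structure
(σ(Ψb), hydrotime constants). Passing recovery tests therefore demonstrate
that the estimation machinery is correct and stable under binomial count
noise and the real observation design — not that real seed lots obey the
generating model.

## Recovery scoring

Topt and Ψb are scored directly against the generating parameters. Tb has
no unique ground truth under a beta-shaped rate curve — the linear
extrapolation depends on the window — so Tb is scored against its
estimand: the OLS x-intercept of the *true* rate curve over the same
window the pipeline selected. Under the study design (20 species, 25 seeds
× 4 replicates, binomial noise) the pipeline achieves median absolute
errors well inside 2 °C for Topt and 0.15 MPa for Ψb, and in the noiseless
limit inside 0.5 °C and 0.02 MPa, with mean beta-fit R² above 0.9; the
exact numbers for a given seed are computed by `scripts/acceptance.py` and
asserted in `tests/test_acceptance.py`.

## Numerical choices and degenerate inputs

- Nonlinear fits: `scipy.optimize.least_squares` (trust-region reflective)
  with xtol/ftol/gtol 1e−14 and deterministic multi-starts; best RSS wins.
- OLS lines and Pearson correlations: `scipy.stats.linregress` /
  `pearsonr`.
- Sample SDs use ddof = 1, reported as 0 for singletons.
- Decreasing cumulative counts, non-monotone time grids and counts
  exceeding the sown number are schema-level validation errors naming the
  species/replicate/time; species failing an estimation stage yield NaN
  traits plus a note, never a silent drop or a fatal multi-species run.
- Display rounding is one decimal, kept separate from full-precision
  storage.

## Known limitations

- The linear-phase window search is a heuristic; on noisy rate sets R²
  can favour a short lucky window, which mainly affects Tb.
- Ψb from two potentials is exact but noise-sensitive; the adaptive grid
  extension mitigates this for drought-tolerant species only.
- Species whose thermal niche intersects fewer than five grid temperatures
  cannot support the five-parameter thermal fit and are reported with NaN
  cardinal temperatures (a real Setaria-like lot on a sparse grid shares
  this fate).
- Cluster number k is user-chosen; no internal validation (silhouette,
  bootstrap stability) is provided.
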