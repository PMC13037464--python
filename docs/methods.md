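# Methods

This note records the models, conventions and numerical choices behind
`redoxniche`, in the spirit of a model-description chapter: what is
assumed, which knobs matter, and what the synthetic tests do and do not
demonstrate about field data.

## The system

Permanently stratified (meromictic) lakes can hold an anoxic
hypolimnion in which nitrate persists for tens of metres below the
oxycline before it is consumed, and in some basins sulfide accumulates
beneath that. Anaerobic ciliates of the class Plagiopylea carrying
denitrifying *Ca.* Azoamicus endosymbionts live in the anoxic,
nitrate-replete, sulfide-free layer: oxygen above excludes the
obligately anaerobic host, nitrate is the symbiont's electron acceptor,
and sulfide below is acutely toxic to the consortium. The package
quantifies (i) where that niche window lies in a given set of depth
profiles, (ii) how many host ciliates are present, and (iii) what
fraction of the downward diffusive nitrate flux their denitrification
can remove.

## Landmarks

**Interface (plateau rule).** The oxic–anoxic interface is defined
operationally: the shallowest depth below which every oxygen reading is
within `tolerance` of the profile minimum, with a plateau of at least
two depths required. Membrane sensors cannot resolve trace oxygen, so
the criterion is "the signal has stopped changing", not "oxygen equals
zero". The default tolerance is the sensor resolution scale at the
floor, 0.1 µM. For noisy profiles, `recover_landmarks` widens the
tolerance to `resolution + 4·f·floor` for a relative noise level *f*:
multiplicative noise spreads floor readings over roughly ±2*f*·floor,
and the plateau criterion must cover that min-to-max spread or a single
deep outlier breaks the plateau. If no plateau exists the deepest depth
is returned with a warning, and `classify_redox` then treats the column
as fully oxic (no credible anoxic zone).

Ties and non-contiguous minima are resolved by the trailing-run rule
(the plateau must extend to the bottom of the profile); this is a
choice, flagged in the classification warnings when degenerate.

**Nitrate depletion.** Shallowest depth at which NO₃⁻ is below the
"still detectable" threshold (default 0.1 µM) *and stays below it* for
all deeper measurements; transient dips do not count. The search is
restricted to depths below the interface when one is supplied.

**Sulfide onset.** Shallowest depth with a detected signal at or above
the threshold that persists downward. Readings flagged below detection
(in particular zeros) never trigger an onset, even at threshold 0. Two
thresholds serve two purposes: the *landmark* is first detectable
sulfide (detection limit, 0.1 µM default in the generator's profiles),
while the *euxinic classification* uses 1 µM by default. Because
bottle sampling quantises depth and the detection-limit crossing lags
the true appearance depth, `recover_landmarks` refines the onset by
back-extrapolating the locally linear sulfide rise to zero signal,
clipped to the sampling interval straddling the first detection; on
noise-free synthetic profiles this recovers the generating onset
essentially exactly.

**Niche window.** The contiguous `anoxic_nitrate_replete` run adjoining
the interface. Its bottom is the last grid depth of that run, so it is
quantised to the profile grid and never exceeds the depletion/onset
landmarks. `population_in_window` integrates abundance by the
trapezoidal rule inside the window (interpolating at the edges) over
the trapezoidal integral of the whole profile; it is undefined (`None`)
for an identically zero profile rather than 0.

Below-detection readings are stored as 0 with an explicit flag (the
reader also clips negative solute values this way), and comparisons
consult the flag instead of sentinel values. Interpolation between
depths is linear throughout; no smoothing is applied before landmark
detection — reproducibility beats cosmetics at these data densities.

## Abundance

`counted / section_fraction / filtered_volume`, evaluated in exact
rational arithmetic before the final float conversion so that section
fractions such as 1/16 divide out exactly. The stated section fraction
is taken as exact (no correction for unusable filter edge area).
Abundances are reported per litre; the single conversion constant to
per-m³ (`CELLS_PER_L_TO_PER_M3 = 1000`) is owned by the abundance
module because unit slips are the dominant failure mode of this kind of
budget. Dividing fractions use counted cells (scale-free), undefined
when nothing was counted. No Poisson confidence intervals in this
version.

## Flux budget

Volumetric rate `R_P = N_P · R_SP` with `R_SP = 12 pmol N d⁻¹
ciliate⁻¹` by default; layer flux by the trapezoidal rule,
`J_P = ½(R_P,i + R_P,i+1)·ΔH · 1000 · 10⁻⁶` µmol N m⁻² d⁻¹ (litre→m³,
pmol→µmol). The nitrate supply is Fick's first law with a constant
turbulent diffusivity, `J_NO3 = D·86400 · (C_i − C_i+1)/ΔH · 1000`
µmol N m⁻² d⁻¹ — note the explicit division by the layer thickness: a
flux written as `D·ΔC` without it is not dimensionally a flux, and only
the gradient form is comparable with `J_P`. Fluxes are positive
downward (into the consuming layer); the contribution
`100·J_P/J_NO3` is computed only where `J_NO3 > 0` (undefined, flagged
`no_downward_supply`, otherwise) and values above 100% are reported
verbatim with an `exceeds_100` flag — they indicate nitrate sources the
1-D diffusive model does not represent, and clipping would hide that.
Layers are half-open `[d_i, d_i+1)` and reported at midpoints for
plotting. Depth-varying diffusivity is out of scope; `D` enters as a
single constant (default 27·10⁻⁶ m² s⁻¹, an eddy-diffusivity scale for
a quiescent hypolimnion). Both the per-layer fluxes and the full table
are emitted, so a user can compare the ciliate flux against the supply
at the top of the consumption zone or layer by layer.

## Permutation test

Pearson's r with a two-sided permutation null: y is permuted against
fixed x; the p-value is the proportion of permutations with `|r_perm| ≥
|r_obs| − ε`, ε = 10⁻¹² guarding against bit-level ties among
permutations of identical multisets. When `n! ≤ n_perm` the test
enumerates all pairings and the p-value is exact (`k/n!`). On the
Monte-Carlo path the default p-value uses the add-one convention
`(k+1)/(n_perm+1)`, which keeps p > 0 and gives the test exactly
nominal size for continuous data; the plain proportion is reported
alongside (the two differ by at most `1/(n_perm+1)`). Incomplete pairs
are dropped listwise with a logged count. Permutations preserve the
mean and norm of the permuted vector, so the vectorised statistic needs
only one dot product per permutation.

## Probe tools

Ungapped sliding-window matching, as in rRNA-database probe-match
utilities: a position mismatches when the target base is outside the
IUPAC set of the oligo base. Probes and reverse primers are matched as
their reverse complement on the gene-sense strand (orientation inferred
from kind and a name suffix, overridable; a both-strands flag exists
because field tools do not always document their strand handling).
"Zero weighted mismatches" coincides with zero unweighted mismatches,
so counts are unweighted here. Windows overlapping an N are skipped;
coverage statistics exclude N-containing sequences from the denominator
entirely (`n_policy="sequence"`, the database convention), with a
window-level policy available. Indels are out of scope. Reported
database coverage percentages are version-dependent properties of an
external resource and are not reproduced here; the module checks the
matching semantics, not the database.

## Synthetic generator

The generator emulates one bottle/CTD snapshot of a stratified lake,
with defaults shaped like a late-summer euxinic-basin profile set:
0–250 m column on a regular 2.5 m grid, oxygen falling logistically
from 300 µM (air-saturated surface water) to a 0.5 µM sensor floor,
interface at 85 m, nitrate ramping to 5 µM at the interface and fading
to zero at 110 m, sulfide rising below 110 m at 0.086 µM m⁻¹ (the
scale implied by a few µM at ~115 m growing to ~12 µM at depth), and a
Gaussian host-ciliate peak of 8400 cells l⁻¹ at 95 m with 5 m width —
inside the anoxic nitrate-replete window, as observed in such basins.
Grid, surface oxygen, oxycline width and peak width are not printed in
any field table; they were fixed once at these field-plausible values.

Two conventions matter:

* **The oxycline parameter is the interface.** The logistic is
  positioned so that O₂ reaches `floor + 0.1 µM` exactly at
  `oxycline_depth`. A logistic *centred* there would put the plateau
  start several widths deeper and make the parameter unrecoverable by
  the interface definition.
* **Noise is multiplicative lognormal** (mean exactly 1, relative sd
  `noise_sd_fraction`, default 5% ≈ CTD accuracy class) on the three
  solutes only. Concentrations stay non-negative and the error scales
  with signal. The abundance profile stays noise-free: it is the
  ground truth against which Poisson *counting* noise is layered by
  `sample_filter_counts` (counts Poisson with mean
  `abundance · volume · section_fraction`, default 0.5 l and 1/16, the
  field counting geometry).

Random-lake draws for recovery checks (`draw_random_params`) keep the
nitrate decline and sulfide rise steep enough that the
detection-threshold crossing sits within a sampling interval of the
generating landmark; a generator can also produce arbitrarily gentle
gradients whose landmarks are *intrinsically* uncertain by many metres,
which would test the profile, not the estimator.

What passing synthetic tests does **not** show about field data: real
profiles have irregular bottle spacing, sensor drift and hysteresis,
internal waves displacing the interface between casts, nitrite
intermediates, and non-Gaussian patchy ciliate distributions. The
generator emits none of these; results on it validate the arithmetic
and the estimators' statistical behaviour, not the field protocol.

## Problem sizes and determinism

Statistical checks use problem sizes where Monte-Carlo error theory is
sharp and runs stay interactive: 100 random lakes per recovery
condition, 1000 count replicates for estimator bias, 2000 null
replicates (n = 15, 199 permutations each) for the test's empirical
size, 20 000 permutations where the field default is exercised. All
randomness flows through `numpy.random.default_rng` seeds;
`run_pipeline` writes no timestamps, so a rerun with the same seed is
byte-identical, and its manifest (input hashes, parameters, version,
output hashes) suffices to reproduce a run. Plotting is deliberately
left out; the delimited tables are the interface to whatever plotting
stack a user prefers.

## Known limitations

The budget is a 1-D two-point gradient model: no reaction–diffusion
inversion, no partitioning against free-living denitrifiers or
anammox, no depth-varying diffusivity. The dividing-cell fraction is a
snapshot quantity, not a growth rate. Probe matching is ungapped.
These bounds are intentional; each would be a separate model with its
own assumptions.
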