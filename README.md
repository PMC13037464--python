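# redoxniche

Quantitative analysis of the redox-defined niche of anaerobic plagiopylid
ciliates that host denitrifying bacterial endosymbionts (*Ca.* Azoamicus)
in the anoxic waters of stratified lakes — and of how much of the
downward nitrate supply these ciliates can remove.

The package is aimed at aquatic microbial ecologists and
biogeochemists working with CTD/bottle depth profiles (O₂, NO₃⁻,
sulfide), FISH filter counts of host ciliates, and rRNA probe or primer
sequences.

## What it computes

**Redox landmarks and the niche window** (`redoxniche.profiles`).
The oxic–anoxic interface is the depth below which the oxygen reading
stays at its constant lowest (sensor-floor) value, operationalised as a
plateau rule with an explicit tolerance. Nitrate depletion is where
NO₃⁻ falls below a detection-scale threshold (default 0.1 µM) and stays
below; sulfide onset is where detectable sulfide appears and persists
downward. Each depth is classified as `oxic`,
`anoxic_nitrate_replete`, `anoxic_nitrate_depleted` or `euxinic`; the
contiguous anoxic, nitrate-replete, sulfide-free span adjoining the
interface is the *niche window* in which the host ciliates concentrate.

**Abundance from filter counts** (`redoxniche.abundance`).
Cells counted on a filter section extrapolate to
`N = counted / section_fraction / filtered_volume` (cells l⁻¹), with
dividing-cell fractions and symbiont partition statistics between
daughter cells.

**The denitrification flux budget** (`redoxniche.budget`), per depth *i*
and layer (*i*, *i*+1):

```
R_P,i   = N_P,i · R_SP                          (pmol N l⁻¹ d⁻¹)
J_P,i   = ½ (R_P,i + R_P,i+1) · ΔH_i            (→ µmol N m⁻² d⁻¹)
J_NO3,i = D · ΔC_NO3,i / ΔH_i                   (Fick's first law, downward positive)
C_i     = 100% · J_P,i / J_NO3,i                (where J_NO3,i > 0)
```

with `R_SP = 12 pmol N d⁻¹ ciliate⁻¹` (per-cell denitrification rate)
and turbulent diffusivity `D = 27·10⁻⁶ m² s⁻¹` by default. `C_i` is the
ciliates' percent contribution to nitrate loss in the layer.

**Statistics** (`redoxniche.permstats`): Pearson correlation with a
two-sided permutation test (20 000 iterations by default, exact
enumeration for small n).

**Probe checking** (`redoxniche.probes`): ungapped IUPAC-aware mismatch
counting of FISH probes/PCR primers against FASTA collections with
N-exclusion and strand handling; ready-made oligos for this
symbiosis ship in
`FIELD_OLIGOS`.

**Synthetic lakes** (`redoxniche.synthetic`): generates stratified-lake
snapshots with known ground truth (sigmoidal oxycline, linear nitrate
decline, linear sulfide rise, Gaussian ciliate peak, multiplicative
lognormal sensor noise, Poisson filter counts), so the whole pipeline is
testable without field data.

## Worked example

```python
from redoxniche import (SyntheticLakeParams, generate_snapshot,
                        classify_redox, population_in_window, run_budget)

snap = generate_snapshot(SyntheticLakeParams(noise_sd_fraction=0.0, seed=4))
cls = classify_redox(snap)
print(cls.interface_depth, cls.no3_depletion_depth, cls.niche_window)
# 85.0 110.0 (85.0, 107.5)
print(round(population_in_window(snap["abundance"], cls), 3))
# 0.968
budget = run_budget(snap)
k = budget.peak_layer()
print(budget.depths[k], budget.depths[k + 1],
      round(budget.j_p[k], 3), round(budget.j_no3[k], 3),
      round(budget.contribution_pct[k], 1))
# 92.5 95.0 237.195 466.56 50.8
```

The default synthetic lake mimics a late-summer snapshot of a meromictic
lake: oxygen reaches its floor at 85 m, nitrate persists to 110 m where
sulfide appears, and the ciliate population peaks at 8400 cells l⁻¹ at
95 m — 97% of it inside the detected 85–107.5 m niche window. In the
92.5–95 m layer the ciliates' areal denitrification flux is
237 µmol N m⁻² d⁻¹ against a downward diffusive nitrate supply of
467 µmol N m⁻² d⁻¹: they remove about half of the nitrate diffusing into
that layer.

The same analysis runs from the shell:

```sh
redoxniche simulate --out lake.tsv --seed 4 --noise 0.05
redoxniche landmarks --snapshot lake.tsv --noise-sd-fraction 0.05
# {"interface_depth": 85.0, "no3_depletion_depth": 110.0, "sulfide_onset_depth": 110.003...}
redoxniche budget --snapshot lake.tsv --rsp 12 --diff 27e-6 --out budget.tsv
redoxniche run --config run.yaml        # full pipeline + manifest.json
```

Subcommands: `simulate`, `landmarks`, `classify`, `abundance`, `budget`,
`cortest`, `probe`, `run`.

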