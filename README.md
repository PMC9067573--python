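# uniquacmc

Activity-coefficient and vapor–liquid-equilibrium prediction for binary
and multicomponent liquid mixtures, including systems for which **no
experimental data exist**, by embedding a matrix-completion model of the
symmetric lattice pair-interaction energies inside the UNIQUAC
Gibbs-excess-energy model and training the hybrid end to end on sparse
binary ln γ data.

Intended users: thermodynamics and process-engineering researchers who
have sparse activity-coefficient data over a large roster of components
(typical laboratory databases cover under 2 % of the possible binary
systems) and need predictions for the unstudied pairs and for
multicomponent mixtures.

## The model

UNIQUAC writes the activity coefficient of component *i* in a mixture as
ln γ*ᵢ* = ln γ*ᵢ*ᶜ + ln γ*ᵢ*ᴿ, a combinatorial (size/shape) part driven by
the van der Waals parameters (*rᵢ*, *qᵢ*) and a residual (energetic) part
driven by Boltzmann factors of the lattice pair-interaction energies,

τ*ᵢⱼ* = exp(−(*Uᵢⱼ* − *Uⱼⱼ*)/(R·T)).

The lattice derivation makes the unlike energies physically symmetric,
*Uᵢⱼ* = *Uⱼᵢ* — one binary parameter per system plus one like energy
*Uᵢᵢ* per component — although conventional practice fits two
independent parameters Δ*Uᵢⱼ* = *Uᵢⱼ* − *Uⱼⱼ* and Δ*Uⱼᵢ* = *Uᵢⱼ* − *Uᵢᵢ*
per system (`check_delta_consistency` demonstrates that such independent
fits over three or more components cannot be reconciled with any single
symmetric matrix).

The symmetric matrix is completed from sparse data with per-component
latent feature vectors **θ***ᵢ*, **β***ᵢ* of shared dimension K:

*Uᵢⱼ* = **θ***ᵢ*·**β***ⱼ* + **θ***ⱼ*·**β***ᵢ*  (*i* ≠ *j*),

symmetric by construction. All component parameters are inferred jointly
("end to end") from ln γ observations — finite-composition records
through the full binary UNIQUAC equations and infinite-dilution records
through the closed-form limit — either as a MAP point estimate (L-BFGS
with analytic gradients) or by mean-field Gaussian variational
inference, which also yields standard deviations for every predicted
pair energy. Phase equilibria then follow from the extended Raoult's
law *yᵢ*·P = *xᵢ*·γ*ᵢ*·*pᵢ*ˢ(T) with Antoine vapor pressures.

## Worked example

Generate a synthetic study (60 components, rank-3 truth, 30 % of the
1770 possible systems observed, 20 records per system, noise sd 0.1 on
ln γ), train with a system-wise 80/10/10 split, and predict a system
that was never measured:

```sh
$ uniquacmc simulate --seed 1 --outdir demo/fixture
wrote fixture with 10620 records for 531 systems to demo/fixture

$ uniquacmc fit --observations demo/fixture/observations.csv \
      --geometry demo/fixture/geometry.csv --seed 1 --k 3 --outdir demo/fit
train_MAE=0.0767...; validation_MAE=0.1118...; test_MAE=0.1105...; ...
```

The test systems were held out entirely, so a test MAE of 0.11 on ln γ —
at observation noise sd 0.1 — means held-out binary systems are predicted
essentially to the noise floor. Predictions for a pair that never
co-occurred in the data (`C00`–`C01` here):

```sh
$ uniquacmc predict gamma --fit-dir demo/fit \
      --geometry demo/fixture/geometry.csv --pair C00 C01 -t 350 --n-grid 7
   x_1  ln_gamma_1  ln_gamma_2
0.1667      3.8460      0.1177
0.3333      2.7027      0.5017
0.5000      1.7007      1.2231
0.6667      0.8657      2.4041
0.8333      0.2557      4.2659
```

Both ln γ curves approach 0 as their component becomes pure (the
Raoult reference state) and grow toward dilution — a strongly
positive-deviation system. The same fit drives an isobaric T–x–y
diagram:

```sh
$ uniquacmc predict vle-binary --fit-dir demo/fit \
      --geometry demo/fixture/geometry.csv \
      --antoine demo/fixture/antoine.csv \
      --pair C00 C01 -p 101.325 --n-grid 21 --out demo/diagram.csv
wrote 21 grid points to demo/diagram.csv; azeotrope at x1=0.3386, T=329.15 K
```

— the positive deviations are strong enough to pinch the diagram into a
minimum-boiling azeotrope.

Other commands: `uniquacmc fit --method vi` (variational fit; the
exported pair-energy table then carries a standard-deviation column),
`uniquacmc evaluate`, `uniquacmc export-params`,
`uniquacmc check-delta-consistency`. Everything is available as a
library through `import uniquacmc`.

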