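# Methods

## Model

The package couples two components:

1. **UNIQUAC** (`uniquacmc.core`). Activity coefficients are
   ln γᵢ = ln γᵢᶜ + ln γᵢᴿ with the Stavermann–Guggenheim combinatorial
   part (volume fractions Φᵢ from rᵢ, surface fractions ϑᵢ from qᵢ,
   lattice coordination number z = 10) and the residual part built from
   Boltzmann factors τᵢⱼ = exp(−(Uᵢⱼ − Uⱼⱼ)/(R T)). All interaction
   parameters are temperature- and composition-independent. Energies are
   J/mol with R = 8.314462618 J/(mol K). Two parameterizations are
   supported: the physically symmetric one (Uᵢⱼ = Uⱼᵢ plus like energies
   Uᵢᵢ) and the conventional difference form (ΔUᵢⱼ = Uᵢⱼ − Uⱼⱼ,
   ΔUⱼᵢ = Uᵢⱼ − Uᵢᵢ fitted independently). `check_delta_consistency`
   solves the overdetermined linear system relating the two in least
   squares; because the difference equations see energies only through
   differences, the reconstruction is determined up to one global
   additive constant.

2. **Low-rank completion** (`uniquacmc.factorization`). Unlike energies
   are Uᵢⱼ = θᵢ·βⱼ + θⱼ·βᵢ with per-component feature vectors of
   dimension K. The form equals (PPᵀ − QQᵀ)/2 with P = θ+β, Q = θ−β, so
   it spans exactly the symmetric matrices of signature at most (K, K).
   Features are gauge variables — (θM, βM⁻ᵀ) gives identical energies —
   so only energies, never raw features, are compared anywhere.

## Inference

The log joint (`uniquacmc.inference`) sums Gaussian priors over all
feature entries and like energies and a likelihood term per observation:
finite-composition records go through the full binary equations,
infinite-dilution records through the closed-form limit
q₁(1 − ln τ₂₁ − τ₁₂) plus the combinatorial limit. Both record types
carry equal weight (one record, one likelihood term).

Internally energies are handled as U/R in Kelvin and features are
standardized: U/R = c_K (θ̃ᵢ·β̃ⱼ + θ̃ⱼ·β̃ᵢ) with c_K = 300/√(2K), so
unit-normal features produce pair energies with a spread of ~300 K —
the magnitude that yields realistic ln γ. Exported features absorb
√(R c_K), making their dot products J/mol exactly.

Defaults (exposed in `PriorSpec`, swept by `select_hyperparameters`):
feature prior sd 1.0 (standardized), like-energy prior Normal(0, 500 K)
on U/R, Gaussian likelihood with scale 0.15 on ln γ (Cauchy available
for robustness). Latent dimension K is a hyperparameter chosen by
validation MAE over a small grid (default K = 4, grid {1, 2, 3, 4, 6,
8}); the synthetic studies in the tests fit at the generating rank.

Gradients of the binary ln γ (and its infinite-dilution limit) with
respect to the two interaction differences are exact closed forms
(`uniquacmc.binary`), chained through the feature reconstruction; a
finite-difference check is part of the test suite.

**MAP** maximizes the log joint with L-BFGS-B (scipy). L-BFGS was chosen
over plain first-order ascent because the Gauss–Newton curvature of the
residual term varies by orders of magnitude across parameters; it is
deterministic given the seed. Convergence tolerances: ftol 1e-11,
gtol 1e-7, at most 20,000 iterations (non-convergence is flagged in the
diagnostics, not raised).

**Initialization.** The joint surface of a bilinear factorization behind
a stiff exponential link has many poor basins; a random start is
unreliable. The staged initialization is: (1) fit the per-system
symmetric baseline (one unlike energy per observed system plus shared
like energies — a well-conditioned problem); (2) build two feature
initializations from its unlike energies — a hard-impute completion
(iterated signature-(K,K) eigendecomposition truncation) and a
ridge-regularized least-squares factorization, each co-estimating the
global gauge constant that the baseline cannot determine (a constant
offset is not representable within the signature budget, so it must be
removed before factoring); (3) short L-BFGS burn-in of the true
objective from each candidate, keeping the better. All stages are
deterministic given the seed.

**VI** uses a mean-field Gaussian family over all unconstrained
parameters, maximizing the ELBO with reparameterized Monte-Carlo
gradients (default 4 samples/step) and Adam (default lr 0.02, 3000
steps). Entropy and its gradient are analytic. Pair-energy means and
standard deviations come from pushing 1000 posterior draws through the
reconstruction. A MAP warm start is available (`init_summary`); as for
any mean-field approximation, posterior standard deviations tend to be
underestimated where parameters are strongly correlated.

**Baselines.** Mode "deltaU" fits two difference parameters per system
by per-system Levenberg–Marquardt. Mode "U" fits one unlike energy per
system with like energies *shared across systems* (giving the S + N
parameter count), jointly by L-BFGS; a tiny ridge (1e-8) on U/R toward
−300 K fixes the additive gauge of that fit without influencing the
described energy differences.

**Splitting** is always by system (component pair), never by record,
with sizes ⌊f·S⌋ and the remainder assigned train-first. Fitting
functions use only train-labelled records; the test suite asserts that
perturbing test records leaves a fit bit-identical.

## Synthetic data

`uniquacmc.synthetic` emulates the structure of laboratory ln γ
collections without any external data: N components with r ~ U(1, 10),
q = r·U(0.75, 1.1); a rank-K truth with U_ii/R ~ N(−300 K, 150 K) and
feature entries scaled so the spread of (Uᵢⱼ − Uⱼⱼ)/R across pairs is
≈300 K (the like-energy variance is subtracted from the target before
solving for the feature scale); a fraction of systems observed uniformly
at random; per record, a finite composition x ~ U(0.02, 0.98) or, with
probability 0.25, an infinite-dilution record; T ~ U(183, 638) K;
Gaussian noise sd 0.1 on ln γ. Defaults: N = 60, K = 3, 30 % of systems
observed, 20 records/system — small enough to fit in minutes on one CPU
while leaving >1200 never-observed pairs for recovery checks.

What the generator does **not** emulate: correlated measurement errors
within a data series, heteroscedastic noise across record types,
non-random selection of which systems chemists actually measure,
components whose behavior violates the low-rank assumption, and any
deviation of real mixtures from UNIQUAC itself. Passing recovery tests
therefore demonstrates that the estimator recovers the model's own
structure from sparse noisy data — not that real mixtures follow that
structure.

Antoine tables are drawn (A ~ U(5.8, 7.2), B ~ U(1200, 2400),
C ~ U(−80, −30), rejection-sampled until the normal boiling point lies
in 250–550 K) in the log10/kPa/K dialect, declared in a mandatory header
comment; no other dialect is supported.

## Phase equilibria

`uniquacmc.vle` implements the extended Raoult's law with an ideal vapor
phase; Poynting and fugacity corrections are deliberately omitted (they
matter only near the critical region, outside the intended pressure
range). Bubble points bracket T on [150, 700] K and solve by Brent
bisection to 1e-8 K; dew points nest a fixed-point iteration on the
liquid composition inside the same T solve. Components with exactly zero
mole fraction are dropped from the mixture, so simplex edges and
vertices reduce exactly to the lower-order problem (used by the
ternary-to-binary reduction check). Azeotropes are located from a sign
change (or an exact zero at a grid node, the symmetric-system case) of
y₁ − x₁ on a composition grid, refined by bisection. Heteroazeotropes
and liquid–liquid splits are out of scope; crossing anomalies are only
logged.

## Degenerate inputs and numerical guards

- τ exponents are clipped at ±500 before exponentiation (with a logged
  warning and zero gradient in the clipped region) so optimizer
  excursions cannot overflow.
- `ln_gamma` refuses compositions on the boundary {0, 1}; the
  infinite-dilution limit has its own closed form, avoiding the 0·log 0
  ambiguity.
- Conflicting duplicate entries in interaction tables are an error, as
  are unknown components (cold-start prediction is not supported: a
  component without data has no features).
- `check_delta_consistency` with N < 3 or missing pairs is reported as
  trivially consistent with an explanatory note (the system is
  underdetermined).
- Per-system fits with fewer records than parameters are returned but
  flagged.

## Known limitations

- All parameters are temperature-independent; strongly T-dependent
  systems are outside the model class.
- Mean-field VI underestimates uncertainties where parameters are
  correlated (features of a component always are).
- Recovery degrades for small rosters (N ≲ 30) at moderate observation
  fractions: the per-component information and the redundancy the
  completion relies on both shrink, and the optimizer may settle in a
  suboptimal basin even when a better one exists.
- The VLE layer assumes an ideal vapor phase and Antoine validity; no
  equation of state is provided.
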