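"""Synthetic ground truth and observations for end-to-end testing.

Real training data for this kind of model (sparse ln gamma measurements
over thousands of binary systems) live in proprietary databases, so the
package ships a generator that emulates their statistical structure: a
roster of components with UNIQUAC geometry, a low-rank symmetric
interaction-energy truth, a small observed fraction of all systems, a
mix of finite-composition and infinite-dilution records over a wide
temperature range, and measurement noise on ln gamma.

Default condition choices (all overridable in :class:`GeneratorConfig`):

* r_i ~ U(1, 10), q_i = r_i * U(0.75, 1.1) — the range of tabulated van
  der Waals parameters for small-to-medium organic molecules;
* U_ii/R ~ N(-300, 150) K and latent features scaled so the spread of
  (U_ij - U_jj)/R across pairs is ~300 K, which keeps ln gamma_inf
  roughly within [-2, 8], the span seen in real mixtures;
* temperatures U(183, 638) K, matching the span of typical VLE and
  infinite-dilution measurements;
* Gaussian noise with sd 0.1 on ln gamma.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .binary import ln_gamma_binary, ln_gamma_inf_binary
from .constants import R_GAS
from .core import ComponentGeometry, SymmetricInteractionSet
from .factorization import LatentFeatures, assemble_interactions
from .inference import Dataset, ObservationRecord
from .vle import AntoineParameters, boiling_temperature

__all__ = [
    "GeneratorConfig",
    "SyntheticTruth",
    "generate_truth",
    "generate_observations",
    "generate_antoine",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Settings of the synthetic-data generator."""

    N_components: int = 60
    K_true: int = 3
    observed_system_fraction: float = 0.3
    records_per_system: int = 20
    infinite_dilution_fraction: float = 0.25
    T_range: tuple[float, float] = (183.0, 638.0)
    x_range: tuple[float, float] = (0.02, 0.98)
    noise_family: str = "gaussian"
    noise_scale: float = 0.1
    seed: int = 0
    #: target spread (K) of (U_ij - U_jj)/R across pairs
    pair_energy_spread: float = 300.0
    like_energy_loc: float = -300.0     # K, on the U/R scale
    like_energy_scale: float = 150.0    # K

    def __post_init__(self) -> None:
        if not 0 < self.observed_system_fraction <= 1:
            raise ValueError("observed_system_fraction must be in (0, 1]")
        if not 0 <= self.infinite_dilution_fraction <= 1:
            raise ValueError("infinite_dilution_fraction must be in [0, 1]")
        if not self.T_range[0] < self.T_range[1]:
            raise ValueError("T_range must be ordered")
        if not 0 < self.x_range[0] < self.x_range[1] < 1:
            raise ValueError("x_range must be inside (0, 1)")
        if self.noise_family not in ("gaussian", "cauchy"):
            raise ValueError("noise_family must be 'gaussian' or 'cauchy'")


@dataclass
class SyntheticTruth:
    """Ground truth behind a synthetic data set."""

    geometries: list[ComponentGeometry]
    features: LatentFeatures
    full_U: SymmetricInteractionSet
    config: GeneratorConfig

    @property
    def component_ids(self) -> list[str]:
        return self.features.component_ids

    def n_unlike_pairs(self) -> int:
        n = len(self.component_ids)
        return n * (n - 1) // 2


def _feature_entry_sd(config: GeneratorConfig) -> float:
    """Feature-entry sd such that sd((U_ij - U_jj)/R) across pairs hits
    the configured target.

    With entries ~ N(0, s): var(U_ij/R) = 2 K s^4 and the like energy
    contributes its own variance, so
    2 K s^4 = spread^2 - like_scale^2 (clipped below at 10% of spread^2).
    """
    var_pair = max(config.pair_energy_spread ** 2
                   - config.like_energy_scale ** 2,
                   0.1 * config.pair_energy_spread ** 2)
    return (var_pair / (2.0 * config.K_true)) ** 0.25


def generate_truth(config: GeneratorConfig) -> SyntheticTruth:
    """Draw a component roster, geometries, latent features and the full
    symmetric interaction matrix. Bit-reproducible for a given seed."""
    rng = np.random.default_rng(config.seed)
    n = config.N_components
    width = len(str(max(n - 1, 1)))
    ids = [f"C{k:0{width}d}" for k in range(n)]
    r = rng.uniform(1.0, 10.0, size=n)
    q = r * rng.uniform(0.75, 1.1, size=n)
    geometries = [ComponentGeometry(component_id=c, r=float(rv), q=float(qv))
                  for c, rv, qv in zip(ids, r, q)]
    s = _feature_entry_sd(config)
    theta = rng.normal(0.0, s, size=(n, config.K_true))
    beta = rng.normal(0.0, s, size=(n, config.K_true))
    u_like = rng.normal(config.like_energy_loc, config.like_energy_scale,
                        size=n)
    # store features in the J/mol convention (dot products are J/mol)
    features = LatentFeatures(component_ids=ids,
                              theta=theta * math.sqrt(R_GAS),
                              beta=beta * math.sqrt(R_GAS),
                              like_energies=u_like * R_GAS)
    full_U = assemble_interactions(features)
    return SyntheticTruth(geometries=geometries, features=features,
                          full_U=full_U, config=config)


def generate_observations(truth: SyntheticTruth,
                          config: GeneratorConfig | None = None) -> Dataset:
    """Sample sparse noisy ln gamma observations from the truth.

    ``ceil(fraction * N(N-1)/2)`` systems are drawn uniformly without
    replacement; each contributes ``records_per_system`` records. A
    record is infinite-dilution with probability
    ``infinite_dilution_fraction`` (x_i = 0, value from the closed-form
    limit), otherwise finite with x_i ~ U(x_range). The measured species
    is chosen uniformly from the pair; T ~ U(T_range); noise is added to
    the exact model value.
    """
    config = config or truth.config
    rng = np.random.default_rng(config.seed + 1)
    ids = truth.component_ids
    n = len(ids)
    pairs = [(a, b) for a in range(n) for b in range(a + 1, n)]
    n_obs = math.ceil(config.observed_system_fraction * len(pairs))
    if n_obs == 0:
        raise ValueError("observed_system_fraction too small: zero systems")
    chosen = rng.choice(len(pairs), size=n_obs, replace=False)

    geo = {g.component_id: g for g in truth.geometries}
    U = truth.full_U.U
    records: list[ObservationRecord] = []
    for k in sorted(chosen):
        a, b = pairs[k]
        for _ in range(config.records_per_system):
            if rng.random() < 0.5:
                i, j = a, b
            else:
                i, j = b, a
            T = rng.uniform(*config.T_range)
            t12 = (U[i, j] - U[j, j]) / R_GAS
            t21 = (U[i, j] - U[i, i]) / R_GAS
            gi, gj = geo[ids[i]], geo[ids[j]]
            if rng.random() < config.infinite_dilution_fraction:
                x = 0.0
                value = float(ln_gamma_inf_binary(gi.r, gi.q, gj.r, gj.q,
                                                  t12, t21, T))
                rec_type = "infinite_dilution"
            else:
                x = rng.uniform(*config.x_range)
                value = float(ln_gamma_binary(gi.r, gi.q, gj.r, gj.q,
                                              t12, t21, T, x))
                rec_type = "finite"
            if config.noise_scale > 0:
                if config.noise_family == "gaussian":
                    value += rng.normal(0.0, config.noise_scale)
                else:
                    value += config.noise_scale * rng.standard_cauchy()
            records.append(ObservationRecord(
                id_i=ids[i], id_j=ids[j], T=T, x_i=x, ln_gamma_obs=value,
                record_type=rec_type))
    return Dataset(records)


def generate_antoine(truth: SyntheticTruth, seed: int,
                     max_rejections: int = 1000) -> list[AntoineParameters]:
    """Plausible Antoine coefficients per component: A ~ U(5.8, 7.2),
    B ~ U(1200, 2400), C ~ U(-80, -30), rejection-resampled until the
    normal boiling point (p_s = 101.325 kPa) lies in [250, 550] K; the
    validity range is the boiling point +/- 120 K."""
    rng = np.random.default_rng(seed)
    out = []
    for c in truth.component_ids:
        for attempt in range(max_rejections + 1):
            A = rng.uniform(5.8, 7.2)
            B = rng.uniform(1200.0, 2400.0)
            C = rng.uniform(-80.0, -30.0)
            trial = AntoineParameters(component_id=c, A=A, B=B, C=C,
                                      T_min=150.0, T_max=700.0)
            try:
                tb = boiling_temperature(trial, 101.325)
            except ValueError:
                continue
            if 250.0 <= tb <= 550.0:
                out.append(AntoineParameters(
                    component_id=c, A=A, B=B, C=C,
                    T_min=tb - 120.0, T_max=tb + 120.0))
                break
        else:
            raise RuntimeError(f"could not draw Antoine coefficients for "
                               f"{c} in {max_rejections} attempts")
    return out
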