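"""End-to-end training of the low-rank UNIQUAC model on ln gamma data.

The forward model maps per-component parameters (latent features theta_i,
beta_i and like energies U_ii) through the pair-energy reconstruction
``U_ij = theta_i.beta_j + theta_j.beta_i`` and the binary UNIQUAC
equations to every observed ln gamma record, so the whole parameter set
is learned jointly from all binary systems at once ("end-to-end").

Two fitting modes share one differentiable objective (the log joint
density of parameters and data):

* :func:`fit_map` — deterministic maximum-a-posteriori point estimation
  (L-BFGS with analytic gradients);
* :func:`fit_vi` — mean-field Gaussian variational inference with
  reparameterized stochastic gradients, yielding per-parameter and
  per-pair-energy posterior standard deviations.

Internally all energies are handled as U/R in Kelvin and the latent
features are standardized: the model energy is
``U_ij/R = c_K (theta_i.beta_j + theta_j.beta_i)`` with a fixed per-K
constant ``c_K = 300/sqrt(2K)`` chosen so that unit-normal features give
pair energies with a spread of roughly 300 K — the magnitude that
produces realistic activity coefficients. Exported
:class:`~uniquacmc.factorization.LatentFeatures` absorb ``sqrt(R c_K)``
so their dot products are J/mol.

Classical per-system baselines (:func:`fit_per_system_baseline`) fit
either the conventional two difference parameters per system ("deltaU")
or a single symmetric unlike energy per system with like energies shared
across all systems ("U").
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.optimize

from .binary import (ln_gamma_binary_grad, ln_gamma_inf_binary_grad)
from .constants import R_GAS
from .core import AsymmetricInteractionSet, ComponentGeometry, SymmetricInteractionSet
from .factorization import LatentFeatures

logger = logging.getLogger(__name__)

__all__ = [
    "ObservationRecord",
    "Dataset",
    "PriorSpec",
    "PosteriorSummary",
    "BaselineFit",
    "system_key",
    "split_by_system",
    "log_joint",
    "fit_map",
    "fit_vi",
    "fit_per_system_baseline",
    "predict_records",
    "evaluate",
    "select_hyperparameters",
    "read_observation_table",
    "write_observation_table",
]

LN_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)


def system_key(id_i: str, id_j: str) -> str:
    """Canonical unordered label of a binary system."""
    a, b = sorted((str(id_i), str(id_j)))
    return f"{a}|{b}"


@dataclass(frozen=True)
class ObservationRecord:
    """One ln gamma measurement of species ``id_i`` in a binary mixture
    with ``id_j`` at temperature ``T`` (K) and mole fraction ``x_i``.

    ``record_type`` is ``"finite"`` (x_i in (0, 1)) or
    ``"infinite_dilution"`` (x_i = 0 exactly).
    """

    id_i: str
    id_j: str
    T: float
    x_i: float
    ln_gamma_obs: float
    record_type: str = "finite"

    def __post_init__(self) -> None:
        if self.id_i == self.id_j:
            raise ValueError("a binary record needs two distinct components")
        if not self.T > 0:
            raise ValueError("temperature must be positive")
        if not np.isfinite(self.ln_gamma_obs):
            raise ValueError("ln_gamma_obs must be finite")
        if self.record_type == "infinite_dilution":
            if self.x_i != 0.0:
                raise ValueError("infinite-dilution records must have x_i = 0")
        elif self.record_type == "finite":
            if not 0.0 < self.x_i < 1.0:
                raise ValueError("finite records need x_i strictly in (0, 1)")
        else:
            raise ValueError(f"unknown record_type {self.record_type!r}")

    @property
    def system_key(self) -> str:
        return system_key(self.id_i, self.id_j)


class Dataset:
    """Collection of observation records with system-wise split labels.

    Splitting is always by binary system, never by record: every record of
    a system shares that system's label, so held-out systems are truly
    unseen during training.
    """

    def __init__(self, records: list[ObservationRecord],
                 split_labels: dict[str, str] | None = None):
        self.records = list(records)
        self.split_labels = dict(split_labels or {})
        for key, lab in self.split_labels.items():
            if lab not in ("train", "validation", "test"):
                raise ValueError(f"unknown split label {lab!r} for {key}")

    def __len__(self) -> int:
        return len(self.records)

    def system_keys(self) -> list[str]:
        return sorted({r.system_key for r in self.records})

    def component_ids(self) -> list[str]:
        return sorted({c for r in self.records for c in (r.id_i, r.id_j)})

    def label_of(self, key: str) -> str:
        return self.split_labels.get(key, "train")

    def subset(self, split: str) -> "Dataset":
        recs = [r for r in self.records if self.label_of(r.system_key) == split]
        labels = {k: v for k, v in self.split_labels.items() if v == split}
        return Dataset(recs, labels)

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for r in self.records:
            lab = self.label_of(r.system_key)
            out[lab] = out.get(lab, 0) + 1
        return out


def split_by_system(dataset: Dataset,
                    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
                    seed: int = 0) -> Dataset:
    """Randomly partition *systems* into train/validation/test.

    Partition sizes are ``floor(f * S)`` per split with the remainder
    assigned train-first. Deterministic for a given seed.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    keys = dataset.system_keys()
    n_nonzero = sum(f > 0 for f in fractions)
    if len(keys) < max(3, n_nonzero):
        raise ValueError("need at least as many systems as nonzero fractions "
                         "(and >= 3 overall) to split")
    rng = np.random.default_rng(seed)
    perm = [keys[k] for k in rng.permutation(len(keys))]
    sizes = [int(math.floor(f * len(keys))) for f in fractions]
    leftover = len(keys) - sum(sizes)
    for k in range(leftover):          # remainder goes train-first
        sizes[k % 3] += 1
    labels: dict[str, str] = {}
    names = ("train", "validation", "test")
    pos = 0
    for name, size in zip(names, sizes):
        for key in perm[pos:pos + size]:
            labels[key] = name
        pos += size
    return Dataset(dataset.records, labels)


@dataclass(frozen=True)
class PriorSpec:
    """Priors and observation-noise model for the probabilistic fit.

    feature_scale
        Prior standard deviation of the standardized latent-feature
        entries (dimensionless; 1.0 corresponds to pair energies with a
        spread of ~300 K on the U/R scale).
    like_energy_loc, like_energy_scale
        Gaussian prior on the like energies U_ii, J/mol. The default
        scale, 500 K on the U/R scale, is weakly informative.
    likelihood_family
        "gaussian" (default) or "cauchy" (robust) noise on ln gamma.
    likelihood_scale
        Scale of the observation noise on ln gamma (dimensionless).
    """

    feature_scale: float = 1.0
    like_energy_loc: float = 0.0
    like_energy_scale: float = 500.0 * R_GAS
    likelihood_family: str = "gaussian"
    likelihood_scale: float = 0.15

    def __post_init__(self) -> None:
        if self.feature_scale <= 0 or self.like_energy_scale <= 0 \
                or self.likelihood_scale <= 0:
            raise ValueError("all prior/likelihood scales must be > 0")
        if self.likelihood_family not in ("gaussian", "cauchy"):
            raise ValueError("likelihood_family must be 'gaussian' or 'cauchy'")


def energy_scale_constant(K: int) -> float:
    """Standardization constant c_K (Kelvin): U_ij/R = c_K * (feature dot
    products), so unit-normal features give sd(U_ij/R) = 300 K."""
    return 300.0 / math.sqrt(2.0 * K)


# ---------------------------------------------------------------------------
# Vectorized record views and the differentiable objective
# ---------------------------------------------------------------------------

class _RecordArrays:
    """Column view of a record list against a fixed component roster."""

    def __init__(self, records: list[ObservationRecord],
                 roster: list[str],
                 geometries: list[ComponentGeometry]):
        index = {c: k for k, c in enumerate(roster)}
        geo = {g.component_id: g for g in geometries}
        for c in roster:
            if c not in geo:
                raise KeyError(f"no geometry for component {c!r}")
        try:
            self.i_idx = np.array([index[r.id_i] for r in records], dtype=int)
            self.j_idx = np.array([index[r.id_j] for r in records], dtype=int)
        except KeyError as exc:
            raise KeyError(f"record references unknown component "
                           f"{exc.args[0]!r}") from None
        self.T = np.array([r.T for r in records])
        self.x = np.array([r.x_i for r in records])
        self.obs = np.array([r.ln_gamma_obs for r in records])
        self.is_inf = np.array(
            [r.record_type == "infinite_dilution" for r in records])
        r_arr = np.array([geo[c].r for c in roster])
        q_arr = np.array([geo[c].q for c in roster])
        self.r1, self.q1 = r_arr[self.i_idx], q_arr[self.i_idx]
        self.r2, self.q2 = r_arr[self.j_idx], q_arr[self.j_idx]
        self.n = len(records)

    def predict_grads(self, t12: np.ndarray, t21: np.ndarray):
        """ln gamma prediction and d/dt12, d/dt21 per record, given the
        interaction-difference parameters in Kelvin."""
        pred = np.empty(self.n)
        g12 = np.empty(self.n)
        g21 = np.empty(self.n)
        fin = ~self.is_inf
        if fin.any():
            s = fin
            pred[s], g12[s], g21[s] = ln_gamma_binary_grad(
                self.r1[s], self.q1[s], self.r2[s], self.q2[s],
                t12[s], t21[s], self.T[s], self.x[s])
        if self.is_inf.any():
            s = self.is_inf
            pred[s], g12[s], g21[s] = ln_gamma_inf_binary_grad(
                self.r1[s], self.q1[s], self.r2[s], self.q2[s],
                t12[s], t21[s], self.T[s])
        return pred, g12, g21


def _loglik_terms(resid: np.ndarray, family: str, scale: float):
    """(log-likelihood per record, d loglik / d prediction)."""
    if family == "gaussian":
        ll = -0.5 * (resid / scale) ** 2 - math.log(scale) - LN_SQRT_2PI
        dpred = -resid / scale ** 2
    else:  # cauchy
        ll = -np.log(math.pi * scale * (1.0 + (resid / scale) ** 2))
        dpred = -2.0 * resid / (scale ** 2 + resid ** 2)
    return ll, dpred


class _Objective:
    """Negative log joint of the low-rank model, with analytic gradient.

    Parameter vector layout: theta (N*K), beta (N*K), u (N), where theta
    and beta are standardized features and u = U_ii/R in Kelvin.
    """

    def __init__(self, records: list[ObservationRecord], roster: list[str],
                 geometries: list[ComponentGeometry], priors: PriorSpec, K: int):
        self.arrays = _RecordArrays(records, roster, geometries)
        self.roster = list(roster)
        self.N = len(roster)
        self.K = K
        self.c = energy_scale_constant(K)
        self.priors = priors
        self.u_loc = priors.like_energy_loc / R_GAS
        self.u_scale = priors.like_energy_scale / R_GAS
        self.dim = 2 * self.N * K + self.N

    def unpack(self, p: np.ndarray):
        N, K = self.N, self.K
        theta = p[:N * K].reshape(N, K)
        beta = p[N * K:2 * N * K].reshape(N, K)
        u = p[2 * N * K:]
        return theta, beta, u

    def pack(self, theta, beta, u) -> np.ndarray:
        return np.concatenate([theta.ravel(), beta.ravel(), u])

    def predictions(self, p: np.ndarray) -> np.ndarray:
        theta, beta, u = self.unpack(p)
        a = self.arrays
        thi, thj = theta[a.i_idx], theta[a.j_idx]
        bei, bej = beta[a.i_idx], beta[a.j_idx]
        v = self.c * ((thi * bej).sum(axis=1) + (thj * bei).sum(axis=1))
        pred, _, _ = a.predict_grads(v - u[a.j_idx], v - u[a.i_idx])
        return pred

    def value_and_grad(self, p: np.ndarray) -> tuple[float, np.ndarray]:
        theta, beta, u = self.unpack(p)
        a = self.arrays
        sf = self.priors.feature_scale

        # log prior and its gradient
        lp = (-0.5 * float((theta ** 2).sum() + (beta ** 2).sum()) / sf ** 2
              - 2 * self.N * self.K * (math.log(sf) + LN_SQRT_2PI))
        du = (u - self.u_loc) / self.u_scale
        lp += float(-0.5 * (du ** 2).sum()
                    - self.N * (math.log(self.u_scale) + LN_SQRT_2PI))
        g_theta = -theta / sf ** 2
        g_beta = -beta / sf ** 2
        g_u = -du / self.u_scale

        if a.n:
            thi, thj = theta[a.i_idx], theta[a.j_idx]
            bei, bej = beta[a.i_idx], beta[a.j_idx]
            v = self.c * ((thi * bej).sum(axis=1) + (thj * bei).sum(axis=1))
            pred, g12, g21 = a.predict_grads(v - u[a.j_idx], v - u[a.i_idx])
            ll, dpred = _loglik_terms(pred - a.obs,
                                      self.priors.likelihood_family,
                                      self.priors.likelihood_scale)
            lp += float(ll.sum())
            w_v = dpred * (g12 + g21) * self.c         # d loglik / d (theta.beta terms)
            np.add.at(g_theta, a.i_idx, w_v[:, None] * bej)
            np.add.at(g_theta, a.j_idx, w_v[:, None] * bei)
            np.add.at(g_beta, a.j_idx, w_v[:, None] * thi)
            np.add.at(g_beta, a.i_idx, w_v[:, None] * thj)
            np.add.at(g_u, a.i_idx, -dpred * g21)
            np.add.at(g_u, a.j_idx, -dpred * g12)

        grad = self.pack(g_theta, g_beta, g_u)
        return -lp, -grad

    # conversions between internal and exported (J/mol) conventions -------
    @property
    def feature_unit(self) -> float:
        return math.sqrt(R_GAS * self.c)

    def export_features(self, p: np.ndarray) -> LatentFeatures:
        theta, beta, u = self.unpack(p)
        s = self.feature_unit
        return LatentFeatures(component_ids=list(self.roster),
                              theta=theta * s, beta=beta * s,
                              like_energies=u * R_GAS)

    def internalize_features(self, features: LatentFeatures) -> np.ndarray:
        s = self.feature_unit
        return self.pack(features.theta / s, features.beta / s,
                         features.like_energies / R_GAS)

    def pair_energy_matrix(self, p: np.ndarray) -> np.ndarray:
        """Full symmetric U matrix, J/mol."""
        theta, beta, u = self.unpack(p)
        U = R_GAS * self.c * (theta @ beta.T + beta @ theta.T)
        np.fill_diagonal(U, R_GAS * u)
        return np.triu(U) + np.triu(U, 1).T


def _train_records(dataset: Dataset) -> list[ObservationRecord]:
    return [r for r in dataset.records
            if dataset.label_of(r.system_key) == "train"]


def log_joint(features: LatentFeatures, dataset: Dataset, priors: PriorSpec,
              geometries: list[ComponentGeometry]) -> float:
    """Log joint density of parameters and the train-split records.

    Sum of the log prior over all feature entries and like energies plus
    the log likelihood of every training observation around the model
    prediction (finite records through the full binary equation,
    infinite-dilution records through the closed-form limit).
    """
    obj = _Objective(_train_records(dataset), features.component_ids,
                     geometries, priors, features.K)
    neg, _ = obj.value_and_grad(obj.internalize_features(features))
    return -neg


@dataclass
class PosteriorSummary:
    """Per-parameter posterior means and standard deviations plus the
    derived pair-energy summaries (all J/mol in the exported convention).

    For MAP fits all standard deviations are zero.
    """

    mean: LatentFeatures
    theta_sd: np.ndarray
    beta_sd: np.ndarray
    like_sd: np.ndarray
    U_mean: np.ndarray
    U_sd: np.ndarray
    diagnostics: dict = field(default_factory=dict)

    @property
    def component_ids(self) -> list[str]:
        return self.mean.component_ids

    @property
    def K(self) -> int:
        return self.mean.K

    def interactions(self, subset: list[str] | None = None) -> SymmetricInteractionSet:
        ids = subset or self.component_ids
        sel = [self.mean.index(c) for c in ids]
        return SymmetricInteractionSet(list(ids),
                                       self.U_mean[np.ix_(sel, sel)])


def _init_params(obj: _Objective, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    theta = rng.normal(0.0, 0.1, size=(obj.N, obj.K))
    beta = rng.normal(0.0, 0.1, size=(obj.N, obj.K))
    u = np.full(obj.N, obj.u_loc)
    return obj.pack(theta, beta, u)


def _signature_factors(M: np.ndarray, K: int) -> tuple[np.ndarray, np.ndarray]:
    """Factor a symmetric matrix as theta beta' + beta theta' with N x K
    factors, keeping the K most positive and K most negative eigenpairs.

    Uses the identity theta beta' + beta theta' = (P P' - Q Q')/2 with
    P = theta + beta, Q = theta - beta: any symmetric matrix of signature
    at most (K, K) is exactly representable.
    """
    w, V = np.linalg.eigh(M)
    N = M.shape[0]
    P = np.zeros((N, K))
    Q = np.zeros((N, K))
    for col, idx in enumerate(np.argsort(w)[::-1][:K]):
        if w[idx] > 0:
            P[:, col] = math.sqrt(2.0 * w[idx]) * V[:, idx]
    for col, idx in enumerate(np.argsort(w)[:K]):
        if w[idx] < 0:
            Q[:, col] = math.sqrt(2.0 * (-w[idx])) * V[:, idx]
    return (P + Q) / 2.0, (P - Q) / 2.0


def _impute_init(obj: _Objective, base: "BaselineFit") -> np.ndarray:
    """Initialization candidate via hard-impute matrix completion.

    The per-system unlike energies from the baseline fill the observed
    entries of the (standardized) pair-energy matrix; missing entries are
    iteratively replaced by a signature-(K, K) eigendecomposition
    truncation until the completion is self-consistent, and the completed
    matrix is factored exactly into feature vectors. Deterministic.

    The baseline determines interaction energies only up to a global
    additive constant (its likelihood sees energy differences), and a
    constant is not representable within the signature budget, so a
    scalar offset is co-estimated inside the loop (the mean observed
    residual) and removed from both the unlike and the like energies.
    """
    index = {c: k for k, c in enumerate(obj.roster)}
    N, K = obj.N, obj.K
    M = np.zeros((N, N))
    mask = np.zeros((N, N), dtype=bool)
    for (i, j), val in base.unlike_energies.items():
        a, b = index[i], index[j]
        M[a, b] = M[b, a] = val / R_GAS / obj.c
        mask[a, b] = mask[b, a] = True
    c0 = 0.0
    low = np.zeros((N, N))
    X = M.copy()
    for _ in range(300):
        if mask.any():
            c0 = float(np.mean(M[mask] - low[mask]))
        X_new = np.where(mask, M - c0, low)
        w, V = np.linalg.eigh(X_new)
        keep = np.concatenate([np.argsort(w)[::-1][:K], np.argsort(w)[:K]])
        keep = keep[np.abs(w[keep]) > 0]
        low = (V[:, keep] * w[keep]) @ V[:, keep].T
        if np.abs(X_new - X).max() < 1e-10:
            X = X_new
            break
        X = X_new
    theta, beta = _signature_factors(X, K)
    u0 = np.array([base.like_energies.get(comp, obj.u_loc * R_GAS) / R_GAS
                   for comp in obj.roster]) - c0 * obj.c
    return obj.pack(theta, beta, u0)


def _factor_init(obj: _Objective, base: "BaselineFit", seed: int,
                 n_restarts: int = 4) -> np.ndarray:
    """Initialization candidate via ridge-regularized least-squares
    factorization of the observed per-system unlike energies, best of
    ``n_restarts`` seeded random starts. A free global offset (the gauge
    constant the baseline cannot determine) is co-fitted and removed
    from the like energies."""
    index = {c: k for k, c in enumerate(obj.roster)}
    ii = np.array([index[i] for (i, j) in base.unlike_energies], dtype=int)
    jj = np.array([index[j] for (i, j) in base.unlike_energies], dtype=int)
    v_obs = np.array(list(base.unlike_energies.values())) / R_GAS
    N, K, c = obj.N, obj.K, obj.c
    n_feat = 2 * N * K
    lam = 0.5

    def sse_grad(p):
        th = p[:N * K].reshape(N, K)
        be = p[N * K:n_feat].reshape(N, K)
        c0 = p[n_feat]              # Kelvin, gauge offset
        res = (c * ((th[ii] * be[jj]).sum(1) + (th[jj] * be[ii]).sum(1))
               + c0 - v_obs)
        g_th = np.zeros((N, K))
        g_be = np.zeros((N, K))
        w = 2.0 * res * c
        np.add.at(g_th, ii, w[:, None] * be[jj])
        np.add.at(g_th, jj, w[:, None] * be[ii])
        np.add.at(g_be, jj, w[:, None] * th[ii])
        np.add.at(g_be, ii, w[:, None] * th[jj])
        grad = np.concatenate([g_th.ravel(), g_be.ravel(),
                               [2.0 * float(res.sum())]])
        grad[:n_feat] += 2.0 * lam * p[:n_feat]
        return float(res @ res) + lam * float(p[:n_feat] @ p[:n_feat]), grad

    best = None
    for restart in range(n_restarts):
        rng = np.random.default_rng([seed, restart])
        x0 = np.concatenate([rng.normal(0.0, 0.7, n_feat), [0.0]])
        sol = scipy.optimize.minimize(
            sse_grad, x0, jac=True, method="L-BFGS-B",
            options={"maxiter": 10000, "maxfun": 20000,
                     "ftol": 1e-14, "gtol": 1e-10})
        if best is None or sol.fun < best.fun:
            best = sol
    c0 = best.x[n_feat]
    u0 = np.array([base.like_energies.get(comp, obj.u_loc * R_GAS) / R_GAS
                   for comp in obj.roster]) - c0
    return np.concatenate([best.x[:n_feat], u0])


def _staged_init(obj: _Objective, dataset: Dataset,
                 geometries: list[ComponentGeometry], seed: int,
                 short_iter: int = 3000) -> np.ndarray:
    """Deterministic staged initialization of the end-to-end fit.

    The joint posterior surface of a bilinear factorization behind a
    stiff nonlinear link has many poor basins, so a single random start
    is unreliable. Instead: (1) fit the per-system symmetric baseline
    (one unlike energy per observed system plus shared like energies — a
    well-conditioned problem); (2) build two feature initializations
    from its unlike energies — a hard-impute eigendecomposition
    completion and a ridge-regularized factorization — and (3) run a
    short burn-in of the full objective from each, keeping the better
    one. Initialization device only; the final estimate maximizes the
    true objective.
    """
    base = fit_per_system_baseline(dataset, geometries, mode="U")
    candidates = [_impute_init(obj, base), _factor_init(obj, base, seed)]
    best = None
    for x0 in candidates:
        sol = scipy.optimize.minimize(
            obj.value_and_grad, x0, jac=True, method="L-BFGS-B",
            options={"maxiter": short_iter, "maxfun": 2 * short_iter,
                     "ftol": 1e-11, "gtol": 1e-7})
        if best is None or sol.fun < best.fun:
            best = sol
    return best.x


def fit_map(dataset: Dataset, priors: PriorSpec,
            geometries: list[ComponentGeometry], K: int, seed: int,
            *, roster: list[str] | None = None,
            max_iter: int = 20000) -> PosteriorSummary:
    """Maximum-a-posteriori fit: maximizes the log joint over the latent
    features and like energies by L-BFGS with analytic gradients, from a
    deterministic staged initialization (see :func:`_staged_init`).
    Deterministic given the seed.

    Only train-split records enter the objective; the roster (default:
    every component appearing in ``dataset``) fixes which components get
    parameters, so held-out systems can still be predicted.
    """
    roster = list(roster) if roster is not None else dataset.component_ids()
    train = _train_records(dataset)
    if not train:
        raise ValueError("train split is empty")
    obj = _Objective(train, roster, geometries, priors, K)
    try:
        x0 = _staged_init(obj, dataset, geometries, seed)
    except Exception:
        logger.exception("staged initialization failed; falling back to a "
                         "random start")
        x0 = _init_params(obj, seed)
    res = scipy.optimize.minimize(
        obj.value_and_grad, x0, jac=True, method="L-BFGS-B",
        options={"maxiter": max_iter, "maxfun": 2 * max_iter,
                 "ftol": 1e-11, "gtol": 1e-7})
    if not res.success:
        logger.warning("MAP optimizer stopped without convergence: %s",
                       res.message)
    features = obj.export_features(res.x)
    U = obj.pair_energy_matrix(res.x)
    zeros_nk = np.zeros_like(features.theta)
    return PosteriorSummary(
        mean=features,
        theta_sd=zeros_nk, beta_sd=zeros_nk.copy(),
        like_sd=np.zeros(obj.N),
        U_mean=U, U_sd=np.zeros_like(U),
        diagnostics={"method": "map", "converged": bool(res.success),
                     "n_iter": int(res.nit), "final_objective": float(res.fun),
                     "seed": seed, "K": K, "n_train_records": len(train)})


def fit_vi(dataset: Dataset, priors: PriorSpec,
           geometries: list[ComponentGeometry], K: int, seed: int,
           *, roster: list[str] | None = None,
           n_iter: int = 3000, n_samples: int = 4, learning_rate: float = 0.02,
           n_energy_draws: int = 1000,
           init_summary: PosteriorSummary | None = None) -> PosteriorSummary:
    """Mean-field Gaussian variational inference.

    Every unconstrained parameter gets an independent Gaussian factor
    q(p) = N(mu, sigma^2); the evidence lower bound
    ``E_q[log joint] + entropy(q)`` is maximized with reparameterized
    Monte-Carlo gradients (``n_samples`` draws per step) and Adam.
    Pair-energy means and standard deviations are obtained by pushing
    ``n_energy_draws`` posterior samples through the reconstruction.

    ``init_summary`` (e.g. a previous MAP fit over the same roster and K)
    warm-starts the variational means; otherwise the deterministic staged
    initialization is used.
    """
    roster = list(roster) if roster is not None else dataset.component_ids()
    train = _train_records(dataset)
    obj = _Objective(train, roster, geometries, priors, K)
    rng = np.random.default_rng(seed)

    if init_summary is not None:
        mu = obj.internalize_features(init_summary.mean)
    elif train:
        try:
            mu = _staged_init(obj, dataset, geometries, seed)
        except Exception:
            logger.exception("staged initialization failed; falling back "
                             "to a random start")
            mu = _init_params(obj, seed)
    else:
        mu = _init_params(obj, seed)
    log_sigma = np.full(obj.dim, math.log(0.1))
    # Adam state
    m_mu = np.zeros_like(mu); v_mu = np.zeros_like(mu)
    m_ls = np.zeros_like(mu); v_ls = np.zeros_like(mu)
    b1, b2, eps_adam = 0.9, 0.999, 1e-8

    elbo = math.nan
    for step in range(1, n_iter + 1):
        sigma = np.exp(log_sigma)
        g_mu = np.zeros_like(mu)
        g_ls = np.zeros_like(mu)
        lj_acc = 0.0
        for _ in range(n_samples):
            eps = rng.standard_normal(obj.dim)
            p = mu + sigma * eps
            neg, neg_grad = obj.value_and_grad(p)
            grad = -neg_grad
            lj_acc += -neg
            g_mu += grad
            g_ls += grad * eps * sigma
        g_mu /= n_samples
        g_ls /= n_samples
        g_ls += 1.0                       # entropy gradient d/dlog_sigma
        elbo = lj_acc / n_samples + float(log_sigma.sum()) \
            + 0.5 * obj.dim * (1.0 + math.log(2.0 * math.pi))
        if not np.isfinite(elbo) or not np.isfinite(g_mu).all():
            raise RuntimeError(
                f"ELBO diverged at step {step} (elbo={elbo}); try a smaller "
                f"learning rate or a larger likelihood_scale")
        # Adam ascent
        for g, m_, v_, target in ((g_mu, m_mu, v_mu, mu),
                                  (g_ls, m_ls, v_ls, log_sigma)):
            m_ *= b1; m_ += (1 - b1) * g
            v_ *= b2; v_ += (1 - b2) * g * g
            mhat = m_ / (1 - b1 ** step)
            vhat = v_ / (1 - b2 ** step)
            target += learning_rate * mhat / (np.sqrt(vhat) + eps_adam)

    sigma = np.exp(log_sigma)
    features = obj.export_features(mu)
    theta_sd, beta_sd, u_sd = obj.unpack(sigma)
    s_unit = obj.feature_unit

    # pair-energy summaries from posterior draws
    draws = rng.standard_normal((n_energy_draws, obj.dim)) * sigma + mu
    U_acc = np.zeros((obj.N, obj.N))
    U2_acc = np.zeros((obj.N, obj.N))
    for d in draws:
        U_d = obj.pair_energy_matrix(d)
        U_acc += U_d
        U2_acc += U_d ** 2
    U_mean = U_acc / n_energy_draws
    U_var = np.maximum(U2_acc / n_energy_draws - U_mean ** 2, 0.0)
    U_mean = np.triu(U_mean) + np.triu(U_mean, 1).T
    U_sd = np.sqrt(np.triu(U_var) + np.triu(U_var, 1).T)

    return PosteriorSummary(
        mean=features,
        theta_sd=theta_sd * s_unit, beta_sd=beta_sd * s_unit,
        like_sd=u_sd * R_GAS,
        U_mean=U_mean, U_sd=U_sd,
        diagnostics={"method": "vi", "final_elbo": float(elbo),
                     "n_iter": n_iter, "n_samples": n_samples,
                     "seed": seed, "K": K, "n_train_records": len(train)})


# ---------------------------------------------------------------------------
# Per-system classical baselines
# ---------------------------------------------------------------------------

@dataclass
class BaselineFit:
    """Per-system UNIQUAC fit in either parameterization.

    ``delta`` maps ordered pairs (i, j) of every fitted system to
    ``dU_ij = U_ij - U_jj`` in J/mol (for mode "U" these are derived from
    the fitted unlike energy and the shared like energies). Mode "U"
    additionally populates ``like_energies`` and ``unlike_energies``.
    """

    mode: str
    delta: dict[tuple[str, str], float]
    like_energies: dict[str, float] = field(default_factory=dict)
    unlike_energies: dict[tuple[str, str], float] = field(default_factory=dict)
    flagged_systems: list[str] = field(default_factory=list)
    train_mae: float = math.nan
    train_mse: float = math.nan

    def to_asymmetric_set(self) -> AsymmetricInteractionSet:
        ids = sorted({c for pair in self.delta for c in pair})
        return AsymmetricInteractionSet(ids, self.delta)

    def n_parameters(self) -> int:
        n_systems = len(self.delta) // 2
        if self.mode == "deltaU":
            return 2 * n_systems
        return n_systems + len(self.like_energies)


def _records_by_system(records: list[ObservationRecord]):
    groups: dict[str, list[ObservationRecord]] = {}
    for r in records:
        groups.setdefault(r.system_key, []).append(r)
    return groups


def fit_per_system_baseline(dataset: Dataset,
                            geometries: list[ComponentGeometry],
                            mode: str = "U") -> BaselineFit:
    """Classical UNIQUAC fitting, system by system, on the train split.

    mode "deltaU": two independent difference parameters per system,
    least squares per system. mode "U": one symmetric unlike energy per
    system plus like energies shared across *all* systems, fitted jointly
    (the shared like energies are what make the symmetric parameter count
    S + N instead of 2S). Systems with fewer records than parameters are
    fitted anyway but flagged.
    """
    if mode not in ("U", "deltaU"):
        raise ValueError("mode must be 'U' or 'deltaU'")
    train = _train_records(dataset)
    if not train:
        raise ValueError("train split is empty")
    groups = _records_by_system(train)
    geo = {g.component_id: g for g in geometries}
    flagged = [k for k, recs in groups.items()
               if len(recs) < (2 if mode == "deltaU" else 1) + 1]
    if flagged:
        logger.warning("%d systems have fewer records than parameters; "
                       "fits are returned but flagged", len(flagged))

    delta: dict[tuple[str, str], float] = {}
    like: dict[str, float] = {}
    unlike: dict[tuple[str, str], float] = {}

    if mode == "deltaU":
        for key, recs in sorted(groups.items()):
            i, j = key.split("|")
            arrays = _RecordArrays(recs, [i, j], [geo[i], geo[j]])

            def resid_jac(t):
                t12 = np.where(arrays.i_idx == 0, t[0], t[1])
                t21 = np.where(arrays.i_idx == 0, t[1], t[0])
                pred, g12, g21 = arrays.predict_grads(t12, t21)
                res = pred - arrays.obs
                jac = np.empty((arrays.n, 2))
                first = arrays.i_idx == 0
                jac[:, 0] = np.where(first, g12, g21)
                jac[:, 1] = np.where(first, g21, g12)
                return res, jac

            sol = scipy.optimize.least_squares(
                lambda t: resid_jac(t)[0], x0=np.zeros(2),
                jac=lambda t: resid_jac(t)[1], method="lm")
            t12, t21 = sol.x            # dU_ij/R, dU_ji/R with i < j
            delta[(i, j)] = float(t12 * R_GAS)
            delta[(j, i)] = float(t21 * R_GAS)
    else:
        sys_keys = sorted(groups.items())
        roster = sorted({c for k, _ in sys_keys for c in k.split("|")})
        index = {c: a for a, c in enumerate(roster)}
        arrays = _RecordArrays(train, roster, [geo[c] for c in roster])
        sys_of_record = np.empty(arrays.n, dtype=int)
        key_index = {k: s for s, (k, _) in enumerate(sys_keys)}
        for n_, r in enumerate(train):
            sys_of_record[n_] = key_index[r.system_key]
        S, N = len(sys_keys), len(roster)
        ridge = 1e-8                     # fixes the additive gauge of U_ii

        def value_and_grad(p):
            v = p[:S]
            u = p[S:]
            v_rec = v[sys_of_record]
            pred, g12, g21 = arrays.predict_grads(
                v_rec - u[arrays.j_idx], v_rec - u[arrays.i_idx])
            res = pred - arrays.obs
            sse = float(res @ res) + ridge * float(((u + 300.0) ** 2).sum())
            w = 2.0 * res
            g_v = np.zeros(S)
            np.add.at(g_v, sys_of_record, w * (g12 + g21))
            g_u = 2.0 * ridge * (u + 300.0)
            np.add.at(g_u, arrays.i_idx, -w * g21)
            np.add.at(g_u, arrays.j_idx, -w * g12)
            return sse, np.concatenate([g_v, g_u])

        x0 = np.concatenate([np.zeros(S), np.full(N, -300.0)])
        res = scipy.optimize.minimize(
            value_and_grad, x0, jac=True, method="L-BFGS-B",
            options={"maxiter": 20000, "maxfun": 40000,
                     "ftol": 1e-14, "gtol": 1e-10})
        if not res.success:
            logger.warning("mode-U baseline optimizer: %s", res.message)
        v_fit = res.x[:S] * R_GAS
        u_fit = res.x[S:] * R_GAS
        like = {c: float(u_fit[index[c]]) for c in roster}
        for s, (key, _) in enumerate(sys_keys):
            i, j = key.split("|")
            unlike[(i, j)] = float(v_fit[s])
            delta[(i, j)] = float(v_fit[s] - like[j])
            delta[(j, i)] = float(v_fit[s] - like[i])

    fit = BaselineFit(mode=mode, delta=delta, like_energies=like,
                      unlike_energies=unlike, flagged_systems=sorted(flagged))
    pred = predict_records(fit, geometries, train)
    obs = np.array([r.ln_gamma_obs for r in train])
    fit.train_mae = float(np.mean(np.abs(pred - obs)))
    fit.train_mse = float(np.mean((pred - obs) ** 2))
    return fit


# ---------------------------------------------------------------------------
# Prediction and evaluation
# ---------------------------------------------------------------------------

def predict_records(model, geometries: list[ComponentGeometry],
                    records: list[ObservationRecord]) -> np.ndarray:
    """ln gamma predictions for ``records``.

    ``model`` may be a :class:`PosteriorSummary` (posterior-mean
    energies), a :class:`~uniquacmc.factorization.LatentFeatures`, or a
    :class:`BaselineFit`.
    """
    if isinstance(model, BaselineFit):
        missing = [r.system_key for r in records
                   if (r.id_i, r.id_j) not in model.delta]
        if missing:
            raise KeyError(f"baseline has no fit for systems {sorted(set(missing))[:5]}")
        roster = sorted({c for r in records for c in (r.id_i, r.id_j)})
        geo = {g.component_id: g for g in geometries}
        arrays = _RecordArrays(records, roster, [geo[c] for c in roster])
        t12 = np.array([model.delta[(r.id_i, r.id_j)] for r in records]) / R_GAS
        t21 = np.array([model.delta[(r.id_j, r.id_i)] for r in records]) / R_GAS
        pred, _, _ = arrays.predict_grads(t12, t21)
        return pred

    if isinstance(model, PosteriorSummary):
        features = model.mean
        U = model.U_mean
    elif isinstance(model, LatentFeatures):
        features = model
        U = None
    else:
        raise TypeError(f"cannot predict from {type(model).__name__}")
    idx = features.index
    roster = features.component_ids
    geo = {g.component_id: g for g in geometries}
    arrays = _RecordArrays(records, roster, [geo[c] for c in roster])
    if U is None:
        from .factorization import assemble_interactions
        U = assemble_interactions(features).U
    uij = U[arrays.i_idx, arrays.j_idx]
    t12 = (uij - U[arrays.j_idx, arrays.j_idx]) / R_GAS
    t21 = (uij - U[arrays.i_idx, arrays.i_idx]) / R_GAS
    pred, _, _ = arrays.predict_grads(t12, t21)
    return pred


def evaluate(model, dataset: Dataset, geometries: list[ComponentGeometry],
             split: str | None = None) -> dict:
    """Error metrics of ``model`` on one split (or all records).

    Returns MAE and MSE over records together with their standard errors
    of the mean, the record count, and a per-system error table.
    """
    records = (dataset.records if split is None
               else dataset.subset(split).records)
    if not records:
        raise ValueError(f"no records in split {split!r}")
    pred = predict_records(model, geometries, records)
    obs = np.array([r.ln_gamma_obs for r in records])
    err = pred - obs
    ae, se = np.abs(err), err ** 2
    n = len(records)
    per_system = (pd.DataFrame({
        "system_key": [r.system_key for r in records],
        "abs_error": ae, "sq_error": se})
        .groupby("system_key")
        .agg(n_records=("abs_error", "size"), mae=("abs_error", "mean"),
             mse=("sq_error", "mean"))
        .reset_index())
    return {
        "MAE": float(ae.mean()),
        "MSE": float(se.mean()),
        "MAE_sem": float(ae.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0,
        "MSE_sem": float(se.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0,
        "n_records": n,
        "per_system": per_system,
    }


def select_hyperparameters(dataset: Dataset,
                           geometries: list[ComponentGeometry],
                           grid: list[dict], seed: int,
                           base_priors: PriorSpec | None = None,
                           method: str = "map",
                           **fit_kwargs) -> tuple[dict, list[dict]]:
    """Grid search: fit each configuration on the train split, score on
    the validation split, return the configuration with the smallest
    validation MAE (ties broken by smaller K, then smaller
    feature_scale). Failed fits are skipped with a log entry.

    Grid entries are dicts with any of the keys ``K``, ``feature_scale``,
    ``like_energy_scale``, ``likelihood_scale``.
    """
    base = base_priors or PriorSpec()
    if not dataset.subset("validation").records:
        raise ValueError("validation split is empty")
    fitter = fit_map if method == "map" else fit_vi
    results = []
    for config in grid:
        K = int(config.get("K", 4))
        priors = replace(base, **{k: v for k, v in config.items() if k != "K"})
        try:
            summary = fitter(dataset, priors, geometries, K, seed, **fit_kwargs)
            metrics = evaluate(summary, dataset, geometries, "validation")
        except Exception:
            logger.exception("grid point %r failed; skipping", config)
            continue
        results.append({"config": dict(config), "K": K,
                        "feature_scale": priors.feature_scale,
                        "validation_MAE": metrics["MAE"],
                        "summary": summary})
    if not results:
        raise RuntimeError("every grid point failed")
    results.sort(key=lambda r: (r["validation_MAE"], r["K"], r["feature_scale"]))
    return results[0]["config"], results


# ---------------------------------------------------------------------------
# Delimited-text interfaces
# ---------------------------------------------------------------------------

def write_observation_table(dataset: Dataset, path) -> None:
    """Columns: id_i, id_j, T_K, x_i, ln_gamma, record_type; infinite-
    dilution rows carry x_i = 0."""
    pd.DataFrame({
        "id_i": [r.id_i for r in dataset.records],
        "id_j": [r.id_j for r in dataset.records],
        "T_K": [r.T for r in dataset.records],
        "x_i": [r.x_i for r in dataset.records],
        "ln_gamma": [r.ln_gamma_obs for r in dataset.records],
        "record_type": [r.record_type for r in dataset.records],
    }).to_csv(path, index=False)


def read_observation_table(path) -> Dataset:
    df = pd.read_csv(path, dtype={"id_i": str, "id_j": str})
    records = [ObservationRecord(id_i=row.id_i, id_j=row.id_j,
                                 T=float(row.T_K), x_i=float(row.x_i),
                                 ln_gamma_obs=float(row.ln_gamma),
                                 record_type=row.record_type)
               for row in df.itertuples(index=False)]
    return Dataset(records)
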