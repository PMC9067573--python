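"""Low-rank completion of the symmetric pair-interaction energy matrix.

Each component i carries two latent feature vectors theta_i, beta_i of a
shared dimension K and a like energy U_ii. Unlike energies for *any* pair
— including pairs never observed together — are reconstructed as

    U_ij = theta_i . beta_j + theta_j . beta_i        (i != j)

which is symmetric under i <-> j by construction. The features are gauge
variables: (theta M, beta M^-T) gives the same energies for any invertible
K x K matrix M, so only the energies U_ij are comparable across fits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import SymmetricInteractionSet

__all__ = [
    "LatentFeatures",
    "predict_pair_energy",
    "assemble_interactions",
    "count_parameters",
    "read_feature_store",
    "write_feature_store",
    "write_pair_energy_table",
]


@dataclass
class LatentFeatures:
    """Per-component latent features and like energies.

    ``theta`` and ``beta`` are N x K arrays in units such that their dot
    products are J/mol; ``like_energies`` holds U_ii in J/mol.
    """

    component_ids: list[str]
    theta: np.ndarray
    beta: np.ndarray
    like_energies: np.ndarray

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        self.like_energies = np.asarray(self.like_energies, dtype=float)
        n = len(self.component_ids)
        if self.theta.ndim != 2 or self.theta.shape[0] != n:
            raise ValueError("theta must be N x K")
        if self.beta.shape != self.theta.shape:
            raise ValueError("theta and beta must share shape")
        if self.theta.shape[1] < 1:
            raise ValueError("latent dimension K must be >= 1")
        if self.like_energies.shape != (n,):
            raise ValueError("one like energy per component required")
        for arr in (self.theta, self.beta, self.like_energies):
            if not np.isfinite(arr).all():
                raise ValueError("latent features must be finite")
        self._index = {c: k for k, c in enumerate(self.component_ids)}
        if len(self._index) != n:
            raise ValueError("duplicate component ids")

    @property
    def K(self) -> int:
        return self.theta.shape[1]

    @property
    def n(self) -> int:
        return len(self.component_ids)

    def index(self, component_id: str) -> int:
        try:
            return self._index[component_id]
        except KeyError:
            raise KeyError(
                f"component {component_id!r} not in the trained roster "
                f"({self.n} components); cold-start prediction is unsupported"
            ) from None


def predict_pair_energy(features: LatentFeatures, id_i: str, id_j: str) -> float:
    """Unlike pair-interaction energy U_ij = theta_i.beta_j + theta_j.beta_i
    (J/mol); symmetric in its arguments by construction."""
    if id_i == id_j:
        raise ValueError("i = j: like energies live in features.like_energies")
    a, b = features.index(id_i), features.index(id_j)
    return float(features.theta[a] @ features.beta[b]
                 + features.theta[b] @ features.beta[a])


def assemble_interactions(features: LatentFeatures,
                          subset: list[str] | None = None) -> SymmetricInteractionSet:
    """Complete symmetric interaction matrix for ``subset`` (default: the
    whole roster): diagonal from the like energies, off-diagonal from the
    feature reconstruction. Works for pairs never co-observed."""
    ids = list(subset) if subset is not None else list(features.component_ids)
    if len(ids) < 2:
        raise ValueError("need at least two components")
    sel = np.array([features.index(c) for c in ids])
    th = features.theta[sel]
    be = features.beta[sel]
    U = th @ be.T + be @ th.T
    np.fill_diagonal(U, features.like_energies[sel])
    U = np.triu(U) + np.triu(U, 1).T  # exact bitwise symmetry
    return SymmetricInteractionSet(ids, U)


def count_parameters(n_components: int, n_observed_systems: int, mode: str) -> int:
    """Number of free interaction parameters of each parameterization.

    The conventional asymmetric scheme fits two difference parameters per
    observed binary system; the symmetric scheme needs one unlike energy
    per system plus one like energy per component.
    """
    if n_components < 0 or n_observed_systems < 0:
        raise ValueError("counts must be non-negative")
    if mode == "asymmetric":
        return 2 * n_observed_systems
    if mode == "symmetric":
        return n_observed_systems + n_components
    raise ValueError(f"mode must be 'symmetric' or 'asymmetric', got {mode!r}")


# ---------------------------------------------------------------------------
# Delimited-text interfaces
# ---------------------------------------------------------------------------

def write_feature_store(features: LatentFeatures, path) -> None:
    """One row per component: component_id, U_ii, theta_1..K, beta_1..K."""
    K = features.K
    data = {"component_id": features.component_ids,
            "U_ii": features.like_energies}
    for k in range(K):
        data[f"theta_{k + 1}"] = features.theta[:, k]
    for k in range(K):
        data[f"beta_{k + 1}"] = features.beta[:, k]
    pd.DataFrame(data).to_csv(path, index=False)


def read_feature_store(path) -> LatentFeatures:
    """Read a feature store; K is inferred from the header."""
    df = pd.read_csv(path, dtype={"component_id": str})
    theta_cols = sorted((c for c in df.columns if c.startswith("theta_")),
                        key=lambda c: int(c.split("_")[1]))
    beta_cols = sorted((c for c in df.columns if c.startswith("beta_")),
                       key=lambda c: int(c.split("_")[1]))
    if not theta_cols or len(theta_cols) != len(beta_cols):
        raise ValueError("feature store needs matching theta_k/beta_k columns")
    return LatentFeatures(
        component_ids=list(df["component_id"]),
        theta=df[theta_cols].to_numpy(),
        beta=df[beta_cols].to_numpy(),
        like_energies=df["U_ii"].to_numpy(),
    )


def write_pair_energy_table(path, component_ids: list[str],
                            U_mean: np.ndarray,
                            U_sd: np.ndarray | None = None) -> None:
    """Export pair energies (i <= j including the diagonal) with optional
    posterior standard deviations; the sd column is blank for point
    estimates."""
    ids = list(component_ids)
    rows = []
    for a, i in enumerate(ids):
        for b in range(a, len(ids)):
            sd = "" if U_sd is None else U_sd[a, b]
            rows.append((i, ids[b], U_mean[a, b], sd))
    pd.DataFrame(rows, columns=["id_i", "id_j", "U_mean", "U_sd"]).to_csv(
        path, index=False)
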