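"""Exact UNIQUAC activity-coefficient engine.

Implements the UNIversal QUAsi-Chemical Gibbs-excess-energy model for
binary and multicomponent liquid mixtures under two parameterizations of
the lattice pair-interaction energies:

* the *symmetric* one, where every pair of components (i, j) carries like
  energies ``U_ii``, ``U_jj`` and a single unlike energy ``U_ij = U_ji``
  (all J/mol), as the lattice derivation demands; and
* the *asymmetric* one conventional in the fitting literature, with two
  independent parameters per unordered pair,
  ``dU_ij = U_ij - U_jj`` and ``dU_ji = U_ij - U_ii``.

The model splits ln gamma into a combinatorial (size/shape) part driven by
the van der Waals volume and surface parameters (r_i, q_i) and a residual
(energetic) part driven by Boltzmann factors
``tau_ij = exp(-(U_ij - U_jj)/(R T))``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import R_GAS, TAU_EXPONENT_CLIP, Z_COORDINATION

logger = logging.getLogger(__name__)

__all__ = [
    "ComponentGeometry",
    "SymmetricInteractionSet",
    "AsymmetricInteractionSet",
    "MixtureState",
    "ConsistencyReport",
    "tau_matrix",
    "ln_gamma",
    "ln_gamma_inf",
    "delta_from_symmetric",
    "check_delta_consistency",
    "read_geometry_table",
    "write_geometry_table",
    "read_interaction_table",
    "write_interaction_table",
]


@dataclass(frozen=True)
class ComponentGeometry:
    """Pure-component UNIQUAC geometric parameters.

    Parameters
    ----------
    component_id
        Opaque identifier, unique within a roster.
    r
        Dimensionless van der Waals volume parameter, > 0.
    q
        Dimensionless van der Waals surface parameter, > 0.
    """

    component_id: str
    r: float
    q: float
    name: str = ""

    def __post_init__(self) -> None:
        if not (self.r > 0 and np.isfinite(self.r)):
            raise ValueError(f"r must be finite and > 0, got {self.r}")
        if not (self.q > 0 and np.isfinite(self.q)):
            raise ValueError(f"q must be finite and > 0, got {self.q}")


class SymmetricInteractionSet:
    """Symmetric lattice pair-interaction energies, J/mol.

    The diagonal holds the like energies ``U_ii``; off-diagonal entries are
    the unlike energies with the physical constraint ``U_ij = U_ji``
    enforced exactly (bitwise) at construction.
    """

    def __init__(self, component_ids: list[str], U: np.ndarray):
        U = np.asarray(U, dtype=float)
        n = len(component_ids)
        if U.shape != (n, n):
            raise ValueError(f"U must be {n}x{n}, got {U.shape}")
        if not np.isfinite(U).all():
            raise ValueError("all interaction energies must be finite")
        if not np.array_equal(U, U.T):
            raise ValueError("U must be exactly symmetric; build via from_pairs "
                             "or symmetrize explicitly before construction")
        if len(set(component_ids)) != n:
            raise ValueError("duplicate component ids")
        self.component_ids = list(component_ids)
        self.U = U
        self._index = {c: k for k, c in enumerate(self.component_ids)}

    @classmethod
    def from_pairs(cls, like: dict[str, float],
                   unlike: dict[tuple[str, str], float]) -> "SymmetricInteractionSet":
        """Build from per-component like energies and unordered-pair unlike
        energies; symmetry holds by construction."""
        ids = list(like)
        idx = {c: k for k, c in enumerate(ids)}
        U = np.zeros((len(ids), len(ids)))
        for c, u in like.items():
            U[idx[c], idx[c]] = u
        for (i, j), u in unlike.items():
            U[idx[i], idx[j]] = u
            U[idx[j], idx[i]] = u
        return cls(ids, U)

    def index(self, component_id: str) -> int:
        try:
            return self._index[component_id]
        except KeyError:
            raise KeyError(f"component {component_id!r} not in interaction set") from None

    def subset(self, ids: list[str]) -> "SymmetricInteractionSet":
        sel = [self.index(c) for c in ids]
        return SymmetricInteractionSet(list(ids), self.U[np.ix_(sel, sel)])

    def energy(self, id_i: str, id_j: str) -> float:
        return float(self.U[self.index(id_i), self.index(id_j)])

    @property
    def n(self) -> int:
        return len(self.component_ids)


class AsymmetricInteractionSet:
    """Conventional two-parameters-per-system UNIQUAC energies, J/mol.

    Stores, for every ordered pair (i, j) with i != j, the difference
    parameter ``dU_ij = U_ij - U_jj``. No symmetry is required.
    """

    def __init__(self, component_ids: list[str],
                 dU: dict[tuple[str, str], float]):
        if len(set(component_ids)) != len(component_ids):
            raise ValueError("duplicate component ids")
        for (i, j), v in dU.items():
            if i == j:
                raise ValueError(f"dU defined only for i != j, got ({i}, {j})")
            if not np.isfinite(v):
                raise ValueError(f"dU[{i},{j}] not finite")
        self.component_ids = list(component_ids)
        self.dU = dict(dU)
        self._index = {c: k for k, c in enumerate(self.component_ids)}

    def index(self, component_id: str) -> int:
        try:
            return self._index[component_id]
        except KeyError:
            raise KeyError(f"component {component_id!r} not in interaction set") from None

    def delta(self, id_i: str, id_j: str) -> float:
        return self.dU[(id_i, id_j)]

    def subset(self, ids: list[str]) -> "AsymmetricInteractionSet":
        sel = {(i, j): v for (i, j), v in self.dU.items()
               if i in ids and j in ids}
        missing = [(i, j) for i in ids for j in ids
                   if i != j and (i, j) not in sel]
        if missing:
            raise KeyError(f"missing ordered pairs {missing[:4]}")
        return AsymmetricInteractionSet(list(ids), sel)

    def delta_matrix(self, ids: list[str]) -> np.ndarray:
        """Dense dU matrix over ``ids`` (zero diagonal); KeyError on a
        missing ordered pair."""
        n = len(ids)
        D = np.zeros((n, n))
        for a, i in enumerate(ids):
            for b, j in enumerate(ids):
                if a != b:
                    D[a, b] = self.dU[(i, j)]
        return D

    @property
    def n(self) -> int:
        return len(self.component_ids)


@dataclass(frozen=True)
class MixtureState:
    """Liquid composition and temperature of an n >= 2 mixture."""

    component_ids: tuple[str, ...]
    x: np.ndarray
    T: float

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        object.__setattr__(self, "x", x)
        if len(self.component_ids) < 2:
            raise ValueError("a mixture needs at least two components")
        if x.shape != (len(self.component_ids),):
            raise ValueError("x must have one entry per component")
        if (x < 0).any():
            raise ValueError("mole fractions must be non-negative")
        if abs(x.sum() - 1.0) > 1e-12:
            raise ValueError(f"mole fractions must sum to 1, got {x.sum()!r}")
        if not self.T > 0:
            raise ValueError("temperature must be positive (Kelvin)")


def _geometry_arrays(geometries: list[ComponentGeometry],
                     ids: list[str] | tuple[str, ...]) -> tuple[np.ndarray, np.ndarray]:
    by_id = {g.component_id: g for g in geometries}
    try:
        r = np.array([by_id[c].r for c in ids])
        q = np.array([by_id[c].q for c in ids])
    except KeyError as exc:
        raise KeyError(f"no geometry for component {exc.args[0]!r}") from None
    return r, q


def _clipped_exp(exponent: np.ndarray) -> np.ndarray:
    clipped = np.clip(exponent, -TAU_EXPONENT_CLIP, TAU_EXPONENT_CLIP)
    if np.any(clipped != exponent):
        logger.warning("tau exponent clipped to +/-%g (max |exponent| = %.3g)",
                       TAU_EXPONENT_CLIP, float(np.max(np.abs(exponent))))
    return np.exp(clipped)


def tau_matrix(interactions: SymmetricInteractionSet | AsymmetricInteractionSet,
               T: float,
               ids: list[str] | tuple[str, ...] | None = None) -> np.ndarray:
    """Boltzmann-factor matrix ``tau_ij = exp(-(U_ij - U_jj)/(R T))``.

    For the asymmetric parameterization this is ``exp(-dU_ij/(R T))``.
    The diagonal is exactly 1. Exponents are clipped (with a logged
    warning) to avoid overflow during optimizer excursions.
    """
    if not T > 0:
        raise ValueError("temperature must be positive (Kelvin)")
    ids = list(ids) if ids is not None else list(interactions.component_ids)
    if isinstance(interactions, SymmetricInteractionSet):
        sel = [interactions.index(c) for c in ids]
        U = interactions.U[np.ix_(sel, sel)]
        dU = U - np.diag(U)[None, :]  # dU_ij = U_ij - U_jj
    else:
        dU = interactions.delta_matrix(ids)
    tau = _clipped_exp(-dU / (R_GAS * T))
    np.fill_diagonal(tau, 1.0)
    return tau


def ln_gamma(geometries: list[ComponentGeometry],
             interactions: SymmetricInteractionSet | AsymmetricInteractionSet,
             state: MixtureState) -> np.ndarray:
    """Activity coefficients ln gamma_i for every component of ``state``.

    Combinatorial part (Stavermann–Guggenheim):

        Phi_i   = r_i x_i / sum_j r_j x_j        (volume fraction)
        theta_i = q_i x_i / sum_j q_j x_j        (surface fraction)
        l_i     = (z/2)(r_i - q_i) - (r_i - 1)
        ln gC_i = ln(Phi_i/x_i) + (z/2) q_i ln(theta_i/Phi_i)
                  + l_i - (Phi_i/x_i) sum_j x_j l_j

    Residual part:

        ln gR_i = q_i [1 - ln(sum_j theta_j tau_ji)
                        - sum_j theta_j tau_ij / (sum_k theta_k tau_kj)]

    Compositions must be strictly inside (0, 1); the infinite-dilution
    boundary has its own closed form, :func:`ln_gamma_inf`.
    """
    x = state.x
    if (x <= 0).any() or (x >= 1).any():
        raise ValueError(
            "ln_gamma requires mole fractions strictly in (0, 1); "
            "use ln_gamma_inf for the infinite-dilution boundary")
    r, q = _geometry_arrays(geometries, state.component_ids)
    tau = tau_matrix(interactions, state.T, state.component_ids)

    phi_over_x = r / (r @ x)          # Phi_i / x_i
    phi = phi_over_x * x
    theta = q * x / (q @ x)
    l = 0.5 * Z_COORDINATION * (r - q) - (r - 1.0)
    ln_gc = (np.log(phi_over_x)
             + 0.5 * Z_COORDINATION * q * np.log(theta / phi)
             + l - phi_over_x * (x @ l))

    s = theta @ tau           # s_j = sum_k theta_k tau_kj
    ln_gr = q * (1.0 - np.log(s) - (tau * (theta / s)[None, :]).sum(axis=1))
    return ln_gc + ln_gr


def ln_gamma_inf(geometries: list[ComponentGeometry],
                 interactions: SymmetricInteractionSet | AsymmetricInteractionSet,
                 solute_id: str, solvent_id: str, T: float) -> float:
    """Closed-form infinite-dilution ln gamma of ``solute_id`` in
    ``solvent_id`` at temperature ``T`` (K).

    This is the x_solute -> 0 limit of the binary :func:`ln_gamma`:

        ln gC_inf = ln(r1/r2) + (z/2) q1 ln(q1 r2 / (q2 r1))
                    + l1 - (r1/r2) l2
        ln gR_inf = q1 [1 - ln(tau21) - tau12]
    """
    if solute_id == solvent_id:
        raise ValueError("solute and solvent must differ")
    r, q = _geometry_arrays(geometries, (solute_id, solvent_id))
    tau = tau_matrix(interactions, T, (solute_id, solvent_id))
    r1, r2 = r
    q1, q2 = q
    l = 0.5 * Z_COORDINATION * (r - q) - (r - 1.0)
    ln_gc = (np.log(r1 / r2) + 0.5 * Z_COORDINATION * q1 * np.log(q1 * r2 / (q2 * r1))
             + l[0] - (r1 / r2) * l[1])
    ln_gr = q1 * (1.0 - np.log(tau[1, 0]) - tau[0, 1])
    return float(ln_gc + ln_gr)


def delta_from_symmetric(interactions: SymmetricInteractionSet) -> AsymmetricInteractionSet:
    """Convert symmetric energies to the conventional difference
    parameterization: ``dU_ij = U_ij - U_jj`` for every ordered pair."""
    ids = interactions.component_ids
    U = interactions.U
    dU = {}
    for a, i in enumerate(ids):
        for b, j in enumerate(ids):
            if a != b:
                dU[(i, j)] = float(U[a, b] - U[b, b])
    return AsymmetricInteractionSet(ids, dU)


@dataclass
class ConsistencyReport:
    """Outcome of reconciling difference parameters with a symmetric set."""

    consistent: bool
    best_fit_U: SymmetricInteractionSet | None
    residuals: np.ndarray
    max_residual: float
    note: str = ""


def check_delta_consistency(asym: AsymmetricInteractionSet,
                            tol: float = 1e-6) -> ConsistencyReport:
    """Test whether independently fitted difference parameters can come
    from a single symmetric energy matrix.

    Solves the overdetermined linear system ``dU_ij = U_ij - U_jj``,
    ``dU_ji = U_ij - U_ii`` for the N like energies and the unlike
    energies of the pairs present, in least squares. Consistent iff the
    maximum absolute residual is below ``tol`` (J/mol). With fewer than
    three components, or with pairs missing, the system is underdetermined
    and reported as trivially consistent.
    """
    ids = asym.component_ids
    n = len(ids)
    pairs = sorted({tuple(sorted((i, j))) for (i, j) in asym.dU})
    have_both = all((i, j) in asym.dU and (j, i) in asym.dU for i, j in pairs)
    complete = len(pairs) == n * (n - 1) // 2 and have_both
    if n < 3 or not complete:
        return ConsistencyReport(
            consistent=True, best_fit_U=None, residuals=np.zeros(0),
            max_residual=0.0,
            note="underdetermined system (N < 3 or missing pairs); "
                 "trivially consistent")

    # unknowns: U_ii (n of them) then U_ij per unordered pair
    pair_index = {p: n + k for k, p in enumerate(pairs)}
    idx = {c: k for k, c in enumerate(ids)}
    n_unknown = n + len(pairs)
    rows, rhs = [], []
    for (i, j) in pairs:
        for solvent, d in ((j, asym.dU[(i, j)]), (i, asym.dU[(j, i)])):
            row = np.zeros(n_unknown)
            row[pair_index[(i, j)]] = 1.0
            row[idx[solvent]] = -1.0
            rows.append(row)
            rhs.append(d)
    A = np.array(rows)
    b = np.array(rhs)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    residuals = A @ sol - b
    max_resid = float(np.max(np.abs(residuals))) if residuals.size else 0.0

    U = np.zeros((n, n))
    np.fill_diagonal(U, sol[:n])
    for (i, j), k in pair_index.items():
        U[idx[i], idx[j]] = sol[k]
        U[idx[j], idx[i]] = sol[k]
    return ConsistencyReport(
        consistent=max_resid < tol,
        best_fit_U=SymmetricInteractionSet(ids, U),
        residuals=residuals,
        max_residual=max_resid)


# ---------------------------------------------------------------------------
# Delimited-text interfaces
# ---------------------------------------------------------------------------

def read_geometry_table(path) -> list[ComponentGeometry]:
    """Read a geometry table (columns: component_id, name, r, q)."""
    df = pd.read_csv(path, dtype={"component_id": str, "name": str})
    required = {"component_id", "r", "q"}
    if not required.issubset(df.columns):
        raise ValueError(f"geometry table needs columns {sorted(required)}")
    return [ComponentGeometry(component_id=row.component_id,
                              r=float(row.r), q=float(row.q),
                              name=getattr(row, "name_", "") or "")
            for row in df.rename(columns={"name": "name_"}).itertuples(index=False)]


def write_geometry_table(geometries: list[ComponentGeometry], path) -> None:
    pd.DataFrame({
        "component_id": [g.component_id for g in geometries],
        "name": [g.name for g in geometries],
        "r": [g.r for g in geometries],
        "q": [g.q for g in geometries],
    }).to_csv(path, index=False)


def write_interaction_table(interactions: SymmetricInteractionSet, path) -> None:
    """Export as rows id_i, id_j, U_ij (J/mol) for i <= j, diagonal included."""
    ids = interactions.component_ids
    rows = []
    for a, i in enumerate(ids):
        for b in range(a, len(ids)):
            rows.append((i, ids[b], interactions.U[a, b]))
    pd.DataFrame(rows, columns=["id_i", "id_j", "U_ij"]).to_csv(path, index=False)


def read_interaction_table(path) -> SymmetricInteractionSet:
    """Reconstruct a symmetric set from an i <= j pair listing; conflicting
    duplicate entries are an error."""
    df = pd.read_csv(path, dtype={"id_i": str, "id_j": str})
    like: dict[str, float] = {}
    unlike: dict[tuple[str, str], float] = {}
    for row in df.itertuples(index=False):
        i, j, u = row.id_i, row.id_j, float(row.U_ij)
        if i == j:
            if i in like and like[i] != u:
                raise ValueError(f"conflicting duplicate for U_{i}{i}")
            like[i] = u
        else:
            key = tuple(sorted((i, j)))
            if key in unlike and unlike[key] != u:
                raise ValueError(f"conflicting duplicate for pair {key}")
            unlike[key] = u
    missing = {c for pair in unlike for c in pair} - set(like)
    if missing:
        raise ValueError(f"missing diagonal entries for {sorted(missing)}")
    return SymmetricInteractionSet.from_pairs(like, unlike)
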