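"""Vapor-liquid equilibrium from activity coefficients.

Phase equilibrium is computed with the extended Raoult's law

    y_i P = x_i gamma_i(T, x) p_i^s(T),

i.e. an ideal vapor phase with all liquid non-ideality carried by the
activity coefficients; no Poynting or fugacity corrections. Pure-
component vapor pressures come from Antoine correlations in the
log10 / kPa / K dialect:  log10(p_s/kPa) = A - B/(T/K + C).

Temperature root-solves bracket on [150, 700] K and bisect (brentq) to
1e-8 K; everything is deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.optimize

from .core import (AsymmetricInteractionSet, ComponentGeometry, MixtureState,
                   SymmetricInteractionSet, ln_gamma)

logger = logging.getLogger(__name__)

__all__ = [
    "AntoineParameters",
    "BinaryVLEPoint",
    "TernaryVLEPoint",
    "vapor_pressure",
    "boiling_temperature",
    "bubble_point_T",
    "dew_point_T",
    "isobaric_diagram",
    "find_azeotrope",
    "predict_ternary_vapor",
    "read_antoine_table",
    "write_antoine_table",
    "write_binary_diagram",
]

T_BRACKET = (150.0, 700.0)
ANTOINE_DIALECT = "# Antoine dialect: log10(p_s/kPa) = A - B/(T_K + C)"


@dataclass(frozen=True)
class AntoineParameters:
    """Antoine coefficients, log10/kPa/K dialect, with validity range."""

    component_id: str
    A: float
    B: float
    C: float
    T_min: float
    T_max: float

    def __post_init__(self) -> None:
        if not self.T_min < self.T_max:
            raise ValueError("T_min must be below T_max")


@dataclass(frozen=True)
class BinaryVLEPoint:
    P: float
    T: float
    x1: float
    y1: float


@dataclass(frozen=True)
class TernaryVLEPoint:
    P: float
    T: float
    x: tuple[float, float, float]
    y: tuple[float, float, float]


def vapor_pressure(antoine: AntoineParameters, T: float) -> float:
    """Saturation pressure p_s(T) in kPa; warns (but evaluates) outside
    the stated validity range."""
    if T + antoine.C <= 0:
        raise ValueError(f"T + C = {T + antoine.C} <= 0 for "
                         f"{antoine.component_id}: Antoine form undefined")
    if not antoine.T_min <= T <= antoine.T_max:
        logger.warning("T = %.2f K outside Antoine validity [%.2f, %.2f] "
                       "for %s", T, antoine.T_min, antoine.T_max,
                       antoine.component_id)
    return float(10.0 ** (antoine.A - antoine.B / (T + antoine.C)))


def boiling_temperature(antoine: AntoineParameters, P: float,
                        bracket: tuple[float, float] = T_BRACKET) -> float:
    """Invert the Antoine correlation: the T with p_s(T) = P."""
    lo, hi = bracket
    lo = max(lo, -antoine.C + 1e-6)

    def f(T):
        return vapor_pressure(antoine, T) - P

    if f(lo) * f(hi) > 0:
        raise ValueError(f"no boiling point of {antoine.component_id} at "
                         f"{P} kPa inside [{lo}, {hi}] K")
    return float(scipy.optimize.brentq(f, lo, hi, xtol=1e-10))


class _GammaModel:
    """Uniform activity-coefficient callable over a fixed component list.

    Accepts a SymmetricInteractionSet, anything with an
    ``interactions(subset)`` method (a trained posterior summary), a
    LatentFeatures object, or None (ideal mixture, gamma = 1).
    """

    def __init__(self, model, geometries: list[ComponentGeometry],
                 component_ids: list[str]):
        self.ids = list(component_ids)
        self.geometries = geometries
        if model is None:
            self.interactions = None
        elif isinstance(model, (SymmetricInteractionSet,
                                AsymmetricInteractionSet)):
            self.interactions = model.subset(self.ids)
        elif hasattr(model, "interactions"):
            self.interactions = model.interactions(self.ids)
        else:
            from .factorization import LatentFeatures, assemble_interactions
            if isinstance(model, LatentFeatures):
                self.interactions = assemble_interactions(model, self.ids)
            else:
                raise TypeError(f"cannot build gamma model from "
                                f"{type(model).__name__}")

    def gamma(self, T: float, x: np.ndarray) -> np.ndarray:
        if self.interactions is None:
            return np.ones(len(x))
        if len(x) == 1:
            return np.ones(1)
        state = MixtureState(tuple(self.ids_active), np.asarray(x), T)
        return np.exp(ln_gamma(self.geometries, self.interactions_active, state))

    def restrict(self, mask: np.ndarray) -> None:
        """Restrict evaluation to the components with mask True (used to
        drop exact-zero mole fractions on simplex edges)."""
        self.ids_active = [c for c, m in zip(self.ids, mask) if m]
        if self.interactions is None:
            self.interactions_active = None
        else:
            self.interactions_active = self.interactions.subset(self.ids_active)


def _prepare(x, model, geometries, component_ids, antoine_set):
    x = np.asarray(x, dtype=float)
    if abs(x.sum() - 1.0) > 1e-10 or (x < 0).any():
        raise ValueError("composition must lie on the simplex")
    by_id = {a.component_id: a for a in antoine_set}
    antoine = [by_id[c] for c in component_ids]
    gm = _GammaModel(model, geometries, component_ids)
    return x, antoine, gm


def bubble_point_T(P: float, x, component_ids: list[str], model,
                   geometries: list[ComponentGeometry],
                   antoine_set: list[AntoineParameters],
                   bracket: tuple[float, float] = T_BRACKET
                   ) -> tuple[float, np.ndarray]:
    """Bubble-point temperature and incipient vapor composition at fixed
    pressure ``P`` (kPa) and liquid composition ``x``.

    Solves ``sum_i x_i gamma_i(T, x) p_i^s(T) = P`` for T by bracketed
    bisection, then ``y_i = x_i gamma_i p_i^s / P``. Components with
    exactly zero mole fraction are dropped from the mixture (so simplex
    edges and vertices reduce to the lower-order problem).
    """
    if P <= 0:
        raise ValueError("pressure must be positive")
    x, antoine, gm = _prepare(x, model, geometries, component_ids, antoine_set)
    active = x > 0.0
    gm.restrict(active)
    xa = x[active]
    ant_a = [a for a, m in zip(antoine, active) if m]

    def total_pressure(T):
        gamma = gm.gamma(T, xa)
        ps = np.array([vapor_pressure(a, T) for a in ant_a])
        return float((xa * gamma * ps).sum())

    lo, hi = bracket
    lo = max([lo] + [-a.C + 1e-6 for a in ant_a])
    f_lo, f_hi = total_pressure(lo) - P, total_pressure(hi) - P
    if f_lo * f_hi > 0:
        raise ValueError(f"no bubble point in [{lo}, {hi}] K at {P} kPa")
    T = float(scipy.optimize.brentq(
        lambda t: total_pressure(t) - P, lo, hi, xtol=1e-8))
    gamma = gm.gamma(T, xa)
    ps = np.array([vapor_pressure(a, T) for a in ant_a])
    y = np.zeros_like(x)
    y[active] = xa * gamma * ps / P
    y /= y.sum()                      # |1 - sum| < 1e-8 by the root solve
    return T, y


def dew_point_T(P: float, y, component_ids: list[str], model,
                geometries: list[ComponentGeometry],
                antoine_set: list[AntoineParameters],
                bracket: tuple[float, float] = T_BRACKET,
                max_inner: int = 200, inner_tol: float = 1e-12
                ) -> tuple[float, np.ndarray]:
    """Dew-point temperature and incipient liquid composition.

    For each trial T the liquid composition solves the fixed point
    ``x_i proportional to y_i P / (gamma_i(T, x) p_i^s(T))``; the outer
    bisection drives ``sum_i y_i P / (gamma_i p_i^s)`` to 1.
    """
    if P <= 0:
        raise ValueError("pressure must be positive")
    y, antoine, gm = _prepare(y, model, geometries, component_ids, antoine_set)
    active = y > 0.0
    gm.restrict(active)
    ya = y[active]
    ant_a = [a for a, m in zip(antoine, active) if m]

    def liquid_and_sum(T):
        ps = np.array([vapor_pressure(a, T) for a in ant_a])
        xa = ya.copy()
        for _ in range(max_inner):
            gamma = gm.gamma(T, xa)
            raw = ya * P / (gamma * ps)
            new = raw / raw.sum()
            if np.max(np.abs(new - xa)) < inner_tol:
                xa = new
                break
            xa = new
        else:
            raise RuntimeError(f"dew-point inner iteration did not converge "
                               f"at T = {T:.3f} K; last x = {xa}")
        gamma = gm.gamma(T, xa)
        return xa, float((ya * P / (gamma * ps)).sum())

    lo, hi = bracket
    lo = max([lo] + [-a.C + 1e-6 for a in ant_a])
    f_lo = liquid_and_sum(lo)[1] - 1.0
    f_hi = liquid_and_sum(hi)[1] - 1.0
    if f_lo * f_hi > 0:
        raise ValueError(f"no dew point in [{lo}, {hi}] K at {P} kPa")
    T = float(scipy.optimize.brentq(
        lambda t: liquid_and_sum(t)[1] - 1.0, lo, hi, xtol=1e-8))
    xa, _ = liquid_and_sum(T)
    x = np.zeros_like(y)
    x[active] = xa
    return T, x


def isobaric_diagram(P: float, component_ids: list[str], model,
                     geometries: list[ComponentGeometry],
                     antoine_set: list[AntoineParameters],
                     n_grid: int = 101) -> pd.DataFrame:
    """Binary T-x-y diagram at fixed pressure: bubble and dew curves on a
    uniform composition grid including the pure endpoints. Grid points
    where the solver fails are omitted with a logged warning.

    Returns a DataFrame with columns P_kPa, x1, T_bubble_K, y1_at_bubble,
    T_dew_K (the dew curve is evaluated at vapor fraction y1 = the grid
    value).
    """
    if len(component_ids) != 2:
        raise ValueError("isobaric_diagram is for binary systems")
    rows = []
    for z in np.linspace(0.0, 1.0, n_grid):
        row = {"P_kPa": P, "x1": z, "T_bubble_K": np.nan,
               "y1_at_bubble": np.nan, "T_dew_K": np.nan}
        try:
            Tb, y = bubble_point_T(P, [z, 1.0 - z], component_ids, model,
                                   geometries, antoine_set)
            row["T_bubble_K"] = Tb
            row["y1_at_bubble"] = y[0]
        except Exception as exc:
            logger.warning("bubble point failed at x1 = %.3f: %s", z, exc)
        try:
            Td, _ = dew_point_T(P, [z, 1.0 - z], component_ids, model,
                                geometries, antoine_set)
            row["T_dew_K"] = Td
        except Exception as exc:
            logger.warning("dew point failed at y1 = %.3f: %s", z, exc)
        rows.append(row)
    return pd.DataFrame(rows)


def find_azeotrope(P: float, component_ids: list[str], model,
                   geometries: list[ComponentGeometry],
                   antoine_set: list[AntoineParameters],
                   n_grid: int = 51) -> dict:
    """Locate an azeotrope of a binary system at fixed pressure: an
    interior composition with y1 = x1, found from a sign change of
    y1 - x1 on a grid refined by bisection."""
    if len(component_ids) != 2:
        raise ValueError("find_azeotrope is for binary systems")

    def deviation(x1):
        _, y = bubble_point_T(P, [x1, 1.0 - x1], component_ids, model,
                              geometries, antoine_set)
        return y[0] - x1

    grid = np.linspace(0.0, 1.0, n_grid)[1:-1]
    vals = np.array([deviation(z) for z in grid])
    # a grid point sitting exactly on the root (e.g. the x = 0.5 of a
    # perfectly symmetric system) counts as a crossing
    on_root = np.where(np.abs(vals) < 1e-12)[0]
    if len(on_root):
        x1 = float(grid[on_root[0]])
    else:
        sign_change = np.where(np.sign(vals[:-1]) * np.sign(vals[1:]) < 0)[0]
        if len(sign_change) == 0:
            return {"exists": False, "x1": None, "T": None}
        k = int(sign_change[0])
        x1 = float(scipy.optimize.brentq(deviation, grid[k], grid[k + 1],
                                         xtol=1e-10))
    T, _ = bubble_point_T(P, [x1, 1.0 - x1], component_ids, model,
                          geometries, antoine_set)
    return {"exists": True, "x1": x1, "T": T}


def predict_ternary_vapor(P: float, x, component_ids: list[str], model,
                          geometries: list[ComponentGeometry],
                          antoine_set: list[AntoineParameters]) -> TernaryVLEPoint:
    """Given pressure and a ternary liquid composition, predict the
    equilibrium temperature and vapor composition (bubble-point solve
    with n = 3)."""
    if len(component_ids) != 3:
        raise ValueError("predict_ternary_vapor is for ternary systems")
    T, y = bubble_point_T(P, x, component_ids, model, geometries, antoine_set)
    x = np.asarray(x, dtype=float)
    return TernaryVLEPoint(P=P, T=T, x=tuple(x), y=tuple(y))


# ---------------------------------------------------------------------------
# Delimited-text interfaces
# ---------------------------------------------------------------------------

def write_antoine_table(antoine_set: list[AntoineParameters], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(ANTOINE_DIALECT + "\n")
        pd.DataFrame({
            "component_id": [a.component_id for a in antoine_set],
            "A": [a.A for a in antoine_set],
            "B": [a.B for a in antoine_set],
            "C": [a.C for a in antoine_set],
            "T_min_K": [a.T_min for a in antoine_set],
            "T_max_K": [a.T_max for a in antoine_set],
        }).to_csv(fh, index=False)


def read_antoine_table(path) -> list[AntoineParameters]:
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
        if not first.startswith("#"):
            raise ValueError("Antoine table must start with a dialect "
                             "comment line (log10/kPa/K)")
        df = pd.read_csv(fh, dtype={"component_id": str})
    return [AntoineParameters(component_id=row.component_id,
                              A=float(row.A), B=float(row.B), C=float(row.C),
                              T_min=float(row.T_min_K), T_max=float(row.T_max_K))
            for row in df.itertuples(index=False)]


def write_binary_diagram(diagram: pd.DataFrame, path) -> None:
    diagram.to_csv(path, index=False)
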