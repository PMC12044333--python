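"""Two-component mass-action equilibrium for a cytokine and its binding protein.

Serum assays measure *total* IL-18 and *total* IL-18 binding protein
(IL-18BP), but only the unbound ("free") cytokine can engage the IL-18
receptor.  At equilibrium the three species — free IL-18, free IL-18BP and
the 1:1 complex — satisfy the law of mass action

    Kd = [free IL-18] * [free IL-18BP] / [complex]

together with the two conservation identities

    [total IL-18]   = [free IL-18]   + [complex]
    [total IL-18BP] = [free IL-18BP] + [complex].

Eliminating the complex gives a quadratic whose admissible root is

    free = ( -(BP - T + Kd) + sqrt((BP - T + Kd)^2 + 4*Kd*T) ) / 2

with T the total ligand and BP the total binding protein.  All
concentrations are in pmol/l; the default dissociation constant is
0.4 nM = 400 pmol/l, the literature value for the IL-18·IL-18BP complex.

In serum BP is typically 30–100x larger than T, so the subtraction in the
root above loses precision when evaluated literally.  When BP - T + Kd >= 0
the algebraically identical conjugate form 2*Kd*T / (b + sqrt(b^2 + 4*Kd*T))
is used instead, which is cancellation-free.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

__all__ = [
    "DEFAULT_KD_PMOL_L",
    "IL18_MOLAR_MASS_KDA",
    "EquilibriumState",
    "free_ligand",
    "free_ligand_numeric",
    "solve_equilibrium",
    "mass_to_molar",
    "FreeIL18Transformer",
]

#: Dissociation constant of the IL-18 / IL-18BP complex, pmol/l (0.4 nM).
DEFAULT_KD_PMOL_L: float = 400.0

#: Molar mass of IL-18, kDa.  Used to convert ELISA pg/ml readings to pmol/l.
IL18_MOLAR_MASS_KDA: float = 18.4


class ConcentrationError(ValueError):
    """Raised when a concentration or constant violates its domain."""


def _validate(name: str, value, *, positive: bool = False) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ConcentrationError(f"{name} must be finite, got {value!r}")
    if positive:
        if np.any(arr <= 0):
            raise ConcentrationError(f"{name} must be > 0, got {value!r}")
    elif np.any(arr < 0):
        raise ConcentrationError(f"{name} must be >= 0, got {value!r}")
    return arr


@dataclass(frozen=True)
class EquilibriumState:
    """Full species breakdown of the ligand / binding-protein equilibrium.

    All fields are concentrations in pmol/l (scalars or arrays, matching the
    input shape).  Conservation holds exactly up to floating point:
    ``free_ligand + complex == total`` and ``free_bp + complex == bp``.
    """

    free_ligand: float | np.ndarray
    free_bp: float | np.ndarray
    complex: float | np.ndarray


def free_ligand(total_ligand, binding_protein, kd: float = DEFAULT_KD_PMOL_L):
    """Free-ligand concentration (pmol/l) from totals, by mass action.

    Parameters
    ----------
    total_ligand : float or array-like
        Total (free + complexed) ligand, pmol/l. Must be >= 0 and finite.
    binding_protein : float or array-like
        Total binding protein, pmol/l. Must be >= 0 and finite.
    kd : float
        Dissociation constant of the complex, pmol/l (default 400 = 0.4 nM).

    Returns
    -------
    float or ndarray
        Free ligand in pmol/l, always within [max(0, T - BP), T].
    """
    t = _validate("total_ligand", total_ligand)
    bp = _validate("binding_protein", binding_protein)
    k = _validate("kd", kd, positive=True)
    out = _free_root(t, bp, np.asarray(k, dtype=float))
    if np.ndim(t) == 0 and np.ndim(bp) == 0:
        return float(out)
    return out


def _free_root(t, bp, k):
    """Admissible quadratic root, cancellation-free in both regimes."""
    b = bp - t + k
    disc = np.sqrt(b * b + 4.0 * k * t)
    with np.errstate(invalid="ignore", divide="ignore"):
        stable = np.where(b >= 0, 2.0 * k * t / (b + disc), 0.5 * (disc - b))
    return np.where((t == 0) | (disc + b == 0), 0.0, stable)


def solve_equilibrium(
    total_ligand, binding_protein, kd: float = DEFAULT_KD_PMOL_L
) -> EquilibriumState:
    """Solve for all three species: free ligand, free binding protein, complex.

    The free binding protein comes from the role-symmetric closed form and
    the complex from the Kd identity ``free * free_bp / kd``, so the mass-
    action ratio is exact by construction and both conservation identities
    (``free + complex == T``, ``free_bp + complex == BP``) hold to machine
    precision even when one species nearly vanishes.
    """
    t = _validate("total_ligand", total_ligand)
    bp = _validate("binding_protein", binding_protein)
    k = _validate("kd", kd, positive=True)
    free = _free_root(t, bp, k)
    free_bp = _free_root(bp, t, k)
    cplx = free * free_bp / k
    if np.ndim(t) == 0 and np.ndim(bp) == 0:
        return EquilibriumState(float(free), float(free_bp), float(cplx))
    return EquilibriumState(np.asarray(free), np.asarray(free_bp), np.asarray(cplx))


def free_ligand_numeric(
    total_ligand, binding_protein, kd: float = DEFAULT_KD_PMOL_L
):
    """Free ligand by bisection on the complex concentration.

    Independent of the closed form: solves f(c) = (T-c)(BP-c) - Kd*c = 0 for
    the complex c on [0, min(T, BP)] (f is strictly decreasing there),
    iterating until the bracket collapses to floating-point spacing — well
    inside 1e-12 * max(1, T) absolute — and returns T - c.  Exists as a
    verification oracle; the closed form is the production path.  ``kd`` may
    be an array broadcastable against the concentrations.
    """
    t = _validate("total_ligand", total_ligand)
    bp = _validate("binding_protein", binding_protein)
    k = _validate("kd", kd, positive=True)

    scalar = np.ndim(t) == 0 and np.ndim(bp) == 0 and np.ndim(k) == 0
    t, bp, k = np.atleast_1d(*np.broadcast_arrays(t, bp, k))

    lo = np.zeros_like(t)
    hi = np.minimum(t, bp)
    for _ in range(120):
        if np.all(hi - lo <= 2 * np.spacing(hi)):
            break
        mid = 0.5 * (lo + hi)
        f = (t - mid) * (bp - mid) - k * mid
        lo = np.where(f > 0, mid, lo)
        hi = np.where(f > 0, hi, mid)
    c = 0.5 * (lo + hi)
    free = t - c
    return float(free[0]) if scalar else free


def mass_to_molar(conc_pg_ml, molar_mass_kda: float = IL18_MOLAR_MASS_KDA):
    """Convert a mass concentration in pg/ml to pmol/l.

    pg/ml divided by kDa is pmol/l: 1 pg/ml = 1 ng/l, and 1 kDa = 1 ng/pmol.
    """
    c = _validate("conc_pg_ml", conc_pg_ml)
    m = _validate("molar_mass_kda", molar_mass_kda, positive=True)
    out = c / m
    return float(out) if np.ndim(out) == 0 else out


class FreeIL18Transformer(BaseEstimator, TransformerMixin):
    """Map (total IL-18, IL-18BP) columns to the equilibrium species.

    A stateless scikit-learn transformer: ``fit`` only validates, ``transform``
    takes an ``(n, 2)`` array with columns ``[total_il18, il18bp]`` in pmol/l
    and returns an ``(n, 3)`` array with columns
    ``[free_il18, free_il18bp, complex]``.

    Parameters
    ----------
    kd : float, default 400.0
        Dissociation constant in pmol/l.
    """

    def __init__(self, kd: float = DEFAULT_KD_PMOL_L):
        self.kd = kd

    def fit(self, X, y=None):
        X = check_array(X, ensure_min_features=2)
        if X.shape[1] != 2:
            raise ValueError(
                f"expected 2 columns [total_il18, il18bp], got {X.shape[1]}"
            )
        _validate("kd", self.kd, positive=True)
        self.n_features_in_ = 2
        return self

    def transform(self, X):
        check_is_fitted(self)
        X = check_array(X)
        if X.shape[1] != 2:
            raise ValueError(
                f"expected 2 columns [total_il18, il18bp], got {X.shape[1]}"
            )
        state = solve_equilibrium(X[:, 0], X[:, 1], self.kd)
        return np.column_stack([state.free_ligand, state.free_bp, state.complex])

    def get_feature_names_out(self, input_features=None):
        return np.asarray(["free_il18", "free_il18bp", "complex"], dtype=object)
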