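"""Three-state site-exposure kinetics of TF binding within a nucleosome.

The model (Polach & Widom site exposure) has three states:

* state 1 — nucleosome fully wrapped, binding site buried (high FRET);
* state 2 — nucleosome transiently unwrapped, site exposed but unbound;
* state 3 — TF bound to the exposed site (low FRET).

Transitions are 1 -> 2 (unwrapping, ``k12``), 2 -> 1 (rewrapping, ``k21``),
2 -> 3 (bimolecular binding, ``k23 * [TF]``) and 3 -> 2 (dissociation,
``k32``).  Concentrations are in nM and rates in 1/s throughout the package.

Because rewrapping is fast (k21 on the 100 /s scale) the intermediate state 2
is almost never occupied and the observable FRET dynamics collapse onto
effective two-state rates with closed forms::

    k_HL(c) = k12 / (1 + k12 / (kon_eff * c))      # high -> low
    k_LH(c) = k32 / (1 + kon_eff * c / k12)        # low  -> high

with ``kon_eff = (k12 / k21) * k23``, the site-exposure-limited on-rate.
Only the triple (k12, k32, kon_eff) is identifiable from rate-vs-concentration
data; k21 and k23 enter only through their ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm

__all__ = [
    "RateSet",
    "EffectiveParams",
    "StateDistribution",
    "SpectralSolution",
    "build_rate_matrix",
    "k_high_to_low",
    "k_low_to_high",
    "propagate_master_equation",
    "spectral_solution",
    "regime_metrics",
]

_KONEFF_RTOL = 1e-12


@dataclass(frozen=True)
class RateSet:
    """The four elementary rates of the three-state scheme.

    Parameters
    ----------
    k12, k21 : float
        Nucleosome unwrapping / rewrapping rates (1/s).
    k23 : float
        Bimolecular TF binding rate constant to the exposed site (1/nM/s).
    k32 : float
        TF dissociation rate from the nucleosomal site (1/s).
    """

    k12: float
    k21: float
    k23: float
    k32: float

    def __post_init__(self) -> None:
        for name in ("k12", "k21", "k23", "k32"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")

    @property
    def kon_eff(self) -> float:
        """Effective binding rate constant, (k12/k21)*k23 (1/nM/s)."""
        if self.k21 <= 0:
            raise ValueError("kon_eff undefined for k21 == 0")
        return self.k12 * self.k23 / self.k21

    @property
    def regime_valid(self) -> bool:
        """True iff unwrapping is slow relative to rewrapping (k12 < k21)."""
        return self.k12 < self.k21

    def effective(self) -> "EffectiveParams":
        return EffectiveParams(k12=self.k12, k32=self.k32, kon_eff=self.kon_eff)


@dataclass(frozen=True)
class EffectiveParams:
    """The identifiable triple recovered by global fits: (k12, k32, kon_eff)."""

    k12: float
    k32: float
    kon_eff: float

    def __post_init__(self) -> None:
        for name in ("k12", "k32", "kon_eff"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")

    def to_rateset(self, k21: float = 100.0) -> RateSet:
        """Expand to a full RateSet for a chosen (non-identifiable) k21."""
        if self.k12 <= 0:
            raise ValueError("k12 must be > 0 to expand to a RateSet")
        return RateSet(
            k12=self.k12, k21=k21, k23=self.kon_eff * k21 / self.k12, k32=self.k32
        )


@dataclass(frozen=True)
class StateDistribution:
    """Occupancy probabilities of states 1 (wrapped), 2 (exposed), 3 (bound)."""

    p1: float
    p2: float
    p3: float

    def __post_init__(self) -> None:
        p = self.as_array()
        if np.any(p < -1e-9) or np.any(p > 1 + 1e-9):
            raise ValueError(f"probabilities must lie in [0, 1], got {p}")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"probabilities must sum to 1, got {p.sum()!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.p1, self.p2, self.p3], dtype=float)

    @staticmethod
    def from_array(p: np.ndarray) -> "StateDistribution":
        p = np.clip(np.asarray(p, dtype=float), 0.0, 1.0)
        return StateDistribution(*(p / p.sum()))


@dataclass(frozen=True)
class SpectralSolution:
    """Eigen-solution of the master equation dX/dt = R X.

    ``X(t) = C0 exp(l0 t) + Cm exp(lm t) + Cp exp(lp t)`` where the C_i are
    eigenvector contributions for a given initial condition and the
    eigenvalues are ordered ``Re(lm) <= Re(lp) <= l0 = 0``.
    """

    eigenvalues: tuple[float, float, float]  # (l0, lm, lp)
    coefficients: np.ndarray  # shape (3, 3): rows C0, Cm, Cp
    degenerate: bool = False

    def evaluate(self, t: float) -> np.ndarray:
        l0, lm, lp = self.eigenvalues
        lam = np.array([l0, lm, lp])
        return (self.coefficients * np.exp(lam * t)[:, None]).sum(axis=0)


def _validate_rates_conc(rates: RateSet, conc: float) -> None:
    if not isinstance(rates, RateSet):
        rates = RateSet(*rates)
    if conc < 0 or not np.isfinite(conc):
        raise ValueError(f"concentration must be finite and >= 0, got {conc}")


def build_rate_matrix(rates: RateSet, conc: float, variant: str = "full") -> np.ndarray:
    """Build the 3x3 generator matrix R (column convention, dX/dt = R X).

    ``variant="binding"`` zeroes k32 so state 3 absorbs (third column zero):
    the matrix whose slow relaxation is the high->low FRET transition rate.
    ``variant="release"`` zeroes k12 so state 1 absorbs (first column zero):
    its slow relaxation is the low->high rate.  ``variant="full"`` keeps all
    four rates; its columns sum to zero exactly.
    """
    _validate_rates_conc(rates, conc)
    b = rates.k23 * conc  # pseudo-first-order binding rate, 1/s
    if variant == "full":
        return np.array(
            [
                [-rates.k12, rates.k21, 0.0],
                [rates.k12, -(rates.k21 + b), rates.k32],
                [0.0, b, -rates.k32],
            ]
        )
    if variant == "binding":
        return np.array(
            [
                [-rates.k12, rates.k21, 0.0],
                [rates.k12, -(rates.k21 + b), 0.0],
                [0.0, b, 0.0],
            ]
        )
    if variant == "release":
        return np.array(
            [
                [0.0, rates.k21, 0.0],
                [0.0, -(rates.k21 + b), rates.k32],
                [0.0, b, -rates.k32],
            ]
        )
    raise ValueError(f"unknown variant {variant!r}")


def k_high_to_low(k12: float, kon_eff: float, conc) -> float | np.ndarray:
    """Closed-form high->low FRET transition rate, k12/(1 + k12/(kon_eff c)).

    Increases with concentration and saturates at k12 (unwrapping-limited).
    Returns 0 at zero concentration (the limit of the closed form).
    """
    if k12 < 0 or kon_eff < 0:
        raise ValueError("rates must be >= 0")
    c = np.asarray(conc, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be >= 0")
    with np.errstate(divide="ignore"):
        out = np.where(c > 0, k12 / (1.0 + k12 / np.where(c > 0, kon_eff * c, 1.0)), 0.0)
    return float(out) if np.isscalar(conc) else out


def k_low_to_high(k32: float, kon_eff: float, k12: float, conc) -> float | np.ndarray:
    """Closed-form low->high FRET transition rate, k32/(1 + kon_eff c / k12).

    Equals k32 at zero concentration and decays hyperbolically as the TF
    rebinds faster than the nucleosome can rewrap.
    """
    if k32 < 0 or kon_eff < 0 or k12 <= 0:
        raise ValueError("k32, kon_eff must be >= 0 and k12 > 0")
    c = np.asarray(conc, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be >= 0")
    out = k32 / (1.0 + kon_eff * c / k12)
    return float(out) if np.isscalar(conc) else out


def _is_generator_like(matrix: np.ndarray) -> bool:
    """Accept proper generators and the absorbing variants (a zero column)."""
    m = np.asarray(matrix, dtype=float)
    if m.shape != (3, 3):
        return False
    if np.any(m - np.diag(np.diag(m)) < -1e-12):
        return False  # negative off-diagonal
    colsums = m.sum(axis=0)
    return bool(np.all(np.abs(colsums) < 1e-9))


def propagate_master_equation(
    matrix: np.ndarray, x0: StateDistribution, t: float
) -> StateDistribution:
    """Propagate dX/dt = R X from x0 for time t (exact linear-ODE solution).

    Uses eigendecomposition; falls back to a scaling-and-squaring matrix
    exponential when the eigenbasis is ill-conditioned (near-defective R).
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    if not _is_generator_like(matrix):
        raise ValueError("matrix is not a valid generator (columns must sum to 0)")
    p0 = x0.as_array()
    if t == 0:
        return x0
    lam, vec = np.linalg.eig(matrix)
    cond = np.linalg.cond(vec)
    if np.isfinite(cond) and cond < 1e8:
        c = np.linalg.solve(vec, p0)
        p = (vec * np.exp(lam * t)) @ c
        p = np.real_if_close(p, tol=1e6)
    else:  # near-defective: robust matrix exponential
        p = expm(matrix * t) @ p0
    return StateDistribution.from_array(np.real(p))


def spectral_solution(
    matrix: np.ndarray, x0: StateDistribution | None = None
) -> SpectralSolution:
    """Eigen-solve the master equation for a given initial condition.

    The zero eigenvalue of the generator is snapped to exactly 0; the two
    relaxation eigenvalues are ordered so ``Re(lm) <= Re(lp) <= 0``.  For the
    binding variant in the fast-rewrapping regime, ``-lp`` approaches the
    closed-form k_high_to_low.
    """
    if not _is_generator_like(matrix):
        raise ValueError("matrix is not a valid generator (columns must sum to 0)")
    p0 = np.array([1.0, 0.0, 0.0]) if x0 is None else x0.as_array()
    lam, vec = np.linalg.eig(matrix)
    degenerate = False
    # snap the stationary eigenvalue to exactly zero
    i0 = int(np.argmin(np.abs(lam)))
    lam = lam.copy()
    lam[i0] = 0.0
    order = np.argsort(lam.real)  # most negative first
    rest = [i for i in order if i != i0]
    idx = [i0, rest[0], rest[1]]  # l0, lm, lp
    cond = np.linalg.cond(vec)
    if not np.isfinite(cond) or cond > 1e10:
        degenerate = True
    try:
        c = np.linalg.solve(vec, p0)
    except np.linalg.LinAlgError:
        degenerate = True
        c = np.linalg.lstsq(vec, p0, rcond=None)[0]
    coeff = np.real_if_close((vec * c[None, :]).T[idx, :], tol=1e6)
    return SpectralSolution(
        eigenvalues=tuple(float(np.real(lam[i])) for i in idx),
        coefficients=np.real(coeff),
        degenerate=degenerate,
    )


def regime_metrics(params: EffectiveParams) -> dict[str, float]:
    """Derived concentration-scale metrics of the kinetic regime.

    Returns
    -------
    dict with keys
        ``KD_eff`` — apparent dissociation constant of occupancy,
        k32/kon_eff (nM); comparable to the ensemble S1/2.
        ``c_cross`` — k12/kon_eff = k21/k23 (nM), the concentration above
        which binding to the exposed site outpaces rewrapping (the boundary
        between the outer- and inner-region kinetic regimes).
        ``regime_ratio`` — KD_eff/c_cross = k32/k12 (dimensionless); << 1
        means occupancy saturates well below the regime crossover.
    """
    if params.kon_eff <= 0:
        raise ValueError("kon_eff must be > 0")
    kd_eff = params.k32 / params.kon_eff
    c_cross = params.k12 / params.kon_eff
    ratio = params.k32 / params.k12 if params.k12 > 0 else float("inf")
    return {"KD_eff": kd_eff, "c_cross": c_cross, "regime_ratio": ratio}
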