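"""Relative free-energy profile of TF occupancy vs the unwrapping landscape.

Half-saturation concentrations (ensemble) or effective dissociation
constants KD_eff = k32/kon_eff (single-molecule) convert to relative binding
free energies::

    ddG_occupancy(i) = kBT * ln(v_i / v_ref)

taken relative to a reference construct.  Binding sites map onto the
DNA-unwrapping coordinate by assuming the DNA unwraps ``offset_bp`` (default
3) beyond the inner edge of the site.  The profile is then calibrated to a
reference position of an unwrapping free-energy landscape table and compared
by a two-sample Kolmogorov-Smirnov test (a paired sign-flip permutation test
is available as an alternative).  Energies are in kBT throughout;
``KBT_TO_KCAL_MOL`` converts at 298 K for output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "KBT_TO_KCAL_MOL",
    "ProfileEntry",
    "EnergyProfile",
    "LandscapeTable",
    "map_to_unwrap_coordinate",
    "ddg_profile",
    "compare_to_landscape",
    "synthetic_unwrapping_landscape",
    "read_landscape_table",
    "write_landscape_table",
]

KBT_TO_KCAL_MOL = 0.593  # kcal/mol per kBT at 298 K


@dataclass(frozen=True)
class ProfileEntry:
    label: str
    inner_edge_bp: int
    position_bp: int  # mapped unwrapping coordinate
    ddg: float  # kBT, relative to the reference construct
    ddg_err: float  # kBT

    def __post_init__(self) -> None:
        if self.ddg_err < 0:
            raise ValueError("errors must be >= 0")


@dataclass(frozen=True)
class EnergyProfile:
    """Relative TF-occupancy free energies mapped onto the unwrap coordinate."""

    entries: tuple[ProfileEntry, ...]
    reference: str
    source: str  # "ensemble" or "kinetic"

    def __post_init__(self) -> None:
        labels = [e.label for e in self.entries]
        if self.reference not in labels:
            raise ValueError(f"reference {self.reference!r} missing from profile")
        ref = self[self.reference]
        if ref.ddg != 0.0:
            raise ValueError("reference entry must have ddG exactly 0")

    def __getitem__(self, label: str) -> ProfileEntry:
        for e in self.entries:
            if e.label == label:
                return e
        raise KeyError(label)

    @property
    def positions(self) -> np.ndarray:
        return np.array([e.position_bp for e in self.entries])

    @property
    def ddg(self) -> np.ndarray:
        return np.array([e.ddg for e in self.entries])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "label": [e.label for e in self.entries],
                "inner_edge_bp": [e.inner_edge_bp for e in self.entries],
                "position_bp": [e.position_bp for e in self.entries],
                "ddg_kBT": [e.ddg for e in self.entries],
                "ddg_err_kBT": [e.ddg_err for e in self.entries],
            }
        )


@dataclass(frozen=True)
class LandscapeTable:
    """Unwrapping free-energy landscape: ddG_unwrap (kBT) vs bp unwrapped."""

    bp: np.ndarray
    ddg: np.ndarray

    def __post_init__(self) -> None:
        bp = np.asarray(self.bp, float)
        if len(bp) != len(self.ddg) or len(bp) < 2:
            raise ValueError("need matching bp/ddg columns with >= 2 rows")
        if np.any(np.diff(bp) <= 0):
            raise ValueError("bp positions must be strictly increasing")

    def covers(self, positions) -> bool:
        p = np.asarray(positions, float)
        return bool(p.min() >= self.bp[0] and p.max() <= self.bp[-1])

    def interp(self, positions) -> np.ndarray:
        """Linear interpolation between tabulated integer-bp positions."""
        p = np.asarray(positions, float)
        if not self.covers(p):
            raise ValueError("query positions fall outside the landscape table")
        return np.interp(p, self.bp, self.ddg)


def map_to_unwrap_coordinate(inner_edge_bp: int, offset_bp: int = 3) -> int:
    """Map a binding site's inner edge to the unwrapping coordinate.

    The DNA must unwrap a few bp beyond the inner edge of the site for the
    TF to bind; the default offset of 3 bp places construct P26 (inner edge
    bp 26) at unwrapping position 29.
    """
    if inner_edge_bp < 1:
        raise ValueError("inner_edge_bp must be >= 1")
    return int(inner_edge_bp) + int(offset_bp)


def ddg_profile(values, reference: str, source: str = "ensemble",
                offset_bp: int = 3) -> EnergyProfile:
    """Build the relative occupancy free-energy profile from S1/2 or KD_eff.

    ``values`` is an iterable of ``(label, inner_edge_bp, value, error)``
    where value is an S1/2 (ensemble) or KD_eff (kinetic) in nM.  Relative
    energies are ``ln(v/v_ref)`` in kBT with first-order error propagation
    ``sqrt((dv/v)^2 + (dv_ref/v_ref)^2)``; the reference entry is exactly 0
    with its own error zeroed.
    """
    rows = [(str(l), int(bp), float(v), float(dv)) for l, bp, v, dv in values]
    by_label = {r[0]: r for r in rows}
    if reference not in by_label:
        raise ValueError(f"reference {reference!r} not among the values")
    if any(r[2] <= 0 for r in rows):
        raise ValueError("S1/2 / KD values must be > 0")
    if any(r[3] < 0 for r in rows):
        raise ValueError("errors must be >= 0")
    _, _, v_ref, dv_ref = by_label[reference]
    entries = []
    for label, bp, v, dv in rows:
        if label == reference:
            ddg, err = 0.0, 0.0
        else:
            ddg = float(np.log(v / v_ref))
            err = float(np.sqrt((dv / v) ** 2 + (dv_ref / v_ref) ** 2))
        entries.append(
            ProfileEntry(label, bp, map_to_unwrap_coordinate(bp, offset_bp), ddg, err)
        )
    return EnergyProfile(entries=tuple(entries), reference=reference, source=source)


def compare_to_landscape(
    profile: EnergyProfile,
    table: LandscapeTable,
    calibration_bp: int = 29,
    method: str = "ks",
    n_perm: int = 10000,
    seed: int = 0,
) -> dict:
    """Calibrate the profile to the landscape and test their agreement.

    The profile is shifted by a constant so its value at ``calibration_bp``
    equals the landscape value there (the comparison is therefore invariant
    to any constant offset, including the choice of reference construct).
    ``method="ks"`` runs a two-sample Kolmogorov-Smirnov test between the
    calibrated profile values and the landscape interpolated at the same
    positions; ``method="permutation"`` runs a paired sign-flip permutation
    test on the residuals (statistic: mean absolute residual).
    """
    pos = profile.positions
    if not table.covers(pos):
        raise ValueError("profile positions fall outside the landscape table")
    if calibration_bp not in set(int(p) for p in pos):
        raise ValueError(f"calibration position {calibration_bp} not in the profile")
    prof_vals = profile.ddg.astype(float)
    at_cal = prof_vals[pos == calibration_bp][0]
    offset = float(table.interp(calibration_bp) - at_cal)
    calibrated = prof_vals + offset
    table_vals = table.interp(pos)
    residuals = calibrated - table_vals
    out = {
        "offset_applied": offset,
        "positions_bp": pos.tolist(),
        "calibrated_ddg": calibrated.tolist(),
        "landscape_ddg": table_vals.tolist(),
        "residuals": residuals.tolist(),
    }
    if method == "ks":
        if np.allclose(calibrated, table_vals):
            out.update({"statistic": 0.0, "p_value": 1.0, "method": "ks"})
        else:
            ks = stats.ks_2samp(calibrated, table_vals)
            out.update({"statistic": float(ks.statistic),
                        "p_value": float(ks.pvalue), "method": "ks"})
    elif method == "permutation":
        rng = np.random.default_rng(seed)
        observed = float(np.mean(np.abs(residuals)))
        # sign-flip null: residuals symmetric about zero under agreement
        flips = rng.choice([-1.0, 1.0], size=(n_perm, len(residuals)))
        null = np.mean(np.abs(flips * residuals), axis=1)
        pval = float((np.sum(null >= observed) + 1) / (n_perm + 1))
        out.update({"statistic": observed, "p_value": pval, "method": "permutation"})
    else:
        raise ValueError("method must be 'ks' or 'permutation'")
    return out


def synthetic_unwrapping_landscape(max_bp: int = 45) -> LandscapeTable:
    """SYNTHETIC stand-in for a nucleosome unwrapping free-energy landscape.

    This is *not* the published force-spectroscopy landscape (which is not
    redistributed here); it is a generated table with the same qualitative
    shape: a shallow, slowly rising outer region up to ~30 bp and a sharp
    ~4-5 kBT rise between 30 and 35 bp, flattening beyond.  Use
    :func:`read_landscape_table` to supply a real landscape.
    """
    bp = np.arange(1, max_bp + 1, dtype=float)
    ddg = np.where(
        bp <= 30,
        0.08 * bp,
        np.where(bp <= 35, 0.08 * 30 + 0.9 * (bp - 30), 0.08 * 30 + 0.9 * 5 + 0.1 * (bp - 35)),
    )
    return LandscapeTable(bp=bp, ddg=ddg)


def read_landscape_table(path) -> LandscapeTable:
    """Read a TSV landscape table with columns ``bp`` and ``ddg_kBT``."""
    df = pd.read_csv(path, sep="\t")
    for col in ("bp", "ddg_kBT"):
        if col not in df.columns:
            raise ValueError(f"landscape table missing column {col!r}")
    return LandscapeTable(bp=df["bp"].to_numpy(float), ddg=df["ddg_kBT"].to_numpy(float))


def write_landscape_table(table: LandscapeTable, path) -> None:
    pd.DataFrame({"bp": table.bp, "ddg_kBT": table.ddg}).to_csv(
        path, sep="\t", index=False
    )
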