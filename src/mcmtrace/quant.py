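"""Band-intensity and qPCR arithmetic for licensing and array-size assays.

These operations work on quantified intensities and Ct values, not on
images: the licensing fraction from Southern-blot depletion of a
restriction fragment, relative array size from the uncut band, the
2D-gel bubble-to-single-ARS ratio (active origins per cell), two-point
qPCR copy-number calibration, and copy-adjusted C-pro expression.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

__all__ = [
    "BandQuant",
    "QpcrPanel",
    "LicensedFraction",
    "licensed_fraction",
    "relative_array_size",
    "active_origins_per_cell",
    "copies_from_qpcr",
    "cpro_per_copy",
]


@dataclass(frozen=True)
class BandQuant:
    """Quantified band intensities (arbitrary units).

    ``target`` is the MNase-sensitive restriction fragment spanning the
    origin, measured before (t0) and after (t) MCM-MNase activation;
    ``control`` is a loading-control band from a region without MCM.
    ``uncut`` optionally carries the uncut array band used for relative
    array-size estimates against a reference sample.
    """

    target_t0: float
    target_t: float
    control_t0: float
    control_t: float
    uncut: float | None = None
    uncut_reference: float | None = None

    def __post_init__(self) -> None:
        if min(self.target_t0, self.target_t) < 0:
            raise ValueError("band intensities must be >= 0")
        if min(self.control_t0, self.control_t) <= 0:
            raise ValueError("loading-control intensities must be > 0")

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame([self.__dict__]).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "BandQuant":
        row = pd.read_csv(path, sep="\t").iloc[0]
        d = {k: (None if pd.isna(v) else float(v)) for k, v in row.items()}
        return cls(**d)


@dataclass(frozen=True)
class LicensedFraction:
    value: float
    clipped: bool

    def __float__(self) -> float:
        return self.value


def licensed_fraction(b: BandQuant,
                      cut_efficiency: float = 1.0) -> LicensedFraction:
    """Fraction of repeats with a loaded MCM, from target-band depletion.

    Depletion D = 1 - (T_t/T_0)/(C_t/C_0); licensed = D / cut_efficiency.
    The result is clipped to [0, 1] with ``clipped`` set if noise pushed
    it outside.  Invariant to global exposure scaling.
    """
    if not 0.0 < cut_efficiency <= 1.0:
        raise ValueError("cut_efficiency must be in (0, 1]")
    if b.target_t0 == 0:
        raise ZeroDivisionError("target t0 intensity is zero")
    depletion = 1.0 - (b.target_t / b.target_t0) / (b.control_t / b.control_t0)
    licensed = depletion / cut_efficiency
    clipped = not 0.0 <= licensed <= 1.0
    return LicensedFraction(min(1.0, max(0.0, licensed)), clipped)


def relative_array_size(b: BandQuant) -> float:
    """Control-normalized uncut-band intensity relative to the reference
    sample — an estimate of the rDNA array size ratio."""
    if b.uncut is None or b.uncut_reference is None:
        raise ValueError("uncut and uncut_reference intensities required")
    if b.uncut_reference <= 0:
        raise ZeroDivisionError("reference uncut intensity must be > 0")
    return (b.uncut / b.control_t0) / (b.uncut_reference / b.control_t0)


def active_origins_per_cell(bubble_signal: float,
                            single_ars_signal: float) -> float:
    """2D-gel bubble-arc signal over the single-copy ARS signal: the
    average number of active rDNA origins per cell."""
    if single_ars_signal <= 0:
        raise ZeroDivisionError("single-ARS signal must be > 0")
    if bubble_signal < 0:
        raise ValueError("bubble signal must be >= 0")
    return bubble_signal / single_ars_signal


@dataclass(frozen=True)
class QpcrPanel:
    """Ct values for copy-number calibration against two standards of
    known rDNA size (defaults 180 and 35 copies)."""

    ct_query: float
    ct_ref: float
    std1_ct_query: float
    std1_ct_ref: float
    std2_ct_query: float
    std2_ct_ref: float
    std1_copies: float = 180.0
    std2_copies: float = 35.0
    efficiency: float = 2.0

    def __post_init__(self) -> None:
        for v in (self.ct_query, self.ct_ref, self.std1_ct_query,
                  self.std1_ct_ref, self.std2_ct_query, self.std2_ct_ref):
            if not math.isfinite(v):
                raise ValueError("Ct values must be finite")
        if self.std1_copies <= 0 or self.std2_copies <= 0:
            raise ValueError("standard copy numbers must be > 0")
        if self.std1_copies == self.std2_copies:
            raise ValueError("standard copy numbers must be distinct")
        if self.efficiency <= 1:
            raise ValueError("amplification efficiency must be > 1")

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame([self.__dict__]).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "QpcrPanel":
        row = pd.read_csv(path, sep="\t").iloc[0]
        return cls(**{k: float(v) for k, v in row.items()})


def copies_from_qpcr(p: QpcrPanel) -> float:
    """rDNA copy number by two-point log-linear calibration.

    log_E(copies) is fit linearly in dCt = Ct_query - Ct_ref through the
    two standards and inverted for the unknown.  With efficiency E, one
    cycle of dCt corresponds to an E-fold copy difference.
    """
    d_unknown = p.ct_query - p.ct_ref
    d1 = p.std1_ct_query - p.std1_ct_ref
    d2 = p.std2_ct_query - p.std2_ct_ref
    if d1 == d2:
        raise ValueError("degenerate calibration: standards have equal dCt")
    logE = math.log(p.efficiency)
    y1, y2 = math.log(p.std1_copies) / logE, math.log(p.std2_copies) / logE
    slope = (y2 - y1) / (d2 - d1)
    y = y1 + slope * (d_unknown - d1)
    return float(p.efficiency ** y)


def cpro_per_copy(ct_cpro: float, ct_ref: float, copies: float,
                  baseline_ct_cpro: float, baseline_ct_ref: float,
                  baseline_copies: float, efficiency: float = 2.0) -> float:
    """Copy-adjusted relative C-pro expression vs a baseline sample:
    E^(-ddCt) divided by the copy-number ratio."""
    if copies <= 0 or baseline_copies <= 0:
        raise ValueError("copy numbers must be > 0")
    ddct = (ct_cpro - ct_ref) - (baseline_ct_cpro - baseline_ct_ref)
    rel_expr = efficiency ** (-ddct)
    return float(rel_expr / (copies / baseline_copies))
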