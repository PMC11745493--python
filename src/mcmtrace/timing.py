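"""Relative replication timing (Trel) from G1/S libraries and rDNA copy
number from the G1 read fraction.

In a sorted S-phase population an early-replicating locus is present in
two copies in most cells, a late one in a single copy, so the S/G1 depth
ratio tracks replication timing.  Per bin b,

    r_b = (S_b / S_tot) / (G_b / G_tot),      Trel_b = r_b / median(r),

where the median runs over bins passing the G1 coverage filter.  Trel is
1 for a locus replicating at the genome-average time and typically spans
~1.4 (earliest) to ~0.8 (latest).  Because both libraries scale with DNA
copy number, Trel at the rDNA is copy-number invariant, while the G1
read fraction of the collapsed array estimates the copy number itself:

    N = frac * U / ((1 - frac) * l)

with U the unique genome length and l the repeat length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fragments import FragmentLibrary, midpoint_track
from .locus import GenomeModel, InvalidParameterError

__all__ = [
    "TimingProfile",
    "trel_profile",
    "region_trel",
    "rdna_g1_fraction",
    "copies_from_fraction",
    "moving_median",
]


@dataclass
class TimingProfile:
    """Binned Trel values; bins failing the G1 coverage filter are NaN.
    By construction the median of defined values is 1."""

    bin_size: int
    values: dict[str, np.ndarray]
    median_ratio: float
    min_g1_count: int

    def region_bins(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Trel of covered bins lying fully inside [start, end)."""
        v = self.values[chrom]
        first = -(-start // self.bin_size)          # first bin fully inside
        last = end // self.bin_size                 # exclusive
        sel = v[first:last]
        return sel[~np.isnan(sel)]


def trel_profile(g1: FragmentLibrary, s: FragmentLibrary,
                 model: GenomeModel, bin_size: int = 1000,
                 min_g1_count: int = 20) -> TimingProfile:
    """Median-normalized per-bin S/G1 depth ratio."""
    if bin_size < 100:
        raise InvalidParameterError("bin_size must be >= 100")
    g1.require_nonempty()
    s.require_nonempty()
    lens = model.chrom_lengths
    g_track = midpoint_track(g1, lens, bin_size)
    s_track = midpoint_track(s, lens, bin_size)
    g_tot = sum(int(t.sum()) for t in g_track.values())
    s_tot = sum(int(t.sum()) for t in s_track.values())
    if g_tot == 0 or s_tot == 0:
        raise InvalidParameterError("zero in-bounds totals")

    ratios: dict[str, np.ndarray] = {}
    defined = []
    for chrom in lens:
        g = g_track[chrom].astype(float)
        sdep = s_track[chrom].astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            r = (sdep / s_tot) / (g / g_tot)
        r[g < min_g1_count] = np.nan
        ratios[chrom] = r
        defined.append(r[~np.isnan(r)])
    defined = np.concatenate(defined)
    if defined.size == 0:
        raise InvalidParameterError(
            f"no bin reaches min_g1_count={min_g1_count}")
    med = float(np.median(defined))
    values = {c: r / med for c, r in ratios.items()}
    return TimingProfile(bin_size=bin_size, values=values,
                         median_ratio=med, min_g1_count=min_g1_count)


def region_trel(profile: TimingProfile, chrom: str, start: int,
                end: int) -> float:
    """Unweighted mean Trel over covered bins fully inside the interval."""
    vals = profile.region_bins(chrom, start, end)
    if vals.size == 0:
        raise InvalidParameterError(
            f"no covered bins inside {chrom}:{start}-{end}")
    return float(vals.mean())


def rdna_g1_fraction(g1: FragmentLibrary, model: GenomeModel) -> float:
    """Fraction of fragment midpoints inside the collapsed rDNA interval."""
    g1.require_nonempty()
    lo, hi = model.rdna.collapsed_interval
    on_chrom = np.asarray(g1.chroms == model.rdna.chrom)
    mids = g1.midpoints
    inside = on_chrom & (mids >= lo) & (mids < hi)
    return float(inside.sum() / len(g1))


def copies_from_fraction(frac: float, model: GenomeModel) -> float:
    """Invert the expected G1 read share N*l/(N*l + U) for copy number."""
    if not 0.0 <= frac < 1.0:
        raise InvalidParameterError("fraction must be in [0, 1)")
    U = model.unique_length
    ell = model.rdna.repeat_length
    return frac * U / ((1.0 - frac) * ell)


def moving_median(values: np.ndarray, width: int = 5) -> np.ndarray:
    """Moving median for display; NaNs propagate where the window is all-NaN."""
    if width % 2 == 0 or width < 1:
        raise InvalidParameterError("width must be odd and >= 1")
    half = width // 2
    padded = np.pad(values.astype(float), half, constant_values=np.nan)
    out = np.empty_like(values, dtype=float)
    for i in range(len(values)):
        win = padded[i:i + width]
        win = win[~np.isnan(win)]
        out[i] = np.median(win) if win.size else np.nan
    return out
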