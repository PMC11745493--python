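"""Fragment-size-resolved ChEC/MNase profiles, closely spaced peak calling
and window quantification.

Two fragment-length classes carry distinct biology: 51–100 bp fragments
are MCM double-hexamer footprints (~65 bp protections), 151–200 bp
fragments are nucleosomal.  Profiles over the rDNA are computed on the
collapsed repeat — midpoints from every collapsed copy folded to their
within-repeat offset — which doubles the signal per coordinate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .fragments import FragmentLibrary, SizeCoordMatrix
from .locus import GenomeModel, InvalidParameterError

__all__ = [
    "MCM_SIZE_CLASS",
    "NUCLEOSOME_SIZE_CLASS",
    "OccupancyProfile",
    "Peak",
    "PeakSet",
    "size_coord_matrix",
    "class_profile",
    "repeat_class_profile",
    "call_peaks",
    "window_signal",
    "repeat_window_signal",
    "nucleosome_occupancy",
    "mcm_site_windows",
]

MCM_SIZE_CLASS = (51, 100)
NUCLEOSOME_SIZE_CLASS = (151, 200)


@dataclass
class OccupancyProfile:
    """Per-coordinate midpoint counts of one size class over a region.
    ``chrom == "repeat"`` marks repeat-relative (folded) coordinates."""

    chrom: str
    start: int
    values: np.ndarray
    size_class: tuple[int, int] | None = None

    @property
    def coords(self) -> np.ndarray:
        return np.arange(self.start, self.start + len(self.values))

    def normalized(self, ref_window: tuple[int, int]) -> np.ndarray:
        """Values divided by the total count inside the reference window."""
        lo, hi = ref_window
        ref = self.values[lo - self.start:hi - self.start].sum()
        if ref == 0:
            raise ZeroDivisionError("empty normalization reference window")
        return self.values / ref


@dataclass(frozen=True)
class Peak:
    position: int
    height: float
    prominence: float


@dataclass(frozen=True)
class PeakSet:
    peaks: tuple[Peak, ...]
    min_separation: int

    def __post_init__(self) -> None:
        pos = self.positions
        if np.any(np.diff(pos) < self.min_separation):
            raise ValueError("peaks closer than min_separation")

    def __len__(self) -> int:
        return len(self.peaks)

    @property
    def positions(self) -> np.ndarray:
        return np.array([p.position for p in self.peaks])

    def top(self, n: int) -> tuple[Peak, ...]:
        return tuple(sorted(self.peaks, key=lambda p: (-p.height,
                                                       p.position))[:n])


# --- size-resolved matrices and profiles ------------------------------------

def size_coord_matrix(lib: FragmentLibrary, chrom: str, start: int, end: int,
                      size_range: tuple[int, int] = (1, 500),
                      fold_repeat: GenomeModel | None = None,
                      ) -> SizeCoordMatrix:
    """Counts of fragments by (midpoint, length) over a region.

    With ``fold_repeat`` set, midpoints inside the collapsed array are
    first folded to within-repeat offsets and ``chrom``/``start``/``end``
    are interpreted repeat-relative.
    """
    if end <= start:
        raise InvalidParameterError("empty region")
    lo, hi = size_range
    if lo > hi or lo < 1:
        raise InvalidParameterError(f"invalid size range ({lo}, {hi})")
    mids, lens = _region_midpoints(lib, chrom, fold_repeat)
    sel = (mids >= start) & (mids < end) & (lens >= lo) & (lens <= hi)
    counts = np.zeros((end - start, hi - lo + 1), dtype=np.int64)
    np.add.at(counts, (mids[sel] - start, lens[sel] - lo), 1)
    return SizeCoordMatrix(chrom=chrom, coord_start=start, coord_end=end,
                           size_min=lo, size_max=hi, counts=counts)


def _region_midpoints(lib: FragmentLibrary, chrom: str,
                      fold_repeat: GenomeModel | None):
    if fold_repeat is None:
        m = np.asarray(lib.chroms == chrom)
        return lib.midpoints[m], lib.lengths[m]
    rdna = fold_repeat.rdna
    m = np.asarray(lib.chroms == rdna.chrom)
    mids = lib.midpoints[m]
    inside = (mids >= rdna.collapsed_start) & (mids < rdna.collapsed_end)
    folded = (mids[inside] - rdna.collapsed_start) % rdna.repeat_length
    return folded, lib.lengths[m][inside]


def class_profile(matrix: SizeCoordMatrix,
                  size_class: tuple[int, int]) -> OccupancyProfile:
    """Per-coordinate sum over the length columns of one size class."""
    cols = matrix.class_columns(size_class)
    return OccupancyProfile(chrom=matrix.chrom, start=matrix.coord_start,
                            values=matrix.counts[:, cols].sum(axis=1),
                            size_class=size_class)


def repeat_class_profile(lib: FragmentLibrary, model: GenomeModel,
                         size_class: tuple[int, int]) -> OccupancyProfile:
    """Size-class midpoint profile folded onto one rDNA repeat."""
    mids, lens = _region_midpoints(lib, "repeat", model)
    sel = (lens >= size_class[0]) & (lens <= size_class[1])
    values = np.bincount(mids[sel], minlength=model.rdna.repeat_length)
    return OccupancyProfile(chrom="repeat", start=0, values=values,
                            size_class=size_class)


# --- peak calling -----------------------------------------------------------

def call_peaks(profile: OccupancyProfile, smoothing_bw: float = 10.0,
               min_separation: int = 100,
               min_prominence: float = 0.05) -> PeakSet:
    """Local maxima of the Gaussian-smoothed profile, accepted greedily in
    decreasing height (ties to the leftmost position) with the separation
    constraint enforced; candidates below ``min_prominence`` of the
    highest smoothed value are discarded.  Invariant to uniform scaling.
    """
    if smoothing_bw < 1:
        raise InvalidParameterError("smoothing_bw must be >= 1")
    y = profile.values.astype(float)
    if y.size == 0 or y.max() == 0:
        return PeakSet(peaks=(), min_separation=min_separation)
    sm = gaussian_filter1d(y, smoothing_bw, mode="constant")
    # local maxima; plateaus credit their leftmost coordinate
    left = np.r_[-np.inf, sm[:-1]]
    right = np.r_[sm[1:], -np.inf]
    cand = np.flatnonzero((sm > left) & (sm >= right))
    cand = cand[sm[cand] >= min_prominence * sm.max()]
    order = sorted(cand, key=lambda i: (-sm[i], i))
    accepted: list[int] = []
    for i in order:
        if all(abs(i - j) >= min_separation for j in accepted):
            accepted.append(i)
    accepted.sort()
    base = sm.min()
    peaks = tuple(Peak(position=int(i) + profile.start,
                       height=float(sm[i]),
                       prominence=float(sm[i] - base))
                  for i in accepted)
    return PeakSet(peaks=peaks, min_separation=min_separation)


# --- window quantification --------------------------------------------------

def window_signal(lib: FragmentLibrary,
                  windows: list[tuple[str, str, int, int, str]],
                  size_class: tuple[int, int] | None = None) -> np.ndarray:
    """Midpoint counts per (name, chrom, start, end, class) window,
    restricted to the size class.  Empty windows count 0."""
    mask = lib.size_class_mask(size_class)
    counts = np.zeros(len(windows), dtype=np.int64)
    mids_by_chrom: dict[str, np.ndarray] = {}
    for i, (_, chrom, start, end, _) in enumerate(windows):
        if chrom not in mids_by_chrom:
            m = mask & np.asarray(lib.chroms == chrom)
            mids_by_chrom[chrom] = np.sort(lib.midpoints[m])
        mids = mids_by_chrom[chrom]
        counts[i] = (np.searchsorted(mids, end, "left")
                     - np.searchsorted(mids, start, "left"))
    return counts


def repeat_window_signal(lib: FragmentLibrary, model: GenomeModel,
                         windows: list[tuple[str, int, int]],
                         size_class: tuple[int, int] | None = None
                         ) -> np.ndarray:
    """Midpoint counts per repeat-relative (name, start, end) window,
    folded across all collapsed copies."""
    mids, lens = _region_midpoints(lib, "repeat", model)
    if size_class is not None:
        lo, hi = size_class
        sel = (lens >= lo) & (lens <= hi)
        mids = mids[sel]
    mids = np.sort(mids)
    return np.array([np.searchsorted(mids, e, "left")
                     - np.searchsorted(mids, s, "left")
                     for _, s, e in windows], dtype=np.int64)


def mcm_site_windows(model: GenomeModel,
                     width: int = 100) -> list[tuple[str, int, int]]:
    """Repeat-relative windows on the nondisplaced and displaced MCM sites.

    Default width 100 bp keeps the two windows disjoint at the 150 bp
    site separation."""
    if width < 2 or width % 2:
        raise InvalidParameterError("width must be even and >= 2")
    half = width // 2
    rdna = model.rdna
    return [("mcm_nondisplaced", rdna.mcm_nondisplaced - half,
             rdna.mcm_nondisplaced + half),
            ("mcm_displaced", rdna.mcm_displaced - half,
             rdna.mcm_displaced + half)]


# --- nucleosome occupancy ---------------------------------------------------

def nucleosome_occupancy(profile: OccupancyProfile, model: GenomeModel,
                         dyad_window: int = 100) -> dict[str, float]:
    """+1-normalized counts in dyad-centered windows at +1/+2/+3.

    The profile must be repeat-relative (see :func:`repeat_class_profile`).
    The +1 nucleosome is the high-occupancy normalization reference; a
    zero +1 count is an error.
    """
    if dyad_window < 20 or dyad_window % 2:
        raise InvalidParameterError("dyad_window must be even and >= 20")
    if profile.chrom != "repeat":
        raise InvalidParameterError("occupancy requires a repeat-folded "
                                    "profile")
    half = dyad_window // 2
    raw = {}
    for label, dyad in zip(("+1", "+2", "+3"), model.rdna.nucleosome_dyads):
        lo, hi = dyad - half, dyad + half
        raw[label] = float(profile.values[max(0, lo - profile.start):
                                          hi - profile.start].sum())
    if raw["+1"] == 0:
        raise ZeroDivisionError("+1 dyad window empty: no normalization "
                                "reference")
    return {k: v / raw["+1"] for k, v in raw.items()}
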