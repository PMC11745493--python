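"""Fragment-library IO, coverage tracks and cross-library normalization.

A fragment library is one sample's sequenced fragments (BED3-style
intervals) plus assay/genotype/timepoint metadata.  All quantification in
the package assigns a fragment to a single base pair — the midpoint
``floor((start + end) / 2)`` — and a fragment belongs to a window iff its
midpoint lies in the half-open window.  Fragment length is ``end - start``.

On-disk formats are plain text: BED3 for fragments with a JSON metadata
sidecar (``<path>.json``), bedGraph for coverage tracks, and a TSV with a
one-line header for the coordinate-by-fragment-size matrix.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SampleInfo",
    "FragmentLibrary",
    "SizeCoordMatrix",
    "read_fragments",
    "write_fragments",
    "midpoint_track",
    "write_bedgraph",
    "scale_to_max_total",
    "ParseError",
    "EmptyLibraryError",
]


class ParseError(ValueError):
    """A fragment file line could not be parsed."""


class EmptyLibraryError(ValueError):
    """An analysis operation received an empty fragment library."""


ASSAYS = ("chec", "mnase", "sseq_g1", "sseq_s", "edu")


@dataclass(frozen=True)
class SampleInfo:
    """Sample metadata. ``timepoint`` is minutes after release into HU;
    0.0 denotes the G1 reference (serialized as "G1")."""

    assay: str
    genotype: str = "wt"
    timepoint: float = 0.0

    def to_dict(self) -> dict:
        d = asdict(self)
        if self.timepoint == 0.0:
            d["timepoint"] = "G1"
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SampleInfo":
        t = d.get("timepoint", 0.0)
        t = 0.0 if t in ("G1", None) else float(t)
        return cls(assay=d["assay"], genotype=d.get("genotype", "wt"),
                   timepoint=t)


@dataclass
class FragmentLibrary:
    """One sample's fragments as parallel arrays.

    ``chroms`` is a pandas Categorical (compact for millions of rows);
    ``starts``/``ends`` are int64, 0-based half-open.
    """

    sample: SampleInfo
    chroms: pd.Categorical
    starts: np.ndarray
    ends: np.ndarray

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.ends = np.asarray(self.ends, dtype=np.int64)
        if not isinstance(self.chroms, pd.Categorical):
            self.chroms = pd.Categorical(self.chroms)
        if len(self.starts) != len(self.ends) or len(self.starts) != len(self.chroms):
            raise ValueError("chroms/starts/ends must have equal length")
        if len(self.starts) and np.any(self.starts >= self.ends):
            bad = int(np.argmax(self.starts >= self.ends))
            raise ValueError(
                f"fragment {bad} has start >= end "
                f"({self.starts[bad]} >= {self.ends[bad]})")

    def __len__(self) -> int:
        return len(self.starts)

    @property
    def midpoints(self) -> np.ndarray:
        """Fragment midpoints; even lengths round down."""
        return (self.starts + self.ends) // 2

    @property
    def lengths(self) -> np.ndarray:
        return self.ends - self.starts

    def require_nonempty(self) -> None:
        if len(self) == 0:
            raise EmptyLibraryError(
                f"empty library ({self.sample.assay}/{self.sample.genotype})")

    def subset(self, mask: np.ndarray) -> "FragmentLibrary":
        return FragmentLibrary(self.sample, self.chroms[mask],
                               self.starts[mask], self.ends[mask])

    def size_class_mask(self, size_class: tuple[int, int] | None) -> np.ndarray:
        if size_class is None:
            return np.ones(len(self), dtype=bool)
        lo, hi = size_class
        if lo > hi:
            raise ValueError(f"inverted size range ({lo}, {hi})")
        lens = self.lengths
        return (lens >= lo) & (lens <= hi)

    def validate_bounds(self, chrom_lengths: dict[str, int]) -> None:
        """Raise listing offenders if any interval leaves its chromosome."""
        offenders = []
        for chrom in self.chroms.categories:
            if chrom not in chrom_lengths:
                offenders.append(f"unknown chromosome {chrom}")
                continue
            m = np.asarray(self.chroms == chrom)
            bad = m & ((self.starts < 0) | (self.ends > chrom_lengths[chrom]))
            for i in np.flatnonzero(bad)[:10]:
                offenders.append(
                    f"{chrom}:{self.starts[i]}-{self.ends[i]} (row {i})")
        if offenders:
            raise ValueError("intervals outside model bounds: "
                             + "; ".join(offenders))


# --- BED3 + sidecar ---------------------------------------------------------

def _sidecar_path(path: str | Path) -> Path:
    return Path(str(path) + ".json")


def write_fragments(lib: FragmentLibrary, path: str | Path) -> None:
    """Write BED3 plus a ``<path>.json`` metadata sidecar.

    Writing an empty library is allowed (empty BED, sidecar with n=0)."""
    path = Path(path)
    df = pd.DataFrame({"chrom": lib.chroms.astype(str),
                       "start": lib.starts, "end": lib.ends})
    df.to_csv(path, sep="\t", header=False, index=False)
    meta = lib.sample.to_dict()
    meta["n_fragments"] = len(lib)
    _sidecar_path(path).write_text(json.dumps(meta, sort_keys=True) + "\n")


def read_fragments(path: str | Path,
                   sample: SampleInfo | None = None) -> FragmentLibrary:
    """Read a BED3(+) file; metadata from the sidecar unless supplied.

    Malformed lines raise :class:`ParseError` with a 1-based line number.
    """
    path = Path(path)
    if sample is None:
        side = _sidecar_path(path)
        if not side.exists():
            raise FileNotFoundError(
                f"no metadata sidecar {side} and no SampleInfo supplied")
        sample = SampleInfo.from_dict(json.loads(side.read_text()))
    chroms, starts, ends = [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: expected >= 3 columns")
            try:
                s, e = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
            if s >= e:
                raise ParseError(f"{path}:{lineno}: start >= end ({s} >= {e})")
            chroms.append(parts[0])
            starts.append(s)
            ends.append(e)
    return FragmentLibrary(sample, pd.Categorical(chroms),
                           np.array(starts, dtype=np.int64),
                           np.array(ends, dtype=np.int64))


# --- coverage tracks --------------------------------------------------------

def midpoint_track(lib: FragmentLibrary,
                   chrom_lengths: dict[str, int],
                   bin_size: int = 1,
                   size_class: tuple[int, int] | None = None,
                   ) -> dict[str, np.ndarray]:
    """Binned midpoint counts per chromosome, optionally restricted to a
    fragment-length class [min, max] (inclusive)."""
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    mask = lib.size_class_mask(size_class)
    mids = lib.midpoints[mask]
    chroms = lib.chroms[mask]
    out: dict[str, np.ndarray] = {}
    for chrom, length in chrom_lengths.items():
        nbins = -(-length // bin_size)
        m = np.asarray(chroms == chrom)
        idx = mids[m] // bin_size
        idx = idx[(idx >= 0) & (idx < nbins)]
        out[chrom] = np.bincount(idx, minlength=nbins)
    return out


def write_bedgraph(track: dict[str, np.ndarray], bin_size: int,
                   path: str | Path, skip_zero: bool = True) -> None:
    with open(path, "w") as fh:
        for chrom, values in track.items():
            nz = np.flatnonzero(values) if skip_zero else np.arange(len(values))
            for i in nz:
                fh.write(f"{chrom}\t{i * bin_size}\t{(i + 1) * bin_size}\t"
                         f"{values[i]:g}\n")


def scale_to_max_total(libs: list[FragmentLibrary]) -> np.ndarray:
    """Max-total normalization factors: factor_i = max_j(total_j) / total_i.

    Multiplying each library's counts by its factor equalizes totals; the
    deepest library's factor is 1.
    """
    if not libs:
        raise ValueError("need at least one library")
    totals = np.array([len(lib) for lib in libs], dtype=float)
    if np.any(totals == 0):
        raise EmptyLibraryError("cannot normalize an empty library")
    return totals.max() / totals


# --- coordinate x fragment-size matrix -------------------------------------

@dataclass
class SizeCoordMatrix:
    """Counts matrix with one row per coordinate (midpoint) and one column
    per fragment length — the source-data layout used for size-resolved
    footprint plots."""

    chrom: str
    coord_start: int
    coord_end: int
    size_min: int
    size_max: int
    counts: np.ndarray

    def __post_init__(self) -> None:
        expect = (self.coord_end - self.coord_start,
                  self.size_max - self.size_min + 1)
        if self.counts.shape != expect:
            raise ValueError(f"counts shape {self.counts.shape} != {expect}")

    @property
    def coords(self) -> np.ndarray:
        return np.arange(self.coord_start, self.coord_end)

    @property
    def sizes(self) -> np.ndarray:
        return np.arange(self.size_min, self.size_max + 1)

    def class_columns(self, size_class: tuple[int, int]) -> slice:
        lo, hi = size_class
        if lo < self.size_min or hi > self.size_max:
            raise ValueError(f"size class {size_class} outside matrix range "
                             f"[{self.size_min}, {self.size_max}]")
        return slice(lo - self.size_min, hi - self.size_min + 1)

    def to_tsv(self, path: str | Path) -> None:
        """First column = 1-based coordinate; remaining columns = lengths."""
        df = pd.DataFrame(self.counts, columns=self.sizes)
        df.insert(0, "coord", self.coords + 1)
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, chrom: str = "") -> "SizeCoordMatrix":
        df = pd.read_csv(path, sep="\t")
        coords = df.iloc[:, 0].to_numpy() - 1
        sizes = df.columns[1:].astype(int)
        return cls(chrom=chrom, coord_start=int(coords[0]),
                   coord_end=int(coords[-1]) + 1,
                   size_min=int(sizes[0]), size_max=int(sizes[-1]),
                   counts=df.iloc[:, 1:].to_numpy())
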