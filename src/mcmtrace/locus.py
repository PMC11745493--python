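"""Genome/locus data model for a collapsed-reference rDNA array.

The budding-yeast rDNA is a tandem array of ~150 copies of a 9.1 kb repeat
on chrXII. Short-read references collapse the array to a small number of
repeats (here two), so the physical copy number manifests only as read
depth over the collapsed interval. This module defines the genome model
(chromosomes, annotated repeat array, origin catalog) and the coordinate
arithmetic every analysis stage consumes.

Coordinates are 0-based half-open internally; exported reports are 1-based
inclusive where a format demands it (bedGraph stays 0-based half-open).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = [
    "RepeatArrayAnnotation",
    "OriginEntry",
    "OriginCatalog",
    "GenomeModel",
    "default_genome_model",
    "default_origin_catalog",
    "repeat_to_genome",
    "origin_windows",
    "model_to_dict",
    "model_from_dict",
    "save_model",
    "load_model",
    "write_feature_bed",
    "write_origin_bed6",
    "InvalidParameterError",
]

#: Classes an origin may carry.  ``weak_early`` origins are early origins
#: whose firing is preferentially suppressed when Sir2 is lost; selections
#: for "early" include them (111 early = strict-early plus weak-early).
ORIGIN_CLASSES = ("early", "weak_early", "late", "rdna")


class InvalidParameterError(ValueError):
    """A parameter violates a documented precondition."""


@dataclass(frozen=True)
class RepeatArrayAnnotation:
    """Annotation of the collapsed rDNA repeat array.

    Offsets are base pairs from the start of one repeat.  The helicase
    loading site (``mcm_nondisplaced``) sits just left of the ACS; the
    displaced site (``mcm_displaced``), occupied when C-pro transcription
    pushes the loaded double-hexamer rightward, lies 150 bp further right.
    The replication fork block (``rfb``) is ~1.5 kb to the right of the
    loading site.
    """

    chrom: str
    collapsed_start: int
    repeat_length: int = 9100
    collapsed_copies: int = 2
    physical_copies: int = 150
    acs: int = 2000
    mcm_nondisplaced: int = 1850
    mcm_displaced: int = 2000
    nucleosome_dyads: tuple[int, int, int] = (1760, 2165, 2330)
    cpro_start: int = 1800
    rfb: int = 3350
    timing_region: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.repeat_length <= 0:
            raise InvalidParameterError("repeat_length must be > 0")
        if self.physical_copies < 0:
            raise InvalidParameterError("physical_copies must be >= 0")
        if self.collapsed_copies < 1:
            raise InvalidParameterError("collapsed_copies must be >= 1")
        offsets = (self.acs, self.mcm_nondisplaced, self.mcm_displaced,
                   *self.nucleosome_dyads, self.cpro_start, self.rfb)
        for off in offsets:
            if not 0 <= off < self.repeat_length:
                raise InvalidParameterError(
                    f"offset {off} outside [0, {self.repeat_length})")
        if self.mcm_displaced <= self.mcm_nondisplaced:
            raise InvalidParameterError(
                "mcm_displaced must lie right of mcm_nondisplaced")
        if self.timing_region is not None:
            lo, hi = self.timing_region
            if not (self.collapsed_start <= lo < hi <= self.collapsed_end):
                raise InvalidParameterError(
                    "timing_region must lie within the collapsed array")

    @property
    def collapsed_length(self) -> int:
        return self.collapsed_copies * self.repeat_length

    @property
    def collapsed_end(self) -> int:
        return self.collapsed_start + self.collapsed_length

    @property
    def collapsed_interval(self) -> tuple[int, int]:
        """Half-open genome interval occupied by the collapsed array."""
        return (self.collapsed_start, self.collapsed_end)

    @property
    def displacement(self) -> int:
        return self.mcm_displaced - self.mcm_nondisplaced

    @property
    def physical_length(self) -> int:
        """Length of the physical (uncollapsed) array in bp."""
        return self.physical_copies * self.repeat_length


@dataclass(frozen=True)
class OriginEntry:
    name: str
    chrom: str
    position: int
    oclass: str

    def __post_init__(self) -> None:
        if self.oclass not in ORIGIN_CLASSES:
            raise InvalidParameterError(f"unknown origin class {self.oclass!r}")

    @property
    def is_early(self) -> bool:
        return self.oclass in ("early", "weak_early")


@dataclass(frozen=True)
class OriginCatalog:
    entries: tuple[OriginEntry, ...]

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def select(self, oclass: str) -> tuple[OriginEntry, ...]:
        """Origins of a class. ``"early"`` includes the weak-early subset;
        use ``"early_strict"`` for early origins that are not weak."""
        if oclass == "early":
            return tuple(e for e in self.entries if e.is_early)
        if oclass == "early_strict":
            return tuple(e for e in self.entries if e.oclass == "early")
        return tuple(e for e in self.entries if e.oclass == oclass)


@dataclass(frozen=True)
class GenomeModel:
    chromosomes: tuple[tuple[str, int], ...]
    rdna: RepeatArrayAnnotation
    origins: OriginCatalog

    def __post_init__(self) -> None:
        names = [n for n, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise InvalidParameterError("chromosome names must be unique")
        for n, length in self.chromosomes:
            if length <= 0:
                raise InvalidParameterError(f"chromosome {n} has length <= 0")
        lengths = dict(self.chromosomes)
        if self.rdna.chrom not in lengths:
            raise InvalidParameterError("rDNA chromosome missing from model")
        if self.rdna.collapsed_end > lengths[self.rdna.chrom]:
            raise InvalidParameterError("collapsed array exceeds chromosome")
        for e in self.origins:
            if e.chrom not in lengths or not 0 <= e.position < lengths[e.chrom]:
                raise InvalidParameterError(
                    f"origin {e.name} outside chromosome bounds")

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    @property
    def total_length(self) -> int:
        return sum(length for _, length in self.chromosomes)

    @property
    def unique_length(self) -> int:
        """Total non-rDNA sequence (reference minus the collapsed array)."""
        return self.total_length - self.rdna.collapsed_length

    @property
    def expected_rdna_fraction(self) -> float:
        """Expected share of G1 reads from the rDNA: N*l / (N*l + U)."""
        nl = self.rdna.physical_length
        return nl / (nl + self.unique_length) if nl else 0.0

    @property
    def timing_region(self) -> tuple[str, int, int]:
        """(chrom, start, end) interval used for rDNA timing reports."""
        region = self.rdna.timing_region or self.rdna.collapsed_interval
        return (self.rdna.chrom, region[0], region[1])

    def with_copies(self, physical_copies: int) -> "GenomeModel":
        return replace(self, rdna=replace(self.rdna,
                                          physical_copies=physical_copies))


# --- default model ----------------------------------------------------------

#: Non-rDNA genome content, bp.  Chosen so the 150-copy array contributes
#: ~10% of genomic DNA, the typical wild-type share.
UNIQUE_GENOME_LENGTH = 12_100_000

#: Portion of the unique genome placed on the array chromosome, left of the
#: collapsed array, so the array starts at coordinate 450,000 as in the
#: S288C-style reference used for rDNA timing reports.
ARRAY_CHROM_FLANK = 450_000

N_EARLY_ORIGINS = 111   # includes the weak-early subset
N_WEAK_EARLY = 25
N_LATE_ORIGINS = 101


def default_origin_catalog(rdna: RepeatArrayAnnotation,
                           unique_chrom: str = "chrU",
                           unique_length: int = UNIQUE_GENOME_LENGTH
                           - ARRAY_CHROM_FLANK) -> OriginCatalog:
    """Synthetic catalog: 111 early (25 of them weak-early) + 101 late
    origins evenly interleaved on the unique chromosome, plus the rDNA
    origin at the helicase loading site of the first collapsed repeat."""
    n = N_EARLY_ORIGINS + N_LATE_ORIGINS
    spacing = unique_length // (n + 1)
    positions = [(i + 1) * spacing for i in range(n)]
    # spread 111 early indices evenly among 212 slots; remainder are late
    early_idx = {round(i * (n - 1) / (N_EARLY_ORIGINS - 1))
                 for i in range(N_EARLY_ORIGINS)}
    early_list = sorted(early_idx)
    weak_idx = set(early_list[::len(early_list) // N_WEAK_EARLY][:N_WEAK_EARLY])
    entries = []
    for i, pos in enumerate(positions):
        if i in early_idx:
            cls = "weak_early" if i in weak_idx else "early"
        else:
            cls = "late"
        entries.append(OriginEntry(f"ori{i:03d}", unique_chrom, pos, cls))
    entries.append(OriginEntry("rARS", rdna.chrom,
                               rdna.collapsed_start + rdna.mcm_nondisplaced,
                               "rdna"))
    return OriginCatalog(tuple(entries))


def default_genome_model(physical_copies: int = 150) -> GenomeModel:
    """Default two-chromosome model: one unique chromosome plus an array
    chromosome carrying a two-repeat collapsed rDNA.

    The unique (non-rDNA) content totals 12.1 Mb, so ``physical_copies=150``
    gives an expected rDNA read share of ~10%.
    """
    if physical_copies < 0:
        raise InvalidParameterError("physical_copies must be >= 0")
    rdna = RepeatArrayAnnotation(
        chrom="chrXII",
        collapsed_start=ARRAY_CHROM_FLANK,
        physical_copies=physical_copies,
    )
    rdna = replace(rdna, timing_region=rdna.collapsed_interval)
    chroms = (
        ("chrU", UNIQUE_GENOME_LENGTH - ARRAY_CHROM_FLANK),
        ("chrXII", ARRAY_CHROM_FLANK + rdna.collapsed_length),
    )
    catalog = default_origin_catalog(rdna)
    return GenomeModel(chromosomes=chroms, rdna=rdna, origins=catalog)


# --- serialization ----------------------------------------------------------

def model_to_dict(model: GenomeModel) -> dict:
    rd = model.rdna
    return {
        "chromosomes": [{"name": n, "length": l} for n, l in model.chromosomes],
        "rdna": {
            "chrom": rd.chrom, "collapsed_start": rd.collapsed_start,
            "repeat_length": rd.repeat_length,
            "collapsed_copies": rd.collapsed_copies,
            "physical_copies": rd.physical_copies,
            "acs": rd.acs, "mcm_nondisplaced": rd.mcm_nondisplaced,
            "mcm_displaced": rd.mcm_displaced,
            "nucleosome_dyads": list(rd.nucleosome_dyads),
            "cpro_start": rd.cpro_start, "rfb": rd.rfb,
            "timing_region": list(rd.timing_region)
            if rd.timing_region else None,
        },
        "origins": [{"name": e.name, "chrom": e.chrom,
                     "position": e.position, "class": e.oclass}
                    for e in model.origins],
    }


def model_from_dict(d: dict) -> GenomeModel:
    rd = dict(d["rdna"])
    rd["nucleosome_dyads"] = tuple(rd["nucleosome_dyads"])
    if rd.get("timing_region"):
        rd["timing_region"] = tuple(rd["timing_region"])
    origins = OriginCatalog(tuple(
        OriginEntry(o["name"], o["chrom"], o["position"], o["class"])
        for o in d["origins"]))
    return GenomeModel(
        chromosomes=tuple((c["name"], c["length"])
                          for c in d["chromosomes"]),
        rdna=RepeatArrayAnnotation(**rd),
        origins=origins)


def save_model(model: GenomeModel, path) -> None:
    """Serialize the model as YAML (readable as a plain config)."""
    import yaml
    with open(path, "w") as fh:
        yaml.safe_dump(model_to_dict(model), fh, sort_keys=False)


def load_model(path) -> GenomeModel:
    """Load a model from YAML or TOML."""
    from pathlib import Path
    text = Path(path).read_text()
    if str(path).endswith(".toml"):
        import tomllib
        d = tomllib.loads(text)
    else:
        import yaml
        d = yaml.safe_load(text)
    return model_from_dict(d)


def write_feature_bed(model: GenomeModel, path) -> None:
    """Named rDNA features of every collapsed repeat as BED6."""
    rd = model.rdna
    feats = [("acs", rd.acs), ("mcm_nondisplaced", rd.mcm_nondisplaced),
             ("mcm_displaced", rd.mcm_displaced),
             ("nuc_p1", rd.nucleosome_dyads[0]),
             ("nuc_p2", rd.nucleosome_dyads[1]),
             ("nuc_p3", rd.nucleosome_dyads[2]),
             ("cpro_start", rd.cpro_start), ("rfb", rd.rfb)]
    with open(path, "w") as fh:
        for rep in range(rd.collapsed_copies):
            base = rd.collapsed_start + rep * rd.repeat_length
            for name, off in feats:
                fh.write(f"{rd.chrom}\t{base + off}\t{base + off + 1}\t"
                         f"{name}.r{rep}\t0\t+\n")


def write_origin_bed6(catalog: OriginCatalog, path) -> None:
    """Origin catalog as BED6 with the class in the name field."""
    with open(path, "w") as fh:
        for e in catalog:
            fh.write(f"{e.chrom}\t{e.position}\t{e.position + 1}\t"
                     f"{e.name}|{e.oclass}\t0\t+\n")


# --- coordinate arithmetic --------------------------------------------------

def repeat_to_genome(model: GenomeModel, repeat_index: int,
                     offset: int) -> tuple[str, int]:
    """Map a (collapsed repeat index, within-repeat offset) to a genome
    coordinate on the array chromosome."""
    rdna = model.rdna
    if not 0 <= repeat_index < rdna.collapsed_copies:
        raise IndexError(
            f"repeat_index {repeat_index} outside [0, {rdna.collapsed_copies})")
    if not 0 <= offset < rdna.repeat_length:
        raise IndexError(f"offset {offset} outside [0, {rdna.repeat_length})")
    return (rdna.chrom,
            rdna.collapsed_start + repeat_index * rdna.repeat_length + offset)


def origin_windows(catalog: OriginCatalog, width: int,
                   chrom_lengths: dict[str, int] | None = None,
                   classes: tuple[str, ...] | None = None,
                   ) -> list[tuple[str, str, int, int, str]]:
    """Half-open windows of ``width`` bp centered on each origin, clipped to
    chromosome bounds.  Returns (name, chrom, start, end, class) tuples."""
    if width < 2 or width % 2:
        raise InvalidParameterError("width must be even and >= 2")
    half = width // 2
    out = []
    for e in catalog:
        if classes is not None and e.oclass not in classes:
            continue
        start = max(0, e.position - half)
        end = e.position + half
        if chrom_lengths is not None:
            end = min(end, chrom_lengths[e.chrom])
        out.append((e.name, e.chrom, start, end, e.oclass))
    return out
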