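"""Synthetic fragment libraries with the statistical structure of the
rDNA licensing/firing system.

The generator emulates five assays on the collapsed-reference genome model:

* **S-seq** — G1 and S-phase libraries whose depths follow local copy
  number and, in S, the per-bin replicated fraction ``f`` (an early locus
  with ``f`` near 1 is present in ~2 copies per cell).
* **MCM2-ChEC time course** — ~65 bp footprints under MCM double-hexamers
  at a nondisplaced loading site and a displaced site 150 bp to its right,
  plus 151–200 bp nucleosome-adjacent fragments, in G1 and at time points
  after release into hydroxyurea.  Firing removes a footprint with
  exponential kinetics and redeposits the helicase signal immediately left
  of the replication fork barrier (RFB).
* **MNase-seq** — nucleosomal fragments at the +1/+2/+3 dyads flanking the
  rDNA origin plus a phased genome-wide background.
* **EdU-seq** — nascent-DNA reads around origins that fired before
  harvest, with fork extent set by the HU-slowed fork speed.
* **Licensing Southern** — band intensities for the restriction-fragment
  depletion assay (MCM-MNase cutting eliminates the target fragment in
  licensed cells).

Fragments are sampled directly from mixture weights rather than from
individual cells and repeats — equivalent in distribution and far cheaper.
Signal lost from a decaying component is redeposited (MCM loss at the
rDNA into the RFB window, everything else into uniform background) so the
expected total weight of the mixture is constant across a time course:
fragments move, none vanish.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .fragments import FragmentLibrary, SampleInfo
from .locus import GenomeModel, default_genome_model, InvalidParameterError
from .quant import BandQuant

__all__ = [
    "GenotypeParams",
    "SimulationSpec",
    "FractionTrack",
    "make_f_track",
    "simulate_sseq",
    "simulate_chec_timecourse",
    "simulate_mnase",
    "simulate_edu",
    "simulate_licensing_assay",
    "GENOTYPES",
]

# decay rates of genomic-origin MCM footprints in HU, per minute
LAMBDA_EARLY = 0.02
LAMBDA_LATE = 0.0005

# substream codes so each assay draws from an independent stream
_ASSAY_STREAM = {"sseq": 0, "chec": 1, "mnase": 2, "edu": 3, "licensing": 4}


@dataclass(frozen=True)
class GenotypeParams:
    """Parameters through which genotype shapes every assay.

    ``licensing_prob`` (L) is the fraction of repeats with a loaded MCM;
    ``displaced_fraction`` (p_d) the fraction of loaded MCMs pushed to the
    displaced site by C-pro transcription; firing rates are per minute in
    HU.  ``weak_early_scale`` multiplies the firing rate of the weak-early
    origin subset (suppressed when the rDNA fires early in *sir2*).
    """

    sir2_deleted: bool = False
    fun30_deleted: bool = False
    licensing_prob: float = 0.75
    displaced_fraction: float = 0.10
    firing_rate_nondisplaced: float = 0.002
    firing_rate_displaced: float = 0.02
    occ1: float = 0.9
    occ2: float = 0.25
    occ3: float = 0.35
    weak_early_scale: float = 1.0
    cpro_level: float = 1.0
    physical_copies: int | None = None   # None: use the model's copy number

    def __post_init__(self) -> None:
        for name in ("licensing_prob", "displaced_fraction",
                     "occ1", "occ2", "occ3"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidParameterError(f"{name}={v} outside [0, 1]")
        if self.firing_rate_nondisplaced < 0 or self.firing_rate_displaced < 0:
            raise InvalidParameterError("firing rates must be >= 0")
        if not 0.0 < self.weak_early_scale <= 1.0:
            raise InvalidParameterError("weak_early_scale outside (0, 1]")
        if self.physical_copies is not None and self.physical_copies < 0:
            raise InvalidParameterError("physical_copies must be >= 0")

    @classmethod
    def for_genotype(cls, name: str) -> "GenotypeParams":
        """Defaults for 'wt', 'sir2', 'fun30' and 'sir2 fun30'.

        sir2 loss de-represses C-pro (displacement jumps to 0.70, rDNA
        fires early, weak-early origins are suppressed 2x); fun30 loss
        raises +2/+3 nucleosome occupancy 2x, slows displaced firing 4x
        and adds 0.10 of displacement.  The sir2 fun30 double mutant also
        carries a contracted array (52 copies, ~0.35x wild type).
        """
        key = " ".join(sorted(name.lower().replace("Δ", "").split()))
        if key not in GENOTYPES:
            raise InvalidParameterError(f"unknown genotype {name!r}")
        sir2 = "sir2" in key
        fun30 = "fun30" in key
        p_d = 0.70 if sir2 else 0.10
        if fun30:
            p_d = min(1.0, p_d + 0.10)
        lam_d = 0.02 * (0.25 if fun30 else 1.0)
        occ2, occ3 = (0.25, 0.35)
        if fun30:
            occ2, occ3 = min(1.0, occ2 * 2), min(1.0, occ3 * 2)
        cpro = 1.0 * (20.0 if sir2 else 1.0) * (2.0 if fun30 else 1.0)
        copies = 52 if (sir2 and fun30) else 150
        # weak-early suppression tracks the rDNA's early-firing burden:
        # full in sir2, mostly relieved when fun30 slows displaced firing
        wes = 1.0 if not sir2 else (0.75 if fun30 else 0.5)
        return cls(sir2_deleted=sir2, fun30_deleted=fun30,
                   displaced_fraction=p_d, firing_rate_displaced=lam_d,
                   occ2=occ2, occ3=occ3,
                   weak_early_scale=wes,
                   cpro_level=cpro, physical_copies=copies)


GENOTYPES = ("wt", "sir2", "fun30", "fun30 sir2")


@dataclass(frozen=True)
class SimulationSpec:
    """One simulated experiment: model + genotype + sampling parameters."""

    model: GenomeModel
    genotype: GenotypeParams = field(default_factory=GenotypeParams)
    n_fragments: int = 200_000
    seed: int = 0
    timepoints: tuple[float, ...] = (0.0, 15.0, 30.0, 45.0, 60.0, 90.0)
    fork_speed: float = 50.0          # bp/min under 200 mM HU (~20x slowed)
    footprint_mean: float = 65.0
    footprint_sd: float = 4.0
    footprint_clip: tuple[int, int] = (51, 100)
    nucleosomal_mean: float = 165.0
    nucleosomal_sd: float = 10.0
    nucleosomal_clip: tuple[int, int] = (151, 200)
    midpoint_jitter_sd: float = 3.0
    background_fraction: float = 0.05
    rfb_deposit_width: int = 300

    def __post_init__(self) -> None:
        if self.n_fragments <= 0:
            raise InvalidParameterError("n_fragments must be > 0")
        tps = tuple(self.timepoints)
        if not tps or tps[0] != 0.0 or list(tps) != sorted(tps):
            raise InvalidParameterError(
                "timepoints must be ascending and start at 0 (G1)")

    def rng(self, assay: str) -> np.random.Generator:
        return np.random.default_rng([self.seed, _ASSAY_STREAM[assay]])

    @property
    def copies(self) -> int:
        """Physical rDNA copy number: the genotype's if set, else the
        model's."""
        if self.genotype.physical_copies is not None:
            return self.genotype.physical_copies
        return self.model.rdna.physical_copies

    def with_model(self) -> GenomeModel:
        """Model with the effective physical copy number applied."""
        return self.model.with_copies(self.copies)


def _draw_lengths(rng: np.random.Generator, n: int, mean: float, sd: float,
                  clip: tuple[int, int]) -> np.ndarray:
    lens = np.rint(rng.normal(mean, sd, size=n)).astype(np.int64)
    return np.clip(lens, clip[0], clip[1])


def _fragments_from_midpoints(mids: np.ndarray, lens: np.ndarray,
                              chrom_len: int) -> tuple[np.ndarray, np.ndarray]:
    starts = mids - lens // 2
    starts = np.clip(starts, 0, np.maximum(chrom_len - lens, 0))
    return starts, starts + lens


def _assemble(sample: SampleInfo, parts) -> FragmentLibrary:
    """Concatenate (chrom, starts, ends) parts into one library, sorted by
    (chrom, start) for reproducible byte-identical output."""
    chroms = np.concatenate([np.repeat(c, len(s)) for c, s, _ in parts]) \
        if parts else np.array([], dtype=object)
    starts = np.concatenate([s for _, s, _ in parts]) if parts else \
        np.array([], dtype=np.int64)
    ends = np.concatenate([e for _, _, e in parts]) if parts else \
        np.array([], dtype=np.int64)
    order = np.lexsort((ends, starts, chroms))
    return FragmentLibrary(sample, pd.Categorical(chroms[order]),
                           starts[order], ends[order])


# --- S-seq ------------------------------------------------------------------

@dataclass(frozen=True)
class FractionTrack:
    """Per-bin replicated fraction f in [0, 1] over the genome."""

    bin_size: int
    values: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for chrom, v in self.values.items():
            if np.any((v < 0) | (v > 1)):
                raise InvalidParameterError(
                    f"replicated fraction outside [0, 1] on {chrom}")


def make_f_track(model: GenomeModel, rdna_f: float = 0.35,
                 bin_size: int = 1000, seed: int = 0) -> FractionTrack:
    """Replicated-fraction track whose unique-genome values are a seeded
    permutation of an even grid on [0, 1] — the genome-wide median is 0.5
    by construction — with rDNA bins set to ``rdna_f``."""
    if not 0.0 <= rdna_f <= 1.0:
        raise InvalidParameterError("rdna_f outside [0, 1]")
    rng = np.random.default_rng([seed, 17])
    rd_lo, rd_hi = model.rdna.collapsed_interval
    values: dict[str, np.ndarray] = {}
    unique_slots = []
    for chrom, length in model.chromosomes:
        nbins = -(-length // bin_size)
        v = np.empty(nbins)
        v.fill(np.nan)
        if chrom == model.rdna.chrom:
            starts = np.arange(nbins) * bin_size
            in_rdna = (starts + bin_size > rd_lo) & (starts < rd_hi)
            v[in_rdna] = rdna_f
        values[chrom] = v
        unique_slots.extend((chrom, i) for i in np.flatnonzero(np.isnan(v)))
    grid = np.linspace(0.0, 1.0, len(unique_slots))
    rng.shuffle(grid)
    for (chrom, i), f in zip(unique_slots, grid):
        values[chrom][i] = f
    return FractionTrack(bin_size=bin_size, values=values)


def simulate_sseq(spec: SimulationSpec, f_track: FractionTrack
                  ) -> tuple[FragmentLibrary, FragmentLibrary]:
    """G1 and S-phase libraries.

    G1 depth follows local copy number (rDNA bins weighted N per physical
    array, i.e. N/collapsed_copies per collapsed bp); S depth additionally
    carries the factor (1 + f).  Fragment lengths model sonication
    (uniform 150–450 bp).
    """
    model = spec.with_model()
    rdna = model.rdna
    rng = spec.rng("sseq")
    bs = f_track.bin_size
    copy_per_bp = rdna.physical_copies / rdna.collapsed_copies
    rd_lo, rd_hi = rdna.collapsed_interval

    chrom_bins = []   # (chrom, bin_start, bin_len, copy_weight, f)
    for chrom, length in model.chromosomes:
        f = f_track.values[chrom]
        nbins = -(-length // bs)
        if len(f) != nbins:
            raise InvalidParameterError(
                f"f_track does not cover {chrom} ({len(f)} != {nbins} bins)")
        starts = np.arange(nbins, dtype=np.int64) * bs
        blens = np.minimum(starts + bs, length) - starts
        if chrom == rdna.chrom:
            ov = (np.minimum(starts + blens, rd_hi)
                  - np.maximum(starts, rd_lo)).clip(min=0)
        else:
            ov = np.zeros(nbins)
        weight = (blens - ov) + ov * copy_per_bp
        chrom_bins.append((chrom, starts, blens, weight, f))

    def draw(weights_per_bin: list[np.ndarray], assay: str) -> FragmentLibrary:
        w = np.concatenate(weights_per_bin)
        p = w / w.sum()
        counts = rng.multinomial(spec.n_fragments, p)
        parts = []
        offset = 0
        for (chrom, starts, blens, _, _), _w in zip(chrom_bins,
                                                    weights_per_bin):
            nb = len(starts)
            c = counts[offset:offset + nb]
            offset += nb
            mids = np.repeat(starts, c) + np.floor(
                rng.random(int(c.sum())) * np.repeat(blens, c)).astype(np.int64)
            lens = rng.integers(150, 451, size=len(mids))
            s, e = _fragments_from_midpoints(
                mids, lens, model.chrom_lengths[chrom])
            parts.append((chrom, s, e))
        return _assemble(SampleInfo(assay, _genotype_label(spec)), parts)

    g1_w = [w for _, _, _, w, _ in chrom_bins]
    s_w = [w * (1.0 + f) for (_, _, _, w, f) in chrom_bins]
    g1 = draw(g1_w, "sseq_g1")
    s = draw(s_w, "sseq_s")
    return g1, s


def _genotype_label(spec: SimulationSpec) -> str:
    g = spec.genotype
    # canonical label: deletions in alphabetical order, as for_genotype keys
    parts = [n for flag, n in ((g.fun30_deleted, "fun30"),
                               (g.sir2_deleted, "sir2")) if flag]
    return " ".join(parts) or "wt"


# --- MCM2-ChEC time course --------------------------------------------------

def _chec_weights(spec: SimulationSpec, t: float) -> dict[str, float]:
    """Unnormalized mixture weights of every ChEC component at time t.

    The rDNA block conserves N*L across (nondisplaced + displaced + RFB);
    nucleosome-adjacent and genomic-origin losses are redeposited into the
    uniform background so the grand total is constant in t.
    """
    g = spec.genotype
    N, L, pd_ = spec.copies, g.licensing_prob, g.displaced_fraction
    surv_n = np.exp(-g.firing_rate_nondisplaced * t)
    surv_d = np.exp(-g.firing_rate_displaced * t)
    w = {
        "fp_nd": N * L * (1 - pd_) * surv_n,
        "fp_d": N * L * pd_ * surv_d,
        "rfb": N * L * (pd_ * (1 - surv_d) + (1 - pd_) * (1 - surv_n)),
        "nuc1": N * L * (1 - pd_) * surv_n * g.occ1,
        "nuc2": N * L * pd_ * surv_d * g.occ2,
        "nuc3": N * L * pd_ * surv_d * g.occ3,
    }
    return w


def _origin_rates(spec: SimulationSpec) -> tuple[np.ndarray, np.ndarray,
                                                 np.ndarray]:
    """(positions, base weights, rates) for non-rDNA catalog origins."""
    g = spec.genotype
    entries = [e for e in spec.model.origins if e.oclass != "rdna"]
    pos = np.array([e.position for e in entries], dtype=np.int64)
    rates = np.array([
        LAMBDA_EARLY * (g.weak_early_scale if e.oclass == "weak_early" else 1.0)
        if e.is_early else LAMBDA_LATE for e in entries])
    weights = np.full(len(entries), 1.0)
    return pos, weights, rates


def simulate_chec_timecourse(spec: SimulationSpec) -> list[FragmentLibrary]:
    """One MCM2-ChEC library per timepoint (t=0 is the G1 reference).

    Each library holds ``spec.n_fragments`` fragments drawn from the
    mixture described in :func:`_chec_weights` plus single-copy genomic
    origin footprints (decay rate 0.02/min early, 0.0005/min late, the
    weak-early subset's rate scaled by ``weak_early_scale``) and a uniform
    background that absorbs everything the decaying components lose.
    """
    model = spec.with_model()
    rdna = model.rdna
    g = spec.genotype
    rng = spec.rng("chec")
    ori_pos, ori_w0, ori_rates = _origin_rates(spec)
    ori_chrom = [e.chrom for e in spec.model.origins if e.oclass != "rdna"]
    if len(set(ori_chrom)) > 1:
        raise InvalidParameterError("genomic origins must share a chromosome")
    ori_chrom = ori_chrom[0] if ori_chrom else None

    w0 = _chec_weights(spec, 0.0)
    signal0 = sum(w0.values()) + ori_w0.sum()
    bg0 = spec.background_fraction / (1 - spec.background_fraction) * signal0

    chrom_names = [c for c, _ in model.chromosomes]
    chrom_lens = np.array([l for _, l in model.chromosomes], dtype=float)

    # within-repeat midpoint offsets per rDNA component
    site_offset = {"fp_nd": rdna.mcm_nondisplaced, "fp_d": rdna.mcm_displaced,
                   "nuc1": rdna.nucleosome_dyads[0],
                   "nuc2": rdna.nucleosome_dyads[1],
                   "nuc3": rdna.nucleosome_dyads[2]}

    libs = []
    for t in spec.timepoints:
        w = _chec_weights(spec, t)
        ori_w = ori_w0 * np.exp(-ori_rates * t)
        lost = (signal0 - sum(w.values()) - ori_w.sum())
        bg = bg0 + lost
        comp_names = list(w) + ["origins", "background"]
        comp_w = np.array(list(w.values()) + [ori_w.sum(), bg])
        counts = rng.multinomial(spec.n_fragments, comp_w / comp_w.sum())
        n_of = dict(zip(comp_names, counts))

        parts = []
        jit = spec.midpoint_jitter_sd

        def rdna_mids(n: int, offsets: np.ndarray) -> np.ndarray:
            rep = rng.integers(0, rdna.collapsed_copies, size=n)
            return (rdna.collapsed_start + rep * rdna.repeat_length + offsets)

        for comp, off in site_offset.items():
            n = n_of[comp]
            if n == 0:
                continue
            offs = off + np.rint(rng.normal(0, jit, size=n)).astype(np.int64)
            mids = rdna_mids(n, offs)
            if comp.startswith("nuc"):
                lens = _draw_lengths(rng, n, spec.nucleosomal_mean,
                                     spec.nucleosomal_sd, spec.nucleosomal_clip)
            else:
                lens = _draw_lengths(rng, n, spec.footprint_mean,
                                     spec.footprint_sd, spec.footprint_clip)
            s, e = _fragments_from_midpoints(
                mids, lens, model.chrom_lengths[rdna.chrom])
            parts.append((rdna.chrom, s, e))

        n = n_of["rfb"]
        if n:
            offs = rng.integers(rdna.rfb - spec.rfb_deposit_width, rdna.rfb,
                                size=n)
            mids = rdna_mids(n, offs)
            lens = _draw_lengths(rng, n, spec.footprint_mean,
                                 spec.footprint_sd, spec.footprint_clip)
            s, e = _fragments_from_midpoints(
                mids, lens, model.chrom_lengths[rdna.chrom])
            parts.append((rdna.chrom, s, e))

        n = n_of["origins"]
        if n and len(ori_pos):
            per_ori = rng.multinomial(n, ori_w / ori_w.sum())
            mids = (np.repeat(ori_pos, per_ori)
                    + np.rint(rng.normal(0, jit, size=n)).astype(np.int64))
            lens = _draw_lengths(rng, n, spec.footprint_mean,
                                 spec.footprint_sd, spec.footprint_clip)
            s, e = _fragments_from_midpoints(
                mids, lens, model.chrom_lengths[ori_chrom])
            parts.append((ori_chrom, s, e))

        n = n_of["background"]
        if n:
            per_chrom = rng.multinomial(n, chrom_lens / chrom_lens.sum())
            for cname, clen, cn in zip(chrom_names, chrom_lens, per_chrom):
                if cn == 0:
                    continue
                mids = rng.integers(0, int(clen), size=cn)
                lens = rng.integers(spec.footprint_clip[0],
                                    spec.nucleosomal_clip[1] + 51, size=cn)
                s, e = _fragments_from_midpoints(mids, lens, int(clen))
                parts.append((cname, s, e))

        libs.append(_assemble(
            SampleInfo("chec", _genotype_label(spec), float(t)), parts))
    return libs


# --- MNase-seq --------------------------------------------------------------

def simulate_mnase(spec: SimulationSpec,
                   background_spacing: int = 165) -> FragmentLibrary:
    """Nucleosomal library: +1/+2/+3 rDNA dyads emit with probabilities
    (occ1, occ2, occ3) scaled by physical copy number; the unique genome
    carries a phased background nucleosome every ``background_spacing`` bp.
    Inside the collapsed array only the modeled dyads emit, so dyad-window
    occupancy ratios are background-free.
    """
    model = spec.with_model()
    rdna = model.rdna
    g = spec.genotype
    rng = spec.rng("mnase")
    N = spec.copies

    dyad_w = np.array([g.occ1, g.occ2, g.occ3]) * N * g.licensing_prob
    # phased background over non-array sequence
    bg_sites = []   # (chrom, position array)
    n_bg = 0
    for chrom, length in model.chromosomes:
        pos = np.arange(background_spacing // 2, length, background_spacing,
                        dtype=np.int64)
        if chrom == rdna.chrom:
            lo, hi = rdna.collapsed_interval
            pos = pos[(pos < lo) | (pos >= hi)]
        bg_sites.append((chrom, pos))
        n_bg += len(pos)

    weights = np.concatenate([dyad_w, [float(n_bg)]])
    counts = rng.multinomial(spec.n_fragments, weights / weights.sum())

    parts = []
    jit = spec.midpoint_jitter_sd
    for k in range(3):
        n = counts[k]
        if n == 0:
            continue
        rep = rng.integers(0, rdna.collapsed_copies, size=n)
        mids = (rdna.collapsed_start + rep * rdna.repeat_length
                + rdna.nucleosome_dyads[k]
                + np.rint(rng.normal(0, jit, size=n)).astype(np.int64))
        lens = _draw_lengths(rng, n, spec.nucleosomal_mean,
                             spec.nucleosomal_sd, spec.nucleosomal_clip)
        s, e = _fragments_from_midpoints(
            mids, lens, model.chrom_lengths[rdna.chrom])
        parts.append((rdna.chrom, s, e))

    n = counts[3]
    if n:
        site_counts = rng.multinomial(
            n, np.concatenate([np.full(len(p), 1.0) for _, p in bg_sites])
            / n_bg)
        offset = 0
        for chrom, pos in bg_sites:
            cn = site_counts[offset:offset + len(pos)]
            offset += len(pos)
            tot = int(cn.sum())
            if tot == 0:
                continue
            mids = (np.repeat(pos, cn)
                    + np.rint(rng.normal(0, jit, size=tot)).astype(np.int64))
            lens = _draw_lengths(rng, tot, spec.nucleosomal_mean,
                                 spec.nucleosomal_sd, spec.nucleosomal_clip)
            s, e = _fragments_from_midpoints(mids, lens,
                                             model.chrom_lengths[chrom])
            parts.append((chrom, s, e))

    return _assemble(SampleInfo("mnase", _genotype_label(spec)), parts)


# --- EdU-seq ----------------------------------------------------------------

def simulate_edu(spec: SimulationSpec, harvest_minutes: float = 60.0,
                 cells_per_origin: int = 200) -> FragmentLibrary:
    """Nascent-DNA library at ``harvest_minutes`` after release into HU.

    For each origin, ``cells_per_origin`` exponential firing times are
    sampled at the origin's class rate (early 0.02/min, weak-early
    scaled, late 0.0005/min; each rDNA repeat draws a displaced or
    nondisplaced rate and the array contributes N*L repeats' worth of
    signal).  A cell whose origin fired at T contributes reads uniform on
    +-fork_speed*(harvest - T); signal is the average over cells, so the
    library mimics a sequenced cell population.
    """
    if harvest_minutes <= 0:
        raise InvalidParameterError("harvest_minutes must be > 0")
    if cells_per_origin < 1:
        raise InvalidParameterError("cells_per_origin must be >= 1")
    model = spec.with_model()
    g = spec.genotype
    rng = spec.rng("edu")
    v = spec.fork_speed
    K = cells_per_origin

    entries = list(spec.model.origins)
    n_ori = len(entries)
    rates = np.empty((n_ori, K))
    mults = np.empty(n_ori)
    for i, e in enumerate(entries):
        if e.oclass == "rdna":
            displaced = rng.random(K) < g.displaced_fraction
            rates[i] = np.where(displaced, g.firing_rate_displaced,
                                g.firing_rate_nondisplaced)
            mults[i] = float(spec.copies) * g.licensing_prob
        else:
            if e.oclass == "weak_early":
                r = LAMBDA_EARLY * g.weak_early_scale
            elif e.oclass == "early":
                r = LAMBDA_EARLY
            else:
                r = LAMBDA_LATE
            rates[i] = r
            mults[i] = 1.0
    with np.errstate(divide="ignore"):
        fire_t = rng.exponential(np.where(rates > 0, 1.0 / rates, np.inf))
    extent = np.where(fire_t < harvest_minutes,
                      v * (harvest_minutes - fire_t), 0.0)   # (n_ori, K)
    weights = mults * 2.0 * extent.mean(axis=1)
    signal = weights.sum()
    bg = (spec.background_fraction / (1 - spec.background_fraction) * signal
          if signal > 0 else 1.0)

    chrom_names = [c for c, _ in model.chromosomes]
    chrom_lens = np.array([l for _, l in model.chromosomes], dtype=float)
    all_w = np.concatenate([weights, [bg]])
    counts = rng.multinomial(spec.n_fragments, all_w / all_w.sum())

    parts = []
    for i, (e, n) in enumerate(zip(entries, counts[:-1])):
        if n == 0:
            continue
        ext = extent[i]
        fired = np.flatnonzero(ext > 0)
        cell = fired[rng.choice(len(fired), size=n,
                                p=ext[fired] / ext[fired].sum())]
        offs = (rng.random(n) * 2.0 - 1.0) * ext[cell]
        mids = e.position + np.rint(offs).astype(np.int64)
        mids = np.clip(mids, 0, model.chrom_lengths[e.chrom] - 1)
        lens = rng.integers(150, 451, size=n)
        s, en = _fragments_from_midpoints(mids, lens,
                                          model.chrom_lengths[e.chrom])
        parts.append((e.chrom, s, en))
    n = counts[-1]
    if n:
        per_chrom = rng.multinomial(n, chrom_lens / chrom_lens.sum())
        for cname, clen, cn in zip(chrom_names, chrom_lens, per_chrom):
            if cn == 0:
                continue
            mids = rng.integers(0, int(clen), size=cn)
            lens = rng.integers(150, 451, size=cn)
            s, en = _fragments_from_midpoints(mids, lens, int(clen))
            parts.append((cname, s, en))
    return _assemble(SampleInfo("edu", _genotype_label(spec),
                                float(harvest_minutes)), parts)


# --- licensing Southern -----------------------------------------------------

def simulate_licensing_assay(spec: SimulationSpec,
                             cut_efficiency: float = 1.0,
                             baseline: float = 100.0,
                             noise_sigma: float = 0.05,
                             reference_copies: int = 150) -> BandQuant:
    """Band intensities for the restriction-fragment licensing assay.

    MCM-MNase activation destroys the target fragment in the licensed
    fraction L of repeats: the target band at time t has expectation
    baseline*(1 - L*cut_efficiency); the loading control is constant; the
    uncut band scales with physical copy number.  All intensities carry
    multiplicative lognormal noise (sigma 0.05).
    """
    if not 0.0 <= cut_efficiency <= 1.0:
        raise InvalidParameterError("cut_efficiency outside [0, 1]")
    g = spec.genotype
    rng = spec.rng("licensing")

    def noisy(x: float) -> float:
        return float(x * rng.lognormal(0.0, noise_sigma))

    depleted = baseline * (1.0 - g.licensing_prob * cut_efficiency)
    per_copy = baseline / reference_copies
    return BandQuant(
        target_t0=noisy(baseline),
        target_t=noisy(depleted),
        control_t0=noisy(baseline),
        control_t=noisy(baseline),
        uncut=noisy(per_copy * spec.copies),
        uncut_reference=noisy(per_copy * reference_copies),
    )
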