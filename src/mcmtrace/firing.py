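"""Origin-firing inference from MCM-ChEC signal loss across an HU time
course.

A loaded MCM double-hexamer protects its footprint until the origin
fires; firing converts the footprint into a moving replisome, so the
ChEC signal at the binding site disappears with first-order kinetics.
At the rDNA the stalled forks pile up left of the replication fork
barrier (RFB), so rDNA footprint loss is mirrored by RFB-proximal gain —
a built-in control that the signal moved rather than degraded.

Retained fraction: R(t) = scaled count at t / scaled count in G1 per
window, after max-total depth normalization across the time course.
The minimal kinetic summary is the zero-intercept exponential fit
R(t) = exp(-lambda t), with the closed form

    lambda = -sum(t * ln R(t)) / sum(t^2).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .fragments import FragmentLibrary, scale_to_max_total
from .locus import GenomeModel, OriginCatalog, InvalidParameterError
from .profiles import (MCM_SIZE_CLASS, mcm_site_windows, repeat_window_signal,
                       window_signal)

__all__ = [
    "decay_table",
    "early_late_separation",
    "displaced_vs_nondisplaced",
    "rfb_accumulation",
    "FiringEstimate",
    "fit_firing_rate",
    "MIN_RELIABLE_G1_COUNT",
]

#: Windows with fewer G1 counts than this are flagged unreliable.
MIN_RELIABLE_G1_COUNT = 50


def _check_timecourse(timecourse: list[FragmentLibrary]) -> None:
    if not timecourse:
        raise InvalidParameterError("empty time course")
    tps = [lib.sample.timepoint for lib in timecourse]
    if 0.0 not in tps:
        raise InvalidParameterError("time course lacks a G1 (t=0) library")
    if len(set(lib.sample.genotype for lib in timecourse)) > 1:
        raise InvalidParameterError("libraries mix genotypes")


def decay_table(timecourse: list[FragmentLibrary],
                windows,
                size_class: tuple[int, int] | None = MCM_SIZE_CLASS,
                model: GenomeModel | None = None,
                repeat_relative: bool = False) -> pd.DataFrame:
    """Per-window, per-timepoint raw/scaled counts and retained fraction.

    ``windows`` are (name, chrom, start, end, class) genome windows, or
    repeat-relative (name, start, end) windows with ``repeat_relative``
    (then ``model`` is required).  Scaling is max-total across the
    libraries; R = scaled_t / scaled_G1, NaN where the G1 count is zero.
    """
    _check_timecourse(timecourse)
    factors = scale_to_max_total(timecourse)
    names = [w[0] for w in windows]
    rows = []
    for lib, factor in zip(timecourse, factors):
        if repeat_relative:
            if model is None:
                raise InvalidParameterError(
                    "repeat-relative windows need a model")
            raw = repeat_window_signal(lib, model, windows, size_class)
        else:
            raw = window_signal(lib, windows, size_class)
        for name, r in zip(names, raw):
            rows.append((name, lib.sample.timepoint, int(r),
                         float(r) * factor))
    df = pd.DataFrame(rows, columns=["window", "timepoint", "raw", "scaled"])
    g1 = df[df.timepoint == 0.0].set_index("window")["scaled"]
    df["retained"] = [
        row.scaled / g1[row.window] if g1[row.window] > 0 else np.nan
        for row in df.itertuples()]
    df["flagged"] = df["window"].map(g1 < MIN_RELIABLE_G1_COUNT)
    return df


def early_late_separation(table: pd.DataFrame, catalog: OriginCatalog,
                          t: float, equal_var: bool = True
                          ) -> tuple[float, float, float, float]:
    """Two-sample t test on per-origin log2 retained fractions of early vs
    late origins at timepoint t.  Returns (mean log2 R early, mean log2 R
    late, t statistic, two-tailed p)."""
    classes = {e.name: ("early" if e.is_early else e.oclass)
               for e in catalog}
    at_t = table[(table.timepoint == t) & table.retained.notna()
                 & (table.retained > 0)]
    log2r = {}
    for cls in ("early", "late"):
        vals = at_t[at_t.window.map(classes) == cls].retained
        if len(vals) < 2:
            raise InvalidParameterError(
                f"class {cls!r} has < 2 origins at t={t}")
        log2r[cls] = np.log2(vals.to_numpy())
    tstat, p = stats.ttest_ind(log2r["early"], log2r["late"],
                               equal_var=equal_var)
    return (float(log2r["early"].mean()), float(log2r["late"].mean()),
            float(tstat), float(p))


def displaced_vs_nondisplaced(table: pd.DataFrame) -> pd.DataFrame:
    """Paired retained fractions of the displaced and nondisplaced rDNA
    MCM windows per timepoint, with their difference."""
    need = {"mcm_displaced", "mcm_nondisplaced"}
    if not need <= set(table.window):
        raise InvalidParameterError(
            "table lacks the rDNA MCM windows " + str(need))
    piv = (table[table.window.isin(need)]
           .pivot(index="timepoint", columns="window", values="retained"))
    out = pd.DataFrame({
        "R_displaced": piv["mcm_displaced"],
        "R_nondisplaced": piv["mcm_nondisplaced"],
    })
    out["difference"] = out.R_displaced - out.R_nondisplaced
    return out.reset_index()


def rfb_accumulation(timecourse: list[FragmentLibrary], model: GenomeModel,
                     window_width: int = 300,
                     size_class: tuple[int, int] | None = MCM_SIZE_CLASS
                     ) -> pd.DataFrame:
    """Scaled footprint-class counts in [rfb - width, rfb) per timepoint,
    as gain over the G1 baseline."""
    _check_timecourse(timecourse)
    factors = scale_to_max_total(timecourse)
    rfb = model.rdna.rfb
    win = [("rfb", rfb - window_width, rfb)]
    rows = []
    for lib, factor in zip(timecourse, factors):
        raw = repeat_window_signal(lib, model, win, size_class)[0]
        rows.append((lib.sample.timepoint, int(raw), float(raw) * factor))
    df = pd.DataFrame(rows, columns=["timepoint", "raw", "scaled"])
    baseline = float(df.loc[df.timepoint == 0.0, "scaled"].iloc[0])
    df["gain"] = df["scaled"] - baseline
    return df


def rdna_decay_table(timecourse: list[FragmentLibrary], model: GenomeModel,
                     width: int = 100,
                     size_class: tuple[int, int] = MCM_SIZE_CLASS
                     ) -> pd.DataFrame:
    """Decay table for the two rDNA MCM windows (repeat-folded)."""
    return decay_table(timecourse, mcm_site_windows(model, width),
                       size_class=size_class, model=model,
                       repeat_relative=True)


class FiringEstimate:
    """Zero-intercept exponential decay fit of one window's R(t)."""

    def __init__(self, window: str, rate: float, residual: float,
                 timepoints: tuple[float, ...]):
        if rate < 0:
            rate = 0.0
        self.window = window
        self.rate = rate
        self.residual = residual
        self.timepoints = timepoints

    def __repr__(self) -> str:
        return (f"FiringEstimate({self.window!r}, rate={self.rate:.4g}/min, "
                f"residual={self.residual:.3g})")


def fit_firing_rate(table: pd.DataFrame, window: str) -> FiringEstimate:
    """Least-squares exponential rate through R(0) = 1:
    lambda = -sum(t ln R)/sum(t^2) over post-G1 timepoints with R > 0."""
    rows = table[(table.window == window) & (table.timepoint > 0)
                 & table.retained.notna()]
    zero = rows[rows.retained == 0]
    if len(zero):
        warnings.warn(f"{window}: dropping {len(zero)} timepoint(s) with "
                      "R = 0 from the rate fit", stacklevel=2)
        rows = rows[rows.retained > 0]
    if len(rows) < 2:
        raise InvalidParameterError(
            f"window {window!r}: need >= 2 usable post-G1 timepoints")
    t = rows.timepoint.to_numpy(dtype=float)
    lnr = np.log(rows.retained.to_numpy(dtype=float))
    lam = -(t * lnr).sum() / (t * t).sum()
    resid = float(((lnr + lam * t) ** 2).sum())
    return FiringEstimate(window, float(lam), resid, tuple(t))
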