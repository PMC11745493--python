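"""Origin activity from EdU-seq: depth-normalized 5 kb window sums,
per-class medians of log10 signal, and genotype drop comparisons.

EdU marks DNA synthesized after release into HU, so window sums around
origins report how much each origin fired.  Libraries are normalized to
the deepest sample (max-total rule), sums are taken over windows
centered on the MCM binding site, and genotype effects are summarized
as the median log10 signal of an origin class and compared via t tests
on per-origin drops.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .fragments import FragmentLibrary, scale_to_max_total
from .locus import GenomeModel, OriginCatalog, InvalidParameterError
from .locus import origin_windows
from .profiles import window_signal

__all__ = ["origin_activity", "median_log10", "compare_drops"]


def origin_activity(libs: list[FragmentLibrary], catalog: OriginCatalog,
                    model: GenomeModel | None = None,
                    window: int = 5000) -> pd.DataFrame:
    """Scaled per-origin window sums for each library.

    Columns: origin, oclass, genotype, total (scaled midpoint count in the
    window), log10 (NaN for zero totals, which are flagged)."""
    if not libs:
        raise InvalidParameterError("no libraries")
    for lib in libs:
        lib.require_nonempty()
    chrom_lengths = model.chrom_lengths if model is not None else None
    wins = origin_windows(catalog, window, chrom_lengths)
    factors = scale_to_max_total(libs)
    rows = []
    for lib, factor in zip(libs, factors):
        raw = window_signal(lib, wins)
        for (name, _, _, _, cls), r in zip(wins, raw):
            total = float(r) * factor
            rows.append((name, cls, lib.sample.genotype, total,
                         np.log10(total) if total > 0 else np.nan))
    return pd.DataFrame(rows, columns=["origin", "oclass", "genotype",
                                       "total", "log10"])


def _select(table: pd.DataFrame, oclass: str, genotype: str) -> pd.DataFrame:
    if oclass == "early":
        m = table.oclass.isin(("early", "weak_early"))
    else:
        m = table.oclass == oclass
    return table[m & (table.genotype == genotype)]


def median_log10(table: pd.DataFrame, oclass: str, genotype: str) -> float:
    """Median log10 window sum of one origin class in one genotype;
    zero-signal origins are excluded (their count is in the table)."""
    sel = _select(table, oclass, genotype)
    vals = sel.log10.dropna()
    if vals.empty:
        raise InvalidParameterError(
            f"no positive sums for class {oclass!r} genotype {genotype!r}")
    return float(vals.median())


def compare_drops(table: pd.DataFrame, wt: str, mut_a: str, mut_b: str,
                  oclass: str = "early", paired: bool = False
                  ) -> tuple[float, float]:
    """t test comparing the per-origin log10 drop from WT to mutant A with
    the drop from WT to mutant B.

    Drops d_X = log10(WT) - log10(X) are computed origin-by-origin on the
    matched origin set; origins with zero signal in any of the three
    samples are excluded pairwise.  Default is the unpaired two-sample
    Student t on the two drop vectors; ``paired`` switches to the paired
    test on d_A - d_B.
    """
    frames = {}
    for g in (wt, mut_a, mut_b):
        sel = _select(table, oclass, g).set_index("origin")["log10"]
        if sel.empty:
            raise InvalidParameterError(f"genotype {g!r} absent from table")
        frames[g] = sel
    merged = pd.concat(frames, axis=1, join="inner").dropna()
    if merged.empty or len(merged) < 2:
        raise InvalidParameterError("fewer than 2 matched origins")
    d_a = (merged[wt] - merged[mut_a]).to_numpy()
    d_b = (merged[wt] - merged[mut_b]).to_numpy()
    if paired:
        tstat, p = stats.ttest_rel(d_a, d_b)
    else:
        tstat, p = stats.ttest_ind(d_a, d_b, equal_var=True)
    if np.isnan(tstat):
        # degenerate zero-variance case: identical drops are a clean null
        if np.allclose(d_a, d_b):
            return 0.0, 1.0
        return float(np.inf) * np.sign(d_a.mean() - d_b.mean()), 0.0
    return float(tstat), float(p)
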