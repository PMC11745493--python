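import numpy as np
import pandas as pd
import pytest

from mcmtrace.firing import (decay_table, displaced_vs_nondisplaced,
                             early_late_separation, fit_firing_rate,
                             rdna_decay_table, rfb_accumulation)
from mcmtrace.fragments import FragmentLibrary, SampleInfo
from mcmtrace.locus import (InvalidParameterError, OriginCatalog,
                            OriginEntry)
from mcmtrace.simulate import (GenotypeParams, SimulationSpec,
                               simulate_chec_timecourse)


def make_lib(midpoints, t, chrom="chrU"):
    mids = np.asarray(midpoints, dtype=np.int64)
    return FragmentLibrary(SampleInfo("chec", "wt", t),
                           pd.Categorical([chrom] * len(mids)),
                           mids - 32, mids + 33)


def synth_table(rows):
    """rows: (window, timepoint, retained)"""
    return pd.DataFrame(
        [(w, t, 100, 100.0, r, False) for w, t, r in rows],
        columns=["window", "timepoint", "raw", "scaled", "retained",
                 "flagged"])


class TestDecayTable:
    def test_duplicate_g1_gives_unit_retention(self):
        mids = list(range(1000, 1100)) * 3
        libs = [make_lib(mids, 0.0), make_lib(mids, 15.0)]
        wins = [("w", "chrU", 900, 1200, "early")]
        tab = decay_table(libs, wins, size_class=(51, 100))
        assert np.allclose(tab.retained, 1.0)

    def test_missing_g1_rejected(self):
        libs = [make_lib([1000], 15.0)]
        with pytest.raises(InvalidParameterError):
            decay_table(libs, [("w", "chrU", 0, 2000, "early")])

    def test_mixed_genotypes_rejected(self):
        a = make_lib([1000], 0.0)
        b = make_lib([1000], 15.0)
        b.sample = SampleInfo("chec", "sir2", 15.0)
        with pytest.raises(InvalidParameterError):
            decay_table([a, b], [("w", "chrU", 0, 2000, "early")])

    def test_global_count_scaling_leaves_R_unchanged(self):
        mids0 = list(range(1000, 1200))
        mids1 = list(range(1000, 1100))
        wins = [("w", "chrU", 900, 1300, "early")]
        tab1 = decay_table([make_lib(mids0, 0.0), make_lib(mids1, 30.0)],
                           wins, size_class=(51, 100))
        tab2 = decay_table([make_lib(mids0 * 3, 0.0),
                            make_lib(mids1 * 3, 30.0)],
                           wins, size_class=(51, 100))
        assert np.allclose(tab1.retained, tab2.retained)


class TestEarlyLateSeparation:
    @staticmethod
    def catalog(n_early=3, n_late=3):
        entries = [OriginEntry(f"e{i}", "chrU", 1000 * (i + 1), "early")
                   for i in range(n_early)]
        entries += [OriginEntry(f"l{i}", "chrU", 50_000 + 1000 * i, "late")
                    for i in range(n_late)]
        return OriginCatalog(tuple(entries))

    def test_pooled_t_closed_form(self):
        # log2 R groups {1,2,3} vs {2,3,4}: t = -1.2247, p = 0.2861 (df 4)
        rows = [(f"e{i}", 60.0, 2.0 ** v) for i, v in enumerate((1, 2, 3))]
        rows += [(f"l{i}", 60.0, 2.0 ** v) for i, v in enumerate((2, 3, 4))]
        me, ml, t, p = early_late_separation(synth_table(rows),
                                             self.catalog(), 60.0)
        assert (me, ml) == (2.0, 3.0)
        assert t == pytest.approx(-1.224745, abs=1e-5)
        assert p == pytest.approx(0.287823, abs=1e-4)

    def test_identical_groups_null(self):
        rows = [(f"e{i}", 60.0, 2.0 ** v) for i, v in enumerate((1, 2, 3))]
        rows += [(f"l{i}", 60.0, 2.0 ** v) for i, v in enumerate((1, 2, 3))]
        _, _, t, p = early_late_separation(synth_table(rows),
                                           self.catalog(), 60.0)
        assert t == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0, abs=1e-12)

    def test_underpopulated_class_rejected(self):
        rows = [("e0", 60.0, 0.5), ("l0", 60.0, 0.9), ("l1", 60.0, 0.8)]
        with pytest.raises(InvalidParameterError):
            early_late_separation(synth_table(rows), self.catalog(), 60.0)


class TestDisplacedVsNondisplaced:
    def test_sir2_displaced_disappears_faster(self, sir2_chec):
        spec, libs = sir2_chec
        tab = rdna_decay_table(libs, spec.with_model())
        dn = displaced_vs_nondisplaced(tab)
        post = dn[dn.timepoint > 0]
        assert (post.R_displaced < post.R_nondisplaced).all()
        # survival at 60 min tracks the generative rates
        at60 = dn[dn.timepoint == 60.0].iloc[0]
        assert at60.R_displaced == pytest.approx(np.exp(-1.2), abs=0.03)
        assert at60.R_nondisplaced == pytest.approx(np.exp(-0.12), abs=0.03)

    def test_equal_rates_equal_decay(self, model150):
        gt = GenotypeParams(displaced_fraction=0.5,
                            firing_rate_nondisplaced=0.01,
                            firing_rate_displaced=0.01)
        spec = SimulationSpec(model=model150, genotype=gt,
                              n_fragments=200_000, seed=51)
        libs = simulate_chec_timecourse(spec)
        dn = displaced_vs_nondisplaced(
            rdna_decay_table(libs, spec.with_model()))
        assert np.all(np.abs(dn.difference) < 0.03)

    def test_missing_windows_rejected(self):
        with pytest.raises(InvalidParameterError):
            displaced_vs_nondisplaced(synth_table([("w", 0.0, 1.0)]))


class TestRfbAccumulation:
    def test_baseline_gain_zero(self, wt_chec):
        spec, libs = wt_chec
        acc = rfb_accumulation(libs, spec.with_model())
        assert acc.loc[acc.timepoint == 0.0, "gain"].iloc[0] == 0.0

    def test_gain_matches_mcm_loss(self, wt_chec):
        """Helicases leaving the origin pile up left of the RFB: scaled
        window loss and RFB gain agree within counting error."""
        spec, libs = wt_chec
        model = spec.with_model()
        tab = rdna_decay_table(libs, model)
        acc = rfb_accumulation(libs, model)
        g1 = tab[tab.timepoint == 0].set_index("window").scaled
        for t in (30.0, 60.0, 90.0):
            at = tab[tab.timepoint == t].set_index("window").scaled
            loss = float((g1 - at).sum())
            gain = float(acc.loc[acc.timepoint == t, "gain"].iloc[0])
            rfb0 = float(acc.loc[acc.timepoint == 0.0, "scaled"].iloc[0])
            rfbt = float(acc.loc[acc.timepoint == t, "scaled"].iloc[0])
            se = np.sqrt(g1.sum() + at.sum() + rfb0 + rfbt)
            assert abs(gain - loss) < 3 * se

    def test_fun30_suppresses_sir2_accumulation(self, model150):
        gains = {}
        for name in ("sir2", "fun30 sir2"):
            gt = GenotypeParams.for_genotype(name)
            spec = SimulationSpec(model=model150, genotype=gt,
                                  n_fragments=200_000, seed=52)
            libs = simulate_chec_timecourse(spec)
            acc = rfb_accumulation(libs, spec.with_model())
            gains[name] = float(
                acc.loc[acc.timepoint == 60.0, "gain"].iloc[0])
        assert gains["fun30 sir2"] < gains["sir2"]


class TestFitFiringRate:
    def test_no_decay_zero_rate(self):
        tab = synth_table([("w", t, 1.0) for t in (0, 15, 30, 45, 60, 90)])
        assert fit_firing_rate(tab, "w").rate == 0.0

    def test_noiseless_exponential_exact(self):
        tab = synth_table([("w", t, np.exp(-0.02 * t))
                           for t in (0, 15, 30, 45, 60, 90)])
        est = fit_firing_rate(tab, "w")
        assert est.rate == pytest.approx(0.02, abs=1e-12)
        assert est.residual == pytest.approx(0.0, abs=1e-20)

    def test_zero_retention_dropped_with_warning(self):
        rows = [("w", t, np.exp(-0.02 * t)) for t in (0, 15, 30, 45)]
        rows.append(("w", 90.0, 0.0))
        with pytest.warns(UserWarning, match="R = 0"):
            est = fit_firing_rate(synth_table(rows), "w")
        assert est.rate == pytest.approx(0.02, abs=1e-12)

    def test_too_few_timepoints_rejected(self):
        with pytest.raises(InvalidParameterError):
            fit_firing_rate(synth_table([("w", 0.0, 1.0),
                                         ("w", 15.0, 0.7)]), "w")

    def test_ordering_of_rates_orders_retention(self, sir2_chec):
        spec, libs = sir2_chec
        tab = rdna_decay_table(libs, spec.with_model())
        fast = fit_firing_rate(tab, "mcm_displaced")
        slow = fit_firing_rate(tab, "mcm_nondisplaced")
        assert fast.rate > slow.rate
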