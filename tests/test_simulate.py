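import numpy as np
import pytest

from mcmtrace.fragments import write_fragments
from mcmtrace.locus import InvalidParameterError, default_genome_model
from mcmtrace.profiles import MCM_SIZE_CLASS, NUCLEOSOME_SIZE_CLASS
from mcmtrace.quant import licensed_fraction
from mcmtrace.simulate import (GENOTYPES, FractionTrack, GenotypeParams,
                               SimulationSpec, _chec_weights, make_f_track,
                               simulate_chec_timecourse,
                               simulate_licensing_assay, simulate_mnase,
                               simulate_sseq)


class TestGenotypeParams:
    def test_probability_bounds_enforced(self):
        with pytest.raises(InvalidParameterError):
            GenotypeParams(licensing_prob=1.2)
        with pytest.raises(InvalidParameterError):
            GenotypeParams(firing_rate_displaced=-0.1)

    def test_unknown_genotype_rejected(self):
        with pytest.raises(InvalidParameterError):
            GenotypeParams.for_genotype("rad52")

    def test_genotype_table(self):
        wt = GenotypeParams.for_genotype("wt")
        sir2 = GenotypeParams.for_genotype("sir2")
        dbl = GenotypeParams.for_genotype("sir2 fun30")
        assert (wt.displaced_fraction, sir2.displaced_fraction) == (0.10,
                                                                    0.70)
        assert dbl.displaced_fraction == pytest.approx(0.80)
        assert dbl.firing_rate_displaced == pytest.approx(0.005)
        assert dbl.occ2 == pytest.approx(0.50)
        assert dbl.physical_copies == 52
        assert sir2.cpro_level == 20.0 and dbl.cpro_level == 40.0

    def test_genotype_name_order_insensitive(self):
        assert (GenotypeParams.for_genotype("sir2 fun30")
                == GenotypeParams.for_genotype("fun30 sir2"))


class TestFractionTrack:
    def test_median_exactly_half(self, model150):
        track = make_f_track(model150, rdna_f=0.35, seed=5)
        unique = np.concatenate([
            v[~np.isclose(v, 0.35)] if c == "chrXII" else v
            for c, v in track.values.items()])
        assert np.median(unique) == pytest.approx(0.5, abs=1e-9)

    def test_rdna_bins_hold_target_fraction(self, model150):
        track = make_f_track(model150, rdna_f=0.8, seed=5)
        v = track.values["chrXII"]
        assert np.allclose(v[450:468], 0.8)

    def test_out_of_range_rejected(self, model150):
        with pytest.raises(InvalidParameterError):
            make_f_track(model150, rdna_f=1.2)
        with pytest.raises(InvalidParameterError):
            FractionTrack(1000, {"chrU": np.array([0.5, -0.1])})


class TestSseq:
    def test_flat_track_unit_depth_ratio(self, mini_model):
        spec = SimulationSpec(model=mini_model, n_fragments=200_000, seed=71)
        flat = FractionTrack(1000, {
            "chrU": np.zeros(91), "chrR": np.zeros(19)})
        g1, s = simulate_sseq(spec, flat)
        # S and G1 depth profiles agree in expectation everywhere
        ratio = len(s) / len(g1)
        assert ratio == 1.0
        hg = np.histogram(g1.midpoints[np.asarray(g1.chroms == "chrU")],
                          bins=10, range=(0, 91_000))[0]
        hs = np.histogram(s.midpoints[np.asarray(s.chroms == "chrU")],
                          bins=10, range=(0, 91_000))[0]
        assert np.all(np.abs(hs / hg - 1) < 0.05)

    def test_replicated_bin_doubles_depth(self, mini_model):
        spec = SimulationSpec(model=mini_model, n_fragments=400_000, seed=72)
        f = np.zeros(91)
        f[10] = 1.0            # bin 10 fully replicated, bin 20 not
        track = FractionTrack(1000, {"chrU": f, "chrR": np.zeros(19)})
        _, s = simulate_sseq(spec, track)
        mids = s.midpoints[np.asarray(s.chroms == "chrU")]
        n10 = np.sum((mids >= 10_000) & (mids < 11_000))
        n20 = np.sum((mids >= 20_000) & (mids < 21_000))
        assert n10 / n20 == pytest.approx(2.0, abs=0.15)

    def test_f_track_must_cover_genome(self, mini_model):
        spec = SimulationSpec(model=mini_model, n_fragments=1000, seed=73)
        with pytest.raises(InvalidParameterError):
            simulate_sseq(spec, FractionTrack(1000, {
                "chrU": np.zeros(10), "chrR": np.zeros(19)}))


class TestChecMixture:
    def test_determinism_byte_identical(self, model150, tmp_path):
        spec = SimulationSpec(model=model150, n_fragments=30_000, seed=74,
                              timepoints=(0.0, 30.0))
        for run in ("a", "b"):
            libs = simulate_chec_timecourse(spec)
            for i, lib in enumerate(libs):
                write_fragments(lib, tmp_path / f"{run}{i}.bed")
        for i in range(2):
            assert ((tmp_path / f"a{i}.bed").read_bytes()
                    == (tmp_path / f"b{i}.bed").read_bytes())

    def test_total_mixture_weight_conserved(self, model150):
        gt = GenotypeParams.for_genotype("sir2")
        spec = SimulationSpec(model=model150, genotype=gt, n_fragments=1,
                              seed=0)
        w0 = sum(_chec_weights(spec, 0.0).values())
        for t in (15.0, 60.0, 90.0):
            w = _chec_weights(spec, t)
            fp = w["fp_nd"] + w["fp_d"] + w["rfb"]
            # footprint + RFB deposit conserve the licensed signal N*L
            assert fp == pytest.approx(
                spec.copies * gt.licensing_prob, rel=1e-12)

    def test_monotone_footprint_decay(self, model150):
        spec = SimulationSpec(model=model150, n_fragments=1, seed=0)
        ts = np.linspace(0, 120, 25)
        for comp in ("fp_nd", "fp_d", "nuc1", "nuc2", "nuc3"):
            vals = [_chec_weights(spec, t)[comp] for t in ts]
            assert np.all(np.diff(vals) <= 1e-12)

    def test_size_classes_pure_at_their_sites(self, wt_chec):
        spec, libs = wt_chec
        model = spec.with_model()
        rdna = model.rdna
        lib = libs[0]
        on = np.asarray(lib.chroms == rdna.chrom)
        folded = (lib.midpoints[on] - rdna.collapsed_start) \
            % rdna.repeat_length
        inside = (lib.midpoints[on] >= rdna.collapsed_start) & (
            lib.midpoints[on] < rdna.collapsed_end)
        lens = lib.lengths[on]
        at_mcm = inside & (np.abs(folded - rdna.mcm_nondisplaced) <= 15)
        frac_fp = np.mean((lens[at_mcm] >= 51) & (lens[at_mcm] <= 100))
        assert frac_fp >= 0.99
        at_nuc = inside & (np.abs(folded - rdna.nucleosome_dyads[0]) <= 15)
        nuc_lens = lens[at_nuc & (lens >= 151)]
        assert np.all(nuc_lens <= 200)

    def test_empirical_conservation_across_timepoints(self, wt_chec):
        """Counts in footprint windows + RFB deposit stay constant in t
        within counting error: fragments move, none vanish."""
        spec, libs = wt_chec
        model = spec.with_model()
        rdna = model.rdna
        w = spec.rfb_deposit_width
        totals = []
        for lib in libs:
            on = np.asarray(lib.chroms == rdna.chrom)
            mids = lib.midpoints[on]
            inside = (mids >= rdna.collapsed_start) & (
                mids < rdna.collapsed_end)
            folded = (mids - rdna.collapsed_start) % rdna.repeat_length
            lens = lib.lengths[on]
            fp = (lens >= 51) & (lens <= 100) & inside
            near = (np.abs(folded - rdna.mcm_nondisplaced) <= 20) | \
                   (np.abs(folded - rdna.mcm_displaced) <= 20) | \
                   ((folded >= rdna.rfb - w) & (folded < rdna.rfb))
            totals.append(int(np.sum(fp & near)))
        totals = np.array(totals)
        se = np.sqrt(totals[0] + totals)
        assert np.all(np.abs(totals - totals[0]) < 3 * se)


class TestMnase:
    def test_nucleosome_class_lengths_clipped(self, model150):
        spec = SimulationSpec(model=model150, n_fragments=50_000, seed=75)
        lib = simulate_mnase(spec)
        assert lib.lengths.min() >= 151 and lib.lengths.max() <= 200

    def test_zero_occupancy_silences_dyads(self, model150):
        gt = GenotypeParams(occ2=0.0, occ3=0.0)
        spec = SimulationSpec(model=model150, genotype=gt,
                              n_fragments=100_000, seed=76)
        lib = simulate_mnase(spec)
        rdna = spec.with_model().rdna
        on = np.asarray(lib.chroms == rdna.chrom)
        mids = lib.midpoints[on]
        inside = (mids >= rdna.collapsed_start) & (mids < rdna.collapsed_end)
        folded = (mids[inside] - rdna.collapsed_start) % rdna.repeat_length
        for dyad in rdna.nucleosome_dyads[1:]:
            assert np.sum(np.abs(folded - dyad) <= 50) == 0


class TestLicensingAssay:
    def test_unlicensed_no_depletion(self, model150):
        gt = GenotypeParams(licensing_prob=0.0)
        spec = SimulationSpec(model=model150, genotype=gt, n_fragments=1,
                              seed=77)
        bq = simulate_licensing_assay(spec)
        assert licensed_fraction(bq).value == pytest.approx(0.0, abs=0.12)

    def test_full_licensing_full_cut(self, model150):
        gt = GenotypeParams(licensing_prob=1.0)
        spec = SimulationSpec(model=model150, genotype=gt, n_fragments=1,
                              seed=78)
        bq = simulate_licensing_assay(spec, cut_efficiency=1.0)
        assert bq.target_t == 0.0
        assert licensed_fraction(bq).value == 1.0

    def test_invalid_cut_efficiency(self, model150):
        spec = SimulationSpec(model=model150, n_fragments=1, seed=79)
        with pytest.raises(InvalidParameterError):
            simulate_licensing_assay(spec, cut_efficiency=1.5)

    def test_uncut_band_tracks_copy_number(self, model150):
        sizes = []
        for copies in (52, 150):
            gt = GenotypeParams(physical_copies=copies)
            spec = SimulationSpec(model=model150, genotype=gt,
                                  n_fragments=1, seed=80)
            bq = simulate_licensing_assay(spec)
            sizes.append(bq.uncut / bq.uncut_reference)
        assert sizes[0] / sizes[1] == pytest.approx(52 / 150, rel=0.2)


class TestSpecValidation:
    def test_bad_timepoints_rejected(self, model150):
        with pytest.raises(InvalidParameterError):
            SimulationSpec(model=model150, timepoints=(15.0, 30.0))
        with pytest.raises(InvalidParameterError):
            SimulationSpec(model=model150, timepoints=(0.0, 60.0, 30.0))

    def test_nonpositive_fragments_rejected(self, model150):
        with pytest.raises(InvalidParameterError):
            SimulationSpec(model=model150, n_fragments=0)

    def test_genotype_grid_is_complete(self):
        for name in GENOTYPES:
            GenotypeParams.for_genotype(name)
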