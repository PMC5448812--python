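"""Lane densitometry, migration calibration, and cleavage-site mapping."""

import numpy as np
import pytest

from meioquant import simulate
from meioquant.footprint import (
    CalibrationModel,
    LaneProfile,
    MarkerLadder,
    ProteinRecord,
    assign_ladder_peaks,
    detect_lane_peaks,
    domain_intensity_ratio,
    estimate_cleavage_sites,
    fit_migration_calibration,
    select_candidate_residues,
)

P = np.polynomial.polynomial


def gaussian_lane(centers, heights, sigma=1.0, n=2000):
    x = np.linspace(0.0, 100.0, n)
    y = np.zeros_like(x)
    for c, h in zip(centers, heights):
        y += h * np.exp(-0.5 * ((x - c) / sigma) ** 2)
    return LaneProfile(x, y)


class TestPeakDetection:
    def test_flat_trace_has_no_peaks(self):
        lane = LaneProfile(np.linspace(0, 100, 500), np.full(500, 3.0))
        assert detect_lane_peaks(lane) == []

    def test_two_separated_bands_recovered(self):
        # sigma = 1% of lane, separation 10 sigma
        lane = gaussian_lane([40.0, 50.0], [1.0, 0.8], sigma=1.0)
        peaks = detect_lane_peaks(lane)
        assert len(peaks) == 2
        step = 100.0 / 1999
        assert abs(peaks[0][0] - 40.0) < step / 2
        assert abs(peaks[1][0] - 50.0) < step / 2

    def test_close_bands_merge(self):
        # equal Gaussians closer than ~2 sigma (0.85 FWHM) have a single
        # maximum: the resolution limit of densitometry peak-picking
        sigma = 1.0
        lane = gaussian_lane([50.0 - 0.9 * sigma, 50.0 + 0.9 * sigma], [1, 1], sigma)
        assert len(detect_lane_peaks(lane)) == 1

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            detect_lane_peaks(LaneProfile(np.arange(10.0), np.zeros(10)))

    def test_profile_validation(self):
        with pytest.raises(ValueError):
            LaneProfile(np.array([1.0, 1.0, 2.0]), np.zeros(3))
        with pytest.raises(ValueError):
            LaneProfile(np.arange(3.0), np.array([1.0, -1.0, 0.0]))


class TestCalibration:
    def test_exact_quartic_recovered(self):
        coeffs_true = np.array([95.0, -1.2, 8e-3, -3e-5, 4.5e-8])
        kda = np.array([20.0, 30.0, 45.0, 60.0, 80.0, 100.0])
        mig = P.polyval(kda, coeffs_true)
        model = fit_migration_calibration(MarkerLadder(kda=kda, positions=mig))
        assert model.residual_rms == pytest.approx(0.0, abs=1e-8)
        assert model.coeffs == pytest.approx(coeffs_true, rel=1e-6)

    def test_log_law_ladder_low_residual(self):
        # markers under migration = a - b ln(MW), 1% positional noise
        rng = np.random.default_rng(0)
        kda = np.array([120.0, 100.0, 80.0, 70.0, 60.0, 50.0, 40.0, 30.0, 20.0])
        mig = 190.0 - 44.0 * np.log(kda)
        mig = mig + rng.normal(0, 0.01 * (mig.max() - mig.min()), size=mig.shape)
        model = fit_migration_calibration(MarkerLadder(kda=kda, positions=np.sort(mig)))
        lane_length = mig.max() - mig.min()
        assert model.residual_rms < 0.02 * lane_length

    def test_leave_one_out_60kda(self):
        kda = np.array([120.0, 100.0, 80.0, 60.0, 50.0, 40.0, 30.0, 20.0])
        mig = 190.0 - 44.0 * np.log(kda)
        keep = kda != 60.0
        model = fit_migration_calibration(
            MarkerLadder(kda=kda[keep], positions=mig[keep])
        )
        mig_60 = 190.0 - 44.0 * np.log(60.0)
        assert model.mw_at(mig_60) == pytest.approx(60.0, rel=0.05)

    def test_too_few_markers(self):
        kda = np.array([80.0, 60.0, 40.0, 20.0])
        with pytest.raises(ValueError):
            fit_migration_calibration(MarkerLadder(kda=kda, positions=np.arange(4.0)))

    def test_non_monotone_fit_rejected(self):
        # a quartic across the sparse 120-220 kDa gap of a log-law ladder
        kda = np.array([220.0, 120.0, 100.0, 80.0, 60.0, 50.0, 40.0, 30.0, 20.0])
        mig = 190.0 - 33.4 * np.log(kda)
        with pytest.raises(ValueError, match="monotone"):
            fit_migration_calibration(MarkerLadder(kda=kda, positions=mig))

    def test_inversion_round_trip_identity(self):
        kda = np.array([120.0, 100.0, 80.0, 60.0, 50.0, 40.0, 30.0, 20.0])
        mig = 190.0 - 44.0 * np.log(kda)
        model = fit_migration_calibration(MarkerLadder(kda=kda, positions=mig))
        for mw in np.linspace(22, 118, 25):
            mig_mw = float(model.migration(mw))
            assert model.mw_at(mig_mw) == pytest.approx(mw, abs=1e-6)


def make_protein(seed=10):
    return simulate.make_synthetic_protein(seed=seed)


class TestCleavageSites:
    def quartic_calibration(self, protein):
        kda = np.array([120.0, 100.0, 80.0, 60.0, 50.0, 40.0, 30.0, 20.0])
        mig = 190.0 - 44.0 * np.log(kda)
        return fit_migration_calibration(MarkerLadder(kda=kda, positions=mig))

    def test_full_length_peak_maps_to_terminus(self):
        prot = make_protein()
        cal = self.quartic_calibration(prot)
        full_kda = prot.prefix_masses_da()[-1] / 1000.0
        peak = (float(cal.migration(full_kda)), 1.0)
        [site] = estimate_cleavage_sites([peak], cal, prot)
        assert site.residue == len(prot)

    def test_exact_prefix_mass_maps_to_its_residue(self):
        prot = make_protein()
        cal = self.quartic_calibration(prot)
        mass_150 = prot.prefix_masses_da()[149] / 1000.0
        peak = (float(cal.migration(mass_150)), 1.0)
        [site] = estimate_cleavage_sites([peak], cal, prot)
        assert site.residue == 150
        assert site.uncertainty_residues >= 5.0

    def test_out_of_range_peak_flagged(self):
        prot = make_protein()
        cal = self.quartic_calibration(prot)
        lo, hi = cal.migration_range
        [site] = estimate_cleavage_sites([(hi + 5.0, 1.0)], cal, prot)
        assert site.out_of_range and site.residue is None

    def test_mw_to_residue_monotone(self):
        prot = make_protein()
        cal = self.quartic_calibration(prot)
        mws = np.linspace(25.0, 80.0, 40)
        peaks = [(float(cal.migration(m)), 1.0) for m in mws]
        residues = [s.residue for s in estimate_cleavage_sites(peaks, cal, prot)]
        # larger fragment MW never yields a smaller residue index
        assert all(r2 >= r1 for r1, r2 in zip(residues, residues[1:]))

    def test_noiseless_round_trip_exact(self):
        # generated under an exact quartic law, mapping is identity +/- 1
        prot = make_protein()
        kda = np.array([120.0, 100.0, 80.0, 60.0, 50.0, 40.0, 30.0, 20.0])
        b = 80.0 / np.log(120.0 / 20.0)  # ladder spans lane coords 10..90
        coeffs = P.polyfit(kda, 10.0 + b * np.log(120.0) - b * np.log(kda), deg=4)
        law = lambda mw: P.polyval(mw, coeffs)
        sites = [214, 300, 450, 600]
        sim = simulate.simulate_lane_set(
            prot, sites, noise_frac=0.0, migration_law=law, seed=0
        )
        cal = fit_migration_calibration(
            assign_ladder_peaks(
                sim.ladder,
                detect_lane_peaks(sim.ladder_lane, smooth_frac=0.004, prominence_frac=0.02),
            )
        )
        est = estimate_cleavage_sites(
            detect_lane_peaks(sim.sample_lane, smooth_frac=0.004, prominence_frac=0.02),
            cal,
            prot,
        )
        found = sorted(s.residue for s in est if s.residue is not None)
        for true, got in zip(sites + [len(prot)], found):
            assert abs(got - true) <= 1

    def test_synthetic_lane_mlh1_like_sites_within_ten_residues(self):
        prot = make_protein()
        true_sites = [214, 257, 273, 282, 334, 362, 387, 400]
        sim = simulate.simulate_lane_set(prot, true_sites, seed=11)
        cal = fit_migration_calibration(
            assign_ladder_peaks(
                sim.ladder,
                detect_lane_peaks(sim.ladder_lane, smooth_frac=0.004, prominence_frac=0.02),
            )
        )
        est = estimate_cleavage_sites(
            detect_lane_peaks(sim.sample_lane, smooth_frac=0.004, prominence_frac=0.02),
            cal,
            prot,
        )
        found = [s.residue for s in est if s.residue is not None]
        for true in true_sites:
            assert min(abs(f - true) for f in found) <= 10
        for f in found:
            assert min(abs(f - t) for t in true_sites + [len(prot)]) <= 10


class TestDomainRatio:
    def make_sites(self, pairs, protein):
        from meioquant.footprint import CleavageSite

        return [
            CleavageSite(
                fragment_kda=None, residue=r, intensity=i,
                uncertainty_residues=5.0, domain=protein.domain_of(r),
            )
            for r, i in pairs
        ]

    def test_all_linker_intensity_gives_zero(self):
        prot = make_protein()
        lk = prot.domains["linker"][0]
        ratio = domain_intensity_ratio(self.make_sites([(lk, 2.0)], prot), prot)
        assert ratio.value == 0.0

    def test_equal_intensities_give_one(self):
        prot = make_protein()
        nt = prot.domains["N-terminal"][0]
        lk = prot.domains["linker"][0]
        ratio = domain_intensity_ratio(
            self.make_sites([(nt, 3.0), (lk, 3.0)], prot), prot
        )
        assert ratio.value == pytest.approx(1.0)

    def test_scale_invariance(self):
        prot = make_protein()
        nt, lk = prot.domains["N-terminal"][0], prot.domains["linker"][0]
        pairs = [(nt, 2.0), (nt + 5, 1.0), (lk, 4.0)]
        r1 = domain_intensity_ratio(self.make_sites(pairs, prot), prot)
        r2 = domain_intensity_ratio(
            self.make_sites([(r, 7.3 * i) for r, i in pairs], prot), prot
        )
        assert r1.value == pytest.approx(r2.value, rel=1e-12)

    def test_zero_linker_flagged_infinite(self):
        prot = make_protein()
        nt = prot.domains["N-terminal"][0]
        ratio = domain_intensity_ratio(self.make_sites([(nt, 1.0)], prot), prot)
        assert ratio.infinite and np.isinf(ratio.value)

    def test_ssdna_like_exceeds_hj_like(self):
        # ssDNA-like cleavage spreads over N-terminal domain and linker;
        # HJ-like cleavage is linker-dominated.
        prot = make_protein()
        nt, lk = prot.domains["N-terminal"][0], prot.domains["linker"][0]
        ss = self.make_sites([(nt, 3.0), (nt + 10, 2.0), (lk, 2.0)], prot)
        hj = self.make_sites([(nt, 1.0), (lk, 4.0), (lk + 10, 3.0)], prot)
        assert (
            domain_intensity_ratio(ss, prot).value
            > domain_intensity_ratio(hj, prot).value
        )


class TestCandidateResidues:
    def test_no_basic_residues_gives_empty_set(self):
        prot = ProteinRecord("p", "A" * 100)
        assert select_candidate_residues(prot, 50, window=12) == set()

    def test_direct_scan(self):
        seq = list("A" * 100)
        seq[49] = "K"  # residue 50
        seq[54] = "R"  # residue 55
        prot = ProteinRecord("p", "".join(seq))
        assert select_candidate_residues(prot, 52, window=12) == {50, 55}

    def test_window_edges(self):
        seq = list("A" * 100)
        seq[39] = "K"  # residue 40, exactly site - window
        seq[64] = "R"  # residue 65, outside
        prot = ProteinRecord("p", "".join(seq))
        assert select_candidate_residues(prot, 52, window=12) == {40}

    def test_alignment_conservation_filter(self):
        seq = "A" * 49 + "K" + "A" * 4 + "R" + "A" * 45
        prot = ProteinRecord("p", seq)
        other1 = "A" * 49 + "K" + "A" * 4 + "Q" + "A" * 45
        other2 = "A" * 49 + "R" + "A" * 4 + "Q" + "A" * 45
        aln = [("p", seq), ("o1", other1), ("o2", other2)]
        kept = select_candidate_residues(
            prot, 52, window=12, alignment=aln, min_conservation=0.9
        )
        assert kept == {50}  # K/R in all rows at 50, only 1/3 at 55

    def test_site_out_of_bounds(self):
        prot = ProteinRecord("p", "ACDEFGHIKL")
        with pytest.raises(ValueError):
            select_candidate_residues(prot, 11, window=3)


class TestProteinRecord:
    def test_prefix_masses_increasing_and_plausible(self):
        prot = make_protein()
        masses = prot.prefix_masses_da()
        assert np.all(np.diff(masses) > 0)
        # average residue mass for a uniform composition ~ 110-140 Da
        assert 90 < np.mean(np.diff(masses)) < 150

    def test_domains_must_tile(self):
        with pytest.raises(ValueError):
            ProteinRecord("p", "A" * 10, domains={"N-terminal": (1, 4), "linker": (6, 10)})

    def test_fasta_round_trip(self, tmp_path):
        fasta = tmp_path / "prot.fasta"
        fasta.write_text(">prot1 test\nMKLVR\nAADE\n")
        prot = ProteinRecord.from_fasta(fasta, tag_mass_da=100.0)
        assert prot.identifier == "prot1"
        assert prot.sequence == "MKLVRAADE"
        assert len(prot) == 9
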