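"""Scan orchestration, filtering ledger, dedup, smoothing, core regions."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom

from trdkit import (
    GenotypeTable,
    apply_filters,
    build_null_table,
    dedup_best_bf,
    extract_core_regions,
    integrate,
    kernel_smooth,
    scan,
    significance_halfwidth,
    under_represented,
)
from trdkit.config import ScanConfig
from trdkit.scan_pipeline import RegionRecord, SmoothTrack


# ---------------------------------------------------------------------------
# scan
# ---------------------------------------------------------------------------

class TestScan:
    def test_empty_dataset(self):
        markers = pd.DataFrame({"chrom": ["chr1"], "marker_id": ["m"],
                                "pos_bp": [1]})
        gt = GenotypeTable(["x"], markers, np.array([[0]], dtype=np.int16))
        ped = pd.DataFrame({"offspring": [], "sire": [], "dam": []})
        assert scan(gt, ped) == []

    def test_window_mode_requires_phase(self):
        markers = pd.DataFrame({"chrom": ["chr1", "chr1"],
                                "marker_id": ["m1", "m2"],
                                "pos_bp": [1, 2]})
        gt = GenotypeTable(["x"], markers,
                           np.array([[1], [1]], dtype=np.int16))
        ped = pd.DataFrame({"offspring": [], "sire": [], "dam": []})
        with pytest.raises(ValueError, match="phased"):
            scan(gt, ped, mode="windows")

    def test_null_genome_yields_no_decisive_records(self, null_genome):
        records = scan(null_genome.gt, null_genome.pedigree, seed=5)
        assert len(records) == 100
        decisive = [r for r in records if r.bf >= 100.0]
        assert len(decisive) <= 1    # 1 % calibration level on 100 loci

    def test_window_scan_finds_planted_recessive_haplotype(self):
        from trdkit.synthetic_data import LocusSpec, SimConfig, simulate
        # founder pool: only string 1001 carries the lethal allele A (0) at
        # SNP index 1, so that haplotype is the recessive-lethal allele
        pool = np.array([
            [1, 0, 0, 1], [1, 1, 1, 1], [0, 1, 1, 0],
            [1, 1, 1, 0], [0, 1, 1, 1],
        ], dtype=np.int8)
        freqs = np.array([0.15, 0.35, 0.2, 0.2, 0.1])
        sim = simulate(SimConfig(
            n_sires=150, offspring_per_sire=40, n_chromosomes=1,
            snps_per_chrom=4,
            founder_pools={"chr1": (pool, freqs)},
            loci=(LocusSpec("chr1", 1, "recessive_lethal",
                            carrier_frequency=0.15),), seed=17))
        records = scan(sim.gt, sim.pedigree, mode="windows",
                       window_sizes=(4,), seed=1)
        assert records
        best = max(records, key=lambda r: r.fits["genotypic"].log_bf)
        assert best.allele_id.endswith("1001")   # the carrier string
        assert best.pattern == "recessive"
        assert best.bf == max(r.bf for r in records)


# ---------------------------------------------------------------------------
# empirical null table
# ---------------------------------------------------------------------------

class TestNullTable:
    def test_n20_threshold_matches_exact_binomial(self):
        # exact: P(|a| = 0.5) ~ 1.9e-6 <= 1e-5 < P(|a| >= 0.45) ~ 4.0e-5
        assert binom.pmf(0, 20, 0.5) * 2 <= 1e-5
        assert (binom.cdf(1, 20, 0.5) + binom.sf(18, 20, 0.5)) > 1e-5
        nt = build_null_table(bins=(20,), mating_mix={"ABxAA": 1.0},
                              replicates=2_000_000, p_null=1e-5, seed=7)
        assert nt.threshold("alpha", 20) == 0.5

    def test_thresholds_decrease_with_offspring_count(self):
        nt = build_null_table(bins=(100, 10_000), replicates=200_000,
                              p_null=1e-3, seed=1)
        assert nt.threshold("alpha", 100) > nt.threshold("alpha", 10_000)

    def test_same_seed_reproducible(self):
        a = build_null_table(bins=(50,), replicates=50_000, p_null=1e-3,
                             seed=3)
        b = build_null_table(bins=(50,), replicates=50_000, p_null=1e-3,
                             seed=3)
        for p in a.thresholds:
            np.testing.assert_array_equal(a.thresholds[p], b.thresholds[p])

    def test_empty_bins_error(self):
        with pytest.raises(ValueError):
            build_null_table(bins=())


# ---------------------------------------------------------------------------
# filtering ledger
# ---------------------------------------------------------------------------

def _scan_single_locus(sim, **cfg_kw):
    config = ScanConfig(**cfg_kw)
    recs = scan(sim.gt, sim.pedigree, config=config)
    assert len(recs) == 1
    return recs[0], config


class TestApplyFilters:
    def test_informative_parent_rule(self, skewed_sire):
        rec, config = _scan_single_locus(skewed_sire)
        rec.n_het_sires, rec.n_het_dams = 19, 50
        apply_filters([rec], None, config)
        assert rec.flag("informative_parents") is False
        rec.n_het_sires = 20
        apply_filters([rec], None, config)
        assert rec.flag("informative_parents") is True
        rec.n_het_sires, rec.n_het_dams = 0, 100
        apply_filters([rec], None, config)
        assert rec.flag("informative_parents") is True

    def test_single_skewed_sire_fails_robustness(self, skewed_sire):
        rec, config = _scan_single_locus(skewed_sire)
        assert rec.bf >= config.bf_decisive     # decisive before the filter
        apply_filters([rec], None, config)
        assert rec.flag("sire_robustness") is False

    def test_null_exceedance_flag(self, null_genome):
        config = ScanConfig()
        records = scan(null_genome.gt, null_genome.pedigree, seed=2)
        nt = build_null_table(bins=(20, 100, 1000), replicates=100_000,
                              p_null=1e-4, seed=5)
        apply_filters(records, nt, config)
        failed = [r for r in records if r.flag("null_exceedance") is False]
        # the vast majority of null loci fall below the chance threshold
        assert len(failed) >= 0.95 * len(records)

    def test_stability_flag_uses_lead_parameter_cv(self, skewed_sire):
        rec, config = _scan_single_locus(skewed_sire)
        apply_filters([rec], None, config)
        sel = rec.fits[rec.selected_model]
        lead = int(np.argmax(np.abs(sel.mean)))
        expected = float(sel.cv[lead]) <= config.max_cv
        assert rec.flag("stability") == expected


# ---------------------------------------------------------------------------
# dedup
# ---------------------------------------------------------------------------

def _rec(chrom, start, end, bf):
    from trdkit.mating_model import MatingCountTable

    return RegionRecord(
        chrom=chrom, start_bp=start, end_bp=end, n_snp=1,
        allele_id=f"{chrom}:{start}", carrier_frequency=0.1,
        n_het_sires=0, n_het_dams=0, n_informative=0, n_inconsistent=0,
        counts=MatingCountTable(np.zeros(11, int)), fits={},
        selected_model="allelic_overall", delta_dic={}, pattern="overall-TRD",
        bf=bf, bf_model="allelic_overall", under_represented_count=0)


class TestDedup:
    def test_overlapping_keeps_highest_bf(self):
        kept = dedup_best_bf([_rec("chr1", 100, 200, 150.0),
                              _rec("chr1", 150, 250, 90.0)])
        assert len(kept) == 1 and kept[0].bf == 150.0

    def test_disjoint_all_kept(self):
        kept = dedup_best_bf([_rec("chr1", 100, 200, 10.0),
                              _rec("chr1", 300, 400, 20.0),
                              _rec("chr2", 100, 200, 5.0)])
        assert len(kept) == 3

    def test_chain_matches_brute_force_clustering(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            recs = []
            for i in range(30):
                s = int(rng.integers(0, 1000))
                recs.append(_rec("chr1", s, s + int(rng.integers(1, 120)),
                                 float(rng.integers(1, 1000))))
            kept = dedup_best_bf(recs)
            # brute force: transitive overlap clusters + argmax
            clusters = []
            for r in recs:
                merged = [c for c in clusters
                          if any(r.start_bp <= x.end_bp
                                 and r.end_bp >= x.start_bp for x in c)]
                newc = [r] + [x for c in merged for x in c]
                clusters = [c for c in clusters if c not in merged]
                clusters.append(newc)
            expected = sorted(
                (max(c, key=lambda r: (r.bf, -(r.end_bp - r.start_bp),
                                       -r.start_bp)).allele_id)
                for c in clusters)
            assert sorted(r.allele_id for r in kept) == expected


# ---------------------------------------------------------------------------
# smoothing and core regions
# ---------------------------------------------------------------------------

class TestKernelSmooth:
    def test_isolated_peak_preserved(self):
        track = kernel_smooth([_rec("chr1", 1_000_000, 1_000_000, 100.0)],
                              500_000.0,
                              query={"chr1": np.array([1_000_000.0])})
        assert np.isclose(track.chroms["chr1"][1][0], 100.0)

    def test_value_at_one_bandwidth(self):
        track = kernel_smooth([_rec("chr1", 1_000_000, 1_000_000, 100.0)],
                              500_000.0,
                              query={"chr1": np.array([1_500_000.0])})
        assert np.isclose(track.chroms["chr1"][1][0],
                          100.0 * np.exp(-0.5), rtol=1e-12)

    def test_distant_peaks_separate(self):
        recs = [_rec("chr1", 0, 0, 100.0), _rec("chr1", 10_000_000,
                                                10_000_000, 100.0)]
        track = kernel_smooth(recs, 500_000.0,
                              query={"chr1": np.array([5_000_000.0])})
        assert track.chroms["chr1"][1][0] < 1e-10 * 100.0

    def test_linear_in_bf_and_translation_equivariant(self):
        rng = np.random.default_rng(6)
        pos = rng.integers(0, 10_000_000, size=8)
        bf = rng.uniform(1, 500, size=8)
        q = np.linspace(0, 10_000_000, 23)
        t1 = kernel_smooth([_rec("chr1", p, p, b) for p, b in zip(pos, bf)],
                           500_000.0, query={"chr1": q})
        t2 = kernel_smooth([_rec("chr1", p, p, 2 * b)
                            for p, b in zip(pos, bf)],
                           500_000.0, query={"chr1": q})
        np.testing.assert_allclose(2 * t1.chroms["chr1"][1],
                                   t2.chroms["chr1"][1])
        shift = 7_777
        t3 = kernel_smooth([_rec("chr1", p + shift, p + shift, b)
                            for p, b in zip(pos, bf)],
                           500_000.0, query={"chr1": q + shift})
        np.testing.assert_allclose(t1.chroms["chr1"][1],
                                   t3.chroms["chr1"][1])

    def test_sigma_must_be_positive(self):
        with pytest.raises(ValueError):
            kernel_smooth([], 0.0)


class TestSignificanceHalfwidth:
    @pytest.mark.parametrize("coverage,expected", [
        (0.95, 980_000.0), (0.99, 1_290_000.0), (0.999, 1_645_000.0)])
    def test_published_halfwidths(self, coverage, expected):
        assert significance_halfwidth(500_000.0, coverage) == expected

    def test_domain_error(self):
        with pytest.raises(ValueError):
            significance_halfwidth(500_000.0, 1.5)


class TestExtractCoreRegions:
    def test_single_isolated_peak(self):
        track = kernel_smooth([_rec("chr1", 2_000_000, 2_000_000, 200.0)],
                              500_000.0)
        cores = extract_core_regions(track, min_peak=100.0)
        assert len(cores) == 1
        assert abs(cores[0].peak_bp - 2_000_000) <= 50_000
        assert np.isclose(cores[0].end_bp - cores[0].peak_bp, 980_000.0)

    def test_two_planted_signals_two_cores(self):
        recs = [_rec("chr1", 2_000_000, 2_000_000, 200.0),
                _rec("chr1", 7_000_000, 7_000_000, 150.0)]
        cores = extract_core_regions(kernel_smooth(recs, 500_000.0),
                                     min_peak=100.0)
        assert len(cores) == 2

    def test_flat_zero_track(self):
        track = SmoothTrack(500_000.0, {"chr1": (np.linspace(0, 1e6, 50),
                                                 np.zeros(50))})
        assert extract_core_regions(track, min_peak=1.0) == []


class TestUnderRepresented:
    @pytest.mark.parametrize("n,trd,expected", [
        (10_000, 0.25, 5_000), (123, 0.0, 0), (0, 0.4, 0)])
    def test_arithmetic(self, n, trd, expected):
        assert under_represented(n, trd) == expected

    def test_domain(self):
        with pytest.raises(ValueError):
            under_represented(10, 0.7)
        with pytest.raises(ValueError):
            under_represented(-1, 0.1)
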