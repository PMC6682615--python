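"""Synthetic cohort generator: determinism, geometry, spatial trends."""

import numpy as np
import pandas as pd
import pytest

from gliodist.association import ols_fit, pearson_correlation
from gliodist.cnv import build_event_matrix, cnv_pair_distances, union_breakpoints
from gliodist.cohort import enumerate_pairs, pairs_to_frame
from gliodist.methylation import l1_distance
from gliodist.mutations import build_af_matrix, filter_variants, mutation_pair_distances
from gliodist.simulate import (
    DEFAULT_LINEAR_TARGETS,
    SimulationConfig,
    simulate_cnv,
    simulate_cohort,
    simulate_coordinates,
    simulate_distance_pairs,
    simulate_linear_cohort,
    simulate_methylation,
    simulate_mutations,
    three_sample_example,
)


def small_config(seed=11, **kw):
    cfg = SimulationConfig(seed=seed, n_patients=kw.pop("n_patients", 5), **kw)
    cfg.methylation.n_probes = 500
    return cfg


def _segments_fingerprint(segments):
    return [(s.sample_id, s.chrom, s.start, s.end, round(s.log2, 12)) for s in segments]


class TestDeterminism:
    def test_identical_seed_reproduces_everything(self):
        a = simulate_cohort(small_config())
        b = simulate_cohort(small_config())
        assert [(s.sample_id, s.x, s.y, s.z) for s in a.sites] == [
            (s.sample_id, s.x, s.y, s.z) for s in b.sites
        ]
        assert [(c.sample_id, c.key, c.alt_freq) for c in a.calls] == [
            (c.sample_id, c.key, c.alt_freq) for c in b.calls
        ]
        assert _segments_fingerprint(a.segments) == _segments_fingerprint(b.segments)
        pd.testing.assert_frame_equal(a.beta.beta, b.beta.beta)

    def test_different_seed_differs(self):
        a = simulate_cohort(small_config(seed=11))
        b = simulate_cohort(small_config(seed=12))
        assert [(s.x, s.y, s.z) for s in a.sites] != [(s.x, s.y, s.z) for s in b.sites]

    def test_earlier_patients_stable_when_cohort_grows(self):
        small = simulate_coordinates(small_config(n_patients=3))
        large = simulate_coordinates(small_config(n_patients=6))
        small_p1 = [(s.sample_id, s.x) for s in small if s.patient_id == "P01"]
        large_p1 = [(s.sample_id, s.x) for s in large if s.patient_id == "P01"]
        assert small_p1 == large_p1


class TestCoordinates:
    def test_all_sites_within_radius_bound(self):
        cfg = small_config(n_patients=10)
        sites = simulate_coordinates(cfg)
        for s in sites:
            # split sub-samples may sit 5 mm outside the sphere
            assert np.linalg.norm(s.coordinates) <= cfg.tumor_radius_mm + 5 + 1e-9
        pairs = enumerate_pairs(sites)
        assert all(p.euclidean_mm <= 2 * cfg.tumor_radius_mm + 10 for p in pairs)

    def test_shallow_deep_split_geometry(self):
        cfg = small_config(n_patients=10)
        cfg.shallow_deep_fraction = 1.0
        sites = simulate_coordinates(cfg)
        by_source = {}
        for s in sites:
            by_source.setdefault(s.source_site_id, []).append(s)
        for group in by_source.values():
            assert {s.depth_label for s in group} == {"shallow", "deep"}
            a, b = group
            d = np.linalg.norm(np.subtract(a.coordinates, b.coordinates))
            assert d == pytest.approx(5.0)

    def test_mean_pair_distance_matches_independent_rejection_sampler(self):
        # oracle: rejection-sample points uniform in the ball and compare the
        # empirical mean pairwise distance (E[d] = 36R/35 for uniform ball)
        R = 30.0
        rng = np.random.default_rng(123)
        pts = []
        while len(pts) < 2000:
            p = rng.uniform(-R, R, 3)
            if np.linalg.norm(p) <= R:
                pts.append(p)
        pts = np.array(pts)
        oracle = np.linalg.norm(pts[:1000] - pts[1000:], axis=1)

        cfg = small_config(n_patients=250, sites_per_patient=(2, 2))
        cfg.shallow_deep_fraction = 0.0
        sites = simulate_coordinates(cfg)
        sim_d = [p.euclidean_mm for p in enumerate_pairs(sites)]
        se = np.std(oracle) / np.sqrt(len(sim_d))
        assert np.mean(sim_d) == pytest.approx(np.mean(oracle), abs=4 * se + 0.05 * np.mean(oracle))


class TestMutations:
    def test_zero_subclone_rate_gives_zero_distance_everywhere(self):
        cfg = small_config()
        cfg.mutation.subclone_rate_per_mm = 0.0
        cfg.mutation.decoy_fraction = 0.0
        cohort = simulate_cohort(cfg)
        by_patient = {}
        for c in cohort.calls:
            by_patient.setdefault(c.patient_id, []).append(c)
        for calls in by_patient.values():
            df = mutation_pair_distances(build_af_matrix(calls))
            assert (df["jaccard_distance"] == 0).all()
            assert (df["count_distance"] == 0).all()

    def test_filter_retains_exactly_intended_pass_set(self):
        cfg = small_config()
        cfg.mutation.decoy_fraction = 0.5
        sites = simulate_coordinates(cfg)
        calls, truth = simulate_mutations(cfg, sites)
        kept = filter_variants(calls)
        kept_ids = {(c.patient_id, c.sample_id, *c.key) for c in kept}
        assert kept_ids == {tuple(t) for t in truth["intended_pass"]}
        assert kept_ids.isdisjoint({tuple(t) for t in truth["decoys"]})
        assert len(truth["decoys"]) > 0

    def test_truncal_af_exceeds_private_af_on_average(self):
        cfg = small_config(n_patients=10)
        cohort = simulate_cohort(cfg)
        by_patient = {}
        for c in filter_variants(cohort.calls):
            by_patient.setdefault(c.patient_id, []).append(c)
        truncal, private = [], []
        for calls in by_patient.values():
            m = build_af_matrix(calls)
            shared_all = (m.af > 0).all(axis=1)
            truncal.extend(m.af[shared_all][m.af[shared_all] > 0])
            private.extend(m.af[~shared_all][m.af[~shared_all] > 0])
        assert np.mean(truncal) > np.mean(private)

    def test_three_sample_example_reproduces_canonical_pattern(self):
        from gliodist.mutations import mutation_sharing_tree

        m = build_af_matrix(three_sample_example())
        tree = mutation_sharing_tree(m)
        assert tree.newick == "((P1S1:1,P1S2:0,P1S3:1):10)N;"

    def test_monotone_in_subclone_rate(self):
        means = []
        for rate in (0.05, 0.3, 1.0):
            cfg = small_config(n_patients=8)
            cfg.mutation.subclone_rate_per_mm = rate
            cfg.mutation.decoy_fraction = 0.0
            sites = simulate_coordinates(cfg)
            calls, _ = simulate_mutations(cfg, sites)
            by_patient = {}
            for c in calls:
                by_patient.setdefault(c.patient_id, []).append(c)
            dists = pd.concat(
                [mutation_pair_distances(build_af_matrix(v)) for v in by_patient.values()]
            )
            means.append(dists["count_distance"].mean())
        assert means[0] < means[1] < means[2]


class TestCnv:
    def test_zero_perturbation_gives_zero_canberra(self):
        cfg = small_config()
        cfg.cnv.perturbation_sd_per_mm = 0.0
        cohort = simulate_cohort(cfg)
        by_patient = {}
        for s in cohort.segments:
            by_patient.setdefault(s.patient_id, []).append(s)
        for segs in by_patient.values():
            m = build_event_matrix(union_breakpoints(segs), segs)
            df = cnv_pair_distances(m)
            assert df["canberra_distance"].abs().max() == pytest.approx(0.0)

    def test_no_extra_breakpoints_union_equals_base(self):
        cfg = small_config()
        cfg.cnv.extra_breakpoint_prob = 0.0
        cohort = simulate_cohort(cfg)
        by_patient = {}
        for s in cohort.segments:
            by_patient.setdefault(s.patient_id, []).append(s)
        for segs in by_patient.values():
            sample_ids = {s.sample_id for s in segs}
            one_sample = sorted(
                (s.chrom, s.start, s.end) for s in segs if s.sample_id == min(sample_ids)
            )
            events = union_breakpoints(segs)
            assert sorted(events) == one_sample

    def test_inserted_breakpoint_adds_one_event(self):
        from gliodist.cnv import CNVSegment

        base = [("chr1", 0, 50), ("chr1", 50, 100)]
        segs = [CNVSegment("P1", "A", c, lo, hi, 0.5) for c, lo, hi in base]
        segs += [
            CNVSegment("P1", "B", "chr1", 0, 30, 0.5),
            CNVSegment("P1", "B", "chr1", 30, 50, 0.7),
            CNVSegment("P1", "B", "chr1", 50, 100, 0.5),
        ]
        assert len(union_breakpoints(segs)) == len(base) + 1

    def test_monotone_in_perturbation_rate(self):
        means = []
        for sd in (0.002, 0.01, 0.05):
            cfg = small_config(n_patients=8)
            cfg.cnv.perturbation_sd_per_mm = sd
            sites = simulate_coordinates(cfg)
            segs = simulate_cnv(cfg, sites)
            by_patient = {}
            for s in segs:
                by_patient.setdefault(s.patient_id, []).append(s)
            dists = pd.concat(
                [
                    cnv_pair_distances(build_event_matrix(union_breakpoints(v), v))
                    for v in by_patient.values()
                ]
            )
            means.append(dists["canberra_distance"].mean())
        assert means[0] < means[1] < means[2]


class TestMethylation:
    def test_zero_field_sd_gives_zero_l1(self):
        cfg = small_config()
        cfg.methylation.field_sd = 0.0
        cfg.methylation.missing_rate = 0.0
        beta = simulate_methylation(cfg, simulate_coordinates(cfg))
        for patient in beta.patient_ids:
            samples = beta.patient_samples(patient)
            for i, a in enumerate(samples):
                for b in samples[i + 1 :]:
                    assert l1_distance(beta.beta[a], beta.beta[b]) == pytest.approx(0.0)

    def test_all_values_in_unit_interval_or_missing(self):
        cfg = small_config()
        cfg.methylation.missing_rate = 0.02
        beta = simulate_methylation(cfg, simulate_coordinates(cfg))
        vals = beta.beta.to_numpy()
        finite = vals[~np.isnan(vals)]
        assert finite.min() >= 0.0 and finite.max() <= 1.0
        assert np.isnan(vals).any()

    def test_l1_larger_at_20mm_than_5mm(self):
        # two fixed sites per patient at controlled separations; oracle:
        # deviations with squared-exponential correlation make E|dP - dQ|
        # increase as the correlation decays with separation
        from gliodist.cohort import BiopsySite

        cfg = small_config(n_patients=0)
        cfg.methylation.missing_rate = 0.0
        cfg.methylation.n_probes = 300
        results = {}
        for sep, patient_base in ((5.0, "N"), (20.0, "F")):
            sites = []
            for p in range(100):
                pid = f"{patient_base}{p:03d}"
                sites.append(BiopsySite(pid, f"{pid}S1", 0.0, 0.0, 0.0))
                sites.append(BiopsySite(pid, f"{pid}S2", sep, 0.0, 0.0))
            beta = simulate_methylation(cfg, sites)
            dists = [
                l1_distance(beta.beta[f"{pid}S1"], beta.beta[f"{pid}S2"])
                for pid in {s.patient_id for s in sites}
            ]
            results[sep] = np.mean(dists)
        assert results[20.0] > results[5.0]

        # independent Monte-Carlo oracle on the deviation scale: the mean
        # absolute difference of two unit-variance Gaussians with correlation
        # rho(d) = exp(-d^2/(2 * 10^2)) is sqrt(2 (1 - rho)) * sqrt(2 / pi)
        rho5 = np.exp(-25 / 200)
        rho20 = np.exp(-400 / 200)
        assert np.sqrt(2 * (1 - rho20)) > np.sqrt(2 * (1 - rho5))

    def test_monotone_in_field_sd(self):
        means = []
        for sd in (0.1, 0.5, 1.5):
            cfg = small_config(n_patients=6)
            cfg.methylation.field_sd = sd
            cfg.methylation.missing_rate = 0.0
            sites = simulate_coordinates(cfg)
            beta = simulate_methylation(cfg, sites)
            dists = []
            for patient in beta.patient_ids:
                samples = beta.patient_samples(patient)
                for i, a in enumerate(samples):
                    for b in samples[i + 1 :]:
                        dists.append(l1_distance(beta.beta[a], beta.beta[b]))
            means.append(np.mean(dists))
        assert means[0] < means[1] < means[2]


class TestLinearGenerator:
    def test_noiseless_recovery_is_exact(self):
        df = simulate_distance_pairs(-11.6, 1.7, 0.0, 50, (10, 30), seed=4)
        fit = ols_fit(df["euclidean_mm"], df["genomic_distance"])
        assert fit.slope == pytest.approx(1.7)
        assert fit.intercept == pytest.approx(-11.6)

    def test_small_noise_recovery_within_5_percent(self):
        df = simulate_distance_pairs(-11.6, 1.7, 1.0, 200, (10, 30), seed=5)
        fit = ols_fit(df["euclidean_mm"], df["genomic_distance"])
        assert abs(fit.slope - 1.7) / 1.7 < 0.05

    def test_truncation_keeps_distances_non_negative(self):
        df = simulate_distance_pairs(-50.0, 1.0, 30.0, 500, (0, 30), seed=6)
        assert (df["genomic_distance"] >= 0).all()

    def test_null_slope_p_values_approximately_uniform(self):
        from scipy import stats

        pvals = []
        for seed in range(300):
            df = simulate_distance_pairs(5.0, 0.0, 1.0, 20, (5, 30), seed=seed)
            _, p = pearson_correlation(df["euclidean_mm"], df["genomic_distance"])
            pvals.append(p)
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_pooled_cohort_recovers_target_slopes(self):
        records = simulate_linear_cohort(seed=2024)
        for modality, target in DEFAULT_LINEAR_TARGETS.items():
            sub = records[records["modality"] == modality]
            fit = ols_fit(sub["euclidean_mm"], sub["genomic_distance"])
            assert fit.slope == pytest.approx(target.slope, abs=2 * fit.stderr_slope)


def test_round_trip_files_feed_every_consumer(tmp_path):
    import warnings

    from gliodist.pipeline import RunConfig, run_pipeline
    from gliodist.simulate import write_cohort

    cfg = small_config(n_patients=4)
    cohort = simulate_cohort(cfg)
    paths = write_cohort(cohort, tmp_path / "cohort")
    rc = RunConfig(
        coordinates=paths["coordinates"],
        variants=paths["variants"],
        cnv_dir=paths["cnv_dir"],
        beta=paths["beta"],
        sample_meta=paths["sample_meta"],
        outdir=str(tmp_path / "out"),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        report = run_pipeline(rc)
    expected_pairs = len(enumerate_pairs(cohort.sites))
    assert report["n_pairs"] == expected_pairs
    assert set(report["associations"]) == {"mutation", "cnv", "methylation"}
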