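import numpy as np
import pandas as pd
import pytest

from updscreen.classify import CALL_HUPD, CALL_IUPD, analyze_family
from updscreen.config import AnalysisConfig, FilterConfig
from updscreen.errors import ConfigurationError
from updscreen.genome import AUTOSOMES, get_build
from updscreen.inheritance import classify_origin_frame, count_origins
from updscreen.simulate import (
    FamilySim,
    SimulationConfig,
    SyntheticTruth,
    add_read_noise,
    make_event_plan,
    run_simulated_screen,
    simulate_cohort,
    simulate_family,
    write_cohort,
)
from updscreen.vcf_io import (
    HET,
    HOM_ALT,
    Pedigree,
    apply_site_filters,
    filter_mask,
    read_vcf_frame,
)


def rng_for(seed=0):
    return np.random.default_rng(seed)


def small_cfg(**kw):
    defaults = dict(seed=7, n_families=1, sites_per_chromosome=200)
    defaults.update(kw)
    return SimulationConfig(**defaults)


def variant_frame(fam: FamilySim, role: str) -> pd.DataFrame:
    return fam.calls[role].loc[~fam.calls[role]["artifact"]]


class TestSimulateFamily:
    def test_mendelian_consistency_without_events(self):
        cfg = small_cfg()
        fam = simulate_family(cfg, "F0", "trio", [], rng_for(1))
        child = fam.true_gt["child"]
        mother = fam.true_gt["mother"]
        father = fam.true_gt["father"]
        # child dosage must be achievable from one allele per parent
        child_min = (mother == 2).astype(int) + (father == 2).astype(int)
        child_max = (mother > 0).astype(int) + (father > 0).astype(int)
        assert np.all(child >= child_min)
        assert np.all(child <= child_max)

    def test_iupd_maternal_all_homozygous_and_carried(self):
        cfg = small_cfg()
        build = get_build(cfg.genome_build)
        event = SyntheticTruth(
            "F0", "5", "iUPD", "maternal", 1, build.length("5"), 1.0
        )
        fam = simulate_family(cfg, "F0", "trio", [event], rng_for(2))
        on5 = fam.sites["chrom"].to_numpy() == "5"
        child = fam.true_gt["child"][on5]
        mother = fam.true_gt["mother"][on5]
        assert set(np.unique(child)) <= {0, 2}
        # every child alt allele is present in the mother
        assert np.all(mother[child == 2] > 0)

    def test_hupd_child_equals_parent_genotype(self):
        cfg = small_cfg()
        build = get_build(cfg.genome_build)
        event = SyntheticTruth(
            "F0", "9", "hUPD", "maternal", 1, build.length("9"), 1.0
        )
        fam = simulate_family(cfg, "F0", "trio", [event], rng_for(3))
        on9 = fam.sites["chrom"].to_numpy() == "9"
        assert np.array_equal(
            fam.true_gt["child"][on9], fam.true_gt["mother"][on9]
        )

    def test_hupd_paternal_only_near_zero(self):
        # noise-free check through the inheritance module
        cfg = small_cfg(error_rate=0.0, mean_depth=500.0)
        build = get_build(cfg.genome_build)
        event = SyntheticTruth(
            "F0", "9", "hUPD", "maternal", 1, build.length("9"), 1.0
        )
        fam = simulate_family(cfg, "F0", "trio", [event], rng_for(4))
        config = AnalysisConfig()
        report = analyze_family(
            fam.calls["child"], fam.calls["mother"], fam.calls["father"],
            fam.pedigree, "F0", config=config,
        )
        m = report.metrics["9"]
        assert m.paternal_only <= 2
        assert m.maternal_only > 20

    def test_segmental_event_limited_to_interval(self):
        cfg = small_cfg()
        build = get_build(cfg.genome_build)
        L = build.length("4")
        event = SyntheticTruth(
            "F0", "4", "segUPD_iso", "paternal", 1, L // 2, 0.5
        )
        fam = simulate_family(cfg, "F0", "trio", [event], rng_for(5))
        on4 = fam.sites["chrom"].to_numpy() == "4"
        inside = on4 & (fam.sites["pos"].to_numpy() <= L // 2)
        child = fam.true_gt["child"]
        assert set(np.unique(child[inside])) <= {0, 2}
        # outside the interval hets persist
        assert np.any(child[on4 & ~inside] == 1)

    def test_interval_outside_sites_rejected(self):
        cfg = small_cfg()
        event = SyntheticTruth("F0", "4", "iUPD", "maternal", 10, 20, 0.0)
        with pytest.raises(ConfigurationError):
            simulate_family(cfg, "F0", "trio", [event], rng_for(6))

    def test_two_events_one_chromosome_rejected(self):
        cfg = small_cfg()
        events = [
            SyntheticTruth("F0", "4", "iUPD", "maternal"),
            SyntheticTruth("F0", "4", "hUPD", "paternal"),
        ]
        with pytest.raises(ConfigurationError):
            simulate_family(cfg, "F0", "trio", events, rng_for(7))


class TestReadNoise:
    def test_noise_free_hom_fractions_exact(self):
        cfg = small_cfg(error_rate=0.0)
        fam = simulate_family(cfg, "F0", "trio", [], rng_for(8))
        noisy = add_read_noise(fam.sites, fam.true_gt["child"], cfg, rng_for(9))
        hom_alt_true = fam.true_gt["child"] == 2
        hom_ref_true = fam.true_gt["child"] == 0
        ok = noisy["depth"].to_numpy() > 0
        af = noisy["alt_fraction"].to_numpy()
        assert np.all(af[hom_alt_true & ok] == 1.0)
        assert np.all(af[hom_ref_true & ok] == 0.0)

    def test_high_depth_het_fraction_near_half(self):
        cfg = small_cfg(error_rate=0.0, mean_depth=10_000.0)
        fam = simulate_family(cfg, "F0", "trio", [], rng_for(10))
        noisy = add_read_noise(fam.sites, fam.true_gt["child"], cfg, rng_for(11))
        hets = fam.true_gt["child"] == 1
        af = noisy["alt_fraction"].to_numpy()[hets]
        assert np.all(np.abs(af - 0.5) < 0.05)

    def test_artifact_count_exact_per_chromosome(self):
        cfg = small_cfg(artifact_sites_per_chromosome=30)
        fam = simulate_family(cfg, "F0", "trio", [], rng_for(12))
        artifacts = fam.calls["child"].loc[fam.calls["child"]["artifact"]]
        per_chrom = artifacts.groupby("chrom").size()
        assert set(per_chrom.index) == set(AUTOSOMES)
        assert (per_chrom == 30).all()
        assert (artifacts["gt"] == HET).all()

    def test_default_filters_remove_most_artifacts(self):
        # Monte-Carlo across replicate families at a fixed seed
        cfg = small_cfg(n_families=1, sites_per_chromosome=100)
        removed = total = 0
        for rep in range(20):
            fam = simulate_family(cfg, f"F{rep}", "trio", [], rng_for(100 + rep))
            calls = fam.calls["child"]
            keep = filter_mask(calls, FilterConfig())
            artifact = calls["artifact"].to_numpy()
            removed += int((artifact & ~keep).sum())
            total += int(artifact.sum())
        assert total == 20 * 22 * 30
        assert removed / total >= 0.90


class TestDeterminismAndIO:
    def test_fixed_seed_byte_identical_vcfs(self, tmp_path):
        cfg = small_cfg(n_families=2, setup_mix=(0.0, 0.5, 0.5))
        out1, out2 = tmp_path / "a", tmp_path / "b"
        write_cohort(simulate_cohort(cfg), out1)
        write_cohort(simulate_cohort(cfg), out2)
        files1 = sorted(p.name for p in out1.iterdir())
        assert files1 == sorted(p.name for p in out2.iterdir())
        for name in files1:
            assert (out1 / name).read_bytes() == (out2 / name).read_bytes()

    def test_trio_writes_three_vcfs_and_manifest(self, tmp_path):
        cfg = small_cfg(n_families=1)
        manifest_path, truth_path = write_cohort(simulate_cohort(cfg), tmp_path)
        manifest = pd.read_csv(manifest_path, sep="\t")
        assert len(manifest) == 3
        assert set(manifest["role"]) == {"child", "mother", "father"}
        assert truth_path.exists()

    def test_vcf_round_trip_preserves_genotype_classes(self, tmp_path):
        cfg = small_cfg(n_families=1)
        (fam,) = simulate_cohort(cfg)
        write_cohort([fam], tmp_path)
        back = read_vcf_frame(tmp_path / f"{fam.family}_child.vcf")
        written = fam.calls["child"]
        assert len(back) == len(written)
        assert list(back["gt"]) == list(written["gt"])
        assert list(back["pos"]) == list(written["pos"])
        np.testing.assert_allclose(
            back["alt_fraction"].to_numpy(),
            written["alt_reads"].to_numpy() / written["depth"].to_numpy(),
        )

    def test_family_output_independent_of_cohort_size(self):
        cfg2 = small_cfg(n_families=2)
        cfg3 = small_cfg(n_families=3)
        fams2 = simulate_cohort(cfg2)
        fams3 = simulate_cohort(cfg3)
        pd.testing.assert_frame_equal(
            fams2[0].calls["child"], fams3[0].calls["child"]
        )


class TestEventPlan:
    def test_counts_and_uniqueness(self):
        build = get_build("GRCh38")
        fids = [f"F{i:03d}" for i in range(30)]
        events = make_event_plan(
            fids, rng_for(1), build, n_iupd=5, n_hupd=4, n_segupd=3,
            n_consanguinity=2,
        )
        assert len(events) == 14
        assert len({e.family for e in events}) == 14
        kinds = pd.Series([e.event for e in events]).value_counts()
        assert kinds["iUPD"] == 5 and kinds["hUPD"] == 4
        for e in events:
            if e.event == "segUPD_iso":
                assert 0.3 <= e.fraction <= 0.6

    def test_too_many_events_rejected(self):
        build = get_build("GRCh38")
        with pytest.raises(ConfigurationError):
            make_event_plan(["F0"], rng_for(1), build, n_iupd=2)


@pytest.fixture(scope="module")
def screened():
    """Scaled-down cohort at default site density (full scale in acceptance)."""
    build = get_build("GRCh38")
    rng = rng_for(123)
    fids = [f"F{i:04d}" for i in range(8)]
    events = make_event_plan(
        fids, rng, build, n_iupd=2, n_hupd=2, n_consanguinity=1
    )
    cfg = SimulationConfig(seed=11, n_families=8, events=events)
    cohort, truth, reports = run_simulated_screen(cfg)
    return cohort, truth, reports


class TestStatisticalRecovery:

    def test_iupd_high_roh(self, screened):
        cohort, truth, _ = self.unpack(screened)
        for e in truth.loc[truth["event"] == "iUPD"].itertuples(index=False):
            row = cohort.loc[
                (cohort["family"] == e.family) & (cohort["chrom"] == e.chrom)
            ].iloc[0]
            assert row.roh_fraction > 0.95
            assert row.upd_call == CALL_IUPD

    def test_hupd_relative_ir_extreme(self, screened):
        cohort, truth, _ = self.unpack(screened)
        for e in truth.loc[truth["event"] == "hUPD"].itertuples(index=False):
            row = cohort.loc[
                (cohort["family"] == e.family) & (cohort["chrom"] == e.chrom)
            ].iloc[0]
            assert row.upd_call == CALL_HUPD
            assert row.upd_parent == e.parent
            rel = row.relative_ir
            assert (rel > 0.95) if e.parent == "maternal" else (rel < 0.05)

    def test_outbred_chromosomes_low_roh(self, screened):
        cohort, truth, _ = self.unpack(screened)
        event_pairs = set(zip(truth["family"], truth["chrom"]))
        consang = set(truth.loc[truth["event"] == "consanguinity", "family"])
        normal = cohort.loc[
            [
                (r.family, r.chrom) not in event_pairs and r.family not in consang
                for r in cohort.itertuples(index=False)
            ]
        ]
        assert normal["roh_fraction"].median() < 0.1

    def test_consanguine_family_flagged_with_elevated_autosomes(self, screened):
        cohort, truth, _ = self.unpack(screened)
        consang = set(truth.loc[truth["event"] == "consanguinity", "family"])
        assert consang
        for family in consang:
            rows = cohort.loc[cohort["family"] == family]
            assert rows["consanguinity_flag"].all()
            elevated = rows.loc[
                rows["roh_tag"].isin(["high_mixed", "high"])
            ]
            assert len(elevated) >= 3

    @staticmethod
    def unpack(screened):
        return screened
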