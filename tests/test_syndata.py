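"""Synthetic-data generators: determinism, planted structure, noiseless expectations."""

import numpy as np
import pandas as pd
import pytest

from cnvherd import Chromosome, GenomeLayout, syndata
from cnvherd.core import overlap_bp


class TestMakeProbes:
    def test_probe_count_tracks_mean_spacing(self):
        g = GenomeLayout((Chromosome("1", 1_000_000),))
        probes = syndata.make_probes(g, mean_spacing=3364, probe_len=60, seed=3)
        expected = 1_000_000 / 3364  # ~297
        assert abs(len(probes) - expected) / expected < 0.10
        assert abs(probes.mean_spacing("1") - 3364) / 3364 < 0.05

    def test_mito_contig_gets_exactly_five_probes(self, small_probes):
        assert len(small_probes.chrom_probes("M")) == 5

    def test_same_seed_identical_different_seed_not(self, small_genome):
        a = syndata.make_probes(small_genome, seed=11)
        b = syndata.make_probes(small_genome, seed=11)
        c = syndata.make_probes(small_genome, seed=12)
        assert a == b
        assert a != c

    def test_probe_lengths_and_sorting(self, small_probes):
        df = small_probes.df
        lengths = df["end"] - df["start"]
        assert ((lengths >= 50) & (lengths <= 75)).all()

    def test_rejects_too_short_chromosome(self):
        g = GenomeLayout((Chromosome("tiny", 40),))
        with pytest.raises(ValueError, match="shorter than one probe"):
            syndata.make_probes(g, mean_spacing=300, probe_len=60)

    def test_rejects_spacing_below_probe_length(self, small_genome):
        with pytest.raises(ValueError, match="mean_spacing"):
            syndata.make_probes(small_genome, mean_spacing=50, probe_len=60)


class TestPlantEvents:
    GROUPS = {"t1": "taurine", "t2": "taurine", "y1": "yak", "y2": "yak"}

    def test_zero_design_gives_empty_truth(self, small_genome):
        d = syndata.EventDesign(n_shared=0, n_group=0, n_private=0)
        assert syndata.plant_events(small_genome, self.GROUPS, d, seed=0) == []

    def test_group_event_identical_in_all_members(self, small_genome):
        d = syndata.EventDesign(n_shared=0, n_group=1, n_private=0, min_len=5000, max_len=9000)
        events = syndata.plant_events(small_genome, self.GROUPS, d, seed=1)
        yak = [e for e in events if e.sample.startswith("y")]
        assert len(yak) == 2
        assert (yak[0].chrom, yak[0].start, yak[0].end, yak[0].copy_number) == (
            yak[1].chrom,
            yak[1].start,
            yak[1].end,
            yak[1].copy_number,
        )

    def test_shared_events_identical_everywhere_and_private_unique(self, small_genome):
        d = syndata.EventDesign(n_shared=2, n_group=1, n_private=2, min_len=5000, max_len=20000)
        events = syndata.plant_events(small_genome, self.GROUPS, d, seed=5)
        shared = [e for e in events if e.scope == "shared-all"]
        assert len(shared) == 2 * len(self.GROUPS)
        coords = {(e.chrom, e.start, e.end) for e in shared}
        assert len(coords) == 2
        private = [e for e in events if e.scope == "private"]
        assert len(private) == 2 * len(self.GROUPS)

    def test_per_sample_events_never_overlap(self, small_genome):
        d = syndata.EventDesign(n_shared=3, n_group=3, n_private=3, min_len=20000, max_len=80000)
        events = syndata.plant_events(small_genome, self.GROUPS, d, seed=9)
        for s in self.GROUPS:
            mine = [e for e in events if e.sample == s]
            for i, a in enumerate(mine):
                for b in mine[i + 1 :]:
                    if a.chrom == b.chrom:
                        assert overlap_bp(a.start, a.end, b.start, b.end) == 0

    def test_rejects_event_longer_than_chromosome(self, small_genome):
        d = syndata.EventDesign(max_len=5_000_000)
        with pytest.raises(ValueError, match="exceeds every chromosome"):
            syndata.plant_events(small_genome, self.GROUPS, d, seed=0)


class TestSimulateRatios:
    def test_noiseless_values_follow_log2_cn_over_two(self, small_probes):
        groups = {"s1": "g"}
        events = [
            syndata.TruthEvent("s1", "1", 0, 200_000, 1, "private"),
            syndata.TruthEvent("s1", "1", 300_000, 500_000, 3, "private"),
            syndata.TruthEvent("s1", "1", 600_000, 800_000, 4, "private"),
            syndata.TruthEvent("s1", "2", 0, 200_000, 0, "private"),
        ]
        prof = syndata.simulate_ratios(small_probes, events, groups, noise_sd=0.0)
        v = prof.values["s1"].to_numpy()
        mids = {c: small_probes.midpoints(c) for c in ("1", "2")}
        i1 = small_probes.span("1")[0]
        i2 = small_probes.span("2")[0]

        def vals(chrom, lo, hi):
            base = i1 if chrom == "1" else i2
            m = mids[chrom]
            return v[base + np.searchsorted(m, lo) : base + np.searchsorted(m, hi)]

        assert np.allclose(vals("1", 0, 200_000), -1.0)
        assert np.allclose(vals("1", 300_000, 500_000), np.log2(1.5))
        assert np.allclose(vals("1", 600_000, 800_000), 1.0)
        assert np.allclose(vals("2", 0, 200_000), syndata.CN0_FLOOR)
        assert np.allclose(vals("1", 850_000, 1_000_000), 0.0)  # background

    def test_noise_reproducible_for_fixed_seed(self, small_probes):
        groups = {"a": "g", "b": "g"}
        p1 = syndata.simulate_ratios(small_probes, [], groups, noise_sd=0.3, seed=4)
        p2 = syndata.simulate_ratios(small_probes, [], groups, noise_sd=0.3, seed=4)
        pd.testing.assert_frame_equal(p1.values, p2.values)

    def test_rejects_negative_noise(self, small_probes):
        with pytest.raises(ValueError):
            syndata.simulate_ratios(small_probes, [], {"a": "g"}, noise_sd=-0.1)


class TestMakeFeatures:
    def test_empty_request_gives_empty_set(self, small_genome):
        assert syndata.make_features(small_genome, 0, 0) == []

    def test_qtl_classes_from_the_six_known_classes(self, small_genome):
        feats = syndata.make_features(small_genome, 10, 40, seed=2)
        qtls = [f for f in feats if f.kind == "QTL"]
        assert len(qtls) == 40
        assert {q.trait_class for q in qtls} <= set(syndata.QTL_CLASSES)
        assert all(f.trait_class == "" for f in feats if f.kind == "gene")

    def test_fixed_seed_reproducible(self, small_genome):
        assert syndata.make_features(small_genome, 20, 20, seed=8) == syndata.make_features(
            small_genome, 20, 20, seed=8
        )


class TestSimulatePhenotypes:
    SPEC = syndata.AssocModelSpec(
        trait="heart_girth",
        mu=170.0,
        farm_effects={"f1": 0.0, "f2": 2.0},
        genotype_effects={"normal": 0.0, "loss": 5.0, "gain": -3.0},
        breed_effects={"QC": 0.0, "NY": 1.0},
        error_sd=0.0,
    )

    def test_zero_noise_reproduces_cell_means(self):
        recs = {
            "s1": ("f1", "QC", "normal"),
            "s2": ("f2", "NY", "loss"),
            "s3": ("f1", "NY", "gain"),
        }
        df = syndata.simulate_phenotypes(self.SPEC, recs, seed=0)
        got = dict(zip(df["sample"], df["heart_girth"]))
        assert got["s1"] == pytest.approx(170.0)
        assert got["s2"] == pytest.approx(170.0 + 2.0 + 5.0 + 1.0)
        assert got["s3"] == pytest.approx(170.0 - 3.0 + 1.0)

    def test_sample_means_converge_to_cell_expectation(self):
        import dataclasses

        spec = dataclasses.replace(self.SPEC, error_sd=4.0)
        recs = {f"s{i}": ("f1", "QC", "loss") for i in range(200)}
        df = syndata.simulate_phenotypes(spec, recs, seed=42)
        expect = 170.0 + 5.0
        assert abs(df["heart_girth"].mean() - expect) < 3 * 4.0 / np.sqrt(200)

    def test_unknown_level_rejected(self):
        with pytest.raises(ValueError, match="unknown farm"):
            syndata.simulate_phenotypes(self.SPEC, {"s1": ("nope", "QC", "loss")})


class TestSimulateQpcr:
    def test_noiseless_ct_values(self):
        wells = syndata.simulate_qpcr({"a": 2, "b": 4, "c": 1}, base_ct=26.0, rep_sd=0.0)
        mean = wells.groupby(["sample", "assay"])["ct"].mean()
        assert mean[("a", "target")] == pytest.approx(26.0)
        assert mean[("b", "target")] == pytest.approx(25.0)  # one cycle per doubling
        assert mean[("c", "target")] == pytest.approx(27.0)
        assert mean[("a", "BTF3")] == pytest.approx(20.0)

    def test_cn0_hits_no_amplification_ceiling(self):
        wells = syndata.simulate_qpcr({"z": 0}, rep_sd=0.0, no_amp_ct=40.0)
        z = wells[(wells["sample"] == "z") & (wells["role"] == "target")]
        assert (z["ct"] == 40.0).all()

    def test_calibrator_must_be_two_copies(self):
        with pytest.raises(ValueError, match="calibrator"):
            syndata.simulate_qpcr({"reference": 4})
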