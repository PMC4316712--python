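"""Synthetic cohort / expression generators and their planted truth."""

import numpy as np
import pytest
from scipy import stats

from mdr21 import synth
from mdr21.harmonization import build_anchor_grid


class TestPlatformLayout:
    def test_uniform_placement_formula(self):
        lay = synth.make_platform_layout("t", 10000, 5, 0.1)
        assert lay.probe_positions.tolist() == [1000, 3000, 5000, 7000, 9000]

    def test_smallest_valid_layout(self):
        lay = synth.make_platform_layout("t", 4, 2, 0.0)
        assert lay.probe_positions.tolist() == [1, 3]

    def test_jittered_layout_is_seeded_and_sorted(self):
        a = synth.make_platform_layout("t", 10**6, 50, 0.1, "jittered", seed=3)
        b = synth.make_platform_layout("t", 10**6, 50, 0.1, "jittered", seed=3)
        assert np.array_equal(a.probe_positions, b.probe_positions)
        assert np.all(np.diff(a.probe_positions) > 0)

    @pytest.mark.parametrize("kwargs", [
        {"n_probes": 1}, {"chrom_length": 0}, {"chrom_length": 5, "n_probes": 5},
    ])
    def test_invalid_arguments_rejected(self, kwargs):
        args = {"name": "t", "chrom_length": 1000, "n_probes": 10,
                "noise_sd": 0.1}
        args.update(kwargs)
        with pytest.raises(ValueError):
            synth.make_platform_layout(**args)


def scenario(n_samples=10, lesions=(), noise_sd=0.1, seed=1, n_probes=50):
    layout = synth.make_platform_layout("t", 100_000, n_probes, noise_sd)
    return synth.CohortScenario(
        cohort_name="c", n_samples=n_samples, platform=layout,
        lesions=list(lesions), seed=seed,
    )


def lesion(start, end, freq=0.5, shift=-1.0, name="L"):
    return synth.PlantedLesion(
        start=start, end=end, direction="deletion",
        carrier_frequency=freq, log2_shift=shift, name=name,
    )


class TestSimulateCnCohort:
    def test_null_model_is_exact_zero(self):
        pm, truth = synth.simulate_cn_cohort(scenario(noise_sd=0.0))
        assert np.all(pm.values == 0.0)
        assert truth.carriers.shape == (10, 0)

    def test_carrier_fraction_within_exact_binomial_interval(self):
        scn = scenario(n_samples=1000, lesions=[lesion(10_000, 30_000)])
        _, truth = synth.simulate_cn_cohort(scn)
        carried = int(truth.carriers[:, 0].sum())
        lo, hi = stats.binom.ppf([0.025, 0.975], 1000, 0.5)
        assert lo <= carried <= hi

    def test_same_seed_is_bit_identical(self):
        a, _ = synth.simulate_cn_cohort(scenario(lesions=[lesion(0, 500)]))
        b, _ = synth.simulate_cn_cohort(scenario(lesions=[lesion(0, 500)]))
        assert np.array_equal(a.values, b.values)

    def test_lesion_outside_chromosome_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            scenario(lesions=[lesion(90_000, 200_000)])

    def test_later_lesion_overrides_on_overlap(self):
        scn = scenario(
            n_samples=3, noise_sd=0.0,
            lesions=[lesion(0, 60_000, freq=1.0, shift=-1.0, name="a"),
                     lesion(40_000, 100_000, freq=1.0, shift=-0.3, name="b")],
        )
        pm, _ = synth.simulate_cn_cohort(scn)
        pos = pm.start
        assert np.all(pm.values[pos < 40_000] == -1.0)
        assert np.all(pm.values[pos >= 40_000] == -0.3)

    def test_truth_frequency_matches_carriers_inside_lesion_only(self):
        scn = scenario(n_samples=20, lesions=[lesion(20_000, 40_000, 0.4)])
        _, truth = synth.simulate_cn_cohort(scn)
        grid = build_anchor_grid(100_000, 100, chrom="chr21")
        freq = truth.true_del_freq(grid)
        inside = (grid.positions >= 20_000) & (grid.positions < 40_000)
        assert np.all(freq[inside] == truth.carrier_fraction(0))
        assert np.all(freq[~inside] == 0.0)


class TestExpressionSimulators:
    def test_empty_down_set_means_empty_truth(self):
        ds, truth = synth.simulate_expression_dataset(
            n_genes=50, n_tumor=5, n_normal=5, seed=2
        )
        assert truth == {}
        assert ds.values.shape == (50, 10)

    def test_planted_gene_has_most_negative_difference(self):
        ds, truth = synth.simulate_expression_dataset(
            n_genes=100, n_tumor=20, n_normal=20,
            down_genes={"G0042": -2.0}, noise_sd=0.1, seed=3,
        )
        tum, nor = ds.split()
        diff = tum.mean(axis=1) - nor.mean(axis=1)
        assert ds.feature_ids[int(np.argmin(diff))] == "G0042"

    def test_zero_noise_reproduces_planted_lfc_exactly(self):
        ds, _ = synth.simulate_mirna_dataset(
            n_features=30, n_tumor=4, n_normal=4,
            down_features={"M0007": -1.5}, noise_sd=0.0, seed=1,
        )
        tum, nor = ds.split()
        diff = tum.mean(axis=1) - nor.mean(axis=1)
        assert diff[7] == pytest.approx(-1.5)
        assert np.allclose(np.delete(diff, 7), 0.0)

    def test_mirna_truth_lists_exactly_planted_features(self):
        down = {"M0001": -1.0, "M0100": -2.0, "M0200": -1.5}
        _, truth = synth.simulate_mirna_dataset(down_features=down, seed=4)
        assert truth == down

    def test_same_seed_identical_matrices(self):
        a, _ = synth.simulate_expression_dataset(seed=9)
        b, _ = synth.simulate_expression_dataset(seed=9)
        assert np.array_equal(a.values, b.values)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            synth.simulate_expression_dataset(n_tumor=1, n_normal=5)

    def test_unknown_down_feature_rejected(self):
        with pytest.raises(ValueError, match="not in annotation"):
            synth.simulate_expression_dataset(
                n_genes=10, down_genes={"G9999": -1.0}
            )


class TestDefaultPacks:
    def test_scenario_pack_mirrors_study_cohorts(self):
        pack = synth.default_scenario_pack(0)
        sizes = {c: s.n_samples for c, s in pack.items()}
        assert sizes == {"breast": 359, "lung": 78, "melanoma": 34, "wilms": 18}
        probes = {c: s.platform.n_probes for c, s in pack.items()}
        assert probes == {"breast": 500, "lung": 500, "melanoma": 900,
                          "wilms": 1600}
        freqs = sorted(
            l.carrier_frequency for s in pack.values() for l in s.lesions
        )
        assert freqs == [0.117, 0.269, 0.5, 0.5, 0.617]

    def test_planted_breakpoints_sit_on_carrier_probe_grids(self):
        pack = synth.default_scenario_pack(0)
        for scn in pack.values():
            gap = scn.platform.chrom_length / scn.platform.n_probes
            for les in scn.lesions:
                for bound in (les.start, les.end):
                    # distance to the nearest probe-grid boundary < 1 bp+round
                    assert min(bound % gap, gap - bound % gap) <= 1.0

    def test_expected_candidates_from_planted_truth(self):
        _, _, gene_ann = synth.default_expression_pack(0)
        assert synth.expected_candidates(synth.GENE_DOWN, gene_ann) == {
            "G0044", "G0060", "G0149",
        }
        _, _, mir_ann = synth.default_mirna_pack(0)
        assert synth.expected_candidates(synth.MIRNA_DOWN, mir_ann) == {
            "M0100", "M0101", "M0102",
        }

    def test_annotation_is_deterministic_and_shared(self):
        a = synth.make_feature_annotation(200)
        b = synth.make_feature_annotation(200)
        assert [(iv.start, iv.name) for iv in a] == [
            (iv.start, iv.name) for iv in b
        ]
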