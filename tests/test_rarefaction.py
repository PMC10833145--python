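"""Seeded subsampling experiment: records, summaries, PC1 grids."""

import numpy as np
import pytest

import morphosample as ms


@pytest.fixture(scope="module")
def study():
    spec = ms.GeneratorSpec(
        groups=[ms.GroupSpec("sp", "F", 12), ms.GroupSpec("sp", "M", 12)],
        view="ventral_cranium",
        seed=7,
    )
    return ms.generate_dataset(spec)


class TestRunRarefaction:
    def test_full_bin_records_identical_with_zero_distance(self, study):
        ds, _ = study
        records, full = ms.run_rarefaction(ds, fractions=(1.0,), T=5, base_seed=2)
        assert all(r.dist_to_true == 0.0 for r in records)
        first = records[0]
        for r in records[1:]:
            assert r.member_ids == first.member_ids
            assert np.array_equal(r.mean_shape, first.mean_shape)

    def test_noise_free_data_has_zero_distance_everywhere(self):
        spec = ms.GeneratorSpec(
            groups=[ms.GroupSpec("s", "F", 20)], view="ventral_cranium",
            landmark_noise_sd=0.0, allometry_slope=0.0, seed=1,
        )
        ds, _ = ms.generate_dataset(spec)
        records, _ = ms.run_rarefaction(ds, fractions=(0.5, 0.25), T=3, base_seed=1)
        assert max(r.dist_to_true for r in records) < 1e-9

    def test_byte_identical_reruns(self, study):
        ds, _ = study
        r1, _ = ms.run_rarefaction(ds, fractions=(0.5, 0.25), T=4, base_seed=9)
        r2, _ = ms.run_rarefaction(ds, fractions=(0.5, 0.25), T=4, base_seed=9)
        for a, b in zip(r1, r2):
            assert a.member_ids == b.member_ids
            assert a.seed == b.seed
            assert a.dist_to_true == b.dist_to_true
            assert np.array_equal(a.mean_shape, b.mean_shape)

    def test_seed_schedule_recorded(self, study):
        ds, _ = study
        records, _ = ms.run_rarefaction(ds, fractions=(0.5, 0.25), T=3, base_seed=4)
        for r in records:
            bin_index = (0.5, 0.25).index(r.fraction)
            assert r.seed == ms.subsample_seed(4, bin_index, r.iteration)

    def test_rounding_and_minimum_subsample_guard(self):
        from morphosample.rarefaction import _round_half_up

        assert _round_half_up(72 * 0.1) == 7
        assert _round_half_up(81 * 0.1) == 8
        assert _round_half_up(2.5) == 3

    def test_too_small_fraction_is_an_error(self, study):
        ds, _ = study
        with pytest.raises(ValueError, match="0.1"):
            ms.run_rarefaction(ds, fractions=(0.1,), T=1, base_seed=1)  # 24 * 0.1 -> 2 < 3

    def test_centroid_size_only_fast_path(self, study):
        ds, _ = study
        slow, _ = ms.run_rarefaction(ds, fractions=(0.5,), T=3, base_seed=5)
        fast, _ = ms.run_rarefaction(ds, fractions=(0.5,), T=3, base_seed=5, compute_shapes=False)
        for a, b in zip(slow, fast):
            assert a.member_ids == b.member_ids
            assert a.mean_log_cs == b.mean_log_cs
            assert np.isnan(b.dist_to_true)


@pytest.fixture(scope="module")
def run(study):
    ds, _ = study
    records, full = ms.run_rarefaction(ds, fractions=(1.0, 0.75, 0.5, 0.25), T=30, base_seed=3)
    summary = ms.summarize_rarefaction(records, full, n_perm=200, seed=0)
    return records, full, summary


class TestSummarize:
    def test_distance_grows_as_fraction_shrinks(self, run):
        records, _, _ = run
        df = ms.records_to_dataframe(records)
        means = df[df.fraction < 1].groupby("fraction").dist_to_true.mean()
        assert means.loc[0.25] > means.loc[0.5] > means.loc[0.75]

    def test_full_bin_excluded_from_distance_anova(self, run):
        _, _, summary = run
        labels = set(summary.dist_tukey.group_i) | set(summary.dist_tukey.group_j)
        assert "100%" not in labels
        assert summary.dist_anova.p[0] <= 0.05  # bins differ strongly at T=30

    def test_mean_centroid_size_unbiased(self, run):
        records, full, _ = run
        true_mean = np.log10(full.centroid_sizes).mean()
        df = ms.records_to_dataframe(records)
        for frac, grp in df.groupby("fraction"):
            if frac == 1.0:
                assert np.allclose(grp.mean_log_cs, true_mean)
                continue
            se = grp.mean_log_cs.std(ddof=1) / np.sqrt(len(grp))
            assert abs(grp.mean_log_cs.mean() - true_mean) < 3 * se + 1e-12

    def test_hull_areas_nested_by_fraction(self, run):
        _, _, summary = run
        areas = summary.hull_areas
        assert areas[1.0] == 0.0
        assert areas[0.25] > areas[0.5] > areas[0.75]

    def test_dispersion_battery_covers_all_bin_pairs(self, run):
        _, _, summary = run
        assert len(summary.dispersion_table) == 6  # 4 bins -> 6 pairs
        pair = summary.dispersion_table.set_index(["group_i", "group_j"])
        assert pair.loc[("25%", "75%")].p.item() <= 0.05

    def test_single_bin_rejected(self, study):
        ds, _ = study
        records, full = ms.run_rarefaction(ds, fractions=(0.5,), T=3, base_seed=1)
        with pytest.raises(ValueError, match="2 bins"):
            ms.summarize_rarefaction(records, full, n_perm=50)


class TestPc1Grids:
    def test_noise_free_grids_are_identity(self):
        spec = ms.GeneratorSpec(
            groups=[ms.GroupSpec("s", "F", 12)], view="ventral_cranium",
            landmark_noise_sd=0.0, allometry_slope=0.0, seed=2,
        )
        ds, _ = ms.generate_dataset(spec)
        records, full = ms.run_rarefaction(ds, fractions=(0.5,), T=1, base_seed=1)
        grids = ms.pc1_grids_for_iterations(records, ds, full, [(0.5, 1)])
        for g in grids.values():
            assert np.abs(g.warped_neg - g.grid).max() < 1e-6
            assert np.abs(g.warped_pos - g.grid).max() < 1e-6

    def test_full_grid_equals_100pct_subsample_grid(self, study):
        ds, _ = study
        records, full = ms.run_rarefaction(ds, fractions=(1.0, 0.5), T=2, base_seed=1)
        grids = ms.pc1_grids_for_iterations(records, ds, full, [(0.5, 1)])
        assert "full" in grids and (0.5, 1) in grids
        # the full-sample grid is computed from the complete data, identical
        # to what a 100% "subsample" would produce
        rec100 = [r for r in records if r.fraction == 1.0][0]
        assert rec100.member_ids == ds.ids

    def test_small_subsample_pc1_field_correlates_with_full(self):
        # one dominant shape axis: allometry strong enough to own PC1
        spec = ms.GeneratorSpec(
            groups=[ms.GroupSpec("sp", "F", 12), ms.GroupSpec("sp", "M", 12)],
            view="ventral_cranium", allometry_slope=2.5, seed=7,
        )
        ds, _ = ms.generate_dataset(spec)
        records, full = ms.run_rarefaction(ds, fractions=(0.25,), T=3, base_seed=6)
        grids = ms.pc1_grids_for_iterations(records, ds, full, [(0.25, i) for i in (1, 2, 3)])
        ref = grids["full"].displacement
        cors = []
        for i in (1, 2, 3):
            d = grids[(0.25, i)].displacement
            cors.append(abs(np.corrcoef(ref, d)[0, 1]))
        # dominant allometric axis: small subsamples see the same PC1
        assert np.mean(cors) > 0.8

    def test_missing_record_raises(self, study):
        ds, _ = study
        records, full = ms.run_rarefaction(ds, fractions=(0.5,), T=1, base_seed=1)
        with pytest.raises(KeyError):
            ms.pc1_grids_for_iterations(records, ds, full, [(0.25, 1)])
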