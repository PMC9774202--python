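"""Synthetic dataset generation, rebalancing, splitting, partitioning."""

import numpy as np
import pytest

from fedprune.synthetic import (
    DAY_AGE_COUNTS,
    AugmentationConfig,
    ClassSpec,
    ImageSample,
    SplitSpec,
    generate_dataset,
    partition_clients,
    rebalance,
    split_train_test,
    stack,
    day_age_class_specs,
    uniform_class_specs,
)


def _counts(samples):
    out = {}
    for s in samples:
        out[s.label] = out.get(s.label, 0) + 1
    return out


class TestClassSpecs:
    def test_day_age_preset_reproduces_known_counts(self):
        specs = {cs.label: cs for cs in day_age_class_specs()}
        assert specs[14].count == 3176
        assert specs[14].present
        assert not specs[32].present and specs[32].count == 0
        present = [cs for cs in specs.values() if cs.present]
        assert len(present) == 78
        assert sum(cs.count for cs in present) == sum(DAY_AGE_COUNTS.values())
        # missing spans: 32-34, 51-67, 76, 91
        missing = {cs.label for cs in specs.values() if not cs.present}
        assert missing == set(range(32, 35)) | set(range(51, 68)) | {76, 91}

    def test_present_flag_must_match_count(self):
        with pytest.raises(ValueError):
            ClassSpec(label=5, count=0, present=True)

    def test_scaled_preset_keeps_presence_pattern(self):
        scaled = day_age_class_specs(scale=0.01)
        assert {cs.label for cs in scaled if cs.present} == set(DAY_AGE_COUNTS)
        assert all(cs.count >= 1 for cs in scaled if cs.present)


class TestGenerateDataset:
    def test_generates_exact_counts_and_skips_absent(self):
        specs = [ClassSpec(14, 40), ClassSpec(32, 0, present=False), ClassSpec(35, 7)]
        samples = generate_dataset(specs, (16, 16, 3), rng_seed=1)
        counts = _counts(samples)
        assert counts == {14: 40, 35: 7}

    def test_all_absent_is_an_error(self):
        with pytest.raises(ValueError, match="empty dataset"):
            generate_dataset([ClassSpec(1, 0, present=False)], (16, 16, 3), 0)
        with pytest.raises(ValueError, match="empty dataset"):
            generate_dataset([], (16, 16, 3), 0)

    def test_identical_seed_gives_identical_pixels(self):
        specs = [ClassSpec(10, 5)]
        a = generate_dataset(specs, (16, 16, 3), rng_seed=7)
        b = generate_dataset(specs, (16, 16, 3), rng_seed=7)
        for sa, sb in zip(a, b):
            assert (sa.pixels == sb.pixels).all()
        c = generate_dataset(specs, (16, 16, 3), rng_seed=8)
        assert any((sa.pixels != sc.pixels).any() for sa, sc in zip(a, c))

    def test_visual_signal_is_monotone_in_label(self):
        # mean brightness grows with the day-age label (disc radius grows)
        specs = [ClassSpec(l, 10) for l in (10, 40, 70, 100)]
        samples = generate_dataset(specs, (32, 32, 3), rng_seed=0)
        means = []
        for lab in (10, 40, 70, 100):
            means.append(np.mean([s.pixels.mean() for s in samples if s.label == lab]))
        assert all(a < b for a, b in zip(means, means[1:]))

    def test_pixels_in_range_and_grayscale_supported(self):
        samples = generate_dataset([ClassSpec(50, 3)], (16, 16, 1), rng_seed=0)
        for s in samples:
            assert s.pixels.shape == (16, 16, 1)
            assert 0 <= s.pixels.min() and s.pixels.max() <= 1


class TestRebalance:
    def test_counts_reach_target_and_originals_kept(self):
        samples = generate_dataset([ClassSpec(10, 3), ClassSpec(20, 10)], (16, 16, 3), 0)
        cfg = AugmentationConfig(geometric={"flip", "rotate"}, color={"noise"}, rng_seed=0)
        out = rebalance(samples, 10, cfg)
        assert _counts(out) == {10: 10, 20: 10}
        for orig, kept in zip(samples, out[: len(samples)]):
            assert (orig.pixels == kept.pixels).all()

    def test_sample_pairing_is_pixelwise_mean_of_two_originals(self):
        samples = generate_dataset([ClassSpec(10, 3)], (16, 16, 3), 0)
        cfg = AugmentationConfig(geometric=set(), color=set(),
                                 multi_sample="sample_pairing", rng_seed=3)
        out = rebalance(samples, 5, cfg)
        originals = [s.pixels for s in samples]
        for new in out[3:]:
            # brute force: the mix must equal (A+B)/2 for some pair of originals
            best = min(
                np.abs(new.pixels - (a + b) / 2.0).max()
                for i, a in enumerate(originals)
                for b in originals[i + 1:]
            )
            assert best == 0.0

    def test_already_balanced_is_identity(self):
        samples = generate_dataset([ClassSpec(10, 4), ClassSpec(20, 4)], (16, 16, 3), 0)
        cfg = AugmentationConfig(rng_seed=0)
        out = rebalance(samples, 4, cfg)
        assert len(out) == len(samples)
        for a, b in zip(samples, out):
            assert (a.pixels == b.pixels).all()

    def test_target_below_max_class_rejected(self):
        samples = generate_dataset([ClassSpec(10, 5)], (16, 16, 3), 0)
        with pytest.raises(ValueError, match="target_count"):
            rebalance(samples, 3, AugmentationConfig(rng_seed=0))

    def test_single_sample_class_falls_back_with_warning(self):
        samples = generate_dataset([ClassSpec(10, 1)], (16, 16, 3), 0)
        cfg = AugmentationConfig(geometric={"flip"}, color=set(),
                                 multi_sample="sample_pairing", rng_seed=0)
        with pytest.warns(UserWarning, match="single sample"):
            out = rebalance(samples, 3, cfg)
        assert _counts(out) == {10: 3}

    @pytest.mark.parametrize("op_family,ops", [
        ("geometric", {"flip", "rotate", "crop", "deform", "scale"}),
        ("color", {"noise", "blur", "color_shift", "erase", "fill"}),
    ])
    def test_every_augmentation_op_yields_valid_images(self, op_family, ops):
        samples = generate_dataset([ClassSpec(10, 2)], (16, 16, 3), 0)
        kwargs = {"geometric": set(), "color": set(), op_family: ops}
        out = rebalance(samples, 12, AugmentationConfig(rng_seed=1, **kwargs))
        for s in out:
            assert s.pixels.shape == (16, 16, 3)
            assert np.isfinite(s.pixels).all()
            assert 0 <= s.pixels.min() and s.pixels.max() <= 1

    def test_config_requires_one_family(self):
        with pytest.raises(ValueError):
            AugmentationConfig(geometric=set(), color=set(), multi_sample="none")


class TestSplit:
    def test_seven_three_split_on_ten_samples(self):
        samples = generate_dataset([ClassSpec(10, 10)], (16, 16, 3), 0)
        train, test = split_train_test(samples, SplitSpec(rng_seed=0))
        assert len(train) == 7 and len(test) == 3

    def test_fraction_must_be_in_open_interval(self):
        with pytest.raises(ValueError):
            SplitSpec(train_fraction=1.0)
        with pytest.raises(ValueError):
            SplitSpec(train_fraction=0.0)

    def test_stratified_counts_match_per_class_flooring(self):
        # two classes of 50 at fraction 0.7 -> each contributes 35 train / 15 test
        samples = generate_dataset([ClassSpec(10, 50), ClassSpec(20, 50)], (16, 16, 3), 0)
        train, test = split_train_test(samples, SplitSpec(rng_seed=1))
        assert _counts(train) == {10: 35, 20: 35}
        assert _counts(test) == {10: 15, 20: 15}

    def test_split_is_disjoint_cover(self):
        samples = generate_dataset([ClassSpec(10, 9), ClassSpec(20, 9)], (16, 16, 3), 0)
        train, test = split_train_test(samples, SplitSpec(rng_seed=2))
        assert len(train) + len(test) == len(samples)
        ids_train = {id(s) for s in train}
        ids_test = {id(s) for s in test}
        assert not ids_train & ids_test

    def test_single_sample_class_rejected(self):
        samples = generate_dataset([ClassSpec(10, 1), ClassSpec(20, 5)], (16, 16, 3), 0)
        with pytest.raises(ValueError, match="stratified split impossible"):
            split_train_test(samples, SplitSpec(rng_seed=0))


class TestPartition:
    def test_equal_ratios_give_equal_parts(self):
        samples = generate_dataset([ClassSpec(10, 1000)], (8, 8, 1), 0)
        parts = partition_clients(samples, SplitSpec(client_ratios=(1, 1, 1, 1, 1), rng_seed=0))
        assert [len(p) for p in parts] == [200] * 5

    def test_proportional_ratios(self):
        samples = generate_dataset([ClassSpec(10, 100)], (8, 8, 1), 0)
        parts = partition_clients(samples, SplitSpec(client_ratios=(1, 2, 3, 4), rng_seed=0))
        assert [len(p) for p in parts] == [10, 20, 30, 40]

    def test_single_client_identity(self):
        samples = generate_dataset([ClassSpec(10, 6)], (8, 8, 1), 0)
        parts = partition_clients(samples, SplitSpec(client_ratios=(1.0,), rng_seed=0))
        assert len(parts) == 1
        assert [id(s) for s in parts[0]] == [id(s) for s in samples]

    def test_disjoint_cover_per_class(self):
        samples = generate_dataset([ClassSpec(10, 33), ClassSpec(20, 17)], (8, 8, 1), 0)
        parts = partition_clients(samples, SplitSpec(client_ratios=(1, 3, 3, 3), rng_seed=5))
        assert sum(len(p) for p in parts) == 50
        seen = [id(s) for p in parts for s in p]
        assert len(seen) == len(set(seen))

    def test_more_clients_than_samples_rejected(self):
        samples = generate_dataset([ClassSpec(10, 2)], (8, 8, 1), 0)
        with pytest.raises(ValueError, match="more clients"):
            partition_clients(samples, SplitSpec(client_ratios=(1,) * 5, rng_seed=0))

    def test_partition_is_deterministic(self):
        samples = generate_dataset([ClassSpec(10, 40), ClassSpec(20, 13)], (8, 8, 1), 0)
        split = SplitSpec(client_ratios=(1, 2), rng_seed=9)
        a = partition_clients(samples, split)
        b = partition_clients(samples, split)
        assert [[id(s) for s in p] for p in a] == [[id(s) for s in p] for p in b]


class TestStack:
    def test_contiguous_reindexing_with_label_map(self):
        samples = generate_dataset(
            [ClassSpec(14, 3), ClassSpec(35, 3), ClassSpec(100, 3)], (8, 8, 1), 0)
        X, y, label_map = stack(samples)
        assert X.shape == (9, 8, 8, 1)
        assert label_map == {14: 0, 35: 1, 100: 2}
        assert set(y) == {0, 1, 2}

    def test_shared_label_map_keeps_indices_consistent(self):
        samples = generate_dataset(
            [ClassSpec(14, 3), ClassSpec(35, 3)], (8, 8, 1), 0)
        _, _, label_map = stack(samples)
        subset = [s for s in samples if s.label == 35]
        _, y_sub, _ = stack(subset, label_map)
        assert set(y_sub) == {1}


def test_uniform_specs_are_balanced():
    specs = uniform_class_specs(10, 25)
    assert len(specs) == 10
    assert all(cs.count == 25 for cs in specs)
    assert len({cs.label for cs in specs}) == 10
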