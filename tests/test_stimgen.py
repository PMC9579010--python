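"""Dot displays, timelines and stimulus pools."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage

from numerotune.stimgen import (
    BlockParams,
    LocalizerParams,
    PlacementError,
    PoolSpec,
    Timeline,
    build_block_timeline,
    build_localizer_timeline,
    default_category_pools,
    generate_dot_display,
    generate_fixture_pool,
    render_display,
)


class TestDotDisplay:
    @pytest.mark.parametrize("mode", ["constant_total_area", "constant_dot_size"])
    @pytest.mark.parametrize("n", [1, 2, 7, 20, 42])
    def test_geometry_invariants(self, mode, n):
        d = generate_dot_display(n, mode=mode, field_diameter=4.0, seed=5)
        assert len(d.centers) == d.numerosity == n
        # fully inside the circular field
        assert np.all(
            np.linalg.norm(d.centers, axis=1) + d.radii <= d.field_diameter / 2 + 1e-12
        )
        # pairwise non-overlap beyond tangency
        for i in range(n):
            for j in range(i + 1, n):
                dist = np.linalg.norm(d.centers[i] - d.centers[j])
                assert dist > d.radii[i] + d.radii[j]

    def test_constant_total_area_is_conserved(self):
        areas = [
            generate_dot_display(n, "constant_total_area", seed=n).total_area
            for n in range(1, 8)
        ]
        assert np.std(areas) / np.mean(areas) < 1e-9

    def test_constant_dot_size_keeps_radius(self):
        radii = [
            generate_dot_display(n, "constant_dot_size", seed=n).radii
            for n in range(1, 8)
        ]
        flat = np.concatenate(radii)
        assert np.std(flat) / np.mean(flat) < 1e-9

    def test_single_dot_radius_forced_by_area(self):
        a_total = 0.7
        d = generate_dot_display(1, "constant_total_area", total_area=a_total, seed=0)
        assert d.radii[0] == pytest.approx(np.sqrt(a_total / np.pi), rel=1e-12)

    def test_determinism(self):
        a = generate_dot_display(13, seed=99)
        b = generate_dot_display(13, seed=99)
        np.testing.assert_array_equal(a.centers, b.centers)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            generate_dot_display(0)
        with pytest.raises(PlacementError):
            # far too much total area for this many separated dots
            generate_dot_display(40, total_area=10.0, field_diameter=2.0, seed=0)

    @pytest.mark.parametrize("n", [1, 5, 20, 42])
    def test_rendered_display_counts_back(self, n):
        d = generate_dot_display(n, field_diameter=2.0, seed=n)
        img = render_display(d, n_pixels=512)
        _, n_regions = ndimage.label(img)
        assert n_regions == n

    @given(n=st.integers(1, 30), seed=st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_placement_property(self, n, seed):
        d = generate_dot_display(n, seed=seed)
        dists = np.linalg.norm(
            d.centers[:, None, :] - d.centers[None, :, :], axis=-1
        )
        np.fill_diagonal(dists, np.inf)
        assert dists.min() > 2 * d.radii[0]


class TestLocalizerTimeline:
    def test_epoch_duration_is_3900_ms(self, localizer_timeline):
        p = LocalizerParams()
        assert p.epoch_ms == 3900
        ev = localizer_timeline.events
        first = ev.iloc[: p.repeats_per_numerosity]
        assert (first["numerosity"] == 1).all()
        span = first["onset_ms"].iloc[-1] + p.cycle_ms - first["onset_ms"].iloc[0]
        assert span == 3900

    def test_sweep_structure(self, localizer_timeline):
        ev = localizer_timeline.events
        epochs = ev["numerosity"].to_numpy().reshape(-1, 6)
        assert (epochs == epochs[:, :1]).all(), "numerosity constant within epochs"
        order = epochs[:, 0]
        assert list(order[:7]) == [1, 2, 3, 4, 5, 6, 7], "ascending first sweep"
        assert (order[7:13] == 20).all(), "baseline follows"
        assert list(order[13:20]) == [7, 6, 5, 4, 3, 2, 1], "descending sweep"
        # four repetitions of the 26-epoch sequence
        assert len(order) == 4 * (7 + 6 + 7 + 6)

    def test_oddball_rate(self):
        tl = build_localizer_timeline(seed=3)
        rate = tl.events["attention_flag"].mean()
        assert 0.05 < rate < 0.15
        tl0 = build_localizer_timeline(LocalizerParams(oddball_rate=0.0), seed=3)
        assert not tl0.events["attention_flag"].any()

    def test_duration_exceeding_cycle_rejected(self):
        with pytest.raises(ValueError):
            build_localizer_timeline(LocalizerParams(present_ms=700, cycle_ms=650))

    def test_timeline_arithmetic_from_tsv(self, localizer_timeline, tmp_path):
        """Independent accumulation over the serialized TSV recovers the
        declared total duration."""
        path = tmp_path / "loc.tsv"
        localizer_timeline.to_tsv(path)
        raw = pd.read_csv(path, sep="\t")
        onset_ms = np.round(raw["onset"] * 1000).astype(int)
        lead_in = onset_ms.iloc[0]
        total = lead_in + len(raw) * LocalizerParams().cycle_ms
        assert total == localizer_timeline.total_duration_ms


class TestBlockTimeline:
    def test_block_spans_are_15_s(self, block_timeline):
        p = BlockParams()
        ev = block_timeline.events
        starts = ev["onset_ms"].to_numpy()[:: p.events_per_block]
        assert len(starts) == 12
        # every block occupies exactly 15 s of stimulus followed by 15 s rest
        assert (np.diff(starts) == 30000).all()
        within = ev["onset_ms"].to_numpy().reshape(12, -1)
        span = within[:, -1] + p.on_ms + p.off_ms - within[:, 0]
        assert (span == 15000).all()

    def test_category_composition(self, block_timeline):
        ev = block_timeline.events
        counts = ev.groupby("label").size()
        assert (counts == 60).all() and len(counts) == 6

    def test_total_span_by_independent_accumulation(self, block_timeline, tmp_path):
        p = BlockParams()
        path = tmp_path / "blk.tsv"
        block_timeline.to_tsv(path)
        raw = pd.read_csv(path, sep="\t")
        event_span = len(raw) * (p.on_ms + p.off_ms)
        rest_span = 12 * p.rest_ms
        assert event_span + rest_span == 360_000
        lead = int(round(raw["onset"].iloc[0] * 1000))
        assert lead + event_span + rest_span + p.final_rest_ms == (
            block_timeline.total_duration_ms
        )

    def test_no_repeats_within_block(self, block_timeline):
        ev = block_timeline.events
        for b in range(12):
            refs = ev["display_ref"].iloc[b * 30 : (b + 1) * 30]
            assert refs.is_unique

    def test_seeded_tsv_is_byte_identical(self, tmp_path):
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        build_block_timeline(seed=7).to_tsv(p1)
        build_block_timeline(seed=7).to_tsv(p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_small_pool_rejected(self):
        pools = default_category_pools(seed=0)
        pools["nat_low"] = pools["nat_low"].head(10)
        with pytest.raises(ValueError, match="nat_low"):
            build_block_timeline(seed=0, pools=pools)

    def test_tsv_round_trip(self, block_timeline, tmp_path):
        path = tmp_path / "rt.tsv"
        block_timeline.to_tsv(path)
        back = Timeline.from_tsv(path)
        pd.testing.assert_frame_equal(
            back.events, block_timeline.events, check_dtype=False
        )
        assert back.total_duration_ms == block_timeline.total_duration_ms
        assert back.design == block_timeline.design


class TestFixturePool:
    def test_default_pool_sizes(self):
        man = generate_fixture_pool(seed=0)
        sizes = man.pool_sizes()
        assert sizes == {"one": 93, "two": 95, "three": 70, "high": 70, "scenery": 61}

    def test_high_annotations_in_range(self):
        man = generate_fixture_pool(seed=1)
        high = man.records.loc[man.records["pool"] == "high", "n_objects"]
        assert high.between(10, 42).all()

    def test_empty_category_allowed(self):
        spec = PoolSpec(sizes={"one": 0, "scenery": 3})
        man = generate_fixture_pool(spec, seed=0)
        assert man.pool_sizes().get("one", 0) == 0
        assert man.pool_sizes()["scenery"] == 3

    def test_writes_pngs_and_refuses_overwrite(self, tmp_path):
        spec = PoolSpec(sizes={"one": 2, "scenery": 1}, image_px=64)
        man = generate_fixture_pool(spec, seed=0, out_dir=tmp_path)
        assert (tmp_path / "manifest.json").exists()
        assert len(list(tmp_path.glob("*.png"))) == 3
        assert (man.records["path"] != "").all()
        with pytest.raises(FileExistsError):
            generate_fixture_pool(spec, seed=0, out_dir=tmp_path)
        generate_fixture_pool(spec, seed=0, out_dir=tmp_path, overwrite=True)
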