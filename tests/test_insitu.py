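"""In situ sequencing decoding: base calls, spots, nuclei, compartments."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from circscreen.insitu import (
    DecodeParams,
    RcpSignal,
    assign_compartment,
    assign_compartments,
    call_base,
    decode_rcp,
    decode_stack,
    detect_spots,
    extract_intensities,
    filter_and_assign,
    nuclear_ratio,
    register_translation,
    segment_nuclei,
)
from circscreen.panel import Codebook
from circscreen.simulate import SimConfig, simulate_insitu_stack


class TestCallBase:
    @pytest.mark.parametrize(
        "vec,base,quality",
        [
            ((10, 0, 0, 0), "A", 1.0),
            ((1, 1, 1, 1), "A", 0.25),   # tie broken by channel order
            ((6, 2, 1, 1), "A", 0.6),
            ((0, 0, 0, 5), "T", 1.0),
            ((0, 3, 3, 0), "C", 0.5),    # tie C before G
        ],
    )
    def test_examples(self, vec, base, quality):
        assert call_base(vec) == (base, pytest.approx(quality))

    def test_all_zero_flagged(self):
        assert call_base((0, 0, 0, 0)) == ("N", 0.25)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            call_base((1, -1, 0, 0))

    @given(
        st.lists(
            st.floats(min_value=0, max_value=1e6, allow_nan=False),
            min_size=4, max_size=4,
        ).filter(lambda v: sum(v) > 0)
    )
    def test_quality_bounds(self, vec):
        _, q = call_base(vec)
        assert 0.25 <= q <= 1.0
        positive = sum(1 for x in vec if x > 0)
        if positive == 1:
            assert q == 1.0
        if q == 1.0:
            assert positive == 1
        if len(set(vec)) == 1:
            assert q == 0.25

    @given(
        st.lists(
            st.floats(min_value=0.01, max_value=1e3, allow_nan=False),
            min_size=4, max_size=4,
        ),
        st.floats(min_value=0.01, max_value=100),
    )
    def test_scaling_invariance(self, vec, scale):
        base, q = call_base(vec)
        base2, q2 = call_base([x * scale for x in vec])
        assert base == base2
        assert q == pytest.approx(q2)


def _one_hot(base, amp=10.0):
    return tuple(amp if b == base else 0.0 for b in "ACGT")


class TestDecodeRcp:
    def test_noise_free_sequence(self):
        s = RcpSignal(0, 1, 1, tuple(_one_hot(b) for b in "CGTA"))
        out = decode_rcp(s)
        assert out.sequence == "CGTA" and out.quality == 1.0

    def test_min_rule_uniform_cycle(self):
        cycles = tuple(_one_hot(b) for b in "CGT") + ((2, 2, 2, 2),)
        out = decode_rcp(RcpSignal(0, 1, 1, cycles))
        assert out.quality == 0.25

    def test_quality_is_minimum(self):
        cycles = (
            (9, 1, 0, 0),   # 0.9
            (6, 4, 0, 0),   # 0.6
            (8, 2, 0, 0),   # 0.8
            (7, 3, 0, 0),   # 0.7
        )
        out = decode_rcp(RcpSignal(0, 1, 1, cycles))
        assert out.quality == pytest.approx(0.6)
        assert out.qualities == pytest.approx((0.9, 0.6, 0.8, 0.7))

    def test_missing_cycle_is_error(self):
        with pytest.raises(ValueError, match="cycles"):
            decode_rcp(RcpSignal(0, 1, 1, (_one_hot("A"),)))


class TestFilterAndAssign:
    book = Codebook()
    book["ACGT"] = "geneX"
    book["TGCA"] = "geneY"

    def _signal(self, seq, quality):
        vecs = []
        for b in seq:
            main = quality * 10
            rest = (10 - main) / 3
            vec = [rest] * 4
            vec["ACGT".index(b)] = main
            vecs.append(tuple(vec))
        return decode_rcp(RcpSignal(0, 1, 1, tuple(vecs)))

    def test_boundary_quality_dropped(self):
        params = DecodeParams(quality_threshold=0.40)
        low = self._signal("ACGT", 0.39)
        out = filter_and_assign([low], self.book, params)
        assert out.n_rejected_quality == 1 and out.counts["geneX"] == 0

    def test_exact_match_assigned(self):
        out = filter_and_assign([self._signal("ACGT", 0.9)], self.book)
        assert out.counts == {"geneX": 1, "geneY": 0}

    def test_unexpected_tallied(self):
        out = filter_and_assign([self._signal("AAAA", 0.9)], self.book)
        assert out.n_unexpected == 1 and out.unexpected_sequences["AAAA"] == 1

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(0)
        signals = [
            self._signal("ACGT", q) for q in rng.uniform(0.3, 1.0, 200)
        ]
        prev = None
        for thr in (0.40, 0.45, 0.50, 0.55):
            out = filter_and_assign(
                signals, self.book, DecodeParams(quality_threshold=thr)
            )
            if prev is not None:
                assert out.counts["geneX"] <= prev
            prev = out.counts["geneX"]


def _blob_image(centers, size=128, amp=100.0, sigma=1.5):
    img = np.zeros((size, size))
    yy, xx = np.mgrid[0:size, 0:size]
    for (y, x) in centers:
        img += amp * np.exp(-((yy - y) ** 2 + (xx - x) ** 2) / (2 * sigma ** 2))
    return img


class TestDetectSpots:
    def test_blank_image(self):
        assert detect_spots(np.zeros((64, 64))) == []

    def test_non_2d_rejected(self):
        with pytest.raises(ValueError):
            detect_spots(np.zeros((4, 4, 4)))

    def test_fifty_planted_spots_recovered_within_1px(self):
        rng = np.random.default_rng(7)
        centers = []
        while len(centers) < 50:
            y, x = rng.integers(10, 246, 2)
            if all((y - a) ** 2 + (x - b) ** 2 > 144 for a, b in centers):
                centers.append((int(y), int(x)))
        img = _blob_image(centers, size=256)
        found = detect_spots(img)
        assert len(found) == 50
        for fx, fy in found:
            d = min(math.hypot(fy - y, fx - x) for y, x in centers)
            assert d <= 1.0

    def test_touching_blobs_split_by_watershed(self):
        img = _blob_image([(60, 60), (60, 67)], size=128)
        found = detect_spots(img)
        assert len(found) == 2


class TestExtractIntensities:
    def test_window_mean_at_planted_spot(self):
        stack = np.zeros((1, 4, 32, 32))
        stack[0, 2, 15, 15] = 9.0  # G channel
        (sig,) = extract_intensities(stack, [(15.0, 15.0)],
                                     DecodeParams(n_cycles=1))
        assert sig.intensities[0][2] == pytest.approx(1.0)  # 9 / 9 pixels
        assert sig.intensities[0][0] == 0.0

    def test_jitter_tolerance(self):
        stack = np.zeros((1, 4, 32, 32))
        stack[0, 1, 15, 15] = 9.0
        (a,) = extract_intensities(stack, [(15.6, 14.5)], DecodeParams(n_cycles=1))
        assert a.intensities[0][1] > 0


class TestSegmentNuclei:
    def test_blank_image_empty_mask(self):
        mask = segment_nuclei(np.zeros((64, 64)))
        assert mask.shape == (64, 64) and mask.max() == 0

    def test_disjoint_disks_labeled_with_overlap(self):
        rng = np.random.default_rng(8)
        size = 512
        yy, xx = np.mgrid[0:size, 0:size]
        centers = []
        while len(centers) < 20:
            y, x = rng.integers(30, size - 30, 2)
            if all((y - a) ** 2 + (x - b) ** 2 > (2 * 15 + 8) ** 2 for a, b in centers):
                centers.append((int(y), int(x)))
        img = np.zeros((size, size))
        truth = np.zeros((size, size), dtype=int)
        for k, (y, x) in enumerate(centers, start=1):
            disk = (yy - y) ** 2 + (xx - x) ** 2 <= 15 ** 2
            img[disk] = 100.0
            truth[disk] = k
        mask = segment_nuclei(img)
        assert mask.max() == 20
        for k in range(1, 21):
            planted = truth == k
            labels, counts = np.unique(mask[planted], return_counts=True)
            best = labels[np.argmax(counts)]
            overlap = (mask[planted] == best).mean()
            assert best > 0 and overlap >= 0.9

    def test_two_overlapping_disks_split(self):
        size = 128
        yy, xx = np.mgrid[0:size, 0:size]
        img = np.zeros((size, size))
        for (y, x) in [(60, 50), (60, 78)]:
            img[(yy - y) ** 2 + (xx - x) ** 2 <= 18 ** 2] = 100.0
        mask = segment_nuclei(img)
        assert mask.max() == 2


class TestCompartment:
    mask = np.zeros((10, 10), dtype=int)
    mask[2:5, 2:5] = 3

    def test_inside_nucleus(self):
        s = RcpSignal(0, x=3.0, y=3.0, intensities=())
        assert assign_compartment(s, self.mask) == "nuclear"

    def test_outside_nucleus(self):
        s = RcpSignal(0, x=8.0, y=8.0, intensities=())
        assert assign_compartment(s, self.mask) == "cytoplasmic"

    def test_boundary_pixel_is_nuclear(self):
        s = RcpSignal(0, x=4.0, y=4.0, intensities=())
        assert assign_compartment(s, self.mask) == "nuclear"

    def test_out_of_bounds_unassigned(self):
        s = RcpSignal(0, x=40.0, y=3.0, intensities=())
        assert assign_compartment(s, self.mask) == "unassigned"


class TestNuclearRatio:
    def _signals(self, target, n_nuc, n_cyt):
        out = []
        for i in range(n_nuc + n_cyt):
            out.append(
                RcpSignal(
                    i, 0, 0, (), target_id=target,
                    compartment="nuclear" if i < n_nuc else "cytoplasmic",
                )
            )
        return out

    def test_simple_fraction(self):
        ratios = nuclear_ratio(self._signals("t", 3, 7))
        assert ratios["t"] == pytest.approx(0.3)

    def test_all_nuclear_control(self):
        # the expectation for a nuclear-retained transcript such as MALAT1
        assert nuclear_ratio(self._signals("malat1", 10, 0))["malat1"] == 1.0

    def test_zero_signal_target_excluded(self):
        assert "ghost" not in nuclear_ratio(self._signals("t", 1, 1))

    def test_planted_fraction_recovered_within_3_se(self):
        rng = np.random.default_rng(9)
        p, n = 0.2, 500
        draws = rng.random(n) < p
        signals = [
            RcpSignal(
                i, 0, 0, (), target_id="t",
                compartment="nuclear" if d else "cytoplasmic",
            )
            for i, d in enumerate(draws)
        ]
        est = nuclear_ratio(signals)["t"]
        se = math.sqrt(p * (1 - p) / n)
        assert abs(est - p) <= 3 * se


class TestRegistration:
    def test_translation_recovered(self):
        img = _blob_image([(40, 40), (80, 30), (20, 90)], size=128)
        moved = np.roll(np.roll(img, 3, axis=0), -2, axis=1)
        shifted, shift = register_translation(img, moved)
        assert shift == (-3.0, 2.0)
        assert np.allclose(shifted[10:-10, 10:-10], img[10:-10, 10:-10], atol=1e-6)


class TestEndToEndStack:
    def test_noise_free_stack_decodes_exactly(self, toy_panel):
        from circscreen.panel import assign_barcodes

        book = assign_barcodes([f"g{i}" for i in range(6)], seed=4)
        counts = {f"g{i}": 30 for i in range(6)}
        fracs = {f"g{i}": 0.25 * (i % 4) for i in range(6)}
        cfg = SimConfig(seed=21, channel_noise=0.0, spots_per_image=180)
        stack, dapi, truth = simulate_insitu_stack(book, counts, fracs, cfg)
        result, ratios, _ = decode_stack(stack, dapi, book)
        assert len(result.signals) == len(truth)
        assert result.n_unexpected == 0 and result.n_rejected_quality == 0
        planted_counts = truth["target_id"].value_counts().to_dict()
        assert result.counts == planted_counts
        planted_ratios = (
            truth.assign(nuc=truth["compartment"] == "nuclear")
            .groupby("target_id")["nuc"].mean().to_dict()
        )
        for t, r in planted_ratios.items():
            assert ratios[t] == pytest.approx(r)
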