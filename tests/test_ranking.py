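"""Tests for crop geometry, scoring, selection, and the mock embedder."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from fazseg import (
    MockEmbeddingBackend,
    OctaImage,
    SemanticPrompt,
    crop_for_embedding,
    geometric_score,
    iou,
    rank_and_select,
    rank_proposals,
    rerank,
    semantic_score,
)
from fazseg.errors import ConfigurationError, SelectionError
from fazseg.prompting import PromptPoint, place_prompt_point
from fazseg.proposals import MaskProposal, propose_fallback
from fazseg.ranking import DEFAULT_POSITIVE_PROMPTS, area_factor, centrality_factor


def block_mask(shape, r0, c0, h, w):
    m = np.zeros(shape, dtype=bool)
    m[r0 : r0 + h, c0 : c0 + w] = True
    return m


def proposal(mask, score=0.5):
    return MaskProposal(mask=mask, generator_score=score, source="fallback")


class TestCrop:
    def test_full_frame_mask_gives_whole_image(self, clean_sample):
        mask = np.ones(clean_sample.image.shape, dtype=bool)
        crop = crop_for_embedding(clean_sample.image, mask, margin=0.25)
        assert crop.pixels.shape == clean_sample.image.shape
        assert (crop.row_offset, crop.col_offset) == (0, 0)

    def test_zero_margin_is_tight_bbox(self):
        img = OctaImage(pixels=np.zeros((8, 8), dtype=np.uint8))
        crop = crop_for_embedding(img, block_mask((8, 8), 3, 4, 2, 2), margin=0.0)
        assert crop.pixels.shape == (2, 2)
        assert (crop.row_offset, crop.col_offset) == (3, 4)

    def test_quarter_margin_expands_ten_to_fifteen(self):
        img = OctaImage(pixels=np.zeros((40, 40), dtype=np.uint8))
        crop = crop_for_embedding(img, block_mask((40, 40), 15, 15, 10, 10), margin=0.25)
        assert crop.pixels.shape == (15, 15)


class TestSemanticScore:
    def _unit(self, v):
        v = np.asarray(v, dtype=float)
        return v / np.linalg.norm(v)

    def test_identical_vectors_score_one(self):
        v = self._unit([1, 2, 3])
        assert semantic_score(v, [SemanticPrompt("faz")], [v]) == pytest.approx(1.0)

    def test_orthogonal_vectors_score_zero(self):
        a = self._unit([1, 0, 0])
        b = self._unit([0, 1, 0])
        assert semantic_score(a, [SemanticPrompt("faz")], [b]) == pytest.approx(0.0)

    def test_positive_minus_negative_spans_two(self):
        v = self._unit([1, 1, 0])
        prompts = [SemanticPrompt("faz"), SemanticPrompt("vessel", "negative")]
        assert semantic_score(v, prompts, [v, -v]) == pytest.approx(2.0)

    def test_no_positive_prompts_is_configuration_error(self):
        v = self._unit([1, 0])
        with pytest.raises(ConfigurationError):
            semantic_score(v, [SemanticPrompt("x", "negative")], [v])


class TestGeometricScore:
    def test_optimal_mask_scores_one(self):
        # centred square at exactly the target area fraction
        shape = (100, 100)
        side = int(np.sqrt(0.015 * 100 * 100))  # ~12
        target = side * side / (100 * 100)
        r0 = (100 - side) // 2
        mask = block_mask(shape, r0, r0, side, side)
        prompt = PromptPoint(r0 + side // 2, r0 + side // 2)
        score = geometric_score(mask, prompt, shape, target_area_fraction=target)
        # centroid may sit half a pixel off centre for even sides
        assert score == pytest.approx(1.0, abs=0.02)

    def test_prompt_outside_mask_scores_zero(self):
        mask = block_mask((50, 50), 5, 5, 4, 4)
        assert geometric_score(mask, PromptPoint(40, 40), (50, 50)) == 0.0

    def test_centrality_displaced_by_scale_is_inverse_e(self):
        shape = (100, 100)
        d = np.hypot(100, 100) / 4.0
        centre = ((100 - 1) / 2.0, (100 - 1) / 2.0)
        assert centrality_factor((centre[0] + d, centre[1]), shape) == pytest.approx(np.exp(-1))

    def test_area_factor_triangle(self):
        assert area_factor(0.015) == pytest.approx(1.0)
        assert area_factor(0.0075) == pytest.approx(0.5)
        assert area_factor(0.25) == 0.0
        assert area_factor(0.0) == 0.0


class TestSelection:
    def test_single_proposal_selected(self):
        p = proposal(block_mask((20, 20), 8, 8, 4, 4))
        sel = rank_and_select([p], [0.3], [0.5])
        assert sel.index == 0
        assert sel.semantic_norm == 1.0

    def test_degenerate_weights_reduce_to_generator_argmax(self):
        masks = [block_mask((20, 20), 8, 8, 4, 4), block_mask((20, 20), 2, 2, 4, 4)]
        props = [proposal(masks[0], 0.2), proposal(masks[1], 0.9)]
        sel = rank_and_select(props, [0.9, 0.1], [0.9, 0.1], weights=(0, 0, 1))
        assert sel.index == 1

    def test_centred_beats_peripheral_when_other_scores_tie(self):
        shape = (64, 64)
        centred = block_mask(shape, 28, 28, 8, 8)
        peripheral = block_mask(shape, 0, 0, 8, 8)
        props = [proposal(peripheral, 0.5), proposal(centred, 0.5)]
        geo = [
            geometric_score(peripheral, PromptPoint(2, 2), shape),
            geometric_score(centred, PromptPoint(32, 32), shape),
        ]
        sel = rank_and_select(props, [0.4, 0.4], geo)
        assert sel.index == 1

    def test_empty_proposal_list_raises_selection_error(self):
        with pytest.raises(SelectionError):
            rank_and_select([], [], [])

    def test_order_invariance_up_to_tie_break(self):
        rng = np.random.default_rng(0)
        masks = [block_mask((32, 32), 4 * i + 2, 4 * i + 2, 5, 5) for i in range(4)]
        props = [proposal(m, s) for m, s in zip(masks, rng.uniform(0.2, 0.9, 4))]
        sem = list(rng.uniform(-1, 1, 4))
        geo = list(rng.uniform(0, 1, 4))
        sel = rank_and_select(props, sem, geo)
        perm = [2, 0, 3, 1]
        sel_p = rank_and_select([props[i] for i in perm], [sem[i] for i in perm],
                                [geo[i] for i in perm])
        assert np.array_equal(sel.proposal.mask, sel_p.proposal.mask)

    @given(
        st.lists(
            st.tuples(
                st.floats(-1, 1), st.floats(0, 1), st.floats(0, 1), st.floats(0, 0.5)
            ),
            min_size=2,
            max_size=6,
        ),
        st.integers(0, 5),
        st.floats(0.01, 0.5),
    )
    def test_total_score_monotone_in_each_component(self, tuples, idx, bump):
        """Raising any one component score never lowers a total score."""
        idx = idx % len(tuples)
        masks = [block_mask((16, 16), 2, 2, 3, 3)] * len(tuples)
        props = [proposal(m, g) for m, (_, _, g, _) in zip(masks, tuples)]
        sem = [t[0] for t in tuples]
        geo = [t[1] for t in tuples]
        base = rank_proposals(props, sem, geo)
        geo2 = list(geo)
        geo2[idx] = min(1.0, geo2[idx] + bump)
        bumped = rank_proposals(props, sem, geo2)
        assert bumped[idx].total_score >= base[idx].total_score - 1e-12


class TestMockEmbedder:
    def test_image_embedding_deterministic_and_unit(self, clean_sample):
        mb = MockEmbeddingBackend()
        crop = crop_for_embedding(clean_sample.image, clean_sample.gt_mask)
        a, b = mb.embed_image(crop), mb.embed_image(crop)
        assert np.array_equal(a, b)
        assert np.linalg.norm(a) == pytest.approx(1.0, abs=1e-6)

    def test_text_table_round_trip(self):
        mb = MockEmbeddingBackend()
        for text in mb.TEXT_TABLE:
            v = mb.embed_text(text)
            assert np.linalg.norm(v) == pytest.approx(1.0, abs=1e-6)
            assert np.array_equal(v, mb.embed_text(text))

    def test_unknown_text_is_configuration_error(self):
        with pytest.raises(ConfigurationError):
            MockEmbeddingBackend().embed_text("unrelated phrase")

    def test_dark_centred_crop_beats_bright_crop_on_faz_phrase(self):
        mb = MockEmbeddingBackend()
        dark = np.full((40, 40), 110, dtype=np.uint8)
        dark[12:28, 12:28] = 25
        bright = np.full((40, 40), 180, dtype=np.uint8)
        pos = mb.embed_text(DEFAULT_POSITIVE_PROMPTS[0])
        assert float(mb.embed_image(dark) @ pos) > float(mb.embed_image(bright) @ pos)


class TestPipelineProperty:
    def test_selected_mask_is_argmax_iou_in_ninety_percent(self, clean_cohort):
        """On the clean cohort the re-ranker recovers the best proposal."""
        mb = MockEmbeddingBackend()
        agree = 0
        for s in clean_cohort:
            prompt = place_prompt_point(s.gt_mask)
            props = propose_fallback(s.image, prompt)
            assert props
            selected, _ = rerank(s.image, props, prompt, mb)
            best = max(range(len(props)), key=lambda i: iou(props[i].mask, s.gt_mask))
            agree += selected.index == best
        assert agree >= 0.9 * len(clean_cohort)
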