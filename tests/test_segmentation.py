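"""Colour conversion, clustering, compartment assignment and primary-cell
selection, scored against generator ground truth."""

import numpy as np
import pytest

from cytomorph.errors import DegenerateTileError, ParameterError
from cytomorph.segmentation import (SegmentationParams, assign_compartments,
                                    kmeans_segment, refine_masks,
                                    rgb_to_cielab, segment_tile,
                                    select_primary_cell)
from cytomorph.synthetic import StainProfile, generate_cell_tile


def flat_tile(color):
    return np.tile(np.array(color, dtype=np.uint8), (256, 256, 1))


class TestRgbToCielab:
    def test_white_point(self):
        lab = rgb_to_cielab(flat_tile((255, 255, 255)))
        assert lab.L[0, 0] == pytest.approx(100, abs=0.01)
        assert abs(lab.a[0, 0]) < 0.5 and abs(lab.b[0, 0]) < 0.5

    def test_black_point(self):
        assert rgb_to_cielab(flat_tile((0, 0, 0))).L[0, 0] == 0

    def test_neutral_gray(self):
        lab = rgb_to_cielab(flat_tile((119, 119, 119)))
        assert 0 < lab.L[0, 0] < 100
        assert abs(lab.a[0, 0]) < 0.5 and abs(lab.b[0, 0]) < 0.5


class TestKmeansSegment:
    def _three_color_tile(self):
        stain = StainProfile()
        img = flat_tile(stain.background_color)
        img[64:128, :] = np.array(stain.cytoplasm_color, dtype=np.uint8)
        img[128:192, :] = np.array(stain.nucleus_color, dtype=np.uint8)
        return img

    def test_exact_three_color_recovery(self):
        img = self._three_color_tile()
        labels, centers = kmeans_segment(rgb_to_cielab(img))
        mapping = assign_compartments(labels, centers)
        assert (labels[128:192] == mapping["nucleus"]).all()
        assert (labels[64:128] == mapping["cytoplasm"]).all()
        assert (labels[:64] == mapping["background"]).all()

    def test_deterministic(self):
        img, _ = generate_cell_tile(0.3, rng_seed=4)
        lab = rgb_to_cielab(img)
        l1, c1 = kmeans_segment(lab, rng_seed=0)
        l2, c2 = kmeans_segment(lab, rng_seed=0)
        assert np.array_equal(l1, l2)
        assert np.array_equal(c1, c2)

    def test_noisy_tile_pixel_agreement(self):
        # label agreement with generator truth on noisy tiles >= 98%
        for seed in (0, 1, 2):
            img, truth = generate_cell_tile(0.35, rng_seed=seed)
            labels, centers = kmeans_segment(rgb_to_cielab(img, 1.0))
            mapping = assign_compartments(labels, centers)
            truth_map = np.zeros_like(labels)
            truth_map[truth.cytoplasm_mask] = 1
            truth_map[truth.nucleus_mask] = 2
            pred = np.zeros_like(labels)
            pred[labels == mapping["cytoplasm"]] = 1
            pred[labels == mapping["nucleus"]] = 2
            assert (pred == truth_map).mean() >= 0.98

    def test_single_color_tile_degenerate(self):
        with pytest.raises(DegenerateTileError):
            kmeans_segment(rgb_to_cielab(flat_tile((200, 200, 200))))


class TestAssignCompartments:
    def test_lightness_ordering(self):
        centers = np.array([[70.0, 5, 5], [30.0, 20, -30], [95.0, 0, 1]])
        m = assign_compartments(None, centers)
        assert m == {"nucleus": 1, "cytoplasm": 0, "background": 2}

    def test_chroma_tie_break(self):
        centers = np.array([[50.0, 40, 0], [50.0, 5, 0], [95.0, 0, 0]])
        m = assign_compartments(None, centers)
        assert m["nucleus"] == 0  # higher chroma wins the dark slot

    def test_wrong_k_rejected(self):
        with pytest.raises(ParameterError, match="k = 3"):
            assign_compartments(None, np.zeros((2, 3)))


class TestRefineMasks:
    def test_isolated_pixel_removed(self):
        nuc = np.zeros((64, 64), bool)
        nuc[10, 10] = True
        out, _ = refine_masks(nuc, np.zeros_like(nuc))
        assert not out.any()

    def test_interior_hole_filled(self):
        nuc = np.zeros((64, 64), bool)
        nuc[10:40, 10:40] = True
        nuc[20:25, 20:25] = False
        out, _ = refine_masks(nuc, np.zeros_like(nuc))
        assert out[22, 22]

    def test_refined_masks_disjoint(self):
        rng = np.random.default_rng(0)
        nuc = rng.random((64, 64)) > 0.5
        cyt = rng.random((64, 64)) > 0.5
        n, c = refine_masks(nuc, cyt)
        assert not (n & c).any()

    def test_clean_fixture_changes_few_pixels(self, clean_batch):
        # refinement is a clean-up step: on clean tiles it must not
        # rewrite the segmentation (< 2% of pixels per compartment pair)
        from cytomorph.segmentation import rgb_to_cielab, kmeans_segment
        img, _, _, _ = clean_batch[0]
        labels, centers = kmeans_segment(rgb_to_cielab(img))
        mapping = assign_compartments(labels, centers)
        nuc = labels == mapping["nucleus"]
        cyt = labels == mapping["cytoplasm"]
        rn, rc = refine_masks(nuc, cyt)
        changed = (rn ^ nuc).sum() + (rc ^ cyt).sum()
        assert changed / nuc.size < 0.02


class TestSelectPrimaryCell:
    def test_empty_masks_signal_acellular(self):
        seg = select_primary_cell(np.zeros((64, 64), bool),
                                  np.zeros((64, 64), bool))
        assert seg.nucleus_count == 0 and seg.a_nucleus == 0

    def test_two_nuclei_counted(self):
        nuc = np.zeros((256, 256), bool)
        nuc[20:50, 20:50] = True
        nuc[100:140, 100:140] = True
        cyt = np.zeros_like(nuc)
        seg = select_primary_cell(nuc, cyt)
        assert seg.nucleus_count == 2
        assert seg.a_nucleus == 40 * 40  # largest component selected

    def test_cytoplasm_from_same_connected_region(self):
        nuc = np.zeros((256, 256), bool)
        nuc[30:60, 30:60] = True
        cyt = np.zeros_like(nuc)
        cyt[20:70, 20:70] = True          # ring around the nucleus
        cyt[150:170, 150:170] = True      # disconnected distant patch
        cyt &= ~nuc
        seg = select_primary_cell(nuc, cyt)
        assert seg.a_cytoplasm == 50 * 50 - 30 * 30
        assert not seg.cytoplasm_mask[150:170, 150:170].any()

    def test_sub_minimal_components_reported(self):
        nuc = np.zeros((256, 256), bool)
        nuc[10:14, 10:14] = True  # 16 px speck
        seg = select_primary_cell(nuc, np.zeros_like(nuc))
        assert seg.nucleus_count == 0
        assert seg.small_nucleus_components == 1


class TestEndToEnd:
    def test_segmentation_deterministic(self):
        img, _ = generate_cell_tile(0.3, rng_seed=8)
        s1 = segment_tile(img)
        s2 = segment_tile(img)
        assert np.array_equal(s1.nucleus_mask, s2.nucleus_mask)
        assert s1.a_cytoplasm == s2.a_cytoplasm

    def test_areas_match_truth_within_tolerance(self, clean_batch):
        rel = []
        for _, truth, seg, rep in clean_batch[:30]:
            if not rep.accepted:
                continue
            rel.append(abs(seg.a_nucleus - truth.nucleus_mask.sum())
                       / truth.nucleus_mask.sum())
            rel.append(abs(seg.a_cytoplasm - truth.cytoplasm_mask.sum())
                       / truth.cytoplasm_mask.sum())
        assert np.median(rel) < 0.05

    def test_masks_disjoint_and_areas_consistent(self, clean_batch):
        for _, _, seg, _ in clean_batch[:20]:
            assert not (seg.nucleus_mask & seg.cytoplasm_mask).any()
            assert seg.a_nucleus == seg.nucleus_mask.sum()
            assert seg.a_cytoplasm == seg.cytoplasm_mask.sum()
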