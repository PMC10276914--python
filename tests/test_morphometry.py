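"""Morphometry tests: nucleus segmentation/classification, condensed-nuclei
accumulation scoring, branching recovery, and cell-area arithmetic."""

import numpy as np
import pytest

from tauscope import defaults, morphometry as M, synthetic as S
from tauscope.primitives import BinaryMask


def _segment_and_classify(stack):
    nuclei = M.segment_nuclei(stack.plane("nuclei"))
    return M.classify_nucleus_state(nuclei)


class TestNuclei:
    def test_counts_match_ledger(self, clean_inclusion):
        _, stack, truth = clean_inclusion
        nuclei = _segment_and_classify(stack)
        assert len(nuclei) == len(truth.nuclei)
        assert sum(1 for n in nuclei if n.state == "live") == truth.n_live()
        assert sum(1 for n in nuclei if n.state == "condensed") == truth.n_condensed()

    def test_empty_channel_gives_no_records(self):
        assert M.segment_nuclei(np.zeros((64, 64))) == []

    def test_generator_default_renderings_classify_correctly(self, clean_inclusion):
        _, stack, truth = clean_inclusion
        nuclei = _segment_and_classify(stack)
        truth_states = {(round(t.centroid[0]), round(t.centroid[1])): t.state
                        for t in truth.nuclei}
        for n in nuclei:
            key = (round(n.centroid[0]), round(n.centroid[1]))
            assert truth_states[key] == n.state

    def test_boundary_is_inclusive_for_condensed(self):
        rec = M.NucleusRecord(1, (0, 0), defaults.CONDENSED_MAX_AREA_PX,
                              defaults.CONDENSED_MIN_INTENSITY)
        M.classify_nucleus_state([rec])
        assert rec.state == "condensed"
        rec2 = M.NucleusRecord(2, (0, 0), defaults.CONDENSED_MAX_AREA_PX + 1,
                               defaults.CONDENSED_MIN_INTENSITY)
        M.classify_nucleus_state([rec2])
        assert rec2.state == "live"

    def test_fused_nuclei_merge_as_ledger_predicts(self):
        spec = S.InclusionFieldSpec(seed=6, noise_sd=0.0, n_condensed_nuclei=0,
                                    n_fused_nucleus_pairs=1)
        stack, truth = S.generate_inclusion_field(spec)
        nuclei = M.segment_nuclei(stack.plane("nuclei"))
        assert len(nuclei) == truth.expected_nucleus_components()
        assert len(nuclei) == len(truth.nuclei) - 1


class TestAccumulation:
    def test_forced_arithmetic_example(self):
        # 3 astrocytes containing {0, 2, 5} condensed nuclei
        labels = np.zeros((10, 30), dtype=np.int32)
        labels[:, :10], labels[:, 10:20], labels[:, 20:] = 1, 2, 3
        nuclei = [M.NucleusRecord(i, (5, 5 + 10 * i), 150, 100.0, state="live")
                  for i in range(3)]
        k = 10
        for j, count in enumerate([0, 2, 5]):
            for _ in range(count):
                nuclei.append(M.NucleusRecord(k, (2, 2 + 10 * j), 40, 300.0,
                                              state="condensed"))
                k += 1
        acc = M.score_accumulation(nuclei, labels)
        assert acc.n_condensed_total == 7
        assert acc.n_live_astrocytes == 3
        assert acc.condensed_per_live == pytest.approx(7 / 3)
        assert acc.bin_fractions == pytest.approx(
            {"0": 1 / 3, "1-2": 1 / 3, "3-4": 0.0, "5+": 1 / 3})

    def test_no_condensed_nuclei(self):
        labels = np.ones((5, 5), dtype=np.int32)
        nuclei = [M.NucleusRecord(1, (2, 2), 150, 100.0, state="live")]
        acc = M.score_accumulation(nuclei, labels)
        assert acc.bin_fractions == {"0": 1.0, "1-2": 0.0, "3-4": 0.0, "5+": 0.0}
        assert acc.condensed_per_live == 0.0

    def test_zero_live_astrocytes_flagged(self):
        labels = np.zeros((5, 5), dtype=np.int32)
        nuclei = [M.NucleusRecord(1, (2, 2), 40, 300.0, state="condensed")]
        acc = M.score_accumulation(nuclei, labels)
        assert np.isnan(acc.condensed_per_live)
        assert acc.flags

    def test_random_assignments_match_brute_force(self, rng):
        for _ in range(20):
            n_astro = int(rng.integers(2, 8))
            labels = rng.integers(0, n_astro + 1, size=(40, 40)).astype(np.int32)
            nuclei = []
            # one live nucleus per astrocyte at an arbitrary labeled pixel
            for a in range(1, n_astro + 1):
                pos = np.argwhere(labels == a)
                if len(pos) == 0:
                    continue
                r, c = pos[rng.integers(len(pos))]
                nuclei.append(M.NucleusRecord(a, (float(r), float(c)), 150, 100.0,
                                              state="live"))
            live_ids = {n.label for n in nuclei}
            tally = {a: 0 for a in live_ids}
            unassigned = 0
            for i in range(int(rng.integers(0, 15))):
                r, c = int(rng.integers(40)), int(rng.integers(40))
                nuclei.append(M.NucleusRecord(100 + i, (r, c), 40, 300.0,
                                              state="condensed"))
                lab = int(labels[r, c])
                if lab in tally:
                    tally[lab] += 1
                else:
                    unassigned += 1
            acc = M.score_accumulation(nuclei, labels)
            assert acc.n_unassigned_condensed == unassigned
            if acc.n_live_astrocytes:
                assert sum(acc.bin_fractions.values()) == pytest.approx(1.0)
                want = {"0": 0, "1-2": 0, "3-4": 0, "5+": 0}
                for v in tally.values():
                    want[M._bin_name(v)] += 1
                got = {b: round(f * acc.n_live_astrocytes)
                       for b, f in acc.bin_fractions.items()}
                assert got == want

    def test_image_pipeline_matches_ledger_hosts(self, clean_inclusion):
        _, stack, truth = clean_inclusion
        nuclei = _segment_and_classify(stack)
        live = [n.centroid for n in nuclei if n.state == "live"]
        territories = M.astro_territories(truth.roi_mask, live)
        acc = M.score_accumulation(nuclei, territories)
        assert acc.n_condensed_total == truth.n_condensed()
        assert acc.n_live_astrocytes == truth.n_live()
        # brute-force per-host tally from the ledger
        tally: dict[int, int] = {}
        for t in truth.nuclei:
            if t.state == "condensed":
                tally[t.host_cell_id] = tally.get(t.host_cell_id, 0) + 1
        want = {"0": truth.n_live() - len(tally), "1-2": 0, "3-4": 0, "5+": 0}
        for v in tally.values():
            want[M._bin_name(v)] += 1
        got = {b: round(f * acc.n_live_astrocytes)
               for b, f in acc.bin_fractions.items()}
        assert got == want


class TestBranching:
    def test_y_shaped_cell_has_one_branch_point(self):
        spec = S.BranchFieldSpec(seed=3, n_cells=1, branch_points_per_cell=(1,),
                                 noise_sd=0.0)
        stack, _ = S.generate_branch_field(spec)
        res = M.measure_branching(stack.plane("gfap"), stack.plane("nuclei"))
        assert res.n_cells == 1
        assert res.branch_points_per_cell == 1.0

    def test_straight_stroke_cells_have_zero(self):
        spec = S.BranchFieldSpec(seed=4, n_cells=2, branch_points_per_cell=(0, 0),
                                 noise_sd=0.0)
        stack, _ = S.generate_branch_field(spec)
        res = M.measure_branching(stack.plane("gfap"), stack.plane("nuclei"))
        assert res.total_branch_points == 0
        assert res.branch_points_per_cell == 0.0

    def test_per_cell_breakdown_and_mean(self):
        spec = S.BranchFieldSpec(seed=5, n_cells=2, branch_points_per_cell=(2, 4),
                                 stroke_width_px=3, noise_sd=0.0)
        stack, _ = S.generate_branch_field(spec)
        res = M.measure_branching(stack.plane("gfap"), stack.plane("nuclei"),
                                  pixel_size_um=spec.pixel_size_um)
        assert sorted(res.per_cell_branch_counts) == [2, 4]
        assert res.branch_points_per_cell == pytest.approx(3.0)

    @pytest.mark.parametrize("width", [1, 3, 5])
    def test_recovery_across_stroke_widths(self, width):
        spec = S.BranchFieldSpec(seed=30 + width, n_cells=4,
                                 branch_points_per_cell=(0, 2, 4, 6),
                                 stroke_width_px=width, noise_sd=0.0)
        stack, truth = S.generate_branch_field(spec)
        res = M.measure_branching(stack.plane("gfap"), stack.plane("nuclei"))
        assert sorted(res.per_cell_branch_counts) == \
            sorted(c.branch_count for c in truth.cells)

    def test_rotation_invariance_of_branch_counts(self):
        spec = S.BranchFieldSpec(seed=9, n_cells=2, branch_points_per_cell=(1, 3),
                                 noise_sd=0.0)
        stack, _ = S.generate_branch_field(spec)
        gfap, dapi = stack.plane("gfap"), stack.plane("nuclei")
        a = M.measure_branching(gfap, dapi)
        b = M.measure_branching(np.rot90(gfap).copy(), np.rot90(dapi).copy())
        assert a.total_branch_points == b.total_branch_points
        assert a.n_cells == b.n_cells

    def test_zero_cells_flagged(self):
        gfap = np.full((128, 128), 100.0)
        gfap[40:60, 40:80] = 350.0
        res = M.measure_branching(gfap, np.zeros((128, 128)))
        assert res.n_cells == 0
        assert res.flags


class TestCellArea:
    def test_arithmetic(self):
        mask = np.zeros((20, 20), bool)
        mask.ravel()[:100] = True
        assert M.measure_cell_area(mask, 0.3) == pytest.approx(9.0)

    def test_empty_and_additivity(self, rng):
        assert M.measure_cell_area(np.zeros((5, 5), bool), 0.3) == 0.0
        a = rng.random((30, 30)) > 0.7
        b = (rng.random((30, 30)) > 0.7) & ~a
        total = M.measure_cell_area(a | b, 0.25)
        assert total == pytest.approx(M.measure_cell_area(a, 0.25)
                                      + M.measure_cell_area(b, 0.25))

    def test_mask_object_accepted(self):
        m = BinaryMask(np.ones((10, 10), bool))
        assert M.measure_cell_area(m, 1.0) == 100.0
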