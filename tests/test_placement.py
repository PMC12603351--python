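"""Length sampling, zygosity, ordering, constraint-based placement."""

import numpy as np
import pytest

from svforge.config import LengthRange, SVCategory
from svforge.errors import PlacementError
from svforge.grammar import parse_rule
from svforge.placement import (
    OccupancyIndex,
    PlacedSV,
    assign_zygosity,
    audit_placement,
    order_queue,
    place_sv,
    sample_lengths,
    sv_breakends,
)
from svforge.config import GlobalParams
from svforge.reference import Reference
from svforge.regions import ROI, OverlapMode, PlacementConstraint, ROISet
from svforge.simulate import run_simulation

from conftest import random_sequence


def _cat(rule_str="A→", distances=None, **kw):
    return SVCategory(
        sv_type=rule_str,
        rule=parse_rule(rule_str),
        count=kw.pop("count", 1),
        distances=distances or {"A": LengthRange(10, 20)},
        **kw,
    )


class TestSampleLengths:
    def test_degenerate_range(self, rng):
        cat = _cat(distances={"A": LengthRange(5, 5)})
        assert sample_lengths(cat, rng) == {"A": 5}

    def test_uniform_mean(self):
        cat = _cat(distances={"A": LengthRange(1000, 10000)})
        rng = np.random.default_rng(0)
        draws = np.array([sample_lengths(cat, rng)["A"] for _ in range(10_000)])
        expected_mean = (1000 + 10000) / 2
        se = (10000 - 1000) / np.sqrt(12) / np.sqrt(draws.size)
        assert abs(draws.mean() - expected_mean) < 3 * se
        assert draws.min() >= 1000 and draws.max() <= 10000

    def test_derived_length(self, rng):
        from svforge.config import Derivation

        cat = _cat(
            "AB→b",
            distances={
                "B": LengthRange(8, 8),
                "A": Derivation(0.5, "B", "0.5*length(B)"),
            },
        )
        assert sample_lengths(cat, rng) == {"B": 8, "A": 4}

    def test_derived_length_minimum_one(self, rng):
        from svforge.config import Derivation

        cat = _cat(
            "AB→b",
            distances={
                "B": LengthRange(1, 1),
                "A": Derivation(0.1, "B", "0.1*length(B)"),
            },
        )
        assert sample_lengths(cat, rng)["A"] == 1


def _stub_svs(n):
    rule = parse_rule("A→")
    return [
        PlacedSV(sv_id=f"sv{i}", sv_type="DEL", rule=rule, category_index=0,
                 lengths={"A": 10})
        for i in range(n)
    ]


class TestZygosity:
    def test_policy_one_all_homozygous(self, rng):
        svs = assign_zygosity(_stub_svs(50), 1.0, rng)
        assert all(sv.haplotypes == (0, 1) for sv in svs)

    def test_policy_zero_all_heterozygous(self, rng):
        svs = assign_zygosity(_stub_svs(50), 0.0, rng)
        assert all(len(sv.haplotypes) == 1 for sv in svs)

    def test_policy_half_fraction(self):
        rng = np.random.default_rng(1)
        svs = assign_zygosity(_stub_svs(10_000), 0.5, rng)
        hom = sum(1 for sv in svs if sv.haplotypes == (0, 1))
        se = np.sqrt(0.25 / 10_000)
        assert abs(hom / 10_000 - 0.5) < 3 * se


class TestOrdering:
    def _sv(self, sv_id, mode=None, fixed=False, span=10):
        rule = parse_rule("A→")
        sv = PlacedSV(
            sv_id=sv_id, sv_type="DEL", rule=rule, category_index=0,
            lengths={"A": span}, fixed=fixed,
        )
        if mode is not None:
            sv.constraints = [PlacementConstraint(OverlapMode(mode))]
        return sv

    def test_fixed_then_exact_then_unconstrained(self):
        queue = order_queue([
            self._sv("del", None),
            self._sv("dup", "exact"),
            self._sv("inv", fixed=True),
        ])
        assert [sv.sv_id for sv in queue] == ["inv", "dup", "del"]

    def test_full_stage_order(self):
        modes = ["contained", "partial", None, "containing", "exact"]
        queue = order_queue([self._sv(m or "none", m) for m in modes])
        assert [sv.sv_id for sv in queue] == [
            "exact", "partial", "containing", "contained", "none",
        ]

    def test_unconstrained_preserve_input_order(self):
        svs = [self._sv(f"sv{i}") for i in range(5)]
        assert [sv.sv_id for sv in order_queue(svs)] == [
            f"sv{i}" for i in range(5)
        ]

    def test_span_tiebreak(self):
        a = self._sv("small", "exact", span=1000)
        b = self._sv("large", "exact", span=5000)
        assert [sv.sv_id for sv in order_queue([a, b])] == ["large", "small"]


class TestPlaceSV:
    def _place(self, cat, ref, rois=None, blacklist=None, params=None, seed=0,
               occupied=None):
        from svforge.placement import instantiate_category

        rng = np.random.default_rng(seed)
        (sv,) = instantiate_category(cat, rng, 0)
        return place_sv(
            sv, occupied or OccupancyIndex(), rois or ROISet(),
            blacklist or ROISet(), ref,
            params or GlobalParams(reference_path=""), rng,
        )

    def test_exact_mode_unique_solution(self):
        ref = Reference({"chr1": "A" * 1000})
        cat = _cat(
            distances={"A": LengthRange(100, 100)},
            constraints=[PlacementConstraint(OverlapMode.EXACT)],
        )
        rois = ROISet([ROI("chr1", 100, 200, "R")])
        sv = self._place(cat, ref, rois=rois)
        assert sv.placements["A"] == ("chr1", 100, 200)

    def test_blacklist_covering_genome_fails(self):
        ref = Reference({"chr1": "A" * 1000})
        cat = _cat(constraints=[PlacementConstraint(OverlapMode.BLACKLIST)])
        rois = ROISet([ROI("chr1", 0, 1000, "BL")])
        with pytest.raises(PlacementError, match="sv0"):
            self._place(cat, ref, rois=rois)

    def test_contained_mode_always_inside_roi(self):
        ref = Reference({"chr1": "A" * 10_000})
        rois = ROISet([ROI("chr1", 0, 1000, "R")])
        for seed in range(50):
            cat = _cat(
                distances={"A": LengthRange(100, 100)},
                constraints=[PlacementConstraint(OverlapMode.CONTAINED)],
            )
            sv = self._place(cat, ref, rois=rois, seed=seed)
            _, s, e = sv.placements["A"]
            assert 0 <= s and e <= 1000

    def test_partial_mode_exactly_one_breakend_inside(self):
        ref = Reference({"chr1": "A" * 10_000})
        rois = ROISet([ROI("chr1", 4000, 5000, "R")])
        for seed in range(50):
            cat = _cat(
                distances={"A": LengthRange(2000, 2000)},
                constraints=[PlacementConstraint(OverlapMode.PARTIAL)],
            )
            sv = self._place(cat, ref, rois=rois, seed=seed)
            _, s, e = sv.placements["A"]
            inside = [4000 < p < 5000 for p in (s, e)]
            assert sum(inside) == 1

    def test_terminal_mode_touches_chromosome_end(self):
        ref = Reference({"chr1": "A" * 5000})
        for seed in range(20):
            cat = _cat(
                distances={"A": LengthRange(100, 200)},
                constraints=[PlacementConstraint(OverlapMode.TERMINAL)],
            )
            sv = self._place(cat, ref, seed=seed)
            _, s, e = sv.placements["A"]
            assert s == 0 or e == 5000

    def test_whole_chromosome_mode(self):
        ref = Reference({"chr1": "A" * 5000})
        cat = _cat(
            distances={"A": LengthRange(1000, 10_000)},
            constraints=[PlacementConstraint(OverlapMode.WHOLE_CHROMOSOME)],
        )
        sv = self._place(cat, ref)
        assert sv.placements["A"] == ("chr1", 0, 5000)

    def test_min_distance_enforced(self):
        ref = Reference({"chr1": "A" * 2000})
        params = GlobalParams(reference_path="", min_inter_sv_distance=300)
        occupied = OccupancyIndex()
        rng = np.random.default_rng(0)
        from svforge.placement import instantiate_category

        placed = []
        for i in range(3):
            cat = _cat(distances={"A": LengthRange(50, 50)})
            (sv,) = instantiate_category(cat, rng, i)
            place_sv(sv, occupied, ROISet(), ROISet(), ref, params, rng)
            occupied.commit(sv, False)
            placed.append(sv)
        points = sorted(p for sv in placed for _, p in sv_breakends(sv))
        own = {
            sv.sv_id: {p for _, p in sv_breakends(sv)} for sv in placed
        }
        for sv in placed:
            for other in placed:
                if sv.sv_id >= other.sv_id:
                    continue
                for p in own[sv.sv_id]:
                    for q in own[other.sv_id]:
                        assert abs(p - q) >= 300

    def test_interchromosomal_translocation(self):
        rng_seq = np.random.default_rng(2)
        ref = Reference({
            "chr1": random_sequence(rng_seq, 3000),
            "chr2": random_sequence(rng_seq, 3000),
        })
        from svforge.library import lookup_type

        entry = lookup_type("rTRA_INTER")
        cat = SVCategory(
            sv_type="rTRA_INTER",
            rule=entry.rule,
            count=1,
            distances={
                "A": LengthRange(100, 100),
                "B": LengthRange(100, 100),
                "_1": LengthRange(1, 1),
            },
            interchromosomal=True,
            entry=entry,
        )
        sv = self._place(cat, ref)
        ca = sv.placements["A"][0]
        cb = sv.placements["B"][0]
        assert ca != cb


class TestPlaceAll:
    def test_500_deletions_on_ample_reference(
        self, write_fasta_file, make_config, tmp_path
    ):
        rng = np.random.default_rng(10)
        ref_path = write_fasta_file({"chr1": random_sequence(rng, 2_000_000)})
        cfg = make_config(
            ref_path,
            [{"type": "DEL", "number": 100, "length": [1000, 10_000]}],
            min_intersv_dist=100, random_seed=4,
        )
        res = run_simulation(cfg, str(tmp_path / "out"))
        assert len(res.placed) == 100

    def test_zero_categories(self, write_fasta_file, make_config, tmp_path):
        ref_path = write_fasta_file({"chr1": "ACGT" * 300})
        res = run_simulation(
            make_config(ref_path, [], random_seed=1), str(tmp_path / "out")
        )
        assert res.placed == []

    def test_same_seed_identical_coordinates(
        self, write_fasta_file, make_config, tmp_path
    ):
        rng = np.random.default_rng(11)
        ref_path = write_fasta_file({"chr1": random_sequence(rng, 200_000)})
        cfg = make_config(
            ref_path,
            [{"type": "DEL", "number": 20, "length": [100, 1000]},
             {"type": "INV", "number": 10, "length": [100, 500]}],
            random_seed=9,
        )
        res1 = run_simulation(cfg, str(tmp_path / "out1"))
        res2 = run_simulation(cfg, str(tmp_path / "out2"))
        coords1 = [(sv.sv_id, sv.placements) for sv in res1.placed]
        coords2 = [(sv.sv_id, sv.placements) for sv in res2.placed]
        assert coords1 == coords2

    def test_infeasible_exact_diagnosed_early(
        self, write_fasta_file, make_config, tmp_path
    ):
        rng = np.random.default_rng(12)
        ref_path = write_fasta_file({"chr1": random_sequence(rng, 50_000)})
        bed = tmp_path / "roi.bed"
        bed.write_text("chr1\t100\t150\tR\n")  # length 50, below range
        cfg = make_config(
            ref_path,
            [{"type": "DEL", "number": 1, "length": [1000, 2000],
              "overlap_mode": "exact"}],
            overlap_regions=["roi.bed"],
        )
        with pytest.raises(PlacementError, match="infeasible"):
            run_simulation(cfg, str(tmp_path / "out"))


def test_randomized_constraint_audit(write_fasta_file, make_config, tmp_path):
    """Placed SVs across ROI modes re-verify against a standalone checker."""
    rng = np.random.default_rng(21)
    seq = random_sequence(rng, 400_000)
    ref_path = write_fasta_file({"chr1": seq})
    lines = []
    pos = 2000
    labels = ["R1", "R2"]
    i = 0
    while pos < 380_000:
        length = int(rng.integers(500, 3000))
        lines.append(f"chr1\t{pos}\t{pos + length}\t{labels[i % 2]}\n")
        pos += length + int(rng.integers(1500, 4000))
        i += 1
    (tmp_path / "rois.bed").write_text("".join(lines))
    cfg = make_config(
        ref_path,
        [
            {"type": "DEL", "number": 10, "length": [500, 3000],
             "overlap_mode": "exact", "overlap_region_type": ["R1"]},
            {"type": "INV", "number": 10, "length": [100, 400],
             "overlap_mode": "contained"},
            {"type": "DEL", "number": 10, "length": [3500, 5000],
             "overlap_mode": "containing", "overlap_region_type": ["R2"]},
            {"type": "DEL", "number": 10, "length": [1000, 2000],
             "overlap_mode": "partial"},
            {"type": "DEL", "number": 10, "length": [100, 300],
             "overlap_mode": "blacklist"},
        ],
        overlap_regions=["rois.bed"],
        random_seed=33,
        max_placement_attempts=300,
    )
    res = run_simulation(cfg, str(tmp_path / "out"))
    assert len(res.placed) == 50
    from svforge.regions import read_bed

    rois = ROISet(read_bed(str(tmp_path / "rois.bed")))
    for sv in res.placed:
        assert audit_placement(sv, rois, contig_lengths={"chr1": 400_000}) == []
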