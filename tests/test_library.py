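"""Predefined SV type registry, VCF import, SNPs and tandem-repeat events."""

import numpy as np
import pytest

from svforge.errors import ImportError_, PlacementError, SVForgeError
from svforge.grammar import derive_operations
from svforge.library import (
    all_entries,
    import_vcf_svs,
    lookup_type,
    registry_names,
    registry_size,
    tandem_repeat_event,
)
from svforge.reference import Reference
from svforge.regions import ROI
from svforge.simulate import run_simulation
from svforge.synthesis import replay_oracle

from conftest import random_sequence


class TestRegistry:
    def test_exactly_26_types(self):
        assert registry_size() == 26
        assert len(all_entries()) == 26

    def test_names_unique_and_rules_parse(self):
        names = registry_names()
        assert len(set(names)) == 26
        for entry in all_entries():
            derive_operations(entry.rule)  # parses and derives cleanly

    def test_required_classes_present(self):
        required = {
            "DEL", "INS", "INV", "DUP", "dDUP", "INV_dDUP", "INV_DUP",
            "delINV", "INVdel", "delINVdel", "dupINV", "INVdup",
            "rTRA", "rTRA_INTER", "trEXP", "trCON", "SNP",
        }
        assert required <= set(registry_names())

    def test_lookup_del(self):
        assert lookup_type("DEL").rule_string == "A→"

    def test_lookup_delinvdel_composition(self):
        assert lookup_type("delINVdel").rule.canonical_string == "ABC→b"

    def test_unknown_name_enumerates_valid_names(self):
        with pytest.raises(SVForgeError, match="DEL"):
            lookup_type("")
        with pytest.raises(SVForgeError, match="Did you mean"):
            lookup_type("delINVdl")


class TestVCFImport:
    def _write_vcf(self, tmp_path, body, contig="chr1", length=1000):
        path = tmp_path / "in.vcf"
        header = (
            "##fileformat=VCFv4.2\n"
            f"##contig=<ID={contig},length={length}>\n"
            '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="t">\n'
            '##INFO=<ID=END,Number=1,Type=Integer,Description="e">\n'
            '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="l">\n'
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="g">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS\n"
        )
        path.write_text(header + body)
        return str(path)

    def test_single_del_import(self, tmp_path):
        path = self._write_vcf(
            tmp_path,
            "chr1\t100\tdel1\tN\t<DEL>\t.\t.\tSVTYPE=DEL;END=200;SVLEN=-100\tGT\t1|0\n",
        )
        (sv,) = import_vcf_svs(path, {"chr1": 1000})
        assert (sv.chrom, sv.start, sv.end) == ("chr1", 100, 200)
        assert sv.type_name == "DEL"
        assert sv.genotype == (0,)

    def test_header_only_vcf(self, tmp_path):
        assert import_vcf_svs(self._write_vcf(tmp_path, ""), {"chr1": 1000}) == []

    def test_end_beyond_contig_names_record(self, tmp_path):
        path = self._write_vcf(
            tmp_path,
            "chr1\t100\tbad1\tN\t<DEL>\t.\t.\tSVTYPE=DEL;END=5000;SVLEN=-4900\tGT\t1|1\n",
        )
        with pytest.raises(ImportError_, match="bad1"):
            import_vcf_svs(path, {"chr1": 1000})

    def test_unparseable_svtype(self, tmp_path):
        path = self._write_vcf(
            tmp_path,
            "chr1\t100\tx\tN\t<CPX>\t.\t.\tSVTYPE=WEIRD;END=120\tGT\t1|1\n",
        )
        with pytest.raises(ImportError_, match="WEIRD"):
            import_vcf_svs(path, {"chr1": 1000})

    def test_imported_svs_bypass_random_placement(
        self, tmp_path, write_fasta_file, make_config
    ):
        rng = np.random.default_rng(5)
        ref = write_fasta_file({"chr1": random_sequence(rng, 1000)})
        vcf = self._write_vcf(
            tmp_path,
            "chr1\t101\tfix1\tN\t<DEL>\t.\t.\tSVTYPE=DEL;END=201;SVLEN=-100\tGT\t1|1\n",
        )
        cfg = make_config(ref, [{"vcf": "in.vcf"}], random_seed=1)
        res = run_simulation(cfg, str(tmp_path / "out"))
        (sv,) = res.placed
        assert sv.fixed
        # interval reconstructed from END and SVLEN: [END-|SVLEN|, END)
        assert sv.placements["A"] == ("chr1", 101, 201)
        assert sv.haplotypes == (0, 1)
        assert len(res.sequences[0]["chr1_hapA"]) == 900


def test_registry_replay_roundtrip(write_fasta_file, make_config, tmp_path):
    """One homozygous instance of every simulable registry type on a random
    fixture reference: replaying the emitted VCF with the naive string editor
    reproduces both haplotype FASTAs byte-for-byte."""
    rng = np.random.default_rng(99)
    seqs = {
        "chr1": random_sequence(rng, 50_000),
        "chr2": random_sequence(rng, 30_000),
    }
    # plant two tandem repeat loci (trEXP and trCON each need their own)
    motif = "CAG"
    seqs["chr1"] = seqs["chr1"][:2000] + motif * 30 + seqs["chr1"][2000 + 90:]
    seqs["chr2"] = seqs["chr2"][:5000] + motif * 30 + seqs["chr2"][5000 + 90:]
    ref_path = write_fasta_file(seqs)
    bed = tmp_path / "tr.bed"
    bed.write_text(
        f"chr1\t2000\t2090\tTR_{motif}\nchr2\t5000\t5090\tTR_{motif}\n"
    )
    variant_sets = []
    for entry in all_entries():
        vs = {"type": entry.name, "number": 1, "homozygous_prob": 1.0}
        if entry.special in ("trEXP", "trCON"):
            vs["overlap_mode"] = "exact"
            vs["overlap_region_type"] = [f"TR_{motif}"]
            vs["copy_delta"] = [2, 5]
        elif entry.special == "SNP":
            pass
        else:
            vs["length"] = [30, 80]
        variant_sets.append(vs)
    cfg = make_config(
        ref_path, variant_sets, overlap_regions=["tr.bed"],
        min_intersv_dist=10, random_seed=11,
    )
    res = run_simulation(cfg, str(tmp_path / "out"))
    assert len(res.placed) == 26
    reference = Reference(ref_path)
    replayed = replay_oracle(reference, res.paths["vcf"])
    for hap, tag in ((0, "_hapA"), (1, "_hapB")):
        for chrom in ("chr1", "chr2"):
            assert replayed[(hap, chrom)] == res.sequences[hap][chrom + tag], (
                hap, chrom,
            )


class TestSmallVariants:
    def test_snps_substitute_single_bases(
        self, write_fasta_file, make_config, tmp_path
    ):
        rng = np.random.default_rng(3)
        seq = random_sequence(rng, 10_000)
        ref_path = write_fasta_file({"chr1": seq})
        cfg = make_config(
            ref_path, [{"type": "SNP", "number": 10}], random_seed=2
        )
        res = run_simulation(cfg, str(tmp_path / "out"))
        assert len(res.placed) == 10
        import pysam

        with pysam.VariantFile(res.paths["vcf"]) as vf:
            recs = list(vf)
        assert len(recs) == 10
        for rec in recs:
            assert len(rec.ref) == 1 and len(rec.alts[0]) == 1
            assert rec.alts[0] != rec.ref
            assert rec.ref == seq[rec.start]

    def test_zero_snps(self, write_fasta_file, make_config, tmp_path):
        ref_path = write_fasta_file({"chr1": "ACGT" * 100})
        cfg = make_config(ref_path, [], random_seed=1)
        res = run_simulation(cfg, str(tmp_path / "out"))
        assert res.placed == []

    def test_snp_forced_to_only_unblacklisted_base(
        self, write_fasta_file, make_config, tmp_path
    ):
        rng = np.random.default_rng(4)
        ref_path = write_fasta_file({"chr1": random_sequence(rng, 20)})
        bed = tmp_path / "bl.bed"
        # every interior breakend position except 10/11 is blacklisted
        bed.write_text("chr1\t0\t10\tBL\nchr1\t11\t20\tBL\n")
        cfg = make_config(
            ref_path,
            [{"type": "SNP", "number": 1}],
            blacklist_regions=["bl.bed"],
            max_placement_attempts=500,
            random_seed=6,
        )
        res = run_simulation(cfg, str(tmp_path / "out"))
        assert res.placed[0].placements["A"] == ("chr1", 10, 11)


class TestTandemRepeats:
    def _setup(self, write_fasta_file, copies=10):
        rng = np.random.default_rng(8)
        motif = "CAG"
        left = random_sequence(rng, 500)
        right = random_sequence(rng, 500)
        seq = left + motif * copies + right
        ref = Reference({"chr1": seq})
        roi = ROI("chr1", 500, 500 + 3 * copies, "TR_CAG")
        return ref, roi, motif

    def _category(self, tmp_path, write_fasta_file, make_config, name, delta):
        # build through the config layer so defaults match real runs
        from svforge.config import SVCategory
        from svforge.library import lookup_type
        from svforge.regions import OverlapMode, PlacementConstraint

        entry = lookup_type(name)
        return SVCategory(
            sv_type=name,
            rule=entry.rule,
            count=1,
            constraints=[
                PlacementConstraint(OverlapMode.EXACT, frozenset({"TR_CAG"}))
            ],
            copy_delta=delta,
            entry=entry,
        )

    def test_expansion_adds_motif_copies(
        self, tmp_path, write_fasta_file, make_config
    ):
        ref, roi, motif = self._setup(write_fasta_file)
        cat = self._category(tmp_path, write_fasta_file, make_config,
                             "trEXP", (5, 5))
        rng = np.random.default_rng(1)
        sv = tandem_repeat_event(cat, roi, ref, rng)
        from svforge.synthesis import build_haplotype

        seqs, _ = build_haplotype(ref, [sv], 0)
        assert motif * 15 in seqs["chr1_hapA"]
        assert len(seqs["chr1_hapA"]) == ref.lengths["chr1"] + 15

    def test_contraction_removes_copies(
        self, tmp_path, write_fasta_file, make_config
    ):
        ref, roi, motif = self._setup(write_fasta_file)
        cat = self._category(tmp_path, write_fasta_file, make_config,
                             "trCON", (4, 4))
        rng = np.random.default_rng(1)
        sv = tandem_repeat_event(cat, roi, ref, rng)
        from svforge.synthesis import build_haplotype

        seqs, _ = build_haplotype(ref, [sv], 0)
        assert len(seqs["chr1_hapA"]) == ref.lengths["chr1"] - 12
        assert motif * 6 in seqs["chr1_hapA"]
        assert motif * 7 not in seqs["chr1_hapA"]

    def test_contraction_exceeding_copies_fails(
        self, tmp_path, write_fasta_file, make_config
    ):
        ref, roi, _ = self._setup(write_fasta_file, copies=10)
        cat = self._category(tmp_path, write_fasta_file, make_config,
                             "trCON", (12, 12))
        with pytest.raises(PlacementError):
            tandem_repeat_event(cat, roi, ref, np.random.default_rng(1))
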