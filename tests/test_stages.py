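"""Align/trim/tree stages: batch semantics, native fallbacks, adapters."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

import phyloprov as pp
from phyloprov.stages import StageConf, nj_tree, run_external, trim_gap_threshold
from phyloprov.treecmp import rf_distance


def _unaligned_project(n_loci=3, aligned=()):
    project = pp.create_project([pp.Locus(name=f"L{i}") for i in range(n_loci)])
    for i in range(n_loci):
        for otu in "ABCD":
            project.add_record(
                pp.SequenceRecord(
                    record_id=f"L{i}_{otu}_f{project.next_record_serial()}",
                    locus_name=f"L{i}",
                    otu=otu,
                    sequence="ACGTACGT",
                    metadata={"organism": otu},
                )
            )
    for name in aligned:
        from phyloprov.stages import register_pass_through_alignment

        register_pass_through_alignment(project, name, "0000_seed")
    return project


class TestAlignBatch:
    def test_only_unaligned_loci_touched(self):
        project = _unaligned_project(3, aligned=["L0"])
        new = pp.align(project, StageConf(stage="align"))
        assert len(new) == 2
        assert {project.alignments[i].locus_name for i in new} == {"L1", "L2"}

    def test_scope_limits_batch(self):
        project = _unaligned_project(3)
        new = pp.align(project, StageConf(stage="align", scope=["L1"]))
        assert len(new) == 1
        assert project.alignments[new[0]].locus_name == "L1"

    def test_empty_scope_warns(self):
        project = _unaligned_project(1, aligned=["L0"])
        with pytest.warns(UserWarning):
            assert pp.align(project, StageConf(stage="align")) == []

    def test_batch_closure(self):
        project = _unaligned_project(4)
        pp.align(project, StageConf(stage="align"))
        aligned = {a.locus_name for a in project.alignments.values()}
        assert aligned == set(project.locus_names())

    def test_pass_through_degapping_identity(self):
        project = _unaligned_project(1)
        (aln_id,) = pp.align(project, StageConf(stage="align"))
        for rid, gapped in project.alignments[aln_id].rows:
            assert gapped.replace("-", "") == project.records[rid].sequence


class TestTrim:
    def _aln(self, rows):
        return pp.Alignment(object_id="a", locus_name="L0", rows=rows)

    def test_gt_zero_is_identity(self):
        project = _unaligned_project(1)
        aln = self._aln([("r1", "A--T"), ("r2", "AC-T")])
        assert trim_gap_threshold(project, aln, 0.0).rows == aln.rows

    def test_gt_one_keeps_only_gapfree(self):
        project = _unaligned_project(1)
        aln = self._aln([("r1", "A--T"), ("r2", "AC-T")])
        trimmed = trim_gap_threshold(project, aln, 1.0)
        assert [s for _, s in trimmed.rows] == ["AT", "AT"]

    def test_column_counting_oracle(self):
        # 4 rows, per-column gap counts {0,1,2,3}; gt=0.5 keeps <=2 gaps
        project = _unaligned_project(1)
        aln = self._aln(
            [("r1", "ACGT"), ("r2", "AC-T"), ("r3", "A--T"), ("r4", "A---")]
        )
        trimmed = trim_gap_threshold(project, aln, 0.5)
        assert trimmed.length == 3

    def test_zero_columns_is_error(self):
        project = _unaligned_project(1)
        aln = self._aln([("r1", "-A"), ("r2", "A-")])
        with pytest.raises(ValueError, match="lower"):
            trim_gap_threshold(project, aln, 1.0)

    @given(
        rows=st.integers(2, 6),
        cols=st.integers(1, 12),
        data=st.data(),
        gt1=st.floats(0, 1),
        gt2=st.floats(0, 1),
    )
    def test_monotonicity_in_threshold(self, rows, cols, data, gt1, gt2):
        seqs = [
            data.draw(st.text(alphabet="ACGT-", min_size=cols, max_size=cols))
            for _ in range(rows)
        ]
        aln = self._aln([(f"r{i}", s) for i, s in enumerate(seqs)])
        lo, hi = sorted((gt1, gt2))

        def kept(gt):
            n = len(aln.rows)
            return {
                i
                for i, col in enumerate(aln.columns())
                if sum(c != "-" for c in col) / n >= gt
            }

        project = _unaligned_project(1)
        assert kept(hi) <= kept(lo)
        if kept(hi):
            a = trim_gap_threshold(project, aln, hi)
            b = trim_gap_threshold(project, aln, lo)
            assert a.length == len(kept(hi)) and b.length == len(kept(lo))


class TestNeighborJoining:
    def _quartet_project(self):
        """Sequences with additive hamming distances on ((A,B),(C,D))."""
        L = 1000
        sites = {"A": range(0, 50), "B": range(50, 110), "C": range(110, 180),
                 "D": range(180, 260), "internal": range(260, 300)}
        base = ["A"] * L

        def make(leaf, on_ab_side):
            seq = base[:]
            if on_ab_side:
                for i in sites["internal"]:
                    seq[i] = "C"
            for i in sites[leaf]:
                seq[i] = "G" if leaf in ("A", "C") else "T"
            return "".join(seq)

        project = pp.create_project([pp.Locus(name="q")])
        rows = []
        for leaf in "ABCD":
            seq = make(leaf, leaf in "AB")
            project.add_record(
                pp.SequenceRecord(record_id=leaf, locus_name="q", otu=leaf,
                                  sequence=seq)
            )
            rows.append((leaf, seq))
        aln = pp.Alignment(object_id="q_aln", locus_name="q", rows=rows)
        project.alignments["q_aln"] = aln
        return project, aln

    def test_quartet_topology_recovered(self):
        project, aln = self._quartet_project()
        tree = nj_tree(project, aln, model="p")
        assert rf_distance(tree.newick, "((A:1,B:1):1,(C:1,D:1):1);") == 0

    def test_three_taxa_forced_topology(self):
        project = pp.create_project([pp.Locus(name="t")])
        rows = [("A", "AAAA"), ("B", "AAAT"), ("C", "AATT")]
        for rid, seq in rows:
            project.add_record(
                pp.SequenceRecord(record_id=rid, locus_name="t", otu=rid,
                                  sequence=seq)
            )
        aln = pp.Alignment(object_id="t_aln", locus_name="t", rows=rows)
        tree = nj_tree(project, aln, model="p")
        from phyloprov.treecmp import bipartitions

        leaves, _ = bipartitions(tree.newick)
        assert leaves == frozenset("ABC")

    def test_identical_sequences_deterministic(self):
        project = pp.create_project([pp.Locus(name="z")])
        rows = [(c, "ACGTACGT") for c in "ABCD"]
        for rid, seq in rows:
            project.add_record(
                pp.SequenceRecord(record_id=rid, locus_name="z", otu=rid,
                                  sequence=seq)
            )
        aln = pp.Alignment(object_id="z_aln", locus_name="z", rows=rows)
        t1 = nj_tree(project, aln, model="p")
        t2 = nj_tree(project, aln, model="p")
        assert t1.newick == t2.newick
        assert t1.tree_length == 0.0

    def test_jc69_saturation_names_pair(self):
        project = pp.create_project([pp.Locus(name="s")])
        rows = [("A", "ACGT" * 5), ("B", "CATG" * 5), ("C", "ACGT" * 5)]
        for rid, seq in rows:
            project.add_record(
                pp.SequenceRecord(record_id=rid, locus_name="s", otu=rid,
                                  sequence=seq)
            )
        aln = pp.Alignment(object_id="s_aln", locus_name="s", rows=rows)
        with pytest.raises(ValueError, match="JC69"):
            nj_tree(project, aln, model="JC69")

    def test_branch_lengths_non_negative(self, small_project):
        aln = small_project.alignment_for_locus("locus_0005")
        tree = nj_tree(small_project, aln, model="p")
        import io

        from Bio import Phylo

        ptree = Phylo.read(io.StringIO(tree.newick), "newick")
        for clade in ptree.find_clades():
            assert clade.branch_length is None or clade.branch_length >= 0


class TestExternalAdapters:
    def test_identity_adapter_registers_alignment(self, tmp_path):
        project = _unaligned_project(1)
        adapter = {
            "name": "mock-aligner",
            "command": "cp {in} {out}",
            "version_probe": "echo mock-aligner 1.0",
            "stage": "align",
            "output_format": "fasta",
        }
        conf = StageConf(
            stage="align",
            method="mock-aligner",
            parameters={"adapter": adapter, "locus": "L0",
                        "workdir": str(tmp_path / "w")},
        )
        (aln_id,) = run_external(project, conf)
        assert project.alignments[aln_id].locus_name == "L0"
        assert "mock-aligner 1.0" in project.ledger[-1].tool

    def test_failing_probe_blocks_execution(self, tmp_path):
        project = _unaligned_project(1)
        adapter = {
            "name": "broken",
            "command": "cp {in} {out}",
            "version_probe": "python -c 'import sys; sys.exit(1)'",
        }
        conf = StageConf(
            stage="align",
            method="broken",
            parameters={"adapter": adapter, "locus": "L0",
                        "workdir": str(tmp_path / "w")},
        )
        with pytest.raises(RuntimeError, match="probe"):
            run_external(project, conf)
        assert project.alignments == {}

    def test_tree_adapter_newick_round_trip(self, tmp_path):
        project = _unaligned_project(1)
        pp.align(project, StageConf(stage="align"))
        fixture = tmp_path / "fix.nwk"
        newick = "((L0_A_f1:0.1,L0_B_f2:0.1):0.05,(L0_C_f3:0.1,L0_D_f4:0.1):0.05);"
        fixture.write_text(newick + "\n")
        adapter = {
            "name": "mock-treebuilder",
            "command": f"cp {fixture} {{out}}",
            "version_probe": "echo mock-treebuilder 2.0",
            "stage": "tree",
            "output_format": "newick",
        }
        conf = StageConf(
            stage="tree",
            method="mock-treebuilder",
            parameters={"adapter": adapter, "locus": "L0",
                        "workdir": str(tmp_path / "w")},
        )
        (tree_id,) = run_external(project, conf)
        assert rf_distance(project.trees[tree_id].newick, newick) == 0
        assert set(project.trees[tree_id].leaf_map) == {
            f"L0_{c}_f{i}" for c, i in zip("ABCD", (1, 2, 3, 4))
        }
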