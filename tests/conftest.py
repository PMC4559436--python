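import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord as BioRecord

import phyloprov as pp


@pytest.fixture(scope="session")
def small_project():
    """6 loci x 6 taxa, 200 bp, full occupancy, descending entropy gradient."""
    project = pp.synth_dataset(n_loci=6, n_taxa=6, locus_length=200, seed=11)
    pp.compute_stats(project)
    return project


@pytest.fixture()
def fresh_small_project():
    project = pp.synth_dataset(n_loci=4, n_taxa=5, locus_length=120, seed=13)
    pp.compute_stats(project)
    return project


def _gb_entry(acc, organism, feats, seq):
    rec = BioRecord(
        Seq(seq), id=acc, name=acc.split(".")[0], description=f"{organism} voucher"
    )
    rec.annotations.update({"organism": organism, "molecule_type": "DNA"})
    rec.features = [
        SeqFeature(SimpleLocation(start, end), type=ftype, qualifiers={"gene": [gene]})
        for ftype, gene, start, end in feats
    ]
    return rec


@pytest.fixture()
def toy_genbank(tmp_path):
    """Two-entry GenBank flat file with cox1 CDS and 18S rRNA features."""
    path = tmp_path / "toy.gb"
    entries = [
        _gb_entry(
            "AB000001.1",
            "Papilio machaon",
            [("CDS", "COX1", 0, 30), ("rRNA", "18S", 30, 60)],
            "ATGGCCATTGTAATGGGCCGCTGAAAGGGT" + "GCTTGTCTCAAAGATTAAGCCATGCATGTC",
        ),
        _gb_entry(
            "AB000002.1",
            "Pieris rapae",
            [("CDS", "cox-1", 0, 30), ("CDS", "EF1a", 30, 57)],
            "ATGGCAATTGTAATGGGCCGATGAAAGGGA" + "ATGGGTAAAGAGAAGATTCACATCAAT",
        ),
    ]
    SeqIO.write(entries, str(path), "genbank")
    return path


@pytest.fixture()
def two_locus_project():
    """Hand-built project: two aligned loci (lengths 5 and 7), 3 OTUs, complete."""
    project = pp.create_project(
        [pp.Locus(name="L1"), pp.Locus(name="L2")], title="toy"
    )
    seqs = {
        "L1": {"A": "ACGTA", "B": "ACGTT", "C": "ACCTA"},
        "L2": {"A": "TTGCAAC", "B": "TTGCAAT", "C": "TTGCGAC"},
    }
    for locus, by_otu in seqs.items():
        rows = []
        for otu, seq in sorted(by_otu.items()):
            rid = f"{locus}_{otu}_f{project.next_record_serial()}"
            project.add_record(
                pp.SequenceRecord(
                    record_id=rid,
                    locus_name=locus,
                    otu=otu,
                    sequence=seq,
                    metadata={"organism": otu},
                )
            )
            rows.append((rid, seq))
        project.alignments[f"aln_{locus}"] = pp.Alignment(
            object_id=f"aln_{locus}", locus_name=locus, rows=rows
        )
    project.log("register_alignments", {})
    return project
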