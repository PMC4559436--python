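"""Readers and writers for the standard formats the workflow touches.

Harvesting walks GenBank flat files, routes each feature whose
``gene``/``product`` qualifier alias-folds to a project locus into a
:class:`~phyloprov.core.SequenceRecord`, and reports (never drops) the
rest.  Unpublished data enters through FASTA with an optional CSV/TSV
metadata table.  Writers cover FASTA, Newick, PhyloXML (with per-leaf
metadata annotations), relaxed PHYLIP, RAxML-style partition files and
CSV metadata dumps.
"""

from __future__ import annotations

import io as _io
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

from Bio import AlignIO, Phylo, SeqIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from .core import Locus, Project, SequenceRecord, Tree, fold_alias

__all__ = [
    "read_genbank",
    "read_fasta",
    "list_loci",
    "write",
    "LocusInventory",
    "HARVEST_FEATURE_TYPES",
]

log = logging.getLogger(__name__)

HARVEST_FEATURE_TYPES = ("CDS", "rRNA", "gene", "tRNA")

WRITE_FORMATS = {
    "records": ("fasta",),
    "alignments": ("fasta", "phylip-relaxed"),
    "trees": ("newick", "phyloxml"),
    "supermatrix": ("fasta", "phylip-relaxed"),
    "metadata": ("csv", "tsv"),
}


def _feature_name(feature) -> str | None:
    for qualifier in ("gene", "product", "locus_tag"):
        if qualifier in feature.qualifiers:
            return feature.qualifiers[qualifier][0]
    return None


def read_genbank(
    paths: list[str | Path],
    project: Project,
    feature_types: tuple[str, ...] = HARVEST_FEATURE_TYPES,
) -> int:
    """Harvest features from GenBank flat files into the project.

    Each feature of a harvestable type whose name alias-folds to a
    project locus becomes one record carrying the feature sub-sequence,
    the source organism as OTU, and the accession plus all qualifiers as
    metadata.  Features matching no locus are tallied in the ledger
    entry's ``unassigned`` parameter; matched + unassigned equals the
    number of scanned harvestable features.  Returns the record count
    added.
    """
    added = 0
    scanned = 0
    unassigned: dict[str, int] = {}
    for path in paths:
        path = Path(path)
        entries = list(SeqIO.parse(str(path), "genbank"))
        if not entries:
            warnings.warn(f"no GenBank entries found in {path}")
        for entry in entries:
            organism = entry.annotations.get("organism", "")
            for feature in entry.features:
                if feature.type not in feature_types:
                    continue
                name = _feature_name(feature)
                if name is None:
                    continue
                scanned += 1
                locus = next((lc for lc in project.loci if lc.matches(name)), None)
                if locus is None:
                    key = fold_alias(name)
                    unassigned[key] = unassigned.get(key, 0) + 1
                    continue
                seq = str(feature.extract(entry.seq))
                metadata = {
                    "accession": entry.id,
                    "description": entry.description,
                    "organism": organism,
                    "feature_type": feature.type,
                    "source_file": path.name,
                }
                for qual, values in feature.qualifiers.items():
                    if qual not in ("translation",):
                        metadata.setdefault(qual, values[0])
                serial = project.next_record_serial()
                record = SequenceRecord(
                    record_id=f"{locus.name}_{entry.id}_f{serial}",
                    locus_name=locus.name,
                    otu=organism,
                    sequence=seq,
                    metadata=metadata,
                )
                project.add_record(record)
                added += 1
    project.log(
        "read_genbank",
        {
            "paths": [str(p) for p in paths],
            "added": added,
            "scanned": scanned,
            "unassigned": unassigned,
        },
        output_ids=[],
    )
    return added


def read_fasta(
    path: str | Path,
    project: Project,
    locus_name: str,
    metadata_table: str | Path | None = None,
) -> int:
    """Add unpublished FASTA sequences to one locus bin.

    Headers must be unique.  If a CSV/TSV ``metadata_table`` is given its
    first column keys rows by header and an ``organism`` column (if
    present) defines each record's OTU; without a table the OTU defaults
    to the header itself.
    """
    import pandas as pd

    path = Path(path)
    locus = project.find_locus(locus_name)
    entries = list(SeqIO.parse(str(path), "fasta"))
    headers = [e.id for e in entries]
    dupes = {h for h in headers if headers.count(h) > 1}
    if dupes:
        raise ValueError(f"duplicate FASTA header(s) in {path}: {sorted(dupes)}")

    table = {}
    if metadata_table is not None:
        sep = "\t" if str(metadata_table).endswith((".tsv", ".tab")) else ","
        frame = pd.read_csv(metadata_table, sep=sep, dtype=str)
        key_col = frame.columns[0]
        table = {row[key_col]: row.dropna().to_dict() for _, row in frame.iterrows()}
        orphans = set(table) - set(headers)
        if orphans:
            warnings.warn(f"metadata rows with no matching header: {sorted(orphans)}")

    added = 0
    for entry in entries:
        meta = {"description": entry.description, "source_file": path.name}
        meta.update(table.get(entry.id, {}))
        otu = meta.get("organism", entry.id)
        serial = project.next_record_serial()
        record = SequenceRecord(
            record_id=f"{locus.name}_{path.stem}_f{serial}",
            locus_name=locus.name,
            otu=otu,
            sequence=str(entry.seq).replace("-", ""),
            metadata=meta,
        )
        project.add_record(record)
        added += 1
    project.log(
        "read_fasta",
        {"path": str(path), "locus": locus.name, "added": added,
         "metadata_table": str(metadata_table) if metadata_table else None},
    )
    return added


@dataclass
class LocusInventory:
    """Survey of feature names found in GenBank files, grouped by alias folding."""

    rows: list[tuple[str, str, int, str]]  # (feature_type, observed_name, count, group)

    def total(self) -> int:
        return sum(count for _, _, count, _ in self.rows)

    def groups(self) -> dict[str, int]:
        """Aggregate counts per folded group key."""
        agg: dict[str, int] = {}
        for _, _, count, group in self.rows:
            agg[group] = agg.get(group, 0) + count
        return agg

    def to_loci(self, chosen_groups: list[str], char_type: str = "dna") -> list[Locus]:
        """Turn chosen inventory groups into Locus definitions."""
        loci = []
        for group in chosen_groups:
            names = {name for _, name, _, g in self.rows if g == group}
            ftypes = {ft for ft, _, _, g in self.rows if g == group}
            primary = sorted(names)[0]
            loci.append(
                Locus(
                    name=primary,
                    aliases=names - {primary},
                    feature_type=sorted(ftypes)[0],
                    char_type=char_type,
                )
            )
        return loci


def list_loci(
    paths: list[str | Path],
    feature_types: tuple[str, ...] = HARVEST_FEATURE_TYPES,
) -> LocusInventory:
    """Inventory every gene/product name in GenBank files with counts.

    Names that alias-fold to the same key share a ``suggested_group`` so
    synonyms (cox1 / COX-1 / COI declared as aliases) can be merged into
    one locus before harvesting.
    """
    counts: dict[tuple[str, str], int] = {}
    for path in paths:
        for entry in SeqIO.parse(str(path), "genbank"):
            for feature in entry.features:
                if feature.type not in feature_types:
                    continue
                name = _feature_name(feature)
                if name is None:
                    continue
                key = (feature.type, name)
                counts[key] = counts.get(key, 0) + 1
    rows = [
        (ftype, name, count, fold_alias(name))
        for (ftype, name), count in sorted(counts.items())
    ]
    return LocusInventory(rows=rows)


# -- writers ----------------------------------------------------------------


def _alignment_to_biopython(aln) -> MultipleSeqAlignment:
    return MultipleSeqAlignment(
        [BioSeqRecord(Seq(seq), id=rid, description="") for rid, seq in aln.rows]
    )


def _tree_to_phyloxml(tree: Tree):
    from Bio.Phylo import PhyloXML

    ptree = Phylo.read(_io.StringIO(tree.newick), "newick")
    phylogeny = ptree.as_phyloxml()
    for clade in phylogeny.get_terminals():
        ann = tree.annotations.get(clade.name, {})
        for field_name, value in ann.items():
            if value is None:
                continue
            clade.properties.append(
                PhyloXML.Property(
                    value=str(value),
                    ref=f"phyloprov:{field_name}",
                    applies_to="clade",
                    datatype="xsd:string",
                )
            )
    return phylogeny


def write(
    project: Project, what: str, format: str, path: str | Path, _log: bool = True
) -> list[Path]:
    """Write project objects to standard-format files; returns paths written.

    ``what`` is one of records, alignments, trees, supermatrix, metadata;
    ``path`` is a directory (created if needed) except for metadata,
    where it is the output file.  Formats round-trip: re-reading a
    written FASTA or Newick reproduces sequences and topology exactly.
    """
    if what not in WRITE_FORMATS:
        raise ValueError(f"unknown target {what!r}; choose from {sorted(WRITE_FORMATS)}")
    if format not in WRITE_FORMATS[what]:
        raise ValueError(
            f"unsupported format {format!r} for {what}; supported: {WRITE_FORMATS[what]}"
        )
    path = Path(path)
    written: list[Path] = []

    if what == "metadata":
        import pandas as pd

        rows = []
        for record in project.records.values():
            row = {"record_id": record.record_id, "locus": record.locus_name, "otu": record.otu}
            row.update({k: str(v) for k, v in record.metadata.items()})
            rows.append(row)
        frame = pd.DataFrame(rows)
        path.parent.mkdir(parents=True, exist_ok=True)
        frame.to_csv(path, sep="\t" if format == "tsv" else ",", index=False)
        written.append(path)

    elif what == "records":
        path.mkdir(parents=True, exist_ok=True)
        for locus in project.loci:
            records = project.records_for_locus(locus.name)
            if not records:
                continue
            out = path / f"{locus.name}.fasta"
            SeqIO.write(
                [BioSeqRecord(Seq(r.sequence), id=r.record_id, description=r.otu) for r in records],
                str(out),
                "fasta",
            )
            written.append(out)

    elif what == "alignments":
        path.mkdir(parents=True, exist_ok=True)
        for pool in (project.alignments, project.trimmed):
            for aln in pool.values():
                out = path / f"{aln.object_id}.{'fasta' if format == 'fasta' else 'phy'}"
                AlignIO.write(_alignment_to_biopython(aln), str(out), format)
                written.append(out)

    elif what == "trees":
        path.mkdir(parents=True, exist_ok=True)
        for tree in project.trees.values():
            if format == "newick":
                out = path / f"{tree.object_id}.nwk"
                out.write_text(tree.newick.rstrip("\n") + "\n")
            else:
                out = path / f"{tree.object_id}.xml"
                Phylo.write(_tree_to_phyloxml(tree), str(out), "phyloxml")
            written.append(out)

    elif what == "supermatrix":
        path.mkdir(parents=True, exist_ok=True)
        for matrix in project.supermatrices.values():
            ext = "fasta" if format == "fasta" else "phy"
            out = path / f"{matrix.name}.{ext}"
            aln = MultipleSeqAlignment(
                [BioSeqRecord(Seq(seq), id=otu.replace(" ", "_"), description="")
                 for otu, seq in sorted(matrix.rows.items())]
            )
            AlignIO.write(aln, str(out), format)
            written.append(out)
            parts = path / f"{matrix.name}.partitions.txt"
            parts.write_text("\n".join(matrix.partition_lines()) + "\n")
            written.append(parts)

    if _log:
        project.log(
            "write",
            {"what": what, "format": format, "files": [str(p) for p in written]},
        )
    return written
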