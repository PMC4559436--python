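"""Reproducibility layer: serialization, checkpoints, report and archive.

The project serializes to a single self-describing JSON document — open
formats readable without this library — with an embedded checksum.  The
serialization is deterministic (sorted keys, no generation-time wall
clock in the content section), so the checksum doubles as a content
address: a :class:`CheckpointStore` saves one file per distinct state
under ``objects/<hash>`` and appends the chain to ``chain.jsonl``.
Restoring an older checkpoint brings back the full project of that
moment — every intermediate object and the ledger prefix — and, because
the store is append-only, toggling forward to the head again always
works.

:func:`report` assembles a human-readable methods document from the
ledger (tools, versions, parameters, accessions); :func:`archive`
packages the serialized project, all standard-format exports, the report
and a checksummed manifest into one zip suitable for a data repository.
"""

from __future__ import annotations

import datetime
import hashlib
import json
import platform
import zipfile
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .core import Alignment, Locus, ProcessEntry, Project, SequenceRecord, Tree
from .locistats import LocusStats
from .supermatrix import Concatenation, Supermatrix

__all__ = [
    "serialize",
    "deserialize",
    "project_fingerprint",
    "projects_equal",
    "Checkpoint",
    "CheckpointStore",
    "report",
    "write_report",
    "archive",
]

FORMAT_VERSION = 1


class IntegrityError(ValueError):
    """Serialized project failed its embedded checksum or structure check."""


# -- (de)serialization ------------------------------------------------------


def _content_dict(project: Project) -> dict:
    return {
        "title": project.title,
        "loci": [
            {"name": lc.name, "aliases": sorted(lc.aliases),
             "feature_type": lc.feature_type, "char_type": lc.char_type}
            for lc in project.loci
        ],
        "records": {
            rid: {"locus_name": r.locus_name, "otu": r.otu, "sequence": r.sequence,
                  "metadata": {k: str(v) for k, v in sorted(r.metadata.items())}}
            for rid, r in sorted(project.records.items())
        },
        "excluded": {
            rid: {"locus_name": r.locus_name, "otu": r.otu, "sequence": r.sequence,
                  "metadata": {k: str(v) for k, v in sorted(r.metadata.items())}}
            for rid, r in sorted(project.excluded.items())
        },
        "alignments": {
            oid: {"locus_name": a.locus_name, "rows": [list(t) for t in a.rows],
                  "produced_by": a.produced_by}
            for oid, a in sorted(project.alignments.items())
        },
        "trimmed": {
            oid: {"locus_name": a.locus_name, "rows": [list(t) for t in a.rows],
                  "produced_by": a.produced_by}
            for oid, a in sorted(project.trimmed.items())
        },
        "trees": {
            oid: {"newick": t.newick, "leaf_map": dict(sorted(t.leaf_map.items())),
                  "produced_by": t.produced_by, "annotations": t.annotations,
                  "rooted": t.rooted}
            for oid, t in sorted(project.trees.items())
        },
        "concatenations": {
            name: {"locus_names": c.locus_names, "otu_field": c.otu_field,
                   "rules": c.rules, "produced_by": c.produced_by}
            for name, c in sorted(project.concatenations.items())
        },
        "supermatrices": {
            name: {"rows": dict(sorted(m.rows.items())),
                   "partitions": [list(p) for p in m.partitions],
                   "occupancy": {o: dict(sorted(v.items()))
                                 for o, v in sorted(m.occupancy.items())},
                   "produced_by": m.produced_by}
            for name, m in sorted(project.supermatrices.items())
        },
        "stats": {
            name: {
                "column_entropy": _arr(s.column_entropy),
                "column_gap_score": _arr(s.column_gap_score),
                "column_conservation": _arr(s.column_conservation),
                "record_lengths": _arr(s.record_lengths),
                "record_gc": _arr(s.record_gc),
                "summaries": s.summaries,
            }
            for name, s in sorted(project.stats.items())
        },
        "ledger": [asdict(e) for e in project.ledger],
        "selected_loci": project.selected_loci,
        "serials": {"process": project._serial, "record": project._record_serial},
    }


def _arr(a) -> list:
    return [None if np.isnan(x) else float(x) for x in np.asarray(a, dtype=float)]


def _canonical_json(content: dict) -> str:
    return json.dumps(content, sort_keys=True, separators=(",", ":"), allow_nan=False)


def project_fingerprint(project: Project) -> str:
    """Content hash of the project; identical content ⇒ identical hash.

    Ledger timestamps are wall-clock bookkeeping, not scientific content:
    they are blanked before hashing so that two replays of the same
    operations on the same inputs address the same checkpoint object.
    """
    content = _content_dict(project)
    content["ledger"] = [
        {**entry, "timestamp": ""} for entry in content["ledger"]
    ]
    return hashlib.sha256(_canonical_json(content).encode()).hexdigest()


def projects_equal(a: Project, b: Project) -> bool:
    return _content_dict(a) == _content_dict(b)


def serialize(project: Project, path: str | Path) -> Path:
    """Write the whole project to one self-describing JSON file."""
    path = Path(path)
    content = _content_dict(project)
    payload = _canonical_json(content)
    document = {
        "phyloprov_format": FORMAT_VERSION,
        "checksum": hashlib.sha256(payload.encode()).hexdigest(),
        "content": content,
    }
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(document, sort_keys=True, indent=1))
    return path


def deserialize(path: str | Path) -> Project:
    """Load a serialized project, verifying the embedded checksum."""
    try:
        document = json.loads(Path(path).read_text())
    except (json.JSONDecodeError, OSError) as exc:
        raise IntegrityError(f"cannot read serialized project {path}: {exc}") from exc
    if not isinstance(document, dict) or "content" not in document:
        raise IntegrityError(f"{path} is not a serialized project")
    content = document["content"]
    digest = hashlib.sha256(_canonical_json(content).encode()).hexdigest()
    if digest != document.get("checksum"):
        raise IntegrityError(f"{path}: checksum mismatch; file is corrupt or edited")
    return _from_content(content)


def _from_content(content: dict) -> Project:
    project = Project(title=content["title"])
    for lc in content["loci"]:
        project.loci.append(Locus(name=lc["name"], aliases=set(lc["aliases"]),
                                  feature_type=lc["feature_type"], char_type=lc["char_type"]))
    for bin_name in ("records", "excluded"):
        pool = getattr(project, bin_name)
        for rid, r in content[bin_name].items():
            pool[rid] = SequenceRecord(record_id=rid, locus_name=r["locus_name"],
                                       otu=r["otu"], sequence=r["sequence"],
                                       metadata=dict(r["metadata"]))
    for bin_name in ("alignments", "trimmed"):
        pool = getattr(project, bin_name)
        for oid, a in content[bin_name].items():
            pool[oid] = Alignment(object_id=oid, locus_name=a["locus_name"],
                                  rows=[tuple(t) for t in a["rows"]],
                                  produced_by=a["produced_by"])
    for oid, t in content["trees"].items():
        project.trees[oid] = Tree(object_id=oid, newick=t["newick"],
                                  leaf_map=dict(t["leaf_map"]),
                                  produced_by=t["produced_by"],
                                  annotations=t.get("annotations", {}),
                                  rooted=t.get("rooted", False))
    for name, c in content["concatenations"].items():
        project.concatenations[name] = Concatenation(
            name=name, locus_names=list(c["locus_names"]), otu_field=c["otu_field"],
            rules=dict(c["rules"]), produced_by=c["produced_by"])
    for name, m in content["supermatrices"].items():
        project.supermatrices[name] = Supermatrix(
            name=name, rows=dict(m["rows"]),
            partitions=[tuple(p) for p in m["partitions"]],
            occupancy={o: dict(v) for o, v in m["occupancy"].items()},
            produced_by=m["produced_by"])
    for name, s in content["stats"].items():
        project.stats[name] = LocusStats(
            locus_name=name,
            column_entropy=_unarr(s["column_entropy"]),
            column_gap_score=_unarr(s["column_gap_score"]),
            column_conservation=_unarr(s["column_conservation"]),
            record_lengths=_unarr(s["record_lengths"]),
            record_gc=_unarr(s["record_gc"]),
            summaries={k: dict(v) for k, v in s["summaries"].items()})
    project.ledger = [ProcessEntry(**e) for e in content["ledger"]]
    project.selected_loci = content["selected_loci"]
    project._serial = content["serials"]["process"]
    project._record_serial = content["serials"]["record"]
    return project


def _unarr(values: list) -> np.ndarray:
    return np.array([np.nan if v is None else v for v in values], dtype=float)


# -- checkpoint store -------------------------------------------------------


@dataclass
class Checkpoint:
    """One saved state: content hash, parent link, message, timestamp."""

    checkpoint_id: str
    parent_id: str | None
    message: str
    timestamp: str


class CheckpointStore:
    """Append-only content-addressed store of whole-project states.

    Layout: ``objects/<hash>`` hold serialized projects; ``chain.jsonl``
    is the linear checkpoint history.  Saving an unchanged project is a
    no-op returning the head checkpoint.
    """

    def __init__(self, path: str | Path):
        self.path = Path(path)
        (self.path / "objects").mkdir(parents=True, exist_ok=True)
        self.chain_file = self.path / "chain.jsonl"

    def chain(self) -> list[Checkpoint]:
        if not self.chain_file.exists():
            return []
        return [
            Checkpoint(**json.loads(line))
            for line in self.chain_file.read_text().splitlines()
            if line.strip()
        ]

    def head(self) -> Checkpoint | None:
        chain = self.chain()
        return chain[-1] if chain else None

    def checkpoint(self, project: Project, message: str = "") -> Checkpoint:
        checkpoint_id = project_fingerprint(project)
        head = self.head()
        if head is not None and head.checkpoint_id == checkpoint_id:
            return head
        serialize(project, self.path / "objects" / checkpoint_id)
        entry = Checkpoint(
            checkpoint_id=checkpoint_id,
            parent_id=head.checkpoint_id if head else None,
            message=message,
            timestamp=datetime.datetime.now(datetime.timezone.utc).isoformat(),
        )
        with self.chain_file.open("a") as fh:
            fh.write(json.dumps(asdict(entry)) + "\n")
        return entry

    def restore(self, checkpoint_id: str) -> Project:
        target = self.path / "objects" / checkpoint_id
        if not target.exists():
            known = [c.checkpoint_id[:12] for c in self.chain()]
            raise KeyError(
                f"unknown checkpoint {checkpoint_id[:12]}; available: {known}"
            )
        return deserialize(target)


# -- report -----------------------------------------------------------------


def _environment_lines() -> list[str]:
    import Bio
    import pandas
    import scipy

    return [
        f"- Platform: {platform.platform()}",
        f"- Python: {platform.python_version()}",
        f"- numpy {np.__version__}, scipy {scipy.__version__}, "
        f"pandas {pandas.__version__}, biopython {Bio.__version__}",
    ]


def report(project: Project) -> str:
    """Methods-section-ready Markdown report assembled from the ledger."""
    lines = [f"# Project report: {project.title}", ""]
    lines.append(
        f"_Generated {datetime.datetime.now(datetime.timezone.utc).isoformat()}_"
    )
    lines += ["", "## Environment", ""] + _environment_lines()

    lines += ["", "## Data", ""]
    lines.append(f"- Loci defined: {len(project.loci)} "
                 f"({', '.join(lc.name for lc in project.loci[:10])}"
                 f"{'…' if len(project.loci) > 10 else ''})")
    lines.append(f"- Records: {len(project.records)} kept, {len(project.excluded)} excluded")
    accessions = sorted({
        str(r.metadata["accession"]) for r in project.records.values()
        if "accession" in r.metadata
    })
    if accessions:
        lines.append(f"- Accessions: {', '.join(accessions[:50])}"
                     f"{'…' if len(accessions) > 50 else ''}")

    lines += ["", "## Methods", ""]
    for entry in project.ledger:
        params = ", ".join(
            f"{k}={v}" for k, v in entry.parameters.items()
            if not isinstance(v, (list, dict)) or len(str(v)) < 60
        )
        lines.append(
            f"- `{entry.process_id}` — {entry.operation} using {entry.tool}"
            + (f" ({params})" if params else "")
        )

    if project.stats or project.supermatrices or project.trees:
        lines += ["", "## Results", ""]
    if project.stats:
        lines.append(f"- Per-locus statistics computed for {len(project.stats)} loci")
    for name, matrix in sorted(project.supermatrices.items()):
        lines.append(
            f"- Supermatrix `{name}`: {len(matrix.rows)} OTUs × "
            f"{matrix.total_length} columns, {len(matrix.partitions)} partitions, "
            f"{matrix.missing_cells} missing cells"
        )
    if project.trees:
        lines.append(f"- Trees: {len(project.trees)} "
                     f"({', '.join(sorted(project.trees)[:8])})")
    return "\n".join(lines) + "\n"


def write_report(project: Project, directory: str | Path) -> tuple[Path, Path]:
    """Write report.md and a minimal standalone report.html."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    md = report(project)
    md_path = directory / "report.md"
    md_path.write_text(md)
    html = "<html><head><meta charset='utf-8'><title>{}</title></head><body><pre>{}</pre></body></html>".format(
        project.title,
        md.replace("&", "&amp;").replace("<", "&lt;").replace(">", "&gt;"),
    )
    html_path = directory / "report.html"
    html_path.write_text(html)
    return md_path, html_path


# -- archive ----------------------------------------------------------------


def archive(project: Project, path: str | Path, store: CheckpointStore | None = None) -> Path:
    """Package the experiment into one zip for a data repository.

    Contents: the serialized project, per-locus alignments (FASTA),
    trees (Newick + PhyloXML), supermatrices with partition files and
    occupancy tables, the report, the checkpoint chain listing, and a
    manifest of SHA-256 checksums covering every member.
    """
    import tempfile

    from . import io as pio
    from .supermatrix import occupancy_table

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    members: dict[str, bytes] = {}

    with tempfile.TemporaryDirectory() as tmp:
        tmp = Path(tmp)
        serialize(project, tmp / "project.json")
        members["project.json"] = (tmp / "project.json").read_bytes()

        if project.alignments or project.trimmed:
            for f in pio.write(project, "alignments", "fasta", tmp / "alignments", _log=False):
                members[f"alignments/{f.name}"] = f.read_bytes()
        if project.trees:
            for f in pio.write(project, "trees", "newick", tmp / "trees", _log=False):
                members[f"trees/{f.name}"] = f.read_bytes()
            for f in pio.write(project, "trees", "phyloxml", tmp / "trees_xml", _log=False):
                members[f"trees/{f.name}"] = f.read_bytes()
        if project.supermatrices:
            for f in pio.write(project, "supermatrix", "fasta", tmp / "supermatrices", _log=False):
                members[f"supermatrices/{f.name}"] = f.read_bytes()
            for name, matrix in sorted(project.supermatrices.items()):
                table, _, _ = occupancy_table(matrix)
                members[f"supermatrices/{name}.occupancy.tsv"] = table.to_csv(
                    sep="\t"
                ).encode()
        md_path, html_path = write_report(project, tmp / "report")
        members["report.md"] = md_path.read_bytes()
        members["report.html"] = html_path.read_bytes()
        if store is not None:
            members["chain.jsonl"] = (
                store.chain_file.read_bytes() if store.chain_file.exists() else b""
            )

    manifest = {
        name: hashlib.sha256(blob).hexdigest() for name, blob in members.items()
    }
    members["manifest.json"] = json.dumps(manifest, sort_keys=True, indent=1).encode()

    with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
        for name in sorted(members):
            zf.writestr(name, members[name])
    return path
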