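"""Alignment, trimming and tree-building stages with batch semantics.

Batch commands act on every relevant dataset in scope: ``align`` touches
all unaligned selected loci, ``trim`` every alignment, ``tree`` every
trimmed (or raw) alignment.  Native fallbacks — equal-length pass-through
registration, a gap-threshold column trimmer and neighbor joining on p or
JC69 distances — make the full pipeline runnable with no external
binaries; production aligners and tree builders (MAFFT, TrimAl, RAxML…)
plug in through :func:`run_external` adapters whose tool name and version
are captured in the ledger.
"""

from __future__ import annotations

import math
import shlex
import subprocess
import warnings
from dataclasses import dataclass, field
from pathlib import Path

from .core import GAP_CHARS, Alignment, Project, Tree, UnknownIdError

__all__ = [
    "StageConf",
    "align",
    "trim_gap_threshold",
    "trim",
    "nj_tree",
    "build_trees",
    "run_external",
    "register_pass_through_alignment",
]


@dataclass
class StageConf:
    """Configuration of one analytic step (align / trim / tree)."""

    stage: str
    method: str = "native"
    parameters: dict = field(default_factory=dict)
    scope: list[str] | None = None  # locus names or object ids; None = all

    def __post_init__(self) -> None:
        if self.stage not in ("align", "trim", "tree"):
            raise ValueError(f"unknown stage {self.stage!r}")


def _in_scope(project: Project, conf: StageConf) -> list[str]:
    names = project.locus_names()
    if conf.scope is None:
        return names
    resolved = [project.find_locus(n).name for n in conf.scope]
    return [n for n in names if n in resolved]


def register_pass_through_alignment(project: Project, locus_name: str, pid: str) -> Alignment:
    """Register already-aligned (equal-length) records as an Alignment."""
    records = sorted(project.records_for_locus(locus_name), key=lambda r: r.record_id)
    if not records:
        raise ValueError(f"locus {locus_name!r} has no records to align")
    lengths = {r.length for r in records}
    if len(lengths) > 1:
        raise ValueError(
            f"locus {locus_name!r}: records have unequal lengths {sorted(lengths)}; "
            "configure an external aligner"
        )
    aln = Alignment(
        object_id=f"{pid}_{locus_name}",
        locus_name=locus_name,
        rows=[(r.record_id, r.sequence) for r in records],
        produced_by=pid,
    )
    project.alignments[aln.object_id] = aln
    return aln


def align(project: Project, conf: StageConf) -> list[str]:
    """Align every in-scope locus that has no alignment yet.

    With ``method='native'`` records must already be of equal length
    (pre-aligned input) and are registered as-is; otherwise the named
    adapter runs.  Returns new alignment ids; loci already aligned are
    skipped, so repeating the command is a no-op.
    """
    if conf.stage != "align":
        raise ValueError("conf.stage must be 'align'")
    aligned_loci = {a.locus_name for a in project.alignments.values()}
    todo = [n for n in _in_scope(project, conf) if n not in aligned_loci
            and project.records_for_locus(n)]
    if not todo:
        warnings.warn("align: no unaligned loci in scope")
        project.log("align", {"method": conf.method, "new": []})
        return []
    pid = project.next_process_id("align")
    new_ids = []
    if conf.method == "native":
        for locus_name in todo:
            new_ids.append(register_pass_through_alignment(project, locus_name, pid).object_id)
        tool = "phyloprov pass-through (pre-aligned input)"
    else:
        adapter = conf.parameters.get("adapter")
        if adapter is None:
            raise ValueError(f"align method {conf.method!r} needs an 'adapter' parameter")
        tool = None
        for locus_name in todo:
            out_ids, tool = _run_adapter_on_locus(project, adapter, locus_name, pid)
            new_ids.extend(out_ids)
    project.log(
        "align",
        {"method": conf.method, "loci": todo, "new": new_ids},
        tool=tool,
        output_ids=new_ids,
        process_id=pid,
    )
    return new_ids


def trim_gap_threshold(project: Project, alignment: Alignment, gt: float) -> Alignment:
    """Keep only columns whose non-gap fraction is at least ``gt``.

    ``gt=0`` is the identity, ``gt=1`` keeps only gap-free columns, and
    kept-column sets shrink monotonically as ``gt`` grows.  Column order
    is preserved.  A result with zero columns is an error advising a
    lower threshold.
    """
    if not 0 <= gt <= 1:
        raise ValueError(f"gap threshold must be in [0, 1], got {gt}")
    n_rows = len(alignment.rows)
    keep = [
        i
        for i, col in enumerate(alignment.columns())
        if sum(1 for c in col if c not in GAP_CHARS) / n_rows >= gt
    ]
    if not keep:
        raise ValueError(
            f"gap threshold {gt} removes every column of {alignment.object_id}; "
            "lower the threshold"
        )
    pid = project.next_process_id("trim")
    trimmed = Alignment(
        object_id=f"{pid}_{alignment.locus_name}",
        locus_name=alignment.locus_name,
        rows=[(rid, "".join(seq[i] for i in keep)) for rid, seq in alignment.rows],
        produced_by=pid,
    )
    project.trimmed[trimmed.object_id] = trimmed
    project.log(
        "trim",
        {"gap_threshold": gt, "columns_kept": len(keep), "columns_in": alignment.length},
        input_ids=[alignment.object_id],
        output_ids=[trimmed.object_id],
        process_id=pid,
    )
    return trimmed


def trim(project: Project, conf: StageConf) -> list[str]:
    """Batch gap-threshold trimming of all in-scope alignments."""
    if conf.stage != "trim":
        raise ValueError("conf.stage must be 'trim'")
    gt = conf.parameters.get("gap_threshold", 0.5)
    scope = set(_in_scope(project, conf))
    done = {a.locus_name for a in project.trimmed.values()}
    new_ids = []
    for aln in list(project.alignments.values()):
        if aln.locus_name in scope and aln.locus_name not in done:
            new_ids.append(trim_gap_threshold(project, aln, gt).object_id)
    return new_ids


# -- distances and neighbor joining ----------------------------------------

def _pairwise_p(seq1: str, seq2: str) -> float:
    """p-distance over sites where both rows hold unambiguous residues."""
    import numpy as np

    a = np.frombuffer(seq1.upper().encode(), dtype="S1")
    b = np.frombuffer(seq2.upper().encode(), dtype="S1")
    dna = np.array([b"A", b"C", b"G", b"T"])
    ok = np.isin(a, dna) & np.isin(b, dna)
    total = int(ok.sum())
    if total == 0:
        raise ValueError("no comparable (unambiguous, ungapped) sites between sequences")
    return int((a[ok] != b[ok]).sum()) / total


def _distance(seq1: str, seq2: str, model: str, pair: tuple[str, str]) -> float:
    p = _pairwise_p(seq1, seq2)
    if model == "p":
        return p
    if model == "JC69":
        if p >= 0.75:
            raise ValueError(
                f"JC69 distance undefined for pair {pair}: p-distance {p:.3f} >= 3/4"
            )
        return -0.75 * math.log1p(-4.0 * p / 3.0)
    raise ValueError(f"unknown distance model {model!r}; choose 'p' or 'JC69'")


def nj_tree(project: Project, alignment: Alignment, model: str = "JC69") -> Tree:
    """Neighbor-joining tree from pairwise p or JC69 distances.

    Rows are ordered lexicographically by record id before joining, so
    ties (e.g. identical sequences, all-zero distances) resolve
    deterministically.  Negative NJ branch lengths are clamped to zero
    with the deficit transferred to the sibling branch.
    """
    from Bio.Phylo.TreeConstruction import DistanceMatrix as BioDM
    from Bio.Phylo.TreeConstruction import DistanceTreeConstructor

    rows = sorted(alignment.rows)
    if len(rows) < 3:
        raise ValueError("neighbor joining needs at least 3 sequences")
    ids = [rid for rid, _ in rows]
    matrix = [
        [_distance(rows[i][1], rows[j][1], model, (ids[i], ids[j])) for j in range(i)] + [0.0]
        for i in range(len(rows))
    ]
    nj = DistanceTreeConstructor().nj(BioDM(names=ids, matrix=matrix))
    for clade in nj.find_clades():
        clade.confidence = None
        if not clade.is_terminal():
            clade.name = None  # drop the constructor's InnerN labels
    _clamp_negative_lengths(nj)
    import io as _io

    from Bio import Phylo

    buf = _io.StringIO()
    Phylo.write(nj, buf, "newick", plain=False)
    pid = project.next_process_id("tree")
    tree = Tree(
        object_id=f"{pid}_{alignment.locus_name}",
        newick=buf.getvalue().strip(),
        leaf_map={rid: rid for rid in ids},
        produced_by=pid,
    )
    project.trees[tree.object_id] = tree
    project.log(
        "tree",
        {"method": "nj", "model": model},
        input_ids=[alignment.object_id],
        output_ids=[tree.object_id],
        process_id=pid,
    )
    return tree


def _clamp_negative_lengths(ptree) -> None:
    for parent in ptree.find_clades():
        kids = parent.clades
        for child in kids:
            bl = child.branch_length
            if bl is not None and bl < 0:
                siblings = [c for c in kids if c is not child and c.branch_length is not None]
                if siblings:
                    siblings[0].branch_length = max(0.0, siblings[0].branch_length + bl)
                child.branch_length = 0.0


def build_trees(project: Project, conf: StageConf) -> list[str]:
    """Batch tree building over all in-scope alignments (trimmed preferred)."""
    if conf.stage != "tree":
        raise ValueError("conf.stage must be 'tree'")
    model = conf.parameters.get("model", "JC69")
    new_ids = []
    for locus_name in _in_scope(project, conf):
        try:
            aln = project.alignment_for_locus(locus_name)
        except UnknownIdError:
            continue
        if len(aln.rows) < 3:
            continue
        new_ids.append(nj_tree(project, aln, model).object_id)
    return new_ids


# -- external-tool adapters -------------------------------------------------


def probe_version(adapter: dict) -> str:
    """Run the adapter's version probe; raise before execution if it fails."""
    probe = adapter.get("version_probe")
    if not probe:
        return adapter.get("version", "unknown")
    try:
        result = subprocess.run(
            shlex.split(probe), capture_output=True, text=True, timeout=60
        )
    except (OSError, subprocess.TimeoutExpired) as exc:
        raise RuntimeError(f"adapter {adapter.get('name')}: version probe failed: {exc}")
    if result.returncode != 0:
        raise RuntimeError(
            f"adapter {adapter.get('name')}: version probe exited "
            f"{result.returncode}: {result.stderr.strip()}"
        )
    return (result.stdout or result.stderr).strip().splitlines()[0]


def _run_adapter_on_locus(project, adapter, locus_name, pid):
    workdir = Path(adapter.get("workdir", "scratch/adapters")) / pid
    out_ids = run_external(
        project,
        StageConf(
            stage=adapter.get("stage", "align"),
            method=adapter["name"],
            parameters={"adapter": adapter, "locus": locus_name, "workdir": str(workdir)},
        ),
        _log=False,
        _pid=pid,
    )
    return out_ids, adapter.get("_version", adapter.get("name"))


def run_external(
    project: Project,
    conf: StageConf,
    _log: bool = True,
    _pid: str | None = None,
) -> list[str]:
    """Invoke an external tool through its adapter and parse results back.

    The adapter dict declares: ``name``, ``command`` (template with
    ``{in}``, ``{out}`` and optional ``{params}`` placeholders),
    ``version_probe``, ``stage`` (align or tree) and ``output_format``
    (fasta or newick).  Inputs are written to a scratch directory, the
    command runs, captured stdout/stderr are archived next to the files,
    and outputs are registered as project objects.  The probed version
    string lands in the ledger entry.
    """
    from Bio import AlignIO

    adapter = conf.parameters["adapter"]
    version = probe_version(adapter)
    adapter["_version"] = f"{adapter['name']} {version}"
    locus_name = conf.parameters.get("locus")
    workdir = Path(conf.parameters.get("workdir", "scratch/adapters"))
    workdir.mkdir(parents=True, exist_ok=True)

    stage = adapter.get("stage", conf.stage)
    in_path = workdir / "input.fasta"
    out_format = adapter.get("output_format", "fasta" if stage == "align" else "newick")
    out_path = workdir / ("output.fasta" if out_format == "fasta" else "output.nwk")

    if stage == "align":
        records = sorted(project.records_for_locus(locus_name), key=lambda r: r.record_id)
        in_path.write_text(
            "".join(f">{r.record_id}\n{r.sequence}\n" for r in records)
        )
        input_ids = [r.record_id for r in records]
    else:
        aln = project.alignment_for_locus(locus_name)
        in_path.write_text(
            "".join(f">{rid}\n{seq}\n" for rid, seq in aln.rows)
        )
        input_ids = [aln.object_id]

    command = adapter["command"].format(
        **{"in": str(in_path), "out": str(out_path),
           "params": adapter.get("params", "")}
    )
    result = subprocess.run(
        command, shell=True, capture_output=True, text=True,
        timeout=adapter.get("timeout", 3600),
    )
    (workdir / "stdout.txt").write_text(result.stdout)
    (workdir / "stderr.txt").write_text(result.stderr)
    if result.returncode != 0:
        raise RuntimeError(
            f"adapter {adapter['name']} exited {result.returncode}; stderr: "
            f"{result.stderr.strip()[:500]}"
        )
    if not out_path.exists():
        candidates = [p for p in workdir.iterdir() if p.name.startswith("output")]
        if not candidates:
            raise RuntimeError(
                f"adapter {adapter['name']} produced no output; inspect {workdir}"
            )
        out_path = candidates[0]

    pid = _pid or project.next_process_id(stage)
    out_ids: list[str] = []
    if out_format == "fasta":
        try:
            bio_aln = AlignIO.read(str(out_path), "fasta")
        except ValueError as exc:
            raise RuntimeError(
                f"adapter {adapter['name']}: unparseable output retained at {out_path}: {exc}"
            )
        aln = Alignment(
            object_id=f"{pid}_{locus_name}",
            locus_name=locus_name,
            rows=[(rec.id, str(rec.seq)) for rec in bio_aln],
            produced_by=pid,
        )
        project.alignments[aln.object_id] = aln
        out_ids.append(aln.object_id)
    else:
        newick = out_path.read_text().strip()
        if not newick.endswith(";"):
            raise RuntimeError(
                f"adapter {adapter['name']}: unparseable tree retained at {out_path}"
            )
        from . import treecmp

        treecmp.bipartitions(newick)  # validates parse + leaf uniqueness
        tree = Tree(
            object_id=f"{pid}_{locus_name}",
            newick=newick,
            leaf_map={},
            produced_by=pid,
        )
        leaves, _ = treecmp.bipartitions(newick)
        tree.leaf_map = {leaf: leaf for leaf in leaves}
        project.trees[tree.object_id] = tree
        out_ids.append(tree.object_id)

    if _log:
        project.log(
            stage,
            {"adapter": adapter["name"], "command": command, "locus": locus_name},
            tool=adapter["_version"],
            input_ids=input_ids,
            output_ids=out_ids,
            process_id=pid,
        )
    return out_ids
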