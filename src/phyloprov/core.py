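"""Project container and identifier scheme.

A :class:`Project` is the single in-memory object threading a multilocus
phylogenomic experiment: locus definitions, harvested sequence records,
alignments (raw and trimmed), trees, supermatrix recipes and their realized
matrices, per-locus statistics, and an append-only provenance ledger.  Every
data object carries a stable unique identifier and every mutating operation
appends exactly one :class:`ProcessEntry`, so the origin of any object can be
traced back through tool names, versions and parameters.
"""

from __future__ import annotations

import copy
import datetime
import difflib
import re
from dataclasses import dataclass, field
from typing import Any, Callable, Iterable, Mapping

__all__ = [
    "Locus",
    "SequenceRecord",
    "Alignment",
    "Tree",
    "ProcessEntry",
    "Project",
    "create_project",
    "fetch",
    "edit_metadata",
    "fold_alias",
    "LocusCollisionError",
    "UnknownIdError",
]

GAP_CHARS = frozenset("-?.")

_FOLD_RE = re.compile(r"[_\-\s]+")


def fold_alias(name: str) -> str:
    """Normalize a locus name or alias for matching.

    Folding is case-insensitive and ignores underscores, hyphens and
    whitespace, so GenBank variants like ``cox1``, ``COX-1`` and ``COI``
    aliases declared by the user all resolve to the same locus bin.
    """
    return _FOLD_RE.sub("", name.strip().lower())


def _jsonable(value):
    """Coerce ledger parameter values to JSON-safe structures.

    Sets become sorted lists, tuples become lists, non-finite floats and
    unknown objects become strings, numpy scalars become Python scalars.
    """
    import math as _math

    if isinstance(value, dict):
        return {str(k): _jsonable(v) for k, v in value.items()}
    if isinstance(value, (set, frozenset)):
        return sorted(str(v) for v in value)
    if isinstance(value, (list, tuple)):
        return [_jsonable(v) for v in value]
    if isinstance(value, bool) or value is None:
        return value
    if isinstance(value, (int, str)):
        return value
    if isinstance(value, float):
        return value if _math.isfinite(value) else str(value)
    if hasattr(value, "item"):  # numpy scalar
        return _jsonable(value.item())
    return str(value)


class LocusCollisionError(ValueError):
    """Two loci claim the same folded name or alias."""


class UnknownIdError(KeyError):
    """An object id does not resolve; carries near-match suggestions."""

    def __init__(self, object_id: str, candidates: Iterable[str]):
        near = difflib.get_close_matches(object_id, list(candidates), n=3)
        msg = f"unknown object id {object_id!r}"
        if near:
            msg += f"; did you mean one of {near}?"
        super().__init__(msg)
        self.object_id = object_id
        self.near_matches = near


@dataclass
class Locus:
    """Descriptor of one analysed locus: name, synonyms, feature and char type.

    ``aliases`` are alternative names under which the locus appears in
    GenBank ``gene``/``product`` qualifiers; matching uses :func:`fold_alias`.
    """

    name: str
    aliases: set[str] = field(default_factory=set)
    feature_type: str = "CDS"
    char_type: str = "dna"  # "dna" | "protein"

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("locus name must be non-empty")
        if self.char_type not in ("dna", "protein"):
            raise ValueError(f"char_type must be 'dna' or 'protein', got {self.char_type!r}")
        self.aliases = set(self.aliases)

    def folded_keys(self) -> set[str]:
        return {fold_alias(self.name)} | {fold_alias(a) for a in self.aliases}

    def matches(self, name: str) -> bool:
        return fold_alias(name) in self.folded_keys()


@dataclass
class SequenceRecord:
    """One ungapped sequence assigned to a locus bin.

    ``otu`` holds the value of the OTU-defining metadata field (by default
    the source organism); ``metadata`` carries accession, description and
    source qualifiers as plain strings.
    """

    record_id: str
    locus_name: str
    otu: str
    sequence: str
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = set(self.sequence) & GAP_CHARS
        if bad:
            raise ValueError(
                f"record {self.record_id}: sequence must be ungapped, found {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class Alignment:
    """A gapped multiple sequence alignment of one locus.

    ``rows`` preserves input order as ``(record_id, gapped_sequence)`` pairs;
    all rows share the same column count.
    """

    object_id: str
    locus_name: str
    rows: list[tuple[str, str]]
    produced_by: str = ""

    def __post_init__(self) -> None:
        lengths = {len(s) for _, s in self.rows}
        if len(lengths) > 1:
            raise ValueError(f"alignment {self.object_id}: ragged rows, lengths {sorted(lengths)}")

    @property
    def length(self) -> int:
        return len(self.rows[0][1]) if self.rows else 0

    @property
    def record_ids(self) -> list[str]:
        return [rid for rid, _ in self.rows]

    def row(self, record_id: str) -> str:
        for rid, seq in self.rows:
            if rid == record_id:
                return seq
        raise UnknownIdError(record_id, self.record_ids)

    def columns(self) -> list[str]:
        return ["".join(col) for col in zip(*(seq for _, seq in self.rows))]


@dataclass
class Tree:
    """A phylogenetic tree stored as Newick plus a leaf resolution map.

    ``leaf_map`` maps every leaf label in the Newick string to a record id
    or OTU name known to the project.
    """

    object_id: str
    newick: str
    leaf_map: dict[str, str] = field(default_factory=dict)
    produced_by: str = ""
    annotations: dict[str, dict[str, Any]] = field(default_factory=dict)
    rooted: bool = False

    @property
    def tree_length(self) -> float:
        """Sum of all branch lengths in the Newick string."""
        from . import treecmp

        return treecmp.tree_length(self.newick)


@dataclass
class ProcessEntry:
    """One provenance ledger entry: what ran, on what, producing what."""

    process_id: str
    operation: str
    parameters: dict[str, Any] = field(default_factory=dict)
    tool: str = "phyloprov (native)"
    timestamp: str = ""
    input_ids: list[str] = field(default_factory=list)
    output_ids: list[str] = field(default_factory=list)


class Project:
    """Container for input, intermediate and output datasets plus metadata.

    All mutation goes through methods that append a :class:`ProcessEntry`;
    the ledger is therefore a complete, ordered provenance record and its
    length equals the number of mutating operations plus one (creation).
    """

    def __init__(self, title: str = "untitled"):
        self.title = title
        self.loci: list[Locus] = []
        self.records: dict[str, SequenceRecord] = {}
        self.excluded: dict[str, SequenceRecord] = {}
        self.alignments: dict[str, Alignment] = {}
        self.trimmed: dict[str, Alignment] = {}
        self.trees: dict[str, Tree] = {}
        self.concatenations: dict[str, Any] = {}
        self.supermatrices: dict[str, Any] = {}
        self.stats: dict[str, Any] = {}
        self.ledger: list[ProcessEntry] = []
        self.selected_loci: list[str] | None = None  # None = all loci selected
        self._serial = 0
        self._record_serial = 0

    # -- identifier scheme -------------------------------------------------

    def next_process_id(self, operation: str) -> str:
        self._serial += 1
        return f"{self._serial:04d}_{operation}"

    def next_record_serial(self) -> int:
        self._record_serial += 1
        return self._record_serial

    def log(
        self,
        operation: str,
        parameters: Mapping[str, Any] | None = None,
        tool: str = "phyloprov (native)",
        input_ids: Iterable[str] = (),
        output_ids: Iterable[str] = (),
        process_id: str | None = None,
    ) -> ProcessEntry:
        """Append one ledger entry and return it.

        ``process_id`` may be pre-drawn with :meth:`next_process_id` when
        output object ids need to embed it before the entry is written.
        """
        entry = ProcessEntry(
            process_id=process_id or self.next_process_id(operation),
            operation=operation,
            parameters=_jsonable(dict(parameters or {})),
            tool=tool,
            timestamp=datetime.datetime.now(datetime.timezone.utc).isoformat(),
            input_ids=list(input_ids),
            output_ids=list(output_ids),
        )
        self.ledger.append(entry)
        return entry

    # -- locus bookkeeping -------------------------------------------------

    def add_locus(self, locus: Locus, _log: bool = True) -> None:
        taken: dict[str, str] = {}
        for existing in self.loci:
            for key in existing.folded_keys():
                taken[key] = existing.name
        for key in locus.folded_keys():
            if key in taken:
                raise LocusCollisionError(
                    f"locus {locus.name!r} collides with locus {taken[key]!r} on key {key!r}"
                )
        self.loci.append(locus)
        if _log:
            self.log("add_locus", {"name": locus.name, "aliases": sorted(locus.aliases)})

    def find_locus(self, name: str) -> Locus:
        for locus in self.loci:
            if locus.matches(name):
                return locus
        raise UnknownIdError(name, [lc.name for lc in self.loci])

    def locus_names(self, selected_only: bool = True) -> list[str]:
        names = [lc.name for lc in self.loci]
        if selected_only and self.selected_loci is not None:
            sel = set(self.selected_loci)
            names = [n for n in names if n in sel]
        return names

    # -- record / object access --------------------------------------------

    def records_for_locus(self, locus_name: str) -> list[SequenceRecord]:
        locus = self.find_locus(locus_name)
        return [r for r in self.records.values() if r.locus_name == locus.name]

    def add_record(self, record: SequenceRecord) -> None:
        if record.record_id in self.records or record.record_id in self.excluded:
            raise ValueError(f"duplicate record id {record.record_id!r}")
        self.find_locus(record.locus_name)  # must resolve
        self.records[record.record_id] = record

    def all_object_ids(self) -> set[str]:
        ids: set[str] = set(self.records) | set(self.excluded)
        ids |= set(self.alignments) | set(self.trimmed) | set(self.trees)
        ids |= set(self.concatenations) | set(self.supermatrices)
        return ids

    def resolve(self, object_id: str):
        for pool in (
            self.records,
            self.excluded,
            self.alignments,
            self.trimmed,
            self.trees,
            self.supermatrices,
            self.concatenations,
        ):
            if object_id in pool:
                return pool[object_id]
        raise UnknownIdError(object_id, self.all_object_ids())

    def alignment_for_locus(self, locus_name: str, prefer_trimmed: bool = True) -> Alignment:
        """Latest alignment registered for a locus, trimmed-if-present by default."""
        pools = (self.trimmed, self.alignments) if prefer_trimmed else (self.alignments,)
        for pool in pools:
            hits = [a for a in pool.values() if a.locus_name == locus_name]
            if hits:
                return hits[-1]
        raise UnknownIdError(
            locus_name, [a.locus_name for a in list(self.alignments.values())]
        )

    # -- integrity ----------------------------------------------------------

    def check_referential_closure(self) -> list[str]:
        """Return a list of dangling-reference descriptions (empty = clean)."""
        problems = []
        known = self.all_object_ids()
        for aln in list(self.alignments.values()) + list(self.trimmed.values()):
            for rid, _ in aln.rows:
                if rid not in self.records and rid not in self.excluded:
                    problems.append(f"alignment {aln.object_id} references unknown record {rid}")
        otus = {r.otu for r in self.records.values()} | {r.otu for r in self.excluded.values()}
        for tree in self.trees.values():
            for leaf, target in tree.leaf_map.items():
                if target not in known and target not in otus:
                    problems.append(f"tree {tree.object_id} leaf {leaf} maps to unknown {target}")
        return problems


# -- module-level operations ----------------------------------------------


def create_project(loci: Iterable[Locus] = (), title: str = "untitled") -> Project:
    """Create an empty project with the given locus definitions.

    Raises :class:`LocusCollisionError` if any two loci share a folded
    name or alias.  The returned project's ledger holds exactly one
    creation entry.
    """
    project = Project(title=title)
    for locus in loci:
        project.add_locus(locus, _log=False)
    project.log(
        "create_project",
        {"title": title, "loci": [lc.name for lc in project.loci]},
    )
    return project


def fetch(project: Project, object_id: str):
    """Copy a project attribute into an independent variable.

    The returned object is a deep copy: mutating it never changes the
    project.  Unknown ids raise :class:`UnknownIdError` with near-matches.
    """
    return copy.deepcopy(project.resolve(object_id))


def edit_metadata(
    project: Project,
    selector: Mapping[str, Any] | None,
    field_name: str,
    value_or_rule: Any | Callable[[SequenceRecord], Any],
) -> int:
    """Programmatically edit record metadata; returns the number updated.

    ``selector`` narrows the target set: ``{"ids": [...]}``,
    ``{"locus": name}``, ``{"where": {field: value}}`` or any combination
    (conjunction).  ``None`` or ``{}`` selects every record.  ``value_or_rule``
    is either a literal value or a callable mapping the record to the new
    value.  A selector matching nothing returns 0 (not an error).
    """
    selector = dict(selector or {})
    targets = list(project.records.values())
    if "ids" in selector:
        wanted = set(selector["ids"])
        targets = [r for r in targets if r.record_id in wanted]
    if "locus" in selector:
        locus = project.find_locus(selector["locus"])
        targets = [r for r in targets if r.locus_name == locus.name]
    if "where" in selector:
        for key, val in selector["where"].items():
            targets = [
                r
                for r in targets
                if (r.otu if key == "otu" else r.metadata.get(key)) == val
            ]
    count = 0
    for record in targets:
        new_value = value_or_rule(record) if callable(value_or_rule) else value_or_rule
        if field_name == "otu":
            record.otu = new_value
        else:
            record.metadata[field_name] = new_value
        count += 1
    rule_repr = (
        getattr(value_or_rule, "__name__", repr(value_or_rule))
        if callable(value_or_rule)
        else value_or_rule
    )
    project.log(
        "edit_metadata",
        {"selector": selector, "field": field_name, "rule": rule_repr, "updated": count},
        input_ids=[r.record_id for r in targets],
    )
    return count
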