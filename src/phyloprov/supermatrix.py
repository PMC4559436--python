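"""Supermatrix recipes and their realization.

A :class:`Concatenation` is a declarative recipe: which loci, which
metadata field defines the OTUs, and which occupancy rules an OTU must
satisfy to be included.  :func:`build` realizes the recipe against the
project's per-locus alignments into a :class:`Supermatrix` — one
concatenated gapped row per OTU, with 1-based inclusive partition
intervals, an OTU × locus occupancy table and a missing-cell count.

Missing loci are filled with ``?`` so absence of data is distinguishable
from alignment gaps ``-``.  When one OTU has several records for a locus
the longest ungapped sequence wins, ties broken by lexicographic record
id, and each such choice is logged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .core import GAP_CHARS, Project, SequenceRecord, UnknownIdError

__all__ = ["Concatenation", "Supermatrix", "build", "occupancy_table", "complete_rules"]

MISSING_CHAR = "?"


def complete_rules(locus_names: list[str]) -> dict:
    """Preset requiring every OTU to have every locus (no missing data)."""
    return {"otus_must_have": list(locus_names), "min_loci_per_otu": len(locus_names)}


@dataclass
class Concatenation:
    """Recipe for a supermatrix: loci, OTU definition and occupancy rules."""

    name: str
    locus_names: list[str]
    otu_field: str = "organism"
    rules: dict = field(default_factory=lambda: {"min_loci_per_otu": 1})
    produced_by: str = ""

    def __post_init__(self) -> None:
        if not self.locus_names:
            raise ValueError(f"concatenation {self.name!r}: locus list is empty")
        if len(set(self.locus_names)) != len(self.locus_names):
            raise ValueError(f"concatenation {self.name!r}: duplicate locus names")
        must = self.rules.get("otus_must_have") or []
        extra = set(must) - set(self.locus_names)
        if extra:
            raise ValueError(
                f"concatenation {self.name!r}: otus_must_have lists loci outside "
                f"the recipe: {sorted(extra)}"
            )


@dataclass
class Supermatrix:
    """A realized concatenated alignment with partitions and occupancy."""

    name: str
    rows: dict[str, str]  # otu -> concatenated gapped sequence
    partitions: list[tuple[str, int, int]]  # (locus, start, end), 1-based inclusive
    occupancy: dict[str, dict[str, bool]]  # otu -> locus -> present
    produced_by: str = ""

    @property
    def total_length(self) -> int:
        return self.partitions[-1][2] if self.partitions else 0

    @property
    def missing_cells(self) -> int:
        return sum(1 for per_otu in self.occupancy.values() for v in per_otu.values() if not v)

    @property
    def otus(self) -> list[str]:
        return list(self.rows)

    def partition_lines(self) -> list[str]:
        """RAxML-style partition file lines, ``DNA, <name> = <start>-<end>``."""
        return [f"DNA, {name} = {start}-{end}" for name, start, end in self.partitions]


def _otu_of(record: SequenceRecord, otu_field: str) -> str | None:
    value = record.metadata.get(otu_field)
    if value is not None:
        return str(value)
    if otu_field in ("otu", "organism"):
        return record.otu
    return None


def _ungapped_len(gapped: str) -> int:
    return sum(1 for c in gapped if c not in GAP_CHARS)


def build(project: Project, concatenation: Concatenation) -> Supermatrix:
    """Realize a concatenation recipe into a supermatrix.

    Raises if a listed locus has no alignment or no OTU passes the rules.
    Registers both the recipe and the matrix on the project, with one
    ledger entry.
    """
    alignments = {}
    for locus_name in concatenation.locus_names:
        try:
            alignments[locus_name] = project.alignment_for_locus(locus_name)
        except UnknownIdError:
            raise UnknownIdError(locus_name, list(alignments)) from None

    # per locus: otu -> chosen (record_id, gapped row)
    choices: dict[str, dict[str, tuple[str, str]]] = {}
    tie_log: list[dict] = []
    for locus_name, aln in alignments.items():
        per_otu: dict[str, tuple[str, str]] = {}
        for record_id, gapped in aln.rows:
            record = project.records.get(record_id) or project.excluded.get(record_id)
            if record is None or record_id in project.excluded:
                continue
            otu = _otu_of(record, concatenation.otu_field)
            if otu is None:
                continue
            if otu in per_otu:
                cur_id, cur_row = per_otu[otu]
                new_len, cur_len = _ungapped_len(gapped), _ungapped_len(cur_row)
                # longest ungapped wins; ties go to the smaller record id
                if new_len > cur_len or (new_len == cur_len and record_id < cur_id):
                    per_otu[otu] = (record_id, gapped)
                tie_log.append(
                    {"locus": locus_name, "otu": otu, "kept": per_otu[otu][0]}
                )
            else:
                per_otu[otu] = (record_id, gapped)
        choices[locus_name] = per_otu

    all_otus = sorted({otu for per_otu in choices.values() for otu in per_otu})
    must_have = concatenation.rules.get("otus_must_have") or []
    min_loci = concatenation.rules.get("min_loci_per_otu", 1)
    kept_otus = [
        otu
        for otu in all_otus
        if all(otu in choices[lc] for lc in must_have)
        and sum(1 for lc in concatenation.locus_names if otu in choices[lc]) >= min_loci
    ]
    if not kept_otus:
        raise ValueError(
            f"concatenation {concatenation.name!r}: no OTU satisfies the rules "
            f"(candidates: {all_otus[:5]}...)"
        )

    partitions: list[tuple[str, int, int]] = []
    rows = {otu: [] for otu in kept_otus}
    occupancy: dict[str, dict[str, bool]] = {otu: {} for otu in kept_otus}
    cursor = 0
    for locus_name in concatenation.locus_names:
        width = alignments[locus_name].length
        partitions.append((locus_name, cursor + 1, cursor + width))
        cursor += width
        for otu in kept_otus:
            if otu in choices[locus_name]:
                rows[otu].append(choices[locus_name][otu][1])
                occupancy[otu][locus_name] = True
            else:
                rows[otu].append(MISSING_CHAR * width)
                occupancy[otu][locus_name] = False

    pid = project.next_process_id("build_supermatrix")
    matrix = Supermatrix(
        name=concatenation.name,
        rows={otu: "".join(parts) for otu, parts in rows.items()},
        partitions=partitions,
        occupancy=occupancy,
        produced_by=pid,
    )
    project.concatenations[concatenation.name] = concatenation
    project.supermatrices[matrix.name] = matrix
    project.log(
        "build_supermatrix",
        {
            "concatenation": concatenation.name,
            "loci": list(concatenation.locus_names),
            "rules": dict(concatenation.rules),
            "otus": len(kept_otus),
            "duplicate_choices": tie_log,
        },
        input_ids=[a.object_id for a in alignments.values()],
        output_ids=[matrix.name],
        process_id=pid,
    )
    return matrix


def occupancy_table(matrix: Supermatrix):
    """Occupancy as a DataFrame plus per-locus and per-OTU coverage fractions.

    Returns ``(table, per_locus, per_otu)`` where the table is boolean with
    OTUs as rows and loci as columns.
    """
    import pandas as pd

    table = pd.DataFrame(matrix.occupancy).T  # otu rows, locus columns
    table = table.loc[sorted(table.index), [p[0] for p in matrix.partitions]]
    per_locus = table.mean(axis=0)
    per_otu = table.mean(axis=1)
    return table, per_locus, per_otu
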