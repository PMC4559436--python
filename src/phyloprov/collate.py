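"""Dataset selection and filtering between harvest and analysis.

Filtering never deletes: records failing a criterion move to the
project's ``excluded`` bin and can be recovered by checkpoint restore.
A record failing several criteria is attributed to the first failing one
in the fixed order length → GC → id, so reports are deterministic.
Locus-level filtering deselects loci below a record-count or
taxonomic-coverage (distinct OTU count) threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

from .core import Project, UnknownIdError
from .locistats import gc_content

__all__ = ["select_loci", "filter_records", "filter_loci", "FilterReport"]


@dataclass
class FilterReport:
    """Outcome of a filtering pass: who stayed, who left and why."""

    kept: list[str]
    removed: list[tuple[str, str]]  # (id, first failing criterion)
    criterion_counts: dict[str, int] = field(default_factory=dict)

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        lines = ["id\tstatus\tcriterion"]
        lines += [f"{i}\tkept\t-" for i in self.kept]
        lines += [f"{i}\tremoved\t{c}" for i, c in self.removed]
        path.write_text("\n".join(lines) + "\n")
        return path


def select_loci(project: Project, names: list[str]) -> Project:
    """Restrict downstream batch operations to the chosen loci.

    Names resolve through alias folding; an unknown name raises with an
    inventory of available loci.
    """
    resolved = []
    for name in names:
        try:
            resolved.append(project.find_locus(name).name)
        except UnknownIdError:
            raise UnknownIdError(name, [lc.name for lc in project.loci]) from None
    project.selected_loci = resolved
    project.log("select_loci", {"selected": resolved})
    return project


def _first_failure(record, criteria) -> str | None:
    length = record.length
    if "min_len" in criteria and length < criteria["min_len"]:
        return "min_len"
    if "max_len" in criteria and length > criteria["max_len"]:
        return "max_len"
    if "min_gc" in criteria or "max_gc" in criteria:
        gc = gc_content(record.sequence)
        if "min_gc" in criteria and not gc >= criteria["min_gc"]:
            return "min_gc"
        if "max_gc" in criteria and not gc <= criteria["max_gc"]:
            return "max_gc"
    if "include_ids" in criteria and record.record_id not in criteria["include_ids"]:
        return "include_ids"
    if "exclude_ids" in criteria and record.record_id in criteria["exclude_ids"]:
        return "exclude_ids"
    return None


def _validate(criteria: dict) -> None:
    if criteria.get("min_len", 0) > criteria.get("max_len", float("inf")):
        raise ValueError("min_len exceeds max_len")
    for key in ("min_gc", "max_gc"):
        if key in criteria and not 0 <= criteria[key] <= 1:
            raise ValueError(f"{key} must be within [0, 1]")
    if criteria.get("min_gc", 0) > criteria.get("max_gc", 1):
        raise ValueError("min_gc exceeds max_gc")


def filter_records(project: Project, criteria: dict) -> FilterReport:
    """Move records failing the criteria to the excluded bin (recoverable).

    Criteria: ``min_len``/``max_len`` on ungapped residue count (ambiguity
    codes count), ``min_gc``/``max_gc`` on the shared GC definition,
    ``include_ids``/``exclude_ids`` as explicit lists.  Validation happens
    before any mutation.
    """
    _validate(criteria)
    kept, removed = [], []
    counts: dict[str, int] = {}
    for record_id in list(project.records):
        criterion = _first_failure(project.records[record_id], criteria)
        if criterion is None:
            kept.append(record_id)
        else:
            removed.append((record_id, criterion))
            counts[criterion] = counts.get(criterion, 0) + 1
            project.excluded[record_id] = project.records.pop(record_id)
    project.log(
        "filter_records",
        {"criteria": {k: sorted(v) if isinstance(v, (set, list)) else v
                      for k, v in criteria.items()},
         "kept": len(kept), "removed": len(removed), "by_criterion": counts},
        input_ids=[i for i, _ in removed],
    )
    return FilterReport(kept=kept, removed=removed, criterion_counts=counts)


def filter_loci(project: Project, criteria: dict) -> FilterReport:
    """Deselect loci with too few records or too few distinct OTUs.

    ``min_records`` and ``min_otus`` are non-negative integers; loci
    below either threshold are removed from the selection (the data stays
    in the project).
    """
    for key in ("min_records", "min_otus"):
        if key in criteria and (not isinstance(criteria[key], int) or criteria[key] < 0):
            raise ValueError(f"{key} must be a non-negative integer")
    kept, removed = [], []
    counts: dict[str, int] = {}
    for name in project.locus_names():
        records = project.records_for_locus(name)
        n_otus = len({r.otu for r in records})
        if "min_records" in criteria and len(records) < criteria["min_records"]:
            criterion = "min_records"
        elif "min_otus" in criteria and n_otus < criteria["min_otus"]:
            criterion = "min_otus"
        else:
            kept.append(name)
            continue
        removed.append((name, criterion))
        counts[criterion] = counts.get(criterion, 0) + 1
    project.selected_loci = kept
    if not kept:
        warnings.warn("locus filter removed every locus")
    project.log(
        "filter_loci",
        {"criteria": dict(criteria), "kept": kept, "removed": [n for n, _ in removed]},
    )
    return FilterReport(kept=kept, removed=removed, criterion_counts=counts)
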