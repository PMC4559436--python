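"""Per-locus alignment statistics and the parameter-gradient machinery.

Five statistic families are computed per locus:

* ``entropy`` — per-column Shannon entropy (bits) over unambiguous,
  non-gap residues; an all-gap (or all-ambiguous) column is *missing*,
  not zero.
* ``gap_score`` — per-column fraction of rows with a non-gap character
  (1 = gap-free column).
* ``conservation`` — per-column frequency of the modal unambiguous
  residue among unambiguous residues (identity-based score).
* ``length`` — per-record ungapped residue count.
* ``gc`` — per-record GC fraction, (G+C)/(A+C+G+T), ambiguity codes
  excluded from both numerator and denominator.

Loci can then be sorted along any statistic's percentile summary, sliced
by summary bounds into a supermatrix recipe, or walked with a sliding
window (width ``w`` loci, step ``s``) to produce a series of supermatrix
recipes along the gradient — e.g. 200-locus windows stepped by 50 across
a 465-locus dataset yield six windows from the most to the least variable
loci.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import GAP_CHARS, Alignment, Project, UnknownIdError
from .supermatrix import Concatenation

__all__ = [
    "LocusStats",
    "WindowSpec",
    "column_entropy",
    "column_gap_score",
    "column_conservation",
    "gc_content",
    "compute_locus_stats",
    "compute_stats",
    "sort_loci",
    "slice_loci",
    "slide",
    "bias_diagnostic",
    "boxplot_data",
    "five_number_summary",
]

DNA_RESIDUES = frozenset("ACGTU")
PROTEIN_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

STATISTICS = ("entropy", "gap_score", "conservation", "length", "gc")
SUMMARIES = ("median", "p25", "p75")


def _unambiguous(char_type: str) -> frozenset[str]:
    return DNA_RESIDUES if char_type == "dna" else PROTEIN_RESIDUES


def _informative(column: str, char_type: str) -> list[str]:
    ok = _unambiguous(char_type)
    return [c for c in column.upper() if c in ok]


def column_entropy(column: str, char_type: str = "dna") -> float:
    """Shannon entropy of one alignment column in bits.

    Gaps and ambiguity codes are ignored; frequencies are taken over the
    remaining residues.  A column with no informative residue has no
    defined entropy and returns NaN (excluded from summaries downstream).
    """
    residues = _informative(column, char_type)
    if not residues:
        return math.nan
    n = len(residues)
    counts: dict[str, int] = {}
    for c in residues:
        counts[c] = counts.get(c, 0) + 1
    return -sum((k / n) * math.log2(k / n) for k in counts.values()) + 0.0


def column_gap_score(column: str) -> float:
    """Fraction of rows with a non-gap character; 1.0 = gap-free column."""
    if not column:
        return math.nan
    return sum(1 for c in column if c not in GAP_CHARS) / len(column)


def column_conservation(column: str, char_type: str = "dna") -> float:
    """Frequency of the modal unambiguous residue among unambiguous residues."""
    residues = _informative(column, char_type)
    if not residues:
        return math.nan
    counts: dict[str, int] = {}
    for c in residues:
        counts[c] = counts.get(c, 0) + 1
    return max(counts.values()) / len(residues)


def gc_content(sequence: str) -> float:
    """GC fraction of an (optionally gapped) sequence, ambiguity excluded."""
    seq = sequence.upper()
    gc = sum(1 for c in seq if c in "GC")
    at = sum(1 for c in seq if c in "ATU")
    total = gc + at
    return gc / total if total else math.nan


def five_number_summary(values) -> dict[str, float | None]:
    """Box-plot summary: quartiles plus 1.5·IQR whiskers.

    Percentiles use linear interpolation between order statistics.
    Whiskers are the extreme data values within 1.5 box-lengths of the
    box; when the box has zero height the whiskers are null.
    """
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        return {k: None for k in ("p25", "median", "p75", "whisker_low", "whisker_high")}
    p25, median, p75 = np.percentile(arr, [25, 50, 75], method="linear")
    iqr = p75 - p25
    if iqr == 0:
        lo = hi = None
    else:
        inside = arr[(arr >= p25 - 1.5 * iqr) & (arr <= p75 + 1.5 * iqr)]
        lo, hi = float(inside.min()), float(inside.max())
    return {
        "p25": float(p25),
        "median": float(median),
        "p75": float(p75),
        "whisker_low": lo,
        "whisker_high": hi,
    }


@dataclass
class LocusStats:
    """All five statistic families for one locus, with box-plot summaries."""

    locus_name: str
    column_entropy: np.ndarray
    column_gap_score: np.ndarray
    column_conservation: np.ndarray
    record_lengths: np.ndarray
    record_gc: np.ndarray
    summaries: dict[str, dict[str, float | None]] = field(default_factory=dict)

    def values_for(self, statistic: str) -> np.ndarray:
        arrays = {
            "entropy": self.column_entropy,
            "gap_score": self.column_gap_score,
            "conservation": self.column_conservation,
            "length": self.record_lengths,
            "gc": self.record_gc,
        }
        if statistic not in arrays:
            raise ValueError(f"unknown statistic {statistic!r}; choose from {STATISTICS}")
        return arrays[statistic]


def compute_locus_stats(alignment: Alignment, char_type: str = "dna") -> LocusStats:
    """Compute the full statistic suite for one locus alignment."""
    if not alignment.rows:
        raise ValueError(f"alignment {alignment.object_id} is empty")
    columns = alignment.columns()
    ent = np.array([column_entropy(c, char_type) for c in columns])
    gap = np.array([column_gap_score(c) for c in columns])
    cons = np.array([column_conservation(c, char_type) for c in columns])
    lengths = np.array(
        [sum(1 for c in seq if c not in GAP_CHARS) for _, seq in alignment.rows],
        dtype=float,
    )
    gc = np.array([gc_content(seq) for _, seq in alignment.rows])
    stats = LocusStats(
        locus_name=alignment.locus_name,
        column_entropy=ent,
        column_gap_score=gap,
        column_conservation=cons,
        record_lengths=lengths,
        record_gc=gc,
    )
    for statistic in STATISTICS:
        stats.summaries[statistic] = five_number_summary(stats.values_for(statistic))
    return stats


def compute_stats(project: Project) -> dict[str, LocusStats]:
    """Compute stats for every selected locus that has an alignment."""
    computed = {}
    for name in project.locus_names():
        try:
            aln = project.alignment_for_locus(name)
        except UnknownIdError:
            continue
        char_type = project.find_locus(name).char_type
        computed[name] = compute_locus_stats(aln, char_type)
    project.stats.update(computed)
    project.log("compute_stats", {"loci": sorted(computed)})
    return computed


def _summary_value(project: Project, locus_name: str, statistic: str, summary: str) -> float:
    if locus_name not in project.stats:
        raise UnknownIdError(locus_name, list(project.stats))
    if summary not in SUMMARIES:
        raise ValueError(f"summary must be one of {SUMMARIES}, got {summary!r}")
    value = project.stats[locus_name].summaries[statistic][summary]
    return math.nan if value is None else value


def sort_loci(
    project: Project,
    statistic: str = "entropy",
    summary: str = "median",
    order: str = "desc",
) -> list[str]:
    """Total order of selected loci by a summary statistic.

    Ties (and NaN summaries) break lexicographically by locus name so
    the order is deterministic.
    """
    names = project.locus_names()
    missing = [n for n in names if n not in project.stats]
    if missing:
        raise UnknownIdError(missing[0], list(project.stats))
    keyed = [(_summary_value(project, n, statistic, summary), n) for n in names]
    reverse = order == "desc"
    keyed.sort(key=lambda kv: (math.isnan(kv[0]), -kv[0] if reverse else kv[0], kv[1]))
    return [n for _, n in keyed]


def slice_loci(
    project: Project,
    statistic: str,
    summary: str,
    min_value: float = -math.inf,
    max_value: float = math.inf,
    name: str | None = None,
    otu_field: str = "organism",
    rules: dict | None = None,
) -> Concatenation:
    """Supermatrix recipe from loci whose summary lies in [min, max].

    An empty selection is an error (advising different bounds), never an
    empty supermatrix.
    """
    if min_value > max_value:
        raise ValueError(f"min {min_value} exceeds max {max_value}")
    chosen = [
        n
        for n in sort_loci(project, statistic, summary, "desc")
        if min_value <= _summary_value(project, n, statistic, summary) <= max_value
    ]
    if not chosen:
        raise ValueError(
            f"no locus has {summary} {statistic} in [{min_value}, {max_value}]; "
            "widen the bounds"
        )
    name = name or f"slice_{statistic}_{summary}"
    conc = Concatenation(
        name=name,
        locus_names=chosen,
        otu_field=otu_field,
        rules=rules or {"min_loci_per_otu": 1},
    )
    project.concatenations[name] = conc
    project.log(
        "slice",
        {
            "statistic": statistic,
            "summary": summary,
            "min": min_value,
            "max": max_value,
            "loci": chosen,
        },
        output_ids=[name],
    )
    return conc


@dataclass
class WindowSpec:
    """Sliding-window specification along a sorted locus gradient."""

    width: int
    step: int
    statistic: str = "entropy"
    summary: str = "median"
    order: str = "desc"

    def __post_init__(self) -> None:
        if self.width < 1 or self.step < 1:
            raise ValueError("window width and step must be >= 1")

    def offsets(self, n_loci: int) -> list[int]:
        if self.width > n_loci:
            raise ValueError(f"window width {self.width} exceeds locus count {n_loci}")
        return [k * self.step for k in range((n_loci - self.width) // self.step + 1)]


def slide(
    project: Project,
    spec: WindowSpec,
    otu_field: str = "organism",
    rules: dict | None = None,
) -> list[Concatenation]:
    """Sliding-window supermatrix recipes along a statistic gradient.

    Loci are sorted by ``spec.statistic``/``spec.summary`` in
    ``spec.order``; window ``k`` covers loci ``[k·s, k·s + w)`` of that
    ordering and becomes a Concatenation named ``win_k``.  Trailing loci
    that cannot fill a final window are omitted, so all windows hold
    exactly ``w`` loci.
    """
    ordering = sort_loci(project, spec.statistic, spec.summary, spec.order)
    offsets = spec.offsets(len(ordering))
    windows = []
    for k, off in enumerate(offsets):
        conc = Concatenation(
            name=f"win_{k}",
            locus_names=ordering[off : off + spec.width],
            otu_field=otu_field,
            rules=dict(rules) if rules else {"min_loci_per_otu": 1},
        )
        project.concatenations[conc.name] = conc
        windows.append(conc)
    project.log(
        "slide",
        {
            "statistic": spec.statistic,
            "summary": spec.summary,
            "order": spec.order,
            "width": spec.width,
            "step": spec.step,
            "n_loci": len(ordering),
            "windows": len(windows),
        },
        output_ids=[w.name for w in windows],
    )
    return windows


def bias_diagnostic(
    project: Project,
    statistic_a: str,
    statistic_b: str,
    summary: str = "median",
) -> tuple[float, int]:
    """Rank correlation between two per-locus summary statistics.

    Used to check that the entropy gradient is not a disguised GC or
    missing-data gradient.  Returns ``(spearman_rho, n_loci)``; loci with
    a missing summary on either side are dropped pairwise, and a constant
    side yields ``(nan, n)`` — undefined, not zero.
    """
    from scipy import stats as sps

    names = [n for n in project.locus_names() if n in project.stats]
    a = np.array([_summary_value(project, n, statistic_a, summary) for n in names])
    b = np.array([_summary_value(project, n, statistic_b, summary) for n in names])
    keep = ~(np.isnan(a) | np.isnan(b))
    a, b = a[keep], b[keep]
    n = int(keep.sum())
    if n < 3:
        raise ValueError(f"need >= 3 loci with both summaries, have {n}")
    if np.all(a == a[0]) or np.all(b == b[0]):
        return math.nan, n
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho = sps.spearmanr(a, b).statistic
    return float(rho), n


def boxplot_data(project: Project, statistic: str) -> dict[str, dict[str, float | None]]:
    """Per-locus five-number summaries for a statistic, ready to plot."""
    return {
        name: project.stats[name].summaries[statistic]
        for name in project.locus_names()
        if name in project.stats
    }


def stats_table(project: Project):
    """All per-locus summaries as a tidy DataFrame (exportable as TSV)."""
    import pandas as pd

    rows = []
    for name in project.locus_names():
        if name not in project.stats:
            continue
        for statistic in STATISTICS:
            row = {"locus": name, "statistic": statistic}
            row.update(project.stats[name].summaries[statistic])
            rows.append(row)
    return pd.DataFrame(rows)
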