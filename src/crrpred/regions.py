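"""Labelled genomic regions and activity-labeling rules.

Cis-regulatory regions (enhancers and promoters) are assigned a
tissue-specific activity class from CAGE transcription evidence (TPM,
tags per million); exons are classified from RNA-seq peak-max values.
The resulting seven-class label set (AE/IE, AP/IP, AX/IX, UK) feeds the
binary classification tasks evaluated downstream.

Coordinates follow the BED convention: 0-based, half-open.
"""

from __future__ import annotations

import enum
import importlib.resources
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "RegionKind",
    "ClassLabel",
    "LabelledRegion",
    "TaskSpec",
    "ClassCountSummary",
    "HG19_TASKS",
    "HG38_TASKS",
    "predefined_tasks",
    "label_enhancer",
    "label_promoter",
    "label_exon",
    "label_region",
    "build_task",
    "unbalancing_ratio",
    "dataset_summary",
    "class_count_fixture",
    "analysis_window",
    "read_region_table",
    "write_region_table",
]

def _check_genome(genome_version: str) -> None:
    if genome_version not in ("hg19", "hg38"):
        raise ValueError(f"unknown genome version: {genome_version!r}")


PROMOTER_ACTIVE_TPM = 5.0
EXON_ACTIVE_PEAK_MAX = 400.0
WINDOW_LENGTH = 200


class RegionKind(str, enum.Enum):
    ENHANCER = "enhancer"
    PROMOTER = "promoter"
    EXON = "exon"
    UNKNOWN = "unknown"


class ClassLabel(str, enum.Enum):
    AE = "AE"  # active enhancer (TPM > 0)
    IE = "IE"  # inactive enhancer (TPM = 0)
    AP = "AP"  # active promoter (TPM > 5)
    IP = "IP"  # inactive promoter
    AX = "AX"  # active exon (peak-max > 400)
    IX = "IX"  # inactive exon (peak-max = 0)
    UK = "UK"  # unknown / uncharacterized region
    UNDEFINED = "UNDEFINED"  # intermediate evidence, excluded from tasks


#: Labels that a region of each kind may legally carry.
_KIND_LABELS = {
    RegionKind.ENHANCER: {ClassLabel.AE, ClassLabel.IE, ClassLabel.UNDEFINED},
    RegionKind.PROMOTER: {ClassLabel.AP, ClassLabel.IP, ClassLabel.UNDEFINED},
    RegionKind.EXON: {ClassLabel.AX, ClassLabel.IX, ClassLabel.UNDEFINED},
    RegionKind.UNKNOWN: {ClassLabel.UK},
}


class InvalidEvidenceError(ValueError):
    """Raised for negative TPM / peak-max values."""


class DegenerateTaskError(ValueError):
    """Raised when a task has an empty positive or negative side."""


def label_enhancer(tpm: float, genome_version: str = "hg19") -> ClassLabel:
    """Label an enhancer from its CAGE TPM: active iff transcribed (TPM > 0).

    The rule is identical for hg19 and hg38.
    """
    _check_genome(genome_version)
    if tpm < 0:
        raise InvalidEvidenceError(f"negative TPM: {tpm}")
    return ClassLabel.AE if tpm > 0 else ClassLabel.IE


def label_promoter(tpm: float, genome_version: str = "hg19") -> ClassLabel:
    """Label a promoter from its CAGE TPM.

    hg19: AP if TPM > 5, IP if TPM = 0, UNDEFINED for the intermediate
    band 0 < TPM <= 5 (such promoters are excluded from every task).
    hg38: AP if TPM > 5, IP otherwise — the intermediate band is kept
    as inactive rather than dropped.
    """
    _check_genome(genome_version)
    if tpm < 0:
        raise InvalidEvidenceError(f"negative TPM: {tpm}")
    if tpm > PROMOTER_ACTIVE_TPM:
        return ClassLabel.AP
    if genome_version == "hg38":
        return ClassLabel.IP
    return ClassLabel.IP if tpm == 0 else ClassLabel.UNDEFINED


def label_exon(peak_max: float) -> ClassLabel:
    """Label an exon from its RNA-seq peak-max (hg19 dataset only)."""
    if peak_max < 0:
        raise InvalidEvidenceError(f"negative peak-max: {peak_max}")
    if peak_max > EXON_ACTIVE_PEAK_MAX:
        return ClassLabel.AX
    return ClassLabel.IX if peak_max == 0 else ClassLabel.UNDEFINED


def label_region(kind: RegionKind, evidence: float | None, genome_version: str) -> ClassLabel:
    """Dispatch to the per-kind labeling rule; unknown regions are UK."""
    kind = RegionKind(kind)
    if kind is RegionKind.UNKNOWN:
        return ClassLabel.UK
    if evidence is None:
        raise InvalidEvidenceError(f"{kind.value} region without evidence")
    if kind is RegionKind.ENHANCER:
        return label_enhancer(evidence, genome_version)
    if kind is RegionKind.PROMOTER:
        return label_promoter(evidence, genome_version)
    return label_exon(evidence)


@dataclass(frozen=True)
class LabelledRegion:
    """A genomic interval with its cell line, evidence, and activity class."""

    chrom: str
    start: int
    end: int
    cell_line: str
    kind: RegionKind
    evidence: float | None = None
    label: ClassLabel = ClassLabel.UNDEFINED

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(f"bad interval [{self.start}, {self.end})")
        if self.evidence is not None and self.evidence < 0:
            raise InvalidEvidenceError(f"negative evidence: {self.evidence}")
        if self.label not in _KIND_LABELS[RegionKind(self.kind)]:
            raise ValueError(f"label {self.label} inconsistent with kind {self.kind}")

    def relabelled(self, genome_version: str) -> "LabelledRegion":
        return replace(self, label=label_region(self.kind, self.evidence, genome_version))


def analysis_window(region: LabelledRegion, window_length: int = WINDOW_LENGTH) -> tuple[int, int]:
    """The fixed-length bin centered on the region midpoint (half-open)."""
    mid = (region.start + region.end) // 2
    half = window_length // 2
    return mid - half, mid - half + window_length


@dataclass(frozen=True)
class TaskSpec:
    """A binary classification task over activity classes."""

    name: str
    positive_labels: frozenset
    negative_labels: frozenset
    genome_version: str = "hg19"

    def __post_init__(self) -> None:
        pos = frozenset(ClassLabel(l) for l in self.positive_labels)
        neg = frozenset(ClassLabel(l) for l in self.negative_labels)
        if not pos or not neg:
            raise DegenerateTaskError(f"task {self.name}: empty class side")
        if pos & neg:
            raise DegenerateTaskError(f"task {self.name}: overlapping label sets")
        object.__setattr__(self, "positive_labels", pos)
        object.__setattr__(self, "negative_labels", neg)
        _check_genome(self.genome_version)


def _task(name, pos, neg, genome):
    return TaskSpec(name, frozenset(pos), frozenset(neg), genome)


L = ClassLabel
#: The hg19 protocol: five binary tasks over the seven-class dataset. The
#: ELSE side of the fifth task is every labelled region outside {AE, AP}.
HG19_TASKS: tuple[TaskSpec, ...] = (
    _task("IE_vs_IP", [L.IE], [L.IP], "hg19"),
    _task("AP_vs_IP", [L.AP], [L.IP], "hg19"),
    _task("AE_vs_IE", [L.AE], [L.IE], "hg19"),
    _task("AE_vs_AP", [L.AE], [L.AP], "hg19"),
    _task("AEAP_vs_ELSE", [L.AE, L.AP], [L.IE, L.IP, L.AX, L.IX, L.UK], "hg19"),
)
#: The hg38 protocol restricts the combined task to CRRs only.
HG38_TASKS: tuple[TaskSpec, ...] = (
    _task("IE_vs_IP", [L.IE], [L.IP], "hg38"),
    _task("AP_vs_IP", [L.AP], [L.IP], "hg38"),
    _task("AE_vs_IE", [L.AE], [L.IE], "hg38"),
    _task("AE_vs_AP", [L.AE], [L.AP], "hg38"),
    _task("AEAP_vs_IEIP", [L.AE, L.AP], [L.IE, L.IP], "hg38"),
)
del L


def predefined_tasks(genome_version: str) -> tuple[TaskSpec, ...]:
    _check_genome(genome_version)
    return HG19_TASKS if genome_version == "hg19" else HG38_TASKS


def build_task(
    regions: Sequence[LabelledRegion], task: TaskSpec
) -> tuple[list[LabelledRegion], list[int]]:
    """Select the task's regions and attach binary labels, preserving order.

    Returns (selected regions, 0/1 labels). Regions whose class is in
    neither side (including UNDEFINED) are dropped.
    """
    selected: list[LabelledRegion] = []
    y: list[int] = []
    for r in regions:
        if r.label in task.positive_labels:
            selected.append(r)
            y.append(1)
        elif r.label in task.negative_labels:
            selected.append(r)
            y.append(0)
    return selected, y


def unbalancing_ratio(count_a: int, count_b: int) -> float:
    """Cardinality of the larger class over the smaller; symmetric, >= 1."""
    if count_a <= 0 or count_b <= 0:
        raise ValueError(f"undefined ratio for counts ({count_a}, {count_b})")
    return max(count_a, count_b) / min(count_a, count_b)


EP_LABELS = (ClassLabel.AE, ClassLabel.IE, ClassLabel.AP, ClassLabel.IP)


@dataclass
class ClassCountSummary:
    """Per-class counts keyed by (cell line, class), with E+P totals.

    ``total_cell_lines`` lists the cell lines contributing to the
    cross-cell-line grand totals (for the packaged hg19 table this is
    the trio shared with hg38; HelaS3 is tabulated but kept out of the
    reference totals, matching the source counts).
    """

    genome_version: str
    counts: pd.DataFrame  # index: cell_line, columns: class labels
    total_cell_lines: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.total_cell_lines:
            self.total_cell_lines = tuple(self.counts.index)

    def count(self, cell_line: str, label: ClassLabel | str) -> int:
        lab = ClassLabel(label).value
        if lab not in self.counts.columns:
            return 0
        return int(self.counts.loc[cell_line, lab])

    def ep_total(self, cell_line: str) -> int:
        return sum(self.count(cell_line, l) for l in EP_LABELS)

    def ep_grand_total(self) -> int:
        return sum(self.ep_total(c) for c in self.total_cell_lines)

    def class_total(self, label: ClassLabel | str) -> int:
        return sum(self.count(c, label) for c in self.total_cell_lines)

    def grand_total(self, cell_line: str) -> int:
        return int(self.counts.loc[cell_line].sum())


def dataset_summary(
    data: Iterable[LabelledRegion] | pd.DataFrame,
    genome_version: str | None = None,
    include_undefined: bool = False,
) -> ClassCountSummary:
    """Tabulate per-class counts per cell line.

    Accepts either labelled regions or a fixture table (columns
    genome, cell_line, label, count). UNDEFINED regions are excluded
    unless requested: the class lists the tasks draw from omit them.
    """
    if isinstance(data, pd.DataFrame):
        df = data
        if genome_version is not None:
            df = df[df["genome"] == genome_version]
        elif df["genome"].nunique() == 1:
            genome_version = df["genome"].iloc[0]
        else:
            raise ValueError("fixture spans several genome versions; pass genome_version")
        table = df.pivot_table(
            index="cell_line", columns="label", values="count", aggfunc="sum", fill_value=0
        )
        in_total = (
            df.groupby("cell_line")["in_grand_total"].first()
            if "in_grand_total" in df.columns
            else pd.Series(1, index=table.index)
        )
        totals = tuple(c for c in table.index if in_total.get(c, 1))
    else:
        rows = [
            {"cell_line": r.cell_line, "label": r.label.value}
            for r in data
            if include_undefined or r.label is not ClassLabel.UNDEFINED
        ]
        if not rows:
            table = pd.DataFrame(index=pd.Index([], name="cell_line"))
        else:
            table = (
                pd.DataFrame(rows)
                .pivot_table(index="cell_line", columns="label", aggfunc="size", fill_value=0)
            )
        totals = tuple(table.index)
        genome_version = genome_version or "hg19"
    return ClassCountSummary(genome_version, table.astype(int), totals)


def class_count_fixture(genome_version: str | None = None) -> pd.DataFrame:
    """The packaged per-class count table (both genome versions)."""
    with importlib.resources.files("crrpred.data").joinpath("class_counts.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    if genome_version is not None:
        _check_genome(genome_version)
        df = df[df["genome"] == genome_version].reset_index(drop=True)
    return df


# -- BED-like I/O -----------------------------------------------------------

_COLUMNS = ["chrom", "start", "end", "cell_line", "kind", "evidence", "label"]


def write_region_table(regions: Iterable[LabelledRegion], path) -> None:
    df = pd.DataFrame(
        [
            (r.chrom, r.start, r.end, r.cell_line, r.kind.value,
             "" if r.evidence is None else r.evidence, r.label.value)
            for r in regions
        ],
        columns=_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_region_table(path) -> list[LabelledRegion]:
    df = pd.read_csv(path, sep="\t")
    regions = []
    for row in df.itertuples(index=False):
        ev = None if pd.isna(row.evidence) or row.evidence == "" else float(row.evidence)
        regions.append(
            LabelledRegion(
                chrom=str(row.chrom), start=int(row.start), end=int(row.end),
                cell_line=str(row.cell_line), kind=RegionKind(row.kind),
                evidence=ev, label=ClassLabel(row.label),
            )
        )
    return regions

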