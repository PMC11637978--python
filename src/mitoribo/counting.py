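"""Per-feature read counting and protected-fragment length distributions.

Soft-clipped bases are removed before any measurement: the aligned reference
span of a read is the sum of its M/D/N runs and the protected-fragment
length is the number of aligned query bases (M/I runs).  A read is assigned
to the unique feature its span overlaps by at least one nucleotide;
multi-feature overlaps are ambiguous and intergenic reads unassigned, both
excluded from the count matrix but tallied in a QC summary so that
``assigned + ambiguous + unassigned`` equals the stream size per library.
Counting is unstranded.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .io_formats import AlignmentRecord, Annotation

__all__ = [
    "UNASSIGNED",
    "AMBIGUOUS",
    "LibraryMeta",
    "CountTable",
    "LengthDistribution",
    "strip_soft_clips",
    "assign_read",
    "count_features",
    "length_distribution",
    "mean_protected_length",
]

UNASSIGNED = "__unassigned__"
AMBIGUOUS = "__ambiguous__"


@dataclass(frozen=True)
class LibraryMeta:
    """Assay (RPF or RNA) and condition (rescue or KO) labels for a library."""

    assay: str
    condition: str

    def __post_init__(self) -> None:
        if self.assay not in ("RPF", "RNA"):
            raise ValueError(f"assay must be RPF or RNA, got {self.assay!r}")


@dataclass
class CountTable:
    """Feature x library count matrix plus per-library metadata and QC tallies."""

    counts: pd.DataFrame
    meta: pd.DataFrame  # index library_id, columns assay, condition
    annotation: Annotation
    qc: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        unknown = set(self.counts.index) - set(self.annotation.feature_ids)
        if unknown:
            raise ValueError(f"count rows not in annotation: {sorted(unknown)}")
        if self.qc is None:
            self.qc = pd.DataFrame(
                0, index=self.counts.columns, columns=["assigned", "ambiguous", "unassigned"]
            )

    @property
    def library_ids(self) -> list[str]:
        return list(self.counts.columns)

    def libraries_for(self, assay: str, condition: str) -> list[str]:
        m = self.meta
        return list(m.index[(m["assay"] == assay) & (m["condition"] == condition)])


@dataclass
class LengthDistribution:
    """Read-length (nt) x library count matrix after soft-clip removal."""

    counts: pd.DataFrame  # index: length, columns: library_id

    def fractions(self) -> pd.DataFrame:
        """Column-normalized view; refuses empty libraries rather than emit NaN."""
        totals = self.counts.sum(axis=0)
        empty = list(totals.index[totals == 0])
        if empty:
            raise ValueError(f"empty library column(s), normalization undefined: {empty}")
        return self.counts / totals

    @property
    def empty_libraries(self) -> list[str]:
        totals = self.counts.sum(axis=0)
        return list(totals.index[totals == 0])


class _FeatureIndex:
    """Sorted-interval lookup for non-overlapping features on one reference."""

    def __init__(self, annotation: Annotation):
        feats = sorted(annotation.features, key=lambda f: f.start)
        self.starts = [f.start for f in feats]
        self.ends = [f.end for f in feats]
        self.ids = [f.feature_id for f in feats]
        self.reference_name = annotation.reference_name

    def overlapping(self, start: int, end: int) -> list[str]:
        """Feature ids overlapping [start, end) by >=1 nt."""
        hits = []
        i = bisect_right(self.starts, start) - 1
        if i >= 0 and self.ends[i] > start:
            hits.append(self.ids[i])
        j = i + 1
        while j < len(self.starts) and self.starts[j] < end:
            hits.append(self.ids[j])
            j += 1
        return hits


def strip_soft_clips(record: AlignmentRecord) -> tuple[tuple[int, int], int]:
    """Remove soft clips; return the 0-based reference span and fragment length.

    The span is ``[pos-1, pos-1 + sum(M,D,N))``; the protected-fragment
    length is the count of aligned query bases, ``sum(M,I)``.  S ops
    contribute to neither (they neither consume reference nor survive
    clipping), so adding soft clips to a record never changes the result.
    """
    ref_len = 0
    query_len = 0
    for op, run in record.cigar:
        if op in ("M",):
            ref_len += run
            query_len += run
        elif op in ("D", "N"):
            ref_len += run
        elif op == "I":
            query_len += run
        # S: ignored
    if query_len == 0 or ref_len == 0:
        raise ValueError(f"record {record.query_id}: nothing aligned after clip removal")
    start = record.pos - 1
    return (start, start + ref_len), query_len


def assign_read(
    record: AlignmentRecord,
    annotation: Annotation | _FeatureIndex,
) -> str:
    """Assign a read to the unique feature overlapping its aligned span.

    Returns the feature_id, or the sentinels :data:`AMBIGUOUS` (more than one
    overlapping feature) / :data:`UNASSIGNED` (none, or wrong reference).
    """
    index = annotation if isinstance(annotation, _FeatureIndex) else _FeatureIndex(annotation)
    if record.reference_name != index.reference_name:
        return UNASSIGNED
    (start, end), _ = strip_soft_clips(record)
    hits = index.overlapping(start, end)
    if not hits:
        return UNASSIGNED
    if len(hits) > 1:
        return AMBIGUOUS
    return hits[0]


def count_features(
    stream: Iterable[AlignmentRecord],
    annotation: Annotation,
    libraries: Mapping[str, LibraryMeta],
) -> CountTable:
    """Sum read counts across features for every library in the stream."""
    index = _FeatureIndex(annotation)
    feature_ids = annotation.feature_ids
    lib_ids = list(libraries)
    fpos = {f: i for i, f in enumerate(feature_ids)}
    lpos = {l: i for i, l in enumerate(lib_ids)}
    counts = np.zeros((len(feature_ids), len(lib_ids)), dtype=np.int64)
    qc = np.zeros((len(lib_ids), 3), dtype=np.int64)  # assigned, ambiguous, unassigned

    for rec in stream:
        try:
            li = lpos[rec.library_id]
        except KeyError:
            raise ValueError(f"record {rec.query_id}: unknown library {rec.library_id!r}")
        dest = assign_read(rec, index)
        if dest == AMBIGUOUS:
            qc[li, 1] += 1
        elif dest == UNASSIGNED:
            qc[li, 2] += 1
        else:
            counts[fpos[dest], li] += 1
            qc[li, 0] += 1

    meta = pd.DataFrame(
        {"assay": [libraries[l].assay for l in lib_ids],
         "condition": [libraries[l].condition for l in lib_ids]},
        index=pd.Index(lib_ids, name="library_id"),
    )
    return CountTable(
        counts=pd.DataFrame(counts, index=pd.Index(feature_ids, name="feature_id"), columns=lib_ids),
        meta=meta,
        annotation=annotation,
        qc=pd.DataFrame(qc, index=pd.Index(lib_ids, name="library_id"),
                        columns=["assigned", "ambiguous", "unassigned"]),
    )


def length_distribution(
    stream: Iterable[AlignmentRecord],
    annotation: Annotation,
    libraries: Iterable[str] | None = None,
    target_only: bool = True,
) -> LengthDistribution:
    """Tally protected-fragment lengths (post soft-clip removal) per library.

    With ``target_only`` set, only reads assigned to target-organism features
    contribute (the mito-mRNA-mapped subset).
    """
    index = _FeatureIndex(annotation)
    target_ids = {f.feature_id for f in annotation.target_features}
    tallies: dict[str, dict[int, int]] = {l: {} for l in (libraries or [])}
    for rec in stream:
        (_, _), qlen = strip_soft_clips(rec)
        if target_only:
            dest = assign_read(rec, index)
            if dest not in target_ids:
                continue
        col = tallies.setdefault(rec.library_id, {})
        col[qlen] = col.get(qlen, 0) + 1

    lengths = sorted({l for col in tallies.values() for l in col})
    df = pd.DataFrame(
        {lib: [col.get(l, 0) for l in lengths] for lib, col in tallies.items()},
        index=pd.Index(lengths, name="length"),
        dtype=np.int64,
    )
    return LengthDistribution(df)


def mean_protected_length(dist: LengthDistribution, library_id: str) -> float:
    """Count-weighted mean fragment length for one library."""
    col = dist.counts[library_id]
    total = col.sum()
    if total == 0:
        raise ValueError(f"library {library_id!r}: no reads, mean length undefined")
    return float((col.index.to_numpy() * col.to_numpy()).sum() / total)
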