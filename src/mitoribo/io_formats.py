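"""Readers, writers and domain types for every external format the pipeline touches.

All downstream modules consume only the types defined here:

* :class:`Feature` / :class:`Annotation` — BED-like coding-feature annotation
  (0-based, half-open coordinates) tagging each feature as target-organism or
  spike-in, and as heavy- or light-strand encoded.
* :class:`AlignmentRecord` — one aligned read from a SAM text file (1-based
  leftmost position, decoded CIGAR).
* :class:`SequenceRecord` — a protein sequence (20 amino-acid letters).
* ``SpeciesTree`` — a rooted dendropy tree with uniquely labelled leaves.
* :class:`PresenceMatrix` — protein x species presence/absence booleans with
  an optional per-cell "uncertain" flag.
* :class:`PLDDTProfile` — per-residue AlphaFold confidence values.

Readers are strict: a malformed field raises :class:`ParseError` naming the
offending line, and enum-like columns reject unknown values.  Every
reader/writer pair is a lossless round trip on valid input.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "ParseError",
    "ValidationError",
    "Feature",
    "Annotation",
    "AlignmentRecord",
    "SequenceRecord",
    "SpeciesTree",
    "PresenceMatrix",
    "PLDDTProfile",
    "read_annotation",
    "write_annotation",
    "read_alignments",
    "write_alignments",
    "read_fasta",
    "write_fasta",
    "read_newick",
    "write_newick",
    "read_plddt",
    "write_plddt",
    "read_presence",
    "write_presence",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

ORGANISM_CLASSES = ("target", "spikein")
STRAND_CLASSES = ("heavy", "light", "spikein")

# CIGAR ops we accept; H/P/=/X are rejected as out of scope for the
# transcriptome alignments emulated here.
CIGAR_OPS = "MIDSN"
_CIGAR_TOKEN = re.compile(r"(\d+)([A-Za-z=])")


class ParseError(ValueError):
    """A file could not be parsed; message names the offending line."""


class ValidationError(ValueError):
    """Parsed content violates a domain invariant."""


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Feature:
    """One coding feature on the toy single-reference annotation.

    Coordinates are 0-based, half-open (BED convention).
    """

    feature_id: str
    organism_class: str
    strand_class: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.organism_class not in ORGANISM_CLASSES:
            raise ValidationError(
                f"unknown organism_class {self.organism_class!r} for {self.feature_id}"
            )
        if self.strand_class not in STRAND_CLASSES:
            raise ValidationError(
                f"unknown strand_class {self.strand_class!r} for {self.feature_id}"
            )
        if self.end <= self.start:
            raise ValidationError(
                f"feature {self.feature_id}: end ({self.end}) must exceed start ({self.start})"
            )

    @property
    def length_nt(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Annotation:
    """An ordered, non-overlapping collection of features on one reference."""

    features: tuple[Feature, ...]
    reference_name: str = "ref"

    def __post_init__(self) -> None:
        feats = tuple(self.features)
        object.__setattr__(self, "features", feats)
        ids = [f.feature_id for f in feats]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate feature_id(s): {dupes}")
        if not any(f.organism_class == "target" for f in feats):
            raise ValidationError("annotation must contain at least one target feature")
        if not any(f.organism_class == "spikein" for f in feats):
            raise ValidationError("annotation must contain at least one spikein feature")
        by_start = sorted(feats, key=lambda f: f.start)
        for a, b in zip(by_start, by_start[1:]):
            if b.start < a.end:
                raise ValidationError(
                    f"features {a.feature_id} and {b.feature_id} overlap on {self.reference_name}"
                )

    def __iter__(self) -> Iterator[Feature]:
        return iter(self.features)

    def __len__(self) -> int:
        return len(self.features)

    def by_id(self, feature_id: str) -> Feature:
        for f in self.features:
            if f.feature_id == feature_id:
                return f
        raise KeyError(feature_id)

    @property
    def feature_ids(self) -> list[str]:
        return [f.feature_id for f in self.features]

    @property
    def target_features(self) -> list[Feature]:
        return [f for f in self.features if f.organism_class == "target"]

    @property
    def spikein_features(self) -> list[Feature]:
        return [f for f in self.features if f.organism_class == "spikein"]

    @property
    def extent(self) -> int:
        """Rightmost coordinate covered; used as the reference length."""
        return max(f.end for f in self.features)


_ANNOT_COLUMNS = ["feature_id", "organism_class", "strand_class", "start", "end"]


def read_annotation(path: str | Path) -> Annotation:
    """Read a BED-like TSV annotation.

    Columns: feature_id, organism_class, strand_class, start, end.  A header
    row repeating the column names and a ``#reference=<name>`` comment line
    are both optional.
    """
    path = Path(path)
    reference_name = "ref"
    features: list[Feature] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                m = re.match(r"#\s*reference\s*=\s*(\S+)", line)
                if m:
                    reference_name = m.group(1)
                continue
            cols = line.split("\t") if "\t" in line else line.split()
            if cols[: len(_ANNOT_COLUMNS)] == _ANNOT_COLUMNS:
                continue  # header row
            if len(cols) < 5:
                raise ParseError(f"{path}:{lineno}: expected 5 columns, got {len(cols)}")
            fid, org, strand, start_s, end_s = cols[:5]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate: {exc}") from exc
            try:
                features.append(Feature(fid, org, strand, start, end))
            except ValidationError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    try:
        return Annotation(tuple(features), reference_name=reference_name)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def write_annotation(annotation: Annotation, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"#reference={annotation.reference_name}\n")
        fh.write("\t".join(_ANNOT_COLUMNS) + "\n")
        for f in annotation:
            fh.write(
                f"{f.feature_id}\t{f.organism_class}\t{f.strand_class}\t{f.start}\t{f.end}\n"
            )


# ---------------------------------------------------------------------------
# Alignments (SAM text dialect, columns 1-6)
# ---------------------------------------------------------------------------


@dataclass(frozen=True, slots=True)
class AlignmentRecord:
    """One mapped read.

    ``pos`` is the 1-based leftmost aligned reference base (SAM convention);
    ``cigar`` is a decoded list of ``(op, run_length)`` with op in
    ``{M, I, D, S, N}``.
    """

    query_id: str
    reference_name: str
    pos: int
    cigar: tuple[tuple[str, int], ...]
    library_id: str = ""


def decode_cigar(cigar: str) -> tuple[tuple[str, int], ...]:
    """Decode a CIGAR string into an op list, rejecting unsupported ops."""
    if not cigar or cigar == "*":
        raise ParseError("empty CIGAR")
    ops: list[tuple[str, int]] = []
    pos = 0
    for m in _CIGAR_TOKEN.finditer(cigar):
        if m.start() != pos:
            raise ParseError(f"invalid CIGAR token in {cigar!r}")
        run, op = int(m.group(1)), m.group(2)
        if op not in CIGAR_OPS:
            raise ParseError(f"unsupported CIGAR op {op!r} in {cigar!r}")
        if run < 1:
            raise ParseError(f"zero-length CIGAR run in {cigar!r}")
        ops.append((op, run))
        pos = m.end()
    if pos != len(cigar):
        raise ParseError(f"invalid CIGAR token in {cigar!r}")
    if not any(op == "M" for op, _ in ops):
        raise ParseError(f"CIGAR {cigar!r} has no M op (nothing aligned)")
    return tuple(ops)


def encode_cigar(ops: Sequence[tuple[str, int]]) -> str:
    return "".join(f"{run}{op}" for op, run in ops)


def read_alignments(path: str | Path, library_id: str | None = None) -> Iterator[AlignmentRecord]:
    """Stream mapped reads from a SAM text file.

    Header lines (``@``) are skipped; only the mandatory columns 1-6 are
    honoured.  Unmapped records (FLAG bit 4 or CIGAR ``*``) are excluded.
    ``library_id`` defaults to the file stem.
    """
    path = Path(path)
    lib = library_id if library_id is not None else path.stem
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("@"):
                continue
            cols = line.split("\t")
            if len(cols) < 6:
                raise ParseError(f"{path}:{lineno}: expected >=6 SAM columns, got {len(cols)}")
            qname, flag_s, rname, pos_s, _mapq, cigar = cols[:6]
            try:
                flag = int(flag_s)
                pos = int(pos_s)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer FLAG/POS: {exc}") from exc
            if flag & 4 or cigar == "*" or rname == "*":
                continue
            try:
                ops = decode_cigar(cigar)
            except ParseError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            yield AlignmentRecord(qname, rname, pos, ops, lib)


def write_alignments(
    records: Iterable[AlignmentRecord],
    path: str | Path,
    annotation: Annotation | None = None,
) -> int:
    """Write records as SAM text with a minimal @HD/@SQ header.

    Returns the number of records written.  The reference length in @SQ is
    taken from the annotation extent when provided, else from the records.
    """
    path = Path(path)
    records = list(records)
    if annotation is not None:
        ref_lens = {annotation.reference_name: annotation.extent}
    else:
        ref_lens = {}
        for r in records:
            span = sum(run for op, run in r.cigar if op in "MDN")
            end = r.pos - 1 + span
            ref_lens[r.reference_name] = max(ref_lens.get(r.reference_name, 1), end)
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for ref, ln in ref_lens.items():
            fh.write(f"@SQ\tSN:{ref}\tLN:{ln}\n")
        for r in records:
            fh.write(
                f"{r.query_id}\t0\t{r.reference_name}\t{r.pos}\t255\t"
                f"{encode_cigar(r.cigar)}\t*\t0\t0\t*\t*\n"
            )
    return len(records)


# ---------------------------------------------------------------------------
# Protein sequences
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SequenceRecord:
    """A protein sequence; residues uppercase-normalized on read."""

    seq_id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValidationError(f"sequence {self.seq_id}: empty")
        bad = set(self.residues) - set(AMINO_ACIDS)
        if bad:
            raise ValidationError(
                f"sequence {self.seq_id}: non amino-acid letters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(SequenceRecord(rec.id, str(rec.seq).upper()))
    if not records:
        raise ValidationError(f"{path}: no FASTA records")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f">{r.seq_id}\n")
            for i in range(0, len(r.residues), 60):
                fh.write(r.residues[i : i + 60] + "\n")


# ---------------------------------------------------------------------------
# Species trees (Newick via dendropy)
# ---------------------------------------------------------------------------

SpeciesTree = dendropy.Tree


def read_newick(path: str | Path) -> SpeciesTree:
    """Read a single rooted tree; leaf labels must be unique."""
    try:
        tree = dendropy.Tree.get(
            path=str(path),
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise ParseError(f"{path}: malformed Newick: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        raise ValidationError(f"{path}: duplicate leaf labels")
    tree.is_rooted = True
    return tree


def parse_newick(newick: str) -> SpeciesTree:
    try:
        tree = dendropy.Tree.get(
            data=newick,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:
        raise ParseError(f"malformed Newick: {exc}") from exc
    tree.is_rooted = True
    return tree


def write_newick(tree: SpeciesTree, path: str | Path) -> None:
    tree.write(
        path=str(path),
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    )


# ---------------------------------------------------------------------------
# Presence/absence matrices
# ---------------------------------------------------------------------------


@dataclass
class PresenceMatrix:
    """Protein x species booleans; ``uncertain`` flags tentative cells."""

    presence: pd.DataFrame
    uncertain: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.presence = self.presence.astype(bool)
        if self.uncertain is None:
            self.uncertain = pd.DataFrame(
                False, index=self.presence.index, columns=self.presence.columns
            )
        self.uncertain = self.uncertain.astype(bool)
        if not self.uncertain.index.equals(self.presence.index) or not self.uncertain.columns.equals(
            self.presence.columns
        ):
            raise ValidationError("presence and uncertain matrices must be aligned")

    @property
    def proteins(self) -> list[str]:
        return list(self.presence.index)

    @property
    def species(self) -> list[str]:
        return list(self.presence.columns)


def read_presence(path: str | Path) -> PresenceMatrix:
    """Read a presence TSV: rows proteins, columns species, cells 1/0/?.

    ``?`` marks a present-but-uncertain ortholog call.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    valid = {"0", "1", "?"}
    bad = set(df.values.ravel()) - valid
    if bad:
        raise ParseError(f"{path}: invalid presence cells {sorted(bad)} (expected 0/1/?)")
    presence = df.isin(["1", "?"])
    uncertain = df == "?"
    return PresenceMatrix(presence, uncertain)


def write_presence(matrix: PresenceMatrix, path: str | Path) -> None:
    cells = pd.DataFrame("0", index=matrix.presence.index, columns=matrix.presence.columns)
    cells = cells.mask(matrix.presence, "1").mask(matrix.presence & matrix.uncertain, "?")
    cells.to_csv(path, sep="\t", index_label="protein")


# ---------------------------------------------------------------------------
# pLDDT profiles
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PLDDTProfile:
    """Per-residue AlphaFold confidence values on contiguous residue indices."""

    residue_index: np.ndarray
    plddt: np.ndarray

    def __post_init__(self) -> None:
        idx = np.asarray(self.residue_index, dtype=int)
        val = np.asarray(self.plddt, dtype=float)
        object.__setattr__(self, "residue_index", idx)
        object.__setattr__(self, "plddt", val)
        if idx.size == 0:
            raise ValidationError("empty pLDDT profile")
        if idx.size != val.size:
            raise ValidationError("residue_index and plddt length mismatch")
        if not np.all(np.diff(idx) == 1):
            raise ValidationError("residue indices must be contiguous (step 1)")
        if np.any(val < 0) or np.any(val > 100):
            raise ValidationError("pLDDT values must lie in [0, 100]")

    def __len__(self) -> int:
        return len(self.residue_index)


def read_plddt(path: str | Path) -> PLDDTProfile:
    """Read a two-column TSV (residue_index, plddt); strict about gaps/range."""
    path = Path(path)
    idx: list[int] = []
    val: list[float] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t") if "\t" in line else line.split()
            if cols[0] in ("residue_index", "residue"):
                continue
            if len(cols) < 2:
                raise ParseError(f"{path}:{lineno}: expected 2 columns")
            try:
                idx.append(int(cols[0]))
                val.append(float(cols[1]))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    if not idx:
        raise ValidationError(f"{path}: empty pLDDT profile")
    try:
        return PLDDTProfile(np.array(idx), np.array(val))
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def write_plddt(profile: PLDDTProfile, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("residue_index\tplddt\n")
        for i, v in zip(profile.residue_index, profile.plddt):
            fh.write(f"{i}\t{v:.6g}\n")
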