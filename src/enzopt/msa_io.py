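"""Reading, validating and partitioning aligned enzyme families.

An aligned family is a set of equal-length protein sequences over the
21-symbol alphabet ``A`` (the 20 standard amino acids plus the alignment
gap ``-``, which is treated as an ordinary symbol throughout).  Each
sequence may carry an optimal-condition label (e.g. optimal pH); labeled
sequences are split into a high-condition set ``S_h`` and a low-condition
set ``S_l`` by a threshold, the starting point for embedding training.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
#: Full alphabet: 20 amino acids (alphabetical one-letter order) then the gap.
ALPHABET = AMINO_ACIDS + GAP
SYMBOL_INDEX = {s: i for i, s in enumerate(ALPHABET)}
GAP_INDEX = SYMBOL_INDEX[GAP]

#: Ambiguous/non-standard residue codes rejected by default.
AMBIGUOUS_CODES = set("XBZUJO*.")


class AlignmentError(ValueError):
    """Records do not form a valid alignment (unequal lengths, empty file)."""


class AlphabetError(ValueError):
    """A residue symbol falls outside the 21-symbol alphabet."""


class LabelError(ValueError):
    """A label table is malformed or inconsistent with the family."""


@dataclass(frozen=True)
class AlignedSequence:
    """One row of an alignment, optionally labeled with its optimal condition."""

    id: str
    residues: str
    label: float | None = None

    def __post_init__(self) -> None:
        if len(self.residues) == 0:
            raise AlignmentError(f"sequence {self.id!r} is empty")
        bad = set(self.residues) - set(ALPHABET)
        if bad:
            raise AlphabetError(
                f"sequence {self.id!r} contains symbols outside the alphabet: "
                f"{sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def encoded(self) -> np.ndarray:
        """Residues as uint8 indices into :data:`ALPHABET`."""
        return np.frombuffer(
            bytes(SYMBOL_INDEX[s] for s in self.residues), dtype=np.uint8
        ).copy()


@dataclass
class AlignedFamily:
    """An aligned family: equal-length sequences with unique ids."""

    sequences: list[AlignedSequence]

    def __post_init__(self) -> None:
        if not self.sequences:
            raise AlignmentError("family contains no sequences")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise AlignmentError(
                f"sequences have unequal aligned lengths: {sorted(lengths)}"
            )
        ids = [s.id for s in self.sequences]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise AlignmentError(f"duplicate sequence ids: {dupes}")

    @property
    def l(self) -> int:
        """Aligned length (number of columns)."""
        return len(self.sequences[0])

    def __len__(self) -> int:
        return len(self.sequences)

    def __iter__(self):
        return iter(self.sequences)

    def __getitem__(self, seq_id: str) -> AlignedSequence:
        for s in self.sequences:
            if s.id == seq_id:
                return s
        raise KeyError(seq_id)

    @property
    def ids(self) -> list[str]:
        return [s.id for s in self.sequences]

    def labeled(self) -> list[AlignedSequence]:
        return [s for s in self.sequences if s.label is not None]

    def subset(self, ids: Iterable[str]) -> "AlignedFamily":
        wanted = set(ids)
        missing = wanted - set(self.ids)
        if missing:
            raise KeyError(f"ids not in family: {sorted(missing)}")
        return AlignedFamily([s for s in self.sequences if s.id in wanted])

    def to_matrix(self) -> np.ndarray:
        """(n, l) uint8 matrix of symbol indices, row order = sequence order."""
        return np.stack([s.encoded() for s in self.sequences])


@dataclass(frozen=True)
class Partition:
    """Disjoint high/low condition id sets produced by a label threshold."""

    S_h: frozenset[str]
    S_l: frozenset[str]
    threshold: float

    def __post_init__(self) -> None:
        if self.S_h & self.S_l:
            raise ValueError("S_h and S_l overlap")

    @property
    def labeled_ids(self) -> frozenset[str]:
        return self.S_h | self.S_l


def read_aligned_fasta(path: str | Path, *, ambiguous: str = "error") -> AlignedFamily:
    """Read an aligned FASTA file into an :class:`AlignedFamily`.

    Parameters
    ----------
    path:
        Aligned FASTA; all records must have identical length.
    ambiguous:
        ``"error"`` (default) rejects ambiguous codes (X, B, Z, U, ...);
        ``"gap"`` silently maps them to the gap symbol.
    """
    if ambiguous not in ("error", "gap"):
        raise ValueError("ambiguous must be 'error' or 'gap'")
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentError(f"no FASTA records found in {path}")
    seqs = []
    for rec in records:
        residues = str(rec.seq).upper()
        if ambiguous == "gap":
            residues = "".join(GAP if r in AMBIGUOUS_CODES else r for r in residues)
        seqs.append(AlignedSequence(id=rec.id, residues=residues))
    return AlignedFamily(seqs)


def write_aligned_fasta(
    family: AlignedFamily, path: str | Path, *, wrap: int = 60
) -> None:
    """Write a family as aligned FASTA (round-trips with :func:`read_aligned_fasta`)."""
    records = [
        SeqRecord(Seq(s.residues), id=s.id, description="") for s in family
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=wrap)
        writer.write_file(records)


def read_labels(path: str | Path) -> dict[str, float]:
    """Read a two-column TSV (id, optimal-condition value) into a dict.

    A single header row is tolerated when its second field is non-numeric.
    Duplicate ids and non-numeric values raise :class:`LabelError`.
    """
    rows: list[tuple[str, str]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise LabelError(
                    f"{path}:{lineno}: expected 2 tab-separated columns, "
                    f"got {len(parts)}"
                )
            rows.append((parts[0].strip(), parts[1].strip()))
    if not rows:
        raise LabelError(f"{path}: no label rows")
    start = 0
    try:
        float(rows[0][1])
    except ValueError:
        start = 1  # header row
    labels: dict[str, float] = {}
    for sid, value in rows[start:]:
        if sid in labels:
            raise LabelError(f"duplicate id in label table: {sid!r}")
        try:
            labels[sid] = float(value)
        except ValueError as exc:
            raise LabelError(f"non-numeric label for {sid!r}: {value!r}") from exc
    return labels


def write_labels(labels: Mapping[str, float], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("id\toptimal_pH\n")
        for sid, value in labels.items():
            fh.write(f"{sid}\t{value:g}\n")


def attach_labels(
    family: AlignedFamily, labels: Mapping[str, float]
) -> AlignedFamily:
    """Return a copy of *family* whose sequences carry the given labels.

    Every label id must occur in the family; family members absent from the
    label table are retained unlabeled.
    """
    missing = set(labels) - set(family.ids)
    if missing:
        raise LabelError(f"label ids absent from family: {sorted(missing)}")
    return AlignedFamily(
        [
            replace(s, label=labels[s.id]) if s.id in labels else s
            for s in family
        ]
    )


def resolve_threshold(family: AlignedFamily, threshold: float | str) -> float:
    """Resolve a numeric threshold or the string ``"mean"`` (label average)."""
    if isinstance(threshold, str):
        if threshold != "mean":
            raise ValueError(f"unknown threshold spec {threshold!r}")
        labeled = family.labeled()
        if not labeled:
            raise LabelError("no labeled sequences; cannot take the label mean")
        return float(np.mean([s.label for s in labeled]))
    return float(threshold)


def partition_by_threshold(
    family: AlignedFamily, threshold: float | str = 7.0
) -> Partition:
    """Split labeled ids into S_h (label > threshold) and S_l (label <= threshold).

    The boundary label goes to S_l (strict inequality for the high set).  A
    one-sided partition is legal but triggers a warning since contrastive
    training needs both sets.
    """
    thr = resolve_threshold(family, threshold)
    labeled = family.labeled()
    if not labeled:
        raise LabelError("no labeled sequences to partition")
    high = frozenset(s.id for s in labeled if s.label > thr)
    low = frozenset(s.id for s in labeled if s.label <= thr)
    if not high or not low:
        side = "S_h" if not high else "S_l"
        warnings.warn(
            f"partition at threshold {thr:g} leaves {side} empty; "
            "contrastive training downstream is impossible",
            stacklevel=2,
        )
    return Partition(S_h=high, S_l=low, threshold=thr)
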