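"""Alignment and population-label input/output.

Every statistic in this package operates on a multiple sequence alignment
together with a population map assigning each sequence to a group (e.g. the
left/right Amazon-bank *Rhinella marina* groups and *R. schneideri*).

Sites containing an alignment gap (``-``) or missing data (``N``) in *any*
analyzed sequence are removed before computing statistics ("complete
deletion").  The number of remaining columns is the *net* site count; it is
recomputed for every set of sequences under analysis, so a subgroup of an
alignment can have a larger net length than the full alignment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

__all__ = [
    "Alignment",
    "GroupMap",
    "AlignmentError",
    "read_alignment",
    "write_alignment",
    "read_group_map",
    "write_group_map",
    "net_site_mask",
    "apply_mask",
    "subset",
]

#: integer codes used internally for vectorised site arithmetic.
#: Transitions are A<->G and C<->T, i.e. codes sharing the high bit pair.
_CODE = {"A": 0, "G": 1, "C": 2, "T": 3, "-": 4, "N": 5}
_DECODE = np.array(list("AGCT-N"))

_IUPAC_AMBIGUOUS = set("RYSWKMBDHV")


class AlignmentError(ValueError):
    """Raised for malformed alignments (unequal lengths, empty input...)."""


@dataclass(frozen=True)
class Alignment:
    """An aligned set of DNA sequences over the alphabet {A,C,G,T,-,N}.

    Parameters
    ----------
    ids
        Unique sequence identifiers, one per row.
    seqs
        Equal-length uppercase sequence strings.
    """

    ids: tuple[str, ...]
    seqs: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.seqs):
            raise AlignmentError("ids and seqs must have equal length")
        if len(self.ids) == 0:
            raise AlignmentError("empty alignment")
        if len(set(self.ids)) != len(self.ids):
            raise AlignmentError("duplicate sequence identifiers")
        L = len(self.seqs[0])
        if L < 1:
            raise AlignmentError("zero-length sequences")
        for sid, s in zip(self.ids, self.seqs):
            if len(s) != L:
                raise AlignmentError(
                    f"sequence {sid!r} has length {len(s)}, expected {L}"
                )
            bad = set(s) - set("ACGT-N")
            if bad:
                raise AlignmentError(f"sequence {sid!r} has invalid symbols {bad}")

    # -- basic geometry -------------------------------------------------
    @property
    def n(self) -> int:
        """Number of sequences."""
        return len(self.ids)

    @property
    def length(self) -> int:
        """Number of alignment columns (total sites)."""
        return len(self.seqs[0])

    def codes(self) -> np.ndarray:
        """(n, length) int8 matrix; A=0 G=1 C=2 T=3 '-'=4 N=5."""
        flat = np.frombuffer("".join(self.seqs).encode(), dtype=np.uint8)
        lut = np.zeros(128, dtype=np.int8)
        for base, code in _CODE.items():
            lut[ord(base)] = code
        return lut[flat].reshape(self.n, self.length)

    @classmethod
    def from_codes(cls, ids: Iterable[str], codes: np.ndarray) -> "Alignment":
        rows = ["".join(_DECODE[row]) for row in np.asarray(codes)]
        return cls(tuple(ids), tuple(rows))


@dataclass(frozen=True)
class GroupMap:
    """Assignment of sequence ids to population/species labels."""

    mapping: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sid, grp in self.mapping.items():
            if not grp:
                raise ValueError(f"empty group label for id {sid!r}")

    def __getitem__(self, sid: str) -> str:
        return self.mapping[sid]

    def labels(self) -> tuple[str, ...]:
        """Distinct group labels, in first-appearance order."""
        return tuple(dict.fromkeys(self.mapping.values()))

    def ids_for(self, label: str) -> tuple[str, ...]:
        ids = tuple(s for s, g in self.mapping.items() if g == label)
        if not ids:
            raise KeyError(f"no sequences labelled {label!r}")
        return ids


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def read_alignment(path: str | Path, format: str = "fasta") -> Alignment:
    """Read an alignment from a FASTA file.

    Bases are uppercased; IUPAC ambiguity codes other than N are mapped to N
    with a logged warning.  Unequal sequence lengths raise
    :class:`AlignmentError`.
    """
    if format != "fasta":
        raise ValueError(f"unsupported format {format!r}")
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentError(f"no FASTA records in {path}")
    ids, seqs = [], []
    warned = False
    for rec in records:
        s = str(rec.seq).upper()
        ambiguous = set(s) & _IUPAC_AMBIGUOUS
        if ambiguous:
            if not warned:
                logger.warning(
                    "mapping IUPAC ambiguity codes %s to N in %s",
                    "".join(sorted(ambiguous)), path,
                )
                warned = True
            s = "".join("N" if c in _IUPAC_AMBIGUOUS else c for c in s)
        ids.append(rec.id)
        seqs.append(s)
    return Alignment(tuple(ids), tuple(seqs))


def write_alignment(aln: Alignment, path: str | Path) -> None:
    """Write the alignment as FASTA."""
    records = [
        SeqRecord(Seq(s), id=sid, description="")
        for sid, s in zip(aln.ids, aln.seqs)
    ]
    SeqIO.write(records, str(path), "fasta")


def read_group_map(path: str | Path) -> GroupMap:
    """Read a two-column TSV ``id<TAB>group``; '#' starts a comment line."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 'id<TAB>group'")
            sid, grp = parts[0].strip(), parts[1].strip()
            if sid in mapping:
                raise ValueError(f"{path}:{lineno}: duplicate id {sid!r}")
            mapping[sid] = grp
    return GroupMap(mapping)


def write_group_map(gm: GroupMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# id\tgroup\n")
        for sid, grp in gm.mapping.items():
            fh.write(f"{sid}\t{grp}\n")


# ---------------------------------------------------------------------------
# net sites
# ---------------------------------------------------------------------------

def net_site_mask(aln: Alignment) -> np.ndarray:
    """Boolean mask of columns free of gaps and missing data in all rows.

    The count of True entries is the "net" site number; all statistics in
    this package are computed on these columns only (complete deletion).
    """
    codes = aln.codes()
    return np.all(codes < 4, axis=0)


def apply_mask(aln: Alignment, mask: np.ndarray) -> Alignment:
    """Restrict the alignment to the columns where ``mask`` is True."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (aln.length,):
        raise ValueError("mask length does not match alignment length")
    if not mask.any():
        raise AlignmentError("mask removes every column")
    codes = aln.codes()[:, mask]
    return Alignment.from_codes(aln.ids, codes)


def subset(aln: Alignment, gm: GroupMap, label: str) -> Alignment:
    """Alignment restricted to the sequences of one group (same columns)."""
    wanted = set(gm.ids_for(label))
    keep = [i for i, sid in enumerate(aln.ids) if sid in wanted]
    if not keep:
        raise KeyError(f"no sequences of group {label!r} in alignment")
    return Alignment(
        tuple(aln.ids[i] for i in keep), tuple(aln.seqs[i] for i in keep)
    )
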