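"""Reading, validating and writing protein sequences and two-class datasets.

FASTA parsing is delegated to :mod:`Bio.SeqIO`. Sanitization maps records
onto the 20-letter standard alphabet: the default policy silently drops
non-standard letters (B, J, O, U, X, Z, gaps, ``*``) because composition
features are defined only over the 20 standard residues; a strict policy
rejects any record containing them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alphabet import AA_INDEX
from .errors import DatasetError, FastaError

logger = logging.getLogger(__name__)

__all__ = [
    "ProteinSequence",
    "LabeledDataset",
    "sanitize_residues",
    "read_fasta",
    "write_fasta",
    "load_dataset",
]


@dataclass(frozen=True)
class ProteinSequence:
    """A validated protein sequence.

    Parameters
    ----------
    id : str
        Free-text identifier (FASTA header up to the first whitespace).
    residues : str
        Non-empty string over the 20 standard one-letter codes.
    """

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"sequence {self.id!r}: empty residue string")
        bad = {c for c in self.residues if c not in AA_INDEX}
        if bad:
            raise ValueError(
                f"sequence {self.id!r}: non-standard letters "
                f"{''.join(sorted(bad))}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class LabeledDataset:
    """A two-class protein dataset (positives vs negatives).

    The two classes must be disjoint by sequence identifier.
    """

    positives: list[ProteinSequence]
    negatives: list[ProteinSequence]
    name: str = ""

    def __post_init__(self) -> None:
        dup = {s.id for s in self.positives} & {s.id for s in self.negatives}
        if dup:
            raise DatasetError(
                f"dataset {self.name!r}: identifiers present in both "
                f"classes: {sorted(dup)[:5]}"
            )

    @property
    def n_pos(self) -> int:
        return len(self.positives)

    @property
    def n_neg(self) -> int:
        return len(self.negatives)

    def all_sequences(self) -> list[ProteinSequence]:
        return list(self.positives) + list(self.negatives)


def sanitize_residues(raw: str, *, strict: bool = False) -> str:
    """Normalize a raw residue string onto the standard alphabet.

    Upper-cases, strips whitespace, then either drops non-standard letters
    (default) or raises :class:`FastaError` (``strict=True``).
    """
    seq = "".join(raw.split()).upper()
    bad = [c for c in seq if c not in AA_INDEX]
    if bad:
        if strict:
            raise FastaError(
                f"non-standard residues {''.join(sorted(set(bad)))} "
                "(strict alphabet policy)"
            )
        seq = "".join(c for c in seq if c in AA_INDEX)
    return seq


def read_fasta(path: str | Path, *, strict: bool = False) -> list[ProteinSequence]:
    """Read a FASTA file into sanitized :class:`ProteinSequence` records.

    Record order is preserved. Under the default policy, records whose
    residues are all non-standard are skipped with a warning; under
    ``strict=True`` any non-standard letter rejects the whole file.
    """
    path = Path(path)
    try:
        records = list(SeqIO.parse(str(path), "fasta"))
    except (OSError, ValueError) as exc:
        raise FastaError(f"cannot read FASTA file {path}: {exc}") from exc

    sequences: list[ProteinSequence] = []
    for rec in records:
        raw = str(rec.seq)
        try:
            clean = sanitize_residues(raw, strict=strict)
        except FastaError as exc:
            raise FastaError(f"{path}, record {rec.id!r}: {exc}") from exc
        if clean != "".join(raw.split()).upper():
            logger.warning(
                "record %r: dropped %d non-standard residue(s)",
                rec.id, len("".join(raw.split())) - len(clean),
            )
        if not clean:
            logger.warning("record %r emptied by sanitization; skipped", rec.id)
            continue
        sequences.append(ProteinSequence(id=rec.id, residues=clean))
    return sequences


def write_fasta(sequences: list[ProteinSequence], path: str | Path) -> None:
    """Write sequences to a FASTA file (60-column wrapped)."""
    records = [
        SeqRecord(Seq(s.residues), id=s.id, description="") for s in sequences
    ]
    SeqIO.write(records, str(Path(path)), "fasta")


def load_dataset(
    pos_path: str | Path,
    neg_path: str | Path,
    *,
    name: str = "",
    strict: bool = False,
) -> LabeledDataset:
    """Load a labeled two-class dataset from two FASTA files.

    Raises :class:`DatasetError` if either class is empty or the classes
    share an identifier.
    """
    positives = read_fasta(pos_path, strict=strict)
    negatives = read_fasta(neg_path, strict=strict)
    if not positives:
        raise DatasetError(f"positive file {pos_path} contains no usable sequences")
    if not negatives:
        raise DatasetError(f"negative file {neg_path} contains no usable sequences")
    return LabeledDataset(positives=positives, negatives=negatives, name=name)
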