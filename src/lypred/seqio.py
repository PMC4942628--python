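"""Reading, validating and writing protein sequences.

Admissibility rules mirror the prediction server's constraints: sequences
must use only the 20 standard one-letter amino-acid codes and be at least
8 residues long (the encoder imposes stricter per-parameter minima on top
of this). Records with unknown residues such as B, J, O, U, X or Z are
either rejected with an error or skipped with a warning, depending on
policy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Literal

from Bio.SeqIO.FastaIO import SimpleFastaParser

from .errors import (
    EmptyInputError,
    FastaParseError,
    LypredError,
    SequenceValidationError,
)

logger = logging.getLogger(__name__)

#: The 20 standard amino acids, alphabetical one-letter order. This is the
#: canonical residue ordering used by every module in the package.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_SET = frozenset(AMINO_ACIDS)

#: Default minimum admissible sequence length.
DEFAULT_MIN_LENGTH = 8

OnInvalid = Literal["reject", "skip"]


@dataclass(frozen=True)
class ProteinRecord:
    """One validated protein sequence.

    Attributes
    ----------
    id:
        FASTA header token (text after ``>`` up to the first whitespace).
    sequence:
        Uppercase residues over the 20-letter alphabet.
    description:
        Remainder of the FASTA header line, if any.
    """

    id: str
    sequence: str
    description: str = field(default="", compare=False)

    @property
    def length(self) -> int:
        return len(self.sequence)

    def __len__(self) -> int:  # pragma: no cover - convenience
        return len(self.sequence)


def validate_sequence(sequence: str, min_length: int = DEFAULT_MIN_LENGTH) -> str | None:
    """Check a raw sequence against the admissibility rules.

    Returns ``None`` when the sequence is valid, otherwise a human-readable
    reason. Total function: never raises.

    Lowercase letters are accepted (they are uppercased on ingestion);
    anything outside the 20-letter alphabet — including ``*`` stop codes and
    ambiguity codes like B, J, O, U, X, Z — is invalid.
    """
    if not sequence:
        return "empty sequence"
    seq = sequence.upper()
    bad = sorted(set(seq) - AA_SET)
    if bad:
        return "invalid residue(s): " + ", ".join(repr(c) for c in bad)
    if len(seq) < min_length:
        return f"sequence length {len(seq)} is below the minimum of {min_length}"
    return None


def _clean(raw: str) -> str:
    """Strip whitespace inside a sequence block and uppercase."""
    return "".join(raw.split()).upper()


def _iter_fasta(path: Path) -> Iterator[tuple[str, str, str]]:
    """Yield (id, description, raw sequence) triples; disambiguate ids."""
    with open(path) as handle:
        first = ""
        for line in handle:
            if line.strip():
                first = line
                break
        if not first:
            raise EmptyInputError(f"{path}: file contains no records")
        if not first.lstrip().startswith(">"):
            raise FastaParseError(
                f"{path}: sequence data found before the first '>' header"
            )
    seen: dict[str, int] = {}
    with open(path) as handle:
        for title, raw in SimpleFastaParser(handle):
            parts = title.split(None, 1)
            rid = parts[0] if parts else ""
            desc = parts[1] if len(parts) > 1 else ""
            if not rid:
                rid = "unnamed"
            n = seen.get(rid, 0) + 1
            seen[rid] = n
            if n > 1:
                rid = f"{rid}_{n}"
            yield rid, desc, raw


def read_fasta(
    path: str | Path,
    min_length: int = DEFAULT_MIN_LENGTH,
    on_invalid: OnInvalid = "reject",
) -> list[ProteinRecord]:
    """Read and validate a FASTA file of protein sequences.

    Parameters
    ----------
    path:
        FASTA file; single- or multi-line sequence blocks.
    min_length:
        Minimum admissible residue count (default 8).
    on_invalid:
        ``"reject"`` raises on the first invalid record; ``"skip"`` drops
        invalid records with a logged warning.

    Returns records in file order with uppercased sequences. Duplicate ids
    get an occurrence counter suffix (``id_2``, ``id_3``, ...).
    """
    if min_length < 1:
        raise ValueError("min_length must be >= 1")
    if on_invalid not in ("reject", "skip"):
        raise ValueError(f"unknown on_invalid policy: {on_invalid!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)

    records: list[ProteinRecord] = []
    n_parsed = 0
    for rid, desc, raw in _iter_fasta(path):
        n_parsed += 1
        seq = _clean(raw)
        reason = validate_sequence(seq, min_length)
        if reason is not None:
            if on_invalid == "reject":
                raise SequenceValidationError(f"record {rid!r}: {reason}")
            logger.warning("skipping record %r: %s", rid, reason)
            continue
        records.append(ProteinRecord(id=rid, sequence=seq, description=desc))
    if n_parsed == 0:
        raise EmptyInputError(f"{path}: file contains no records")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    """Write records to FASTA, wrapping sequence lines at ``width``."""
    path = Path(path)
    with open(path, "w") as out:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            out.write(f">{header}\n")
            for i in range(0, rec.length, width):
                out.write(rec.sequence[i : i + width] + "\n")


def read_labels(path: str | Path) -> dict[str, int]:
    """Read a two-column TSV of ``id<TAB>label`` with label in {0, 1}.

    1 marks the positive class (lyase). Blank lines and lines starting with
    '#' are ignored.
    """
    labels: dict[str, int] = {}
    path = Path(path)
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise LypredError(
                    f"{path}:{lineno}: expected 'id<TAB>label', got {line!r}"
                )
            rid, lab = parts[0].strip(), parts[1].strip()
            if lab not in ("0", "1"):
                raise LypredError(f"{path}:{lineno}: label must be 0 or 1, got {lab!r}")
            if rid in labels:
                raise LypredError(f"{path}:{lineno}: duplicate id {rid!r}")
            labels[rid] = int(lab)
    if not labels:
        raise EmptyInputError(f"{path}: no labels found")
    return labels


def write_labels(labels: dict[str, int], path: str | Path) -> None:
    with open(path, "w") as out:
        for rid, lab in labels.items():
            out.write(f"{rid}\t{lab}\n")
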