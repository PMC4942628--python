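"""Amino-acid physicochemical property scales.

Nine per-residue scales are built in: hydrophobicity, hydrophilicity,
rigidity, flexibility, irreplaceability, side-chain mass, isoelectric
point (pI at 25 °C), pK of the α-COOH group and pK of the α-NH3+ group.
Before entering the sequence-correlation features each scale is
standardized over the 20 amino acids to zero mean and unit *population*
variance (squared deviations divided by 20, not 19).

Note: the built-in table gives asparagine (N) and arginine (R) identical
pI/pK(α-COOH)/pK(α-NH3+) triples (10.76 / 2.18 / 9.09). This is chemically
suspicious for asparagine but is kept verbatim as the scale this predictor
was defined with; users can substitute their own table via
:meth:`PhysChemTable.from_tsv`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import DegenerateScaleError
from .seqio import AMINO_ACIDS

PROPERTY_NAMES: tuple[str, ...] = (
    "hydrophobicity",
    "hydrophilicity",
    "rigidity",
    "flexibility",
    "irreplaceability",
    "mass",
    "pI",
    "pK_COOH",
    "pK_NH3",
)

# Original values, one row per amino acid (order ACDEFGHIKLMNPQRSTVWY),
# columns in PROPERTY_NAMES order.
_ORIGINAL_BY_AA: dict[str, tuple[float, ...]] = {
    "A": (0.62, -0.5, -1.338, -3.102, 0.52, 15, 6.11, 2.35, 9.87),
    "C": (0.29, -1.0, -1.511, 0.957, 1.12, 47, 5.02, 1.71, 10.78),
    "D": (-0.9, 3.0, -0.204, 0.424, 0.77, 59, 2.98, 1.88, 9.60),
    "E": (-0.74, 3.0, -0.365, 2.009, 0.76, 73, 3.08, 2.19, 9.67),
    "F": (1.19, -2.5, 2.877, -0.466, 0.86, 91, 5.91, 2.58, 9.24),
    "G": (0.48, 0.0, -1.097, -2.746, 0.56, 1, 6.06, 2.34, 9.60),
    "H": (-0.4, -0.5, 2.269, -0.223, 0.94, 82, 7.64, 1.78, 8.97),
    "I": (1.38, -1.8, -1.741, 0.424, 0.65, 57, 6.04, 2.32, 9.76),
    "K": (-1.5, 3.0, -1.822, 3.950, 0.81, 73, 9.47, 2.20, 8.90),
    "L": (1.06, -1.8, -1.741, 0.424, 0.58, 57, 6.04, 2.36, 9.60),
    "M": (0.64, -1.3, -1.741, 2.484, 1.25, 75, 5.74, 2.28, 9.21),
    "N": (-0.78, 0.2, -0.204, 0.424, 0.79, 58, 10.76, 2.18, 9.09),
    "P": (0.12, 0.0, 1.979, -2.404, 0.61, 42, 6.30, 1.99, 10.60),
    "Q": (-0.85, 0.2, -0.365, 2.009, 0.86, 72, 5.65, 2.17, 9.13),
    "R": (-2.53, 3.0, 1.169, 3.060, 0.60, 101, 10.76, 2.18, 9.09),
    "S": (-0.18, 0.3, -1.511, 0.957, 0.64, 31, 5.68, 2.21, 9.15),
    "T": (-0.05, -0.4, -1.641, -1.339, 0.56, 45, 5.60, 2.15, 9.12),
    "V": (1.08, -1.5, -1.641, -1.339, 0.54, 43, 6.02, 2.29, 9.74),
    "W": (0.81, -3.4, 5.913, -1.000, 1.82, 130, 5.88, 2.38, 9.39),
    "Y": (0.26, -2.3, 2.714, -0.672, 0.98, 107, 5.63, 2.20, 9.11),
}


def normalize_properties(original: np.ndarray) -> np.ndarray:
    """Standardize each property row to mean 0, population variance 1.

    ``original`` is a (n_properties, 20) matrix, columns in the canonical
    amino-acid order. Each row x is transformed to
    ``(x - mean(x)) / sqrt(sum((x - mean(x))**2) / 20)``.

    Raises
    ------
    DegenerateScaleError
        If a row is constant (zero population variance).
    """
    original = np.asarray(original, dtype=float)
    if original.ndim != 2 or original.shape[1] != len(AMINO_ACIDS):
        raise ValueError(f"expected a (n, 20) matrix, got shape {original.shape}")
    mean = original.mean(axis=1, keepdims=True)
    centered = original - mean
    popvar = (centered**2).mean(axis=1, keepdims=True)
    if np.any(popvar == 0.0):
        rows = np.flatnonzero(popvar.ravel() == 0.0).tolist()
        raise DegenerateScaleError(f"constant property row(s) {rows}: cannot normalize")
    return centered / np.sqrt(popvar)


@dataclass(frozen=True)
class PhysChemTable:
    """Property scales, original and normalized, for the 20 amino acids.

    ``original`` and ``normalized`` are (n_properties, 20) arrays with
    columns in ``ACDEFGHIKLMNPQRSTVWY`` order.
    """

    property_names: tuple[str, ...]
    original: np.ndarray
    normalized: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        # force one memory layout so summation order (and hence the last
        # bits of the normalized values) is identical however the table
        # was constructed
        orig = np.ascontiguousarray(self.original, dtype=float)
        if orig.shape != (len(self.property_names), len(AMINO_ACIDS)):
            raise ValueError(
                f"original must be ({len(self.property_names)}, 20), got {orig.shape}"
            )
        object.__setattr__(self, "original", orig)
        object.__setattr__(self, "normalized", normalize_properties(orig))

    @property
    def n_properties(self) -> int:
        return len(self.property_names)

    @classmethod
    def default(cls) -> "PhysChemTable":
        """The built-in nine-scale table."""
        original = np.array(
            [_ORIGINAL_BY_AA[a] for a in AMINO_ACIDS], dtype=float
        ).T  # -> (9, 20)
        return cls(property_names=PROPERTY_NAMES, original=original)

    def to_tsv(self, path: str | Path) -> None:
        """Write the original values: rows = properties, columns = residues."""
        with open(path, "w") as out:
            out.write("property\t" + "\t".join(AMINO_ACIDS) + "\n")
            for name, row in zip(self.property_names, self.original):
                out.write(name + "\t" + "\t".join(format(v, ".17g") for v in row) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PhysChemTable":
        """Read a custom property table written in :meth:`to_tsv` layout."""
        with open(path) as handle:
            header = handle.readline().rstrip("\n").split("\t")
            if header[1:] != list(AMINO_ACIDS):
                raise ValueError(
                    "header must list the 20 amino acids in order " + AMINO_ACIDS
                )
            names: list[str] = []
            rows: list[list[float]] = []
            for line in handle:
                if not line.strip():
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) != 21:
                    raise ValueError(f"expected 21 columns, got {len(parts)}")
                names.append(parts[0])
                rows.append([float(v) for v in parts[1:]])
        return cls(property_names=tuple(names), original=np.array(rows))


_DEFAULT: PhysChemTable | None = None


def default_table() -> PhysChemTable:
    """Cached singleton of the built-in table."""
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = PhysChemTable.default()
    return _DEFAULT
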