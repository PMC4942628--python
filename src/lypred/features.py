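"""The improved pseudo amino acid composition (PseAAC) encoder.

A protein of length L is mapped to a vector of dimension 400 + n·δ:

* 400 g-gap dipeptide frequencies. A g-gap dipeptide is an ordered residue
  pair (a, b) separated by exactly g intervening positions; its frequency
  is the count of positions t with sequence[t] = a and sequence[t+g+1] = b
  divided by L − g − 1, so the block sums to one.
* n·δ lagged physicochemical correlation factors. For property j and lag d
  the factor is the average over t of ρj(R_t)·ρj(R_{t+d}), with ρj the
  normalized property value. The block is laid out lag-major: all n
  properties at lag 1, then lag 2, ..., up to lag δ.

The two blocks are concatenated unweighted. Dipeptide indexing is
first-residue-major over the alphabetical residue order, i.e. pair (a, b)
maps to 20·idx(a) + idx(b); feature names make the convention auditable.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import AlignmentError, SequenceTooShortError
from .physchem import PhysChemTable, default_table
from .seqio import AMINO_ACIDS, ProteinRecord

_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
_N_DIPEPTIDES = len(AMINO_ACIDS) ** 2  # 400

#: Parameter ranges explored by the published grid; values outside are
#: allowed but warned about.
G_GRID = range(0, 10)
DELTA_GRID = range(1, 11)


@dataclass(frozen=True)
class PseAACParams:
    """Encoder parameters.

    g:
        Gap length of the dipeptide block (local sequence order).
    delta:
        Maximum correlation lag δ (global sequence order).
    property_subset:
        Indices into the property table rows; default all nine scales.
    """

    g: int = 4
    delta: int = 7
    property_subset: tuple[int, ...] = tuple(range(9))

    def __post_init__(self) -> None:
        if self.g < 0:
            raise ValueError("g must be >= 0")
        if self.delta < 1:
            raise ValueError("delta must be >= 1")
        if not self.property_subset:
            raise ValueError("property_subset must be nonempty")
        if self.g not in G_GRID or self.delta not in DELTA_GRID:
            warnings.warn(
                f"(g={self.g}, delta={self.delta}) lies outside the standard "
                f"grid 0<=g<=9, 1<=delta<=10",
                stacklevel=2,
            )

    @property
    def n_props(self) -> int:
        return len(self.property_subset)

    @property
    def n_features(self) -> int:
        return _N_DIPEPTIDES + self.n_props * self.delta

    @property
    def min_length(self) -> int:
        """Shortest sequence this parameterization can encode."""
        return max(self.g + 2, self.delta + 1)


def _residue_indices(sequence: str) -> np.ndarray:
    try:
        return np.fromiter((_AA_INDEX[c] for c in sequence), dtype=np.intp, count=len(sequence))
    except KeyError as exc:  # pragma: no cover - guarded upstream by seqio
        raise ValueError(f"non-standard residue {exc.args[0]!r}") from exc


def gap_dipeptide_frequencies(record: ProteinRecord | str, g: int) -> np.ndarray:
    """Normalized g-gap dipeptide occurrence frequencies (length 400).

    Entry 20·idx(a) + idx(b) counts positions t (0-based) with
    ``seq[t] == a`` and ``seq[t+g+1] == b``, divided by L − g − 1.
    """
    seq = record.sequence if isinstance(record, ProteinRecord) else record
    L = len(seq)
    if L < g + 2:
        raise SequenceTooShortError(
            f"length {L} sequence cannot host a {g}-gap dipeptide (needs L >= {g + 2})"
        )
    idx = _residue_indices(seq)
    pairs = 20 * idx[: L - g - 1] + idx[g + 1 :]
    counts = np.bincount(pairs, minlength=_N_DIPEPTIDES)
    return counts / float(L - g - 1)


def correlation_factors(
    record: ProteinRecord | str,
    delta: int,
    table: PhysChemTable | None = None,
    property_subset: Sequence[int] | None = None,
) -> np.ndarray:
    """Lagged property-correlation factors, lag-major (length n·δ).

    Position (d−1)·n + j holds the lag-d factor of the j-th selected
    property: ``mean over t of rho_j(seq[t]) * rho_j(seq[t+d])``.
    """
    seq = record.sequence if isinstance(record, ProteinRecord) else record
    table = table or default_table()
    subset = tuple(property_subset) if property_subset is not None else tuple(
        range(table.n_properties)
    )
    L = len(seq)
    if L < delta + 1:
        raise SequenceTooShortError(
            f"length {L} sequence cannot support lag {delta} (needs L >= {delta + 1})"
        )
    idx = _residue_indices(seq)
    rho = table.normalized[list(subset)]  # (n, 20)
    vals = rho[:, idx]  # (n, L)
    n = len(subset)
    out = np.empty(n * delta, dtype=float)
    for d in range(1, delta + 1):
        out[(d - 1) * n : d * n] = (vals[:, : L - d] * vals[:, d:]).mean(axis=1)
    return out


def feature_names(params: PseAACParams, table: PhysChemTable | None = None) -> list[str]:
    """Deterministic names parallel to :func:`encode` output."""
    table = table or default_table()
    names = [
        f"dipeptide:{a}{b}:gap{params.g}"
        for a, b in itertools.product(AMINO_ACIDS, repeat=2)
    ]
    for d in range(1, params.delta + 1):
        for j in params.property_subset:
            names.append(f"corr:{table.property_names[j]}:lag{d}")
    return names


@dataclass(frozen=True)
class FeatureVector:
    """Encoded descriptor of one protein: values with parallel names."""

    values: np.ndarray
    names: list[str] = field(repr=False)

    def __post_init__(self) -> None:
        if len(self.values) != len(self.names):
            raise ValueError("values and names must have equal length")


def encode(
    record: ProteinRecord,
    params: PseAACParams,
    table: PhysChemTable | None = None,
) -> FeatureVector:
    """Encode one protein as the (400 + n·δ)-dimensional descriptor."""
    table = table or default_table()
    values = np.concatenate(
        [
            gap_dipeptide_frequencies(record, params.g),
            correlation_factors(record, params.delta, table, params.property_subset),
        ]
    )
    return FeatureVector(values=values, names=feature_names(params, table))


@dataclass
class FeatureMatrix:
    """Samples × features matrix with ids, named columns, binary labels."""

    X: pd.DataFrame
    y: np.ndarray

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=int)
        if len(self.X) != len(self.y):
            raise ValueError("X and y must have equal length")
        if self.X.columns.duplicated().any():
            raise ValueError("duplicate feature names")

    @property
    def ids(self) -> list[str]:
        return list(self.X.index)

    @property
    def n_samples(self) -> int:
        return len(self.X)

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def to_tsv(self, path) -> None:
        frame = self.X.copy()
        frame.insert(0, "label", self.y)
        frame.to_csv(path, sep="\t", index_label="id")

    @classmethod
    def from_tsv(cls, path) -> "FeatureMatrix":
        frame = pd.read_csv(path, sep="\t", index_col="id")
        y = frame.pop("label").to_numpy()
        return cls(X=frame, y=y)


def encode_matrix(
    records: Iterable[ProteinRecord],
    labels: Mapping[str, int],
    params: PseAACParams,
    table: PhysChemTable | None = None,
) -> FeatureMatrix:
    """Encode many records into a row-per-sample matrix.

    Labels are aligned by record id; a missing label or a duplicate id is
    an alignment error. Row order follows the input record order.
    """
    table = table or default_table()
    records = list(records)
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise AlignmentError(f"duplicate record ids: {dupes}")
    missing = [i for i in ids if i not in labels]
    if missing:
        raise AlignmentError(f"no label for record(s): {missing}")
    names = feature_names(params, table)
    rows = np.empty((len(records), params.n_features), dtype=float)
    for k, rec in enumerate(records):
        rows[k] = np.concatenate(
            [
                gap_dipeptide_frequencies(rec, params.g),
                correlation_factors(rec, params.delta, table, params.property_subset),
            ]
        )
    X = pd.DataFrame(rows, index=pd.Index(ids, name="id"), columns=names)
    y = np.array([labels[i] for i in ids], dtype=int)
    return FeatureMatrix(X=X, y=y)
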