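"""Readers, writers and encoders for alignment, taxonomy and base-pairing tables.

The on-disk dialect is the tab-delimited layout of CRW-style supplementary
tables: one row per organism, first field the organism identifier, remaining
fields single symbols — sequence elements ``A C G U N -`` for alignments,
pairing states ``Y N -`` (paired / unpaired / gap) for base-pairing tables.
An optional first header row of position labels is auto-detected. Aligned
FASTA (gap ``-``) is supported for alignments.

Symbol normalization applied on read: lowercase to uppercase, ``T`` to ``U``,
``.`` to ``-``. Anything else is an error unless coercion to ``N`` is
requested.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "SYMBOLS",
    "PAIRING_SYMBOLS",
    "AlignmentFormatError",
    "SequenceAlignment",
    "TaxonomyTable",
    "PairingTable",
    "NucleotideTensor",
    "read_alignment",
    "write_alignment",
    "read_taxonomy",
    "write_taxonomy",
    "read_pairing",
    "write_pairing",
    "filter_positions",
    "encode_tensor",
    "save_tensor_h5",
    "load_tensor_h5",
]

#: Fixed slice order of the six sequence elements.
SYMBOLS: tuple[str, ...] = ("A", "C", "G", "U", "N", "-")
SYMBOL_SET = frozenset(SYMBOLS)
NUCLEOTIDES = frozenset("ACGU")

#: Base-pairing states: paired, unpaired, gap.
PAIRING_SYMBOLS: tuple[str, ...] = ("Y", "N", "-")
PAIRING_SET = frozenset(PAIRING_SYMBOLS)


class AlignmentFormatError(ValueError):
    """Malformed alignment / taxonomy / pairing input."""


def _normalize_symbol(raw: str, *, coerce_unknown_to_n: bool = False,
                      where: str = "") -> str:
    s = raw.strip().upper()
    if s == "T":
        s = "U"
    elif s == ".":
        s = "-"
    if s in SYMBOL_SET:
        return s
    if coerce_unknown_to_n:
        return "N"
    raise AlignmentFormatError(
        f"unrecognized sequence symbol {raw!r}{' at ' + where if where else ''}; "
        f"expected one of {''.join(SYMBOLS)} (pass coerce_unknown_to_n=True to map to 'N')"
    )


def _normalize_pairing_symbol(raw: str, *, where: str = "") -> str:
    s = raw.strip().upper()
    if s == ".":
        s = "-"
    if s in PAIRING_SET:
        return s
    raise AlignmentFormatError(
        f"unrecognized pairing symbol {raw!r}{' at ' + where if where else ''}; "
        f"expected one of {''.join(PAIRING_SYMBOLS)}"
    )


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise AlignmentFormatError(f"duplicate {what} id {i!r}")
        seen.add(i)


@dataclass
class SequenceAlignment:
    """A K-organisms x M-positions character grid over ``A C G U N -``.

    ``position_labels`` are 1-based original column labels; they survive
    position filtering so that reported positions always refer to the
    unfiltered alignment.
    """

    organism_ids: list[str]
    characters: np.ndarray          # (K, M), dtype '<U1'
    position_labels: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.characters = np.asarray(self.characters, dtype="<U1")
        if self.characters.ndim != 2:
            raise ValueError("characters must be a 2-D grid")
        K, M = self.characters.shape
        if K < 2:
            raise ValueError(f"an alignment needs at least 2 organisms, got {K}")
        if M < 1:
            raise ValueError("an alignment needs at least 1 position")
        if len(self.organism_ids) != K:
            raise ValueError("organism_ids length does not match the grid")
        _check_unique(self.organism_ids, "organism")
        if not self.position_labels:
            self.position_labels = list(range(1, M + 1))
        if len(self.position_labels) != M:
            raise ValueError("position_labels length does not match the grid")
        bad = ~np.isin(self.characters, list(SYMBOLS))
        if bad.any():
            i, m = np.argwhere(bad)[0]
            raise AlignmentFormatError(
                f"invalid symbol {self.characters[i, m]!r} for organism "
                f"{self.organism_ids[i]!r} at column {self.position_labels[m]}"
            )

    @property
    def n_organisms(self) -> int:
        return self.characters.shape[0]

    @property
    def n_positions(self) -> int:
        return self.characters.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.characters.shape

    def row(self, organism_id: str) -> np.ndarray:
        return self.characters[self.organism_ids.index(organism_id)]

    def column_index(self, label: int) -> int:
        try:
            return self.position_labels.index(label)
        except ValueError:
            raise KeyError(f"no alignment column labelled {label}") from None


@dataclass
class TaxonomyTable:
    """Per-organism lineages (root level first), truncated to ``depth`` levels."""

    organism_ids: list[str]
    lineages: dict[str, tuple[str, ...]]
    depth: int = 6

    def __post_init__(self) -> None:
        _check_unique(self.organism_ids, "organism")
        for org in self.organism_ids:
            lin = tuple(self.lineages[org])[: self.depth]
            if not lin:
                raise AlignmentFormatError(f"empty lineage for organism {org!r}")
            self.lineages[org] = lin

    def lineage(self, organism_id: str) -> tuple[str, ...]:
        return self.lineages[organism_id]

    def level(self, organism_id: str, level: int) -> str | None:
        """1-based taxonomic level; None beyond the recorded depth."""
        lin = self.lineages[organism_id]
        return lin[level - 1] if 1 <= level <= len(lin) else None

    def require_coverage(self, organism_ids: Iterable[str]) -> None:
        missing = [o for o in organism_ids if o not in self.lineages]
        if missing:
            raise AlignmentFormatError(
                f"{len(missing)} alignment organisms missing from the taxonomy "
                f"table: {', '.join(missing[:10])}"
                + (", ..." if len(missing) > 10 else "")
            )


@dataclass
class PairingTable:
    """Per-organism, per-position base-pairing state ``Y``/``N``/``-``.

    Shares shape, organism order and position labels with its companion
    alignment; an alignment gap implies a pairing gap.
    """

    organism_ids: list[str]
    states: np.ndarray              # (K, M), dtype '<U1'
    position_labels: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype="<U1")
        if self.states.ndim != 2:
            raise ValueError("states must be a 2-D grid")
        _check_unique(self.organism_ids, "organism")
        if len(self.organism_ids) != self.states.shape[0]:
            raise ValueError("organism_ids length does not match the grid")
        if not self.position_labels:
            self.position_labels = list(range(1, self.states.shape[1] + 1))
        if len(self.position_labels) != self.states.shape[1]:
            raise ValueError("position_labels length does not match the grid")
        bad = ~np.isin(self.states, list(PAIRING_SYMBOLS))
        if bad.any():
            i, m = np.argwhere(bad)[0]
            raise AlignmentFormatError(
                f"invalid pairing symbol {self.states[i, m]!r} for organism "
                f"{self.organism_ids[i]!r} at column {self.position_labels[m]}"
            )

    def validate_against(self, aln: SequenceAlignment, *,
                         gap_mode: str = "error") -> None:
        """Check shape, organism order and gap consistency with ``aln``.

        ``gap_mode``: 'error' raises on any alignment/pairing gap mismatch,
        'warn' emits a warning instead.
        """
        if self.organism_ids != aln.organism_ids:
            raise AlignmentFormatError(
                "pairing table organisms do not match the alignment (same ids, "
                "same order required)")
        if self.states.shape != aln.characters.shape:
            raise AlignmentFormatError(
                f"pairing table shape {self.states.shape} does not match "
                f"alignment shape {aln.characters.shape}")
        mism = (self.states == "-") != (aln.characters == "-")
        if mism.any():
            i, m = np.argwhere(mism)[0]
            msg = (f"gap mismatch between alignment ({aln.characters[i, m]!r}) and "
                   f"pairing table ({self.states[i, m]!r}) for organism "
                   f"{aln.organism_ids[i]!r} at column {aln.position_labels[m]} "
                   f"({int(mism.sum())} mismatches in total)")
            if gap_mode == "error":
                raise AlignmentFormatError(msg)
            warnings.warn(msg)


@dataclass
class NucleotideTensor:
    """K x 6 x M one-hot tensor of nucleotide indicators.

    ``values[i, s, m]`` is 1 iff organism ``i`` carries symbol
    ``slice_order[s]`` at column ``m``; the six slices sum to exactly one at
    every (organism, position).
    """

    values: np.ndarray              # (K, 6, M), {0,1}
    organism_ids: list[str]
    position_labels: list[int]
    slice_order: tuple[str, ...] = SYMBOLS

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3 or self.values.shape[1] != len(self.slice_order):
            raise ValueError(
                f"values must be K x {len(self.slice_order)} x M")
        sums = self.values.sum(axis=1)
        if not (sums == 1).all():
            raise ValueError("tensor is not one-hot: slice sums differ from 1")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def slice(self, symbol: str) -> np.ndarray:
        """The K x M indicator slice for one symbol."""
        return self.values[:, self.slice_order.index(symbol), :]


# ---------------------------------------------------------------------------
# tab dialect
# ---------------------------------------------------------------------------

def _read_rows(path: Path) -> list[list[str]]:
    text = Path(path).read_text(encoding="utf-8")
    rows = [line.rstrip("\r\n").split("\t")
            for line in text.splitlines() if line.strip()]
    if not rows:
        raise AlignmentFormatError(f"empty file: {path}")
    return rows


def _looks_like_header(first_field: str, fields: list[str], validator) -> bool:
    # A header row starts with '#' or carries position labels, none of which
    # parse as single symbols (a data row with a stray bad symbol must still
    # be reported as a format error, not swallowed as a header).
    if first_field.lstrip().startswith("#"):
        return True
    for f in fields:
        try:
            validator(f)
            return False
        except AlignmentFormatError:
            continue
    return True


def _parse_labels(fields: list[str]) -> list:
    out = []
    for f in fields:
        f = f.strip()
        try:
            out.append(int(f))
        except ValueError:
            out.append(f)
    return out


def _parse_grid(path, validator, coerce: bool):
    rows = _read_rows(path)
    labels: list | None = None
    if len(rows[0]) > 1 and _looks_like_header(rows[0][0], rows[0][1:],
                                               validator):
        labels = _parse_labels(rows[0][1:])
        rows = rows[1:]
        if not rows:
            raise AlignmentFormatError(f"{path}: header but no data rows")
    ids: list[str] = []
    grid: list[list[str]] = []
    width = None
    for row in rows:
        org, cells = row[0].strip(), row[1:]
        if width is None:
            width = len(cells)
        elif len(cells) != width:
            raise AlignmentFormatError(
                f"{path}: ragged row for organism {org!r} "
                f"({len(cells)} fields, expected {width})")
        kw = {"coerce_unknown_to_n": coerce} if coerce is not None else {}
        grid.append([validator(c, where=f"{org!r} column {m + 1}", **kw)
                     for m, c in enumerate(cells)])
        ids.append(org)
    if labels is not None and width is not None and len(labels) != width:
        raise AlignmentFormatError(
            f"{path}: header has {len(labels)} labels for {width} columns")
    return ids, np.array(grid, dtype="<U1"), labels


def read_alignment(path, dialect: str = "tab", *,
                   coerce_unknown_to_n: bool = False) -> SequenceAlignment:
    """Read a multiple sequence alignment.

    Parameters
    ----------
    path
        Input file.
    dialect
        ``"tab"`` for the CRW-style tab-delimited character table,
        ``"fasta"`` for aligned FASTA (gap ``-``).
    coerce_unknown_to_n
        Map symbols outside the six-letter alphabet to ``N`` instead of
        raising.
    """
    path = Path(path)
    if dialect == "tab":
        def validator(c, where="", coerce_unknown_to_n=coerce_unknown_to_n):
            if len(c.strip()) != 1:
                raise AlignmentFormatError(
                    f"field {c!r}{' at ' + where if where else ''} is not a "
                    "single symbol")
            return _normalize_symbol(
                c, coerce_unknown_to_n=coerce_unknown_to_n, where=where)
        ids, grid, labels = _parse_grid(path, validator, coerce=None)
        return SequenceAlignment(ids, grid, labels or [])
    if dialect == "fasta":
        from Bio import SeqIO
        ids, rows = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            ids.append(rec.id)
            rows.append([_normalize_symbol(
                c, coerce_unknown_to_n=coerce_unknown_to_n,
                where=f"{rec.id!r}") for c in str(rec.seq)])
        if not ids:
            raise AlignmentFormatError(f"empty file: {path}")
        widths = {len(r) for r in rows}
        if len(widths) != 1:
            raise AlignmentFormatError(
                f"{path}: sequences have unequal aligned lengths {sorted(widths)}")
        _check_unique(ids, "organism")
        return SequenceAlignment(ids, np.array(rows, dtype="<U1"))
    raise ValueError(f"unknown dialect {dialect!r}")


def write_alignment(aln: SequenceAlignment, path, dialect: str = "tab",
                    *, header: bool = True) -> Path:
    """Write an alignment in the tab dialect (default) or aligned FASTA."""
    path = Path(path)
    if dialect == "tab":
        lines = []
        if header:
            lines.append("\t".join(["#organism"] +
                                   [str(l) for l in aln.position_labels]))
        for org, row in zip(aln.organism_ids, aln.characters):
            lines.append("\t".join([org] + list(row)))
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    elif dialect == "fasta":
        from Bio.Seq import Seq
        from Bio.SeqRecord import SeqRecord
        from Bio import SeqIO
        recs = [SeqRecord(Seq("".join(row)), id=org, description="")
                for org, row in zip(aln.organism_ids, aln.characters)]
        SeqIO.write(recs, str(path), "fasta")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return path


def read_taxonomy(path, *, depth: int = 6) -> TaxonomyTable:
    """Read a tab-delimited taxonomy table: organism id, then lineage fields
    root-first, truncated to ``depth`` levels."""
    rows = _read_rows(Path(path))
    ids, lineages = [], {}
    for row in rows:
        org = row[0].strip()
        lin = tuple(f.strip() for f in row[1:] if f.strip())
        if not lin:
            raise AlignmentFormatError(
                f"{path}: empty lineage for organism {org!r}")
        ids.append(org)
        lineages[org] = lin
    _check_unique(ids, "organism")
    return TaxonomyTable(ids, lineages, depth=depth)


def write_taxonomy(tax: TaxonomyTable, path) -> Path:
    path = Path(path)
    lines = ["\t".join([org, *tax.lineages[org]]) for org in tax.organism_ids]
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def read_pairing(path, alignment: SequenceAlignment | None = None, *,
                 gap_mode: str = "error") -> PairingTable:
    """Read a base-pairing table; if ``alignment`` is given, check shape,
    organism order and gap consistency (``gap_mode``: 'error' or 'warn')."""
    def validator(c, where=""):
        if len(c.strip()) != 1:
            raise AlignmentFormatError(
                f"field {c!r}{' at ' + where if where else ''} is not a "
                "single symbol")
        return _normalize_pairing_symbol(c, where=where)
    ids, grid, labels = _parse_grid(Path(path), validator, coerce=None)
    table = PairingTable(ids, grid, labels or [])
    if alignment is not None:
        table.position_labels = list(alignment.position_labels) \
            if len(alignment.position_labels) == grid.shape[1] else table.position_labels
        table.validate_against(alignment, gap_mode=gap_mode)
    return table


def write_pairing(pairing: PairingTable, path, *, header: bool = True) -> Path:
    path = Path(path)
    lines = []
    if header:
        lines.append("\t".join(["#organism"] +
                               [str(l) for l in pairing.position_labels]))
    for org, row in zip(pairing.organism_ids, pairing.states):
        lines.append("\t".join([org] + list(row)))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


# ---------------------------------------------------------------------------
# position filter and tensor encoding
# ---------------------------------------------------------------------------

def _as_fraction(x) -> Fraction:
    # Floats go through their shortest decimal repr so that 0.01 means 1/100
    # exactly; the "at least" boundary must not depend on binary rounding.
    if isinstance(x, float):
        return Fraction(str(x))
    return Fraction(x)


def filter_positions(aln: SequenceAlignment,
                     pairing: PairingTable | None = None,
                     min_fraction=Fraction(1, 100),
                     ) -> tuple[SequenceAlignment, PairingTable | None, list[int]]:
    """Keep columns with A/C/G/U in at least ``min_fraction`` of organisms.

    A column is kept iff its count of cells in {A, C, G, U} is at least
    ``min_fraction * K`` — inclusive boundary, exact rational comparison.
    ``N`` and gap cells never count toward the threshold. Returns the filtered
    alignment, the identically filtered pairing table (or None) and the list
    of kept original column labels.
    """
    frac = _as_fraction(min_fraction)
    if not (0 < frac <= 1):
        raise ValueError(f"min_fraction must be in (0, 1], got {min_fraction}")
    K = aln.n_organisms
    counts = np.isin(aln.characters, list(NUCLEOTIDES)).sum(axis=0)
    threshold = frac * K
    keep = np.array([Fraction(int(c)) >= threshold for c in counts])
    if not keep.any():
        raise ValueError(
            "position filter removed every column "
            f"(min_fraction={min_fraction}, K={K})")
    kept_labels = [l for l, k in zip(aln.position_labels, keep) if k]
    sub = SequenceAlignment(list(aln.organism_ids),
                            aln.characters[:, keep], kept_labels)
    sub_pairing = None
    if pairing is not None:
        sub_pairing = PairingTable(list(pairing.organism_ids),
                                   pairing.states[:, keep], list(kept_labels))
    return sub, sub_pairing, kept_labels


def encode_tensor(aln: SequenceAlignment) -> NucleotideTensor:
    """One-hot encode the alignment as a K x 6 x M indicator tensor."""
    values = np.stack([(aln.characters == s) for s in SYMBOLS],
                      axis=1).astype(np.uint8)
    return NucleotideTensor(values, list(aln.organism_ids),
                            list(aln.position_labels))


def save_tensor_h5(tensor: NucleotideTensor, path) -> Path:
    """Cache an encoded tensor to HDF5."""
    import h5py
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=tensor.values, compression="gzip")
        f.create_dataset("organism_ids",
                         data=np.array(tensor.organism_ids, dtype="S"))
        f.create_dataset("position_labels",
                         data=np.array(tensor.position_labels, dtype=np.int64))
        f.attrs["slice_order"] = ",".join(tensor.slice_order)
    return path


def load_tensor_h5(path) -> NucleotideTensor:
    import h5py
    with h5py.File(path, "r") as f:
        values = f["values"][...]
        ids = [s.decode() for s in f["organism_ids"][...]]
        labels = [int(x) for x in f["position_labels"][...]]
        order = tuple(f.attrs["slice_order"].split(","))
    return NucleotideTensor(values, ids, labels, slice_order=order)
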