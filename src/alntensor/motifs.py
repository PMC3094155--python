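"""Group-exclusive conservation motifs on alignment columns.

Three motif definitions, each a pure function of the alignment, the pairing
table, a taxonomic group and its thresholds:

* exclusive gap — gaps in at least ``in_thr`` (default 80%) of the group's
  organisms but in less than ``out_thr`` (default 20%) of the remaining
  organisms; such columns mark substructures deleted in the group (or
  inserted in the rest).
* exclusive unpaired A — adenosine in at least ``in_thr`` of the group but
  less than ``out_thr`` of the rest, together with a strictly greater
  fraction of unpaired nucleotides within the group than among the rest.
* conserved helix — base-paired ('Y') state in at least ``thr`` (default
  60%) of the group's organisms.

Counting rules: the gap/adenosine numerators count only '-' / 'A' cells ('N'
counts toward neither numerator), the denominator is always the full group
size; the unpaired fraction is computed over non-gap cells, since a gap is
neither paired nor unpaired.  Threshold comparisons use exact rational
arithmetic so that "at least 80%" and "less than 20%" behave exactly at the
boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Sequence

import numpy as np

from .io import PairingTable, SequenceAlignment

__all__ = [
    "ConservationAnnotation",
    "exclusive_gap_columns",
    "exclusive_unpaired_A_columns",
    "conserved_helix_columns",
]

MOTIF_EXCLUSIVE_GAP = "exclusive_gap"
MOTIF_EXCLUSIVE_UNPAIRED_A = "exclusive_unpaired_A"
MOTIF_CONSERVED_HELIX = "conserved_helix"


@dataclass
class ConservationAnnotation:
    """Columns carrying one motif for one group, with the thresholds used."""

    group: str
    motif: str
    columns: tuple[int, ...]                 # original column labels, sorted
    parameters: dict = field(default_factory=dict)
    frequencies: "object | None" = None      # per-column DataFrame or None

    @property
    def column_set(self) -> frozenset:
        return frozenset(self.columns)

    def __len__(self) -> int:
        return len(self.columns)

    def to_frame(self):
        """Per-column TSV-ready table: group, motif, column, frequencies."""
        import pandas as pd
        if self.frequencies is not None:
            df = self.frequencies.copy()
        else:
            df = pd.DataFrame({"column": list(self.columns)})
        df.insert(0, "motif", self.motif)
        df.insert(0, "group", self.group)
        return df


def _as_fraction(x) -> Fraction:
    return Fraction(str(x)) if isinstance(x, float) else Fraction(x)


def _split_rows(organism_ids: Sequence[str], group_members: Iterable[str]
                ) -> tuple[np.ndarray, np.ndarray]:
    members = set(group_members)
    unknown = members - set(organism_ids)
    if unknown:
        raise ValueError(f"group members not in alignment: {sorted(unknown)[:5]}")
    mask = np.array([o in members for o in organism_ids])
    if not mask.any():
        raise ValueError("group is empty")
    return mask, ~mask


def _freq_table(labels, in_counts, n_in, out_counts, n_out):
    import pandas as pd
    return pd.DataFrame({
        "column": labels,
        "in_group_freq": np.asarray(in_counts, float) / n_in,
        "out_group_freq": (np.asarray(out_counts, float) / n_out
                           if n_out else np.nan),
    })


def _exclusive_symbol_columns(grid: np.ndarray, symbol: str,
                              in_mask: np.ndarray, out_mask: np.ndarray,
                              in_thr: Fraction, out_thr: Fraction
                              ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n_in, n_out = int(in_mask.sum()), int(out_mask.sum())
    in_counts = (grid[in_mask] == symbol).sum(axis=0)
    out_counts = (grid[out_mask] == symbol).sum(axis=0)
    keep = np.array([
        Fraction(int(ci), n_in) >= in_thr
        and Fraction(int(co), n_out) < out_thr
        for ci, co in zip(in_counts, out_counts)])
    return keep, in_counts, out_counts


def exclusive_gap_columns(aln: SequenceAlignment,
                          group_members: Iterable[str],
                          in_thr=0.8, out_thr=0.2, *,
                          group_name: str | None = None
                          ) -> ConservationAnnotation:
    """Columns whose gaps are exclusively conserved in the group: gap
    frequency >= ``in_thr`` within the group and < ``out_thr`` among the
    remaining organisms.  The group must be a proper subset of the
    organisms."""
    in_mask, out_mask = _split_rows(aln.organism_ids, group_members)
    if not out_mask.any():
        raise ValueError(
            "exclusive gap conservation needs remaining organisms; the group "
            "covers the whole alignment")
    thr_in, thr_out = _as_fraction(in_thr), _as_fraction(out_thr)
    keep, ci, co = _exclusive_symbol_columns(
        aln.characters, "-", in_mask, out_mask, thr_in, thr_out)
    labels = [l for l, k in zip(aln.position_labels, keep) if k]
    return ConservationAnnotation(
        group=group_name or _group_label(group_members),
        motif=MOTIF_EXCLUSIVE_GAP, columns=tuple(labels),
        parameters={"in_thr": str(thr_in), "out_thr": str(thr_out)},
        frequencies=_freq_table(labels, ci[keep], in_mask.sum(),
                                co[keep], out_mask.sum()))


def exclusive_unpaired_A_columns(aln: SequenceAlignment,
                                 pairing: PairingTable,
                                 group_members: Iterable[str],
                                 in_thr=0.8, out_thr=0.2, *,
                                 group_name: str | None = None
                                 ) -> ConservationAnnotation:
    """Columns of adenosines exclusively conserved in the group that are
    more often unpaired within the group than among the rest.

    Requires: A frequency >= ``in_thr`` in the group and < ``out_thr``
    outside, and a strictly greater unpaired ('N' state) fraction among the
    group's non-gap cells than among the remaining organisms' non-gap cells.
    """
    if pairing is None:
        raise ValueError("exclusive unpaired-A conservation needs a pairing table")
    pairing.validate_against(aln)
    in_mask, out_mask = _split_rows(aln.organism_ids, group_members)
    if not out_mask.any():
        raise ValueError(
            "exclusive unpaired-A conservation needs remaining organisms")
    thr_in, thr_out = _as_fraction(in_thr), _as_fraction(out_thr)
    keep, ci, co = _exclusive_symbol_columns(
        aln.characters, "A", in_mask, out_mask, thr_in, thr_out)

    unpaired_in = (pairing.states[in_mask] == "N").sum(axis=0)
    nongap_in = (pairing.states[in_mask] != "-").sum(axis=0)
    unpaired_out = (pairing.states[out_mask] == "N").sum(axis=0)
    nongap_out = (pairing.states[out_mask] != "-").sum(axis=0)

    def unpaired_ok(m: int) -> bool:
        # fraction over non-gap cells; an all-gap group side cannot exceed,
        # an all-gap outside counts as zero unpaired
        if nongap_in[m] == 0:
            return False
        f_in = Fraction(int(unpaired_in[m]), int(nongap_in[m]))
        f_out = (Fraction(int(unpaired_out[m]), int(nongap_out[m]))
                 if nongap_out[m] else Fraction(0))
        return f_in > f_out

    keep = keep & np.array([unpaired_ok(m) for m in range(aln.n_positions)])
    labels = [l for l, k in zip(aln.position_labels, keep) if k]
    return ConservationAnnotation(
        group=group_name or _group_label(group_members),
        motif=MOTIF_EXCLUSIVE_UNPAIRED_A, columns=tuple(labels),
        parameters={"in_thr": str(thr_in), "out_thr": str(thr_out),
                    "unpaired_rule": "strictly greater, non-gap denominator"},
        frequencies=_freq_table(labels, ci[keep], in_mask.sum(),
                                co[keep], out_mask.sum()))


def conserved_helix_columns(pairing: PairingTable,
                            group_members: Iterable[str],
                            thr=0.6, *, group_name: str | None = None
                            ) -> ConservationAnnotation:
    """Columns base-paired ('Y') in at least ``thr`` of the group's
    organisms (no exclusivity requirement)."""
    in_mask, _ = _split_rows(pairing.organism_ids, group_members)
    thr = _as_fraction(thr)
    n_in = int(in_mask.sum())
    counts = (pairing.states[in_mask] == "Y").sum(axis=0)
    keep = np.array([Fraction(int(c), n_in) >= thr for c in counts])
    labels = [l for l, k in zip(pairing.position_labels, keep) if k]
    return ConservationAnnotation(
        group=group_name or _group_label(group_members),
        motif=MOTIF_CONSERVED_HELIX, columns=tuple(labels),
        parameters={"thr": str(thr)},
        frequencies=_freq_table(labels, counts[keep], n_in, counts[keep] * 0,
                                max(1, len(in_mask) - n_in)))


def _group_label(group_members: Iterable[str]) -> str:
    members = sorted(group_members)
    return f"group({len(members)} organisms)"
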