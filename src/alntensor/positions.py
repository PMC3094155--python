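"""Extreme positions of eigenorganism segments and their motif enrichment.

For component r and symbol s, the positions with the largest increase
(decrease) in the s-specific segment are the positions whose s-frequency
variation across organisms is most correlated (anticorrelated) with
eigenposition r.  Two selection modes handle ties among segment values:

* ``rank`` (default) — the m most extreme positions, expanded to include
  every position tied (within a relative tolerance) with the m-th value;
* ``extreme_set`` — exactly the positions tied at the single most extreme
  value, which can be fewer or more than m.  This replicates selections such
  as a gap segment whose largest value is shared by an entire tie set of
  deleted columns.

Enrichment of the selected positions in a conservation motif is the upper
hypergeometric tail with n hits among the m_effective selected positions, N
motif columns among M alignment positions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .enrichment import hypergeom_tail
from .io import SequenceAlignment
from .model import AlignmentTensorResults
from .motifs import ConservationAnnotation

__all__ = [
    "PositionEnrichmentRecord",
    "default_m",
    "extreme_positions",
    "enrich_segment",
    "map_to_reference",
    "raster_matrix",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PositionEnrichmentRecord:
    component: int
    symbol: str
    direction: str            # "increase" | "decrease"
    motif: str
    group: str
    n: int                    # motif columns in the extreme set
    N: int                    # motif columns in the alignment
    m_effective: int          # extreme-set size actually used
    M: int                    # total alignment columns
    p_value: float
    columns: tuple[int, ...]  # extreme-set labels, most extreme first


def default_m(M: int) -> int:
    """Default extreme-set size by alignment width: the documented presets
    are m=100 for ~3k-column and m=200 for ~6k-column alignments; otherwise
    roughly M/32."""
    if 2000 <= M <= 4000:
        return 100
    if 4000 < M <= 8000:
        return 200
    return max(1, int(round(M / 32)))


def extreme_positions(results: AlignmentTensorResults, r: int, symbol: str,
                      direction: str, m: int | None = None,
                      tie_mode: str = "rank", rtol: float = 1e-9
                      ) -> list[int]:
    """Ordered labels of the most extreme positions of segment (r, symbol).

    ``direction`` 'increase' selects the largest segment values, 'decrease'
    the smallest; output is ordered by extremeness then column order.
    """
    if direction not in ("increase", "decrease"):
        raise ValueError(f"direction must be 'increase' or 'decrease', "
                         f"got {direction!r}")
    if tie_mode not in ("rank", "extreme_set"):
        raise ValueError(f"unknown tie_mode {tie_mode!r}")
    seg = results.segment(r, symbol)
    v = seg.to_numpy(dtype=float)
    if direction == "decrease":
        v = -v
    M = len(v)
    if m is None:
        m = default_m(M)
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    if m > M:
        logger.warning("m=%d exceeds the %d alignment columns; using all", m, M)
        m = M
    order = np.argsort(-v, kind="stable")
    scale = float(np.max(np.abs(v)))
    tol = rtol * scale
    cutoff = v[order[0]] if tie_mode == "extreme_set" else v[order[m - 1]]
    selected = [i for i in order if v[i] >= cutoff - tol]
    labels = list(seg.index)
    return [labels[i] for i in selected]


def enrich_segment(results: AlignmentTensorResults, r: int, symbol: str,
                   direction: str, annotation: ConservationAnnotation,
                   m: int | None = None, tie_mode: str = "rank",
                   rtol: float = 1e-9) -> PositionEnrichmentRecord:
    """Hypergeometric enrichment of segment (r, symbol) extremes in a
    conservation motif computed on the same (filtered) alignment."""
    cols = extreme_positions(results, r, symbol, direction, m=m,
                             tie_mode=tie_mode, rtol=rtol)
    M = len(results.position_labels)
    motif_cols = annotation.column_set
    extra = motif_cols - set(results.position_labels)
    if extra:
        raise ValueError(
            f"annotation refers to {len(extra)} columns absent from the "
            "decomposed alignment; compute motifs on the same filtered "
            "alignment")
    n = len(motif_cols & set(cols))
    m_eff = len(cols)
    return PositionEnrichmentRecord(
        component=r, symbol=symbol, direction=direction,
        motif=annotation.motif, group=annotation.group,
        n=n, N=len(motif_cols), m_effective=m_eff, M=M,
        p_value=hypergeom_tail(n, m_eff, len(motif_cols), M),
        columns=tuple(cols))


def map_to_reference(aln: SequenceAlignment, reference_id: str,
                     columns: list[int]) -> list[tuple[int, int | None]]:
    """Map alignment column labels to 1-based reference-organism coordinates.

    The coordinate is the count of non-gap reference cells up to and
    including the column; None where the reference carries a gap.
    """
    if reference_id not in aln.organism_ids:
        raise KeyError(f"reference organism {reference_id!r} not in alignment")
    row = aln.row(reference_id)
    cum = np.cumsum(row != "-")
    out = []
    for label in columns:
        i = aln.column_index(label)
        out.append((label, None if row[i] == "-" else int(cum[i])))
    return out


def raster_matrix(aln: SequenceAlignment, columns: list[int],
                  organism_order: list[str] | None = None):
    """Organisms x selected-columns character matrix, raster-ready.

    Rows follow ``organism_order`` when given (e.g. organisms sorted by an
    eigenposition), columns follow the given label order (most extreme
    first, per the selection ordering).
    """
    import pandas as pd
    orgs = organism_order or aln.organism_ids
    rows = {org: [aln.characters[aln.organism_ids.index(org),
                                 aln.column_index(c)] for c in columns]
            for org in orgs}
    return pd.DataFrame.from_dict(rows, orient="index", columns=columns)
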