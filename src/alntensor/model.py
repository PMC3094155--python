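"""Mode-1 higher-order SVD of the one-hot alignment tensor.

The K x 6 x M nucleotide-indicator tensor is unfolded along the organisms
axis into a K x 6M matrix — the six K x M nucleotide slices appended side by
side in slice order — and decomposed by a full SVD.  The left singular
vectors are *eigenpositions* (patterns of nucleotide frequency variation
across organisms), the right singular vectors, refolded into six length-M
nucleotide-specific segments, are *eigenorganisms*, and each component's
significance is its fraction of the overall information (squared singular
value by default).

No mean-centering is applied: the first component absorbs the average
nucleotide frequency pattern, and later components are read as deviations
from it.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .io import (SYMBOLS, NucleotideTensor, PairingTable, SequenceAlignment,
                 TaxonomyTable, encode_tensor, filter_positions,
                 read_alignment, read_pairing, read_taxonomy)

__all__ = [
    "mode1_unfold",
    "mode1_refold",
    "mode1_hosvd",
    "significance_fractions",
    "AlignmentTensorModel",
    "AlignmentTensorResults",
    "MeanFrequencyDiagnostics",
]


def mode1_unfold(values: np.ndarray) -> np.ndarray:
    """Unfold a K x L x M tensor into K x LM, slices side by side in slice
    order (column ``s*M + m`` holds slice ``s``, position ``m``)."""
    K, L, M = values.shape
    return values.reshape(K, L * M)


def mode1_refold(matrix: np.ndarray, n_slices: int) -> np.ndarray:
    """Inverse of :func:`mode1_unfold` applied row-wise: R x LM -> R x L x M."""
    R, LM = matrix.shape
    if LM % n_slices:
        raise ValueError(f"{LM} columns do not split into {n_slices} slices")
    return matrix.reshape(R, n_slices, LM // n_slices)


def significance_fractions(singular_values: Sequence[float],
                           convention: str = "squared") -> np.ndarray:
    """Per-component fraction of the overall information.

    ``squared`` (default): sigma_r^2 / sum(sigma^2); ``linear``:
    sigma_r / sum(sigma).  Either way the fractions sum to one.
    """
    s = np.asarray(singular_values, dtype=float)
    if (s < 0).any():
        raise ValueError("singular values must be non-negative")
    if convention == "squared":
        w = s ** 2
    elif convention == "linear":
        w = s
    else:
        raise ValueError(f"unknown convention {convention!r}")
    total = w.sum()
    if total == 0:
        raise ValueError("all singular values are zero")
    return w / total


@dataclass
class MeanFrequencyDiagnostics:
    """Diagnostics for whether a component is the average-frequency pattern.

    ``correlations`` holds, per symbol, the Pearson correlation between the
    component's nucleotide-specific segment and that symbol's mean frequency
    across organisms (NaN where either profile is constant);
    ``eigenposition_cv`` is the coefficient of variation of the eigenposition
    across organisms (small means flat, i.e. organism-invariant).
    """

    component: int
    correlations: dict[str, float]
    eigenposition_cv: float

    @property
    def is_mean_like(self) -> bool:
        defined = [c for c in self.correlations.values() if not math.isnan(c)]
        if not defined:
            return False
        return (self.eigenposition_cv <= 0.5
                and float(np.median(defined)) >= 0.5)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.std() == 0 or y.std() == 0:
        return math.nan
    return float(np.corrcoef(x, y)[0, 1])


class AlignmentTensorResults:
    """Fitted mode-1 HOSVD: eigenpositions, singular values, eigenorganisms.

    Components are 1-based throughout the public API; component 1 is
    normally the average-frequency pattern.
    """

    def __init__(self, eigenpositions: np.ndarray,
                 singular_values: np.ndarray,
                 eigenorganisms: np.ndarray,
                 organism_ids: list[str],
                 position_labels: list[int],
                 slice_order: tuple[str, ...] = SYMBOLS,
                 convention: str = "squared",
                 model: "AlignmentTensorModel | None" = None):
        self.eigenpositions = np.asarray(eigenpositions, float)    # (K, R)
        self.singular_values = np.asarray(singular_values, float)  # (R,)
        self.eigenorganisms = np.asarray(eigenorganisms, float)    # (R, L, M)
        self.organism_ids = list(organism_ids)
        self.position_labels = list(position_labels)
        self.slice_order = tuple(slice_order)
        self.convention = convention
        self.model = model
        if np.any(np.diff(self.singular_values) > 1e-12):
            raise ValueError("singular values must be non-increasing")

    # -- basic quantities --------------------------------------------------

    @property
    def n_components(self) -> int:
        return len(self.singular_values)

    @property
    def fractions(self) -> np.ndarray:
        return significance_fractions(self.singular_values, self.convention)

    def cumulative_fraction(self, top: int) -> float:
        """Information captured by the ``top`` most significant components."""
        return float(self.fractions[:top].sum())

    def eigenposition(self, r: int) -> np.ndarray:
        """Component ``r`` (1-based) pattern across organisms."""
        self._check_component(r)
        return self.eigenpositions[:, r - 1]

    def segment(self, r: int, symbol: str):
        """The nucleotide-``symbol`` segment of eigenorganism ``r`` as a
        pandas Series indexed by original column labels."""
        import pandas as pd
        self._check_component(r)
        s = self.slice_order.index(symbol)
        return pd.Series(self.eigenorganisms[r - 1, s, :],
                         index=self.position_labels, name=f"{symbol}[{r}]")

    def _check_component(self, r: int) -> None:
        if not 1 <= r <= self.n_components:
            raise IndexError(
                f"component {r} out of range 1..{self.n_components}")

    # -- orientation -------------------------------------------------------

    def orient(self, r: int, rule: str = "max_abs_positive",
               group: Sequence[str] | None = None) -> "AlignmentTensorResults":
        """Return a copy with component ``r`` sign-oriented.

        The SVD leaves each (eigenposition, eigenorganism) pair defined only
        up to a joint sign.  ``max_abs_positive`` (default) makes the
        largest-magnitude organism entry positive; ``group`` orients so the
        named organisms sit on the positive (correlated) side.
        """
        self._check_component(r)
        u = self.eigenpositions[:, r - 1]
        if rule == "max_abs_positive":
            flip = u[int(np.argmax(np.abs(u)))] < 0
        elif rule == "group":
            if not group:
                raise ValueError("rule='group' needs a non-empty organism set")
            idx = [self.organism_ids.index(o) for o in group]
            flip = u[idx].mean() < 0
        else:
            raise ValueError(f"unknown orientation rule {rule!r}")
        out = self.copy()
        if flip:
            out.eigenpositions[:, r - 1] *= -1
            out.eigenorganisms[r - 1] *= -1
        return out

    def flip(self, r: int) -> "AlignmentTensorResults":
        """Unconditionally flip the sign of component ``r`` (both factors)."""
        self._check_component(r)
        out = self.copy()
        out.eigenpositions[:, r - 1] *= -1
        out.eigenorganisms[r - 1] *= -1
        return out

    def copy(self) -> "AlignmentTensorResults":
        return AlignmentTensorResults(
            self.eigenpositions.copy(), self.singular_values.copy(),
            self.eigenorganisms.copy(), list(self.organism_ids),
            list(self.position_labels), self.slice_order, self.convention,
            self.model)

    # -- reconstruction & diagnostics --------------------------------------

    def reconstruct(self, rank: int | None = None) -> np.ndarray:
        """Rank-``rank`` reconstruction of the K x L x M tensor (full rank by
        default)."""
        r = self.n_components if rank is None else rank
        unfold = (self.eigenpositions[:, :r] * self.singular_values[:r]) \
            @ mode1_unfold(self.eigenorganisms[:r])
        L = len(self.slice_order)
        return unfold.reshape(unfold.shape[0], L, unfold.shape[1] // L)

    def mean_frequency_correlation(
            self, r: int,
            tensor: NucleotideTensor | None = None) -> MeanFrequencyDiagnostics:
        """Correlate each segment of component ``r`` with the per-column mean
        frequency of its symbol, and measure eigenposition flatness."""
        if tensor is None:
            if self.model is None:
                raise ValueError("pass the tensor the model was fitted to")
            tensor = self.model.tensor
        self._check_component(r)
        corrs = {}
        for s, sym in enumerate(self.slice_order):
            mean_freq = tensor.values[:, s, :].mean(axis=0)
            corrs[sym] = _pearson(self.eigenorganisms[r - 1, s, :], mean_freq)
        u = self.eigenpositions[:, r - 1]
        mu = u.mean()
        cv = math.inf if mu == 0 else float(u.std() / abs(mu))
        return MeanFrequencyDiagnostics(r, corrs, cv)

    # -- presentation -------------------------------------------------------

    def summary(self, top: int = 10) -> str:
        """Text summary of the decomposition."""
        K = len(self.organism_ids)
        M = len(self.position_labels)
        fr = self.fractions
        lines = [
            "Mode-1 HOSVD of nucleotide alignment tensor",
            "=" * 60,
            f"Organisms (K): {K:>6}    Positions (M): {M:>6}    "
            f"Components (R): {self.n_components}",
            f"Information fraction convention: {self.convention}",
            "-" * 60,
            f"{'component':>9}  {'sigma':>12}  {'fraction':>9}  {'cumulative':>10}",
        ]
        cum = 0.0
        for i in range(min(top, self.n_components)):
            cum += fr[i]
            lines.append(f"{i + 1:>9}  {self.singular_values[i]:>12.5f}  "
                         f"{fr[i]:>9.4f}  {cum:>10.4f}")
        diag = self.mean_frequency_correlation(1) if self.model else None
        if diag is not None:
            lines.append("-" * 60)
            lines.append(
                f"component 1 mean-like: {diag.is_mean_like} "
                f"(eigenposition CV {diag.eigenposition_cv:.3f})")
        return "\n".join(lines)

    def eigenposition_frame(self):
        """Organisms x components DataFrame of eigenpositions."""
        import pandas as pd
        return pd.DataFrame(
            self.eigenpositions, index=self.organism_ids,
            columns=[f"comp{r}" for r in range(1, self.n_components + 1)])

    def segment_frame(self, symbol: str):
        """Positions x components DataFrame of one symbol's segments."""
        import pandas as pd
        s = self.slice_order.index(symbol)
        return pd.DataFrame(
            self.eigenorganisms[:, s, :].T, index=self.position_labels,
            columns=[f"comp{r}" for r in range(1, self.n_components + 1)])

    # -- enrichment conveniences (thin wrappers) ----------------------------

    def extreme_organisms(self, r: int, k: int):
        from .enrichment import extreme_organisms
        return extreme_organisms(self, r, k)

    def enrich_organisms(self, taxonomy: TaxonomyTable, r: int,
                         k: int | None = None, **kw):
        from .enrichment import enrich_eigenposition
        return enrich_eigenposition(self, taxonomy, r, k=k, **kw)

    def extreme_positions(self, r: int, symbol: str, direction: str, **kw):
        from .positions import extreme_positions
        return extreme_positions(self, r, symbol, direction, **kw)

    def enrich_positions(self, r: int, symbol: str, direction: str,
                         annotation, **kw):
        from .positions import enrich_segment
        return enrich_segment(self, r, symbol, direction, annotation, **kw)

    # -- serialization -------------------------------------------------------

    def save(self, directory) -> Path:
        """Write the model bundle: ``arrays.npz`` plus ``meta.json``."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savez_compressed(directory / "arrays.npz",
                            eigenpositions=self.eigenpositions,
                            singular_values=self.singular_values,
                            eigenorganisms=self.eigenorganisms)
        meta = {
            "organism_ids": self.organism_ids,
            "position_labels": self.position_labels,
            "slice_order": list(self.slice_order),
            "convention": self.convention,
        }
        (directory / "meta.json").write_text(json.dumps(meta, indent=1),
                                             encoding="utf-8")
        return directory

    @classmethod
    def load(cls, directory) -> "AlignmentTensorResults":
        directory = Path(directory)
        arrays = np.load(directory / "arrays.npz")
        meta = json.loads((directory / "meta.json").read_text(encoding="utf-8"))
        return cls(arrays["eigenpositions"], arrays["singular_values"],
                   arrays["eigenorganisms"], meta["organism_ids"],
                   meta["position_labels"], tuple(meta["slice_order"]),
                   meta["convention"])


def mode1_hosvd(tensor: NucleotideTensor,
                convention: str = "squared",
                model: "AlignmentTensorModel | None" = None
                ) -> AlignmentTensorResults:
    """Compute the mode-1 HOSVD of a one-hot nucleotide tensor.

    Returns the full decomposition with R = min(K, 6M) components, singular
    values non-increasing, and each component sign-oriented so its
    largest-magnitude organism entry is positive (a deterministic canonical
    choice; the joint sign is otherwise arbitrary).
    """
    values = np.asarray(tensor.values, dtype=float)
    if not values.any():
        raise ValueError("cannot decompose an all-zero tensor")
    unfolding = mode1_unfold(values)
    U, s, Vt = np.linalg.svd(unfolding, full_matrices=False)
    R = min(values.shape[0], values.shape[1] * values.shape[2])
    U, s, Vt = U[:, :R], s[:R], Vt[:R]
    # canonical sign: largest-|entry| organism coordinate positive
    for r in range(R):
        if U[np.argmax(np.abs(U[:, r])), r] < 0:
            U[:, r] *= -1
            Vt[r] *= -1
    eigenorganisms = mode1_refold(Vt, len(tensor.slice_order))
    return AlignmentTensorResults(U, s, eigenorganisms,
                                  tensor.organism_ids, tensor.position_labels,
                                  tensor.slice_order, convention, model)


class AlignmentTensorModel:
    """Comparative model of a sequence alignment via mode-1 HOSVD.

    Parameters
    ----------
    alignment
        The multiple sequence alignment over ``A C G U N -``.
    taxonomy, pairing
        Optional companion tables; the taxonomy must cover every alignment
        organism, the pairing table must match the alignment's shape and gaps.
    min_fraction
        "At least" threshold of the position filter: keep columns with
        A/C/G/U in at least this fraction of organisms (default 1%).
    apply_filter
        Set False if the alignment is already filtered.
    """

    def __init__(self, alignment: SequenceAlignment,
                 taxonomy: TaxonomyTable | None = None,
                 pairing: PairingTable | None = None, *,
                 min_fraction=0.01, apply_filter: bool = True,
                 pairing_gap_mode: str = "error"):
        if taxonomy is not None:
            taxonomy.require_coverage(alignment.organism_ids)
        if pairing is not None:
            pairing.validate_against(alignment, gap_mode=pairing_gap_mode)
        self.raw_alignment = alignment
        self.taxonomy = taxonomy
        if apply_filter:
            self.alignment, self.pairing, self.kept_columns = \
                filter_positions(alignment, pairing, min_fraction)
        else:
            self.alignment, self.pairing = alignment, pairing
            self.kept_columns = list(alignment.position_labels)
        self.min_fraction = min_fraction
        self.tensor = encode_tensor(self.alignment)

    @classmethod
    def from_files(cls, alignment_path, taxonomy_path=None, pairing_path=None,
                   *, dialect: str = "tab", taxonomy_depth: int = 6,
                   coerce_unknown_to_n: bool = False, **kw
                   ) -> "AlignmentTensorModel":
        aln = read_alignment(alignment_path, dialect,
                             coerce_unknown_to_n=coerce_unknown_to_n)
        tax = read_taxonomy(taxonomy_path, depth=taxonomy_depth) \
            if taxonomy_path else None
        pairing = read_pairing(pairing_path, aln) if pairing_path else None
        return cls(aln, tax, pairing, **kw)

    def fit(self, convention: str = "squared") -> AlignmentTensorResults:
        """Decompose the encoded tensor; returns the results object."""
        return mode1_hosvd(self.tensor, convention=convention, model=self)
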