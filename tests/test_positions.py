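"""Extreme-position selection with tie handling, segment enrichment and
reference-coordinate mapping."""

import math

import numpy as np
import pytest

import alntensor as at
from alntensor.motifs import ConservationAnnotation
from alntensor.positions import default_m


def results_with_segment(values, symbol="A", r=2):
    """A results object whose component-r segment for ``symbol`` is
    ``values`` (other slices zero-padded to unit norm)."""
    M = len(values)
    K = 4
    eig = np.linalg.qr(np.random.default_rng(0).normal(size=(K, r)))[0]
    eigorg = np.zeros((r, 6, M))
    s = at.SYMBOLS.index(symbol)
    v = np.asarray(values, float)
    eigorg[r - 1, s, :] = v
    # pad another slice so every component is unit-norm
    pad = at.SYMBOLS.index("N")
    resid = 1 - (v ** 2).sum()
    eigorg[r - 1, pad, 0] = math.sqrt(max(resid, 0))
    for q in range(r - 1):
        eigorg[q, pad, q % M] = 1.0
    return at.AlignmentTensorResults(
        eig, np.arange(r, 0, -1).astype(float), eigorg,
        [f"o{i}" for i in range(K)], list(range(1, M + 1)))


class TestExtremePositions:
    def test_no_ties_returns_exactly_m(self):
        res = results_with_segment([0.5, 0.4, 0.3, 0.2, 0.1])
        cols = res.extreme_positions(2, "A", "increase", m=3)
        assert cols == [1, 2, 3]
        cols = res.extreme_positions(2, "A", "decrease", m=2)
        assert cols == [5, 4]

    def test_rank_mode_expands_ties_at_mth_value(self):
        res = results_with_segment([0.5, 0.4, 0.4, 0.4, 0.1])
        cols = res.extreme_positions(2, "A", "increase", m=2)
        assert cols == [1, 2, 3, 4]          # the m-th value is shared

    def test_extreme_set_mode_takes_top_tie_set_only(self):
        res = results_with_segment([0.5, 0.5, 0.4, 0.3, 0.1])
        cols = res.extreme_positions(2, "A", "increase", m=4,
                                     tie_mode="extreme_set")
        assert cols == [1, 2]                # can be fewer than m

    def test_m_larger_than_alignment_warns_and_caps(self, caplog):
        res = results_with_segment([0.5, 0.4, 0.3])
        with caplog.at_level("WARNING", logger="alntensor.positions"):
            cols = res.extreme_positions(2, "A", "increase", m=10)
        assert len(cols) == 3

    def test_default_m_presets(self):
        assert default_m(3249) == 100      # ~3k-column alignment preset
        assert default_m(6636) == 200      # ~6k-column alignment preset
        assert default_m(400) == 12

    def test_ordering_most_extreme_first_then_column_order(self):
        res = results_with_segment([0.1, 0.5, 0.3, 0.5, 0.2])
        cols = res.extreme_positions(2, "A", "increase", m=3)
        assert cols == [2, 4, 3]


class TestEnrichSegment:
    def annotation(self, cols):
        return ConservationAnnotation("G", "exclusive_gap", tuple(cols))

    def test_motif_superset_gives_minimal_p(self):
        res = results_with_segment([0.5, 0.4, 0.3, 0.2, 0.1])
        rec = res.enrich_positions(2, "A", "increase",
                                   self.annotation([1, 2, 3, 4]), m=2)
        assert rec.n == rec.m_effective == 2
        assert rec.p_value == pytest.approx(
            math.comb(4, 2) / math.comb(5, 2), rel=1e-12)

    def test_empty_motif_gives_p_one(self):
        res = results_with_segment([0.5, 0.4, 0.3, 0.2, 0.1])
        rec = res.enrich_positions(2, "A", "increase", self.annotation([]),
                                   m=2)
        assert rec.n == 0 and rec.p_value == 1.0

    def test_n_matches_naive_double_loop(self, fitted, default_dataset):
        model, res = fitted
        ds = default_dataset
        ann = at.exclusive_gap_columns(model.alignment,
                                       ds.truth.groups["CladeA"],
                                       group_name="CladeA")
        res2 = res.orient(2, rule="group", group=ds.truth.groups["CladeA"])
        rec = res2.enrich_positions(2, "-", "increase", ann, m=30)
        n = 0
        for c in rec.columns:
            for a in ann.columns:
                if c == a:
                    n += 1
        assert rec.n == n

    def test_sign_flip_swaps_increase_decrease(self, fitted,
                                               default_dataset):
        model, res = fitted
        ann = at.exclusive_gap_columns(model.alignment,
                                       default_dataset.truth.groups["CladeB"],
                                       group_name="CladeB")
        inc = res.enrich_positions(2, "-", "increase", ann, m=25)
        dec = res.flip(2).enrich_positions(2, "-", "decrease", ann, m=25)
        assert inc.columns == dec.columns
        assert inc.p_value == dec.p_value and inc.n == dec.n

    def test_planted_indel_block_recovered_at_tiny_p(self, fitted,
                                                     default_dataset):
        model, res = fitted
        ds = default_dataset
        res2 = res.orient(2, rule="group", group=ds.truth.groups["CladeA"])
        ann = at.exclusive_gap_columns(model.alignment,
                                       ds.truth.groups["CladeA"],
                                       group_name="CladeA")
        rec = res2.enrich_positions(2, "-", "increase", ann, m=30)
        assert rec.p_value < 1e-10
        planted = set(ds.truth.indel_columns["CladeA"])
        assert len(set(rec.columns) & planted) / len(planted) >= 0.95


class TestMapToReference:
    def test_gapped_reference_row(self):
        aln = at.SequenceAlignment(["ref", "x"],
                                   np.array([list("ACG-U"), list("ACGAU")]))
        got = at.map_to_reference(aln, "ref", [1, 2, 3, 4, 5])
        assert got == [(1, 1), (2, 2), (3, 3), (4, None), (5, 4)]

    def test_all_gap_prefix_maps_to_none(self):
        aln = at.SequenceAlignment(["ref", "x"],
                                   np.array([list("--A"), list("CCA")]))
        assert at.map_to_reference(aln, "ref", [1, 2, 3]) == \
            [(1, None), (2, None), (3, 1)]

    def test_coordinates_strictly_increasing_where_defined(self,
                                                           default_dataset):
        aln = default_dataset.alignment
        ref = aln.organism_ids[0]
        coords = [c for _, c in
                  at.map_to_reference(aln, ref, aln.position_labels)
                  if c is not None]
        assert coords == sorted(coords) and len(set(coords)) == len(coords)

    def test_unknown_reference_rejected(self, default_dataset):
        with pytest.raises(KeyError):
            at.map_to_reference(default_dataset.alignment, "nope", [1])


class TestRaster:
    def test_raster_matrix_shape_and_content(self, default_dataset):
        aln = default_dataset.alignment
        cols = [5, 1, 3]
        mat = at.raster_matrix(aln, cols)
        assert list(mat.columns) == cols
        assert mat.shape == (aln.n_organisms, 3)
        assert mat.iloc[0, 1] == aln.characters[0, 0]
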