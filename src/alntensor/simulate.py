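"""Synthetic alignment / taxonomy / pairing fixtures with planted structure.

The generator emulates the statistical structure the comparative analysis
assumes in curated rRNA alignments:

* K organisms partitioned into nested taxonomic clades;
* group-exclusive contiguous gap blocks — substructures deleted in one clade
  (equivalently, inserted in the others);
* group-exclusive unpaired-adenosine columns with matched pairing states;
* universally conserved helix (base-paired) columns;
* consensus-driven background columns with low-rate substitution, sparse
  random gaps and a small unknown-symbol ('N') rate.

A single integer seed drives one explicit numpy Generator threaded through
all sampling; the same config therefore yields byte-identical fixture files.
The planted features and group memberships are returned as a ground-truth
manifest so recovery can be scored without re-deriving anything.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .io import (PairingTable, SequenceAlignment, TaxonomyTable,
                 write_alignment, write_pairing, write_taxonomy)

__all__ = [
    "GroupNode",
    "IndelBlock",
    "UnpairedASite",
    "SimulationConfig",
    "GroundTruth",
    "SyntheticDataset",
    "default_config",
    "null_config",
    "generate_dataset",
    "write_fixtures",
]


@dataclass(frozen=True)
class GroupNode:
    """A taxonomic group of ``size`` organisms; children partition a prefix
    of the group (a smaller children total leaves parent-only members)."""
    name: str
    size: int
    children: tuple["GroupNode", ...] = ()


@dataclass(frozen=True)
class IndelBlock:
    """A contiguous column range gapped within ``group`` (substructure
    deleted in the group) and mostly present outside it."""
    group: str
    start: int                  # 1-based, inclusive
    end: int                    # 1-based, inclusive
    in_gap_prob: float = 0.95
    out_gap_prob: float = 0.05


@dataclass(frozen=True)
class UnpairedASite:
    """Columns of adenosines conserved within ``group`` and mostly unpaired
    there, rare and more often paired outside it."""
    group: str
    columns: tuple[int, ...]
    in_a_prob: float = 0.97
    out_a_prob: float = 0.02
    in_unpaired_prob: float = 0.9
    out_unpaired_prob: float = 0.4


@dataclass
class SimulationConfig:
    K: int = 60
    M: int = 400
    group_tree: tuple[GroupNode, ...] = ()
    indel_blocks: tuple[IndelBlock, ...] = ()
    unpaired_a_sites: tuple[UnpairedASite, ...] = ()
    helix_columns: tuple[int, ...] = ()
    helix_paired_prob: float = 0.9
    background_paired_prob: float = 0.55
    consensus_prob: float = 0.85
    background_gap_prob: float = 0.02
    n_noise_rate: float = 0.01
    base_composition: tuple[float, ...] = (0.26, 0.22, 0.30, 0.22)  # A C G U
    seed: int = 1
    allow_overlap: bool = False

    def validate(self) -> None:
        if sum(g.size for g in self.group_tree) != self.K:
            raise ValueError("top-level group sizes must sum to K")
        for g in self.group_tree:
            if sum(c.size for c in g.children) > g.size:
                raise ValueError(f"children of {g.name} exceed its size")
        names = self.group_names()
        if len(names) != len(set(names)):
            raise ValueError("group names must be unique")
        for probs in ([self.helix_paired_prob, self.background_paired_prob,
                       self.consensus_prob, self.background_gap_prob,
                       self.n_noise_rate]
                      + [p for b in self.indel_blocks
                         for p in (b.in_gap_prob, b.out_gap_prob)]
                      + [p for s in self.unpaired_a_sites
                         for p in (s.in_a_prob, s.out_a_prob,
                                   s.in_unpaired_prob, s.out_unpaired_prob)]):
            if not 0 <= probs <= 1:
                raise ValueError(f"probability {probs} outside [0, 1]")
        claimed: set[int] = set()
        for cols, what in self._feature_columns():
            if min(cols) < 1 or max(cols) > self.M:
                raise ValueError(f"{what} columns outside 1..{self.M}")
            overlap = claimed & set(cols)
            if overlap and not self.allow_overlap:
                raise ValueError(
                    f"{what} overlaps earlier planted features at columns "
                    f"{sorted(overlap)[:5]} (set allow_overlap=True to permit)")
            claimed |= set(cols)
        for feat in (*self.indel_blocks, *self.unpaired_a_sites):
            if feat.group not in names:
                raise ValueError(f"unknown feature group {feat.group!r}")

    def _feature_columns(self):
        for b in self.indel_blocks:
            yield range(b.start, b.end + 1), f"indel block {b.group}"
        for s in self.unpaired_a_sites:
            yield s.columns, f"unpaired-A site {s.group}"
        if self.helix_columns:
            yield self.helix_columns, "helix columns"

    def group_names(self) -> list[str]:
        out = []
        for g in self.group_tree:
            out.append(g.name)
            out.extend(c.name for c in g.children)
        return out


def default_config(seed: int = 1) -> SimulationConfig:
    """The default study conditions: K=60 organisms in three balanced clades,
    M=400 columns, a 30-column deleted substructure and six unpaired-A sites
    planted in each of the first two clades, 60 universal helix columns, and
    nested subgroups inside the featureless third clade."""
    tree = (
        GroupNode("CladeA", 20),
        GroupNode("CladeB", 20),
        GroupNode("CladeC", 20, children=(GroupNode("CladeC1", 12),
                                          GroupNode("CladeC2", 8))),
    )
    return SimulationConfig(
        K=60, M=400, group_tree=tree,
        indel_blocks=(IndelBlock("CladeA", 101, 130),
                      IndelBlock("CladeB", 201, 230)),
        unpaired_a_sites=(
            UnpairedASite("CladeA", tuple(range(136, 166, 5))),   # 6 columns
            UnpairedASite("CladeB", tuple(range(236, 266, 5))),   # 6 columns
        ),
        helix_columns=tuple(range(301, 361)),
        seed=seed)


def null_config(seed: int = 1) -> SimulationConfig:
    """Pure-background conditions for calibration studies: three balanced
    flat clades, no planted features.  Balanced J=K/3 groups keep the
    attainable size of the discrete hypergeometric test close to nominal."""
    tree = (GroupNode("CladeA", 20), GroupNode("CladeB", 20),
            GroupNode("CladeC", 20))
    return SimulationConfig(K=60, M=400, group_tree=tree, seed=seed)


@dataclass
class GroundTruth:
    """Planted features and memberships, consistent with the emitted files."""

    groups: dict[str, tuple[str, ...]]            # group name -> organism ids
    indel_columns: dict[str, tuple[int, ...]]     # group -> column labels
    unpaired_a_columns: dict[str, tuple[int, ...]]
    helix_columns: tuple[int, ...]
    seed: int

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        return cls(
            groups={g: tuple(v) for g, v in d["groups"].items()},
            indel_columns={g: tuple(v) for g, v in d["indel_columns"].items()},
            unpaired_a_columns={g: tuple(v)
                                for g, v in d["unpaired_a_columns"].items()},
            helix_columns=tuple(d["helix_columns"]),
            seed=d["seed"])


@dataclass
class SyntheticDataset:
    alignment: SequenceAlignment
    taxonomy: TaxonomyTable
    pairing: PairingTable
    truth: GroundTruth
    config: SimulationConfig = field(repr=False, default=None)


def _memberships(config: SimulationConfig
                 ) -> tuple[list[str], dict[str, tuple[str, ...]],
                            dict[str, list[str]]]:
    """Organism ids in file order, their lineages, and group member lists."""
    ids: list[str] = []
    lineages: dict[str, tuple[str, ...]] = {}
    groups: dict[str, list[str]] = {}
    for g in config.group_tree:
        sub: list[tuple[str, ...]] = []
        for c in g.children:
            sub.extend([(g.name, c.name)] * c.size)
        sub.extend([(g.name,)] * (g.size - len(sub)))
        for lin in sub:
            org = f"{lin[-1]}_{len(ids) + 1:03d}"
            ids.append(org)
            lineages[org] = lin
            for name in lin:
                groups.setdefault(name, []).append(org)
    return ids, lineages, groups


def generate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Deterministically generate (alignment, taxonomy, pairing, truth)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    K, M = config.K, config.M
    ids, lineages, groups = _memberships(config)

    nucs = np.array(list("ACGU"))
    consensus = rng.choice(nucs, size=M, p=config.base_composition)
    # consensus background with uniform substitution among the other three
    others = np.array([[s for s in "ACGU" if s != c] for c in consensus])
    alt = others[np.arange(M)[None, :].repeat(K, 0),
                 rng.integers(0, 3, (K, M))]
    chars = np.where(rng.random((K, M)) < config.consensus_prob,
                     consensus[None, :], alt)

    member_mask = {g: np.array([o in set(m) for o in ids])
                   for g, m in groups.items()}
    block_cols = np.zeros(M, dtype=bool)
    for b in config.indel_blocks:
        cols = np.arange(b.start - 1, b.end)
        block_cols[cols] = True
        inm = member_mask[b.group]
        gap = np.where(inm[:, None], rng.random((K, len(cols))) < b.in_gap_prob,
                       rng.random((K, len(cols))) < b.out_gap_prob)
        chars[:, cols] = np.where(gap, "-", chars[:, cols])

    asite_cols: dict[str, list[int]] = {}
    feature_cols = block_cols.copy()   # columns exempt from random gap noise
    for site in config.unpaired_a_sites:
        cols = np.array(site.columns) - 1
        feature_cols[cols] = True
        asite_cols.setdefault(site.group, []).extend(site.columns)
        inm = member_mask[site.group][:, None]
        cgu = np.array(list("CGU"))[rng.integers(0, 3, (K, len(cols)))]
        is_a = np.where(inm, rng.random((K, len(cols))) < site.in_a_prob,
                        rng.random((K, len(cols))) < site.out_a_prob)
        chars[:, cols] = np.where(is_a, "A", cgu)

    # sparse random gaps outside planted feature columns, then unknown noise
    gap_noise = (rng.random((K, M)) < config.background_gap_prob) \
        & ~feature_cols[None, :]
    chars[gap_noise] = "-"
    n_noise = (rng.random((K, M)) < config.n_noise_rate) & (chars != "-")
    chars[n_noise] = "N"

    states = np.where(rng.random((K, M)) < config.background_paired_prob,
                      "Y", "N")
    if config.helix_columns:
        cols = np.array(config.helix_columns) - 1
        states[:, cols] = np.where(
            rng.random((K, len(cols))) < config.helix_paired_prob, "Y", "N")
    for site in config.unpaired_a_sites:
        cols = np.array(site.columns) - 1
        inm = member_mask[site.group][:, None]
        unpaired = np.where(
            inm, rng.random((K, len(cols))) < site.in_unpaired_prob,
            rng.random((K, len(cols))) < site.out_unpaired_prob)
        states[:, cols] = np.where(unpaired, "N", "Y")
    states[chars == "-"] = "-"

    truth = GroundTruth(
        groups={g: tuple(m) for g, m in groups.items()},
        indel_columns={b.group: tuple(range(b.start, b.end + 1))
                       for b in config.indel_blocks},
        unpaired_a_columns={g: tuple(sorted(c))
                            for g, c in asite_cols.items()},
        helix_columns=tuple(config.helix_columns),
        seed=config.seed)
    aln = SequenceAlignment(ids, chars)
    tax = TaxonomyTable(list(ids), dict(lineages))
    pairing = PairingTable(list(ids), states,
                           list(aln.position_labels))
    return SyntheticDataset(aln, tax, pairing, truth, config)


def write_fixtures(dataset: SyntheticDataset, out_dir) -> dict[str, Path]:
    """Emit alignment.tsv, taxonomy.tsv, pairing.tsv and the ground-truth
    manifest ground_truth.json into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "alignment": write_alignment(dataset.alignment, out / "alignment.tsv"),
        "taxonomy": write_taxonomy(dataset.taxonomy, out / "taxonomy.tsv"),
        "pairing": write_pairing(dataset.pairing, out / "pairing.tsv"),
        "ground_truth": out / "ground_truth.json",
    }
    paths["ground_truth"].write_text(dataset.truth.to_json() + "\n",
                                     encoding="utf-8")
    return paths
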