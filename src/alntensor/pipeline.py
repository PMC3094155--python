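"""End-to-end orchestration: filter, encode, decompose, enrich, report.

``run_pipeline`` chains the library stages and writes TSV reports that are
plain views of the serialized model bundle — every number in them can be
recomputed from the bundle by library calls alone.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .enrichment import default_k, enrich_eigenposition
from .io import read_alignment, read_pairing, read_taxonomy
from .model import AlignmentTensorModel
from .motifs import (conserved_helix_columns, exclusive_gap_columns,
                     exclusive_unpaired_A_columns)
from .positions import (enrich_segment, map_to_reference, raster_matrix)

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger(__name__)

SEGMENT_SYMBOLS = ("A", "C", "G", "U", "-")   # N segments are not interpreted


@dataclass
class PipelineConfig:
    alignment: Path
    taxonomy: Path | None = None
    pairing: Path | None = None
    out: Path = Path("alntensor_results")
    dialect: str = "tab"
    min_fraction: float = 0.01
    k: int | None = None
    m: int | None = None
    tie_mode: str = "rank"
    gap_in_threshold: float = 0.8
    gap_out_threshold: float = 0.2
    helix_threshold: float = 0.6
    fraction_convention: str = "squared"
    components: tuple[int, ...] = ()      # empty -> 2..7 (clipped to R)
    reference: str | None = None
    min_group_size: int = 3
    rasters: bool = True
    coerce_unknown_to_n: bool = False
    log_level: str = "INFO"

    def resolved_components(self, R: int) -> tuple[int, ...]:
        comps = self.components or tuple(range(2, 8))
        return tuple(r for r in comps if 1 <= r <= R)


def _configure_log(out: Path, level: str) -> logging.FileHandler:
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "pipeline.log", mode="w",
                                  encoding="utf-8")
    handler.setFormatter(logging.Formatter(
        "%(asctime)s %(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("alntensor")
    root.addHandler(handler)
    root.setLevel(getattr(logging, level.upper(), logging.INFO))
    return handler


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> Path:
    df.to_csv(path, sep="\t", index=index, float_format="%.6g")
    return path


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full comparative analysis; returns the results object, the
    report DataFrames and the output paths."""
    out = Path(config.out)
    handler = _configure_log(out, config.log_level)
    try:
        logger.info("parameters: %s", dataclasses.asdict(config))

        aln = read_alignment(config.alignment, config.dialect,
                             coerce_unknown_to_n=config.coerce_unknown_to_n)
        tax = read_taxonomy(config.taxonomy) if config.taxonomy else None
        pairing = read_pairing(config.pairing, aln) if config.pairing else None
        logger.info("alignment: %d organisms x %d positions",
                    *aln.characters.shape)

        model = AlignmentTensorModel(aln, tax, pairing,
                                     min_fraction=config.min_fraction)
        logger.info("position filter kept %d of %d columns",
                    len(model.kept_columns), aln.n_positions)
        results = model.fit(convention=config.fraction_convention)
        results.save(out / "model")
        (out / "summary.txt").write_text(results.summary() + "\n",
                                         encoding="utf-8")

        fr = results.fractions
        fractions = pd.DataFrame({
            "component": range(1, results.n_components + 1),
            "singular_value": results.singular_values,
            "fraction": fr,
            "cumulative": fr.cumsum(),
        })
        _write_tsv(fractions, out / "fractions.tsv")
        _write_tsv(results.eigenposition_frame(), out / "eigenpositions.tsv",
                   index=True)
        for sym in results.slice_order:
            name = "gap" if sym == "-" else sym
            _write_tsv(results.segment_frame(sym),
                       out / f"segments_{name}.tsv", index=True)

        comps = config.resolved_components(results.n_components)
        K = len(results.organism_ids)
        k = config.k or default_k(K)
        logger.info("analyzing components %s with k=%d", comps, k)

        org_df = pos_df = None
        hit_rows: list[dict] = []
        if tax is not None:
            org_frames = [
                enrich_eigenposition(results, tax, r, k=k,
                                     min_size=config.min_group_size)
                for r in comps]
            org_df = pd.concat(org_frames, ignore_index=True)
            _write_tsv(org_df, out / "organism_enrichment.tsv")

            records = []
            for r, frame in zip(comps, org_frames):
                records.extend(_positions_for_component(
                    results, model, frame, r, config, out, hit_rows))
            if records:
                pos_df = pd.DataFrame(
                    [{k2: v for k2, v in vars(rec).items() if k2 != "columns"}
                     for rec in records]).sort_values(
                         ["component", "p_value"], kind="stable")
                _write_tsv(pos_df, out / "position_enrichment.tsv")
            if hit_rows:
                _write_tsv(pd.DataFrame(hit_rows),
                           out / "position_enrichment_columns.tsv")
        else:
            logger.info("no taxonomy given; skipping enrichment stages")

        diag = results.mean_frequency_correlation(1)
        logger.info("component 1 mean-like=%s cv=%.4f", diag.is_mean_like,
                    diag.eigenposition_cv)
        return {"results": results, "model": model, "fractions": fractions,
                "organism_enrichment": org_df, "position_enrichment": pos_df,
                "out": out}
    finally:
        logging.getLogger("alntensor").removeHandler(handler)
        handler.close()


def _positions_for_component(results, model, org_frame, r,
                             config: PipelineConfig, out: Path,
                             hit_rows: list) -> list:
    """Tables-style position enrichment for one component: motifs of the
    best group per direction tested against every nucleotide segment and
    both directions."""
    best = org_frame[org_frame["best_in_direction"]]
    truth_groups = {row.group: row.direction for row in best.itertuples()}
    tax = model.taxonomy
    from .enrichment import candidate_groups
    group_sets = dict(candidate_groups(tax, min_size=config.min_group_size,
                                       organisms=results.organism_ids))
    annotations = []
    for group in truth_groups:
        members = group_sets.get(group)
        if members is None or len(members) == len(results.organism_ids):
            continue
        annotations.append(exclusive_gap_columns(
            model.alignment, members, config.gap_in_threshold,
            config.gap_out_threshold, group_name=group))
        if model.pairing is not None:
            annotations.append(exclusive_unpaired_A_columns(
                model.alignment, model.pairing, members,
                config.gap_in_threshold, config.gap_out_threshold,
                group_name=group))
            annotations.append(conserved_helix_columns(
                model.pairing, members, config.helix_threshold,
                group_name=group))

    records = []
    for ann in annotations:
        if not ann.columns:
            continue
        for symbol in SEGMENT_SYMBOLS:
            for direction in ("increase", "decrease"):
                rec = enrich_segment(results, r, symbol, direction, ann,
                                     m=config.m, tie_mode=config.tie_mode)
                records.append(rec)
                if rec.p_value < 0.05:
                    _record_hits(rec, ann.column_set, results, model,
                                 config, out, hit_rows)
    return records


def _record_hits(rec, motif_columns: frozenset, results, model,
                 config: PipelineConfig, out: Path, hit_rows: list) -> None:
    ref_map = {}
    if config.reference:
        ref_map = dict(map_to_reference(model.alignment, config.reference,
                                        list(rec.columns)))
    for rank, col in enumerate(rec.columns, 1):
        row = {"component": rec.component, "symbol": rec.symbol,
               "direction": rec.direction, "motif": rec.motif,
               "group": rec.group, "rank": rank, "column": col,
               "in_motif": col in motif_columns}
        if config.reference:
            row["reference_coordinate"] = ref_map.get(col)
        hit_rows.append(row)
    if config.rasters and rec.symbol in ("A", "-"):
        sym = "gap" if rec.symbol == "-" else rec.symbol
        order = [results.organism_ids[i] for i in
                 np.argsort(-results.eigenposition(rec.component),
                            kind="stable")]
        mat = raster_matrix(model.alignment, list(rec.columns), order)
        rdir = out / "rasters"
        rdir.mkdir(exist_ok=True)
        mat.to_csv(rdir / f"comp{rec.component}_{sym}_{rec.direction}_"
                          f"{rec.motif}_{_slug(rec.group)}.tsv", sep="\t")


def _slug(name: str) -> str:
    return "".join(c if c.isalnum() else "_" for c in name)[:60]
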