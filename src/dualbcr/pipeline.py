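"""End-to-end orchestration: classify -> stats -> overlap -> track.

One configured run ingests per-sample contig tables (and optionally
expression matrices), applies the contig filter cascade and pairing
classification, computes the repertoire statistics per sample and per
group (pooled, plus the per-subject mean ± sd the per-group tables
print), the single-vs-dual overlap, and — when expression data is
present — the transcriptome link: QC, subset labels, barcode join,
subset-stratified expansion, and disease-vs-control differential
expression.

Every stage's input and output cell counts are recorded in a manifest
("attrition table") so the effect of each filter is auditable; output
bytes are deterministic for a fixed config and seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bcr_core import (CellChainSet, PairingCall, assign_clonotypes,
                       calls_frame, cells_to_frame, classify_pairing,
                       expansion_stats, filter_functional_contigs,
                       group_cells, summarize_pairing)
from .io_formats import read_contig_table, read_expression_matrix, \
    write_summary_tables
from .overlap import cdr3_overlap, pairwise_overlap_matrix
from .repertoire_stats import (CloneSizeVector, compare_proportions,
                               gene_usage, gini_index, inverse_simpson,
                               isotype_composition)
from .transcriptome_link import (assign_subsets, differential_expression,
                                 join_by_barcode, normalize_log, qc_filter)

__all__ = ["SampleSpec", "RunConfig", "run_pipeline", "PipelineResult"]


@dataclass
class SampleSpec:
    """One sample's inputs."""

    path: str
    sample_id: str
    group: str
    species: str = "mouse"
    dialect: str = "tenx_csv"
    matrix_dir: str | None = None  # directory with matrix.mtx/genes/barcodes


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    samples: list[SampleSpec]
    out_dir: str
    seed: int = 0
    clonotype_level: str = "nt"
    clonotype_scope: str = "all_chains"
    gini_level: str = "aa"
    overlap_chain: str = "IGH"
    overlap_level: str = "aa"
    normalize_suffix: bool = False
    disease_group: str | None = None  # group treated as "A" in DE

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("sample_ids must be unique")
        if not self.samples:
            raise ValueError("at least one sample is required")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        samples = [SampleSpec(**s) for s in raw.pop("samples")]
        return cls(samples=samples, **raw)


@dataclass
class PipelineResult:
    """In-memory view of everything a run wrote."""

    tables: dict[str, pd.DataFrame]
    manifest: dict
    cells: list[CellChainSet]
    calls: list[PairingCall]


def _per_subject_summary(per_sample: pd.DataFrame,
                         sample_groups: dict[str, str],
                         value_cols: list[str]) -> pd.DataFrame:
    """Group-level mean ± sd across biological subjects (samples)."""
    df = per_sample.copy()
    df["group"] = df["stratum"].map(sample_groups)
    rows = []
    for group, sub in df.groupby("group", sort=True):
        row = {"group": group, "n_samples": len(sub)}
        for col in value_cols:
            row[f"{col}_mean"] = sub[col].mean()
            row[f"{col}_sd"] = sub[col].std(ddof=1) if len(sub) > 1 else 0.0
        rows.append(row)
    return pd.DataFrame(rows)


def _compartment_stats(cells_by: dict[tuple[str, str], list[CellChainSet]],
                       cfg: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Diversity/expansion (clonotype level) and Gini per sample x class."""
    div_rows, gini_rows = [], []
    for (sample, klass), cells in sorted(cells_by.items()):
        if not cells:
            continue
        asn = assign_clonotypes(cells, level=cfg.clonotype_level,
                                scope=cfg.clonotype_scope)
        if asn.clones:
            vec = CloneSizeVector.from_sizes(asn.sizes)
            exp = expansion_stats(asn.clones)
            div_rows.append({
                "sample_id": sample, "bcr_class": klass,
                "n_cells": vec.total_cells, "n_clones": vec.n_clones,
                "n_excluded": asn.n_excluded,
                "inverse_simpson": inverse_simpson(vec),
                "prop_expanded": exp["prop_expanded"],
                "prop_singleton": exp["prop_singleton"],
            })
        gini_asn = assign_clonotypes(cells, level=cfg.gini_level,
                                     scope=cfg.clonotype_scope)
        if gini_asn.clones:
            gini_rows.append({
                "sample_id": sample, "bcr_class": klass,
                "n_clones": len(gini_asn.clones),
                "gini": gini_index(CloneSizeVector.from_sizes(gini_asn.sizes)),
            })
    return pd.DataFrame(div_rows), pd.DataFrame(gini_rows)


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute all stages and write the consolidated report tables."""
    cfg = config
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": cfg.seed,
                      "samples": [], "attrition": {}}
    sample_groups = {s.sample_id: s.group for s in cfg.samples}

    # ---- stage 1: read, filter, group, classify -------------------------
    all_cells: list[CellChainSet] = []
    all_calls: list[PairingCall] = []
    for spec in cfg.samples:
        table = read_contig_table(spec.path, dialect=spec.dialect,
                                  sample_id=spec.sample_id)
        filtered, log = filter_functional_contigs(table)
        cells, n_single_chain = group_cells(filtered)
        calls = [classify_pairing(c) for c in cells]
        all_cells.extend(cells)
        all_calls.extend(calls)
        att = log.as_dict()
        att.update({
            "n_single_chain_dropped": n_single_chain,
            "n_cells": len(cells),
            "n_pairable": sum(c.bcr_class != "unpairable" for c in calls),
            "n_unpairable": sum(c.bcr_class == "unpairable" for c in calls),
        })
        manifest["attrition"][spec.sample_id] = att
        manifest["samples"].append(
            {"sample_id": spec.sample_id, "group": spec.group,
             "path": str(spec.path), "dialect": spec.dialect})
    if not all_calls:
        raise RuntimeError("stage classify produced no cells from any sample")

    tables: dict[str, pd.DataFrame] = {}
    calls_df = calls_frame(all_calls)

    # per-cell calls with clonotype ids
    asn_all = assign_clonotypes(all_cells, level=cfg.clonotype_level,
                                scope=cfg.clonotype_scope)
    calls_out = calls_df.merge(asn_all.cell_table,
                               on=["barcode", "sample_id"], how="left")
    tables["calls"] = calls_out

    # ---- stage 2: pairing summaries ------------------------------------
    per_sample = summarize_pairing(all_calls, by="sample_id")
    tables["pairing"] = per_sample
    prop_cols = [c for c in per_sample.columns if c.startswith("prop_")]
    tables["pairing_by_group"] = _per_subject_summary(
        per_sample, sample_groups, prop_cols)
    fine = (calls_df.value_counts(["sample_id", "bcr_class", "fine_code"])
            .rename("count").reset_index()
            .sort_values(["sample_id", "bcr_class", "fine_code"])
            .reset_index(drop=True))
    tables["fine_codes"] = fine

    # ---- stage 3: per-compartment repertoire statistics -----------------
    cells_by: dict[tuple[str, str], list[CellChainSet]] = {}
    call_by_key = {(c.sample_id, c.barcode): c for c in all_calls}
    for cell in all_cells:
        klass = call_by_key[(cell.sample_id, cell.barcode)].bcr_class
        if klass == "unpairable":
            continue
        cells_by.setdefault((cell.sample_id, klass), []).append(cell)
    diversity, gini = _compartment_stats(cells_by, cfg)
    tables["diversity"] = diversity
    tables["gini"] = gini

    # V/J usage per group x compartment, with the dual-vs-single test
    group_of = {c.barcode: f"{sample_groups[c.sample_id]}|{c.bcr_class}"
                for c in all_calls if c.bcr_class != "unpairable"}
    usage_frames = []
    test_rows = []
    for segment in ("V", "J"):
        for chain in ("IGH", "IGK", "IGL"):
            u = gene_usage(all_cells, all_calls, segment=segment, chain=chain,
                           resolution="family", compartment_of=group_of)
            if u.empty:
                continue
            u.insert(0, "chain", chain)
            u.insert(0, "segment", segment)
            usage_frames.append(u)
            # dual vs single within each group
            wide = u.pivot_table(index="gene", columns="compartment",
                                 values="count", fill_value=0)
            for group in sorted({g.split("|")[0] for g in wide.columns}):
                a, b = f"{group}|dual", f"{group}|single"
                if a in wide.columns and b in wide.columns:
                    res = compare_proportions(wide[a].to_numpy(),
                                              wide[b].to_numpy())
                    test_rows.append({
                        "comparison": f"{group}: dual vs single",
                        "segment": segment, "chain": chain,
                        "test_used": res.test_used,
                        "statistic": res.statistic, "p_value": res.p_value,
                        "n": res.n, "min_expected": res.min_expected,
                    })
    tables["usage"] = (pd.concat(usage_frames, ignore_index=True)
                       if usage_frames else pd.DataFrame())
    tables["tests"] = pd.DataFrame(test_rows)
    tables["isotypes"] = isotype_composition(all_cells,
                                             compartment_of=group_of)

    # ---- stage 4: overlap ------------------------------------------------
    comp: dict[str, list[CellChainSet]] = {}
    for (sample, klass), cells in sorted(cells_by.items()):
        comp.setdefault(f"{sample_groups[sample]}|{klass}", []).extend(cells)
    overlap_rows, shared_frames = [], []
    if len(comp) >= 2:
        jac, nsh, results = pairwise_overlap_matrix(
            comp, chain=cfg.overlap_chain, level=cfg.overlap_level)
        tables["overlap_jaccard"] = jac.reset_index(names="compartment")
        tables["overlap_shared_counts"] = nsh.reset_index(names="compartment")
        for (la, lb), res in sorted(results.items()):
            overlap_rows.append({
                "set_a": la, "set_b": lb, "n_a": res.n_a, "n_b": res.n_b,
                "n_shared": res.n_shared, "jaccard": res.jaccard})
            sh = res.shared_sequences.copy()
            if len(sh):
                sh.insert(0, "set_b", lb)
                sh.insert(0, "set_a", la)
                shared_frames.append(sh)
    tables["overlap"] = pd.DataFrame(overlap_rows)
    tables["shared_sequences"] = (pd.concat(shared_frames, ignore_index=True)
                                  if shared_frames else pd.DataFrame())

    # ---- stage 5 (optional): transcriptome link -------------------------
    matrices = [s for s in cfg.samples if s.matrix_dir]
    if matrices:
        try:
            _run_transcriptome_stage(cfg, matrices, calls_out, tables,
                                     manifest, sample_groups)
        except Exception as exc:  # degrade gracefully to BCR-only outputs
            manifest["transcriptome_stage"] = f"failed: {exc}"
    else:
        manifest["transcriptome_stage"] = "skipped (no matrices configured)"

    # ---- write -----------------------------------------------------------
    write_summary_tables({k: v for k, v in tables.items()}, out)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return PipelineResult(tables=tables, manifest=manifest,
                          cells=all_cells, calls=all_calls)


def _run_transcriptome_stage(cfg: RunConfig, specs: list[SampleSpec],
                             calls_out: pd.DataFrame,
                             tables: dict[str, pd.DataFrame],
                             manifest: dict,
                             sample_groups: dict[str, str]) -> None:
    import anndata as ad

    adatas = []
    for spec in specs:
        d = Path(spec.matrix_dir)
        adata = read_expression_matrix(d / "matrix.mtx", d / "genes.txt",
                                       d / "barcodes.txt")
        adata.obs["sample_id"] = spec.sample_id
        adata.obs["group"] = spec.group
        adatas.append(adata)
    adata = ad.concat(adatas, join="outer", merge="same") \
        if len(adatas) > 1 else adatas[0]
    adata.X = adata.X.tocsr()
    species = specs[0].species

    qc = qc_filter(adata, species=species)
    manifest["transcriptome_stage"] = {
        "n_cells_in": int(adata.n_obs),
        "n_cells_qc_pass": int(qc["passes_qc"].sum()),
    }
    passing = qc.loc[qc["passes_qc"], "barcode"]
    adata = adata[adata.obs_names.isin(set(passing))].copy()
    normalized = normalize_log(adata)
    labels = assign_subsets(normalized, species=species)
    tables["qc"] = qc

    tracked, join_report = join_by_barcode(
        calls_out, labels, qc=None, normalize_suffix=cfg.normalize_suffix)
    tracked = tracked.merge(
        adata.obs[["group"]].reset_index()
        .rename(columns={adata.obs.index.name or "index": "barcode_rna"}),
        on="barcode_rna", how="left")
    manifest["transcriptome_stage"]["join"] = join_report
    tables["tracked_cells"] = tracked

    # subset x pairing-class composition per group
    comp = (tracked[tracked["bcr_class"] != "unpairable"]
            .value_counts(["group", "bcr_class", "subset"])
            .rename("count").reset_index()
            .sort_values(["group", "bcr_class", "subset"])
            .reset_index(drop=True))
    comp["proportion"] = comp.groupby(["group", "bcr_class"])["count"] \
        .transform(lambda s: s / s.sum())
    tables["subset_composition"] = comp

    # clonal expansion per subset (clone sizes from the classify stage)
    exp_rows = []
    sub = tracked[(tracked["bcr_class"] != "unpairable")
                  & tracked["clone_size"].notna()]
    for (group, klass, subset), g in sub.groupby(
            ["group", "bcr_class", "subset"], sort=True):
        exp_rows.append({
            "group": group, "bcr_class": klass, "subset": subset,
            "n_cells": len(g),
            "prop_expanded": float((g["clone_size"] >= 2).mean()),
        })
    tables["expansion_by_subset"] = pd.DataFrame(exp_rows)

    # DE: disease vs control within each pairing class
    groups = sorted(tracked["group"].dropna().unique())
    disease = cfg.disease_group or (groups[0] if len(groups) == 1 else None)
    if disease is None and len(groups) == 2:
        disease = groups[0]
    de_frames = []
    if disease is not None and len(groups) >= 2:
        others = [g for g in groups if g != disease]
        control = others[0]
        for klass in ("single", "dual"):
            ga = tracked.loc[(tracked["group"] == disease)
                             & (tracked["bcr_class"] == klass), "barcode_rna"]
            gb = tracked.loc[(tracked["group"] == control)
                             & (tracked["bcr_class"] == klass), "barcode_rna"]
            if len(ga) < 3 or len(gb) < 3:
                continue
            de = differential_expression(normalized, list(ga), list(gb))
            de.insert(0, "comparison", f"{klass}: {disease} vs {control}")
            de_frames.append(de)
    tables["de_results"] = (pd.concat(de_frames, ignore_index=True)
                            if de_frames else pd.DataFrame())
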