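"""Synthetic paired scBCR-seq + scRNA-seq data with known ground truth.

Emulates the statistical structure the pipeline assumes so that every
stage is testable without sequencing data:

* per-cell chain multisets over {IGH, IGK, IGL} with a controllable
  dual-BCR fraction and pairing-type mix (dominant ``H+κ1+κ2``, the
  multi-heavy "others" codes, and ``H+κ+λ``, as observed in spleen
  B cell repertoires);
* clonal structure: clone sizes drawn from a geometric (or zipf) law
  and truncated so that a target fraction of cells sits in clones of
  size >= 2; clone members share every CDR3 and gene call;
* contaminant contigs carrying the failing QC flag of each filter rule,
  plus single-chain barcodes that the cell grouping must discard;
* V/D/J usage, isotype frequencies, and random in-frame CDR3
  nucleotide sequences (30–60 nt, stop-free, translated to amino
  acids);
* a companion expression matrix: negative-binomial background genes, a
  shared gene panel across samples, subset marker genes up-shifted in
  their subset, planted differential genes multiplied in the disease
  group, and mitochondrial pseudo-genes at a controlled count fraction.

Every generated cell is recorded in the ground truth, and realized
summary statistics (dual fraction, expanded fraction, clone sizes) are
recomputable from the per-cell records exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import yaml
from Bio.Seq import Seq

from .io_formats import ContigTable, CONTIG_COLUMNS, write_contig_table, \
    write_expression_matrix

__all__ = ["SimConfig", "GroundTruth", "simulate_repertoire",
           "simulate_expression", "write_simulation"]

_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
           if a + b + c not in ("TAA", "TAG", "TGA")]

# default V/J gene pools (mouse casing; upper-cased for human)
_V_GENES = {
    "IGH": (["Ighv1-5", "Ighv1-85", "Ighv9-3", "Ighv2-2", "Ighv5-17",
             "Ighv8-8", "Ighv11-2", "Ighv14-3", "Ighv3-6", "Ighv6-3"],
            [0.22, 0.13, 0.15, 0.10, 0.10, 0.09, 0.07, 0.06, 0.05, 0.03]),
    "IGK": (["Igkv1-117", "Igkv6-23", "Igkv4-55", "Igkv3-2", "Igkv10-96",
             "Igkv19-93"],
            [0.28, 0.22, 0.18, 0.14, 0.10, 0.08]),
    "IGL": (["Iglv1", "Iglv2", "Iglv3"], [0.55, 0.30, 0.15]),
}
_J_GENES = {
    "IGH": (["Ighj1", "Ighj2", "Ighj3", "Ighj4"], [0.20, 0.30, 0.20, 0.30]),
    "IGK": (["Igkj1", "Igkj2", "Igkj4", "Igkj5"], [0.30, 0.25, 0.25, 0.20]),
    "IGL": (["Iglj1", "Iglj2", "Iglj3"], [0.45, 0.35, 0.20]),
}
_D_GENES = (["Ighd1-1", "Ighd2-4", "Ighd3-2", ""], [0.35, 0.30, 0.25, 0.10])

_ISOTYPE_GENES = {
    "IGHM": ["Ighm"], "IGHD": ["Ighd"],
    "IGHG": ["Ighg1", "Ighg2b", "Ighg2c", "Ighg3"],
    "IGHA": ["Igha"], "IGHE": ["Ighe"],
}
_LIGHT_C = {"IGK": "Igkc", "IGL": "Iglc1"}


def _norm_vec(d: dict[str, float], what: str) -> dict[str, float]:
    total = float(sum(d.values()))
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"{what} probabilities sum to {total}, not 1")
    return d


@dataclass
class SimConfig:
    """Parameters of one simulated sample.

    Defaults describe a healthy mouse spleen B cell repertoire: a 9%
    dual-BCR fraction with ``H+κ1+κ2`` the dominant dual pairing, 15%
    of cells in expanded clones, an IgM/IgD-dominated isotype mix, and
    modest contig contamination at each QC rule.
    """

    n_cells: int = 5000
    sample_id: str = "sim"
    group: str = "control"
    species: str = "mouse"
    seed: int = 0

    # pairing structure
    dual_fraction: float = 0.09
    unpairable_fraction: float = 0.02
    single_lambda_fraction: float = 0.15   # H+λ share among single cells
    pairing_mix: dict[str, float] = field(default_factory=lambda: {
        "1H2K": 0.72, "2H2K": 0.11, "1H1K1L": 0.08, "2H1K": 0.04,
        "1H2L": 0.02, "2H1K1L": 0.02, "2H1L": 0.01})
    unpairable_mix: dict[str, float] = field(default_factory=lambda: {
        "2K": 0.40, "1K1L": 0.30, "2H": 0.30})

    # clonal structure
    clone_size_law: str = "geometric"
    clone_law_param: float = 0.5
    expanded_target: float = 0.15
    shared_clone_fraction: float = 0.05  # dual clones reusing a single-BCR IGH CDR3

    # per-chain gene usage; None -> module defaults
    v_usage: dict[str, tuple[list[str], list[float]]] | None = None
    j_usage: dict[str, tuple[list[str], list[float]]] | None = None
    isotype_mix: dict[str, float] = field(default_factory=lambda: {
        "IGHM": 0.64, "IGHD": 0.30, "IGHA": 0.03, "IGHG": 0.02, "IGHE": 0.01})
    dual_v_enrichment: tuple[str, float] | None = None  # (family, factor)

    # contamination (rates relative to the functional contig count)
    contamination: dict[str, float] = field(default_factory=lambda: {
        "non_cell": 0.02, "low_confidence": 0.02,
        "non_productive": 0.04, "bad_chain": 0.01})
    single_chain_fraction: float = 0.03  # extra barcodes with one chain

    # transcriptome
    subset_mix: dict[str, float] = field(default_factory=lambda: {
        "Naive_B": 0.70, "Memory_B": 0.15, "Plasma": 0.10, "Breg": 0.05})
    n_background_genes: int = 600
    n_mito_genes: int = 10
    mito_target: float = 0.02
    n_high_mito_cells: int = 0       # cells planted to fail the mito rule
    high_mito_fraction: float = 0.10
    marker_mean: float = 12.0        # marker expression in its own subset
    marker_background: float = 0.05
    cd19_mean: float = 4.0
    de_n_genes: int = 20
    de_effect: float = 2.5
    de_group: str = "disease"        # group in which planted genes shift
    panel_seed: int = 12345          # shared across samples of one study

    def __post_init__(self) -> None:
        for name in ("dual_fraction", "unpairable_fraction",
                     "single_lambda_fraction", "expanded_target",
                     "shared_clone_fraction", "single_chain_fraction",
                     "mito_target", "high_mito_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        _norm_vec(self.pairing_mix, "pairing_mix")
        _norm_vec(self.unpairable_mix, "unpairable_mix")
        _norm_vec(self.isotype_mix, "isotype_mix")
        _norm_vec(self.subset_mix, "subset_mix")
        if self.clone_size_law == "geometric":
            if not 0.0 < self.clone_law_param <= 1.0:
                raise ValueError("geometric clone law needs 0 < p <= 1")
        elif self.clone_size_law == "zipf":
            if self.clone_law_param <= 1.0:
                raise ValueError("zipf clone law needs exponent > 1")
        else:
            raise ValueError(f"unknown clone_size_law {self.clone_size_law!r}")
        if self.n_cells < 1:
            raise ValueError("n_cells must be positive")
        if self.expanded_target > 0 and self.n_cells < 2:
            raise ValueError("expanded_target unreachable with < 2 cells")

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class GroundTruth:
    """Per-cell and per-gene truth records plus realized summaries."""

    cells: pd.DataFrame          # barcode, fine_code, bcr_class, clone_id, subset, group, sample_id
    gene_truth: pd.DataFrame     # gene, role, subset, is_de, is_mito
    realized: dict[str, object]

    def recompute_realized(self) -> dict[str, float]:
        """Re-derive the headline summaries from the per-cell records."""
        pairable = self.cells[self.cells["bcr_class"].isin(["single", "dual"])]
        sizes = pairable["clone_id"].value_counts()
        expanded = pairable["clone_id"].map(sizes).ge(2)
        return {
            "dual_fraction": float((pairable["bcr_class"] == "dual").mean()),
            "expanded_fraction": float(expanded.mean()),
        }


def _random_cdr3(rng: np.random.Generator) -> tuple[str, str]:
    n_codons = int(rng.integers(10, 21))  # 30..60 nt
    nt = "".join(rng.choice(_CODONS) for _ in range(n_codons))
    return nt, str(Seq(nt).translate())


def _species_case(gene: str, species: str) -> str:
    return gene.upper() if species == "human" else gene


def _draw(rng, pool: tuple[list[str], list[float]]) -> str:
    genes, probs = pool
    return genes[rng.choice(len(genes), p=np.asarray(probs) / np.sum(probs))]


def _parse_code(code: str) -> dict[str, int]:
    out = {"IGH": 0, "IGK": 0, "IGL": 0}
    for i in range(0, len(code), 2):
        out[{"H": "IGH", "K": "IGK", "L": "IGL"}[code[i + 1]]] = int(code[i])
    return out


def _clone_sizes(rng: np.random.Generator, pool: int, target: float,
                 law: str, param: float) -> list[int]:
    """Clone sizes for one pool of cells, hitting the expanded target.

    Expanded clones (size >= 2) are drawn from the law until the target
    cell count is covered, the last clone truncated to fit; remaining
    cells are singletons.
    """
    if pool == 0:
        return []
    n_expanded = int(round(target * pool))
    if n_expanded == 1:
        n_expanded = 2 if pool >= 2 else 0
    sizes: list[int] = []
    covered = 0
    while covered < n_expanded:
        if law == "geometric":
            s = 1 + int(rng.geometric(param))  # support >= 2
        else:
            s = 1 + int(rng.zipf(param))
        s = min(s, n_expanded - covered)
        if s < 2:  # truncation left a singleton slot: grow the last clone
            if sizes:
                sizes[-1] += s
            else:
                s = 2
                sizes.append(s)
                covered += s
                continue
            covered += s
            continue
        sizes.append(s)
        covered += s
    sizes.extend([1] * (pool - covered))
    return sizes


def _chain_template(rng, chain: str, cfg: SimConfig, dual: bool) -> dict[str, str]:
    v_pool = (cfg.v_usage or _V_GENES)[chain]
    if dual and chain == "IGH" and cfg.dual_v_enrichment is not None:
        family, factor = cfg.dual_v_enrichment
        genes, probs = v_pool
        probs = np.asarray(probs, dtype=float).copy()
        boost = np.array([g.upper().startswith(family.upper())
                          for g in genes])
        probs[boost] *= factor
        v_pool = (genes, list(probs / probs.sum()))
    j_pool = (cfg.j_usage or _J_GENES)[chain]
    nt, aa = _random_cdr3(rng)
    tpl = {"chain": chain,
           "v_gene": _species_case(_draw(rng, v_pool), cfg.species),
           "d_gene": "",
           "j_gene": _species_case(_draw(rng, j_pool), cfg.species),
           "cdr3_nt": nt, "cdr3_aa": aa}
    if chain == "IGH":
        tpl["d_gene"] = _species_case(_draw(rng, _D_GENES), cfg.species)
        iso_classes = list(cfg.isotype_mix)
        iso = iso_classes[rng.choice(len(iso_classes),
                                     p=list(cfg.isotype_mix.values()))]
        tpl["c_gene"] = _species_case(
            _ISOTYPE_GENES[iso][rng.integers(len(_ISOTYPE_GENES[iso]))],
            cfg.species)
    else:
        tpl["c_gene"] = _species_case(_LIGHT_C[chain], cfg.species)
    return tpl


def simulate_repertoire(config: SimConfig) -> tuple[ContigTable, GroundTruth]:
    """Generate one sample's contig table plus its ground truth.

    Deterministic for a fixed config (including seed): the same config
    yields byte-identical tables.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    # --- per-cell class draws (i.i.d., so realized counts are binomial)
    u = rng.random(cfg.n_cells)
    unpairable = u < cfg.unpairable_fraction
    dual = (~unpairable) & (rng.random(cfg.n_cells) < cfg.dual_fraction)
    single = ~unpairable & ~dual

    # --- clone partitions within the single and dual pools
    clones: list[dict] = []  # code, chain templates, member cell indices
    cell_clone = np.empty(cfg.n_cells, dtype=object)
    cell_code = np.empty(cfg.n_cells, dtype=object)
    cell_class = np.where(unpairable, "unpairable",
                          np.where(dual, "dual", "single"))

    single_igh_templates: list[dict] = []
    pair_codes = list(cfg.pairing_mix)
    pair_probs = list(cfg.pairing_mix.values())
    unp_codes = list(cfg.unpairable_mix)
    unp_probs = list(cfg.unpairable_mix.values())

    clone_counter = 0
    for klass, members in (("single", np.flatnonzero(single)),
                           ("dual", np.flatnonzero(dual))):
        sizes = _clone_sizes(rng, len(members), cfg.expanded_target,
                             cfg.clone_size_law, cfg.clone_law_param)
        members = rng.permutation(members)
        pos = 0
        for size in sizes:
            idx = members[pos:pos + size]
            pos += size
            if klass == "single":
                code = ("1H1L" if rng.random() < cfg.single_lambda_fraction
                        else "1H1K")
            else:
                code = pair_codes[rng.choice(len(pair_codes), p=pair_probs)]
            counts = _parse_code(code)
            templates = []
            for chain in ("IGH", "IGK", "IGL"):
                for _ in range(counts[chain]):
                    templates.append(
                        _chain_template(rng, chain, cfg, dual=klass == "dual"))
            clone_id = f"t{clone_counter:06d}"
            clone_counter += 1
            clones.append({"clone_id": clone_id, "code": code,
                           "templates": templates, "members": idx,
                           "class": klass})
            if klass == "single":
                single_igh_templates.extend(
                    t for t in templates if t["chain"] == "IGH")
            for i in idx:
                cell_clone[i] = clone_id
                cell_code[i] = code

    # dual clones optionally reuse a single-BCR heavy CDR3 (clonal sharing
    # between compartments, as seen in diseased repertoires)
    if cfg.shared_clone_fraction > 0 and single_igh_templates:
        for clone in clones:
            if clone["class"] != "dual":
                continue
            if rng.random() < cfg.shared_clone_fraction:
                src = single_igh_templates[
                    rng.integers(len(single_igh_templates))]
                for t in clone["templates"]:
                    if t["chain"] == "IGH":
                        t["cdr3_nt"] = src["cdr3_nt"]
                        t["cdr3_aa"] = src["cdr3_aa"]
                        break

    # unpairable cells: one private template set each
    for i in np.flatnonzero(unpairable):
        code = unp_codes[rng.choice(len(unp_codes), p=unp_probs)]
        counts = _parse_code(code)
        templates = []
        for chain in ("IGH", "IGK", "IGL"):
            for _ in range(counts[chain]):
                templates.append(_chain_template(rng, chain, cfg, dual=False))
        clone_id = f"t{clone_counter:06d}"
        clone_counter += 1
        clones.append({"clone_id": clone_id, "code": code,
                       "templates": templates, "members": np.array([i]),
                       "class": "unpairable"})
        cell_clone[i] = clone_id
        cell_code[i] = code

    barcodes = np.array([f"{cfg.sample_id}_BC{i:06d}-1"
                         for i in range(cfg.n_cells)])

    # --- emit functional contig rows
    rows: list[dict] = []

    def emit(barcode: str, tpl: dict, is_cell=True, high_conf=True,
             productive="True", chain=None) -> None:
        umis = int(rng.integers(2, 60))
        rows.append({
            "barcode": barcode,
            "contig_id": f"{barcode}_contig_{len(rows)}",
            "is_cell": "True" if is_cell else "False",
            "high_confidence": "True" if high_conf else "False",
            "chain": chain or tpl["chain"],
            "v_gene": tpl["v_gene"], "d_gene": tpl["d_gene"],
            "j_gene": tpl["j_gene"], "c_gene": tpl["c_gene"],
            "cdr3_aa": tpl["cdr3_aa"], "cdr3_nt": tpl["cdr3_nt"],
            "productive": productive,
            "umis": umis, "reads": umis * int(rng.integers(10, 50)),
        })

    for clone in clones:
        for i in clone["members"]:
            for tpl in clone["templates"]:
                emit(barcodes[i], tpl)

    # --- single-chain barcodes (discarded by the cell grouping)
    n_single_chain = int(round(cfg.single_chain_fraction * cfg.n_cells))
    sc_barcodes = [f"{cfg.sample_id}_SC{i:06d}-1" for i in range(n_single_chain)]
    for bc in sc_barcodes:
        chain = ("IGH", "IGK", "IGL")[rng.integers(3)]
        emit(bc, _chain_template(rng, chain, cfg, dual=False))

    n_functional = len(rows)

    # --- contaminant contigs, one family per failing filter rule
    rates = cfg.contamination
    for _ in range(int(round(rates.get("non_cell", 0) * n_functional))):
        bc = f"{cfg.sample_id}_NC{rng.integers(10**6):06d}-1"
        tpl = _chain_template(rng, ("IGH", "IGK", "IGL")[rng.integers(3)],
                              cfg, dual=False)
        emit(bc, tpl, is_cell=False)
    for _ in range(int(round(rates.get("low_confidence", 0) * n_functional))):
        bc = barcodes[rng.integers(cfg.n_cells)]
        tpl = _chain_template(rng, ("IGH", "IGK", "IGL")[rng.integers(3)],
                              cfg, dual=False)
        emit(bc, tpl, high_conf=False)
    for _ in range(int(round(rates.get("non_productive", 0) * n_functional))):
        bc = barcodes[rng.integers(cfg.n_cells)]
        tpl = _chain_template(rng, ("IGH", "IGK", "IGL")[rng.integers(3)],
                              cfg, dual=False)
        emit(bc, tpl, productive=("Non" if rng.random() < 0.5 else "False"))
    for _ in range(int(round(rates.get("bad_chain", 0) * n_functional))):
        bc = barcodes[rng.integers(cfg.n_cells)]
        tpl = _chain_template(rng, "IGH", cfg, dual=False)
        emit(bc, tpl, chain="Multi")

    df = pd.DataFrame(rows)
    for col in ("umis", "reads"):
        df[col] = df[col].astype(np.int64)
    from .io_formats import read_contig_table  # reuse the normalizer
    import io as _io
    buf = _io.StringIO()
    df.rename(columns={"cdr3_aa": "cdr3"}).to_csv(buf, index=False)
    buf.seek(0)
    table = read_contig_table(buf, dialect="tenx_csv", sample_id=cfg.sample_id)

    # --- ground truth
    subset_names = list(cfg.subset_mix)
    subset_probs = list(cfg.subset_mix.values())
    subsets = [subset_names[k] for k in
               rng.choice(len(subset_names), size=cfg.n_cells, p=subset_probs)]
    cells = pd.DataFrame({
        "barcode": barcodes,
        "fine_code": cell_code,
        "bcr_class": cell_class,
        "clone_id": cell_clone,
        "subset": subsets,
        "group": cfg.group,
        "sample_id": cfg.sample_id,
    })
    sc_frame = pd.DataFrame({
        "barcode": sc_barcodes,
        "fine_code": "",
        "bcr_class": "dropped_single_chain",
        "clone_id": "",
        "subset": [subset_names[k] for k in
                   rng.choice(len(subset_names), size=n_single_chain,
                              p=subset_probs)],
        "group": cfg.group,
        "sample_id": cfg.sample_id,
    })
    cells = pd.concat([cells, sc_frame], ignore_index=True)

    truth = GroundTruth(cells=cells,
                        gene_truth=pd.DataFrame(
                            columns=["gene", "role", "subset", "is_de",
                                     "is_mito"]),
                        realized={})
    pairable_sizes = [len(c["members"]) for c in clones
                      if c["class"] in ("single", "dual")]
    truth.realized = dict(truth.recompute_realized())
    truth.realized["clone_sizes"] = pairable_sizes
    truth.realized["n_pairable"] = int(single.sum() + dual.sum())
    return table, truth


def _gene_panel(cfg: SimConfig) -> pd.DataFrame:
    """The shared gene panel of a study (drawn from ``panel_seed``)."""
    rng = np.random.default_rng(cfg.panel_seed)
    from .transcriptome_link import markers_for_species, MITO_PREFIX
    markers = markers_for_species(cfg.species)
    rows = []
    seen = set()
    for subset, genes in markers.items():
        for g in genes:
            if g in seen:
                continue
            seen.add(g)
            rows.append({"gene": g, "role": "marker",
                         "subset": "all" if g.upper() == "CD19" else subset,
                         "is_de": False, "is_mito": False,
                         "base_mean": cfg.marker_background})
    mito_names = ["Nd1", "Nd2", "Co1", "Co2", "Co3", "Atp6", "Atp8",
                  "Cytb", "Nd4", "Nd5"]
    prefix = MITO_PREFIX[cfg.species]
    for name in mito_names[:cfg.n_mito_genes]:
        g = prefix + (name.upper() if cfg.species == "human" else name)
        rows.append({"gene": g, "role": "mito", "subset": "",
                     "is_de": False, "is_mito": True, "base_mean": 0.0})
    for i in range(cfg.de_n_genes):
        g = f"Desim{i + 1:02d}" if cfg.species == "mouse" else f"DESIM{i + 1:02d}"
        rows.append({"gene": g, "role": "de", "subset": "",
                     "is_de": True, "is_mito": False,
                     "base_mean": float(np.clip(rng.lognormal(np.log(2.0), 0.4),
                                                0.5, 10.0))})
    for i in range(cfg.n_background_genes):
        g = f"Gene{i + 1:04d}"
        rows.append({"gene": g, "role": "background", "subset": "",
                     "is_de": False, "is_mito": False,
                     "base_mean": float(np.clip(rng.lognormal(np.log(2.0), 0.7),
                                                0.1, 30.0))})
    return pd.DataFrame(rows)


def simulate_expression(truth: GroundTruth, config: SimConfig) -> ad.AnnData:
    """Generate the raw count matrix matching ``truth``'s cells.

    Counts are negative-binomial (dispersion 2) around per-gene means
    from the shared study panel; subset markers are up-shifted in their
    subset, Cd19 in every cell, planted differential genes multiplied
    by the effect size in the disease group, and mitochondrial genes
    drawn to a controlled fraction of each cell's counts (the first
    ``n_high_mito_cells`` cells are forced above, all others below, the
    5% QC boundary).  Also fills ``truth.gene_truth``.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed + 1_000_003)
    panel = _gene_panel(cfg)
    cells = truth.cells
    n_cells, n_genes = len(cells), len(panel)

    means = np.tile(panel["base_mean"].to_numpy(), (n_cells, 1))
    subset_arr = cells["subset"].to_numpy()
    group_arr = cells["group"].to_numpy()

    for j, row in panel.iterrows():
        if row["role"] == "marker":
            if row["subset"] == "all":
                means[:, j] = cfg.cd19_mean
            else:
                means[subset_arr == row["subset"], j] = cfg.marker_mean
        elif row["role"] == "de":
            means[group_arr == cfg.de_group, j] *= cfg.de_effect

    # markers are tighter than background genes: cell-type-defining genes
    # are consistently detected, which is what makes them markers
    disp = np.where(panel["role"].to_numpy() == "marker", 10.0, 2.0)
    nonmito = ~panel["is_mito"].to_numpy()
    counts = np.zeros((n_cells, n_genes), dtype=np.int64)
    mu = means[:, nonmito]
    r = np.broadcast_to(disp[nonmito], mu.shape)
    counts[:, nonmito] = rng.negative_binomial(r, r / (r + mu))

    # mitochondrial genes: Poisson around a per-cell target fraction,
    # then adjusted so the 5% QC boundary is crossed exactly where planted
    mito_idx = np.flatnonzero(panel["is_mito"].to_numpy())
    if len(mito_idx):
        nonmito_tot = counts.sum(axis=1)
        target = np.full(n_cells, cfg.mito_target)
        target[:cfg.n_high_mito_cells] = cfg.high_mito_fraction
        lam = target / (1 - target) * nonmito_tot / len(mito_idx)
        counts[:, mito_idx] = rng.poisson(lam[:, None],
                                          size=(n_cells, len(mito_idx)))
        mito_tot = counts[:, mito_idx].sum(axis=1)
        total = counts.sum(axis=1)
        high = np.zeros(n_cells, dtype=bool)
        high[:cfg.n_high_mito_cells] = True
        # force planted cells over, everyone else under, the boundary
        need_up = high & (20 * mito_tot <= total)
        bump = (total[need_up] - 19 * mito_tot[need_up]) // 19 + 1
        counts[need_up, mito_idx[0]] += bump.astype(np.int64)
        need_down = ~high & (20 * mito_tot > total)
        for i in np.flatnonzero(need_down):
            excess = mito_tot[i] - (total[i] - mito_tot[i]) // 20
            for j in mito_idx:
                take = min(excess, counts[i, j])
                counts[i, j] -= take
                excess -= take
                if excess <= 0:
                    break

    truth.gene_truth = panel[["gene", "role", "subset", "is_de",
                              "is_mito"]].copy()
    import scipy.sparse as sp
    adata = ad.AnnData(
        X=sp.csr_matrix(counts),
        obs=pd.DataFrame({"subset_true": subset_arr, "group": group_arr},
                         index=pd.Index(cells["barcode"], name="barcode")),
        var=pd.DataFrame(index=pd.Index(panel["gene"], name="gene")))
    return adata


def write_simulation(out_dir: str | Path, table: ContigTable,
                     truth: GroundTruth, adata: ad.AnnData | None,
                     config: SimConfig) -> None:
    """Write a simulated sample to disk (10x contig CSV + MTX triplet)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_contig_table(table, out / "contigs.csv", dialect="tenx_csv")
    truth.cells.to_csv(out / "truth.tsv", sep="\t", index=False)
    if not truth.gene_truth.empty:
        truth.gene_truth.to_csv(out / "gene_truth.tsv", sep="\t", index=False)
    if adata is not None:
        write_expression_matrix(adata, out)
    with open(out / "config_used.yaml", "w") as fh:
        yaml.safe_dump(config.as_dict(), fh, sort_keys=False)
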