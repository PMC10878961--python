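"""Generators for bulk compendia and 4-condition single-cell stress experiments.

The bulk generator emulates a multi-batch compendium of young and aged
samples in which an immediate-early-response (IER) gene set is induced only
in a designated "stressed" batch while a disjoint aging set tracks the age
labels: log-normal intensities with multiplicative effects and measurement
noise.  The single-cell generator emulates a hashing experiment with four
conditions (cells kept on ice or incubated at 37 C for 90 min, each with or
without the transcription inhibitor triptolide, TP): negative-binomial
counts with per-cell size factors, per-gene log-normal stress folds on the
IER genes at 37 C (suppressed by TP), TP side-effects (feature downsampling,
elevated mitochondrial fraction, and TP-specific induced genes), cell-cycle
structure via S/G2M marker boosts with less cycling at 37 C, hashtag-oligo
(HTO) counts concentrated on the true hashtag, doublets as summed cell
pairs, and gene lengths drawn shorter for IER genes.

Every generator is a pure function of (config, seed) and returns a
:class:`SimTruth` of planted effects for recovery testing.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core_io import (
    ExpressionMatrix, GeneAnnotationTable, GeneSet, write_gene_lengths,
    write_gmt, write_matrix_tsv, write_mtx,
)

CONDITIONS = ("ice", "ice_tp", "temp37", "temp37_tp")
HTO_OF_CONDITION = {c: f"hto{k + 1}" for k, c in enumerate(CONDITIONS)}


@dataclass
class BulkSimConfig:
    """Bulk compendium design: three batches of young/aged samples, with the
    IER set induced in the stressed batch and an aging set tracking age."""

    n_genes: int = 2000
    n_samples: int = 12
    n_batches: int = 3
    batch_assignment: list | None = None   # per-sample batch labels
    age_assignment: list | None = None     # per-sample young/aged labels
    stressed_batch: str = "batch1"
    ier_gene_count: int = 78
    aging_gene_count: int = 100
    ier_fold: float = 2.0
    aging_fold: float = 1.5
    base_log_mean: float = 4.0
    base_log_sd: float = 1.0
    noise_log_sd: float = 0.25
    seed: int = 123


@dataclass
class ScSimConfig:
    """Four-condition single-cell hashing experiment with planted effects."""

    n_cells: dict = field(default_factory=lambda: {c: 400 for c in CONDITIONS})
    n_genes: int = 2000
    ier_gene_count: int = 50
    stress_fold_median: float = 4.0
    stress_fold_log_sd: float = 0.4
    tp_blocks_induction: bool = True
    tp_induced_count: int = 50
    tp_induced_fold: float = 3.0
    tp_feature_loss: float = 0.25
    tp_mito_shift: float = 0.01
    cycling_fraction: dict = field(default_factory=lambda: {
        "ice": 0.40, "ice_tp": 0.40, "temp37": 0.15, "temp37_tp": 0.15,
    })
    n_cycle_genes_s: int = 50
    n_cycle_genes_g2m: int = 50
    cycle_fold: float = 10.0
    marker_gamma_shape: float = 2.0
    marker_gamma_scale: float = 2.5
    n_mito_genes: int = 13
    mito_base_fraction: float = 0.02
    hto_total_median: float = 150.0
    hto_total_log_sd: float = 0.3
    hto_noise: float = 0.02
    doublet_rate: float = 0.05
    length_ier_median: float = 2000.0
    length_background_median: float = 20000.0
    length_log_sd: float = 0.6
    mean_gamma_shape: float = 0.6
    mean_gamma_scale: float = 5.0
    nb_theta: float = 2.0
    cell_size_log_sd: float = 0.3
    seed: int = 123


@dataclass
class SimTruth:
    """Ground-truth labels emitted by the simulators for recovery tests."""

    ier_genes: frozenset = frozenset()
    aging_genes: frozenset = frozenset()
    tp_induced_genes: frozenset = frozenset()
    cycle_genes_s: frozenset = frozenset()
    cycle_genes_g2m: frozenset = frozenset()
    cell_condition: dict = field(default_factory=dict)
    cell_phase: dict = field(default_factory=dict)
    cell_sample_of_origin: dict = field(default_factory=dict)
    is_doublet: dict = field(default_factory=dict)
    gene_lengths: dict = field(default_factory=dict)

    def planted_sets(self) -> list:
        out = []
        for name, genes in (
            ("IERsig", self.ier_genes), ("aging", self.aging_genes),
            ("tp_induced", self.tp_induced_genes),
            ("cycle_S", self.cycle_genes_s), ("cycle_G2M", self.cycle_genes_g2m),
        ):
            if genes:
                out.append(GeneSet(name, frozenset(genes)))
        return out


# ---------------------------------------------------------------------------
# bulk
# ---------------------------------------------------------------------------


def _bulk_design(cfg: BulkSimConfig):
    if cfg.batch_assignment is not None:
        batches = [str(b) for b in cfg.batch_assignment]
    else:
        per = cfg.n_samples // cfg.n_batches
        batches = []
        for b in range(cfg.n_batches):
            n = per + (1 if b < cfg.n_samples - per * cfg.n_batches else 0)
            batches.extend([f"batch{b + 1}"] * n)
    if cfg.age_assignment is not None:
        ages = [str(a) for a in cfg.age_assignment]
    else:
        ages = ["young" if i % 2 == 0 else "aged" for i in range(cfg.n_samples)]
    if len(batches) != cfg.n_samples or len(ages) != cfg.n_samples:
        raise ValueError("batch/age assignment lengths do not match n_samples")
    return batches, ages


def simulate_bulk(cfg: BulkSimConfig):
    """Log-normal bulk compendium with planted IER and aging effects.

    Returns ``(ExpressionMatrix, SimTruth)``; deterministic under the config
    seed.  The matrix layer is ``normalized`` (intensity-scale values).
    """
    if cfg.ier_gene_count + cfg.aging_gene_count > cfg.n_genes:
        raise ValueError("effect gene counts exceed n_genes")
    if cfg.ier_fold < 1 or cfg.aging_fold < 1:
        raise ValueError("folds must be >= 1")
    rng = np.random.default_rng(cfg.seed)
    batches, ages = _bulk_design(cfg)
    gene_ids = [f"g{i:05d}" for i in range(cfg.n_genes)]
    sample_ids = [f"s{j:02d}" for j in range(cfg.n_samples)]

    perm = rng.permutation(cfg.n_genes)
    ier_idx = perm[:cfg.ier_gene_count]
    aging_idx = perm[cfg.ier_gene_count:cfg.ier_gene_count + cfg.aging_gene_count]

    base = rng.normal(cfg.base_log_mean, cfg.base_log_sd, size=cfg.n_genes)
    stressed = np.array([b == cfg.stressed_batch for b in batches])
    aged = np.array([a == "aged" for a in ages])

    log_expr = np.tile(base[:, None], (1, cfg.n_samples))
    log_expr[np.ix_(ier_idx, np.flatnonzero(stressed))] += np.log(cfg.ier_fold)
    log_expr[np.ix_(aging_idx, np.flatnonzero(aged))] += np.log(cfg.aging_fold)
    log_expr += rng.normal(0, cfg.noise_log_sd,
                           size=(cfg.n_genes, cfg.n_samples))

    meta = pd.DataFrame({"batch": batches, "age_group": ages},
                        index=pd.Index(sample_ids))
    m = ExpressionMatrix(gene_ids, sample_ids, np.exp(log_expr),
                         "normalized", meta)
    truth = SimTruth(
        ier_genes=frozenset(gene_ids[i] for i in ier_idx),
        aging_genes=frozenset(gene_ids[i] for i in aging_idx),
    )
    return m, truth


# ---------------------------------------------------------------------------
# single cell
# ---------------------------------------------------------------------------


def _nb_counts(rng: np.random.Generator, mu: np.ndarray, theta: float):
    """Negative-binomial counts via the gamma-Poisson mixture."""
    lam = rng.gamma(theta, mu / theta)
    return rng.poisson(lam)


def simulate_sc(cfg: ScSimConfig):
    """Four-condition single-cell experiment with HTO labels and ground truth.

    Returns ``(counts ExpressionMatrix, hto ExpressionMatrix, SimTruth)``.
    Doublets are appended as extra barcodes formed by summing two random
    singlets' gene and HTO counts.
    """
    rng = np.random.default_rng(cfg.seed)
    role_counts = (cfg.n_mito_genes + cfg.ier_gene_count + cfg.tp_induced_count
                   + cfg.n_cycle_genes_s + cfg.n_cycle_genes_g2m)
    if role_counts > cfg.n_genes:
        raise ValueError("role gene counts exceed n_genes")
    for cond, n in cfg.n_cells.items():
        if n == 0:
            warnings.warn(f"condition {cond!r} has 0 cells")

    # --- gene roles: mito genes first (prefix-identifiable), the rest random
    n_reg = cfg.n_genes - cfg.n_mito_genes
    gene_ids = [f"mt-{i + 1}" for i in range(cfg.n_mito_genes)] + \
               [f"g{i:05d}" for i in range(n_reg)]
    regular = np.arange(cfg.n_mito_genes, cfg.n_genes)
    perm = rng.permutation(regular)
    k = 0
    ier_idx = perm[k:k + cfg.ier_gene_count]; k += cfg.ier_gene_count
    tp_idx = perm[k:k + cfg.tp_induced_count]; k += cfg.tp_induced_count
    s_idx = perm[k:k + cfg.n_cycle_genes_s]; k += cfg.n_cycle_genes_s
    g2m_idx = perm[k:k + cfg.n_cycle_genes_g2m]

    # --- baseline means; mito genes rescaled to the target baseline fraction
    base = rng.gamma(cfg.mean_gamma_shape, cfg.mean_gamma_scale,
                     size=cfg.n_genes)
    base = np.maximum(base, 1e-3)
    # cycle markers are detectable genes by construction: an undetectable gene
    # could never serve as a phase marker, so their baselines come from a
    # moderately-expressed distribution
    marker_idx = np.concatenate([s_idx, g2m_idx])
    base[marker_idx] = rng.gamma(cfg.marker_gamma_shape, cfg.marker_gamma_scale,
                                 size=marker_idx.size)
    mito = np.arange(cfg.n_mito_genes)
    non_mito_total = base[cfg.n_mito_genes:].sum()
    f = cfg.mito_base_fraction
    base[mito] = f / (1 - f) * non_mito_total / max(cfg.n_mito_genes, 1)

    # --- cells
    conditions, phases = [], []
    for cond in CONDITIONS:
        n = cfg.n_cells.get(cond, 0)
        conditions.extend([cond] * n)
        cyc = rng.random(n) < cfg.cycling_fraction.get(cond, 0.0)
        for c in cyc:
            phases.append("G1" if not c else ("S" if rng.random() < 0.5 else "G2M"))
    n_singlet = len(conditions)
    cell_ids = [f"cell{j:05d}" for j in range(n_singlet)]
    sf = np.exp(rng.normal(0, cfg.cell_size_log_sd, size=n_singlet))

    stress_fold = np.exp(rng.normal(np.log(cfg.stress_fold_median),
                                    cfg.stress_fold_log_sd,
                                    size=cfg.ier_gene_count))

    mu = base[:, None] * sf[None, :]
    cond_arr = np.array(conditions)
    phase_arr = np.array(phases)
    stressed_cells = cond_arr == "temp37"
    if not cfg.tp_blocks_induction:
        stressed_cells = stressed_cells | (cond_arr == "temp37_tp")
    mu[np.ix_(ier_idx, np.flatnonzero(stressed_cells))] *= stress_fold[:, None]
    mu[np.ix_(tp_idx, np.flatnonzero(cond_arr == "temp37_tp"))] *= cfg.tp_induced_fold
    mu[np.ix_(s_idx, np.flatnonzero(phase_arr == "S"))] *= cfg.cycle_fold
    mu[np.ix_(g2m_idx, np.flatnonzero(phase_arr == "G2M"))] *= cfg.cycle_fold
    if cfg.tp_mito_shift > 0:
        shift = (cfg.mito_base_fraction + cfg.tp_mito_shift) / cfg.mito_base_fraction
        mu[np.ix_(mito, np.flatnonzero(cond_arr == "temp37_tp"))] *= shift

    counts = _nb_counts(rng, mu, cfg.nb_theta).astype(float)
    if cfg.tp_feature_loss > 0:  # TP at 37 C degrades libraries: thin counts
        cols = np.flatnonzero(cond_arr == "temp37_tp")
        counts[:, cols] = rng.binomial(counts[:, cols].astype(int),
                                       1 - cfg.tp_feature_loss)

    # --- HTO counts concentrated on the true hashtag
    hto_ids = [HTO_OF_CONDITION[c] for c in CONDITIONS]
    totals = np.exp(rng.normal(np.log(cfg.hto_total_median),
                               cfg.hto_total_log_sd, size=n_singlet))
    totals = np.maximum(totals, 30).astype(int)
    hto_counts = np.zeros((len(hto_ids), n_singlet))
    for j in range(n_singlet):
        true_k = CONDITIONS.index(conditions[j])
        p = np.full(len(hto_ids), cfg.hto_noise / max(len(hto_ids) - 1, 1))
        p[true_k] = 1 - cfg.hto_noise
        hto_counts[:, j] = rng.multinomial(totals[j], p)

    # --- doublets: summed random cell pairs with both hashtags
    truth_cond = dict(zip(cell_ids, conditions))
    truth_phase = dict(zip(cell_ids, phases))
    truth_origin = {c: HTO_OF_CONDITION[cond]
                    for c, cond in zip(cell_ids, conditions)}
    is_doublet = {c: False for c in cell_ids}
    n_doub = int(round(cfg.doublet_rate * n_singlet))
    if n_doub > 0:
        pairs = [rng.choice(n_singlet, size=2, replace=False)
                 for _ in range(n_doub)]
        doub_counts = np.stack([counts[:, p[0]] + counts[:, p[1]]
                                for p in pairs], axis=1)
        doub_hto = np.stack([hto_counts[:, p[0]] + hto_counts[:, p[1]]
                             for p in pairs], axis=1)
        doub_ids = [f"doublet{i:04d}" for i in range(n_doub)]
        counts = np.concatenate([counts, doub_counts], axis=1)
        hto_counts = np.concatenate([hto_counts, doub_hto], axis=1)
        for i, (p, cid) in enumerate(zip(pairs, doub_ids)):
            truth_cond[cid] = "doublet"
            truth_phase[cid] = "doublet"
            truth_origin[cid] = "+".join(sorted(
                {HTO_OF_CONDITION[conditions[p[0]]],
                 HTO_OF_CONDITION[conditions[p[1]]]}
            ))
            is_doublet[cid] = True
        cell_ids = cell_ids + doub_ids

    # --- gene lengths: IER genes drawn short, everything else background
    lengths = np.exp(rng.normal(np.log(cfg.length_background_median),
                                cfg.length_log_sd, size=cfg.n_genes))
    lengths[ier_idx] = np.exp(rng.normal(np.log(cfg.length_ier_median),
                                         cfg.length_log_sd,
                                         size=cfg.ier_gene_count))
    lengths = np.maximum(np.round(lengths), 1).astype(int)

    meta = pd.DataFrame(
        {"condition": [truth_cond[c] for c in cell_ids]},
        index=pd.Index(cell_ids),
    )
    counts_m = ExpressionMatrix(gene_ids, cell_ids, counts, "counts", meta)
    hto_m = ExpressionMatrix(hto_ids, cell_ids, hto_counts, "counts")
    truth = SimTruth(
        ier_genes=frozenset(gene_ids[i] for i in ier_idx),
        tp_induced_genes=frozenset(gene_ids[i] for i in tp_idx),
        cycle_genes_s=frozenset(gene_ids[i] for i in s_idx),
        cycle_genes_g2m=frozenset(gene_ids[i] for i in g2m_idx),
        cell_condition=truth_cond, cell_phase=truth_phase,
        cell_sample_of_origin=truth_origin, is_doublet=is_doublet,
        gene_lengths=dict(zip(gene_ids, map(int, lengths))),
    )
    return counts_m, hto_m, truth


# ---------------------------------------------------------------------------
# fixture bundles
# ---------------------------------------------------------------------------


def _truth_manifest(truth: SimTruth) -> dict:
    return {
        "planted_sets": {s.name: sorted(s.genes) for s in truth.planted_sets()},
        "cell_condition": truth.cell_condition,
        "cell_phase": truth.cell_phase,
        "cell_sample_of_origin": truth.cell_sample_of_origin,
        "is_doublet": truth.is_doublet,
    }


def write_fixture_bundle(out_dir, cfg, seed: int | None = None,
                         force: bool = False) -> dict:
    """Simulate under ``cfg`` and write a plain-text fixture bundle.

    Bulk configs emit a dense TSV matrix + sample metadata; single-cell
    configs emit MTX/TSV counts, an HTO MTX, and a gene-length table.  Both
    include a GMT of every planted gene set, a truth manifest (JSON) and the
    config (YAML).  Refuses to write into a non-empty directory unless
    ``force`` is set.  Returns the map of written file paths.
    """
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()) and not force:
        raise FileExistsError(f"{out_dir} is not empty (pass force=True)")
    out_dir.mkdir(parents=True, exist_ok=True)
    if seed is not None:
        cfg = dataclasses.replace(cfg, seed=seed)
    files = {}
    if isinstance(cfg, BulkSimConfig):
        m, truth = simulate_bulk(cfg)
        write_matrix_tsv(m, out_dir / "bulk_matrix.tsv")
        m.sample_meta.to_csv(out_dir / "sample_meta.tsv", sep="\t",
                             index_label="sample_id")
        files["matrix"] = out_dir / "bulk_matrix.tsv"
        files["sample_meta"] = out_dir / "sample_meta.tsv"
    elif isinstance(cfg, ScSimConfig):
        counts, hto, truth = simulate_sc(cfg)
        write_mtx(counts, out_dir / "counts")
        write_mtx(hto, out_dir / "hto")
        write_gene_lengths(GeneAnnotationTable(truth.gene_lengths),
                           out_dir / "gene_lengths.tsv")
        files["counts"] = out_dir / "counts"
        files["hto"] = out_dir / "hto"
        files["gene_lengths"] = out_dir / "gene_lengths.tsv"
    else:
        raise TypeError(f"unsupported config type {type(cfg).__name__}")
    planted = truth.planted_sets()
    if planted:
        write_gmt(planted, out_dir / "planted_sets.gmt")
        files["planted_sets"] = out_dir / "planted_sets.gmt"
    with open(out_dir / "truth.json", "w") as fh:
        json.dump(_truth_manifest(truth), fh, indent=1)
    with open(out_dir / "config.yaml", "w") as fh:
        yaml.safe_dump(dataclasses.asdict(cfg), fh)
    files["truth"] = out_dir / "truth.json"
    files["config"] = out_dir / "config.yaml"
    return files


def load_config(path):
    """Load a Bulk or Sc simulation config from YAML (kind auto-detected)."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    kind = data.pop("kind", None)
    if kind == "bulk" or (kind is None and "n_samples" in data):
        return BulkSimConfig(**data)
    return ScSimConfig(**data)
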