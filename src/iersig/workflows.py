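"""End-to-end pipeline drivers composing the module-level operations.

These are the computations the numbered analysis scripts, the test suite and
the reproduction script all share: the bulk signature-variability audit and
the four-condition single-cell stress experiment from raw simulated counts to
the DEG intersection and gene-length comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core_io import ExpressionMatrix, GeneAnnotationTable, GeneSet, log_normalize_cp10k
from .scoring import (
    bootstrap_cv_percentile, cell_cycle_phase, module_score, signature_fraction,
)
from .sc_pipeline import (
    QCThresholds, combine_and_intersect, compute_cell_qc, gene_length_comparison,
    hto_demultiplex, phase_stratified_de, qc_filter, select_hvg,
)
from .synthetic_data import HTO_OF_CONDITION, ScSimConfig, simulate_sc

# QC bounds rescaled to simulation-scale libraries (a 2,000-gene simulated
# transcriptome cannot reach the >=2,000 detected genes of a full one); the
# published thresholds stay the defaults of QCThresholds itself
SIM_QC = QCThresholds(max_mito=0.08, min_features=300, max_features=2000,
                      min_counts=1000, max_counts=60000, min_hto=20, max_hto=400)

_CONDITION_OF_HTO = {v: k for k, v in HTO_OF_CONDITION.items()}


@dataclass
class ScStressResult:
    """Everything the single-cell stress analysis produces."""

    kept_cells: list
    qc_tally: dict
    assignments: dict            # cell -> hashtag / doublet / negative
    condition: dict              # kept singlet cell -> condition
    phases: dict                 # kept singlet cell -> called phase
    cycling_estimated: dict      # condition -> estimated cycling fraction
    cycling_true: dict           # condition -> planted cycling fraction (same cells)
    hvg: list
    intersection: object
    length_comparison: object
    deg_37: list = field(repr=False, default_factory=list)
    deg_37tp: list = field(repr=False, default_factory=list)


def run_bulk_audit(m: ExpressionMatrix, S: GeneSet, B: int = 10_000,
                   seed: int = 123):
    """Signature fractions plus the bootstrap CV centile for one signature."""
    frac = signature_fraction(m, S)
    boot = bootstrap_cv_percentile(m, S, B=B, seed=seed)
    return frac, boot


def run_sc_stress_pipeline(cfg: ScSimConfig, thresholds: QCThresholds = SIM_QC,
                           q_threshold: float = 0.05,
                           score_seed: int = 0) -> ScStressResult:
    """Simulate the 4-condition experiment and run every downstream stage.

    QC filtering and HTO demultiplexing select singlet cells per condition;
    cell-cycle phases are called from module scores of the planted S/G2M
    marker sets; the 37 C and 37 C+TP contrasts against the pooled ice
    reference are tested phase-wise on highly variable genes and intersected;
    and the gene lengths of the two "up" response groups are compared against
    the IER-signature background.
    """
    counts, hto, truth = simulate_sc(cfg)
    cells = compute_cell_qc(counts, hto)
    kept, tally = qc_filter(cells, thresholds)
    assignments = hto_demultiplex(hto)
    singlets = [c for c in kept if assignments[c] in _CONDITION_OF_HTO]
    condition = {c: _CONDITION_OF_HTO[assignments[c]] for c in singlets}

    sub = counts.subset_samples(singlets)
    logm = log_normalize_cp10k(sub)
    s_scores = module_score(logm, GeneSet("cycle_S", truth.cycle_genes_s),
                            seed=score_seed)
    g2m_scores = module_score(logm, GeneSet("cycle_G2M", truth.cycle_genes_g2m),
                              seed=score_seed + 1)
    phase_calls = cell_cycle_phase(s_scores.scores, g2m_scores.scores)

    cycling_est, cycling_true = {}, {}
    for cond in cfg.n_cells:
        cc = [c for c in singlets if condition[c] == cond]
        if not cc:
            continue
        cycling_est[cond] = float(np.mean([phase_calls[c] != "G1" for c in cc]))
        cycling_true[cond] = float(np.mean(
            [truth.cell_phase[c] != "G1" for c in cc]
        ))

    hvg = select_hvg(sub, n_top=min(2000, sub.n_genes))
    ice_ref = [c for c in singlets if condition[c] in ("ice", "ice_tp")]
    g37 = [c for c in singlets if condition[c] == "temp37"]
    g37tp = [c for c in singlets if condition[c] == "temp37_tp"]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        deg_37 = phase_stratified_de(logm, g37, ice_ref, phase_calls.phases,
                                     hvg, contrast="37_vs_ice")
        deg_37tp = phase_stratified_de(logm, g37tp, ice_ref, phase_calls.phases,
                                       hvg, contrast="37tp_vs_ice")
        inter = combine_and_intersect(deg_37, deg_37tp, q_threshold=q_threshold)

    length_cmp = None
    ann = GeneAnnotationTable(truth.gene_lengths)
    if len(inter.up_37_only) >= 2 and len(inter.up_37tp_only) >= 2:
        length_cmp = gene_length_comparison(
            sorted(inter.up_37_only), sorted(inter.up_37tp_only), ann,
            background=GeneSet("IERsig", truth.ier_genes),
        )

    return ScStressResult(
        kept_cells=kept, qc_tally=tally, assignments=assignments,
        condition=condition, phases=dict(phase_calls.phases),
        cycling_estimated=cycling_est, cycling_true=cycling_true,
        hvg=hvg, intersection=inter, length_comparison=length_cmp,
        deg_37=deg_37, deg_37tp=deg_37tp,
    ), truth
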