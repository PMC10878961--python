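"""Signature statistics: per-sample fractions, the bootstrap CV null, module scores.

The variability audit works as follows.  For a signature S (the 78-gene
immediate-early-response set in the reference configuration, inside a
19,570-gene array universe) the *signature fraction* of a sample is the sum
of expression over S divided by the sample's total expression.  Its
coefficient of variation (CV) across samples is then ranked against a null
distribution built by drawing B random same-size gene sets (defaults
B = 10,000, seed = 123) and recomputing the fraction CV for each; the
tie-aware centile of the signature CV within that null is the audit
statistic.  A signature whose centile sits near 100 varies across samples far
more than random gene sets of its size — the behaviour expected of a
stress-induction artifact rather than a stable biological program.

Per-cell *module scores* follow the expression-bin control convention: genes
are binned by mean expression, each signature gene contributes control genes
drawn from its bin, and the score is the mean over signature genes minus the
mean over pooled controls.  Cell-cycle phases are called from S and G2M
module scores (both negative -> G1, otherwise the larger score wins).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core_io import ExpressionMatrix, GeneSet, MatrixError


@dataclass
class FractionResult:
    """Per-sample signature fraction in [0, 1]."""

    fractions: dict

    def __getitem__(self, sample: str) -> float:
        return self.fractions[sample]

    def values(self) -> np.ndarray:
        return np.array(list(self.fractions.values()))


@dataclass
class BootstrapNullResult:
    signature_cv: float
    null_cvs: np.ndarray
    percentile: float
    B: int
    seed: int
    set_size: int


@dataclass
class ModuleScoreResult:
    scores: dict
    control_pool: list
    nbins: int
    nctrl: int
    seed: int

    def values(self) -> np.ndarray:
        return np.array(list(self.scores.values()))


@dataclass
class PhaseAssignment:
    phases: dict
    s_scores: dict
    g2m_scores: dict

    def __getitem__(self, cell: str) -> str:
        return self.phases[cell]


# ---------------------------------------------------------------------------
# fractions and the bootstrap CV null
# ---------------------------------------------------------------------------


def signature_fraction(m: ExpressionMatrix, S: GeneSet) -> FractionResult:
    """Per-sample fraction of total expression carried by the signature genes."""
    m.require_layer("counts", "normalized", "log_normalized")
    idx = m.gene_index()
    rows = [idx[g] for g in S.genes if g in idx]
    if not rows:
        raise MatrixError(f"signature {S.name!r} shares no genes with the matrix")
    totals = m.values.sum(axis=0)
    zero = [s for s, t in zip(m.sample_ids, totals) if t == 0]
    if zero:
        raise MatrixError(f"samples with zero total expression: {zero[:10]}")
    frac = m.values[rows].sum(axis=0) / totals
    return FractionResult(dict(zip(m.sample_ids, map(float, frac))))


def coefficient_of_variation(values) -> float:
    """Sample standard deviation (n-1 denominator) divided by the mean."""
    v = np.asarray(list(values), dtype=float)
    if v.size < 2:
        raise ValueError("CV needs at least 2 values")
    mean = v.mean()
    if mean == 0:
        raise ValueError("CV undefined for zero mean")
    return float(v.std(ddof=1) / mean)


def _percentile_rank(value: float, nulls: np.ndarray) -> float:
    """Tie-aware centile: below counts 1, ties count 1/2, scaled to [0, 100]."""
    below = int((nulls < value).sum())
    ties = int((nulls == value).sum())
    return 100.0 * (below + 0.5 * ties) / nulls.size


def bootstrap_cv_percentile(m: ExpressionMatrix, S: GeneSet, B: int = 10_000,
                            seed: int = 123,
                            _chunk: int = 2_000) -> BootstrapNullResult:
    """Centile of the signature-fraction CV against random same-size gene sets.

    Each of the B iterations draws ``|S|`` genes uniformly without replacement
    from the matrix genes (independently across iterations) and computes that
    set's fraction CV across samples.  Deterministic for a fixed seed.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    idx = m.gene_index()
    usable = sorted(g for g in S.genes if g in idx)
    k = len(usable)
    if k == 0:
        raise MatrixError(f"signature {S.name!r} shares no genes with the matrix")
    if k >= m.n_genes:
        raise ValueError("signature size must be smaller than the gene count")
    sig_cv = coefficient_of_variation(
        signature_fraction(m, S).values()
    )
    totals = m.values.sum(axis=0)
    if (totals == 0).any():
        raise MatrixError("samples with zero total expression")
    rng = np.random.default_rng(seed)
    null_cvs = np.empty(B)
    done = 0
    while done < B:
        n = min(_chunk, B - done)
        draws = np.stack([
            rng.choice(m.n_genes, size=k, replace=False) for _ in range(n)
        ])
        fracs = m.values[draws].sum(axis=1) / totals  # (n, n_samples)
        means = fracs.mean(axis=1)
        sds = fracs.std(axis=1, ddof=1)
        null_cvs[done:done + n] = sds / means
        done += n
    return BootstrapNullResult(
        signature_cv=float(sig_cv), null_cvs=null_cvs,
        percentile=_percentile_rank(sig_cv, null_cvs),
        B=B, seed=seed, set_size=k,
    )


# ---------------------------------------------------------------------------
# module scores and phase calls
# ---------------------------------------------------------------------------


def _mean_expression_bins(means: np.ndarray, nbins: int) -> np.ndarray:
    """Equal-frequency bin ids (0..nbins-1) of per-gene mean expression.

    Ties are split deterministically by position in the gene list.
    """
    order = np.argsort(means, kind="stable")
    ranks = np.empty_like(order)
    ranks[order] = np.arange(means.size)
    return (ranks * nbins) // means.size


def module_score(m: ExpressionMatrix, S: GeneSet, nbins: int = 24,
                 nctrl: int = 100, seed: int = 0) -> ModuleScoreResult:
    """Per-cell signature score against expression-bin-matched control genes.

    Genes are placed into ``nbins`` equal-frequency bins of mean expression
    across cells; each signature gene draws ``nctrl`` control genes from its
    bin (excluding signature genes when the bin offers non-signature genes,
    with replacement when the pool is smaller than ``nctrl``).  The score per
    cell is the mean over signature genes minus the mean over the pooled
    control draws.
    """
    m.require_layer("log_normalized")
    idx = m.gene_index()
    sig_rows = sorted(idx[g] for g in S.genes if g in idx)
    if not sig_rows:
        raise MatrixError(f"signature {S.name!r} shares no genes with the matrix")
    means = m.values.mean(axis=1)
    if len(np.unique(means)) < nbins:
        warnings.warn(
            f"fewer than nbins={nbins} distinct mean-expression values; "
            "bins collapse"
        )
    bins = _mean_expression_bins(means, nbins)
    sig_set = set(sig_rows)
    rng = np.random.default_rng(seed)
    ctrl_rows = []
    for row in sig_rows:
        in_bin = np.flatnonzero(bins == bins[row])
        pool = np.array([i for i in in_bin if i not in sig_set])
        if pool.size == 0:  # exclusion impossible: fall back to the whole bin
            pool = in_bin
        replace = pool.size < nctrl
        ctrl_rows.append(rng.choice(pool, size=nctrl, replace=replace))
    ctrl_rows = np.concatenate(ctrl_rows)
    scores = m.values[sig_rows].mean(axis=0) - m.values[ctrl_rows].mean(axis=0)
    return ModuleScoreResult(
        scores=dict(zip(m.sample_ids, map(float, scores))),
        control_pool=[m.gene_ids[i] for i in ctrl_rows],
        nbins=nbins, nctrl=nctrl, seed=seed,
    )


def classify_two_way(scores_a, scores_b, labels) -> dict:
    """Per-cell two-way call: first label iff score_a >= score_b.

    Unlike three-way phase calling there is no neutral class: every cell gets
    one of the two labels, ties going to the first.
    """
    name_a, name_b = labels
    if set(scores_a) != set(scores_b):
        raise ValueError("score dictionaries cover different cells")
    return {
        cell: (name_a if scores_a[cell] >= scores_b[cell] else name_b)
        for cell in scores_a
    }


def cell_cycle_phase(s_scores, g2m_scores) -> PhaseAssignment:
    """Call G1 / S / G2M from the two cycle module scores.

    Both scores negative -> G1; otherwise the phase of the larger score, with
    an exact tie going to S.
    """
    if set(s_scores) != set(g2m_scores):
        raise ValueError("score dictionaries cover different cells")
    phases = {}
    for cell in s_scores:
        s, g = s_scores[cell], g2m_scores[cell]
        if s < 0 and g < 0:
            phases[cell] = "G1"
        else:
            phases[cell] = "S" if s >= g else "G2M"
    return PhaseAssignment(phases, dict(s_scores), dict(g2m_scores))
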