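"""Single-cell stages: QC filtering, HTO demultiplexing, Wilcoxon DE, gene lengths.

The QC thresholds default to the published filtering rules for the
four-condition hashing experiment (ice / ice+TP / 37 C / 37 C+TP): cells are
excluded for a mitochondrial fraction above 6%, detected genes below 2,000 or
above 9,000, total transcripts below 5,000 or above 60,000, or hashtag-oligo
(HTO) totals below 20 or above 400.  Exclusion applies strictly beyond the
bounds, so boundary values are kept.  All thresholds are configurable for
data at other scales.

Differential expression is a two-sided Wilcoxon rank-sum test per gene on
log-normalized values (exact when both groups are small and tie-free,
otherwise a tie- and continuity-corrected normal approximation), restricted
to highly variable genes and optionally stratified by cell-cycle phase; the
per-contrast up/down calls feed a six-way intersection of the 37 C and
37 C+TP responses, and the gene-length comparison contrasts those response
groups with a Mann-Whitney U test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core_io import ExpressionMatrix, GeneAnnotationTable, GeneSet, MatrixError
from .enrichment import bh_adjust

_EXACT_MAX_PRODUCT = 200  # exact rank-sum enumeration limit (n_a * n_b)
_LFC_PSEUDO = 1e-9

QC_RULE_ORDER = ("mito_fraction", "n_features", "n_counts", "hto_total")


@dataclass(frozen=True)
class CellQC:
    cell_id: str
    n_features: int
    n_counts: int
    mito_fraction: float
    hto_total: int


@dataclass(frozen=True)
class QCThresholds:
    """Cell-exclusion bounds; defaults are the published hashing-run values."""

    max_mito: float = 0.06
    min_features: int = 2000
    max_features: int = 9000
    min_counts: int = 5000
    max_counts: int = 60000
    min_hto: int = 20
    max_hto: int = 400


@dataclass(frozen=True)
class DegRecord:
    gene_id: str
    log2_fc: float
    p: float
    q: float
    direction: str  # up | down
    contrast: str
    phase: str = "pooled"  # G1 | S | G2M | pooled


@dataclass
class DegIntersection:
    up_37_only: frozenset
    up_shared: frozenset
    up_37tp_only: frozenset
    down_37_only: frozenset
    down_shared: frozenset
    down_37tp_only: frozenset


@dataclass(frozen=True)
class GroupLengthSummary:
    n: int
    median: float
    q25: float
    q75: float
    min: float
    max: float


@dataclass
class LengthComparison:
    group_a: GroupLengthSummary
    group_b: GroupLengthSummary
    background: GroupLengthSummary | None
    u_statistic: float
    p_two_sided: float
    n_dropped_a: int = 0
    n_dropped_b: int = 0


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------


def compute_cell_qc(counts: ExpressionMatrix, hto: ExpressionMatrix | None = None,
                    mito_prefix: str = "mt-") -> list:
    """Per-cell QC metrics; mitochondrial genes matched by id prefix
    (case-insensitive, default ``mt-``)."""
    counts.require_layer("counts")
    mito = np.array([g.lower().startswith(mito_prefix.lower())
                     for g in counts.gene_ids])
    totals = counts.values.sum(axis=0)
    n_feat = (counts.values > 0).sum(axis=0)
    mito_frac = np.divide(counts.values[mito].sum(axis=0), totals,
                          out=np.zeros_like(totals), where=totals > 0)
    if hto is not None:
        pos = {c: j for j, c in enumerate(hto.sample_ids)}
        hto_tot = [int(hto.values[:, pos[c]].sum()) if c in pos else 0
                   for c in counts.sample_ids]
    else:
        hto_tot = [0] * counts.n_samples
    return [
        CellQC(c, int(n_feat[j]), int(totals[j]), float(mito_frac[j]), hto_tot[j])
        for j, c in enumerate(counts.sample_ids)
    ]


def qc_filter(cells, thresholds: QCThresholds = QCThresholds()):
    """Apply the exclusion rules; returns (kept_ids, per-rule exclusion tally).

    Boundary values are kept (the rules exclude strictly beyond the bounds).
    The tally attributes each excluded cell to the first failed rule in the
    fixed order mito -> n_features -> n_counts -> hto_total.
    """
    t = thresholds
    kept = []
    tally = {rule: 0 for rule in QC_RULE_ORDER}
    for cell in cells:
        for name in ("n_features", "n_counts", "mito_fraction", "hto_total"):
            if getattr(cell, name, None) is None:
                raise ValueError(f"cell {cell.cell_id}: missing QC field {name}")
        if cell.mito_fraction > t.max_mito:
            tally["mito_fraction"] += 1
        elif not (t.min_features <= cell.n_features <= t.max_features):
            tally["n_features"] += 1
        elif not (t.min_counts <= cell.n_counts <= t.max_counts):
            tally["n_counts"] += 1
        elif not (t.min_hto <= cell.hto_total <= t.max_hto):
            tally["hto_total"] += 1
        else:
            kept.append(cell.cell_id)
    return kept, tally


# ---------------------------------------------------------------------------
# HTO demultiplexing
# ---------------------------------------------------------------------------


def hto_demultiplex(hto: ExpressionMatrix, ratio_threshold: float = 3.0,
                    min_total: int = 20) -> dict:
    """Assign each cell to a hashtag, ``doublet`` or ``negative``.

    A transparent ratio rule: cells whose HTO total falls below ``min_total``
    are negative; otherwise the top hashtag is assigned when
    ``top / (second + 1) >= ratio_threshold``, else the cell is a doublet.
    """
    hto.require_layer("counts")
    if hto.n_genes < 2:
        raise MatrixError("HTO demultiplexing needs at least 2 HTO features")
    assignments = {}
    for j, cell in enumerate(hto.sample_ids):
        counts = hto.values[:, j]
        if counts.sum() < min_total:
            assignments[cell] = "negative"
            continue
        order = np.argsort(counts, kind="stable")[::-1]
        top, second = counts[order[0]], counts[order[1]]
        if top / (second + 1.0) >= ratio_threshold:
            assignments[cell] = hto.gene_ids[order[0]]
        else:
            assignments[cell] = "doublet"
    return assignments


# ---------------------------------------------------------------------------
# highly variable genes
# ---------------------------------------------------------------------------


def select_hvg(m: ExpressionMatrix, n_top: int = 2000, nbins: int = 20) -> list:
    """Top genes by standardized dispersion (variance/mean on log data,
    z-scored within equal-frequency mean-expression bins).

    Deterministic: ties are broken by gene id; genes with zero variance can
    never outrank a positive-variance gene.
    """
    m.require_layer("counts")
    if n_top > m.n_genes:
        warnings.warn(
            f"n_top={n_top} exceeds gene count {m.n_genes}; returning all genes"
        )
        n_top = m.n_genes
    from .core_io import log_normalize_cp10k

    logm = log_normalize_cp10k(m)
    means = logm.values.mean(axis=1)
    var = logm.values.var(axis=1, ddof=1) if m.n_samples > 1 else np.zeros(m.n_genes)
    disp = np.divide(var, means, out=np.zeros(m.n_genes), where=means > 0)

    from .scoring import _mean_expression_bins

    nbins = min(nbins, max(1, len(np.unique(means))))
    bins = _mean_expression_bins(means, nbins)
    z = np.zeros(m.n_genes)
    for b in np.unique(bins):
        in_bin = bins == b
        d = disp[in_bin]
        sd = d.std(ddof=0)
        z[in_bin] = (d - d.mean()) / sd if sd > 0 else 0.0
    z = np.where(var == 0, -np.inf, z)  # flat genes rank last
    order = sorted(range(m.n_genes), key=lambda i: (-z[i], m.gene_ids[i]))
    return [m.gene_ids[i] for i in order[:n_top]]


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum differential expression
# ---------------------------------------------------------------------------


def rank_sum_test(x, y, method: str = "auto"):
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) test; returns (U, p).

    ``auto`` uses exact enumeration when ``len(x) * len(y) <= 200`` and the
    pooled values are tie-free, else the tie- and continuity-corrected normal
    approximation.  Degenerate all-identical input gives p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return x.size * y.size / 2.0, 1.0
    if method == "auto":
        tie_free = len(np.unique(pooled)) == pooled.size
        method = ("exact" if x.size * y.size <= _EXACT_MAX_PRODUCT and tie_free
                  else "asymptotic")
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def _log2_fold_change(a: np.ndarray, b: np.ndarray) -> float:
    """log2 ratio of mean back-transformed (expm1) normalized expression."""
    return float(np.log2((np.expm1(a).mean() + _LFC_PSEUDO)
                         / (np.expm1(b).mean() + _LFC_PSEUDO)))


def wilcoxon_de(m: ExpressionMatrix, cells_a, cells_b, genes,
                contrast: str = "A_vs_B", phase: str = "pooled") -> list:
    """Per-gene two-sided rank-sum DE between two cell groups.

    Tested on log-normalized values for the supplied gene list (typically the
    highly variable genes); BH correction is applied across the tested genes.
    """
    m.require_layer("log_normalized")
    cells_a, cells_b = list(cells_a), list(cells_b)
    if len(cells_a) < 3 or len(cells_b) < 3:
        raise ValueError("both groups need >= 3 cells")
    idx = m.gene_index()
    missing = [g for g in genes if g not in idx]
    if missing:
        raise MatrixError(f"genes not in matrix: {missing[:5]}")
    pos = {c: j for j, c in enumerate(m.sample_ids)}
    ja = [pos[c] for c in cells_a]
    jb = [pos[c] for c in cells_b]
    rows = [idx[g] for g in genes]
    A = m.values[np.ix_(rows, ja)]
    B = m.values[np.ix_(rows, jb)]

    n_a, n_b = len(ja), len(jb)
    pvals = np.empty(len(rows))
    if n_a * n_b > _EXACT_MAX_PRODUCT:
        # single vectorized asymptotic call; constant genes handled after
        res = stats.mannwhitneyu(A, B, alternative="two-sided",
                                 method="asymptotic", use_continuity=True,
                                 axis=1)
        pvals[:] = res.pvalue
        flat = (A == A[:, :1]).all(axis=1) & (B == A[:, :1]).all(axis=1)
        pvals[flat] = 1.0
    else:
        for i in range(len(rows)):
            _, pvals[i] = rank_sum_test(A[i], B[i])
    pvals = np.clip(np.nan_to_num(pvals, nan=1.0), 0.0, 1.0)
    qvals = bh_adjust(pvals)
    records = []
    for i, g in enumerate(genes):
        lfc = _log2_fold_change(A[i], B[i])
        records.append(DegRecord(
            gene_id=g, log2_fc=lfc, p=float(pvals[i]), q=float(qvals[i]),
            direction="up" if lfc > 0 else "down",
            contrast=contrast, phase=phase,
        ))
    return records


def phase_stratified_de(m: ExpressionMatrix, cells_a, cells_b, phases,
                        genes, contrast: str = "A_vs_B",
                        min_cells: int = 3) -> list:
    """Run the rank-sum DE separately within each cell-cycle phase.

    Phases where either group has fewer than ``min_cells`` cells are skipped
    with a warning; records are tagged with their phase.
    """
    records = []
    ran_any = False
    for phase in ("G1", "S", "G2M"):
        pa = [c for c in cells_a if phases.get(c) == phase]
        pb = [c for c in cells_b if phases.get(c) == phase]
        if len(pa) < min_cells or len(pb) < min_cells:
            warnings.warn(
                f"{contrast}: phase {phase} skipped "
                f"({len(pa)} vs {len(pb)} cells)"
            )
            continue
        records.extend(wilcoxon_de(m, pa, pb, genes, contrast, phase))
        ran_any = True
    if not ran_any:
        raise ValueError(f"{contrast}: every phase was skipped")
    return records


def _call_directions(records, q_threshold: float, contrast: str):
    """Per-gene up/down call across phases, dropping conflicting genes."""
    up, down = set(), set()
    for r in records:
        if r.q < q_threshold:
            (up if r.log2_fc > 0 else down).add(r.gene_id)
    conflicts = up & down
    if conflicts:
        warnings.warn(
            f"{contrast}: {len(conflicts)} genes significant in opposite "
            "directions across phases were dropped"
        )
    return up - conflicts, down - conflicts


def combine_and_intersect(deg_37_vs_ice, deg_37tp_vs_ice,
                          q_threshold: float = 0.05) -> DegIntersection:
    """Six-way intersection of the 37 C and 37 C+TP response gene calls.

    A gene is called up in a contrast when it is significant with positive
    fold change in at least one phase and shows no significant opposite call
    in another phase (conflicts are dropped with a warning); likewise down.
    """
    univ_a = {r.gene_id for r in deg_37_vs_ice}
    univ_b = {r.gene_id for r in deg_37tp_vs_ice}
    if univ_a != univ_b:
        raise ValueError("the two DE runs cover different gene universes")
    up_a, down_a = _call_directions(deg_37_vs_ice, q_threshold, "37_vs_ice")
    up_b, down_b = _call_directions(deg_37tp_vs_ice, q_threshold, "37tp_vs_ice")
    return DegIntersection(
        up_37_only=frozenset(up_a - up_b),
        up_shared=frozenset(up_a & up_b),
        up_37tp_only=frozenset(up_b - up_a),
        down_37_only=frozenset(down_a - down_b),
        down_shared=frozenset(down_a & down_b),
        down_37tp_only=frozenset(down_b - down_a),
    )


# ---------------------------------------------------------------------------
# gene-length comparison
# ---------------------------------------------------------------------------


def _length_summary(lengths: np.ndarray) -> GroupLengthSummary:
    return GroupLengthSummary(
        n=int(lengths.size),
        median=float(np.median(lengths)),
        q25=float(np.quantile(lengths, 0.25)),
        q75=float(np.quantile(lengths, 0.75)),
        min=float(lengths.min()),
        max=float(lengths.max()),
    )


def gene_length_comparison(genes_a, genes_b, ann: GeneAnnotationTable,
                           background: GeneSet | None = None) -> LengthComparison:
    """Compare gene-length distributions of two gene groups.

    Unannotated genes are dropped (counts reported); quartile summaries are
    computed per group (plus an optional background signature), and a
    two-sided Mann-Whitney U test compares the two groups — exact when
    ``n_a * n_b <= 10,000`` and tie-free, else the corrected normal
    approximation.
    """
    genes_a, genes_b = list(genes_a), list(genes_b)
    la = np.array([ann[g] for g in genes_a if g in ann], dtype=float)
    lb = np.array([ann[g] for g in genes_b if g in ann], dtype=float)
    if la.size < 2 or lb.size < 2:
        raise ValueError("need >= 2 annotated genes per group")
    pooled = np.concatenate([la, lb])
    tie_free = len(np.unique(pooled)) == pooled.size
    method = "exact" if la.size * lb.size <= 10_000 and tie_free else "asymptotic"
    if np.all(pooled == pooled[0]):
        u, p = la.size * lb.size / 2.0, 1.0
    else:
        res = stats.mannwhitneyu(la, lb, alternative="two-sided",
                                 method=method, use_continuity=True)
        u, p = float(res.statistic), float(res.pvalue)
    bg = None
    if background is not None:
        lbg = np.array([ann[g] for g in background.genes if g in ann],
                       dtype=float)
        if lbg.size >= 2:
            bg = _length_summary(lbg)
    return LengthComparison(
        group_a=_length_summary(la), group_b=_length_summary(lb),
        background=bg, u_statistic=u, p_two_sided=p,
        n_dropped_a=len(genes_a) - la.size, n_dropped_b=len(genes_b) - lb.size,
    )
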