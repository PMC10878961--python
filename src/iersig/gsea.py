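"""Preranked gene-set enrichment: ranking metric, running-sum ES, permutation NES/FDR.

The enrichment score is the classic weighted Kolmogorov-Smirnov running sum:
walking down a ranked gene list, hits increment the sum by
``|score|^p / sum_hits |score|^p`` and misses decrement it by
``1 / (N - N_hits)``; the ES is the deviation of largest magnitude (ties
broken toward positive), and the leading edge is the hit genes at or before
the extremum for a positive ES (at or after, for a negative one).

Significance uses a gene-label permutation null: set membership is reassigned
uniformly at random (size preserved) ``n_perm`` times.  The NES divides the
observed ES by the mean magnitude of same-sign null ES values; nominal p is
the add-one-smoothed same-sign tail fraction; FDR q follows the standard
pooling of sign-matched null NES against observed NES.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core_io import ExpressionMatrix, GeneSet, GeneSetCollection, read_rnk


class GseaError(ValueError):
    pass


@dataclass
class RankedList:
    """Gene / score pairs, strictly ordered by score descending.

    Ties in score are ordered deterministically by gene id.
    """

    entries: list

    def __post_init__(self) -> None:
        genes = [g for g, _ in self.entries]
        if len(set(genes)) != len(genes):
            raise GseaError("duplicate gene ids in ranked list")
        scores = np.array([s for _, s in self.entries], dtype=float)
        if not np.all(np.isfinite(scores)):
            raise GseaError("non-finite scores in ranked list")
        if np.any(np.diff(scores) > 0):
            raise GseaError("ranked list not sorted by score descending")

    @classmethod
    def from_scores(cls, scores) -> "RankedList":
        """Build from a gene -> score mapping or (gene, score) pairs."""
        pairs = list(scores.items()) if hasattr(scores, "items") else list(scores)
        pairs = [(str(g), float(s)) for g, s in pairs]
        pairs.sort(key=lambda gs: (-gs[1], gs[0]))
        return cls(pairs)

    @classmethod
    def from_rnk(cls, path) -> "RankedList":
        return cls.from_scores(read_rnk(path))

    @property
    def genes(self) -> list:
        return [g for g, _ in self.entries]

    @property
    def scores(self) -> np.ndarray:
        return np.array([s for _, s in self.entries], dtype=float)

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class GseaOutcome:
    set_name: str
    es: float
    nes: float
    p_nominal: float
    fdr_q: float
    leading_edge: list
    running_profile: np.ndarray = field(repr=False, default=None)


# ---------------------------------------------------------------------------
# ranking metrics
# ---------------------------------------------------------------------------


def rank_by_snr(m: ExpressionMatrix, group_labels, levels=None,
                metric: str = "snr") -> RankedList:
    """Rank genes by a two-group contrast; level 1 enriched at the top.

    ``group_labels`` is either a ``sample_meta`` column name or a sequence of
    per-sample labels with exactly two levels.  The default metric is the
    signal-to-noise ratio ``(mu1 - mu2) / (s1 + s2)`` with each group standard
    deviation floored at ``max(0.2 * |mu|, 0.2)``; ``log2_fc`` (which supports
    single-sample groups) and Welch ``t`` are available as alternatives.
    """
    m.require_layer("normalized", "log_normalized")
    if isinstance(group_labels, str):
        labels = [str(v) for v in m.sample_meta[group_labels]]
    else:
        labels = [str(v) for v in group_labels]
        if len(labels) != m.n_samples:
            raise GseaError("group_labels length does not match sample count")
    if levels is None:
        levels = list(dict.fromkeys(labels))
    levels = [str(l) for l in levels]
    if len(levels) != 2 or set(labels) != set(levels):
        raise GseaError(f"expected exactly two levels, got {sorted(set(labels))}")
    i1 = np.array([l == levels[0] for l in labels])
    i2 = ~i1
    x1, x2 = m.values[:, i1], m.values[:, i2]
    if metric == "snr":
        if x1.shape[1] < 2 or x2.shape[1] < 2:
            raise GseaError(
                "signal-to-noise needs >=2 samples per group; use "
                "metric='log2_fc' for single-sample groups"
            )
        mu1, mu2 = x1.mean(axis=1), x2.mean(axis=1)
        s1 = np.maximum(x1.std(axis=1, ddof=1),
                        np.maximum(0.2 * np.abs(mu1), 0.2))
        s2 = np.maximum(x2.std(axis=1, ddof=1),
                        np.maximum(0.2 * np.abs(mu2), 0.2))
        scores = (mu1 - mu2) / (s1 + s2)
    elif metric == "log2_fc":
        eps = 1e-9
        scores = np.log2((x1.mean(axis=1) + eps) / (x2.mean(axis=1) + eps))
    elif metric == "t":
        if x1.shape[1] < 2 or x2.shape[1] < 2:
            raise GseaError("t metric needs >=2 samples per group")
        v1 = x1.var(axis=1, ddof=1) / x1.shape[1]
        v2 = x2.var(axis=1, ddof=1) / x2.shape[1]
        scores = (x1.mean(axis=1) - x2.mean(axis=1)) / np.sqrt(v1 + v2 + 1e-30)
    else:
        raise GseaError(f"unknown metric {metric!r}")
    return RankedList.from_scores(zip(m.gene_ids, scores))


# ---------------------------------------------------------------------------
# enrichment score
# ---------------------------------------------------------------------------


def _running_sum(weights_p: np.ndarray, hit: np.ndarray) -> np.ndarray:
    """Running deviation profile for one hit indicator over a fixed ranking."""
    n = hit.size
    n_hit = int(hit.sum())
    hit_w = np.where(hit, weights_p, 0.0)
    total = hit_w.sum()
    if total > 0:
        inc = hit_w / total
    else:  # weight_p == 0 path: equal weights
        inc = hit / n_hit
    miss_dec = 1.0 / (n - n_hit) if n > n_hit else 0.0
    step = inc - np.where(hit, 0.0, miss_dec)
    return np.cumsum(step)


def _extremum(running: np.ndarray):
    """(es, index) with magnitude ties broken toward the positive extremum."""
    imax = int(np.argmax(running))
    imin = int(np.argmin(running))
    if running[imax] >= -running[imin]:
        return float(running[imax]), imax
    return float(running[imin]), imin


def enrichment_score(r: RankedList, S: GeneSet, weight_p: float = 1.0):
    """Weighted running-sum enrichment score of gene set S in ranking r.

    Returns ``(es, running_profile, leading_edge)``.
    """
    if weight_p < 0:
        raise GseaError("weight_p must be >= 0")
    genes = r.genes
    scores = r.scores
    members = set(S.genes)
    hit = np.array([g in members for g in genes])
    if not hit.any():
        raise GseaError(f"set {S.name!r} is disjoint from the ranked genes")
    weights_p = np.abs(scores) ** weight_p
    if weight_p > 0 and weights_p[hit].sum() == 0:
        raise GseaError(
            f"all hit scores are zero for set {S.name!r} with weight_p > 0"
        )
    running = _running_sum(weights_p, hit)
    es, idx = _extremum(running)
    if es >= 0:
        le_mask = hit & (np.arange(hit.size) <= idx)
    else:
        le_mask = hit & (np.arange(hit.size) >= idx)
    leading = [g for g, m in zip(genes, le_mask) if m]
    return es, running, leading


# ---------------------------------------------------------------------------
# permutation NES / FDR
# ---------------------------------------------------------------------------


def _null_es(weights_p: np.ndarray, set_size: int, n_perm: int,
             rng: np.random.Generator) -> np.ndarray:
    n = weights_p.size
    out = np.empty(n_perm)
    hit = np.zeros(n, dtype=bool)
    for b in range(n_perm):
        idx = rng.choice(n, size=set_size, replace=False)
        hit[:] = False
        hit[idx] = True
        running = _running_sum(weights_p, hit)
        out[b], _ = _extremum(running)
    return out


def nes_and_fdr(r: RankedList, coll: GeneSetCollection, weight_p: float = 1.0,
                n_perm: int = 1000, seed: int = 0) -> list:
    """Permutation-normalized enrichment for every set in a collection.

    For each set, ``n_perm`` same-size random gene sets drawn from the ranked
    genes form the null ES distribution.  Deterministic for a fixed seed.
    """
    if n_perm < 100:
        raise GseaError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    weights_p = np.abs(r.scores) ** weight_p
    ranked_genes = set(r.genes)

    per_set = []
    for s in coll:
        usable = len(set(s.genes) & ranked_genes)
        if usable == 0:
            raise GseaError(f"set {s.name!r} is disjoint from the ranked genes")
        es, running, leading = enrichment_score(r, s, weight_p)
        nulls = _null_es(weights_p, usable, n_perm, rng)
        per_set.append((s.name, es, running, leading, nulls))

    # per-set sign-matched normalization, then pool null NES across sets
    results = []
    pooled_null_nes = []
    obs_nes = []
    for name, es, running, leading, nulls in per_set:
        pos = nulls[nulls > 0]
        neg = nulls[nulls < 0]
        mean_pos = pos.mean() if pos.size else np.nan
        mean_neg = np.abs(neg).mean() if neg.size else np.nan
        matched = pos if es >= 0 else neg
        if matched.size == 0:
            warnings.warn(
                f"set {name!r}: no matching-sign null ES; p and q floored at "
                f"1/(n_perm+1)"
            )
            floor = 1.0 / (n_perm + 1)
            scale = np.abs(nulls).mean() or 1.0
            nes = es / scale
            p_nom = floor
            results.append([name, es, nes, p_nom, floor, leading, running])
        else:
            scale = mean_pos if es >= 0 else mean_neg
            nes = es / scale
            if es >= 0:
                p_nom = (1 + int((matched >= es).sum())) / (1 + matched.size)
            else:
                p_nom = (1 + int((matched <= es).sum())) / (1 + matched.size)
            results.append([name, es, nes, p_nom, None, leading, running])
        null_nes = np.concatenate([
            pos / mean_pos if pos.size else np.empty(0),
            neg / mean_neg if neg.size else np.empty(0),
        ])
        pooled_null_nes.append(null_nes)
        obs_nes.append(results[-1][2])

    pooled = np.concatenate(pooled_null_nes) if pooled_null_nes else np.empty(0)
    obs = np.array(obs_nes)
    for row in results:
        if row[4] is not None:  # degenerate case already floored
            continue
        nes = row[2]
        if nes >= 0:
            frac_null = (pooled >= nes).mean() if pooled.size else 1.0
            frac_obs = (obs >= nes).mean()
        else:
            frac_null = (pooled <= nes).mean() if pooled.size else 1.0
            frac_obs = (obs <= nes).mean()
        q = frac_null / max(frac_obs, 1.0 / max(len(obs), 1))
        row[4] = float(min(1.0, q))

    return [GseaOutcome(name, float(es), float(nes), float(p), float(q),
                        leading, running)
            for name, es, nes, p, q, leading, running in results]


def outcomes_to_rows(outcomes) -> list:
    """Flatten outcomes into TSV-friendly dict rows."""
    return [
        {
            "set": o.set_name, "es": o.es, "nes": o.nes,
            "p_nominal": o.p_nominal, "fdr_q": o.fdr_q,
            "leading_edge": ",".join(o.leading_edge),
        }
        for o in outcomes
    ]
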