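"""Reporter-algorithm gene-set enrichment with directional classes.

Each gene's significance p (typically a q-value from the differential
expression step) is transformed to a standard-normal quantile
z = Phi^-1(1 - p).  A gene set of size k is scored by

    z_raw = sum(z_members) / sqrt(k)

and standardized against an empirical background: the mean and standard
deviation of the same score over randomly sampled k-subsets of the analyzed
gene universe.  The standardized score is referred to the normal upper tail
for the enrichment p-value.

Direction (over- vs under-represented among up- vs down-regulated genes) is
resolved by two one-sided runs per term: members restricted to up-regulated
genes with p halved, and likewise for down-regulated genes, each
standardized against the matching sign-restricted universe.  The more
significant class wins and determines the sign of the reported score
+/- (-log10 p), the red/blue scale of an enrichment heatmap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateBackgroundError, InputError
from .io import GeneSetCollection

__all__ = [
    "EnrichmentResult",
    "p_to_z",
    "reporter_score",
    "background_adjust",
    "enrich_terms",
    "heatmap_matrix",
]

P_CLIP = 1e-15  # keeps the normal quantile finite
_TINY = np.finfo(float).tiny


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    term_name: str
    k: int  # members scored (within the winning directional class)
    z_raw: float
    z_adjusted: float
    p_enrichment: float
    direction: str  # 'over' | 'under'
    score: float  # signed -log10(p_enrichment)
    selected: bool


def p_to_z(p: np.ndarray) -> np.ndarray:
    """Normal quantile transform z = Phi^-1(1 - p), with p clipped away
    from 0 and 1 so the quantile stays finite."""
    p = np.clip(np.asarray(p, dtype=float), P_CLIP, 1.0 - P_CLIP)
    return stats.norm.isf(p)


def reporter_score(member_p: Sequence[float]) -> float:
    """Raw reporter score of one gene set: sum of member z divided by sqrt(k)."""
    member_p = np.asarray(member_p, dtype=float)
    if member_p.size == 0:
        raise InputError("reporter score of an empty member set")
    return float(p_to_z(member_p).sum() / math.sqrt(member_p.size))


def _subset_scores(z_universe: np.ndarray, k: int, n_samples: int, rng: np.random.Generator) -> np.ndarray:
    """Reporter scores of ``n_samples`` uniform random k-subsets (without
    replacement), vectorized via per-row random keys; chunked to bound
    memory at ~2e7 doubles."""
    n = z_universe.size
    chunk = max(1, int(2e7) // n)
    scores = np.empty(n_samples)
    done = 0
    while done < n_samples:
        m = min(chunk, n_samples - done)
        keys = rng.random((m, n))
        idx = np.argpartition(keys, k - 1, axis=1)[:, :k]
        scores[done : done + m] = z_universe[idx].sum(axis=1) / math.sqrt(k)
        done += m
    return scores


class _BackgroundSampler:
    """Caches per-size background moments for one universe and seed stream."""

    def __init__(self, z_universe: np.ndarray, n_samples: int, rng: np.random.Generator):
        self.z = np.asarray(z_universe, dtype=float)
        self.n_samples = n_samples
        self.rng = rng
        self._cache: dict[int, tuple[float, float]] = {}

    def moments(self, k: int) -> tuple[float, float]:
        if k not in self._cache:
            s = _subset_scores(self.z, k, self.n_samples, self.rng)
            self._cache[k] = (float(s.mean()), float(s.std(ddof=1)))
        return self._cache[k]


def background_adjust(
    z_raw: float,
    k: int,
    gene_universe_p: Sequence[float],
    n_samples: int = 10000,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Standardize a raw reporter score against sampled same-size sets.

    Returns ``(z_adjusted, p_enrichment)`` with p = 1 - Phi(z_adjusted),
    clipped to (0, 1].  When the set is the whole universe every subset is
    identical; z_raw equals the background mean and the score carries no
    information, so (0, 0.5) is returned.  Any other zero-spread background
    raises :class:`DegenerateBackgroundError`.
    """
    z_universe = p_to_z(np.asarray(gene_universe_p, dtype=float))
    if k < 1 or k > z_universe.size:
        raise InputError(f"set size {k} incompatible with universe of {z_universe.size}")
    if k == z_universe.size:
        return 0.0, 0.5
    if rng is None:
        rng = np.random.default_rng(seed)
    mu, sigma = _BackgroundSampler(z_universe, n_samples, rng).moments(k)
    if sigma == 0:
        raise DegenerateBackgroundError(f"background spread is zero at k={k}")
    z_adj = (z_raw - mu) / sigma
    p = float(np.clip(stats.norm.sf(z_adj), _TINY, 1.0))
    return float(z_adj), p


def enrich_terms(
    per_gene_p: Mapping[str, float],
    per_gene_direction: Mapping[str, float],
    go: GeneSetCollection,
    classes: Sequence[str] = ("over", "under"),
    alpha: float = 0.05,
    seed: int = 0,
    n_samples: int = 10000,
    min_members: int = 3,
) -> list[EnrichmentResult]:
    """Directional reporter enrichment of every term against the universe.

    ``per_gene_p`` defines the analyzed universe; ``per_gene_direction`` is
    the sign of each gene's log2 fold change (>= 0 counts as up).  Terms with
    fewer than ``min_members`` genes in the universe are dropped.  For each
    term and each class the members restricted to that sign are scored on
    halved (one-sided) p-values and standardized against the sign-restricted
    universe; the more significant class gives the reported direction
    (ties resolve to 'over').
    """
    if not per_gene_p:
        raise InputError("empty gene universe")
    genes = list(per_gene_p)
    p = np.array([per_gene_p[g] for g in genes], dtype=float)
    sign_up = np.array([per_gene_direction.get(g, 0.0) >= 0 for g in genes], dtype=bool)

    class_universe: dict[str, dict[str, float]] = {}
    samplers: dict[str, _BackgroundSampler] = {}
    for cls in classes:
        mask = sign_up if cls == "over" else ~sign_up
        cls_genes = [g for g, m in zip(genes, mask) if m]
        cls_p = {g: per_gene_p[g] / 2.0 for g in cls_genes}
        class_universe[cls] = cls_p
        if cls_genes:
            rng = np.random.default_rng([seed, 0 if cls == "over" else 1])
            samplers[cls] = _BackgroundSampler(
                p_to_z(np.array(list(cls_p.values()))), n_samples, rng
            )

    universe = set(genes)
    results: list[EnrichmentResult] = []
    for term_id, (term_name, members) in go.sets.items():
        members_u = members & universe
        if len(members_u) < min_members:
            continue
        best: tuple[float, str, int, float, float] | None = None
        for cls in classes:
            cls_p = class_universe[cls]
            member_p = [cls_p[g] for g in members_u if g in cls_p]
            k = len(member_p)
            if k == 0 or cls not in samplers:
                continue
            z_raw = reporter_score(member_p)
            n_cls = len(cls_p)
            if k == n_cls:
                z_adj, p_enr = 0.0, 0.5
            else:
                mu, sigma = samplers[cls].moments(k)
                if sigma == 0:
                    raise DegenerateBackgroundError(f"zero background spread, term {term_id}")
                z_adj = (z_raw - mu) / sigma
                p_enr = float(np.clip(stats.norm.sf(z_adj), _TINY, 1.0))
            cand = (p_enr, cls, k, z_raw, z_adj)
            # strict < keeps 'over' on ties because it is evaluated first
            if best is None or p_enr < best[0]:
                best = cand
        if best is None:
            continue
        p_enr, cls, k, z_raw, z_adj = best
        score = -math.log10(p_enr)
        if cls == "under":
            score = -score
        results.append(
            EnrichmentResult(
                term_id=term_id,
                term_name=term_name,
                k=k,
                z_raw=z_raw,
                z_adjusted=z_adj,
                p_enrichment=p_enr,
                direction=cls,
                score=score,
                selected=p_enr < alpha,
            )
        )
    return results


def heatmap_matrix(
    results_by_contrast: Mapping[str, Sequence[EnrichmentResult]],
    contrasts: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Term x contrast matrix of signed scores for selected terms.

    Rows are the union of selected terms over all contrasts (sorted); a cell
    is the signed score when that term was selected in that contrast, else 0.
    """
    if contrasts is None:
        contrasts = list(results_by_contrast)
    selected_terms = sorted(
        {r.term_id for c in contrasts for r in results_by_contrast.get(c, []) if r.selected}
    )
    mat = pd.DataFrame(0.0, index=pd.Index(selected_terms, name="term_id"), columns=list(contrasts))
    for c in contrasts:
        for r in results_by_contrast.get(c, []):
            if r.selected and r.term_id in mat.index:
                mat.loc[r.term_id, c] = r.score
    return mat


def write_enrichment_table(results: Sequence[EnrichmentResult], path) -> None:
    rows = [
        {
            "term_id": r.term_id,
            "term_name": r.term_name,
            "k": r.k,
            "z_raw": r.z_raw,
            "z_adjusted": r.z_adjusted,
            "p_enrichment": r.p_enrichment,
            "direction": r.direction,
            "score": r.score,
            "selected": int(r.selected),
        }
        for r in results
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
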