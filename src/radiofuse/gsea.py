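"""Pre-ranked gene-set enrichment with permutation-normalised scores.

For each signature feature, genes are ranked by their signed Spearman
correlation with the feature (descending) and each gene set is scored
with the classic weighted Kolmogorov–Smirnov running sum: hits increment
by |metric|^p normalised over the set's hits, misses decrement by
1/(N - n_hits); the enrichment score (ES) is the running-sum value of
maximal absolute deviation.  A null distribution of ES from random
same-size gene subsets yields the sign-matched normalised score (NES) and
an add-one-smoothed permutation p-value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

MIN_UNIVERSE = 15
DEFAULT_SIZE_BOUNDS = (15, 500)


@dataclass
class RankedGeneList:
    """Genes ordered by a signed ranking metric, descending."""

    genes: list[str]
    metric: np.ndarray
    source_feature: str = ""

    def __post_init__(self) -> None:
        self.metric = np.asarray(self.metric, dtype=float)
        if len(self.genes) != len(self.metric):
            raise ValueError("genes and metric lengths differ")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate genes in ranked list")
        if np.any(np.diff(self.metric) > 0):
            raise ValueError("metric must be non-increasing")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class EnrichmentResult:
    """Per gene set: ES, NES, permutation p, effective size, provenance."""

    set_id: str
    es: float
    nes: float
    p: float
    size: int
    source_feature: str = ""
    nes_defined: bool = True
    fallback_full_ranking: bool = False


def rank_genes(rho_by_gene: pd.Series | dict[str, float],
               source_feature: str = "") -> RankedGeneList:
    """Descending sort by signed rho; ties break lexicographically by
    gene symbol; undefined entries are dropped with a warning."""
    s = pd.Series(rho_by_gene, dtype=float)
    if s.isna().any():
        warnings.warn(f"dropping {int(s.isna().sum())} genes with undefined "
                      "ranking metric", stacklevel=2)
        s = s.dropna()
    if len(s) < MIN_UNIVERSE:
        raise ValueError(
            f"ranked universe has {len(s)} genes; need >= {MIN_UNIVERSE}"
        )
    s = s.iloc[np.lexsort((s.index.to_numpy(), -s.to_numpy()))]
    return RankedGeneList(genes=list(s.index), metric=s.to_numpy(),
                          source_feature=source_feature)


def _es_from_hits(metric: np.ndarray, hit_mask: np.ndarray,
                  p: float) -> tuple[float, np.ndarray]:
    n = len(metric)
    n_hits = int(hit_mask.sum())
    weights = np.abs(metric) ** p
    hit_total = weights[hit_mask].sum()
    steps = np.where(hit_mask,
                     (weights / hit_total) if hit_total > 0
                     else (1.0 / max(n_hits, 1)),
                     -1.0 / (n - n_hits))
    if hit_total == 0:
        # all-zero metrics inside the set: fall back to uniform hit steps
        steps = np.where(hit_mask, 1.0 / n_hits, -1.0 / (n - n_hits))
    running = np.cumsum(steps)
    es = running[np.argmax(np.abs(running))]
    return float(es), running


def enrichment_score(rl: RankedGeneList, gene_set: set[str] | list[str],
                     p: float = 1.0) -> tuple[float, np.ndarray]:
    """Weighted-KS enrichment score and its running-sum trace.

    With ``p = 0`` this reduces to the unweighted Kolmogorov–Smirnov
    statistic of the hit positions.
    """
    members = set(gene_set)
    hit_mask = np.fromiter((g in members for g in rl.genes), dtype=bool,
                           count=len(rl))
    n_hits = int(hit_mask.sum())
    if n_hits == 0:
        raise ValueError("gene set does not intersect the ranked universe")
    if n_hits == len(rl):
        raise ValueError("gene set covers the whole ranked universe")
    return _es_from_hits(rl.metric, hit_mask, p)


def normalise_es(rl: RankedGeneList, gene_set: set[str] | list[str],
                 n_perm: int = 1000, seed: int = 0,
                 weight: float = 1.0) -> EnrichmentResult:
    """ES with permutation NES and p-value.

    Null ES values come from ``n_perm`` random same-size gene subsets of
    the universe; NES divides ES by the mean |null ES| of the same sign,
    and the permutation p-value is the add-one-smoothed fraction of
    same-sign null ES at least as extreme.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    es, _ = enrichment_score(rl, gene_set, weight)
    members = set(gene_set) & set(rl.genes)
    size = len(members)
    rng = np.random.default_rng(seed)
    n = len(rl)
    null = np.empty(n_perm)
    for i in range(n_perm):
        hit_mask = np.zeros(n, dtype=bool)
        hit_mask[rng.choice(n, size, replace=False)] = True
        null[i], _ = _es_from_hits(rl.metric, hit_mask, weight)
    same_sign = null[np.sign(null) == np.sign(es)] if es != 0 else null
    if len(same_sign) == 0:
        return EnrichmentResult(set_id="", es=es, nes=np.nan, p=1.0,
                                size=size, nes_defined=False)
    nes = es / np.abs(same_sign).mean()
    p_val = (1 + int((np.abs(same_sign) >= abs(es)).sum())) / \
        (1 + len(same_sign))
    return EnrichmentResult(set_id="", es=es, nes=float(nes), p=float(p_val),
                            size=size)


def signature_enrichment(rho_table: pd.DataFrame,
                         rr_p_table: pd.DataFrame,
                         gene_sets: dict[str, list[str]],
                         size_bounds: tuple[int, int] = DEFAULT_SIZE_BOUNDS,
                         alpha_rr: float = 0.001,
                         alpha_go: float = 0.05,
                         n_perm: int = 1000, seed: int = 0,
                         weight: float = 1.0) -> dict:
    """Per-GO-term enrichment report for one signature.

    ``rho_table``/``rr_p_table`` are features x genes Spearman rho and
    p-value matrices for the signature's features.  For each feature, the
    ranked list is restricted to genes with RR p < ``alpha_rr``; when
    fewer than 15 such genes exist the full ranking is used instead and
    the results are flagged.  Gene sets are filtered to an effective size
    within ``size_bounds`` after intersection with the ranked universe.
    A GO term has an RR with the signature when its permutation p-value is
    below ``alpha_go`` for at least one feature; the term's report carries
    the extreme-|NES| value and the contributing feature.
    """
    if rho_table.shape[0] == 0:
        return {"generated": False, "reason": "signature not generated"}
    results: list[EnrichmentResult] = []
    rng = np.random.default_rng(seed)
    for feature_id in rho_table.index:
        rho = rho_table.loc[feature_id]
        sig_genes = rho[rr_p_table.loc[feature_id] < alpha_rr]
        fallback = len(sig_genes) < MIN_UNIVERSE
        universe = rho.dropna() if fallback else sig_genes
        if len(universe) < MIN_UNIVERSE:
            continue
        rl = rank_genes(universe, source_feature=str(feature_id))
        for set_id, members in gene_sets.items():
            eff = len(set(members) & set(rl.genes))
            if not (size_bounds[0] <= eff <= size_bounds[1]) or eff == len(rl):
                continue
            res = normalise_es(rl, members, n_perm=n_perm,
                               seed=int(rng.integers(0, 2**31 - 1)),
                               weight=weight)
            res.set_id = set_id
            res.source_feature = str(feature_id)
            res.fallback_full_ranking = fallback
            results.append(res)

    per_term: dict[str, dict] = {}
    for res in results:
        entry = per_term.setdefault(res.set_id, {
            "significant": False, "nes": 0.0, "es": 0.0, "p": 1.0,
            "feature": None, "size": res.size, "fallback": False,
        })
        if res.nes_defined and abs(res.nes) > abs(entry["nes"]):
            entry.update(nes=res.nes, es=res.es, p=res.p,
                         feature=res.source_feature, size=res.size,
                         fallback=res.fallback_full_ranking)
        if res.nes_defined and res.p < alpha_go:
            entry["significant"] = True
    return {
        "generated": True,
        "terms": per_term,
        "n_significant": sum(t["significant"] for t in per_term.values()),
        "results": results,
    }


# ------------------------------------------------------------------ GMT I/O

def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """GMT dialect: one set per line — name, description, tab-separated
    symbols."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(gene_sets: dict[str, list[str]], path: str | Path,
              description: str = "synthetic") -> None:
    lines = [
        "\t".join([name, description] + list(members))
        for name, members in gene_sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")
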