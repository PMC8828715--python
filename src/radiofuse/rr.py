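"""Radiogenomics relationship (RR) calling and comparison.

An RR is a statistically significant Spearman rank correlation between
one signature image feature and one gene's expression (default threshold
p < 0.001, uncorrected, with an optional Benjamini–Hochberg mode).  The
module also counts RRs per signature, partitions the correlated genes
into Venn regions across signatures, and compares RR strength (|rho|)
between signatures with direction-stratified one-sided Welch t-tests.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class RRTable:
    """Rows of (feature_id, gene, rho, p, direction) for one signature."""

    rows: pd.DataFrame
    source: str = "FF"

    def __post_init__(self) -> None:
        required = {"feature_id", "gene", "rho", "p", "direction"}
        missing = required - set(self.rows.columns)
        if missing:
            raise ValueError(f"RRTable missing columns: {sorted(missing)}")

    @property
    def n_rr(self) -> int:
        return len(self.rows)

    @property
    def genes(self) -> set[str]:
        return set(self.rows["gene"])


def spearman_matrix(features: pd.DataFrame, expression: pd.DataFrame
                    ) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs Spearman rho and p between feature columns and gene rows.

    rho is Pearson correlation on average ranks (ties handled); p uses the
    t approximation with n - 2 degrees of freedom.  Zero-variance columns
    or genes produce NaN entries (skipped by the caller with a warning).
    """
    if list(features.index) != list(expression.columns):
        raise ValueError("patient orders of features and expression differ")
    n = features.shape[0]
    if n < 3:
        raise ValueError("Spearman correlation needs at least 3 patients")

    def _rank_std(X: np.ndarray) -> np.ndarray:
        R = np.apply_along_axis(sps.rankdata, 0, X)
        R = R - R.mean(axis=0)
        norm = np.sqrt((R ** 2).sum(axis=0))
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(norm > 0, R / norm, np.nan)

    F = _rank_std(features.to_numpy())
    G = _rank_std(expression.to_numpy().T)
    rho = F.T @ G  # features x genes
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = rho * np.sqrt((n - 2) / (1 - rho ** 2))
    p = 2 * sps.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(rho) >= 1.0, 0.0, p)
    return rho, p


def spearman_rr(features: pd.DataFrame, expression: pd.DataFrame,
                alpha: float = 0.001, source: str = "FF",
                fdr: bool = False) -> RRTable:
    """Call RRs between signature features (patients x m) and gene
    expression (genes x patients) at Spearman ``p < alpha``.

    With ``fdr=True`` the threshold is applied to Benjamini–Hochberg
    adjusted p-values instead of raw ones (off by default).
    """
    if features.shape[0] < 5:
        raise ValueError("RR calling needs at least 5 patients")
    rho, p = spearman_matrix(features, expression)
    if np.isnan(rho).any():
        warnings.warn(
            f"skipping {int(np.isnan(rho).sum())} pairs with undefined rho "
            "(zero-variance feature or gene)", stacklevel=2)
    pv = p.copy()
    if fdr:
        flat = pv.ravel()
        ok = ~np.isnan(flat)
        adj = np.full_like(flat, np.nan)
        m = ok.sum()
        order = np.argsort(flat[ok])
        ranked = flat[ok][order] * m / (np.arange(m) + 1)
        adj_ok = np.minimum.accumulate(ranked[::-1])[::-1]
        tmp = np.empty(m)
        tmp[order] = np.clip(adj_ok, 0, 1)
        adj[ok] = tmp
        pv = adj.reshape(pv.shape)
    fi, gi = np.where(pv < alpha)
    rows = pd.DataFrame({
        "feature_id": features.columns.to_numpy()[fi],
        "gene": expression.index.to_numpy()[gi],
        "rho": rho[fi, gi],
        "p": p[fi, gi],
    })
    rows["direction"] = np.where(rows["rho"] >= 0, "positive", "inverse")
    return RRTable(rows=rows, source=source)


def rr_summary(tables: dict[str, RRTable]) -> dict:
    """RR and unique-gene counts per signature plus the Venn partition of
    the correlated gene sets (up to 4 signatures)."""
    if not tables:
        raise ValueError("at least one RR table required")
    out: dict = {"per_signature": {}, "venn": {}}
    for name, tbl in tables.items():
        out["per_signature"][name] = {
            "n_rr": tbl.n_rr, "n_genes": len(tbl.genes),
        }
    names = list(tables)[:4]
    gene_sets = {n: tables[n].genes for n in names}
    for combo in itertools.product([0, 1], repeat=len(names)):
        if not any(combo):
            continue
        inside = set.intersection(*(gene_sets[n] for n, c in
                                    zip(names, combo) if c))
        for n, c in zip(names, combo):
            if not c:
                inside = inside - gene_sets[n]
        key = "&".join(n for n, c in zip(names, combo) if c)
        out["venn"][key] = len(inside)
    return out


def compare_strengths(a: RRTable, b: RRTable) -> dict:
    """Direction-stratified one-sided Welch t-tests on RR strength.

    Within each direction stratum (positive / inverse), tests whether
    ``a``'s |rho| values are larger than ``b``'s.  A stratum empty in
    either table is reported untestable.
    """
    out = {}
    for direction in ("positive", "inverse"):
        sa = a.rows.loc[a.rows["direction"] == direction, "rho"].abs()
        sb = b.rows.loc[b.rows["direction"] == direction, "rho"].abs()
        if len(sa) == 0 or len(sb) == 0:
            out[direction] = {"testable": False}
            continue
        res = sps.ttest_ind(sa, sb, equal_var=False, alternative="greater")
        df = getattr(res, "df", np.nan)
        out[direction] = {
            "testable": True,
            "t": float(res.statistic),
            "df": float(df),
            "p": float(res.pvalue),
            "n_a": int(len(sa)),
            "n_b": int(len(sb)),
        }
    return out
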