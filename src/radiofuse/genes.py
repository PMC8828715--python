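"""Probe collapsing and the three sequential quartile gene filters.

Probe-level expression is collapsed to gene symbols (ambiguous and
unmapped probes dropped, repeated probes averaged), then genes are
filtered in three sequential passes — low variance, low mean absolute
expression, low histogram entropy — each dropping genes strictly below
the quartile of the statistic recomputed on the current survivors.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

ENTROPY_BINS = 16


def collapse_probes(probe_matrix: pd.DataFrame,
                    probe_to_genes: dict[str, list[str]]) -> pd.DataFrame:
    """Collapse probes x patients to genes x patients.

    Probes mapping to zero or to multiple distinct gene symbols are
    discarded; each gene's value is the per-patient arithmetic mean of its
    remaining probes.
    """
    rows = []
    symbols = []
    for probe in probe_matrix.index:
        genes = sorted(set(probe_to_genes.get(probe, ())))
        if len(genes) != 1:
            continue
        rows.append(probe)
        symbols.append(genes[0])
    if not rows:
        raise ValueError("no probes with a unique gene symbol")
    kept = probe_matrix.loc[rows]
    kept.index = pd.Index(symbols, name="gene")
    return kept.groupby(level=0, sort=False).mean()


def gene_entropy(values: np.ndarray, n_bins: int = ENTROPY_BINS) -> float:
    """Histogram entropy (bits) of one gene over ``n_bins`` equal-width
    bins spanning the gene's own range; a constant gene has entropy 0."""
    values = np.asarray(values, dtype=float)
    if values.max() == values.min():
        return 0.0
    hist, _ = np.histogram(values, bins=n_bins,
                           range=(values.min(), values.max()))
    p = hist / hist.sum()
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def filter_genes(expression: pd.DataFrame, q: float = 0.25
                 ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Sequential variance / mean-expression / entropy quartile filters.

    Each stage recomputes its q-quantile on the current survivors and
    drops genes strictly below it, so each pass removes at most a fraction
    ``q`` of the genes it sees.  Returns the surviving matrix (original
    gene order preserved) and per-stage removal counts.
    """
    if expression.shape[1] < 2:
        raise ValueError("gene filtering needs at least 2 patients")
    if expression.shape[0] < 4:
        raise ValueError("gene filtering needs at least 4 genes")

    counts: dict[str, int] = {"input": expression.shape[0]}
    current = expression

    def _cut(stat: pd.Series, name: str) -> pd.DataFrame:
        nonlocal current
        threshold = stat.quantile(q)
        keep = stat >= threshold
        counts[f"removed_{name}"] = int((~keep).sum())
        survivors = current.loc[keep]
        if survivors.shape[0] < 4:
            raise ValueError(
                f"fewer than 4 genes survive the {name} filter"
            )
        current = survivors
        return survivors

    _cut(current.var(axis=1, ddof=1), "variance")
    _cut(current.mean(axis=1), "expression")
    ent = current.apply(lambda row: gene_entropy(row.to_numpy()), axis=1)
    _cut(ent, "entropy")
    counts["survivors"] = current.shape[0]
    return current, counts


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    """Genes x patients TSV with a leading gene-symbol column."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_probe_map(path: str | Path) -> dict[str, list[str]]:
    """Two-column TSV (probe, gene symbol); repeated probes accumulate."""
    mapping: dict[str, list[str]] = {}
    df = pd.read_csv(path, sep="\t", header=None, names=["probe", "gene"])
    for probe, gene in df.itertuples(index=False):
        mapping.setdefault(str(probe), []).append(str(gene))
    return mapping
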