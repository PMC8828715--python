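"""Patient stratification by signature and association with tumour T stage.

Patients are clustered on the z-scored signature feature matrix with
k-means (best of several seeded restarts), and the cluster labels are
tested for independence from the ordinal T stage with a plain Pearson
chi-squared test on the clusters x stages contingency table.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.cluster import KMeans

T_STAGE_ORDER = ("Tis", "T1", "T2", "T3", "T4")


def validate_clinical(clinical: pd.DataFrame) -> pd.DataFrame:
    """Check patient uniqueness and the allowed T-stage vocabulary."""
    if clinical["patient_id"].duplicated().any():
        raise ValueError("duplicate patient_ids in clinical table")
    bad = set(clinical["t_stage"]) - set(T_STAGE_ORDER)
    if bad:
        raise ValueError(f"unknown T stages: {sorted(bad)}")
    return clinical


def zscore_table(sig_matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-feature z-scores across patients (column order preserved).

    Zero-dispersion features are set to all-zero with a warning rather
    than propagating NaNs into the heatmap export.
    """
    if sig_matrix.shape[0] < 2:
        raise ValueError("z-scores need at least 2 patients")
    mu = sig_matrix.mean(axis=0)
    sd = sig_matrix.std(axis=0, ddof=0)
    degenerate = sd == 0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} constant feature(s) z-scored to 0",
            stacklevel=2,
        )
        sd = sd.mask(degenerate, 1.0)
    z = (sig_matrix - mu) / sd
    return z.mask(pd.DataFrame(
        np.broadcast_to(degenerate.to_numpy(), z.shape),
        index=z.index, columns=z.columns), 0.0)


def cluster_patients(sig_matrix: pd.DataFrame, k: int = 3,
                     restarts: int = 10, max_iter: int = 1000,
                     seed: int = 0) -> np.ndarray:
    """k-means on z-scored signature columns, best of ``restarts`` seeded
    initialisations by within-cluster sum of squares."""
    if sig_matrix.shape[1] == 0:
        raise ValueError("signature not generated: no features to cluster on")
    if k > sig_matrix.shape[0]:
        raise ValueError("k exceeds the number of patients")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        Z = zscore_table(sig_matrix).to_numpy()
    km = KMeans(n_clusters=k, n_init=restarts, max_iter=max_iter,
                random_state=seed, algorithm="lloyd")
    return km.fit_predict(Z)


def chi2_stage_association(labels: np.ndarray, clinical: pd.DataFrame
                           ) -> tuple[float, int, float]:
    """Pearson chi-squared test of independence between cluster labels and
    observed T stages; empty stage categories are dropped before computing
    the degrees of freedom."""
    validate_clinical(clinical)
    stages = pd.Categorical(clinical["t_stage"], categories=T_STAGE_ORDER)
    table = pd.crosstab(pd.Series(labels, name="cluster"), stages)
    table = table.loc[table.sum(axis=1) > 0, table.sum(axis=0) > 0]
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError(
            f"degenerate contingency table {table.shape}: need >=2 clusters "
            "and >=2 observed stages"
        )
    chi2, p, df, _ = sps.chi2_contingency(table.to_numpy(), correction=False)
    return float(chi2), int(df), float(p)
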