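"""Reproducibility and group-comparison statistics.

Standardized PCA of descriptor tables, inter/intra-assay reproducibility
via the standard deviation of per-experiment means (SDm, in percent of
the grand mean), and Welch-corrected two-sample t tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.decomposition import PCA

log = logging.getLogger(__name__)


@dataclass
class PCAResult:
    scores: pd.DataFrame            # samples x components
    loadings: pd.DataFrame          # parameters x components
    explained_variance: np.ndarray  # eigenvalues of the standardized data
    explained_variance_ratio: np.ndarray
    dropped: list                   # zero-variance parameters removed


def pca_descriptors(table: pd.DataFrame, n_components: int = 2) -> PCAResult:
    """PCA of a parameter table after per-parameter z-standardization.

    Columns are centred and scaled to unit sample variance (zero-variance
    columns are dropped with a log message), so the eigenvalues sum to the
    number of retained parameters.  Component signs are fixed by making the
    largest-magnitude loading of each component positive.
    """
    numeric = table.select_dtypes(include=[np.number])
    if len(numeric) < 2:
        raise ValueError("PCA needs at least 2 rows")
    if numeric.isna().any().any():
        raise ValueError("PCA input must not contain missing values")
    sd = numeric.std(ddof=1)
    dropped = list(sd.index[(sd == 0) | ~np.isfinite(sd)])
    if dropped:
        log.info("dropping zero-variance parameters: %s", dropped)
    kept = numeric.drop(columns=dropped)
    if kept.shape[1] == 0:
        raise ValueError("no parameters with variance left")
    z = (kept - kept.mean()) / kept.std(ddof=1)
    n_components = min(n_components, z.shape[1], len(z) - 1)
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(z.to_numpy())
    loadings = pca.components_.T.copy()
    # deterministic sign: largest-|loading| entry of each component positive
    for j in range(loadings.shape[1]):
        k = np.argmax(np.abs(loadings[:, j]))
        if loadings[k, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    comp_names = [f"PC{j + 1}" for j in range(loadings.shape[1])]
    return PCAResult(
        scores=pd.DataFrame(scores, index=table.index, columns=comp_names),
        loadings=pd.DataFrame(loadings, index=kept.columns, columns=comp_names),
        explained_variance=pca.explained_variance_.copy(),
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
        dropped=dropped,
    )


def interassay_sdm(
    table: pd.DataFrame, experiment_col: str = "experiment"
) -> pd.DataFrame:
    """Per-parameter SDm: SD of per-experiment means over the grand mean, %.

    The grand mean is the mean of the experiment means; parameters whose
    grand mean is zero are flagged undefined rather than reported.
    """
    if experiment_col not in table.columns:
        raise ValueError(f"missing experiment column {experiment_col!r}")
    groups = table.groupby(experiment_col)
    if groups.ngroups < 2:
        raise ValueError("SDm needs >= 2 experiments")
    means = groups.mean(numeric_only=True)
    rows = []
    for col in means.columns:
        m = means[col].to_numpy(dtype=float)
        grand = float(m.mean())
        if grand == 0 or not np.isfinite(grand):
            rows.append({"parameter": col, "sdm_pct": np.nan, "undefined": True})
            continue
        rows.append(
            {
                "parameter": col,
                "sdm_pct": float(np.std(m, ddof=1) / abs(grand) * 100.0),
                "undefined": False,
            }
        )
    return pd.DataFrame(rows)


def welch_ttest(a, b) -> dict:
    """Welch two-sample t test with Satterthwaite degrees of freedom."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = len(a), len(b)
    se2 = va / na + vb / nb
    if se2 == 0:
        return {"t": 0.0, "df": float(na + nb - 2), "p": 1.0}
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = float(2.0 * sps.t.sf(abs(t), df=df))
    return {"t": float(t), "df": float(df), "p": p}
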