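"""Feature reduction: variance, pairwise correlation and collinearity filters.

Image feature banks are massively redundant; before embedding, features are
filtered in three passes:

1. **variance** -- drop columns whose variance (after optional z-scoring,
   in which case constant columns have zero variance and everything else
   has one, so the filter mainly removes constants) falls below a floor;
2. **correlation** -- a greedy pass in column order dropping any column
   whose absolute Pearson correlation with an earlier retained column
   exceeds a ceiling;
3. **collinearity** -- iteratively drop the column with the largest
   variance inflation factor (VIF, computed on z-scored columns from the
   ridge-stabilised inverse correlation matrix) until all VIFs fall below
   a ceiling.

Every dropped column is recorded with the stage that removed it and the
offending statistic, so the reduction is fully auditable and idempotent.
An optional supervised stage (off by default) keeps only features that
discriminate a binary image-class label, for screens that include control
classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class ReductionConfig:
    variance_min: float = 1e-8
    corr_max: float = 0.95
    vif_max: float = 10.0
    standardize: bool = True
    ridge: float = 1e-8

    def __post_init__(self) -> None:
        if not (0 < self.corr_max <= 1):
            raise ValueError("corr_max must be in (0, 1]")
        if self.vif_max <= 0 or self.variance_min < 0:
            raise ValueError("invalid thresholds")


@dataclass
class ReducedFeatureMatrix:
    """Retained matrix plus a per-dropped-feature provenance table."""

    matrix: pd.DataFrame
    provenance: pd.DataFrame  # columns: feature, dropped_by, statistic_value
    config: ReductionConfig = field(default_factory=ReductionConfig)

    @property
    def retained(self) -> list[str]:
        return list(self.matrix.columns)

    @property
    def dropped(self) -> list[str]:
        return self.provenance["feature"].tolist()


def _zscore(df: pd.DataFrame) -> pd.DataFrame:
    sd = df.std(ddof=1)
    sd = sd.where(sd > 0, 1.0)
    return (df - df.mean()) / sd


def drop_low_variance(
    matrix: pd.DataFrame, variance_min: float = 1e-8, standardize: bool = False
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove columns with variance (ddof=1) below ``variance_min``.

    With ``standardize`` the variance is taken on z-scored columns, where
    it is exactly 0 for constants and 1 otherwise -- the pipeline default,
    which makes this stage a constant-column filter.
    """
    if len(matrix) < 2:
        raise ValueError("variance filter needs at least 2 rows")
    base = matrix
    var = (_zscore(matrix) if standardize else matrix).var(ddof=1)
    # z-scoring maps constant columns to exactly 0 variance
    const = matrix.std(ddof=1) == 0
    var = var.where(~const, 0.0)
    dropped = var.index[var < variance_min]
    prov = pd.DataFrame({
        "feature": dropped,
        "dropped_by": "variance",
        "statistic_value": var[dropped].to_numpy(),
    })
    return base.drop(columns=dropped), prov


def drop_correlated(
    matrix: pd.DataFrame, corr_max: float = 0.95
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Greedy correlation filter in column (manifest) order."""
    if len(matrix) < 3:
        raise ValueError("correlation filter needs at least 3 rows")
    cols = list(matrix.columns)
    X = matrix.to_numpy(dtype=float)
    sd = X.std(axis=0)
    Xc = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    n = len(matrix)
    kept: list[int] = []
    dropped: list[tuple[str, float]] = []
    for j in range(len(cols)):
        if kept:
            r = np.abs(Xc[:, kept].T @ Xc[:, j]) / n
            worst = float(r.max())
            if worst > corr_max:
                dropped.append((cols[j], worst))
                continue
        kept.append(j)
    prov = pd.DataFrame(
        {"feature": [d[0] for d in dropped],
         "dropped_by": "correlation",
         "statistic_value": [d[1] for d in dropped]}
    )
    return matrix.iloc[:, kept], prov


def variance_inflation(matrix: pd.DataFrame, ridge: float = 1e-8) -> pd.Series:
    """VIF per column from the ridge-stabilised inverse correlation matrix."""
    if matrix.shape[1] <= 1:
        return pd.Series(1.0, index=matrix.columns)
    Z = _zscore(matrix).to_numpy(dtype=float)
    R = np.corrcoef(Z, rowvar=False)
    R = np.nan_to_num(R, nan=0.0)
    np.fill_diagonal(R, 1.0)
    inv = np.linalg.inv(R + ridge * np.eye(R.shape[0]))
    return pd.Series(np.diag(inv), index=matrix.columns)


def drop_collinear(
    matrix: pd.DataFrame, vif_max: float = 10.0, ridge: float = 1e-8
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Iteratively drop the highest-VIF column until all VIF <= vif_max."""
    out = matrix
    dropped: list[tuple[str, float]] = []
    while out.shape[1] > 1:
        vif = variance_inflation(out, ridge=ridge)
        worst = vif.idxmax()
        if vif[worst] <= vif_max:
            break
        dropped.append((worst, float(vif[worst])))
        out = out.drop(columns=[worst])
    prov = pd.DataFrame(
        {"feature": [d[0] for d in dropped],
         "dropped_by": "collinearity",
         "statistic_value": [d[1] for d in dropped]}
    )
    return out, prov


def discriminative_filter(
    matrix: pd.DataFrame, labels: np.ndarray, alpha: float = 0.05
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Optional supervised stage: keep features separating two classes.

    Welch t-test per feature against a binary label; features whose p-value
    exceeds ``alpha`` are dropped.  Off by default in
    :func:`reduce_features` (the typical probe screen has no control-image
    classes).
    """
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError("discriminative filter needs a binary label")
    a = matrix[labels == classes[0]]
    b = matrix[labels == classes[1]]
    _, p = stats.ttest_ind(a, b, equal_var=False)
    p = np.nan_to_num(p, nan=1.0)
    dropped = matrix.columns[p > alpha]
    prov = pd.DataFrame({
        "feature": dropped,
        "dropped_by": "discriminative",
        "statistic_value": p[p > alpha],
    })
    return matrix.drop(columns=dropped), prov


def reduce_features(
    matrix: pd.DataFrame,
    config: ReductionConfig | None = None,
    labels: np.ndarray | None = None,
) -> ReducedFeatureMatrix:
    """Run the full reduction pipeline: variance -> correlation -> VIF.

    ``labels`` switches on the optional supervised stage after the three
    unsupervised filters.  Raises if nothing survives (thresholds should
    then be relaxed).
    """
    config = config or ReductionConfig()
    m1, p1 = drop_low_variance(matrix, config.variance_min, config.standardize)
    m2, p2 = drop_correlated(m1, config.corr_max)
    m3, p3 = drop_collinear(m2, config.vif_max, config.ridge)
    provs = [p1, p2, p3]
    if labels is not None:
        m3, p4 = discriminative_filter(m3, labels)
        provs.append(p4)
    if m3.shape[1] == 0:
        raise ValueError(
            "feature reduction removed every column; relax variance_min, "
            "corr_max or vif_max"
        )
    prov = pd.concat(provs, ignore_index=True)
    assert len(prov) + m3.shape[1] == matrix.shape[1]
    return ReducedFeatureMatrix(matrix=m3, provenance=prov, config=config)
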