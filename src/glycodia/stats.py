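"""Differential abundance statistics and PCA for proteins and glycoforms.

Per-analyte two-sided t-tests with log2 fold changes stand behind both
contrast functions; proteins are tested on log2 intensities at a
stringent default threshold (1e-5), glycoforms on relative-abundance
fractions at 0.05.  The default is the pooled-variance (Student) test —
with technical triplicates the group variances are comparable, and at
n=3 the Welch approximation is markedly conservative — with ``welch=True``
available where unequal variances are expected.  Raw p-values are
reported; a Benjamini-Hochberg column is emitted for information only
and is not used for calling significance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.decomposition import PCA

from .quant import AbundanceMatrix, GlycoformProfile

logger = logging.getLogger(__name__)

__all__ = [
    "ContrastResult",
    "glycoform_contrast",
    "protein_contrast",
    "pca_scores",
    "contrasts_to_frame",
]

DEFAULT_GLYCOFORM_ALPHA = 0.05
DEFAULT_PROTEIN_ALPHA = 1e-5


@dataclass(frozen=True)
class ContrastResult:
    """One analyte's B-vs-A comparison."""

    analyte: str
    log2fc: float  # log2(mean_B / mean_A)
    p: float  # two-sided t-test
    n_a: int
    n_b: int
    significant: bool


def _ttest(a: np.ndarray, b: np.ndarray, welch: bool) -> float:
    """Two-sided t-test p-value; degenerate zero-variance cases handled."""
    if np.var(a) == 0 and np.var(b) == 0:
        return 1.0 if np.mean(a) == np.mean(b) else 0.0
    res = sps.ttest_ind(b, a, equal_var=not welch)
    return float(res.pvalue)


def _log2fc(mean_a: float, mean_b: float) -> float:
    if mean_a > 0 and mean_b > 0:
        return float(np.log2(mean_b / mean_a))
    if mean_a == mean_b:
        return 0.0
    return float(np.inf if mean_b > mean_a else -np.inf)


def _contrast_frame(
    values: pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
    alpha: float,
    welch: bool = False,
    log_scale: bool = False,
) -> list[ContrastResult]:
    # log_scale: the values are already log2, so the fold change is a
    # difference of means rather than a log of the mean ratio
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need >= 2 replicates per group")
    out = []
    for analyte, row in values.iterrows():
        a = row[group_a].to_numpy(dtype=float)
        b = row[group_b].to_numpy(dtype=float)
        a = a[~np.isnan(a)]
        b = b[~np.isnan(b)]
        if len(a) < 2 or len(b) < 2:
            continue
        p = _ttest(a, b, welch)
        name = analyte if isinstance(analyte, str) else "/".join(map(str, analyte))
        fc = (
            float(b.mean() - a.mean())
            if log_scale
            else _log2fc(float(a.mean()), float(b.mean()))
        )
        out.append(
            ContrastResult(
                analyte=name,
                log2fc=fc,
                p=p,
                n_a=len(a),
                n_b=len(b),
                significant=p < alpha,
            )
        )
    return out


def glycoform_contrast(
    profiles: GlycoformProfile,
    group_a: list[str],
    group_b: list[str],
    alpha: float = DEFAULT_GLYCOFORM_ALPHA,
    log_fractions: bool = False,
    welch: bool = False,
) -> list[ContrastResult]:
    """Two-sided t-test per glycoform on relative-abundance fractions.

    ``log_fractions`` switches the test to log-transformed fractions
    (zeros dropped); the default tests the fractions themselves.
    ``welch`` drops the pooled-variance assumption.
    """
    values = profiles.fractions
    if log_fractions:
        values = values.where(values > 0)
        n_dropped = int(values.isna().sum().sum() - profiles.fractions.isna().sum().sum())
        if n_dropped:
            logger.info("log transform dropped %d zero fraction(s)", n_dropped)
        values = np.log2(values)
        results = _contrast_frame(
            values, group_a, group_b, alpha, welch, log_scale=True
        )
        # fold change should stay on the fraction scale
        lin = {
            r.analyte: r
            for r in _contrast_frame(profiles.fractions, group_a, group_b, alpha)
        }
        return [
            ContrastResult(
                analyte=r.analyte,
                log2fc=lin[r.analyte].log2fc if r.analyte in lin else r.log2fc,
                p=r.p,
                n_a=r.n_a,
                n_b=r.n_b,
                significant=r.significant,
            )
            for r in results
        ]
    return _contrast_frame(values, group_a, group_b, alpha, welch)


def protein_contrast(
    m: AbundanceMatrix,
    group_a: list[str],
    group_b: list[str],
    alpha: float = DEFAULT_PROTEIN_ALPHA,
    welch: bool = False,
) -> list[ContrastResult]:
    """Two-sided t-test per protein on log2 intensities.

    Zero intensities cannot be log-transformed and are dropped (logged);
    the input should already be normalized (e.g. to total abundance).
    """
    values = m.data.where(m.data > 0)
    n_zero = int(m.data.le(0).sum().sum())
    if n_zero:
        logger.info("dropped %d zero intensity value(s) before log transform", n_zero)
    logged = np.log2(values)
    # the difference of log2 means is the log2 geometric-mean ratio
    return _contrast_frame(logged, group_a, group_b, alpha, welch, log_scale=True)


def pca_scores(
    m: AbundanceMatrix | pd.DataFrame,
    n_components: int = 2,
    log_transform: bool = False,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Principal component scores of the samples.

    Rows of the input are analytes, columns samples; rows containing
    missing values are dropped (logged).  Returns per-sample scores and
    the explained-variance fractions, descending.
    """
    data = m.data if isinstance(m, AbundanceMatrix) else m
    n_samples = data.shape[1]
    if n_samples < 2 or n_samples < n_components:
        raise ValueError("need at least as many samples as components (>= 2)")
    if log_transform:
        data = np.log2(data.where(data > 0))
    complete = data.dropna(axis=0)
    if len(complete) < len(data):
        logger.info(
            "dropped %d analyte row(s) with missing values before PCA",
            len(data) - len(complete),
        )
    x = complete.to_numpy(dtype=float).T  # samples as observations
    if np.allclose(x.var(axis=0), 0):
        logger.warning("degenerate PCA input: all samples identical")
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(x)
    cols = [f"PC{i + 1}" for i in range(n_components)]
    return (
        pd.DataFrame(scores, index=data.columns, columns=cols),
        pca.explained_variance_ratio_,
    )


def contrasts_to_frame(results: list[ContrastResult]) -> pd.DataFrame:
    """Tabulate contrasts with an informational Benjamini-Hochberg column."""
    df = pd.DataFrame(
        {
            "analyte": [r.analyte for r in results],
            "log2fc": [r.log2fc for r in results],
            "p": [r.p for r in results],
            "n_a": [r.n_a for r in results],
            "n_b": [r.n_b for r in results],
            "significant": [r.significant for r in results],
        }
    )
    if len(df):
        df["p_bh"] = sps.false_discovery_control(df["p"].to_numpy(), method="bh")
    else:
        df["p_bh"] = []
    return df
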