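"""Prediction accuracy, bias, and genetic-architecture summaries.

Accuracy is the Pearson correlation between GEBV and the validation
phenotype (trait deviations / daughter trait deviations); bias is the
slope of the regression of phenotype on GEBV (1 = unbiased).
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def accuracy_bias(gebv, phenotype):
    """(Pearson correlation, regression slope of phenotype on GEBV)."""
    gebv = np.asarray(gebv, float)
    phenotype = np.asarray(phenotype, float)
    if gebv.shape != phenotype.shape or gebv.ndim != 1:
        raise ValueError("gebv and phenotype must be equal-length vectors")
    if gebv.shape[0] < 3:
        raise ValueError("need at least 3 paired observations")
    if np.var(gebv) == 0:
        raise ValueError("GEBV has zero variance")
    acc = float(stats.pearsonr(gebv, phenotype).statistic)
    slope = float(np.cov(phenotype, gebv, ddof=1)[0, 1] / np.var(gebv, ddof=1))
    return acc, slope


def architecture_summary(summary) -> np.ndarray:
    """Percent of variants in each mixture class: column means of P x 100."""
    P = np.asarray(summary.P if hasattr(summary, "P") else summary, float)
    return P.mean(axis=0) * 100.0
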