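"""Small statistical helpers shared across modules."""

from __future__ import annotations

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

#: Combined sample size at or below which the exact Mann-Whitney null
#: distribution is enumerated instead of using the normal approximation.
EXACT_MW_MAX_N = 12


def mann_whitney_p(x, y) -> float:
    """Two-sided Mann-Whitney U p-value for two independent samples.

    Uses exact enumeration when the combined sample size is small
    (``len(x) + len(y) <= 12``) and the tie-corrected normal
    approximation otherwise.

    Raises
    ------
    ValueError
        If either sample has fewer than 3 observations.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or y.size < 3:
        raise ValueError(
            f"need >= 3 observations per group, got {x.size} and {y.size}"
        )
    method = "exact" if x.size + y.size <= EXACT_MW_MAX_N else "asymptotic"
    if method == "exact" and len(np.unique(np.r_[x, y])) < x.size + y.size:
        # exact enumeration has no tie handling; fall back
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.pvalue)


def bh_discoveries(pvalues, alpha: float) -> np.ndarray:
    """Benjamini-Hochberg discovery flags at FDR level ``alpha``.

    Returns a boolean array aligned with ``pvalues``. An empty input
    yields an empty array.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    reject, *_ = multipletests(p, alpha=alpha, method="fdr_bh")
    return np.asarray(reject, dtype=bool)
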