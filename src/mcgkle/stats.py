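"""Rank statistics shared by the segment and classification stages."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = ["MannWhitneyResult", "mann_whitney_u"]


@dataclass(frozen=True)
class MannWhitneyResult:
    u: float  # U statistic of the first sample
    p_value: float  # two-sided
    method: str  # "exact" | "asymptotic"


def mann_whitney_u(x, y, exact_max_n: int = 20) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test.

    The exact null distribution is used whenever both groups have at most
    ``exact_max_n`` observations and the combined sample is tie-free (the
    exact distribution assumes no ties); otherwise the normal approximation
    with continuity and tie correction is used.  This rule makes p-values
    bit-reproducible.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    combined = np.concatenate([x, y])
    has_ties = len(np.unique(combined)) < len(combined)
    if len(x) <= exact_max_n and len(y) <= exact_max_n and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method,
                           use_continuity=True)
    return MannWhitneyResult(u=float(res.statistic), p_value=float(res.pvalue),
                             method=method)
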