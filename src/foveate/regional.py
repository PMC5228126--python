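"""Non-phylogenetic inference: the four-region slope comparison.

A one-way fixed-effects linear model of transect slope on retinal axis
(nasal / temporal / dorsal / ventral), with the global F test and Tukey
HSD pairwise comparisons from the studentized-range distribution.  The
within-species slopes are treated as independent observations and
unbalanced tables are accepted (degrees of freedom follow the observed
counts).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class RegionComparison:
    """One-way comparison of gradient slopes among retinal regions."""

    means: dict
    ses: dict
    F: float
    df: tuple
    p_global: float
    pairwise: pd.DataFrame  # symmetric matrix of Tukey-adjusted p-values

    def to_dict(self) -> dict:
        return {
            "means": self.means,
            "ses": self.ses,
            "F": self.F,
            "df": list(self.df),
            "p_global": self.p_global,
            "pairwise": {
                a: {b: float(self.pairwise.loc[a, b]) for b in self.pairwise.columns}
                for a in self.pairwise.index
            },
        }


def tukey_hsd(group_means, pooled_variance, group_sizes) -> pd.DataFrame:
    """Tukey HSD adjusted pairwise p-values.

    For groups i, j the studentized-range statistic is
    q = |m_i - m_j| / sqrt((s2_p / 2) * (1/n_i + 1/n_j)) and the adjusted
    p-value is the upper tail of the studentized range distribution with
    k groups and N - k residual degrees of freedom.  With two groups this
    reduces exactly to the pooled two-sample t-test (q = t * sqrt(2)).
    """
    means = pd.Series(group_means, dtype=float)
    sizes = pd.Series(group_sizes, dtype=int).loc[means.index]
    k = len(means)
    if k < 2:
        raise ValueError("need at least 2 groups")
    df_resid = int(sizes.sum() - k)
    out = pd.DataFrame(np.ones((k, k)), index=means.index, columns=means.index)
    zero_var = pooled_variance <= 0
    if zero_var and means.nunique() > 1:
        warnings.warn(
            "zero pooled variance with unequal group means; pairwise p-values "
            "for separated pairs reported as 0"
        )
    for a, b in itertools.combinations(means.index, 2):
        diff = abs(means[a] - means[b])
        if zero_var:
            p = 1.0 if diff == 0 else 0.0
        else:
            se = np.sqrt(pooled_variance / 2 * (1 / sizes[a] + 1 / sizes[b]))
            q = diff / se
            p = float(stats.studentized_range.sf(q, k, df_resid))
        out.loc[a, b] = out.loc[b, a] = p
    return out


def region_glm(slopes: pd.DataFrame) -> RegionComparison:
    """One-way linear model of slope on retinal axis with Tukey tests.

    Parameters
    ----------
    slopes : DataFrame
        Species x axis table of gradient slopes; an ``overall`` column, if
        present, is ignored.  Missing cells are allowed (unbalanced
        design); each axis needs at least 2 observations.

    Returns
    -------
    RegionComparison with group means +- SE, the global F over
    (k - 1, N - k) degrees of freedom, and Tukey-adjusted pairwise
    p-values.
    """
    cols = [c for c in slopes.columns if c != "overall"]
    if len(cols) < 2:
        raise ValueError("need at least 2 axes")
    groups = {c: slopes[c].dropna().to_numpy(dtype=float) for c in cols}
    for c, v in groups.items():
        if v.size < 2:
            raise ValueError(f"axis {c!r} has fewer than 2 observations")
    sizes = {c: v.size for c, v in groups.items()}
    means = {c: float(v.mean()) for c, v in groups.items()}
    ses = {c: float(v.std(ddof=1) / np.sqrt(v.size)) for c, v in groups.items()}
    k = len(cols)
    N = sum(sizes.values())
    grand = sum(v.sum() for v in groups.values()) / N
    ss_between = sum(sizes[c] * (means[c] - grand) ** 2 for c in cols)
    ss_within = sum(float(((v - means[c]) ** 2).sum()) for c, v in groups.items())
    df_b, df_w = k - 1, N - k
    ms_within = ss_within / df_w
    if ms_within == 0:
        F = 0.0 if ss_between == 0 else np.inf
        p = 1.0 if ss_between == 0 else 0.0
    else:
        F = (ss_between / df_b) / ms_within
        p = float(stats.f.sf(F, df_b, df_w))
    pairwise = tukey_hsd(means, ms_within, sizes)
    return RegionComparison(
        means=means, ses=ses, F=float(F), df=(df_b, df_w), p_global=p,
        pairwise=pairwise,
    )
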