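"""Group summaries, two-sample tests, one-way ANOVA and collagen composition.

Cohort tables carry one row per tested artery segment (a donor may contribute
several segments), with pathology group, donor age, sex and measured
unloaded dimensions.  Summaries report mean, sample SD (n-1 denominator) and
SEM.  Dimensions are summarized over segments; ages over donors — the two
units differ, so summaries take an explicit ``unit`` argument upstream.

Proteomic collagen abundances (label-free quantitation signal) are
re-expressed per sample as a percentage of the sample's total collagen, then
compared between groups with Student t-tests under Bonferroni correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

GROUPS = ("control", "early", "intermediate", "advanced")


@dataclass(frozen=True)
class GroupSummary:
    n: int
    mean: float
    sd: float | None      # sample SD (n-1); None when n == 1
    sem: float | None

    def format(self, digits: int = 1) -> str:
        if self.sd is None:
            return f"{self.mean:.{digits}f}"
        return f"{self.mean:.{digits}f} ± {self.sd:.{digits}f}"


def group_summary(values) -> GroupSummary:
    """Mean, sample SD and SEM of one group's values."""
    vals = np.asarray(list(values), dtype=float)
    if vals.size == 0:
        raise ValueError("cannot summarize an empty group")
    mean = float(vals.mean())
    if vals.size == 1:
        return GroupSummary(n=1, mean=mean, sd=None, sem=None)
    sd = float(vals.std(ddof=1))
    return GroupSummary(n=int(vals.size), mean=mean, sd=sd, sem=sd / math.sqrt(vals.size))


def ttest_two_sample(x, y, variance_assumption: str = "pooled") -> tuple[float, float]:
    """Two-sided two-sample t-test; pooled-variance Student by default."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs n >= 2")
    if variance_assumption not in ("pooled", "welch"):
        raise ValueError(f"unknown variance assumption {variance_assumption!r}")
    res = stats.ttest_ind(x, y, equal_var=(variance_assumption == "pooled"))
    t, p = float(res.statistic), float(res.pvalue)
    if np.isnan(t):  # zero variance in both samples
        return (0.0, 1.0) if np.isclose(x.mean(), y.mean()) else (math.inf, 0.0)
    return t, p


def anova_oneway(groups) -> tuple[float, float]:
    """One-way ANOVA F-test across >= 2 groups."""
    arrays = [np.asarray(list(g), dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    if any(a.size < 2 for a in arrays):
        raise ValueError("each group needs n >= 2")
    if all(np.ptp(a) == 0 for a in arrays):
        # zero within-group variance: F undefined; identical means => no effect
        means = [a.mean() for a in arrays]
        return (0.0, 1.0) if np.ptp(means) == 0 else (math.inf, 0.0)
    res = stats.f_oneway(*arrays)
    return float(res.statistic), float(res.pvalue)


def relative_collagen_abundance(table: pd.DataFrame) -> pd.DataFrame:
    """Per-sample collagen percentages of total collagen abundance.

    ``table`` holds one row per sample and one column per collagen type
    (non-numeric columns such as ``group`` are carried through unchanged).
    Each collagen's value becomes 100 * abundance / (sample's total collagen).
    """
    numeric = table.select_dtypes(include=[np.number])
    if numeric.empty:
        raise ValueError("no collagen abundance columns found")
    if (numeric.to_numpy() < 0).any():
        raise ValueError("abundances must be non-negative")
    totals = numeric.sum(axis=1)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0].tolist()
        raise ValueError(f"zero total collagen abundance in samples {bad}")
    out = table.copy()
    out[numeric.columns] = 100.0 * numeric.div(totals, axis=0)
    return out


def bonferroni(p_values, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Bonferroni-adjusted p-values (min(1, p*m)) and significance flags."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        raise ValueError("no p-values supplied")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    _, p_adj, _, _ = multipletests(p, alpha=alpha, method="bonferroni")
    return p_adj, p_adj < alpha


def summarize_cohort(table: pd.DataFrame) -> pd.DataFrame:
    """Per-group Average rows for a cohort table.

    Ages are summarized over donors (one value per ``donor_id``); the
    dimension columns (``thickness_mm``, ``inner_diameter_mm``,
    ``outer_diameter_mm``) over segments.  Returns one row per group with
    ``<col>_mean`` / ``<col>_sd`` columns.
    """
    rows = []
    for grp, sub in table.groupby("group", sort=False):
        ages = sub.drop_duplicates("donor_id")["age"]
        rec: dict[str, float | str | int] = {"group": grp, "n_donors": len(ages),
                                             "n_segments": len(sub)}
        s = group_summary(ages)
        rec["age_mean"], rec["age_sd"] = s.mean, s.sd
        for col in ("thickness_mm", "inner_diameter_mm", "outer_diameter_mm"):
            s = group_summary(sub[col])
            rec[f"{col}_mean"], rec[f"{col}_sd"] = s.mean, s.sd
        rows.append(rec)
    return pd.DataFrame(rows)
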