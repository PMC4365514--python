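"""Trial-level statistics for balanced genotype x block layouts.

The trial is a split-plot design: plot size (row number, 1-4) is the
whole-plot factor and genotype the sub-plot factor, replicated in four
blocks.  Within each (campaign, rows-per-plot) stratum the data form a
balanced two-way genotype x block table with one observation per cell, so the
variance components of the random-genotype / fixed-block model have exact
ANOVA (method-of-moments) estimators:

    sigma2_eps = MS_residual
    sigma2_gen = (MS_genotype - MS_residual) / r        (clamped at 0)

and the repeatability (broad-sense heritability of plot means) is

    h2 = sigma2_gen / (sigma2_gen + sigma2_eps / r)

with r the number of blocks.  For balanced data these coincide in
expectation with the REML estimates; unbalanced layouts are rejected.

Also provided: Pearson correlation with the conventional significance codes
(*** p<0.001, ** p<0.01, * p<0.05, ns otherwise) and the Tukey honest
significant difference with a compact letter display.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    InsufficientReplicationError,
    UnbalancedDesignError,
    UndefinedCorrelationError,
)

__all__ = [
    "VarianceComponents",
    "estimate_components",
    "repeatability_profile",
    "correlate",
    "significance_code",
    "hsd_compare",
]

TABLE_COLUMNS = ["genotype", "block", "rows_per_plot", "campaign", "trait", "value"]


@dataclass(frozen=True)
class VarianceComponents:
    """ANOVA variance components and repeatability for one stratum."""

    sigma2_gen: float
    sigma2_eps: float
    n_blocks: int
    n_genotypes: int
    h2: float
    ms_gen: float
    ms_res: float
    df_res: int


def _pivot_balanced(sub: pd.DataFrame) -> pd.DataFrame:
    """Genotype x block value matrix; raise if the layout is not balanced."""
    if sub.empty:
        raise UnbalancedDesignError("no data for the requested stratum")
    counts = sub.groupby(["genotype", "block"]).size()
    if (counts != 1).any():
        bad = counts[counts != 1].index.tolist()
        raise UnbalancedDesignError(
            f"expected exactly one observation per (genotype, block); offending "
            f"cells: {bad[:5]}{'...' if len(bad) > 5 else ''} — the balanced "
            f"estimator does not apply, use a general mixed model instead"
        )
    wide = sub.pivot(index="genotype", columns="block", values="value")
    if wide.isna().any().any():
        missing = [
            (g, b) for (g, b) in itertools.product(wide.index, wide.columns)
            if pd.isna(wide.loc[g, b])
        ]
        raise UnbalancedDesignError(f"missing cells: {missing[:5]}")
    return wide


def estimate_components(
    table: pd.DataFrame,
    trait: str,
    campaign=None,
    rows_per_plot=None,
) -> VarianceComponents:
    """Variance components and repeatability for one stratum.

    Blocks are treated as fixed (removed via the two-way ANOVA decomposition)
    and genotypes as random.  Requires a balanced layout: one observation per
    genotype x block cell.

    Parameters
    ----------
    table : DataFrame
        Long trait table with columns genotype, block, rows_per_plot,
        campaign, trait, value.
    trait, campaign, rows_per_plot
        Stratum selectors; ``campaign``/``rows_per_plot`` may be None when
        the table already holds a single stratum.
    """
    sub = table[table["trait"] == trait]
    if campaign is not None:
        sub = sub[sub["campaign"] == campaign]
    if rows_per_plot is not None:
        sub = sub[sub["rows_per_plot"] == rows_per_plot]
    wide = _pivot_balanced(sub)
    y = wide.to_numpy(dtype=float)
    g, r = y.shape
    if r < 2:
        raise InsufficientReplicationError("need >= 2 blocks to estimate residual")
    if g < 2:
        raise UnbalancedDesignError("need >= 2 genotypes")

    grand = y.mean()
    gen_means = y.mean(axis=1)
    block_means = y.mean(axis=0)
    ss_gen = r * float(((gen_means - grand) ** 2).sum())
    resid = y - gen_means[:, None] - block_means[None, :] + grand
    ss_res = float((resid**2).sum())
    df_res = (g - 1) * (r - 1)
    ms_gen = ss_gen / (g - 1)
    ms_res = ss_res / df_res
    sigma2_eps = ms_res
    sigma2_gen = max(0.0, (ms_gen - ms_res) / r)
    denom = sigma2_gen + sigma2_eps / r
    h2 = sigma2_gen / denom if denom > 0 else 0.0
    return VarianceComponents(
        sigma2_gen=sigma2_gen,
        sigma2_eps=sigma2_eps,
        n_blocks=r,
        n_genotypes=g,
        h2=h2,
        ms_gen=ms_gen,
        ms_res=ms_res,
        df_res=df_res,
    )


def repeatability_profile(
    table: pd.DataFrame, trait: str, campaign_degree_days: dict | None = None
) -> pd.DataFrame:
    """Repeatability per (campaign, rows_per_plot) stratum.

    Returns a long table with columns campaign, degree_days (if a mapping is
    given), rows_per_plot, h2, sigma2_gen, sigma2_eps.  Strata that cannot be
    estimated (missing or unbalanced) are omitted with a warning.
    """
    sub = table[table["trait"] == trait]
    if sub.empty:
        warnings.warn(f"trait {trait!r} absent from table", stacklevel=2)
        return pd.DataFrame(
            columns=["campaign", "rows_per_plot", "h2", "sigma2_gen", "sigma2_eps"]
        )
    rows = []
    for (camp, rpp), _ in sub.groupby(["campaign", "rows_per_plot"]):
        try:
            vc = estimate_components(sub, trait, campaign=camp, rows_per_plot=rpp)
        except (UnbalancedDesignError, InsufficientReplicationError) as exc:
            warnings.warn(f"stratum ({camp}, {rpp}) skipped: {exc}", stacklevel=2)
            continue
        row = {
            "campaign": camp,
            "rows_per_plot": rpp,
            "h2": vc.h2,
            "sigma2_gen": vc.sigma2_gen,
            "sigma2_eps": vc.sigma2_eps,
        }
        if campaign_degree_days is not None:
            row["degree_days"] = campaign_degree_days.get(camp)
        rows.append(row)
    return pd.DataFrame(rows)


def significance_code(p: float) -> str:
    """'***' p<0.001, '**' p<0.01, '*' p<0.05, else 'ns'."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def correlate(x, y) -> tuple[float, float, str]:
    """Pearson correlation with two-sided p (t distribution, n-2 df).

    Pairs containing NaN are dropped.  Returns ``(r, p, code)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must be paired (same length)")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise UndefinedCorrelationError("need >= 3 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("zero variance in a series")
    res = stats.pearsonr(x, y)
    r, p = float(res.statistic), float(res.pvalue)
    return r, p, significance_code(p)


def _compact_letter_display(names, different) -> dict:
    """Assign letters so that two levels share a letter iff not different.

    Insert-and-absorb algorithm on the 'not significantly different' graph:
    each letter is a maximal clique covering; greedy and adequate for the
    16-genotype scale used here.
    """
    names = list(names)
    groups: list[set] = []
    for name in names:
        placed = False
        for grp in groups:
            if all(not different[frozenset((name, other))] for other in grp):
                grp.add(name)
                placed = True
        if not placed:
            groups.append({name})
    # absorb duplicate/subset groups
    groups = [g for i, g in enumerate(groups)
              if not any(g < h for j, h in enumerate(groups) if i != j)]
    letters = {name: "" for name in names}
    for letter, grp in zip("abcdefghijklmnopqrstuvwxyz", groups):
        for name in sorted(grp, key=names.index):
            letters[name] += letter
    return letters


def hsd_compare(
    table: pd.DataFrame, trait: str, campaign=None, rows_per_plot=None, alpha=0.05
) -> pd.DataFrame:
    """Genotype means with Tukey HSD grouping letters at level ``alpha``.

    HSD = q(1-alpha; g, df_err) * sqrt(MS_err / r); pairs of genotype means
    differing by more than HSD are declared different.  Returns a DataFrame
    with columns genotype, mean, letters, plus attrs ``hsd`` and ``alpha``.
    """
    sub = table[table["trait"] == trait]
    if campaign is not None:
        sub = sub[sub["campaign"] == campaign]
    if rows_per_plot is not None:
        sub = sub[sub["rows_per_plot"] == rows_per_plot]
    wide = _pivot_balanced(sub)
    y = wide.to_numpy(dtype=float)
    g, r = y.shape
    if r < 2:
        raise InsufficientReplicationError("HSD needs >= 2 blocks")
    vc = estimate_components(sub, trait)
    if vc.ms_res > 0:
        q = stats.studentized_range.ppf(1 - alpha, g, vc.df_res)
        hsd = float(q * np.sqrt(vc.ms_res / r))
    else:
        hsd = 0.0  # noiseless limit: any distinct means differ
    means = wide.mean(axis=1)
    names = means.sort_values(ascending=False).index.tolist()
    different = {
        frozenset((a, b)): abs(means[a] - means[b]) > hsd
        for a, b in itertools.combinations(names, 2)
    }
    letters = _compact_letter_display(names, different)
    out = pd.DataFrame(
        {
            "genotype": names,
            "mean": [means[n] for n in names],
            "letters": [letters[n] for n in names],
        }
    )
    out.attrs["hsd"] = hsd
    out.attrs["alpha"] = alpha
    out.attrs["ms_res"] = vc.ms_res
    return out
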