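"""LoF classification and ST-threshold diagnostics.

Variants are tested against an empirical null: a normal distribution fitted
by moments to the function scores of the neutral variant set. One-sided
p-values in the screen's selection direction are corrected with
Benjamini-Hochberg; q-values below the screen's cutoff are called LoF.
AUC sweeps quantify pLoF/pNeut separation as the ST-activity filter rises.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Optional, Sequence, Set

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .model import PegRNADesign, SchemaError, ScreenConfig, Variant
from . import scoring


@dataclass(frozen=True)
class NullModel:
    """Normal null for neutral function scores (moment fit)."""

    mu: float
    sigma: float
    n_neutral: int


def fit_null(neutral_scores: Sequence[float], min_neutral: int = 5) -> NullModel:
    """Fit N(mu, sigma) to neutral scores: sample mean and SD (ddof=1)."""
    x = pd.Series(neutral_scores, dtype=float).dropna()
    if len(x) < min_neutral:
        raise SchemaError(
            f"need at least {min_neutral} neutral scores, got {len(x)}")
    sigma = float(x.std(ddof=1))
    if sigma == 0:
        raise SchemaError("neutral scores are identical; null SD is zero")
    return NullModel(mu=float(x.mean()), sigma=sigma, n_neutral=len(x))


def p_values(scores: pd.Series, null: NullModel,
             direction: str = "depletion",
             two_sided: bool = False) -> pd.Series:
    """Tail probabilities of the function scores under the null.

    One-sided by default: lower tail for depletion (essentiality) screens,
    upper tail for enrichment (drug-resistance) screens.
    """
    z = (pd.Series(scores, dtype=float) - null.mu) / null.sigma
    if two_sided:
        p = 2.0 * sps.norm.sf(np.abs(z))
    elif direction == "depletion":
        p = sps.norm.cdf(z)
    elif direction == "enrichment":
        p = sps.norm.sf(z)
    else:
        raise SchemaError(f"unknown direction {direction!r}")
    return pd.Series(np.minimum(p, 1.0), index=scores.index, name="p_value")


def bh_adjust(p: pd.Series) -> pd.Series:
    """Benjamini-Hochberg step-up q-values (undefined p stays undefined)."""
    p = pd.Series(p, dtype=float)
    q = pd.Series(np.nan, index=p.index, name="q_value")
    ok = p.notna()
    if ok.any():
        if ((p[ok] < 0) | (p[ok] > 1)).any():
            raise SchemaError("p-values outside [0, 1]")
        q.loc[ok] = multipletests(p[ok].values, method="fdr_bh")[1]
    return q


def call_lof(q: pd.Series, q_cutoff: float) -> pd.Series:
    """LoF iff q strictly below the cutoff."""
    q = pd.Series(q, dtype=float)
    return (q < q_cutoff) & q.notna()


def classify_variants(function_table: pd.DataFrame,
                      variants: Sequence[Variant],
                      config: ScreenConfig) -> pd.DataFrame:
    """Attach p/q-values and LoF calls to a function-score table.

    The null is fitted to the scored neutral variants; the BH family is all
    variants receiving a final function score in the screen.
    """
    table = function_table.copy()
    neutral = scoring.neutral_variant_ids(variants, config)
    scores = table.set_index("variant_id")["function_score"]
    null = fit_null(scores.loc[scores.index.isin(neutral)],
                    config.min_neutral)
    p = p_values(scores, null, config.selection_direction, config.two_sided)
    q = bh_adjust(p)
    table["p_value"] = p.values
    table["q_value"] = q.values
    table["lof_call"] = call_lof(q, config.q_cutoff).values
    return table


def auc(labels: Sequence[bool], scores: Sequence[float],
        direction: str = "depletion") -> float:
    """Probability that a random pLoF variant outscores (in the selection
    direction) a random pNeut variant; ties count half.

    ``labels`` is True for pLoF. For depletion screens lower scores indicate
    LoF, so scores are negated before ranking.
    """
    y = np.asarray(labels, dtype=bool)
    x = np.asarray(scores, dtype=float)
    if not y.any() or y.all():
        raise SchemaError("auc needs both classes non-empty")
    if direction == "depletion":
        x = -x
    elif direction != "enrichment":
        raise SchemaError(f"unknown direction {direction!r}")
    ranks = sps.rankdata(x)  # average ranks handle ties as 1/2
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    u = ranks[y].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def _auc_or_nan(function_table: pd.DataFrame, plof: Set[str],
                pneut: Set[str], direction: str) -> float:
    sub = function_table.loc[
        function_table["variant_id"].isin(plof | pneut)]
    labels = sub["variant_id"].isin(plof).values
    if len(sub) == 0 or labels.all() or not labels.any():
        return np.nan
    return auc(labels, sub["function_score"].values, direction)


def threshold_sweep(tables: Mapping[str, pd.DataFrame],
                    designs: Sequence[PegRNADesign],
                    variants: Sequence[Variant],
                    config: ScreenConfig,
                    grid: Optional[Sequence[float]] = None) -> pd.DataFrame:
    """Recompute function scores over a grid of ST-activity thresholds and
    measure pLoF/pNeut AUC at each.

    Returns columns threshold_pct, auc, n_pegrnas_retained,
    n_variants_scored. AUC is NA when either benchmark class is absent from
    the scored set.
    """
    if grid is None:
        pcts = pd.concat([t["st_editing_pre_pct"] for t in tables.values()])
        grid = sorted(pd.unique(pcts.dropna()))
    from .model import variant_sets

    neutral_ids, plof_ids = variant_sets(
        variants, config.neutral_consequences, config.plof_consequences)
    rows = []
    for t in grid:
        cfg_t = dataclasses.replace(config, st_activity_min_pct=float(t))
        refiltered = {c: scoring.apply_filters(tab, cfg_t)
                      for c, tab in tables.items()}
        n_retained = int(sum(tab["retained"].sum()
                             for tab in refiltered.values()))
        try:
            fs = scoring.function_scores(refiltered, designs, variants, cfg_t)
        except SchemaError:
            rows.append((float(t), np.nan, n_retained, 0))
            continue
        a = _auc_or_nan(fs, plof_ids, neutral_ids,
                        config.selection_direction)
        rows.append((float(t), a, n_retained, len(fs)))
    return pd.DataFrame(rows, columns=["threshold_pct", "auc",
                                       "n_pegrnas_retained",
                                       "n_variants_scored"])


def high_stringency_threshold(function_table: pd.DataFrame,
                              mean_st_editing: pd.Series,
                              variants: Sequence[Variant],
                              config: ScreenConfig,
                              grid: Optional[Sequence[float]] = None
                              ) -> Optional[float]:
    """Smallest mean-ST-editing threshold above which the pLoF and pNeut
    function-score ranges are disjoint.

    Among variants with mean ST editing >= t, the [min, max] score ranges of
    the two benchmark sets must not overlap. Returns None if no grid value
    achieves separation (including when a class empties out).
    """
    from .model import variant_sets

    neutral_ids, plof_ids = variant_sets(
        variants, config.neutral_consequences, config.plof_consequences)
    scores = function_table.set_index("variant_id")["function_score"]
    if grid is None:
        grid = sorted(pd.unique(mean_st_editing.dropna()))
    for t in sorted(grid):
        keep = mean_st_editing.index[mean_st_editing >= t]
        s = scores.loc[scores.index.isin(keep)]
        lo = s.loc[s.index.isin(plof_ids)].dropna()
        ne = s.loc[s.index.isin(neutral_ids)].dropna()
        if lo.empty or ne.empty:
            continue
        if lo.max() < ne.min() or ne.max() < lo.min():
            return float(t)
    return None
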