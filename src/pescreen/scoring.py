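"""pegRNA selection scores and per-variant function scores.

A pegRNA score is the log2 ratio of the pegRNA's pseudocounted frequency in
the post-selection sample over the pre-selection sample. Function scores
aggregate pegRNA scores per variant, normalized so the median of a neutral
variant set (synonymous or deep-intronic) sits at zero:

* single-condition mode — pegRNA scores are normalized to the neutral median
  first, then averaged per variant;
* multi-condition mode — per-condition function scores are computed from
  unnormalized pegRNA scores, normalized per condition, averaged across the
  conditions in which the variant scored (at least two required), and the
  averaged scores are normalized once more.
"""

from __future__ import annotations

from typing import Dict, Iterable, Mapping, Optional, Sequence, Set

import numpy as np
import pandas as pd
from scipy import stats as sps

from .model import PegRNADesign, SchemaError, ScreenConfig, Variant

SCORE_COLUMNS = ("pegrna_id", "freq_pre", "freq_post", "pegrna_score",
                 "st_editing_pre_pct", "passed_negctrl_filter",
                 "passed_freq_filter", "passed_activity_filter", "retained")


def pegrna_frequencies(counts: pd.Series) -> pd.Series:
    """Pseudocounted frequencies: (c_i + 1) / sum_j (c_j + 1)."""
    if counts.empty:
        raise SchemaError("empty count vector")
    if (counts < 0).any():
        raise SchemaError("negative counts")
    inc = counts.astype(float) + 1.0
    return inc / inc.sum()


def pegrna_scores(freq_pre: pd.Series, freq_post: pd.Series) -> pd.Series:
    """log2(freq_post / freq_pre), finite by construction (pseudocounts)."""
    pre, post = freq_pre.align(freq_post, join="inner")
    return np.log2(post / pre)


def score_table(counts_pre: pd.Series, counts_post: pd.Series,
                st_editing_pre_pct: pd.Series, excluded: Set[str],
                config: ScreenConfig) -> pd.DataFrame:
    """Build the per-pegRNA score table for one condition.

    Frequencies are computed over all library pegRNAs that survive the
    negative-control exclusion (the pseudocount denominator); the frequency
    and activity filters are applied afterwards as flags.
    """
    keep = counts_pre.index.difference(pd.Index(sorted(excluded)))
    keep = counts_pre.index[counts_pre.index.isin(keep)]  # preserve order
    fpre = pegrna_frequencies(counts_pre.loc[keep])
    fpost = pegrna_frequencies(counts_post.loc[keep])
    table = pd.DataFrame({
        "pegrna_id": counts_pre.index,
        "freq_pre": fpre.reindex(counts_pre.index),
        "freq_post": fpost.reindex(counts_pre.index),
        "st_editing_pre_pct": st_editing_pre_pct.reindex(counts_pre.index),
    })
    table["pegrna_score"] = np.log2(table["freq_post"] / table["freq_pre"])
    table["passed_negctrl_filter"] = ~table["pegrna_id"].isin(excluded)
    table = apply_filters(table, config)
    return table[list(SCORE_COLUMNS)]


def apply_filters(table: pd.DataFrame, config: ScreenConfig) -> pd.DataFrame:
    """Flag pegRNAs passing the pre-selection frequency and ST-activity
    thresholds (both inclusive); undefined editing cannot certify activity
    and fails the activity filter."""
    table = table.copy()
    table["passed_freq_filter"] = table["freq_pre"] >= config.freq_min
    pct = table["st_editing_pre_pct"]
    table["passed_activity_filter"] = pct.notna() & (
        pct >= config.st_activity_min_pct)
    if "passed_negctrl_filter" not in table:
        table["passed_negctrl_filter"] = True
    table["retained"] = (
        table["passed_negctrl_filter"]
        & table["passed_freq_filter"]
        & table["passed_activity_filter"]
    )
    return table


def normalize_to_neutral(scores: pd.Series, neutral_ids: Iterable,
                         min_neutral: int = 5) -> pd.Series:
    """Subtract the median score of the neutral entries (log2 space)."""
    neutral = scores.loc[scores.index.isin(set(neutral_ids))].dropna()
    if len(neutral) < min_neutral:
        raise SchemaError(
            f"only {len(neutral)} neutral entries with defined scores; "
            f"need at least {min_neutral} for normalization"
        )
    return scores - float(neutral.median())


def pegrna_variant_map(designs: Sequence[PegRNADesign]) -> pd.Series:
    return pd.Series({d.pegrna_id: d.variant_id for d in designs},
                     name="variant_id")


def neutral_variant_ids(variants: Sequence[Variant],
                        config: ScreenConfig) -> Set[str]:
    return {
        v.variant_id for v in variants
        if v.neutral_set or (not v.plof_set
                             and v.consequence in config.neutral_consequences)
    }


def _per_condition_variant_means(table: pd.DataFrame,
                                 p2v: pd.Series) -> pd.Series:
    kept = table.loc[table["retained"]].copy()
    kept["variant_id"] = kept["pegrna_id"].map(p2v)
    if kept["variant_id"].isna().any():
        missing = kept.loc[kept["variant_id"].isna(), "pegrna_id"].iloc[0]
        raise SchemaError(f"pegrna {missing!r} not in library")
    return kept.groupby("variant_id")["pegrna_score"].mean()


def function_scores(tables: Mapping[str, pd.DataFrame],
                    designs: Sequence[PegRNADesign],
                    variants: Sequence[Variant],
                    config: ScreenConfig,
                    min_conditions: Optional[int] = None) -> pd.DataFrame:
    """Aggregate filtered pegRNA scores into per-variant function scores.

    ``tables`` maps condition name -> score table (``score_table`` output).
    Returns one row per scored variant with per-condition scores
    (``score_<condition>`` columns), ``n_conditions``, ``n_pegrnas`` (number
    of retained pegRNA observations across conditions) and the final
    ``function_score``.
    """
    if not tables:
        raise SchemaError("no score tables")
    p2v = pegrna_variant_map(designs)
    neutral = neutral_variant_ids(variants, config)

    if config.scoring_mode == "single":
        if len(tables) != 1:
            raise SchemaError("single-condition mode expects one score table")
        (cond, table), = tables.items()
        kept = table.loc[table["retained"]].copy()
        kept["variant_id"] = kept["pegrna_id"].map(p2v)
        neutral_pegs = kept.index[kept["variant_id"].isin(neutral)]
        scores = kept["pegrna_score"]
        scores = normalize_to_neutral(
            scores, neutral_pegs, config.min_neutral)
        kept["pegrna_score"] = scores
        fs = kept.groupby("variant_id")["pegrna_score"].mean()
        n_pegs = kept.groupby("variant_id").size()
        out = pd.DataFrame({
            "variant_id": fs.index,
            f"score_{cond}": fs.values,
            "n_conditions": 1,
            "n_pegrnas": n_pegs.reindex(fs.index).astype(int).values,
            "function_score": fs.values,
        })
        return out.reset_index(drop=True)

    # multi-condition mode
    if min_conditions is None:
        min_conditions = 2
    per_cond: Dict[str, pd.Series] = {}
    n_pegs_total: Dict[str, int] = {}
    for cond, table in tables.items():
        fs = _per_condition_variant_means(table, p2v)
        fs = normalize_to_neutral(
            fs, neutral, config.min_neutral)
        per_cond[cond] = fs
        kept = table.loc[table["retained"], "pegrna_id"].map(p2v)
        for vid, n in kept.value_counts().items():
            n_pegs_total[vid] = n_pegs_total.get(vid, 0) + int(n)
    wide = pd.DataFrame(per_cond)
    n_conditions = wide.notna().sum(axis=1)
    averaged = wide.mean(axis=1, skipna=True)
    scored = n_conditions >= min_conditions
    final = normalize_to_neutral(
        averaged.loc[scored], neutral, config.min_neutral)
    out = wide.loc[scored].rename(columns=lambda c: f"score_{c}")
    out.insert(0, "variant_id", out.index)
    out["n_conditions"] = n_conditions.loc[scored].astype(int)
    out["n_pegrnas"] = [n_pegs_total.get(v, 0) for v in out.index]
    out["function_score"] = final
    return out.reset_index(drop=True)


def cellline_scores(tables: Mapping[str, pd.DataFrame],
                    condition_cell_line: Mapping[str, str],
                    designs: Sequence[PegRNADesign],
                    variants: Sequence[Variant],
                    config: ScreenConfig) -> pd.DataFrame:
    """Cell-line-specific function scores.

    Per-condition normalized function scores are averaged over the
    conditions belonging to each cell line, then normalized once more. A
    single-condition cell line simply keeps that condition's normalized
    score. Returns rows (cell_line, variant_id, function_score,
    n_conditions).
    """
    p2v = pegrna_variant_map(designs)
    neutral = neutral_variant_ids(variants, config)
    per_cond = {}
    for cond, table in tables.items():
        fs = _per_condition_variant_means(table, p2v)
        per_cond[cond] = normalize_to_neutral(fs, neutral, config.min_neutral)
    rows = []
    lines = sorted(set(condition_cell_line.values()))
    for line in lines:
        conds = [c for c in tables if condition_cell_line[c] == line]
        wide = pd.DataFrame({c: per_cond[c] for c in conds})
        averaged = wide.mean(axis=1, skipna=True).dropna()
        final = normalize_to_neutral(averaged, neutral, config.min_neutral)
        n_conditions = wide.notna().sum(axis=1).loc[final.index]
        for vid, score in final.items():
            rows.append((line, vid, score, int(n_conditions.loc[vid])))
    return pd.DataFrame(rows, columns=["cell_line", "variant_id",
                                       "function_score", "n_conditions"])


def mean_variant_st_editing(observations: Sequence[pd.DataFrame],
                            designs: Sequence[PegRNADesign]) -> pd.Series:
    """Mean ST editing per variant, averaging the defined editing
    percentages of its pegRNAs across all provided condition tables."""
    p2v = pegrna_variant_map(designs)
    frames = []
    for obs in observations:
        f = obs[["pegrna_id", "st_editing_pct"]].copy()
        f["variant_id"] = f["pegrna_id"].map(p2v)
        frames.append(f)
    tidy = pd.concat(frames, ignore_index=True).dropna(
        subset=["st_editing_pct"])
    return tidy.groupby("variant_id")["st_editing_pct"].mean()


def compute_feature_correlations(editing_pct: pd.Series,
                                 designs: Sequence[PegRNADesign]) -> pd.Series:
    """Spearman correlation of ST editing with each design feature.

    Requires at least three pegRNAs with defined editing; a constant feature
    (or constant editing) yields NA.
    """
    feats = pd.DataFrame({d.pegrna_id: dict(d.features)
                          for d in designs}).T
    editing = editing_pct.dropna()
    common = feats.index.intersection(editing.index)
    if len(common) < 3:
        raise SchemaError("need at least 3 pegRNAs with defined editing")
    editing = editing.loc[common]
    out = {}
    for col in feats.columns:
        x = feats.loc[common, col].astype(float)
        ok = x.notna()
        if ok.sum() < 3 or x[ok].nunique() == 1 or editing[ok].nunique() == 1:
            out[col] = np.nan
            continue
        rho, _ = sps.spearmanr(x[ok], editing[ok])
        out[col] = rho
    return pd.Series(out, name="spearman_rho")
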