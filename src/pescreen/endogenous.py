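"""Endogenous-target (ET) variant-count analysis.

ET amplicon sequencing counts each programmed variant in genomic DNA.
Frequencies are corrected for sequencing background using a non-transduced
negative-control sample; site-specific error hotspots (control frequency
above 4e-4) are excluded, as are variants whose frequency did not at least
double over the editing phase (when the gain filter is enabled). Endogenous
function scores are log2 post/pre-selection frequency ratios normalized to
the neutral-variant median, averaged across conditions and normalized once
more — mirroring the pegRNA-based function-score pipeline so the two
readouts can be compared directly.
"""

from __future__ import annotations

from typing import Dict, Iterable, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .model import PegRNADesign, SchemaError, ScreenConfig, Variant
from . import scoring

EXCLUSION_REASONS = ("not_programmed", "high_control_background",
                     "zero_denominator", "low_editing_gain")


def background_correct(freq: pd.Series, control_freq: pd.Series,
                       config: ScreenConfig
                       ) -> Tuple[pd.Series, pd.Series]:
    """Subtract negative-control background; negatives floor at zero.

    Variants whose control frequency exceeds ``et_ctrl_freq_max`` are
    excluded as likely site-specific sequencing error. Returns
    (corrected_freq, excluded_reason) with NaN/'' for retained variants.
    """
    freq, control_freq = freq.align(control_freq, join="left")
    corrected = (freq - control_freq.fillna(0.0)).clip(lower=0.0)
    reason = pd.Series("", index=freq.index, dtype=object)
    hot = control_freq > config.et_ctrl_freq_max
    reason.loc[hot.fillna(False)] = "high_control_background"
    corrected.loc[hot.fillna(False)] = np.nan
    return corrected, reason


def editing_gain_filter(freq_t2: pd.Series, freq_t1: pd.Series,
                        config: ScreenConfig) -> pd.Series:
    """Exclude variants not enriched over the editing phase.

    Keeps variants with log2(freq_t2 / freq_t1) >= ``et_min_log2_gain``
    (inclusive). A zero denominator makes the ratio undefined and excludes
    the variant. Returns the exclusion reason ('' = keep).
    """
    freq_t2, freq_t1 = freq_t2.align(freq_t1, join="left")
    reason = pd.Series("", index=freq_t2.index, dtype=object)
    zero = (freq_t1 <= 0) | freq_t1.isna()
    reason.loc[zero] = "zero_denominator"
    with np.errstate(divide="ignore", invalid="ignore"):
        gain = np.log2(freq_t2 / freq_t1)
    low = (~zero) & (gain < config.et_min_log2_gain)
    reason.loc[low] = "low_editing_gain"
    return reason


def _frequencies(counts: pd.Series) -> pd.Series:
    total = counts.sum()
    if total <= 0:
        raise SchemaError("ET sample has zero total counts")
    return counts / float(total)


def mean_duplicate_frequencies(count_tables: Sequence[pd.DataFrame]
                               ) -> pd.DataFrame:
    """Average variant frequencies across duplicate ET count tables.

    Each table has the same ctrl/pre/post columns; per-sample frequencies
    are computed first so duplicates with different depth weigh equally.
    The result is a frequency table usable via
    ``condition_et_table(..., as_frequencies=True)``.
    """
    if not count_tables:
        raise SchemaError("no ET tables to average")
    freqs = []
    for tab in count_tables:
        freqs.append(pd.DataFrame({c: _frequencies(tab[c])
                                   for c in tab.columns}))
    out = freqs[0]
    for f in freqs[1:]:
        out = out.add(f, fill_value=0.0)
    return out / len(freqs)


def condition_et_table(counts: pd.DataFrame, programmed: Set[str],
                       config: ScreenConfig,
                       as_frequencies: bool = False) -> pd.DataFrame:
    """Per-condition ET bookkeeping from a count table.

    ``counts`` has index variant_id and columns ``ctrl``, ``pre``, ``post``
    (negative control, pre-selection, post-selection counts; or frequencies
    with ``as_frequencies``, e.g. from :func:`mean_duplicate_frequencies`).
    Exclusion precedence: not_programmed, then high_control_background, then
    zero_denominator, then low_editing_gain.
    """
    for col in ("ctrl", "pre", "post"):
        if col not in counts.columns:
            raise SchemaError(f"ET count table lacks column {col!r}")
    out = pd.DataFrame(index=counts.index)
    if as_frequencies:
        freq = {c: counts[c].astype(float) for c in ("ctrl", "pre", "post")}
    else:
        freq = {c: _frequencies(counts[c]) for c in ("ctrl", "pre", "post")}
    out["freq_ctrl"] = freq["ctrl"]
    out["freq_pre"] = freq["pre"]
    out["freq_post"] = freq["post"]
    reason = pd.Series("", index=counts.index, dtype=object)
    reason.loc[~counts.index.isin(programmed)] = "not_programmed"

    if config.et_subtract_background:
        pre_corr, bg_reason = background_correct(
            freq["pre"], freq["ctrl"], config)
        post_corr, _ = background_correct(freq["post"], freq["ctrl"], config)
        hot = (bg_reason == "high_control_background") & (reason == "")
        reason.loc[hot] = "high_control_background"
    else:
        hot = freq["ctrl"] > config.et_ctrl_freq_max
        reason.loc[hot & (reason == "")] = "high_control_background"
        pre_corr, post_corr = freq["pre"].copy(), freq["post"].copy()
    out["corrected_freq_pre"] = pre_corr
    out["corrected_freq_post"] = post_corr

    zero = (pre_corr <= 0) | pre_corr.isna()
    reason.loc[zero & (reason == "")] = "zero_denominator"

    if config.et_gain_filter:
        gain_reason = editing_gain_filter(freq["pre"], freq["ctrl"], config)
        low = (gain_reason == "low_editing_gain") & (reason == "")
        reason.loc[low] = "low_editing_gain"

    out["excluded"] = reason != ""
    out["exclusion_reason"] = reason
    keep = ~out["excluded"]
    score = pd.Series(np.nan, index=counts.index)
    with np.errstate(divide="ignore", invalid="ignore"):
        score.loc[keep] = np.log2(post_corr.loc[keep] / pre_corr.loc[keep])
    score.loc[keep & (post_corr <= 0)] = -np.inf
    # a post frequency fully absorbed by background: treat as strong depletion
    # is not meaningful on the log scale; drop such variants instead
    bad = keep & ~np.isfinite(score)
    out.loc[bad, "excluded"] = True
    out.loc[bad, "exclusion_reason"] = "zero_denominator"
    score.loc[bad] = np.nan
    out["log2_ratio"] = score
    return out


def endogenous_function_scores(condition_counts: Mapping[str, pd.DataFrame],
                               variants: Sequence[Variant],
                               config: ScreenConfig,
                               as_frequencies: bool = False) -> pd.DataFrame:
    """Per-variant endogenous function scores across conditions.

    For each condition: log2(post/pre) for retained variants, normalized to
    the neutral median; scores are then averaged across the conditions in
    which a variant was retained and normalized once more. Single-condition
    inputs skip the averaging but keep both normalizations (they compose to
    one in that case).
    """
    programmed = {v.variant_id for v in variants}
    neutral = scoring.neutral_variant_ids(variants, config)
    per_cond = {}
    details = {}
    for cond, counts in condition_counts.items():
        table = condition_et_table(counts, programmed, config,
                                   as_frequencies=as_frequencies)
        details[cond] = table
        s = table.loc[~table["excluded"], "log2_ratio"]
        per_cond[cond] = scoring.normalize_to_neutral(
            s, neutral, config.min_neutral)
    wide = pd.DataFrame(per_cond)
    averaged = wide.mean(axis=1, skipna=True).dropna()
    final = scoring.normalize_to_neutral(averaged, neutral,
                                         config.min_neutral)
    out = wide.rename(columns=lambda c: f"score_{c}")
    out = out.loc[final.index]
    out.insert(0, "variant_id", out.index)
    out["n_conditions"] = wide.loc[final.index].notna().sum(axis=1).astype(int)
    out["endogenous_score"] = final
    return out.reset_index(drop=True)


def st_variant_frequencies(observations: pd.DataFrame,
                           designs: Sequence[PegRNADesign]) -> pd.Series:
    """Fraction of all STs in the sample that carry a given variant:
    sum of correctly edited STs over the variant's pegRNAs, divided by the
    total ST count across the whole sample."""
    p2v = scoring.pegrna_variant_map(designs)
    obs = observations.copy()
    obs["variant_id"] = obs["pegrna_id"].map(p2v)
    total = obs["st_total"].sum()
    if total <= 0:
        raise SchemaError("sample has no ST reads")
    return obs.groupby("variant_id")["st_correct"].sum() / float(total)


def st_et_concordance(st_freq: pd.Series, et_freq: pd.Series
                      ) -> Tuple[float, pd.DataFrame]:
    """Spearman correlation between ST- and ET-derived variant frequencies,
    over the variants present in both; returns (rho, paired table)."""
    paired = pd.DataFrame({"st_freq": st_freq, "et_freq": et_freq}).dropna()
    if len(paired) < 3:
        raise SchemaError("need at least 3 shared variants")
    rho, _ = sps.spearmanr(paired["st_freq"], paired["et_freq"])
    return float(rho), paired
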