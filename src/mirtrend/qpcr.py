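"""Relative quantification (ddCt) arithmetic for qPCR validation data.

Input is a long-format table of well-level cycle thresholds with columns
``sample, group, gene, replicate, ct``. The pipeline is: exclude undetected
wells (Ct above a cutoff, default 36, strict), average technical replicates,
form dCt against one or more housekeeping genes (arithmetic mean of Cts,
i.e. geometric-mean normalization in linear space), reference dCt to the mean
dCt of the control group, and report fold = 2^(-ddCt).

A ``scale="linear"`` mode applies the same arithmetic to linear-scale signals
(hybridization/luminescence assays): relative signal = target / geometric
mean of housekeeping signals, referenced to the geometric mean of the control
group's relative signals.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import ValidationError

log = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("sample", "group", "gene", "replicate", "ct")


def _check_columns(records: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in records.columns]
    if missing:
        raise ValidationError(f"Ct table missing columns: {missing}")


def filter_ct(records: pd.DataFrame, cutoff: float = 36.0) -> pd.DataFrame:
    """Drop wells with Ct > cutoff (strict: Ct == cutoff is retained) or NaN."""
    _check_columns(records)
    bad = records["ct"].isna() | (records["ct"] > cutoff)
    if bad.any():
        log.info("excluded %d of %d wells (Ct > %g or undetected)",
                 int(bad.sum()), len(records), cutoff)
    return records.loc[~bad].copy()


def average_technical_replicates(records: pd.DataFrame) -> pd.DataFrame:
    """Arithmetic mean Ct per (sample, group, gene) over retained replicates.

    Apply :func:`filter_ct` first so that an undetected replicate does not
    contaminate the mean. Pairs with no retained replicates are simply absent
    from the output (treated downstream as undetected).
    """
    _check_columns(records)
    dup = records.duplicated(subset=["sample", "gene", "replicate"])
    if dup.any():
        raise ValidationError(
            f"duplicate replicate indices: {records.loc[dup, ['sample', 'gene', 'replicate']].values.tolist()}")
    out = (records.groupby(["sample", "group", "gene"], as_index=False)
           .agg(mean_ct=("ct", "mean"), n_replicates=("ct", "size")))
    return out


def delta_delta_ct(mean_cts: pd.DataFrame, target_gene: str,
                   housekeeping: list[str] | str, control_group: str,
                   scale: str = "ct") -> pd.DataFrame:
    """Per-sample relative expression of ``target_gene`` vs the control group.

    ``mean_cts`` is the output of :func:`average_technical_replicates`. The
    normalizer is the arithmetic mean of the housekeeping mean-Cts (equivalent
    to geometric-mean normalization of linear abundances). ddCt is referenced
    to the control group's mean dCt, so the control group's geometric mean
    fold is exactly 1. Samples missing the target are reported with NaN fold
    (undetected); samples missing a housekeeping gene are dropped and logged.

    With ``scale="linear"`` the ``mean_ct`` column is read as a linear signal
    and folds are computed as signal ratios referenced to the control group's
    geometric mean.
    """
    if isinstance(housekeeping, str):
        housekeeping = [housekeeping]
    if not housekeeping:
        raise ValidationError("at least one housekeeping gene is required")
    if scale not in ("ct", "linear"):
        raise ValidationError(f"unknown scale {scale!r}")
    for col in ("sample", "group", "gene", "mean_ct"):
        if col not in mean_cts.columns:
            raise ValidationError(f"mean Ct table missing column {col!r}")

    wide = mean_cts.pivot_table(index=["sample", "group"], columns="gene",
                                values="mean_ct", aggfunc="first")
    missing_hk = [g for g in housekeeping if g not in wide.columns]
    if missing_hk:
        raise ValidationError(f"housekeeping gene(s) absent from table: {missing_hk}")
    if target_gene not in wide.columns:
        raise ValidationError(f"target gene {target_gene!r} absent from table")

    hk_ok = wide[housekeeping].notna().all(axis=1)
    dropped = wide.index[~hk_ok].tolist()
    for sample, group in dropped:
        log.warning("sample %s (%s) dropped: missing housekeeping Ct", sample, group)
    wide = wide.loc[hk_ok]
    if control_group not in {g for _, g in wide.index}:
        raise ValidationError(f"control group {control_group!r} has no usable samples")

    if scale == "ct":
        norm = wide[housekeeping].mean(axis=1)
        dct = wide[target_gene] - norm
        control_ref = dct[[g == control_group for _, g in dct.index]].mean()
        ddct = dct - control_ref
        fold = np.power(2.0, -ddct)
    else:
        norm = np.exp(np.log(wide[housekeeping]).mean(axis=1))
        rel = wide[target_gene] / norm
        is_ctrl = [g == control_group for _, g in rel.index]
        control_ref = np.exp(np.log(rel[is_ctrl].dropna()).mean())
        fold = rel / control_ref
        dct, ddct = -np.log2(rel), -np.log2(fold)

    out = pd.DataFrame({
        "sample": [s for s, _ in wide.index],
        "group": [g for _, g in wide.index],
        "gene": target_gene,
        "mean_ct": wide[target_gene].to_numpy(),
        "delta_ct": dct.to_numpy(),
        "delta_delta_ct": ddct.to_numpy(),
        "fold": fold.to_numpy(),
    })
    undetected = out["mean_ct"].isna()
    if undetected.any():
        log.warning("target %s undetected in samples %s; excluded from summaries",
                    target_gene, out.loc[undetected, "sample"].tolist())
    out.attrs["dropped_samples"] = dropped
    return out


def summarize_relative_expression(relexpr: pd.DataFrame,
                                  value: str = "fold") -> pd.DataFrame:
    """Group mean +/- SEM of per-sample folds (undetected samples excluded)."""
    usable = relexpr.dropna(subset=[value])
    grouped = usable.groupby("group")[value]
    out = grouped.agg(["mean", "std", "count"]).rename(
        columns={"mean": "mean_fold", "std": "sd", "count": "n"})
    out["sem"] = out["sd"] / np.sqrt(out["n"])
    out.loc[out["n"] < 2, "sem"] = np.nan  # SEM undefined for single samples
    return out.reset_index()[["group", "mean_fold", "sem", "n"]]
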