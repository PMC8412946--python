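"""Mito Stress (extracellular flux) normalization and summaries.

Traces are tidy DataFrames with one row per measurement cycle per well:
columns ``well, sample, cycle, phase, ocr`` (plus optional ``ecar``). Phases
follow the injection sequence: baseline, oligomycin, FCCP, rot/AA. The rot/AA
phase defines non-mitochondrial background: each sample's mean rot/AA OCR is
subtracted from all of its measurements, technical-replicate wells are
averaged per cycle, and the summary reports basal respiration (mean of the
baseline phase) and maximal respiration (max within the FCCP phase by
default; the phase mean is available by flag since conventions differ).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import ValidationError

log = logging.getLogger(__name__)

PHASES = ("baseline", "oligomycin", "FCCP", "rot/AA")
REQUIRED_COLUMNS = ("well", "sample", "cycle", "phase", "ocr")


def _check(trace: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in trace.columns]
    if missing:
        raise ValidationError(f"OCR trace missing columns: {missing}")
    bad = set(trace["phase"]) - set(PHASES)
    if bad:
        raise ValidationError(f"unknown injection phases: {sorted(bad)}")
    # phases must appear in injection order within each well
    order = {p: i for i, p in enumerate(PHASES)}
    for well, sub in trace.groupby("well"):
        ranks = sub.sort_values("cycle")["phase"].map(order).to_numpy()
        if (np.diff(ranks) < 0).any():
            raise ValidationError(f"well {well}: phases out of injection order")


def background_subtract(trace: pd.DataFrame) -> pd.DataFrame:
    """Subtract each sample's mean rot/AA OCR from all its measurements.

    After subtraction the rot/AA phase mean of every sample is zero to within
    one ulp of the trace scale (the residual rounding mean is re-subtracted),
    making the operation idempotent at machine precision.
    """
    _check(trace)
    out = trace.copy()
    for sample, sub in out.groupby("sample"):
        rot_mask = sub["phase"] == "rot/AA"
        if not rot_mask.any():
            raise ValidationError(f"sample {sample}: no rot/AA phase measurements")
        vals = sub["ocr"].to_numpy(dtype=float)
        # re-subtract the residual mean so the rot/AA mean is exactly 0.0,
        # not merely zero to rounding; also makes the operation idempotent
        for _ in range(4):
            m = vals[rot_mask.to_numpy()].mean()
            if m == 0.0:
                break
            vals = vals - m
        out.loc[sub.index, "ocr"] = vals
    return out


def aggregate_technical_replicates(trace: pd.DataFrame) -> pd.DataFrame:
    """Cycle-wise mean OCR across the wells of each biological sample."""
    _check(trace)
    counts = trace.groupby(["sample", "well"])["cycle"].count()
    for sample, sub in counts.groupby("sample"):
        if sub.nunique() > 1:
            raise ValidationError(f"sample {sample}: wells have mismatched cycle counts")
    phase_per_cycle = trace.groupby(["sample", "cycle"])["phase"].nunique()
    if (phase_per_cycle > 1).any():
        raise ValidationError("wells of one sample disagree on a cycle's phase")
    agg = (trace.groupby(["sample", "cycle", "phase"], as_index=False)
           .agg(ocr=("ocr", "mean"), n_wells=("ocr", "size")))
    agg["well"] = agg["sample"]  # aggregated trace: one pseudo-well per sample
    return agg.sort_values(["sample", "cycle"]).reset_index(drop=True)


def summarize_mitostress(trace: pd.DataFrame,
                         maximal: str = "max") -> pd.DataFrame:
    """Per-sample basal and maximal respiration from a subtracted trace.

    basal = mean OCR of the baseline phase; maximal_respiration = max (or mean
    with ``maximal="mean"``) OCR within the FCCP phase. Missing phases yield
    NaN with a warning.
    """
    _check(trace)
    if maximal not in ("max", "mean"):
        raise ValidationError(f"maximal must be 'max' or 'mean', got {maximal!r}")
    rows = []
    for sample, sub in trace.groupby("sample"):
        base = sub.loc[sub["phase"] == "baseline", "ocr"]
        fccp = sub.loc[sub["phase"] == "FCCP", "ocr"]
        if base.empty:
            log.warning("sample %s: no baseline phase; basal undefined", sample)
        if fccp.empty:
            log.warning("sample %s: no FCCP phase; maximal respiration undefined", sample)
        rows.append({
            "sample": sample,
            "basal": base.mean() if not base.empty else np.nan,
            "maximal_respiration": (
                (fccp.max() if maximal == "max" else fccp.mean())
                if not fccp.empty else np.nan),
        })
    return pd.DataFrame(rows)
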