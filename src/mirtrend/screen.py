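"""Longitudinal unidirectional-trend screen over a miRNA expression matrix.

The screening procedure, in order:

1. depth normalization — every sample is scaled down to the sample with the
   fewest total reads, so expression is comparable across ages;
2. coverage filtering — a feature whose mean per-base coverage falls below the
   cutoff (default 6x) at any timepoint is removed;
3. pairwise log2 ratios between all ordered sample pairs;
4. trend classification — each consecutive-timepoint ratio r = Exp(n+1)/Exp(n)
   is scored against a no-change band (1-eps, 1+eps), default eps = 0.10: a
   ratio strictly inside the band contributes to neither direction, r <= 1-eps
   is a down-step, r >= 1+eps an up-step. A feature is *decreasing* when it
   has no up-step and at least ``min_changing_steps`` down-steps (increasing
   symmetric);
5. ranking of candidates within each direction by expression at the youngest
   timepoint, descending — the most highly expressed young-age candidates are
   the biologically prioritized ones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .loci import Locus
from .matrix import ExpressionMatrix

log = logging.getLogger(__name__)

DIRECTION_DECREASING = "decreasing"
DIRECTION_INCREASING = "increasing"
DIRECTION_NONE = "none"


@dataclass
class ScreenConfig:
    """Tunable parameters of the screen.

    tolerance
        Half-width eps of the relative no-change band (1-eps, 1+eps); a step
        ratio strictly inside the band is "no change". Default 0.10.
    coverage_cutoff
        Minimum admissible mean per-base coverage; inclusive (coverage == 6
        passes the default cutoff).
    min_changing_steps
        Minimum number of same-direction steps for a unidirectional call; a
        completely flat trajectory is direction "none".
    pseudocount
        Added to numerator and denominator of every ratio. Default 0: with
        zero counts, 0/0 is treated as no change and x/0 (x > 0) as an
        up-step.
    rank_by
        Candidate ranking key; only "expression_at_first_timepoint" is
        currently defined.
    """

    tolerance: float = 0.10
    coverage_cutoff: float = 6.0
    min_changing_steps: int = 1
    pseudocount: float = 0.0
    rank_by: str = "expression_at_first_timepoint"

    def __post_init__(self) -> None:
        if not 0 <= self.tolerance < 1:
            raise ValidationError(f"tolerance must be in [0, 1): {self.tolerance}")
        if self.coverage_cutoff < 0:
            raise ValidationError("coverage_cutoff must be >= 0")
        if self.min_changing_steps < 1:
            raise ValidationError("min_changing_steps must be >= 1")
        if self.pseudocount < 0:
            raise ValidationError("pseudocount must be >= 0")
        if self.rank_by != "expression_at_first_timepoint":
            raise ValidationError(f"unknown rank_by {self.rank_by!r}")


@dataclass
class TrendCall:
    feature: str
    direction: str
    step_ratios: list[float]
    step_verdicts: list[str]
    n_changing_steps: int


@dataclass
class ScreenResult:
    calls: list[TrendCall]
    candidates: pd.DataFrame  # feature, direction, rank_value, rank
    log2_ratios: pd.DataFrame  # long: feature, sample_i, sample_j, log2_ratio
    filter_log: list[tuple[str, str]] = field(default_factory=list)
    matrix: ExpressionMatrix | None = None

    def decreasing(self) -> list[str]:
        return [c.feature for c in self.calls if c.direction == DIRECTION_DECREASING]

    def increasing(self) -> list[str]:
        return [c.feature for c in self.calls if c.direction == DIRECTION_INCREASING]


def normalize_to_min_depth(matrix: ExpressionMatrix,
                           use_column_sums: bool = False) -> ExpressionMatrix:
    """Scale every sample down to the sample with the fewest total reads.

    Each sample's values are multiplied by (min total / sample total); after
    normalization every sample's effective depth equals the minimum, so the
    operation is idempotent.
    """
    if matrix.totals is None:
        if not use_column_sums:
            raise ValidationError(
                "per-sample total read depths are missing; supply totals or "
                "pass use_column_sums=True to normalize on column sums"
            )
        totals = matrix.values.sum(axis=0).to_numpy(dtype=float)
        if (totals <= 0).any():
            raise ValidationError("cannot normalize: a sample has zero column sum")
    else:
        totals = matrix.totals
    factors = totals.min() / totals
    out = matrix.copy()
    out.values = out.values * factors
    out.totals = np.full_like(totals, totals.min())
    return out


def pairwise_log2_ratios(matrix: ExpressionMatrix,
                         pseudocount: float = 0.0) -> pd.DataFrame:
    """log2 ratio for every feature and every ordered sample pair (i, j).

    Computed as log2(Exp(f,j)+c) - log2(Exp(f,i)+c) so that the table is
    exactly antisymmetric in floating point: ratio(i,j) == -ratio(j,i).
    """
    cols = list(matrix.values.columns)
    vals = matrix.values.to_numpy(dtype=float) + pseudocount
    with np.errstate(divide="ignore"):
        logs = np.log2(vals)
    rows = []
    for i, ci in enumerate(cols):
        for j, cj in enumerate(cols):
            if i == j:
                continue
            rows.append(pd.DataFrame({
                "feature": matrix.values.index,
                "sample_i": ci,
                "sample_j": cj,
                "log2_ratio": logs[:, j] - logs[:, i],
            }))
    return pd.concat(rows, ignore_index=True)


def _step_verdict(r: float, eps: float) -> str:
    if np.isnan(r):
        return "no_change"  # 0/0 at pseudocount 0
    if 1 - eps < r < 1 + eps:
        return "no_change"
    return "down" if r < 1 else "up"


def classify_unidirectional(trajectory: Sequence[float], config: ScreenConfig,
                            feature: str = "") -> TrendCall:
    """Classify one ordered trajectory as decreasing / increasing / none.

    Per-step ratio r = (Exp(n+1)+c)/(Exp(n)+c); the no-change band is the open
    interval (1-eps, 1+eps), so a ratio exactly at 1-eps counts as a down-step
    (and 1+eps as an up-step).
    """
    traj = np.asarray(trajectory, dtype=float)
    if traj.size < 2:
        raise ValidationError(f"trajectory for {feature or 'feature'} has < 2 points")
    if (traj < 0).any():
        raise ValidationError(f"negative expression in trajectory for {feature!r}")
    c = config.pseudocount
    num = traj[1:] + c
    den = traj[:-1] + c
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = num / den
    ratios = np.where((num == 0) & (den == 0), np.nan, ratios)
    verdicts = [_step_verdict(r, config.tolerance) for r in ratios]
    n_down = verdicts.count("down")
    n_up = verdicts.count("up")
    if n_up == 0 and n_down >= config.min_changing_steps:
        direction, n_changing = DIRECTION_DECREASING, n_down
    elif n_down == 0 and n_up >= config.min_changing_steps:
        direction, n_changing = DIRECTION_INCREASING, n_up
    else:
        direction, n_changing = DIRECTION_NONE, 0
    return TrendCall(
        feature=feature,
        direction=direction,
        step_ratios=[float(r) for r in ratios],
        step_verdicts=verdicts,
        n_changing_steps=n_changing,
    )


def top_expressed_matrix(matrix: ExpressionMatrix, k: int = 100) -> ExpressionMatrix:
    """Submatrix of the k features with the largest mean expression.

    Rows are ordered by decreasing mean; ties are broken by feature ID
    lexicographic order (logged when the tie crosses the k boundary). Column
    order is preserved.
    """
    if k > matrix.n_features:
        raise ValidationError(f"k={k} exceeds {matrix.n_features} features")
    means = matrix.values.mean(axis=1)
    order = sorted(matrix.values.index, key=lambda f: (-means[f], f))
    if k < matrix.n_features and means[order[k - 1]] == means[order[k]]:
        log.warning("tie at the top-%d boundary broken by feature ID order", k)
    out = matrix.copy()
    out.values = out.values.loc[order[:k]]
    if out.coverage is not None:
        out.coverage = out.coverage.loc[order[:k]]
    return out


def matrix_from_loci(loci_by_age: Mapping[float, Sequence[Locus]],
                     totals: Mapping[float, float] | None = None) -> ExpressionMatrix:
    """Build a feature x age matrix from per-timepoint annotated loci.

    Values are per-annotation read counts; the coverage table carries the
    per-annotation mean coverage (minimum over a feature's loci when several
    loci share an annotation). Every timepoint must provide the same feature
    set; missing features are reported.
    """
    ages = sorted(float(a) for a in loci_by_age)
    per_age_counts: dict[float, dict[str, float]] = {}
    per_age_cov: dict[float, dict[str, float]] = {}
    for age in ages:
        counts: dict[str, float] = {}
        cov: dict[str, float] = {}
        for locus in loci_by_age[age]:
            if locus.annotation_id is None:
                raise ValidationError("matrix_from_loci requires annotated loci")
            counts[locus.annotation_id] = counts.get(locus.annotation_id, 0) + locus.read_count
            cov[locus.annotation_id] = min(
                cov.get(locus.annotation_id, np.inf), locus.coverage)
        per_age_counts[age], per_age_cov[age] = counts, cov
    features = sorted(set().union(*(per_age_counts[a] for a in ages)))
    missing = {
        a: sorted(set(features) - set(per_age_counts[a])) for a in ages
        if set(features) - set(per_age_counts[a])
    }
    if missing:
        raise ValidationError(f"inconsistent feature sets across timepoints: {missing}")
    values = pd.DataFrame(
        {str(a): [per_age_counts[a][f] for f in features] for a in ages},
        index=pd.Index(features, name="feature"),
    )
    coverage = pd.DataFrame(
        {str(a): [per_age_cov[a][f] for f in features] for a in ages},
        index=values.index,
    )
    tot = None
    if totals is not None:
        tot = np.array([float(totals[a]) for a in ages])
    return ExpressionMatrix(values=values, ages=ages, totals=tot, coverage=coverage)


def run_screen(data: ExpressionMatrix | Mapping[float, Sequence[Locus]],
               config: ScreenConfig | None = None,
               use_column_sums: bool = False) -> ScreenResult:
    """Run the full screen: normalize, filter, classify, rank.

    ``data`` is either a prebuilt :class:`ExpressionMatrix` or a mapping of
    age -> annotated loci. The coverage cutoff applies per timepoint: a
    feature below the cutoff at any timepoint is removed before
    classification and recorded in the filter log. When the matrix carries no
    coverage table (e.g. an rpm table that was already coverage-filtered
    upstream), the cutoff stage is skipped and logged.
    """
    config = config or ScreenConfig()
    if isinstance(data, ExpressionMatrix):
        matrix = data
    else:
        matrix = matrix_from_loci(data)

    filter_log: list[tuple[str, str]] = []
    if matrix.totals is None and not use_column_sums:
        norm = matrix.copy()
        log.info("no per-sample totals supplied; depth normalization skipped")
        filter_log.append(("*", "depth normalization skipped: no totals"))
    else:
        norm = normalize_to_min_depth(matrix, use_column_sums=use_column_sums)

    if norm.coverage is not None:
        below = norm.coverage.lt(config.coverage_cutoff)
        for feature in norm.values.index[below.any(axis=1)]:
            ages_below = [c for c in norm.coverage.columns if below.at[feature, c]]
            filter_log.append(
                (feature, f"coverage < {config.coverage_cutoff} at {ages_below}"))
        keep = norm.values.index[~below.any(axis=1)]
        norm.values = norm.values.loc[keep]
        norm.coverage = norm.coverage.loc[keep]
    else:
        log.info("no coverage table: coverage cutoff stage skipped")

    ratios = pairwise_log2_ratios(norm, pseudocount=config.pseudocount)
    calls = [
        classify_unidirectional(norm.trajectory(f), config, feature=f)
        for f in norm.values.index
    ]

    first_col = norm.values.columns[0]
    rows = []
    for direction in (DIRECTION_DECREASING, DIRECTION_INCREASING):
        members = [c.feature for c in calls if c.direction == direction]
        members.sort(key=lambda f: (-norm.values.at[f, first_col], f))
        for rank, f in enumerate(members, start=1):
            rows.append({
                "feature": f,
                "direction": direction,
                "rank_value": norm.values.at[f, first_col],
                "rank": rank,
            })
    candidates = pd.DataFrame(rows, columns=["feature", "direction", "rank_value", "rank"])
    log.info(
        "screen: tolerance=%.3g coverage_cutoff=%.3g pseudocount=%.3g -> "
        "%d decreasing, %d increasing of %d classified",
        config.tolerance, config.coverage_cutoff, config.pseudocount,
        sum(c.direction == DIRECTION_DECREASING for c in calls),
        sum(c.direction == DIRECTION_INCREASING for c in calls),
        len(calls),
    )
    return ScreenResult(calls=calls, candidates=candidates, log2_ratios=ratios,
                        filter_log=filter_log, matrix=norm)


def calls_to_frame(calls: Sequence[TrendCall]) -> pd.DataFrame:
    """Flatten trend calls for TSV output."""
    return pd.DataFrame({
        "feature": [c.feature for c in calls],
        "direction": [c.direction for c in calls],
        "n_changing_steps": [c.n_changing_steps for c in calls],
        "step_ratios": [",".join(f"{r:.6g}" for r in c.step_ratios) for c in calls],
        "step_verdicts": [",".join(c.step_verdicts) for c in calls],
    })
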