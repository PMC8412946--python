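"""Synthetic inputs with known ground truth for every pipeline stage.

Three generators mirror the three experimental data types the analysis
consumes:

* :func:`generate_trajectory_matrix` — a miRNA x age expression matrix with
  per-feature programmed trend classes (down / up / flat / nonmonotone) and a
  configurable noise model. The default scale is the study design: 572
  features across ages 3, 6, 12, 18, 24 and 30 months, one pooled sample per
  age.
* :func:`generate_reads_for_loci` — aligned-read intervals over planned loci,
  for exercising locus assembly and the coverage cutoff.
* :func:`generate_qpcr_plate` — long-format Ct tables with technical
  duplicates, housekeeping genes and programmed fold changes, for exercising
  the ddCt arithmetic.

Every generator returns a truth object alongside the data and draws all
randomness from a single seeded ``numpy`` generator, so identical spec + seed
give identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .loci import ReadInterval
from .matrix import ExpressionMatrix

TREND_CLASSES = ("down", "up", "flat", "nonmonotone")
DEFAULT_TIMEPOINTS = (3.0, 6.0, 12.0, 18.0, 24.0, 30.0)


@dataclass
class ScreenSimSpec:
    """Design of a synthetic longitudinal screen.

    ``noise_model`` is one of ``"none"``, ``"lognormal"`` (multiplicative,
    median-preserving, parameter ``noise_sigma``) or ``"negative_binomial"``
    (variance mu + dispersion * mu^2, parameter ``nb_dispersion``). Counts are
    generated as real-valued rpm-like expression; set ``integer_counts`` to
    round after noise.
    """

    n_features: int = 572
    timepoints: tuple[float, ...] = DEFAULT_TIMEPOINTS
    trend_assignment: dict[str, str] = field(default_factory=dict)
    baseline_expression: dict[str, float] = field(default_factory=dict)
    step_fold: dict[str, float] = field(default_factory=dict)
    noise_model: str = "none"
    noise_sigma: float = 0.0
    nb_dispersion: float = 0.0
    depth_per_sample: tuple[float, ...] | None = None
    integer_counts: bool = False
    default_step_fold_down: float = 0.85
    default_step_fold_up: float = 1.0 / 0.85
    baseline_log_mean: float = np.log(50.0)
    baseline_log_sigma: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_features < 1:
            raise ValidationError("n_features must be >= 1")
        tps = tuple(float(t) for t in self.timepoints)
        if len(tps) < 2 or any(b <= a for a, b in zip(tps, tps[1:])):
            raise ValidationError(f"timepoints must be strictly increasing: {tps}")
        self.timepoints = tps
        if self.noise_model not in ("none", "lognormal", "negative_binomial"):
            raise ValidationError(f"unknown noise model {self.noise_model!r}")
        for f, cls in self.trend_assignment.items():
            if cls not in TREND_CLASSES:
                raise ValidationError(f"feature {f!r}: unknown trend class {cls!r}")
        for f, b in self.baseline_expression.items():
            if b <= 0:
                raise ValidationError(f"feature {f!r}: baseline must be > 0")
        for f, sf in self.step_fold.items():
            if sf <= 0:
                raise ValidationError(f"feature {f!r}: step_fold must be > 0")
            cls = self.trend_assignment.get(f)
            if cls == "down" and sf >= 1:
                raise ValidationError(f"feature {f!r}: class down needs step_fold < 1")
            if cls == "up" and sf <= 1:
                raise ValidationError(f"feature {f!r}: class up needs step_fold > 1")


@dataclass
class SimTruth:
    """Ground truth emitted with every generated dataset."""

    trend_class: dict[str, str]
    step_fold: dict[str, float]
    noise_free: pd.DataFrame | None = None
    locus_spans: list[tuple[str, int, int, str | None, int]] | None = None
    fold_change: dict[tuple[str, str], float] | None = None  # (gene, group) -> fold

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "feature": list(self.trend_class),
            "trend_class": [self.trend_class[f] for f in self.trend_class],
            "step_fold": [self.step_fold.get(f, 1.0) for f in self.trend_class],
        })


def _feature_names(n: int) -> list[str]:
    width = len(str(n - 1))
    return [f"mir-{i:0{width}d}" for i in range(n)]


def generate_trajectory_matrix(spec: ScreenSimSpec) -> tuple[ExpressionMatrix, SimTruth]:
    """Generate a feature x timepoint matrix with programmed trends.

    Monotone classes follow exact geometric trajectories, value(t_k) =
    baseline * step_fold**k; flat features stay at baseline; the nonmonotone
    class follows its step fold but one randomly placed step is inverted
    (magnitude kept), violating unidirectionality by construction.
    """
    rng = np.random.default_rng(spec.seed)
    features = _feature_names(spec.n_features)
    unknown = set(spec.trend_assignment) - set(features)
    if unknown:
        raise ValidationError(f"trend_assignment names unknown features: {sorted(unknown)}")

    n_t = len(spec.timepoints)
    classes = {f: spec.trend_assignment.get(f, "flat") for f in features}
    baselines = dict(spec.baseline_expression)
    drawn = np.exp(rng.normal(spec.baseline_log_mean, spec.baseline_log_sigma,
                              size=len(features)))
    for f, b in zip(features, drawn):
        baselines.setdefault(f, float(b))

    folds: dict[str, float] = {}
    for f in features:
        cls = classes[f]
        if f in spec.step_fold:
            folds[f] = spec.step_fold[f]
        elif cls == "down":
            folds[f] = spec.default_step_fold_down
        elif cls == "up":
            folds[f] = spec.default_step_fold_up
        elif cls == "nonmonotone":
            folds[f] = spec.default_step_fold_down
        else:
            folds[f] = 1.0

    clean = np.empty((len(features), n_t))
    for i, f in enumerate(features):
        cls = classes[f]
        if cls == "flat":
            clean[i] = baselines[f]
        else:
            steps = np.full(n_t - 1, folds[f])
            if cls == "nonmonotone":
                flip = rng.integers(0, n_t - 1)
                steps[flip] = 1.0 / steps[flip]
            clean[i] = baselines[f] * np.concatenate([[1.0], np.cumprod(steps)])

    if spec.noise_model == "none":
        noisy = clean.copy()
    elif spec.noise_model == "lognormal":
        noisy = clean * np.exp(rng.normal(0.0, spec.noise_sigma, size=clean.shape))
    else:  # negative binomial on the expression scale
        if spec.nb_dispersion <= 0:
            raise ValidationError("negative_binomial noise needs nb_dispersion > 0")
        n_param = 1.0 / spec.nb_dispersion
        p = n_param / (n_param + clean)
        noisy = rng.negative_binomial(n_param, p).astype(float)
    if spec.integer_counts:
        noisy = np.rint(noisy)

    depths = spec.depth_per_sample
    totals = None if depths is None else np.asarray(depths, dtype=float)
    if totals is not None and totals.shape != (n_t,):
        raise ValidationError("depth_per_sample needs one value per timepoint")

    cols = [str(t) for t in spec.timepoints]
    values = pd.DataFrame(noisy, index=pd.Index(features, name="feature"), columns=cols)
    matrix = ExpressionMatrix(values=values, ages=list(spec.timepoints), totals=totals)
    truth = SimTruth(
        trend_class=classes,
        step_fold=folds,
        noise_free=pd.DataFrame(clean, index=values.index, columns=cols),
    )
    return matrix, truth


def default_screen_spec(n_down: int = 30, step_fold: float = 0.85,
                        noise_model: str = "none", noise_sigma: float = 0.0,
                        nb_dispersion: float = 0.0, seed: int = 0) -> ScreenSimSpec:
    """Study-scale spec: 572 features, 6 ages, ``n_down`` programmed decliners."""
    features = _feature_names(572)
    assignment = {f: "down" for f in features[:n_down]}
    return ScreenSimSpec(
        n_features=572,
        trend_assignment=assignment,
        step_fold={f: step_fold for f in features[:n_down]},
        noise_model=noise_model,
        noise_sigma=noise_sigma,
        nb_dispersion=nb_dispersion,
        seed=seed,
    )


def generate_reads_for_loci(locus_plan: list[tuple[ReadInterval, int, int]],
                            seed: int = 0) -> tuple[list[ReadInterval], SimTruth]:
    """Generate reads over planned loci; each plan yields one merged cluster.

    ``locus_plan`` items are (interval, read_count, read_length). Reads are
    placed on evenly spaced anchors with bounded jitter so consecutive reads
    always overlap or abut: the plan's reads assemble into exactly one locus.
    Planned loci overlapping on the same chromosome and strand are rejected
    (ground truth would be ambiguous). Truth records the realized read-union
    span of each plan.
    """
    rng = np.random.default_rng(seed)
    for idx, (iv, count, length) in enumerate(locus_plan):
        if count < 1:
            raise ValidationError(f"plan {idx}: read_count must be >= 1")
        if length < 1 or length > iv.length:
            raise ValidationError(f"plan {idx}: read_length must be in [1, {iv.length}]")
        if count * length < iv.length and count > 1:
            # anchors would be farther apart than a read length somewhere
            max_step = (iv.length - length) / (count - 1)
            if max_step > length:
                raise ValidationError(
                    f"plan {idx}: {count} reads of length {length} cannot tile "
                    f"a {iv.length} bp interval into one connected locus")
    for i, (a, _, _) in enumerate(locus_plan):
        for b, _, _ in locus_plan[i + 1:]:
            if (a.chrom == b.chrom and a.strand == b.strand
                    and a.start < b.end and b.start < a.end):
                raise ValidationError(
                    f"planned loci overlap on {a.chrom}({a.strand}): {a} vs {b}")

    reads: list[ReadInterval] = []
    spans: list[tuple[str, int, int, str | None, int]] = []
    for iv, count, length in locus_plan:
        slack = iv.length - length
        if count == 1:
            starts = np.array([iv.start + int(rng.integers(0, slack + 1))])
        else:
            step = slack / (count - 1)
            anchors = iv.start + np.floor(np.arange(count) * step).astype(int)
            jitter_half = max(0, int((length - np.ceil(step)) // 2))
            jitter = rng.integers(-jitter_half, jitter_half + 1, size=count)
            starts = np.clip(anchors + jitter, iv.start, iv.start + slack)
            starts.sort()
        plan_reads = [ReadInterval(iv.chrom, int(s), int(s) + length, iv.strand)
                      for s in starts]
        reads.extend(plan_reads)
        spans.append((iv.chrom, int(starts.min()), int(starts.max()) + length,
                      iv.strand, count))
    truth = SimTruth(trend_class={}, step_fold={}, locus_spans=spans)
    return reads, truth


@dataclass
class QpcrSimSpec:
    """Design of a synthetic qPCR plate.

    ``fold_change`` maps (gene, group) to the true expression fold relative to
    ``control_group`` (control folds are implicitly 1). ``efficiency`` is the
    per-cycle amplification factor (2.0 = perfect doubling): a fold f shifts
    the expected Ct by -log_efficiency(f).
    """

    genes: tuple[str, ...]
    groups: dict[str, int]  # group -> number of biological samples
    control_group: str
    fold_change: dict[tuple[str, str], float] = field(default_factory=dict)
    housekeeping: dict[str, float] = field(default_factory=lambda: {"U6": 20.0})
    base_ct: dict[str, float] = field(default_factory=dict)  # gene -> control-group Ct
    technical_replicates: int = 2
    ct_noise_sd: float = 0.0
    efficiency: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.control_group not in self.groups:
            raise ValidationError(
                f"control group {self.control_group!r} missing from groups")
        if self.technical_replicates < 1:
            raise ValidationError("technical_replicates must be >= 1")
        if self.efficiency <= 1:
            raise ValidationError("efficiency must be > 1")
        for (gene, group), f in self.fold_change.items():
            if f <= 0:
                raise ValidationError(f"fold change for {(gene, group)} must be > 0")
            if group == self.control_group and f != 1.0:
                raise ValidationError("control-group fold change must be 1")
        if self.ct_noise_sd < 0:
            raise ValidationError("ct_noise_sd must be >= 0")


def generate_qpcr_plate(spec: QpcrSimSpec) -> tuple[pd.DataFrame, SimTruth]:
    """Long-format Ct table: sample, group, gene, replicate, ct.

    Housekeeping Cts are group-independent; a target gene with true fold f in
    group g is shifted by -log_efficiency(f) cycles relative to the control
    group. Gaussian noise (sd ``ct_noise_sd``) is added per well.
    """
    rng = np.random.default_rng(spec.seed)
    base_ct = {g: spec.base_ct.get(g, 24.0) for g in spec.genes}
    rows = []
    truth_folds: dict[tuple[str, str], float] = {}
    for group, n_samples in spec.groups.items():
        for s in range(n_samples):
            sample = f"{group}_{s + 1}"
            for gene in spec.genes:
                fold = 1.0 if group == spec.control_group else \
                    spec.fold_change.get((gene, group), 1.0)
                truth_folds[(gene, group)] = fold
                mean_ct = base_ct[gene] - np.log(fold) / np.log(spec.efficiency)
                for rep in range(1, spec.technical_replicates + 1):
                    rows.append({
                        "sample": sample, "group": group, "gene": gene,
                        "replicate": rep,
                        "ct": mean_ct + rng.normal(0.0, spec.ct_noise_sd),
                    })
            for hk, hk_ct in spec.housekeeping.items():
                for rep in range(1, spec.technical_replicates + 1):
                    rows.append({
                        "sample": sample, "group": group, "gene": hk,
                        "replicate": rep,
                        "ct": hk_ct + rng.normal(0.0, spec.ct_noise_sd),
                    })
    table = pd.DataFrame(rows, columns=["sample", "group", "gene", "replicate", "ct"])
    truth = SimTruth(trend_class={}, step_fold={}, fold_change=truth_folds)
    return table, truth
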