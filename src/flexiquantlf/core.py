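"""Per-protein, per-sample RM scoring from label-free peptide intensities.

The underlying idea: the copy number of a protein is shared by all of its
proteolytic peptides, so any post-translational modification (of whatever
chemical nature) removes intensity from the *unmodified* species of the
affected peptide.  Regressing a sample's unmodified peptide intensities
against a reference sample therefore puts unmodified, stably quantified
peptides on a common line through the origin,

    y_i = beta * x_i + eps_i,

while differentially modified peptides fall below it.  The slope ``beta``
absorbs global protein-abundance differences between sample and reference.
The line is fitted robustly with RANSAC so that modified peptides do not
drag the fit; the vertical distance of each peptide to the line, normalised
by its expected intensity ``beta * x_i``, yields a *raw score*

    s_i = 1 - (beta * x_i - y_i) / (beta * x_i) = y_i / (beta * x_i),

i.e. 1 for peptides on the line and f for a peptide whose unmodified
intensity dropped to a fraction f of expectation.  High-side outliers
(raw score above median + 3 MAD) are removed, the survivors are rescaled by
the median of the three highest raw scores, and the resulting RM score
("Relative Modification" score, = 1 - modification extent) is thresholded
into three categories: likely (< 0.5), possibly (0.5-0.6) and likely-not
(>= 0.6) differentially modified.

This module houses the numerical core: the intensity container, the robust
regression (single run and best-of-K selection), score computation, outlier
gating, RM scaling and classification, plus ``analyze_protein`` which chains
them for every sample of one protein.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Category",
    "FitError",
    "IntensityTable",
    "ModelFit",
    "RansacConfig",
    "ScoreSet",
    "ProteinResult",
    "analyze_protein",
    "best_of_k_fits",
    "classify",
    "fit_origin_ols",
    "flag_high_outliers",
    "mad",
    "median_reference_vector",
    "ransac_fit",
    "raw_scores",
    "rm_scores",
]

_SEED_MOD = 2**31


class FitError(RuntimeError):
    """Raised when a robust regression cannot be obtained."""


class Category(str, Enum):
    """Classification of a peptide at the call sample."""

    LIKELY = "likely"
    POSSIBLY = "possibly"
    LIKELY_NOT = "likely_not"
    REMOVED_OUTLIER = "removed_outlier"
    NOT_EVALUATED = "not_evaluated"


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class IntensityTable:
    """Samples x peptides intensity matrix with reference-group membership.

    ``data`` has one row per sample (index = sample id, order meaningful) and
    one column per peptide; columns are a two-level MultiIndex
    ``(protein_id, peptide_id)``.  Intensities are non-negative; NaN marks a
    missing quantification (removed by the completeness filter before
    scoring).  ``reference_samples`` designates the reference group; a group
    of more than one sample is collapsed to its element-wise median when the
    reference vector is built.
    """

    data: pd.DataFrame
    reference_samples: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not isinstance(self.data.columns, pd.MultiIndex) or self.data.columns.nlevels != 2:
            raise ValueError("data columns must be a (protein, peptide) MultiIndex")
        if self.data.columns.duplicated().any():
            dup = self.data.columns[self.data.columns.duplicated()].tolist()
            raise ValueError(f"duplicate (protein, peptide) columns: {dup}")
        values = self.data.to_numpy(dtype=float, copy=False)
        if np.nanmin(values, initial=0.0) < 0:
            raise ValueError("negative intensities are not allowed")
        self.reference_samples = [str(s) for s in self.reference_samples]
        missing = [s for s in self.reference_samples if s not in self.data.index]
        if missing:
            raise ValueError(f"reference samples not present in table: {missing}")

    @property
    def samples(self) -> list[str]:
        return [str(s) for s in self.data.index]

    @property
    def proteins(self) -> list[str]:
        seen: dict[str, None] = {}
        for prot in self.data.columns.get_level_values(0):
            seen.setdefault(str(prot), None)
        return list(seen)

    @property
    def peptide_keys(self) -> list[tuple[str, str]]:
        return [(str(p), str(q)) for p, q in self.data.columns]

    def protein_frame(self, protein: str) -> pd.DataFrame:
        """Samples x peptides sub-matrix of one protein (columns: peptide ids)."""
        if protein not in self.data.columns.get_level_values(0):
            raise KeyError(f"unknown protein: {protein!r}")
        sub = self.data[protein]
        return sub

    def subset_proteins(self, proteins: Sequence[str]) -> "IntensityTable":
        cols = [c for p in proteins for c in self.data.columns if c[0] == p]
        return IntensityTable(self.data[cols], list(self.reference_samples))


@dataclass(frozen=True)
class RansacConfig:
    """Tunable parameters of the scoring procedure.

    ``max_trials`` random subsets per RANSAC run; ``min_samples_fraction``
    the fraction of peptides drawn per trial; ``n_initiations`` independent
    RANSAC runs among which the best model (by r^2) is kept;
    ``cutoff_likely``/``cutoff_possibly`` the RM thresholds of the three-way
    classification; ``min_peptides`` the minimum number of complete peptides
    a protein needs to be analysed on its own.
    """

    max_trials: int = 1000
    min_samples_fraction: float = 0.5
    n_initiations: int = 30
    cutoff_likely: float = 0.5
    cutoff_possibly: float = 0.6
    min_peptides: int = 5
    random_seed: int | None = None

    def __post_init__(self) -> None:
        if self.max_trials < 1:
            raise ValueError("max_trials must be positive")
        if not 0 < self.min_samples_fraction <= 1:
            raise ValueError("min_samples_fraction must be in (0, 1]")
        if self.n_initiations < 1:
            raise ValueError("n_initiations must be positive")
        if not self.cutoff_likely < self.cutoff_possibly:
            raise ValueError("cutoff_likely must be below cutoff_possibly")
        if self.min_peptides < 3:
            raise ValueError("min_peptides must be >= 3 (top-3 median must exist)")


@dataclass
class ModelFit:
    """Result of one robust origin regression for a (protein, sample) pair."""

    slope: float
    inlier_mask: np.ndarray
    r_squared: float
    residual_threshold: float  # squared-intensity units (MAD of y, squared)
    initiation_index: int = 0

    @property
    def n_inliers(self) -> int:
        return int(self.inlier_mask.sum())


@dataclass
class ScoreSet:
    """Raw scores, outlier gate and RM scores for one (protein, sample)."""

    peptides: list[str]
    raw_scores: np.ndarray
    outlier_flags: np.ndarray
    outlier_threshold: float
    scaling_factor: float  # NaN when the RM step could not be evaluated
    rm_scores: np.ndarray  # NaN for flagged peptides / unevaluated sets
    evaluated: bool

    @property
    def modification_extent(self) -> np.ndarray:
        """1 - RM score: fraction of molecules modified relative to reference."""
        return 1.0 - self.rm_scores


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------


def mad(values: Iterable[float]) -> float:
    """Unscaled median absolute deviation, median(|v - median(v)|).

    No normal-consistency factor is applied: the MAD itself is used as the
    deviation unit both for the RANSAC residual threshold and for the
    high-side raw-score gate.
    """
    v = np.asarray(list(values) if not isinstance(values, np.ndarray) else values, dtype=float)
    if v.size == 0:
        raise ValueError("mad() of an empty vector")
    if not np.isfinite(v).all():
        raise ValueError("mad() requires finite values")
    return float(np.median(np.abs(v - np.median(v))))


def fit_origin_ols(
    x: np.ndarray, y: np.ndarray, subset: np.ndarray | Sequence[int] | None = None
) -> float:
    """Least-squares slope through the origin, beta = sum(x*y) / sum(x^2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if subset is not None:
        subset = np.asarray(subset)
        x = x[subset]
        y = y[subset]
    if x.size < 2:
        raise FitError("origin fit needs at least two points")
    sxx = float(np.dot(x, x))
    if sxx == 0.0:
        raise FitError("degenerate origin fit: sum of x^2 is zero")
    return float(np.dot(x, y) / sxx)


def _r2(y: np.ndarray, pred: np.ndarray) -> float:
    """Coefficient of determination with the mean-centred total sum of squares."""
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        return 1.0 if ss_res == 0.0 else -math.inf
    return 1.0 - ss_res / ss_tot


def ransac_fit(
    x: np.ndarray,
    y: np.ndarray,
    config: RansacConfig | None = None,
    seed: int | None = None,
) -> ModelFit:
    """One RANSAC run of the origin regression.

    For up to ``max_trials`` trials a random subset of
    ``ceil(min_samples_fraction * n)`` peptides is drawn without replacement,
    an origin-OLS slope is fitted to the subset, and peptide j counts as an
    inlier iff ``(y_j - beta x_j)^2 <= MAD(y)^2``.  The candidate with the
    most inliers wins (ties broken by higher r^2 of the candidate model on
    its own inliers, then by trial order); the final slope is an origin-OLS
    refit on the winning inlier set and ``r_squared`` is the coefficient of
    determination of that refit evaluated on all n peptides.  Deterministic
    for a given seed; never stops before ``max_trials``.
    """
    config = config or RansacConfig()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if y.size != n:
        raise ValueError("x and y must have equal length")
    if n < 2:
        raise FitError("too few peptides for a regression")
    if not (x > 0).all():
        raise ValueError("reference intensities must be strictly positive")
    m = max(2, math.ceil(config.min_samples_fraction * n))
    if m > n:
        raise FitError("subset size exceeds number of peptides")
    threshold = mad(y)

    rng = np.random.default_rng(seed)
    # each trial's subset = indices of the m smallest of n iid uniforms
    order = np.argpartition(rng.random((config.max_trials, n)), m - 1, axis=1)[:, :m]
    member = np.zeros((config.max_trials, n), dtype=bool)
    np.put_along_axis(member, order, True, axis=1)

    xy = x * y
    xx = x * x
    beta = (member @ xy) / (member @ xx)
    resid = np.abs(y[None, :] - beta[:, None] * x[None, :])
    inlier = resid <= threshold
    counts = inlier.sum(axis=1)
    best_count = int(counts.max())
    if best_count < 2:
        raise FitError("no trial produced a consensus of at least two inliers")

    tied = np.flatnonzero(counts == best_count)
    masks = inlier[tied]
    betas = beta[tied]
    ybar = (masks @ y) / best_count
    ss_tot = (masks * (y[None, :] - ybar[:, None]) ** 2).sum(axis=1)
    ss_res = (masks * (y[None, :] - betas[:, None] * x[None, :]) ** 2).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2_cand = np.where(
            ss_tot > 0,
            1.0 - ss_res / np.where(ss_tot > 0, ss_tot, 1.0),
            np.where(ss_res == 0, 1.0, -np.inf),
        )
    winner = tied[int(np.argmax(r2_cand))]

    mask = inlier[winner]
    slope = fit_origin_ols(x, y, np.flatnonzero(mask))
    return ModelFit(
        slope=slope,
        inlier_mask=mask,
        r_squared=_r2(y, slope * x),
        residual_threshold=threshold**2,
    )


def _normalize_seed(seed: int | None) -> int:
    if seed is None:
        seed = int(np.random.SeedSequence().generate_state(1, np.uint32)[0])
    return int(seed) % _SEED_MOD


def best_of_k_fits(
    x: np.ndarray,
    y: np.ndarray,
    config: RansacConfig | None = None,
    seed: int | None = None,
) -> ModelFit:
    """Run RANSAC ``n_initiations`` times and keep the model with highest r^2.

    Initiation k uses the sub-seed ``seed + k`` (reproducible for a given
    top-level seed); ties in r^2 go to the lowest initiation index.
    """
    config = config or RansacConfig()
    base = _normalize_seed(seed if seed is not None else config.random_seed)
    best: ModelFit | None = None
    last_error: FitError | None = None
    for k in range(config.n_initiations):
        try:
            fit = ransac_fit(x, y, config, seed=(base + k) % _SEED_MOD)
        except FitError as err:
            last_error = err
            continue
        fit.initiation_index = k
        if best is None or fit.r_squared > best.r_squared:
            best = fit
    if best is None:
        raise FitError(f"all {config.n_initiations} initiations failed: {last_error}")
    return best


def raw_scores(x: np.ndarray, y: np.ndarray, slope: float) -> np.ndarray:
    """Raw score s_j = 1 - (beta x_j - y_j)/(beta x_j) = y_j / (beta x_j).

    The distance is taken as expected minus measured, so a peptide whose
    unmodified intensity dropped scores below 1; complete signal loss gives 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if slope <= 0:
        raise ValueError("slope must be positive for interpretable scores")
    if not (x > 0).all():
        raise ValueError("reference intensities must be strictly positive")
    return y / (slope * x)


def flag_high_outliers(scores: np.ndarray) -> tuple[np.ndarray, float]:
    """One-sided outlier gate: flag raw scores strictly above median + 3 MAD.

    Only the high side is gated: low raw scores are the modification signal.
    Flagged peptides are excluded from RM scaling and reported separately.
    """
    s = np.asarray(scores, dtype=float)
    if s.size == 0:
        raise ValueError("no raw scores to gate")
    threshold = float(np.median(s) + 3.0 * mad(s))
    return s > threshold, threshold


def rm_scores(scores: np.ndarray, flags: np.ndarray) -> tuple[np.ndarray, float]:
    """Scale surviving raw scores by the median of the three highest.

    Returns an array aligned with ``scores`` (NaN at flagged positions) and
    the scaling factor.  Requires at least three unflagged raw scores.
    """
    s = np.asarray(scores, dtype=float)
    flags = np.asarray(flags, dtype=bool)
    surviving = s[~flags]
    if surviving.size < 3:
        raise FitError("fewer than three unflagged raw scores: RM step not evaluable")
    top3 = np.partition(surviving, surviving.size - 3)[-3:]
    scaling = float(np.median(top3))
    if scaling <= 0:
        raise FitError("non-positive scaling factor")
    rm = np.where(flags, np.nan, s / scaling)
    return rm, scaling


def classify(rm: float, config: RansacConfig | None = None) -> Category:
    """Three-way call from an RM score: likely / possibly / likely-not modified."""
    config = config or RansacConfig()
    if not np.isfinite(rm):
        raise ValueError("RM score must be finite")
    if rm < config.cutoff_likely:
        return Category.LIKELY
    if rm < config.cutoff_possibly:
        return Category.POSSIBLY
    return Category.LIKELY_NOT


# ---------------------------------------------------------------------------
# per-protein pipeline
# ---------------------------------------------------------------------------


def median_reference_vector(
    table: IntensityTable, protein: str
) -> tuple[pd.Series, list[str]]:
    """Element-wise median of the reference samples for one protein.

    Returns the reference vector over usable peptides together with the list
    of peptides that were dropped because their reference median is zero,
    missing or non-finite (the later division by x_j would be undefined).
    """
    if not table.reference_samples:
        raise ValueError("table has no reference samples")
    sub = table.protein_frame(protein)
    ref = sub.loc[table.reference_samples].median(axis=0)
    usable = ref.notna() & (ref > 0) & np.isfinite(ref)
    dropped = [str(p) for p in ref.index[~usable]]
    if dropped:
        logger.warning(
            "protein %s: dropping %d peptide(s) with zero/missing reference intensity: %s",
            protein,
            len(dropped),
            dropped,
        )
    return ref[usable], dropped


def _sample_seed(base_seed: int, position: int) -> int:
    """Deterministic per-sample sub-seed (< 2^31) from the top-level seed."""
    state = np.random.SeedSequence([base_seed, position]).generate_state(1, np.uint32)
    return int(state[0]) % _SEED_MOD


@dataclass
class ProteinResult:
    """All per-sample fits, scores and calls of one protein (or pool member)."""

    protein: str
    peptides: list[str]
    samples: list[str]
    reference_samples: list[str]
    fits: dict[str, ModelFit | None]
    scores: dict[str, ScoreSet]
    dropped_peptides: list[str] = field(default_factory=list)
    group_id: str | None = None  # set when scored inside a superprotein pool
    failed_samples: list[str] = field(default_factory=list)

    def rm_frame(self) -> pd.DataFrame:
        """Samples x peptides RM scores (NaN for flagged / unevaluated cells)."""
        return pd.DataFrame(
            {s: self.scores[s].rm_scores for s in self.samples},
            index=self.peptides,
        ).T.rename_axis(index="sample")

    def raw_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {s: self.scores[s].raw_scores for s in self.samples},
            index=self.peptides,
        ).T.rename_axis(index="sample")

    def flags_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {s: self.scores[s].outlier_flags for s in self.samples},
            index=self.peptides,
        ).T.rename_axis(index="sample")

    def diagnostics_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.samples:
            fit = self.fits.get(s)
            sc = self.scores[s]
            rows.append(
                {
                    "protein": self.protein,
                    "sample": s,
                    "group_id": self.group_id,
                    "slope": fit.slope if fit else math.nan,
                    "r_squared": fit.r_squared if fit else math.nan,
                    "n_inliers": fit.n_inliers if fit else 0,
                    "n_peptides": len(self.peptides),
                    "residual_threshold": fit.residual_threshold if fit else math.nan,
                    "initiation_index": fit.initiation_index if fit else -1,
                    "outlier_threshold": sc.outlier_threshold,
                    "scaling_factor": sc.scaling_factor,
                    "evaluated": sc.evaluated,
                }
            )
        return pd.DataFrame(rows)

    def removed_frame(self) -> pd.DataFrame:
        """Long table of peptides flagged as high-side raw-score outliers."""
        rows = []
        for s in self.samples:
            sc = self.scores[s]
            for pep, raw, flag in zip(self.peptides, sc.raw_scores, sc.outlier_flags):
                if flag:
                    rows.append(
                        {
                            "protein": self.protein,
                            "sample": s,
                            "peptide": pep,
                            "raw_score": raw,
                            "outlier_threshold": sc.outlier_threshold,
                        }
                    )
        return pd.DataFrame(
            rows, columns=["protein", "sample", "peptide", "raw_score", "outlier_threshold"]
        )

    def calls(self, call_sample: str | None = None, config: RansacConfig | None = None) -> pd.DataFrame:
        """Per-peptide category at the call sample (default: last sample)."""
        config = config or RansacConfig()
        if call_sample is None:
            call_sample = self.samples[-1]
        if call_sample not in self.scores:
            raise KeyError(f"call sample {call_sample!r} was not scored")
        sc = self.scores[call_sample]
        rows = []
        for pep, rm, flag in zip(self.peptides, sc.rm_scores, sc.outlier_flags):
            if flag:
                cat = Category.REMOVED_OUTLIER
            elif not sc.evaluated or not np.isfinite(rm):
                cat = Category.NOT_EVALUATED
            else:
                cat = classify(float(rm), config)
            rows.append(
                {
                    "protein": self.protein,
                    "peptide": pep,
                    "call_sample": call_sample,
                    "rm_score": rm,
                    "category": cat.value,
                }
            )
        return pd.DataFrame(rows)


def _nan_score_set(peptides: list[str]) -> ScoreSet:
    """Placeholder for a sample whose robust fit failed (no consensus)."""
    n = len(peptides)
    return ScoreSet(
        peptides=list(peptides),
        raw_scores=np.full(n, np.nan),
        outlier_flags=np.zeros(n, dtype=bool),
        outlier_threshold=math.nan,
        scaling_factor=math.nan,
        rm_scores=np.full(n, np.nan),
        evaluated=False,
    )


def _score_sample(
    x: np.ndarray,
    y: np.ndarray,
    peptides: list[str],
    config: RansacConfig,
    seed: int,
) -> tuple[ModelFit, ScoreSet]:
    fit = best_of_k_fits(x, y, config, seed=seed)
    s = raw_scores(x, y, fit.slope)
    flags, threshold = flag_high_outliers(s)
    try:
        rm, scaling = rm_scores(s, flags)
        evaluated = True
    except FitError:
        rm = np.full_like(s, np.nan)
        scaling = math.nan
        evaluated = False
    score_set = ScoreSet(
        peptides=list(peptides),
        raw_scores=s,
        outlier_flags=flags,
        outlier_threshold=threshold,
        scaling_factor=scaling,
        rm_scores=rm,
        evaluated=evaluated,
    )
    return fit, score_set


def analyze_protein(
    table: IntensityTable,
    protein: str,
    config: RansacConfig | None = None,
    seed: int | None = None,
    score_samples: Sequence[str] | None = None,
) -> ProteinResult:
    """Full scoring of one protein across samples.

    Builds the reference vector (median over the reference group), fits the
    robust origin regression per sample (best of ``n_initiations`` RANSAC
    runs), computes raw scores, applies the high-side outlier gate and the
    top-3-median RM scaling, sample by sample.  All samples are scored by
    default, including reference members (which trivially score close to 1);
    ``score_samples`` restricts scoring to a subset, in table order of that
    subset.  Peptides with a zero or missing reference intensity, or missing
    anywhere among the scored samples, are dropped before the
    ``min_peptides`` check.
    """
    config = config or RansacConfig()
    base_seed = _normalize_seed(seed if seed is not None else config.random_seed)

    ref, dropped = median_reference_vector(table, protein)
    sub = table.protein_frame(protein)
    samples = [str(s) for s in (score_samples if score_samples is not None else table.samples)]
    unknown = [s for s in samples if s not in sub.index]
    if unknown:
        raise KeyError(f"samples not present in table: {unknown}")

    complete = sub.loc[samples, ref.index].notna().all(axis=0)
    incomplete = [str(p) for p in ref.index[~complete]]
    if incomplete:
        logger.warning(
            "protein %s: dropping %d peptide(s) with missing sample intensities: %s",
            protein,
            len(incomplete),
            incomplete,
        )
        dropped = dropped + incomplete
        ref = ref[complete]

    peptides = [str(p) for p in ref.index]
    if len(peptides) < config.min_peptides:
        raise FitError(
            f"protein {protein}: only {len(peptides)} complete peptide(s), "
            f"fewer than min_peptides={config.min_peptides}; consider pooling it "
            "into a superprotein group of co-stoichiometric proteins"
        )

    x = ref.to_numpy(dtype=float)
    fits: dict[str, ModelFit | None] = {}
    scores: dict[str, ScoreSet] = {}
    failed: list[str] = []
    for pos, sample in enumerate(samples):
        y = sub.loc[sample, ref.index].to_numpy(dtype=float)
        try:
            fit, score_set = _score_sample(x, y, peptides, config, _sample_seed(base_seed, pos))
        except FitError as err:
            logger.warning("protein %s, sample %s: %s", protein, sample, err)
            fit, score_set = None, _nan_score_set(peptides)
            failed.append(sample)
        fits[sample] = fit
        scores[sample] = score_set

    return ProteinResult(
        protein=protein,
        peptides=peptides,
        samples=samples,
        reference_samples=list(table.reference_samples),
        fits=fits,
        scores=scores,
        dropped_peptides=dropped,
        failed_samples=failed,
    )
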