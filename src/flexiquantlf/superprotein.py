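"""Pooled "superprotein" analysis for proteins with too few peptides.

Proteins contributing fewer than ``min_peptides`` complete peptides cannot be
regressed on their own.  When a set of proteins is known to be
co-stoichiometric (e.g. the core subunits of a stable complex), their
peptides can be pooled and treated as one protein: the robust origin
regression and the raw scores are computed once on the pooled peptide set
per sample, after which the raw scores are split by parent protein and the
high-side outlier gate plus the top-3-median RM scaling run independently
within each protein's partition.

Because the RM score of peptide j is the ratio of y_j/x_j to the top-3
median of the same ratios within its protein, the fitted slope cancels;
for member proteins that are analysable on their own the pooled result is
therefore identical to the individual analysis (a useful internal check).
Proteins whose partition keeps fewer than three unflagged peptides receive
raw scores and flags but no RM scores and are reported as not evaluated.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    Category,
    FitError,
    IntensityTable,
    ModelFit,
    ProteinResult,
    RansacConfig,
    ScoreSet,
    _nan_score_set,
    _normalize_seed,
    _sample_seed,
    best_of_k_fits,
    flag_high_outliers,
    raw_scores,
    rm_scores,
)

logger = logging.getLogger(__name__)

__all__ = ["SuperproteinGroup", "SuperproteinResult", "analyze_superprotein"]


@dataclass
class SuperproteinGroup:
    """User-asserted set of co-stoichiometric proteins to pool.

    ``excluded`` names proteins deliberately left out with a reason, e.g. a
    subunit whose abundance within the complex is known to change over the
    studied conditions and would distort the pooled regression.
    """

    group_id: str
    members: list[str]
    excluded: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("superprotein group needs at least one member protein")
        if len(set(self.members)) != len(self.members):
            raise ValueError("duplicate member proteins in superprotein group")
        overlap = set(self.members) & set(self.excluded)
        if overlap:
            raise ValueError(f"proteins both member and excluded: {sorted(overlap)}")


@dataclass
class SuperproteinResult:
    """Per-protein results of a pooled analysis plus the shared fits."""

    group: SuperproteinGroup
    fits: dict[str, ModelFit]  # one pooled fit per sample
    per_protein: dict[str, ProteinResult]
    dropped_peptides: list[tuple[str, str]] = field(default_factory=list)

    def calls(self, call_sample: str | None = None, config: RansacConfig | None = None) -> pd.DataFrame:
        frames = [res.calls(call_sample, config) for res in self.per_protein.values()]
        return pd.concat(frames, ignore_index=True)


def analyze_superprotein(
    table: IntensityTable,
    group: SuperproteinGroup,
    config: RansacConfig | None = None,
    seed: int | None = None,
    score_samples: list[str] | None = None,
) -> SuperproteinResult:
    """Pooled regression and raw scores; per-protein outlier gating and RM.

    The pooled peptide set must contain at least ``config.min_peptides``
    complete peptides.  Regression and raw scores are shared across the
    pool; flags and RM scaling run within each member protein's partition.
    """
    config = config or RansacConfig()
    base_seed = _normalize_seed(seed if seed is not None else config.random_seed)

    missing = [p for p in group.members if p not in table.proteins]
    if missing:
        raise KeyError(f"superprotein members absent from table: {missing}")

    pooled = table.subset_proteins(group.members)
    ref = pooled.data.loc[pooled.reference_samples].median(axis=0)
    samples = [str(s) for s in (score_samples if score_samples is not None else pooled.samples)]
    complete = pooled.data.loc[samples].notna().all(axis=0)
    usable = ref.notna() & (ref > 0) & np.isfinite(ref) & complete
    dropped = [(str(p), str(q)) for p, q in ref.index[~usable]]
    if dropped:
        logger.warning(
            "superprotein %s: dropping %d peptide(s) with zero/missing intensities",
            group.group_id,
            len(dropped),
        )
    ref = ref[usable]
    keys = [(str(p), str(q)) for p, q in ref.index]
    if len(keys) < config.min_peptides:
        raise FitError(
            f"superprotein {group.group_id}: pooled peptide count {len(keys)} "
            f"below min_peptides={config.min_peptides}"
        )

    x = ref.to_numpy(dtype=float)
    proteins_in_pool = list(dict.fromkeys(p for p, _ in keys))
    partitions = {
        prot: np.array([i for i, (p, _) in enumerate(keys) if p == prot]) for prot in proteins_in_pool
    }

    fits: dict[str, ModelFit | None] = {}
    failed: list[str] = []
    per_sample_scores: dict[str, dict[str, ScoreSet]] = {prot: {} for prot in proteins_in_pool}
    for pos, sample in enumerate(samples):
        y = pooled.data.loc[sample, ref.index].to_numpy(dtype=float)
        try:
            fit = best_of_k_fits(x, y, config, seed=_sample_seed(base_seed, pos))
        except FitError as err:
            logger.warning("superprotein %s, sample %s: %s", group.group_id, sample, err)
            fits[sample] = None
            failed.append(sample)
            for prot, idx in partitions.items():
                per_sample_scores[prot][sample] = _nan_score_set(
                    [q for p, q in keys if p == prot]
                )
            continue
        fits[sample] = fit
        s_pool = raw_scores(x, y, fit.slope)
        for prot, idx in partitions.items():
            s = s_pool[idx]
            flags, threshold = flag_high_outliers(s)
            try:
                rm, scaling = rm_scores(s, flags)
                evaluated = True
            except FitError:
                rm = np.full_like(s, np.nan)
                scaling = math.nan
                evaluated = False
            per_sample_scores[prot][sample] = ScoreSet(
                peptides=[q for p, q in keys if p == prot],
                raw_scores=s,
                outlier_flags=flags,
                outlier_threshold=threshold,
                scaling_factor=scaling,
                rm_scores=rm,
                evaluated=evaluated,
            )

    per_protein: dict[str, ProteinResult] = {}
    for prot in proteins_in_pool:
        per_protein[prot] = ProteinResult(
            protein=prot,
            peptides=[q for p, q in keys if p == prot],
            samples=samples,
            reference_samples=list(table.reference_samples),
            fits=fits,  # pooled fits shared by every member
            scores=per_sample_scores[prot],
            dropped_peptides=[q for p, q in dropped if p == prot],
            group_id=group.group_id,
            failed_samples=list(failed),
        )

    return SuperproteinResult(
        group=group, fits=fits, per_protein=per_protein, dropped_peptides=dropped
    )
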