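"""Readers, preprocessing filters, writers and the end-to-end pipeline.

Input is a peptide-level intensity table exported from upstream search /
DIA-extraction software (after reshaping by the user), in one of two
layouts:

* **wide** -- two header rows (protein identifiers, then peptide
  identifiers), first column sample id, second column group label, one data
  row per sample.  A single flat header of ``protein::peptide`` column names
  is also accepted.
* **long** -- tidy rows with ``sample``, ``protein``, ``peptide``,
  ``intensity`` columns (optionally ``group``, ``modification``, ``start``,
  ``end``), pivoted on read.

Empty cells are missing values; they are distinct from zero in the input
but both fail the completeness filter, since a zero intensity cannot anchor
the regression denominator.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    FitError,
    IntensityTable,
    ProteinResult,
    RansacConfig,
    _normalize_seed,
    analyze_protein,
)
from .superprotein import SuperproteinGroup, SuperproteinResult, analyze_superprotein

logger = logging.getLogger(__name__)

__all__ = [
    "PeptideAnnotation",
    "RunConfig",
    "aggregate_replicates",
    "filter_allowed_modifications",
    "filter_complete",
    "read_intensity_table",
    "read_replicate_map",
    "read_superprotein_groups",
    "run_pipeline",
]

#: Canonical names of the modifications that do not disqualify a peptide
#: from scoring: methionine oxidation and cysteine carbamidomethylation
#: (a fixed chemical artefact of alkylation, not a biological PTM).
DEFAULT_ALLOWED_MODIFICATIONS = frozenset({"oxidation", "carbamidomethyl"})

# upstream dialects spell the same two modifications differently
_MOD_SYNONYMS = {
    "oxidation": "oxidation",
    "ox": "oxidation",
    "carbamidomethyl": "carbamidomethyl",
    "carbamidomethylation": "carbamidomethyl",
    "cam": "carbamidomethyl",
}

_UNMODIFIED_TOKENS = {"", "unmodified", "none", "nan"}


@dataclass
class PeptideAnnotation:
    """Identity and modification state of one peptide.

    Positions, when present, are 1-based inclusive residue coordinates
    within the parent protein.
    """

    protein_id: str
    peptide_sequence: str
    modification_string: str = ""
    start: int | None = None
    end: int | None = None

    def __post_init__(self) -> None:
        if not self.peptide_sequence:
            raise ValueError("peptide sequence must be non-empty")
        if self.start is not None and self.end is not None and not 1 <= self.start <= self.end:
            raise ValueError("positions must satisfy 1 <= start <= end")


def _sep_for(path: Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "\t" if path.suffix.lower() in {".tsv", ".txt", ".tab"} else ","


def _sniff_layout(path: Path, sep: str) -> str:
    with open(path) as handle:
        first = handle.readline().rstrip("\n").split(sep)
    lowered = [f.strip().lower() for f in first]
    if {"sample", "protein", "peptide", "intensity"} <= set(lowered):
        return "long"
    if any("::" in f for f in first[2:]):
        return "wide-flat"
    return "wide"


def _coerce_intensities(values: pd.DataFrame, cell_name) -> pd.DataFrame:
    """String -> float with cell-precise error reporting; empty -> NaN."""
    out = pd.DataFrame(index=values.index, columns=values.columns, dtype=float)
    for col in values.columns:
        raw = values[col].astype(str).str.strip()
        num = pd.to_numeric(raw.replace("", np.nan), errors="coerce")
        bad = num.isna() & (raw != "") & ~raw.str.lower().isin({"nan", "na"})
        if bad.any():
            row = bad.idxmax()
            raise ValueError(
                f"non-numeric intensity {values.at[row, col]!r} at {cell_name(row, col)}"
            )
        neg = num < 0
        if neg.any():
            row = neg.idxmax()
            raise ValueError(f"negative intensity at {cell_name(row, col)}")
        out[col] = num
    return out


def read_intensity_table(
    path: str | Path,
    layout: str = "auto",
    reference_label: str | None = None,
    reference_samples: Sequence[str] | None = None,
    sep: str | None = None,
) -> tuple[IntensityTable, pd.DataFrame | None]:
    """Read a peptide intensity table; returns (table, annotations-or-None).

    The reference group is resolved either from explicit sample ids or from
    the group label column.  Annotations (modification strings, positions)
    are only available from the long layout; wide files carry none and the
    modification filter is then the caller's responsibility upstream.
    """
    path = Path(path)
    sep = _sep_for(path, sep)
    if layout == "auto":
        layout = _sniff_layout(path, sep)
    if layout not in {"wide", "wide-flat", "long"}:
        raise ValueError(f"unknown layout: {layout!r}")

    annotations: pd.DataFrame | None = None
    if layout == "long":
        frame = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
        frame.columns = [c.strip().lower() for c in frame.columns]
        required = {"sample", "protein", "peptide", "intensity"}
        if not required <= set(frame.columns):
            raise ValueError(f"long layout needs columns {sorted(required)}")
        dup = frame.duplicated(subset=["sample", "protein", "peptide"])
        if dup.any():
            row = frame[dup].iloc[0]
            raise ValueError(
                f"duplicate record for sample={row['sample']} protein={row['protein']} "
                f"peptide={row['peptide']}"
            )
        inten = _coerce_intensities(
            frame[["intensity"]],
            lambda row, col: (
                f"row {row + 2} (sample={frame.at[row, 'sample']}, "
                f"protein={frame.at[row, 'protein']}, peptide={frame.at[row, 'peptide']})"
            ),
        )["intensity"]
        wide = pd.DataFrame(
            {"sample": frame["sample"], "protein": frame["protein"], "peptide": frame["peptide"], "intensity": inten}
        ).pivot(index="sample", columns=["protein", "peptide"], values="intensity")
        # preserve input order of samples and peptides
        sample_order = list(dict.fromkeys(frame["sample"]))
        key_order = list(dict.fromkeys(zip(frame["protein"], frame["peptide"])))
        wide = wide.loc[sample_order, pd.MultiIndex.from_tuples(key_order)]
        groups = (
            frame.drop_duplicates("sample").set_index("sample")["group"]
            if "group" in frame.columns
            else pd.Series("", index=wide.index)
        )
        ann_cols = [c for c in ("modification", "start", "end") if c in frame.columns]
        if ann_cols:
            annotations = (
                frame.drop_duplicates(subset=["protein", "peptide"])[["protein", "peptide", *ann_cols]]
                .reset_index(drop=True)
            )
            if "modification" not in annotations.columns:
                annotations["modification"] = ""
    else:
        if layout == "wide":
            raw = pd.read_csv(path, sep=sep, header=None, dtype=str, keep_default_na=False)
            if len(raw) < 3:
                raise ValueError("wide layout needs two header rows and at least one sample row")
            proteins = raw.iloc[0, 2:].astype(str).str.strip().tolist()
            peptides = raw.iloc[1, 2:].astype(str).str.strip().tolist()
            body = raw.iloc[2:].reset_index(drop=True)
        else:  # wide-flat: single "protein::peptide" header
            raw = pd.read_csv(path, sep=sep, header=None, dtype=str, keep_default_na=False)
            header = raw.iloc[0, 2:].astype(str).str.strip().tolist()
            pairs = []
            for name in header:
                if "::" not in name:
                    raise ValueError(f"flat wide header {name!r} is not of the form protein::peptide")
                prot, pep = name.split("::", 1)
                pairs.append((prot, pep))
            proteins = [p for p, _ in pairs]
            peptides = [q for _, q in pairs]
            body = raw.iloc[1:].reset_index(drop=True)
        sample_ids = body.iloc[:, 0].astype(str).str.strip()
        groups = pd.Series(body.iloc[:, 1].astype(str).str.strip().values, index=sample_ids.values)
        values = body.iloc[:, 2:]
        values.index = sample_ids.values
        columns = pd.MultiIndex.from_arrays([proteins, peptides], names=["protein", "peptide"])
        if columns.duplicated().any():
            dup = columns[columns.duplicated()].tolist()
            raise ValueError(f"duplicate (protein, peptide) columns: {dup}")
        values.columns = columns
        values = _coerce_intensities(
            values, lambda row, col: f"sample {row!r}, peptide {col[0]}::{col[1]}"
        )
        wide = values

    wide.columns = pd.MultiIndex.from_tuples(
        [(str(p), str(q)) for p, q in wide.columns], names=["protein", "peptide"]
    )
    wide.index = [str(s) for s in wide.index]

    if reference_samples is not None:
        members = [str(s) for s in reference_samples]
        absent = [s for s in members if s not in wide.index]
        if absent:
            raise ValueError(f"reference samples not found in input: {absent}")
    elif reference_label is not None:
        members = [str(s) for s in wide.index if str(groups.get(s, "")) == reference_label]
        if not members:
            raise ValueError(f"no sample carries reference group label {reference_label!r}")
    else:
        members = []
    return IntensityTable(wide, members), annotations


def _parse_modification_set(text: object) -> set[str] | None:
    """Modification string -> set of canonical modification names.

    Accepts MaxQuant-style ("Oxidation (M); Carbamidomethyl (C)") and
    Spectronaut-style ("Oxidation; Carbamidomethyl") strings.  Returns None
    when the string cannot be interpreted.
    """
    if text is None or (isinstance(text, float) and math.isnan(text)):
        return set()
    tokens = [t for t in re.split(r"[;,+]", str(text)) if t.strip()]
    names: set[str] = set()
    for token in tokens:
        name = re.sub(r"\(.*?\)", "", token).strip().lower()
        name = re.sub(r"^\d+\s*x?\s*", "", name).strip()  # "2 Oxidation (M)" counts once
        if name in _UNMODIFIED_TOKENS:
            continue
        if not name:
            return None
        names.add(_MOD_SYNONYMS.get(name, name))
    return names


def filter_allowed_modifications(
    annotations: pd.DataFrame | Sequence[PeptideAnnotation],
    allowed: frozenset[str] | set[str] | None = None,
) -> tuple[list[tuple[str, str]], list[tuple[str, str]]]:
    """Keep peptides that are unmodified or carry only allowed modifications.

    Returns (retained keys, removed keys).  The default allowed set covers
    methionine oxidation and cysteine carbamidomethylation; peptides with
    unparseable modification strings are removed with a warning.
    """
    allowed_set = {_MOD_SYNONYMS.get(a.lower(), a.lower()) for a in (allowed or DEFAULT_ALLOWED_MODIFICATIONS)}
    if not isinstance(annotations, pd.DataFrame):
        annotations = pd.DataFrame(
            [
                {"protein": a.protein_id, "peptide": a.peptide_sequence, "modification": a.modification_string}
                for a in annotations
            ]
        )
    retained: list[tuple[str, str]] = []
    removed: list[tuple[str, str]] = []
    for _, row in annotations.iterrows():
        key = (str(row["protein"]), str(row["peptide"]))
        mods = _parse_modification_set(row.get("modification", ""))
        if mods is None:
            logger.warning("unparseable modification string for %s; peptide removed", key)
            removed.append(key)
        elif mods <= allowed_set:
            retained.append(key)
        else:
            removed.append(key)
    logger.info(
        "modification filter: %d peptide(s) retained, %d removed", len(retained), len(removed)
    )
    return retained, removed


def filter_complete(table: IntensityTable) -> IntensityTable:
    """Keep only peptides quantified (non-missing, non-zero) in every sample."""
    data = table.data
    ok = data.notna().all(axis=0) & (data > 0).all(axis=0)
    removed = data.columns[~ok]
    if len(removed):
        per_protein = pd.Series(1, index=removed).groupby(level=0).sum()
        for prot, count in per_protein.items():
            logger.info("completeness filter: protein %s lost %d peptide(s)", prot, count)
    return IntensityTable(data.loc[:, ok], list(table.reference_samples))


def aggregate_replicates(
    table: IntensityTable, replicate_map: Mapping[str, str]
) -> IntensityTable:
    """Collapse replicate samples to their condition-level element-wise median.

    Every sample must map to exactly one condition; conditions keep the
    order in which they first appear among the samples.  A condition is a
    reference member when any of its replicates belongs to the reference
    group (mixed conditions trigger a warning).
    """
    unmapped = [s for s in table.samples if s not in replicate_map]
    if unmapped:
        raise ValueError(f"samples without a replicate-map entry: {unmapped}")
    conditions = list(dict.fromkeys(replicate_map[s] for s in table.samples))
    rows = {}
    reference: list[str] = []
    ref_set = set(table.reference_samples)
    for cond in conditions:
        members = [s for s in table.samples if replicate_map[s] == cond]
        if not members:
            raise ValueError(f"condition {cond!r} has no replicates")
        rows[cond] = table.data.loc[members].median(axis=0)
        in_ref = [s for s in members if s in ref_set]
        if in_ref:
            if len(in_ref) != len(members):
                logger.warning(
                    "condition %s mixes reference and non-reference replicates", cond
                )
            reference.append(cond)
    merged = pd.DataFrame(rows).T
    merged.columns = table.data.columns
    return IntensityTable(merged, reference)


def read_superprotein_groups(path: str | Path) -> list[SuperproteinGroup]:
    """Group definition CSV: columns group_id, protein_id, role in {member, excluded}."""
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    frame.columns = [c.strip().lower() for c in frame.columns]
    required = {"group_id", "protein_id", "role"}
    if not required <= set(frame.columns):
        raise ValueError(f"superprotein file needs columns {sorted(required)}")
    groups: list[SuperproteinGroup] = []
    for gid, sub in frame.groupby("group_id", sort=False):
        members = [r["protein_id"] for _, r in sub.iterrows() if r["role"] == "member"]
        excluded = {
            r["protein_id"]: r.get("reason", "") or "excluded"
            for _, r in sub.iterrows()
            if r["role"] == "excluded"
        }
        bad = sub[~sub["role"].isin(["member", "excluded"])]
        if len(bad):
            raise ValueError(f"unknown role {bad.iloc[0]['role']!r} in group {gid}")
        groups.append(SuperproteinGroup(group_id=str(gid), members=members, excluded=excluded))
    return groups


def read_replicate_map(path: str | Path) -> dict[str, str]:
    """Replicate map CSV: columns sample, condition."""
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    frame.columns = [c.strip().lower() for c in frame.columns]
    if not {"sample", "condition"} <= set(frame.columns):
        raise ValueError("replicate map needs columns sample, condition")
    if frame["sample"].duplicated().any():
        raise ValueError("replicate map assigns a sample to more than one condition")
    return dict(zip(frame["sample"], frame["condition"]))


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """End-to-end run configuration for :func:`run_pipeline`."""

    input_path: str | Path
    output_dir: str | Path
    reference_label: str | None = None
    reference_samples: Sequence[str] | None = None
    layout: str = "auto"
    call_sample: str | None = None
    ransac: RansacConfig = field(default_factory=RansacConfig)
    superprotein_path: str | Path | None = None
    replicate_map_path: str | Path | None = None
    allowed_modifications: frozenset[str] | None = None
    seed: int | None = None
    base_name: str | None = None


def _protein_seed(base_seed: int, index: int) -> int:
    state = np.random.SeedSequence([base_seed, 104729, index]).generate_state(1, np.uint32)
    return int(state[0]) % 2**31


def _write_wide(frames: dict[str, pd.DataFrame], path: Path) -> None:
    """Concatenate per-protein samples x peptides frames and write one CSV."""
    pieces = []
    for protein, frame in frames.items():
        piece = frame.copy()
        piece.columns = pd.MultiIndex.from_product(
            [[protein], piece.columns], names=["protein", "peptide"]
        )
        pieces.append(piece)
    combined = pd.concat(pieces, axis=1)
    combined.index.name = "sample"
    combined.to_csv(path)


def run_pipeline(config: RunConfig) -> dict:
    """Read -> filter -> (aggregate) -> score every analysable protein -> write CSVs.

    Writes ``<base>_RM_scores.csv``, ``<base>_raw_scores.csv``,
    ``<base>_removed_peptides.csv``, ``<base>_diagnostics.csv`` and
    ``<base>_calls.csv`` into the output directory.  Proteins below the
    ``min_peptides`` threshold are skipped with a warning unless rescued by a
    superprotein group; pooled results enter the main outputs only for
    proteins that could not be analysed individually (the pooled run is
    otherwise redundant with the individual one).
    """
    in_path = Path(config.input_path)
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    base = config.base_name or in_path.stem
    seed = _normalize_seed(config.seed)

    table, annotations = read_intensity_table(
        in_path,
        layout=config.layout,
        reference_label=config.reference_label,
        reference_samples=config.reference_samples,
    )
    if not table.reference_samples:
        raise ValueError("no reference group: pass reference_label or reference_samples")
    n_initial = len(table.peptide_keys)

    if annotations is not None and "modification" in annotations.columns:
        retained, removed = filter_allowed_modifications(annotations, config.allowed_modifications)
        keep = [k for k in table.peptide_keys if k in set(retained)]
        table = IntensityTable(table.data[keep], table.reference_samples)
        logger.info("modification filter: %d -> %d peptides", n_initial, len(keep))

    table = filter_complete(table)
    logger.info("completeness filter: %d peptides remain", len(table.peptide_keys))

    if config.replicate_map_path is not None:
        table = aggregate_replicates(table, read_replicate_map(config.replicate_map_path))

    if config.call_sample is not None and config.call_sample not in table.samples:
        raise ValueError(f"call sample {config.call_sample!r} not present after preprocessing")

    results: dict[str, ProteinResult] = {}
    skipped: list[str] = []
    for idx, protein in enumerate(table.proteins):
        try:
            results[protein] = analyze_protein(
                table, protein, config.ransac, seed=_protein_seed(seed, idx)
            )
        except FitError as err:
            logger.warning("%s", err)
            skipped.append(protein)

    super_results: list[SuperproteinResult] = []
    if config.superprotein_path is not None:
        for gidx, group in enumerate(read_superprotein_groups(config.superprotein_path)):
            res = analyze_superprotein(
                table, group, config.ransac, seed=_protein_seed(seed, 10_000 + gidx)
            )
            super_results.append(res)
            for protein, prot_res in res.per_protein.items():
                if protein not in results:
                    results[protein] = prot_res

    if not results:
        raise FitError("no protein passed the min_peptides threshold")

    ordered = {p: results[p] for p in table.proteins if p in results}
    rm_path = out_dir / f"{base}_RM_scores.csv"
    raw_path = out_dir / f"{base}_raw_scores.csv"
    removed_path = out_dir / f"{base}_removed_peptides.csv"
    diag_path = out_dir / f"{base}_diagnostics.csv"
    calls_path = out_dir / f"{base}_calls.csv"

    _write_wide({p: r.rm_frame() for p, r in ordered.items()}, rm_path)
    _write_wide({p: r.raw_frame() for p, r in ordered.items()}, raw_path)
    removed_frames = [f for r in ordered.values() if len(f := r.removed_frame())]
    if removed_frames:
        pd.concat(removed_frames, ignore_index=True).to_csv(removed_path, index=False)
    else:
        next(iter(ordered.values())).removed_frame().to_csv(removed_path, index=False)
    pd.concat([r.diagnostics_frame() for r in ordered.values()], ignore_index=True).to_csv(
        diag_path, index=False
    )
    pd.concat(
        [r.calls(config.call_sample, config.ransac) for r in ordered.values()],
        ignore_index=True,
    ).to_csv(calls_path, index=False)

    return {
        "results": ordered,
        "superprotein_results": super_results,
        "skipped_proteins": skipped,
        "paths": {
            "rm_scores": rm_path,
            "raw_scores": raw_path,
            "removed_peptides": removed_path,
            "diagnostics": diag_path,
            "calls": calls_path,
        },
    }
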