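"""Ratio computation, two-point reference calibration, parcel aggregation,
and age-balanced subject subsampling for measurement tables.

Ratio values are in arbitrary units throughout; calibration maps each
individual's reference-structure values (high = white-matter-like, low =
CSF-like) onto the group-average references with an affine transform.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

__all__ = [
    "compute_ratio",
    "calibrate_ratio",
    "aggregate_to_table",
    "balanced_subsample",
    "validate_table",
]

log = logging.getLogger(__name__)

TABLE_COLUMNS = ["subject_id", "species", "age", "sex", "parcel_id", "depth_bin", "value"]


def compute_ratio(t1w, t2w):
    """Elementwise ``t1w / t2w`` with invalid samples masked.

    Samples with zero or non-finite ``t2w`` (or non-finite ``t1w``) are
    returned as NaN; the number of masked samples is logged.
    """
    t1 = np.asarray(t1w, dtype=float)
    t2 = np.asarray(t2w, dtype=float)
    bad = ~np.isfinite(t1) | ~np.isfinite(t2) | (t2 == 0)
    n_bad = int(np.sum(bad))
    if n_bad:
        log.info("compute_ratio: masked %d invalid samples", n_bad)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(bad, np.nan, t1 / np.where(bad, 1.0, t2))
    return out if out.ndim else float(out)


def calibrate_ratio(
    values,
    ref_high_individual: float,
    ref_low_individual: float,
    ref_high_group: float,
    ref_low_group: float,
):
    """Affine calibration mapping individual reference values to group references.

    Sends ``(ref_low_individual, ref_high_individual)`` exactly onto
    ``(ref_low_group, ref_high_group)``:
    ``v' = ref_low_group + (v - ref_low_individual) * scale`` with
    ``scale = (ref_high_group - ref_low_group) /
    (ref_high_individual - ref_low_individual)``.
    """
    if ref_high_individual <= ref_low_individual:
        raise ValueError("individual references degenerate: high must exceed low")
    v = np.asarray(values, dtype=float)
    scale = (ref_high_group - ref_low_group) / (ref_high_individual - ref_low_individual)
    out = ref_low_group + (v - ref_low_individual) * scale
    return out if out.ndim else float(out)


def aggregate_to_table(samples: pd.DataFrame, value_col: str = "value") -> pd.DataFrame:
    """Average per-sample values into a (subject, parcel, depth-bin) table.

    ``samples`` must carry ``subject_id``, ``parcel_id`` and ``depth_bin``
    labels per sample (plus any of ``species``, ``age``, ``sex``, ``visit``
    which are carried through); the cell value is the arithmetic mean of the
    member samples and a ``n_samples`` count is retained for QC.  Cells with
    no finite samples are omitted and logged.
    """
    required = {"subject_id", "parcel_id", "depth_bin", value_col}
    if not required <= set(samples.columns):
        raise ValueError(f"samples must have columns {sorted(required)}")
    keys = ["subject_id", "parcel_id", "depth_bin"]
    if "visit" in samples.columns:
        keys = ["subject_id", "visit", "parcel_id", "depth_bin"]
    carry = [c for c in ("species", "age", "sex") if c in samples.columns]
    work = samples.dropna(subset=[value_col])
    n_dropped_cells = samples.groupby(keys, sort=True).size().shape[0] - (
        work.groupby(keys, sort=True).size().shape[0] if len(work) else 0
    )
    if n_dropped_cells:
        log.info("aggregate_to_table: %d empty cells omitted", n_dropped_cells)
    agg = (
        work.groupby(keys, sort=True)
        .agg(**{
            "value": (value_col, "mean"),
            "n_samples": (value_col, "size"),
            **{c: (c, "first") for c in carry},
        })
        .reset_index()
    )
    return agg


def balanced_subsample(
    table: pd.DataFrame, bin_width: float, per_bin: int, seed: int
) -> pd.DataFrame:
    """Subsample subjects to an age-balanced design.

    Subjects are binned by age into left-closed right-open intervals of width
    ``bin_width`` anchored at the minimum age; within each bin at most
    ``per_bin`` subjects are drawn uniformly without replacement, and all rows
    of the selected subjects are retained.
    """
    if per_bin < 1:
        raise ValueError("per_bin must be >= 1")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    subj = table.groupby("subject_id", sort=True)["age"].min()
    origin = subj.min()
    bins = np.floor((subj - origin) / bin_width).astype(int)
    # the oldest subject falls on a right edge; keep it in the last bin
    rng = np.random.default_rng(seed)
    keep: list = []
    for _, members in subj.groupby(bins, sort=True):
        ids = members.index.to_numpy()
        if len(ids) > per_bin:
            ids = rng.choice(ids, size=per_bin, replace=False)
        keep.extend(ids)
    return table[table["subject_id"].isin(set(keep))].copy()


def validate_table(table: pd.DataFrame) -> None:
    """Check measurement-table invariants; raise ``ValueError`` on violation."""
    missing = set(TABLE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"table missing columns {sorted(missing)}")
    if (table["age"] <= 0).any():
        raise ValueError("ages must be positive")
    keys = ["subject_id", "parcel_id", "depth_bin"]
    if "visit" in table.columns:
        keys.insert(1, "visit")
    if table.duplicated(subset=keys).any():
        raise ValueError("duplicate (subject, visit, parcel, depth_bin) keys")
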