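"""Ingest, validate and aggregate raw per-image grimace scores.

Raw data are one row per scored video frame: animal identity, treatment
(``Oil`` vehicle control vs ``CCl4``), study week (0 = un-injected baseline),
injection day within week (1-3), intervention phase (``bsl``/``pre``/``post``)
and five ordinal facial action unit (FAU) scores, each in {0, 1, 2} with -1
marking a frame rejected for that criterion (poor quality, FAU not visible).

The analysis table is per *video*: for every (animal, week, day, intervention)
cell the accepted images are aggregated into one FAU score per criterion and
an average picture score (mean per-image sum over all five FAUs, range 0-10).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Facial action units, in the conventional reporting order:
#: orbital tightening, nose bulge, cheek bulge, ear position, whisker change.
FAUS: tuple[str, ...] = ("ot", "nb", "cb", "ep", "wc")

TREATMENTS: tuple[str, ...] = ("Oil", "CCl4")
INTERVENTIONS: tuple[str, ...] = ("bsl", "pre", "post")

#: Columns identifying one video.
VIDEO_KEY: tuple[str, ...] = ("animal_id", "week", "day", "intervention")

IMAGE_COLUMNS: tuple[str, ...] = (
    "animal_id",
    "treatment",
    "week",
    "day",
    "intervention",
    *FAUS,
)

AGGREGATION_MODES: tuple[str, ...] = ("mean", "sum", "scaled_sum")

#: Nominal number of randomly selected frames per video; ``scaled_sum``
#: multiplies the per-accepted-image mean by this count so that videos with
#: rejected frames stay on the same 0-16 per-FAU scale.
NOMINAL_IMAGES_PER_VIDEO = 8


class ConfigurationError(ValueError):
    """A required column is missing or a column map is inconsistent."""


@dataclass
class Dataset:
    """Per-video analysis table plus provenance.

    Attributes
    ----------
    records
        One row per retained video with the key columns, per-FAU aggregated
        scores (``ot_score`` ... ``wc_score``), per-FAU accepted-image counts
        (``n_images_ot`` ...) and ``avg_picture_score``.
    provenance
        Source path / generator settings and the aggregation mode used.
    n_dropped
        Videos dropped because every frame was rejected for some FAU.
    """

    records: pd.DataFrame
    provenance: dict = field(default_factory=dict)
    n_dropped: int = 0

    @property
    def n_animals(self) -> int:
        return int(self.records["animal_id"].nunique())

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.records)

    def validate(self) -> None:
        """Raise ``ValueError`` on violated table invariants."""
        df = self.records
        dup = df.duplicated(subset=list(VIDEO_KEY))
        if dup.any():
            raise ValueError(
                f"duplicate video keys: {df.loc[dup, list(VIDEO_KEY)].values[:5]}"
            )
        bsl = df["intervention"] == "bsl"
        if not ((df["week"] == 0) == bsl).all():
            raise ValueError("week 0 must coincide exactly with intervention 'bsl'")
        if (df["avg_picture_score"].dropna() < 0).any() or (
            df["avg_picture_score"].dropna() > 10
        ).any():
            raise ValueError("avg_picture_score outside [0, 10]")
        score_cols = [f"{k}_score" for k in FAUS]
        if (df[score_cols] < 0).any().any():
            raise ValueError("negative aggregated FAU score")


def _apply_column_map(df: pd.DataFrame, column_map: Mapping[str, str] | None) -> pd.DataFrame:
    if column_map:
        df = df.rename(columns={v: k for k, v in column_map.items()})
    missing = [c for c in IMAGE_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigurationError(
            f"missing required column(s) {missing}; available: {list(df.columns)}"
        )
    return df


def validate_image_scores(df: pd.DataFrame) -> pd.DataFrame:
    """Check domains of an image-score table; returns the validated frame."""
    for col in ("week", "day"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            bad = df.index[vals.isna()][0]
            raise ValueError(f"non-integer {col!r} in row {bad}")
        df[col] = vals.astype(int)
    if not df["week"].between(0, 4).all():
        bad = df.index[~df["week"].between(0, 4)][0]
        raise ValueError(f"week outside 0-4 in row {bad}")
    if not df["day"].between(1, 3).all():
        bad = df.index[~df["day"].between(1, 3)][0]
        raise ValueError(f"day outside 1-3 in row {bad}")
    bad_treat = ~df["treatment"].isin(TREATMENTS)
    if bad_treat.any():
        raise ValueError(
            f"unknown treatment {df.loc[bad_treat, 'treatment'].iloc[0]!r} "
            f"in row {df.index[bad_treat][0]}"
        )
    bad_iv = ~df["intervention"].isin(INTERVENTIONS)
    if bad_iv.any():
        raise ValueError(
            f"unknown intervention {df.loc[bad_iv, 'intervention'].iloc[0]!r} "
            f"in row {df.index[bad_iv][0]}"
        )
    for fau in FAUS:
        vals = pd.to_numeric(df[fau], errors="coerce")
        if vals.isna().any():
            bad = df.index[vals.isna()][0]
            raise ValueError(f"non-integer {fau} score in row {bad}")
        if not vals.isin((-1, 0, 1, 2)).all():
            bad = df.index[~vals.isin((-1, 0, 1, 2))][0]
            raise ValueError(
                f"{fau} score {vals.loc[bad]} outside {{-1,0,1,2}} in row {bad}"
            )
        df[fau] = vals.astype(int)
    bsl = df["intervention"] == "bsl"
    if not ((df["week"] == 0) == bsl).all():
        bad = df.index[(df["week"] == 0) != bsl][0]
        raise ValueError(f"week/intervention mismatch in row {bad} (week 0 <=> bsl)")
    return df


def read_image_scores(
    path: str | Path, column_map: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Read a per-image score CSV into the canonical column layout.

    Parameters
    ----------
    path
        CSV file with one row per scored frame.
    column_map
        Optional mapping from canonical names (``animal_id``, ``treatment``,
        ``week``, ``day``, ``intervention``, ``ot`` ... ``wc``) to the file's
        actual headers, for adapting arbitrary raw layouts.
    """
    df = pd.read_csv(path)
    df = _apply_column_map(df, column_map)
    df = validate_image_scores(df[list(IMAGE_COLUMNS)].copy())
    logger.info("read %d image scores from %s", len(df), path)
    return df


def aggregate_videos(images: pd.DataFrame, mode: str = "scaled_sum") -> Dataset:
    """Aggregate per-image scores into one record per video.

    Rejected values (-1) are excluded per FAU before aggregating. ``mode``:

    ``mean``
        mean score per accepted image (0-2 scale),
    ``sum``
        sum over accepted images (0-16 at 8 frames),
    ``scaled_sum``
        per-image mean times the nominal 8 frames (default; keeps videos with
        rejected frames comparable on the 0-16 scale).

    ``avg_picture_score`` is the mean, over images with *all five* FAUs
    accepted, of the per-image sum of the five scores. Videos in which every
    image is rejected for some FAU are dropped (counted in ``n_dropped``).
    """
    if images.empty:
        raise ValueError("no image scores to aggregate")
    if mode not in AGGREGATION_MODES:
        raise ValueError(f"unknown aggregation mode {mode!r}; use {AGGREGATION_MODES}")

    masked = images.copy()
    for fau in FAUS:
        masked[fau] = masked[fau].where(masked[fau] >= 0)
    complete = masked[list(FAUS)].notna().all(axis=1)
    masked["picture_score"] = masked[list(FAUS)].sum(axis=1).where(complete)

    # duplicate keys are pooled: repeated rows are frames of the same video
    grouped = masked.groupby(list(VIDEO_KEY), sort=True, observed=True)
    agg: dict[str, pd.Series] = {"treatment": grouped["treatment"].first()}
    for fau in FAUS:
        n = grouped[fau].count()
        agg[f"n_images_{fau}"] = n
        if mode == "mean":
            agg[f"{fau}_score"] = grouped[fau].mean()
        elif mode == "sum":
            agg[f"{fau}_score"] = grouped[fau].sum()
        else:
            agg[f"{fau}_score"] = grouped[fau].mean() * NOMINAL_IMAGES_PER_VIDEO
    agg["n_images"] = grouped[FAUS[0]].size()
    agg["avg_picture_score"] = grouped["picture_score"].mean()

    records = pd.DataFrame(agg).reset_index()
    incomplete = pd.DataFrame(
        {f: records[f"n_images_{f}"] == 0 for f in FAUS}
    ).any(axis=1)
    n_dropped = int(incomplete.sum())
    if n_dropped:
        warnings.warn(
            f"dropped {n_dropped} video(s) with every image rejected for some FAU",
            stacklevel=2,
        )
        records = records.loc[~incomplete]
    records = records.reset_index(drop=True)
    cols = [
        "animal_id",
        "treatment",
        "week",
        "day",
        "intervention",
        *[f"{f}_score" for f in FAUS],
        *[f"n_images_{f}" for f in FAUS],
        "n_images",
        "avg_picture_score",
    ]
    ds = Dataset(
        records=records[cols],
        provenance={"aggregation": mode, "n_images_in": int(len(images))},
        n_dropped=n_dropped,
    )
    ds.validate()
    return ds


def summarize_dataset(ds: Dataset) -> dict:
    """Deterministic bookkeeping summary of a per-video dataset."""
    df = ds.records
    by_cell = (
        df.groupby(["treatment", "intervention", "week"], observed=True)
        .size()
        .sort_index()
    )
    return {
        "n_records": int(len(df)),
        "n_animals": ds.n_animals,
        "n_dropped_videos": ds.n_dropped,
        "records_by_treatment_intervention_week": {
            f"{t}/{i}/week{w}": int(n) for (t, i, w), n in by_cell.items()
        },
        "records_by_treatment": {
            t: int(n) for t, n in df.groupby("treatment", observed=True).size().items()
        },
        "mean_images_per_video": float(df["n_images"].mean()) if len(df) else 0.0,
    }


def write_dataset(ds: Dataset, path: str | Path) -> None:
    ds.records.to_csv(path, index=False)


def read_dataset(path: str | Path, provenance: dict | None = None) -> Dataset:
    records = pd.read_csv(path)
    ds = Dataset(records=records, provenance=provenance or {"source": str(path)})
    ds.validate()
    return ds


def write_image_scores(images: pd.DataFrame, path: str | Path) -> None:
    images[list(IMAGE_COLUMNS)].to_csv(path, index=False)
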