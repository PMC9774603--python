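"""PSPI labeling: scores from action units, level clustering, rebalancing, splits.

The Prkachin–Solomon Pain Intensity (PSPI) score summarises a facial
expression frame as a linear combination of FACS action-unit intensities:

    PSPI = AU4 + max(AU6, AU7) + max(AU9, AU10) + AU43

where AU4 (brow lowerer), AU6 (cheek raiser), AU7 (lid tightener), AU9
(nose wrinkler) and AU10 (upper-lip raiser) carry integer intensities 0-5
and AU43 (eye closure) is binary.  Frame-level datasets annotated this way
are extremely imbalanced — neutral (PSPI 0) frames dominate — so the
standard curation pipeline clusters the 16 raw scores into 6 classes and
subsamples the neutral class before training.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AUVector",
    "FrameRecord",
    "FrequencyTable",
    "compute_pspi",
    "cluster_level",
    "rebalance_level0",
    "frequency_table",
    "stratified_split",
    "read_label_table",
    "records_to_frame",
    "UNBC_TABLE1",
    "table1_records",
]

N_CLUSTERED_LEVELS = 6

_AU_RANGES = {
    "au4": (0, 5),
    "au6": (0, 5),
    "au7": (0, 5),
    "au9": (0, 5),
    "au10": (0, 5),
    "au43": (0, 1),
}


@dataclass(frozen=True)
class AUVector:
    """Action-unit intensities for one frame (integers within FACS ranges)."""

    au4: int
    au6: int
    au7: int
    au9: int
    au10: int
    au43: int

    def __post_init__(self) -> None:
        for name, (lo, hi) in _AU_RANGES.items():
            value = getattr(self, name)
            if not isinstance(value, (int, np.integer)) or isinstance(value, bool):
                raise ValueError(f"{name} must be an integer, got {value!r}")
            if not lo <= value <= hi:
                raise ValueError(f"{name}={value} outside valid range [{lo}, {hi}]")

    def as_dict(self) -> dict[str, int]:
        return {k: int(getattr(self, k)) for k in _AU_RANGES}


@dataclass
class FrameRecord:
    """One curated frame: image reference, PSPI score and clustered level."""

    frame_id: str
    image_path: str | None
    pspi: int
    clustered_level: int | None = None
    au: AUVector | None = None

    def __post_init__(self) -> None:
        if self.pspi < 0:
            raise ValueError(f"pspi must be >= 0, got {self.pspi}")
        if self.clustered_level is not None:
            expected = cluster_level(self.pspi)
            if self.clustered_level != expected:
                raise ValueError(
                    f"clustered_level={self.clustered_level} inconsistent with "
                    f"pspi={self.pspi} (expected {expected})"
                )


@dataclass
class FrequencyTable:
    """Per-level frame counts and percent frequencies."""

    raw_counts: dict[int, int]
    raw_frequencies: dict[int, float]
    clustered_counts: dict[int, int]
    clustered_frequencies: dict[int, float]
    total: int

    def to_frame(self) -> pd.DataFrame:
        levels = sorted(self.raw_counts)
        return pd.DataFrame(
            {
                "pspi": levels,
                "frames": [self.raw_counts[l] for l in levels],
                "frequency_pct": [self.raw_frequencies[l] for l in levels],
            }
        )


def compute_pspi(au: AUVector) -> int:
    """PSPI score: au4 + max(au6, au7) + max(au9, au10) + au43."""
    return int(au.au4 + max(au.au6, au.au7) + max(au.au9, au.au10) + au.au43)


def cluster_level(pspi: int) -> int:
    """Map a raw PSPI score to the 6-class label space.

    Scores 0-3 keep their value, 4 and 5 merge into class 4, and everything
    from 6 upward becomes class 5.
    """
    if pspi < 0:
        raise ValueError(f"pspi must be >= 0, got {pspi}")
    if pspi <= 3:
        return int(pspi)
    if pspi <= 5:
        return 4
    return 5


def rebalance_level0(
    records: Sequence[FrameRecord],
    keep_every: int = 10,
    seed: int | None = None,
    strategy: str = "stride",
) -> list[FrameRecord]:
    """Subsample the neutral class, keeping one of every ``keep_every`` frames.

    All records with clustered_level != 0 are retained.  With the default
    ``stride`` strategy the k-th, 2k-th, ... level-0 records (in input order)
    survive, so exactly floor(n0 / keep_every) remain and the output is
    deterministic.  The ``random`` strategy instead draws the same number of
    level-0 records uniformly without replacement using ``seed``.  Output
    preserves input order.
    """
    if keep_every < 1:
        raise ValueError(f"keep_every must be >= 1, got {keep_every}")
    level0_positions = [
        i for i, r in enumerate(records) if _require_level(r) == 0
    ]
    n_keep = len(level0_positions) // keep_every
    if strategy == "stride":
        kept0 = {level0_positions[keep_every * (j + 1) - 1] for j in range(n_keep)}
    elif strategy == "random":
        rng = np.random.default_rng(seed)
        kept0 = set(
            np.asarray(level0_positions)[
                rng.choice(len(level0_positions), size=n_keep, replace=False)
            ].tolist()
        )
    else:
        raise ValueError(f"unknown strategy {strategy!r}")
    return [
        r
        for i, r in enumerate(records)
        if r.clustered_level != 0 or i in kept0
    ]


def _require_level(record: FrameRecord) -> int:
    if record.clustered_level is None:
        raise ValueError(f"record {record.frame_id!r} has no clustered_level")
    return record.clustered_level


def frequency_table(records: Sequence[FrameRecord]) -> FrequencyTable:
    """Count frames per raw PSPI level and per clustered level.

    Percent frequencies are recomputed from the counts (they sum to 100
    within rounding).
    """
    raw: dict[int, int] = {}
    clustered: dict[int, int] = {}
    for r in records:
        raw[r.pspi] = raw.get(r.pspi, 0) + 1
        lvl = r.clustered_level if r.clustered_level is not None else cluster_level(r.pspi)
        clustered[lvl] = clustered.get(lvl, 0) + 1
    total = len(records)
    raw_freq = {k: 100.0 * v / total for k, v in raw.items()} if total else {}
    clu_freq = {k: 100.0 * v / total for k, v in clustered.items()} if total else {}
    return FrequencyTable(
        raw_counts=dict(sorted(raw.items())),
        raw_frequencies=dict(sorted(raw_freq.items())),
        clustered_counts=dict(sorted(clustered.items())),
        clustered_frequencies=dict(sorted(clu_freq.items())),
        total=total,
    )


def stratified_split(
    records: Sequence[FrameRecord],
    train_fraction: float = 0.8,
    seed: int | None = None,
) -> tuple[list[FrameRecord], list[FrameRecord]]:
    """Split records into train/test stratified by clustered level.

    Per-level train counts are round(n_level * train_fraction), so every
    level's proportions are within one record of exact stratification.
    Levels with a single record go to the train set with a warning.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError(f"train_fraction must be in (0, 1), got {train_fraction}")
    rng = np.random.default_rng(seed)
    by_level: dict[int, list[int]] = {}
    for i, r in enumerate(records):
        by_level.setdefault(_require_level(r), []).append(i)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for level in sorted(by_level):
        idx = np.asarray(by_level[level])
        if len(idx) < 2:
            warnings.warn(
                f"level {level} has {len(idx)} record(s); assigned to train",
                stacklevel=2,
            )
            train_idx.extend(idx.tolist())
            continue
        perm = rng.permutation(len(idx))
        n_train = int(round(len(idx) * train_fraction))
        n_train = min(max(n_train, 1), len(idx) - 1)
        train_idx.extend(idx[perm[:n_train]].tolist())
        test_idx.extend(idx[perm[n_train:]].tolist())
    train_idx.sort()
    test_idx.sort()
    return [records[i] for i in train_idx], [records[i] for i in test_idx]


# ---------------------------------------------------------------------------
# Label-table I/O

_AU_COLUMNS = ["au4", "au6", "au7", "au9", "au10", "au43"]


def read_label_table(path: str | Path, images_dir: str | Path | None = None) -> list[FrameRecord]:
    """Read a frame label table (CSV/TSV with header) into FrameRecords.

    Accepts either AU-annotation columns (frame_id, au4, au6, au7, au9,
    au10, au43) — PSPI is computed — or a precomputed score column
    (frame_id, pspi).  An optional image_path column is honoured; otherwise
    image paths are ``images_dir / frame_id``.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep)
    cols = {c.lower(): c for c in df.columns}
    if "frame_id" not in cols:
        raise ValueError(f"{path}: label table must have a frame_id column")
    records = []
    has_au = all(c in cols for c in _AU_COLUMNS)
    if not has_au and "pspi" not in cols:
        raise ValueError(
            f"{path}: need either AU columns ({', '.join(_AU_COLUMNS)}) or a pspi column"
        )
    for _, row in df.iterrows():
        frame_id = str(row[cols["frame_id"]])
        au = None
        if has_au:
            au = AUVector(**{c: int(row[cols[c]]) for c in _AU_COLUMNS})
            pspi = compute_pspi(au)
        else:
            pspi = int(row[cols["pspi"]])
        if "image_path" in cols and not pd.isna(row[cols["image_path"]]):
            image_path = str(row[cols["image_path"]])
        elif images_dir is not None:
            image_path = str(Path(images_dir) / frame_id)
        else:
            image_path = None
        records.append(
            FrameRecord(
                frame_id=frame_id,
                image_path=image_path,
                pspi=pspi,
                clustered_level=cluster_level(pspi),
                au=au,
            )
        )
    return records


def records_to_frame(records: Iterable[FrameRecord]) -> pd.DataFrame:
    """Serialize records to the manifest dialect (CSV-ready DataFrame)."""
    rows = []
    for r in records:
        row = {
            "frame_id": r.frame_id,
            "image_path": r.image_path,
            "pspi": r.pspi,
            "clustered_level": r.clustered_level,
        }
        if r.au is not None:
            row.update(r.au.as_dict())
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Published UNBC-McMaster frequency table (per-level frame counts and the
# printed percent frequencies), used for data-curation arithmetic when the
# restricted image archive itself is unavailable.

UNBC_TABLE1: dict[int, tuple[int, float]] = {
    0: (40029, 82.7439),
    1: (2909, 6.0132),
    2: (2351, 4.8597),
    3: (1412, 2.9187),
    4: (802, 1.6578),
    5: (242, 0.5002),
    6: (270, 0.5581),
    7: (53, 0.1096),
    8: (79, 0.1633),
    9: (32, 0.0661),
    10: (67, 0.1385),
    11: (76, 0.1571),
    12: (48, 0.0992),
    13: (22, 0.0455),
    14: (1, 0.0021),
    15: (5, 0.0103),
}


def table1_records() -> list[FrameRecord]:
    """Expand the published per-level counts into synthetic FrameRecords.

    Image paths are None: these records only carry labels, enough for the
    clustering / rebalancing / frequency bookkeeping.
    """
    records = []
    for level, (count, _pct) in UNBC_TABLE1.items():
        for i in range(count):
            records.append(
                FrameRecord(
                    frame_id=f"l{level:02d}_{i:05d}",
                    image_path=None,
                    pspi=level,
                    clustered_level=cluster_level(level),
                )
            )
    return records
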