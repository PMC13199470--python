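"""Bioactivity profiles: assay selection and fixed-width conditioning vectors.

A compound's in-silico bioactivity profile is a vector of predicted pAC50
values (negative log10 molar half-maximal activity concentration), one entry
per assay, produced upstream by a massively multitask QSAR model.  Before a
profile can condition the image generator two things happen here:

1. *Assay selection* — the raw assay panel is reduced to a useful subset by a
   quality cascade: per annotated protein target keep the single best model
   with r^2 above a floor; per drug-discovery project keep the single best
   purely-phenotypic model above the same floor; keep unannotated assays only
   when their models are of very high quality.
2. *Zero padding* — the selected-assay vector is padded with trailing zeros to
   the fixed conditioning width expected by the denoiser's cross-attention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AssayRecord",
    "BioactivityProfile",
    "select_assays",
    "pad_profile",
    "read_profile_table",
    "write_profile_table",
    "read_assay_table",
    "standardize_profiles",
]

Category = Literal["target_annotated", "project_annotated", "unannotated"]

DEFAULT_WIDTH = 2048
DEFAULT_R2_MIN = 0.3
DEFAULT_R2_HQ = 0.9


@dataclass(frozen=True)
class AssayRecord:
    """One assay and the quality of its activity-prediction model.

    ``r2`` is the squared Pearson correlation between predicted and
    experimental pAC50 on a held-out set, so it lives in [0, 1].  Categories
    are exclusive: an assay with a target annotation is target_annotated even
    if it also belongs to a project.
    """

    assay_id: str
    r2: float
    category: Category
    target_id: str | None = None
    project_id: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.r2 <= 1.0:
            raise ValueError(f"r2 must be in [0, 1], got {self.r2} for {self.assay_id}")
        if self.category == "target_annotated" and self.target_id is None:
            raise ValueError(f"target_annotated assay {self.assay_id} lacks target_id")
        if self.category == "project_annotated" and self.project_id is None:
            raise ValueError(f"project_annotated assay {self.assay_id} lacks project_id")
        if self.category not in ("target_annotated", "project_annotated", "unannotated"):
            raise ValueError(f"unknown category {self.category!r}")


@dataclass
class BioactivityProfile:
    """Per-compound activity vector plus its padded conditioning form."""

    compound_id: str
    values: np.ndarray
    width: int = DEFAULT_WIDTH
    padded: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"profile for {self.compound_id} contains non-finite values")
        self.padded = pad_profile(self.values, self.width)


def select_assays(
    assays: Sequence[AssayRecord],
    r2_min: float = DEFAULT_R2_MIN,
    r2_hq: float = DEFAULT_R2_HQ,
) -> list[str]:
    """Apply the quality cascade and return selected assay ids, sorted.

    Per distinct target: the max-r2 target-annotated assay with r2 > r2_min.
    Per distinct project: the max-r2 project-annotated assay with r2 > r2_min.
    Unannotated assays: kept iff r2 > r2_hq.  Ties on r2 break toward the
    lexicographically smaller assay_id so selection is deterministic.
    """
    if not r2_min < r2_hq:
        raise ValueError(f"require r2_min < r2_hq, got {r2_min} >= {r2_hq}")
    seen: set[str] = set()
    for a in assays:
        if a.assay_id in seen:
            raise ValueError(f"duplicate assay_id {a.assay_id!r}")
        seen.add(a.assay_id)

    best_per_target: dict[str, AssayRecord] = {}
    best_per_project: dict[str, AssayRecord] = {}
    unannotated: list[str] = []

    def better(a: AssayRecord, b: AssayRecord) -> AssayRecord:
        if a.r2 != b.r2:
            return a if a.r2 > b.r2 else b
        return a if a.assay_id < b.assay_id else b

    for a in assays:
        if a.category == "target_annotated":
            if a.r2 > r2_min:
                key = a.target_id
                cur = best_per_target.get(key)
                best_per_target[key] = a if cur is None else better(a, cur)
        elif a.category == "project_annotated":
            if a.r2 > r2_min:
                key = a.project_id
                cur = best_per_project.get(key)
                best_per_project[key] = a if cur is None else better(a, cur)
        else:
            if a.r2 > r2_hq:
                unannotated.append(a.assay_id)

    selected = (
        [a.assay_id for a in best_per_target.values()]
        + [a.assay_id for a in best_per_project.values()]
        + unannotated
    )
    return sorted(selected)


def pad_profile(values: np.ndarray, width: int = DEFAULT_WIDTH) -> np.ndarray:
    """Zero-pad a profile vector to the conditioning width.

    The canonical case appends 30 zeros to a 2018-assay profile to reach the
    2048-wide cross-attention input.
    """
    values = np.asarray(values, dtype=np.float64)
    if values.ndim != 1:
        raise ValueError(f"expected 1-D profile, got shape {values.shape}")
    if len(values) > width:
        raise ValueError(f"profile length {len(values)} exceeds conditioning width {width}")
    out = np.zeros(width, dtype=np.float64)
    out[: len(values)] = values
    return out


def read_profile_table(path, width: int = DEFAULT_WIDTH) -> list[BioactivityProfile]:
    """Read a CSV of compound_id x assay columns into profiles.

    The first column must be ``compound_id``; every other column is one assay
    of pAC50 values.  Missing or non-numeric cells are rejected with the
    offending row and column named.
    """
    df = pd.read_csv(path)
    if "compound_id" not in df.columns:
        raise ValueError(f"{path}: missing required 'compound_id' column")
    assay_cols = [c for c in df.columns if c != "compound_id"]
    for col in assay_cols:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[numeric.isna()]
        if len(bad):
            row = df.loc[bad[0], "compound_id"]
            raise ValueError(
                f"{path}: non-numeric or missing value at compound {row!r}, assay {col!r}"
            )
        df[col] = numeric
    return [
        BioactivityProfile(
            compound_id=str(row["compound_id"]),
            values=row[assay_cols].to_numpy(dtype=np.float64),
            width=width,
        )
        for _, row in df.iterrows()
    ]


def write_profile_table(
    profiles: Iterable[BioactivityProfile],
    path,
    assay_ids: Sequence[str] | None = None,
) -> None:
    """Write profiles as a compound_id x assay CSV (unpadded values)."""
    profiles = list(profiles)
    if not profiles:
        raise ValueError("no profiles to write")
    n = len(profiles[0].values)
    if any(len(p.values) != n for p in profiles):
        raise ValueError("profiles have inconsistent lengths")
    if assay_ids is None:
        assay_ids = [f"assay_{i:04d}" for i in range(n)]
    if len(assay_ids) != n:
        raise ValueError(f"got {len(assay_ids)} assay ids for {n}-assay profiles")
    df = pd.DataFrame(
        np.stack([p.values for p in profiles]), columns=list(assay_ids)
    )
    df.insert(0, "compound_id", [p.compound_id for p in profiles])
    df.to_csv(path, index=False)


def read_assay_table(path) -> list[AssayRecord]:
    """Read assay metadata (assay_id, r2, category, target_id, project_id) CSV."""
    df = pd.read_csv(path)
    required = {"assay_id", "r2", "category"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        records.append(
            AssayRecord(
                assay_id=str(row["assay_id"]),
                r2=float(row["r2"]),
                category=row["category"],
                target_id=_opt(row.get("target_id")),
                project_id=_opt(row.get("project_id")),
            )
        )
    return records


def _opt(v) -> str | None:
    if v is None or (isinstance(v, float) and np.isnan(v)) or v == "":
        return None
    return str(v)


def standardize_profiles(
    values: np.ndarray, stats: tuple[np.ndarray, np.ndarray] | None = None
) -> tuple[np.ndarray, tuple[np.ndarray, np.ndarray]]:
    """Per-assay z-score used before conditioning the denoiser.

    Raw pAC50 columns have assay-specific locations and scales; standardizing
    each assay over the training compounds keeps the cross-attention inputs on
    one scale.  Returns the transformed matrix and the (mean, std) statistics
    so the same transform can be replayed at inference; constant assays get
    std 1 so they map to zero rather than dividing by zero.
    """
    values = np.asarray(values, dtype=np.float64)
    if stats is None:
        mean = values.mean(axis=0)
        std = values.std(axis=0)
        std = np.where(std < 1e-12, 1.0, std)
        stats = (mean, std)
    mean, std = stats
    return (values - mean) / std, stats
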