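"""Readers and writers for every external representation the pipeline touches.

No science lives here: subject tables, long-format intensity samples,
similarity matrices, and (optionally) NIfTI volume pairs all pass through
this module so that the analysis code only ever sees validated in-memory
objects with a canonical region order.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

GROUPS = ("HC", "MDD", "BD")
SEXES = ("M", "F")
MEDICATION_CODES = (1, 2, 3)


def aal90_labels() -> list[str]:
    """Canonical AAL-90 region labels (odd indices left, even right)."""
    ref = importlib.resources.files("morphnet.data").joinpath("aal90_regions.tsv")
    with ref.open() as fh:
        table = pd.read_csv(fh, sep="\t")
    labels = table["label"].tolist()
    if len(labels) != 90:
        raise RuntimeError("bundled AAL-90 table is corrupt")
    return labels


@dataclass
class SubjectRecord:
    """One row of the cohort table: identity, diagnosis, covariates, scores."""

    subject_id: str
    group: str
    age: float
    sex: str
    medication_code: int = 1
    hamd: float | None = None
    hama: float | None = None
    ymrs: float | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group label {self.group!r}; expected one of {GROUPS}")
        if self.sex not in SEXES:
            raise ValueError(f"unknown sex code {self.sex!r}; expected one of {SEXES}")
        if int(self.medication_code) not in MEDICATION_CODES:
            raise ValueError(f"medication_code must be in {MEDICATION_CODES}")
        self.medication_code = int(self.medication_code)
        for name in ("hamd", "hama", "ymrs"):
            value = getattr(self, name)
            if value is not None and not np.isnan(value) and value < 0:
                raise ValueError(f"{name} must be non-negative, got {value}")


@dataclass
class ROISampleSet:
    """Per-region gray-matter intensity samples for one subject.

    ``samples[i]`` holds the intensity values of region ``region_labels[i]``;
    regions are stored in canonical AAL-90 order.
    """

    subject_id: str
    region_labels: list[str]
    samples: list[np.ndarray]
    min_samples: int = 30

    def __post_init__(self) -> None:
        if len(self.region_labels) != len(self.samples):
            raise ValueError("region_labels and samples length mismatch")
        if len(set(self.region_labels)) != len(self.region_labels):
            raise ValueError(f"subject {self.subject_id}: duplicate region labels")
        canonical = aal90_labels()
        # full AAL-90 sets are reordered to the canonical numbering; smaller
        # custom parcellations (e.g. from ad-hoc atlases) are kept as given
        if sorted(self.region_labels) == sorted(canonical) and self.region_labels != canonical:
            order = [self.region_labels.index(lab) for lab in canonical]
            self.samples = [np.asarray(self.samples[i], dtype=float) for i in order]
            self.region_labels = list(canonical)
        else:
            self.samples = [np.asarray(s, dtype=float) for s in self.samples]
        for lab, vals in zip(self.region_labels, self.samples):
            if vals.size < self.min_samples:
                raise ValueError(
                    f"subject {self.subject_id}, region {lab}: "
                    f"{vals.size} samples < required {self.min_samples}"
                )
            if not np.all(np.isfinite(vals)):
                raise ValueError(f"subject {self.subject_id}, region {lab}: non-finite sample")

    @property
    def n_regions(self) -> int:
        return len(self.region_labels)

    def pooled(self) -> np.ndarray:
        return np.concatenate(self.samples)


@dataclass
class AtlasVolumePair:
    """Optional NIfTI entry point for already-preprocessed data."""

    gm_volume: Path
    atlas_volume: Path
    label_map: dict[int, str] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# cohort tables


def write_cohort(
    records: Sequence[SubjectRecord],
    sample_sets: Sequence[ROISampleSet],
    subject_table_path: str | Path,
    samples_path: str | Path,
) -> None:
    """Write a cohort as a subject CSV plus a long-format samples CSV."""
    rows = []
    for r in records:
        rows.append(
            {
                "subject_id": r.subject_id,
                "group": r.group,
                "age": r.age,
                "sex": r.sex,
                "medication_code": r.medication_code,
                "hamd": r.hamd,
                "hama": r.hama,
                "ymrs": r.ymrs,
            }
        )
    pd.DataFrame(rows).to_csv(subject_table_path, index=False)

    with open(samples_path, "w") as fh:
        fh.write("subject_id,region_label,value\n")
        for ss in sample_sets:
            for lab, vals in zip(ss.region_labels, ss.samples):
                for v in vals:
                    fh.write(f"{ss.subject_id},{lab},{float(v)!r}\n")


def read_cohort(
    subject_table_path: str | Path, samples_path: str | Path
) -> tuple[list[SubjectRecord], list[ROISampleSet]]:
    """Read a subject table and long-format samples file into aligned lists.

    Subjects are returned in subject-table order; sample sets are aligned by
    ``subject_id`` and canonicalized to AAL-90 region order.
    """
    table = pd.read_csv(subject_table_path)
    required = {"subject_id", "group", "age", "sex"}
    if not required.issubset(table.columns):
        raise ValueError(f"subject table missing columns {required - set(table.columns)}")
    if table["subject_id"].duplicated().any():
        dupes = table.loc[table["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValueError(f"duplicate subject ids: {dupes}")

    records = []
    for _, row in table.iterrows():
        def _opt(name: str) -> float | None:
            if name not in table.columns or pd.isna(row[name]):
                return None
            return float(row[name])

        records.append(
            SubjectRecord(
                subject_id=str(row["subject_id"]),
                group=str(row["group"]),
                age=float(row["age"]),
                sex=str(row["sex"]),
                medication_code=int(row["medication_code"]) if "medication_code" in table.columns else 1,
                hamd=_opt("hamd"),
                hama=_opt("hama"),
                ymrs=_opt("ymrs"),
            )
        )

    samples = pd.read_csv(
        samples_path,
        dtype={"subject_id": str, "region_label": str},
        float_precision="round_trip",
    )
    if not {"subject_id", "region_label", "value"}.issubset(samples.columns):
        raise ValueError("samples file must have columns subject_id, region_label, value")
    bad = ~np.isfinite(pd.to_numeric(samples["value"], errors="coerce"))
    if bad.any():
        # +2: header line plus 1-based numbering
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
        raise ValueError(f"non-numeric sample value at line {line} of {samples_path}")
    samples["value"] = samples["value"].astype(float)

    known_ids = {r.subject_id for r in records}
    orphans = set(samples["subject_id"].unique()) - known_ids
    if orphans:
        raise ValueError(f"samples present for subjects absent from subject table: {sorted(orphans)}")

    canonical = aal90_labels()
    grouped = {sid: g for sid, g in samples.groupby("subject_id")}
    sample_sets = []
    for r in records:
        if r.subject_id not in grouped:
            raise ValueError(f"no samples for subject {r.subject_id}")
        g = grouped[r.subject_id]
        by_region = {lab: sub["value"].to_numpy() for lab, sub in g.groupby("region_label")}
        for lab in canonical:
            if lab not in by_region:
                raise ValueError(f"subject {r.subject_id}: missing region {lab}")
        sample_sets.append(
            ROISampleSet(
                subject_id=r.subject_id,
                region_labels=list(canonical),
                samples=[by_region[lab] for lab in canonical],
            )
        )
    return records, sample_sets


# ---------------------------------------------------------------------------
# similarity matrices


def write_matrix(labels: Sequence[str], values: np.ndarray, path: str | Path) -> None:
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError("matrix must be square")
    if values.shape[0] != len(labels):
        raise ValueError("label count does not match matrix dimension")
    if np.abs(values - values.T).max() > 1e-9:
        raise ValueError("matrix is asymmetric beyond 1e-9")
    frame = pd.DataFrame(values, index=list(labels), columns=list(labels))
    frame.to_csv(path, float_format="%.17g")


def read_matrix(path: str | Path) -> tuple[list[str], np.ndarray]:
    frame = pd.read_csv(path, index_col=0, float_precision="round_trip")
    values = frame.to_numpy(dtype=float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError(f"{path}: matrix is not square")
    if list(frame.index) != list(frame.columns):
        raise ValueError(f"{path}: row and column labels differ")
    if np.abs(values - values.T).max() > 1e-9:
        raise ValueError(f"{path}: matrix asymmetric beyond 1e-9")
    return list(frame.index), values


# ---------------------------------------------------------------------------
# NIfTI extraction


def extract_roi_samples(
    pair: AtlasVolumePair,
    subject_id: str,
    drop_nonpositive: bool = True,
    min_samples: int = 1,
) -> ROISampleSet:
    """Collect the GM-volume values within each atlas parcel.

    ``drop_nonpositive`` removes GM values <= 0 before building the sample
    set (default policy; the raw multiset is available with the flag off).
    """
    import nibabel as nib

    gm_img = nib.load(str(pair.gm_volume))
    atlas_img = nib.load(str(pair.atlas_volume))
    gm = np.asarray(gm_img.get_fdata(), dtype=float)
    atlas = np.asarray(atlas_img.get_fdata())
    if gm.shape != atlas.shape:
        raise ValueError(f"volume shape mismatch: GM {gm.shape} vs atlas {atlas.shape}")
    atlas = np.rint(atlas).astype(int)

    labels, samples = [], []
    for parcel, name in sorted(pair.label_map.items()):
        mask = atlas == parcel
        if not mask.any():
            raise ValueError(f"atlas label {parcel} ({name}) has zero voxels")
        vals = gm[mask]
        if drop_nonpositive:
            vals = vals[vals > 0]
        if vals.size == 0:
            raise ValueError(f"parcel {parcel} ({name}) empty after masking GM <= 0")
        labels.append(name)
        samples.append(vals)
    return ROISampleSet(
        subject_id=subject_id, region_labels=labels, samples=samples, min_samples=min_samples
    )
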