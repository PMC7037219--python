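"""Data model and I/O for concentration-time study data.

The canonical exchange format is a long (tidy) CSV with one row per animal
per matrix per assay: ``subject_id,dose_group,matrix,assay,time_h,conc,blq``.
Destructive (terminal) sampling means each subject contributes exactly one
timepoint, so profiles are built from per-timepoint group means.

Units: time in hours; plasma concentrations in μg/mL; tumor concentrations
in μg/g, treated as numerically equal to μg/mL under unit tissue density.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "MATRICES",
    "ASSAYS",
    "ConcentrationRecord",
    "StudyDesign",
    "PKDataset",
    "read_pk_csv",
    "write_pk_csv",
    "summarize_by_timepoint",
    "apply_blq_rule",
]

MATRICES = ("plasma", "tumor")
#: Assay platforms: ligand binding assay, immunocapture-LC/MS via the
#: interferon-alpha signature peptide, and via the generic IgG4 peptide.
ASSAYS = ("LBA", "ICMS_IFNA", "ICMS_IGG4")

#: Concentration-column tokens that mark a below-quantification observation.
BLQ_TOKENS = {"BLQ", "<LLOQ"}

CSV_COLUMNS = ["subject_id", "dose_group", "matrix", "assay", "time_h", "conc", "blq"]


class PKDataError(ValueError):
    """Raised when study data violate the format contract."""


@dataclass(frozen=True)
class ConcentrationRecord:
    """One measured concentration in one animal.

    ``conc`` is NaN when ``blq`` is true — a below-quantification record
    carries no usable concentration value.
    """

    subject_id: str
    dose_group: float  # mg/kg
    matrix: str
    assay: str
    time: float  # h since dose
    conc: float  # μg/mL (plasma) or μg/g (tumor); NaN if blq
    blq: bool = False

    def __post_init__(self) -> None:
        if self.matrix not in MATRICES:
            raise PKDataError(f"unknown matrix {self.matrix!r}")
        if self.assay not in ASSAYS:
            raise PKDataError(f"unknown assay {self.assay!r}")
        if self.time < 0:
            raise PKDataError(f"negative time {self.time!r}")
        if self.blq:
            if not math.isnan(self.conc):
                object.__setattr__(self, "conc", float("nan"))
        else:
            if math.isnan(self.conc) or self.conc < 0:
                raise PKDataError(
                    f"non-BLQ record needs conc >= 0, got {self.conc!r}"
                )


@dataclass
class StudyDesign:
    """Dosing and sampling design of a terminal-sampling PK study.

    Attributes
    ----------
    doses : list of float
        Dose levels, mg/kg.
    body_weight : float
        Body weight in kg used to convert mg/kg doses to absolute amounts.
    sampling_times : list of float
        Strictly increasing sampling times, h.
    n_per_timepoint : int
        Animals sacrificed per timepoint per dose group.
    assays : list of str
        Assay platforms measured on every sample.
    lloq : dict[(assay, matrix) -> float]
        Lower limit of quantification per assay/matrix.
    destructive : bool
        Each subject contributes exactly one timepoint.
    """

    doses: Sequence[float]
    body_weight: float
    sampling_times: Sequence[float]
    n_per_timepoint: int
    assays: Sequence[str] = ASSAYS
    lloq: dict = field(default_factory=dict)
    destructive: bool = True

    def __post_init__(self) -> None:
        times = list(self.sampling_times)
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise PKDataError("sampling times must be strictly increasing")
        if self.n_per_timepoint < 1:
            raise PKDataError("n_per_timepoint must be >= 1")
        if self.body_weight <= 0:
            raise PKDataError("body_weight must be > 0")
        for assay in self.assays:
            if assay not in ASSAYS:
                raise PKDataError(f"unknown assay {assay!r}")

    def dose_ug(self, dose_mg_per_kg: float) -> float:
        """Absolute administered amount in μg for a mg/kg dose level."""
        return dose_mg_per_kg * self.body_weight * 1000.0

    def to_dict(self) -> dict:
        return {
            "doses": list(map(float, self.doses)),
            "body_weight": float(self.body_weight),
            "sampling_times": list(map(float, self.sampling_times)),
            "n_per_timepoint": int(self.n_per_timepoint),
            "assays": list(self.assays),
            "lloq": {f"{a}:{m}": float(v) for (a, m), v in self.lloq.items()},
            "destructive": bool(self.destructive),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StudyDesign":
        d = dict(d)
        lloq = {}
        for key, value in (d.pop("lloq", {}) or {}).items():
            assay, matrix = key.split(":")
            lloq[(assay, matrix)] = float(value)
        return cls(lloq=lloq, **d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "StudyDesign":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class PKDataset:
    """A collection of concentration records plus the study design."""

    records: list
    design: StudyDesign
    provenance: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __eq__(self, other) -> bool:
        if not isinstance(other, PKDataset):
            return NotImplemented

        def key(r):
            return (r.subject_id, r.dose_group, r.matrix, r.assay, r.time)

        a = sorted(self.records, key=key)
        b = sorted(other.records, key=key)
        if len(a) != len(b):
            return False
        for ra, rb in zip(a, b):
            if key(ra) != key(rb) or ra.blq != rb.blq:
                return False
            if not ra.blq and not np.isclose(ra.conc, rb.conc, rtol=0, atol=1e-12):
                return False
        return True

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "subject_id": r.subject_id,
                    "dose_group": r.dose_group,
                    "matrix": r.matrix,
                    "assay": r.assay,
                    "time_h": r.time,
                    "conc": r.conc,
                    "blq": r.blq,
                }
                for r in self.records
            ],
            columns=CSV_COLUMNS,
        )

    def filter(self, *, matrix=None, assay=None, dose_group=None) -> "PKDataset":
        """Subset records; None means no constraint on that field."""
        kept = [
            r
            for r in self.records
            if (matrix is None or r.matrix == matrix)
            and (assay is None or r.assay == assay)
            and (dose_group is None or r.dose_group == dose_group)
        ]
        return PKDataset(kept, self.design, list(self.provenance))

    def mean_profile(self, dose_group: float, matrix: str, assay=None):
        """(times, mean concentrations) over non-BLQ records of one profile.

        Timepoints with no quantifiable record are omitted.
        """
        summary = summarize_by_timepoint(self.filter(matrix=matrix, assay=assay,
                                                     dose_group=dose_group))
        summary = summary[summary["n"] > 0].sort_values("time_h")
        return summary["time_h"].to_numpy(), summary["mean"].to_numpy()


def write_pk_csv(dataset: PKDataset, path) -> None:
    """Write the canonical long CSV; BLQ rows get the token ``BLQ``."""
    frame = dataset.to_frame().copy()
    frame["conc"] = [
        "BLQ" if blq else repr(float(c))
        for c, blq in zip(frame["conc"], frame["blq"])
    ]
    frame["blq"] = frame["blq"].map({True: "true", False: "false"})
    frame.to_csv(path, index=False)


def read_pk_csv(path, design: StudyDesign) -> PKDataset:
    """Parse the canonical long CSV into a :class:`PKDataset`.

    Every row is parsed or rejected with an error naming its line number
    (header is line 1). Concentration tokens ``BLQ`` and ``<LLOQ`` map to
    ``blq=True``.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise PKDataError(f"{path}: missing column(s) {missing}")

    records = []
    for idx, row in frame.iterrows():
        line = idx + 2  # header occupies line 1
        try:
            token = row["conc"].strip()
            blq_flag = row["blq"].strip().lower() in {"true", "1", "yes"}
            if token in BLQ_TOKENS or blq_flag:
                conc, blq = float("nan"), True
            else:
                conc, blq = float(token), False
            records.append(
                ConcentrationRecord(
                    subject_id=row["subject_id"],
                    dose_group=float(row["dose_group"]),
                    matrix=row["matrix"].strip(),
                    assay=row["assay"].strip(),
                    time=float(row["time_h"]),
                    conc=conc,
                    blq=blq,
                )
            )
        except (ValueError, PKDataError) as exc:
            raise PKDataError(f"{path}, line {line}: {exc}") from exc
    return PKDataset(records, design, provenance=[f"read_pk_csv({path})"])


def summarize_by_timepoint(dataset: PKDataset) -> pd.DataFrame:
    """Per-timepoint mean/SD over non-BLQ records.

    Returns one row per observed (dose_group, matrix, assay, time_h) cell
    with columns mean, sd, n, all_blq. ``n`` counts non-BLQ records; cells
    that are entirely BLQ appear with ``n=0`` and ``all_blq=True`` rather
    than being dropped. ``sd`` is NaN for n < 2.
    """
    if not dataset.records:
        raise PKDataError("cannot summarize an empty dataset")
    frame = dataset.to_frame()
    rows = []
    for (dose, matrix, assay, t), cell in frame.groupby(
        ["dose_group", "matrix", "assay", "time_h"], sort=True
    ):
        # sorted so the floating-point sum (hence the summary) is invariant
        # to the row order of the input
        values = np.sort(cell.loc[~cell["blq"], "conc"].to_numpy(dtype=float))
        n = values.size
        rows.append(
            {
                "dose_group": dose,
                "matrix": matrix,
                "assay": assay,
                "time_h": t,
                "mean": values.mean() if n else float("nan"),
                "sd": values.std(ddof=1) if n >= 2 else float("nan"),
                "n": n,
                "all_blq": n == 0,
            }
        )
    return pd.DataFrame(rows)


BLQ_RULES = ("drop", "zero_before_cmax")


def apply_blq_rule(dataset: PKDataset, rule: str) -> PKDataset:
    """Return a new dataset with BLQ records resolved by ``rule``.

    ``drop``
        Remove every BLQ record.
    ``zero_before_cmax``
        Within each (dose, matrix, assay) profile, BLQ records observed
        before the time of the profile's maximum mean concentration are set
        to conc=0 (and become usable); BLQ records at or after that time are
        dropped. Profiles that are entirely BLQ lose all records either way
        and are noted in the provenance.
    """
    if rule not in BLQ_RULES:
        raise PKDataError(f"unknown BLQ rule {rule!r}; choose from {BLQ_RULES}")

    provenance = list(dataset.provenance) + [f"apply_blq_rule({rule})"]
    if rule == "drop":
        kept = [r for r in dataset.records if not r.blq]
        _note_empty_profiles(dataset, kept, provenance)
        return PKDataset(kept, dataset.design, provenance)

    # zero_before_cmax: find tmax of each profile from quantifiable records
    tmax: dict = {}
    for r in dataset.records:
        if r.blq:
            continue
        key = (r.dose_group, r.matrix, r.assay)
        best = tmax.get(key)
        if best is None or r.conc > best[1]:
            tmax[key] = (r.time, r.conc)
    kept = []
    for r in dataset.records:
        if not r.blq:
            kept.append(r)
            continue
        key = (r.dose_group, r.matrix, r.assay)
        if key in tmax and r.time < tmax[key][0]:
            kept.append(replace(r, conc=0.0, blq=False))
    _note_empty_profiles(dataset, kept, provenance)
    return PKDataset(kept, dataset.design, provenance)


def _note_empty_profiles(original: PKDataset, kept: Iterable, provenance: list) -> None:
    before = {(r.dose_group, r.matrix, r.assay) for r in original.records}
    after = {(r.dose_group, r.matrix, r.assay) for r in kept}
    for key in sorted(before - after):
        provenance.append(f"profile {key} entirely BLQ; removed")
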