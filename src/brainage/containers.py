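"""Tabular containers flowing through the pipeline.

Two tables carry everything: an :class:`ROITable` holding subject-by-ROI
gray-matter volumes (mm^3) together with the scanner (batch) label and the
cohort label of every subject, and a :class:`CovariatePanel` holding
per-subject demographics plus visit-level longitudinal risk-factor records
in long format.  Both are thin wrappers over :class:`pandas.DataFrame` with
validation and round-trippable CSV I/O.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import BrainageError

#: recognised cohort labels
STUDY = "study"
CONTROL = "control"
REFERENCE_CONTROL = "reference_control"
REFERENCE_AD = "reference_ad"
LABELS = (STUDY, CONTROL, REFERENCE_CONTROL, REFERENCE_AD)

_META_COLS = ("scanner_id", "study_label")


@dataclass
class ROITable:
    """Subjects x ROI volumes plus scanner and cohort labels.

    Parameters
    ----------
    volumes : DataFrame
        Indexed by subject_id; one column per ROI, values in mm^3.
    scanner : Series
        Scanner/batch label per subject (same index as ``volumes``).
    label : Series
        Cohort label per subject, one of ``study``, ``control``,
        ``reference_control``, ``reference_ad``.
    """

    volumes: pd.DataFrame
    scanner: pd.Series
    label: pd.Series

    def __post_init__(self) -> None:
        self.volumes = self.volumes.copy()
        self.scanner = self.scanner.reindex(self.volumes.index)
        self.label = self.label.reindex(self.volumes.index)
        self.validate()

    def validate(self) -> None:
        if self.volumes.isna().any().any():
            raise BrainageError("ROI table contains missing volumes")
        if (self.volumes.to_numpy() <= 0).any():
            raise BrainageError("ROI volumes must be strictly positive")
        if self.scanner.isna().any():
            raise BrainageError("every subject needs exactly one scanner_id")
        bad = set(self.label.unique()) - set(LABELS)
        if bad:
            raise BrainageError(f"unknown study_label values: {sorted(bad)}")

    @property
    def roi_names(self) -> list[str]:
        return list(self.volumes.columns)

    @property
    def subjects(self) -> pd.Index:
        return self.volumes.index

    def subset(self, mask) -> "ROITable":
        """Row subset by boolean mask or index list."""
        return ROITable(self.volumes.loc[mask], self.scanner.loc[mask], self.label.loc[mask])

    def with_volumes(self, volumes: pd.DataFrame) -> "ROITable":
        """Same subjects/labels with replaced volume matrix."""
        return ROITable(volumes, self.scanner, self.label)

    def concat(self, other: "ROITable") -> "ROITable":
        if list(other.roi_names) != self.roi_names:
            raise BrainageError("cannot concatenate ROI tables with different ROI rosters")
        return ROITable(
            pd.concat([self.volumes, other.volumes]),
            pd.concat([self.scanner, other.scanner]),
            pd.concat([self.label, other.label]),
        )

    # -- I/O -----------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        out = self.volumes.copy()
        out.insert(0, "scanner_id", self.scanner)
        out.insert(1, "study_label", self.label)
        out.index.name = "subject_id"
        return out

    def to_csv(self, path: str | Path, header_comment: str | None = None) -> None:
        _write_csv(self.to_frame(), path, header_comment)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ROITable":
        df = pd.read_csv(path, comment="#", index_col="subject_id")
        missing = [c for c in _META_COLS if c not in df.columns]
        if missing:
            raise BrainageError(f"ROI CSV missing columns: {missing}")
        vols = df.drop(columns=list(_META_COLS))
        return cls(vols, df["scanner_id"], df["study_label"])

    def __len__(self) -> int:
        return len(self.volumes)


@dataclass
class CovariatePanel:
    """Per-subject demographics plus visit-level risk-factor histories.

    ``frame`` is indexed by subject_id with columns ``age`` (years), ``sex``
    ("male"/"female"), ``icv`` (mm^3), ``education`` (years) and ``group``
    (cohort label).  ``visits`` is long-format with columns ``subject_id``,
    ``covariate``, ``time`` (years since baseline) and ``value``.
    """

    frame: pd.DataFrame
    visits: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["subject_id", "covariate", "time", "value"]))

    def __post_init__(self) -> None:
        self.frame = self.frame.copy()
        self.visits = self.visits.reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        required = {"age", "sex", "icv", "group"}
        missing = required - set(self.frame.columns)
        if missing:
            raise BrainageError(f"covariate panel missing columns: {sorted(missing)}")
        if len(self.visits):
            g = self.visits.groupby(["subject_id", "covariate"])["time"]
            if not (g.apply(lambda t: bool(np.all(np.diff(t.to_numpy()) > 0)))).all():
                raise BrainageError("risk-history visit times must be strictly increasing")

    @property
    def subjects(self) -> pd.Index:
        return self.frame.index

    def subset(self, mask) -> "CovariatePanel":
        frame = self.frame.loc[mask]
        visits = self.visits[self.visits["subject_id"].isin(frame.index)]
        return CovariatePanel(frame, visits)

    def concat(self, other: "CovariatePanel") -> "CovariatePanel":
        return CovariatePanel(
            pd.concat([self.frame, other.frame]),
            pd.concat([self.visits, other.visits], ignore_index=True),
        )

    # -- I/O -----------------------------------------------------------------
    def to_csv(self, path: str | Path, header_comment: str | None = None) -> None:
        out = self.frame.copy()
        out.index.name = "subject_id"
        _write_csv(out, path, header_comment)

    def visits_to_csv(self, path: str | Path, header_comment: str | None = None) -> None:
        _write_csv(self.visits, path, header_comment, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, visits_path: str | Path | None = None) -> "CovariatePanel":
        frame = pd.read_csv(path, comment="#", index_col="subject_id")
        if visits_path is not None:
            visits = pd.read_csv(visits_path, comment="#")
        else:
            visits = pd.DataFrame(columns=["subject_id", "covariate", "time", "value"])
        return cls(frame, visits)

    def __len__(self) -> int:
        return len(self.frame)


def _write_csv(df: pd.DataFrame, path: str | Path,
               header_comment: str | None = None, index: bool = True) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, index=index)
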