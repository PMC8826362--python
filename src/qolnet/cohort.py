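"""Patient-by-scale cohort tables for longitudinal questionnaire data.

The central container is :class:`CohortTable`: one row per (subject,
timepoint), one column per questionnaire scale, with an explicit missing
mask and per-scale metadata (:class:`ScaleDefinition`).  Scores live on the
instrument's reporting scale (0-100 for EORTC scales, 0-39 for the 13-item
depression sum score).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ScaleDefinition",
    "CohortTable",
    "read_cohort_csv",
    "write_cohort_csv",
    "apply_exclusions",
]

_ID = "subject_id"
_TP = "timepoint"


@dataclass
class ScaleDefinition:
    """Metadata for one questionnaire scale.

    Parameters
    ----------
    name : str
        Scale identifier, used as the column name.
    kind : {"ordinal", "continuous"}
        Ordinal scales take fewer than 7 distinct reporting values
        (single-item EORTC scales have 4); anything with 7 or more levels
        is treated as interval/continuous.
    range : (float, float)
        Attainable (min, max) on the reporting scale.
    direction : {"higher-is-better", "higher-is-worse"}
        Interpretation of large values before any reversal.
    levels : int, optional
        Number of attainable values; required (and < 7) for ordinal scales.
    mean, sd : float, optional
        Target population mean / SD used by the synthetic-cohort generator.
    """

    name: str
    kind: str = "continuous"
    range: tuple[float, float] = (0.0, 100.0)
    direction: str = "higher-is-better"
    levels: int | None = None
    mean: float | None = None
    sd: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("ordinal", "continuous"):
            raise ValueError(f"unknown scale kind {self.kind!r}")
        lo, hi = self.range
        if not lo < hi:
            raise ValueError(f"scale {self.name}: range min must be < max")
        if self.kind == "ordinal":
            if self.levels is None:
                raise ValueError(f"ordinal scale {self.name} needs `levels`")
            if not 2 <= self.levels < 7:
                raise ValueError(
                    f"ordinal scale {self.name}: levels must be in [2, 7); "
                    "scales with >= 7 levels are continuous"
                )
        if self.direction not in ("higher-is-better", "higher-is-worse"):
            raise ValueError(f"unknown direction {self.direction!r}")

    def attainable_values(self) -> np.ndarray | None:
        """Equispaced reporting values for an ordinal scale, else None."""
        if self.kind != "ordinal":
            return None
        lo, hi = self.range
        return np.linspace(lo, hi, self.levels)


class CohortTable:
    """Scores for a cohort of subjects observed at one or more time points.

    Wraps a wide :class:`pandas.DataFrame` indexed by (subject_id,
    timepoint) with one column per scale; missing cells are NaN.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        scale_defs: Sequence[ScaleDefinition],
        timepoint_order: Sequence[str] | None = None,
    ) -> None:
        defs = {d.name: d for d in scale_defs}
        missing = [c for c in data.columns if c not in defs]
        if missing:
            raise ValueError(f"no ScaleDefinition for columns {missing}")
        if list(data.index.names) != [_ID, _TP]:
            raise ValueError("data must be indexed by (subject_id, timepoint)")
        if data.index.duplicated().any():
            dups = data.index[data.index.duplicated()].tolist()
            raise ValueError(f"duplicate (subject, timepoint) rows: {dups[:5]}")
        self.data = data.astype(float)
        self.scale_defs = defs
        tps = list(dict.fromkeys(data.index.get_level_values(_TP)))
        if timepoint_order is None:
            timepoint_order = tps
        else:
            unknown = set(tps) - set(timepoint_order)
            if unknown:
                raise ValueError(f"timepoints {unknown} not in timepoint_order")
        self.timepoint_order = [t for t in timepoint_order if t in tps]

    # -- basic accessors ---------------------------------------------------
    @property
    def scales(self) -> list[str]:
        return list(self.data.columns)

    @property
    def timepoints(self) -> list[str]:
        return list(self.timepoint_order)

    @property
    def subjects(self) -> list:
        return list(dict.fromkeys(self.data.index.get_level_values(_ID)))

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def scores(self, timepoint: str) -> pd.DataFrame:
        """Subject-by-scale score matrix at one time point."""
        if timepoint not in self.timepoints:
            raise KeyError(f"unknown timepoint {timepoint!r}")
        return self.data.xs(timepoint, level=_TP)

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.data.isna()

    def missing_fraction(self) -> float:
        return float(self.data.isna().to_numpy().mean())

    def copy(self) -> "CohortTable":
        return CohortTable(
            self.data.copy(),
            [dataclasses.replace(d) for d in self.scale_defs.values()],
            timepoint_order=self.timepoint_order,
        )

    def subset_subjects(self, subjects: Iterable) -> "CohortTable":
        keep = list(subjects)
        sub = self.data.loc[self.data.index.get_level_values(_ID).isin(keep)]
        return CohortTable(
            sub.copy(), list(self.scale_defs.values()), self.timepoint_order
        )

    # -- validation --------------------------------------------------------
    def validate(self) -> list[str]:
        """Return a list of out-of-range cell descriptions (empty if clean)."""
        problems = []
        for name, d in self.scale_defs.items():
            col = self.data[name]
            lo, hi = d.range
            bad = col[(col < lo) | (col > hi)]
            for (sid, tp), v in bad.items():
                problems.append(
                    f"{name}[{sid}, {tp}] = {v} outside [{lo}, {hi}]"
                )
        return problems

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<CohortTable {self.n_subjects} subjects x "
            f"{len(self.scales)} scales x {len(self.timepoints)} timepoints, "
            f"{100 * self.missing_fraction():.1f}% missing>"
        )


def apply_exclusions(
    table: CohortTable,
    discontinued: Iterable | None = None,
    min_participations: int = 2,
) -> CohortTable:
    """Drop discontinued subjects and those seen at too few time points.

    Mirrors the trial's analysis-set rule: subjects flagged as having
    discontinued are removed, then subjects who participated at fewer than
    ``min_participations`` time points (a participation = a row for that
    subject at that time point) are removed.
    """
    drop = set(discontinued or ())
    counts = table.data.groupby(level=_ID).size()
    few = set(counts[counts < min_participations].index)
    keep = [s for s in table.subjects if s not in drop and s not in few]
    return table.subset_subjects(keep)


# -- CSV / YAML round trip -----------------------------------------------

def write_cohort_csv(table: CohortTable, path, metadata_path=None) -> None:
    """Write the tidy CSV (subject_id, timepoint, one column per scale).

    Missing cells are written empty.  Scale metadata goes to a side-car
    YAML file (default: ``<path>.meta.yaml``).
    """
    out = table.data.reset_index()
    out.to_csv(path, index=False)
    if metadata_path is None:
        metadata_path = str(path) + ".meta.yaml"
    def _plain(v):
        if isinstance(v, dict):
            return {str(k): float(x) for k, x in v.items()}
        return None if v is None else float(v)

    meta = {
        "timepoint_order": list(table.timepoint_order),
        "scales": [
            {
                "name": d.name,
                "kind": d.kind,
                "range": [float(d.range[0]), float(d.range[1])],
                "direction": d.direction,
                "levels": None if d.levels is None else int(d.levels),
                "mean": _plain(d.mean),
                "sd": _plain(d.sd),
            }
            for d in table.scale_defs.values()
        ],
    }
    with open(metadata_path, "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)


def read_cohort_csv(path, metadata_path=None, strict: bool = True) -> CohortTable:
    """Read a tidy cohort CSV plus its side-car metadata.

    Raises on duplicate (subject, timepoint) rows; with ``strict`` (default)
    also raises on out-of-range values, listing the offending cells.  Empty
    cells become missing, never an error.
    """
    if metadata_path is None:
        metadata_path = str(path) + ".meta.yaml"
    with open(metadata_path) as fh:
        meta = yaml.safe_load(fh)
    defs = [
        ScaleDefinition(
            name=s["name"],
            kind=s["kind"],
            range=tuple(s["range"]),
            direction=s["direction"],
            levels=s.get("levels"),
            mean=s.get("mean"),
            sd=s.get("sd"),
        )
        for s in meta["scales"]
    ]
    raw = pd.read_csv(path)
    for col in (_ID, _TP):
        if col not in raw.columns:
            raise ValueError(f"cohort CSV must have a {col!r} column")
    raw = raw.set_index([_ID, _TP])
    table = CohortTable(raw, defs, timepoint_order=meta.get("timepoint_order"))
    if strict:
        problems = table.validate()
        if problems:
            raise ValueError(
                "out-of-range values:\n  " + "\n  ".join(problems[:20])
            )
    return table
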