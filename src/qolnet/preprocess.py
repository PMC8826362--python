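"""Scale reversal and longitudinal copy-mean single imputation.

Symptom and depression scores are reflected (``pivot - value``) so that on
every scale a higher score means a better state, matching how functioning
scales read.  Missing cells are then filled by the copy-mean rule for
longitudinal data: within-subject linear interpolation adjusted by the
shape of the population mean trajectory, with leading/trailing gaps copied
from the nearest observation plus the population mean shift.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import CohortTable

__all__ = [
    "ReversalRule",
    "reverse_scales",
    "default_reversal_rules",
    "impute_copy_mean",
    "missing_summary",
]


@dataclass(frozen=True)
class ReversalRule:
    """Reflect one scale about its range maximum (the pivot).

    Applying the rule twice is the identity: pivot - (pivot - x) = x.
    """

    scale: str
    pivot: float


def default_reversal_rules(table: CohortTable) -> list[ReversalRule]:
    """Rules reversing every higher-is-worse scale about its range max."""
    return [
        ReversalRule(scale=d.name, pivot=d.range[1])
        for d in table.scale_defs.values()
        if d.direction == "higher-is-worse"
    ]


def reverse_scales(table: CohortTable, rules: list[ReversalRule]) -> CohortTable:
    """Return a new table with the named scales reflected.

    Missing cells stay missing; the direction metadata of reversed scales
    is flipped.  Unknown scale names raise.
    """
    out = table.copy()
    for rule in rules:
        if rule.scale not in out.scale_defs:
            raise ValueError(f"unknown scale {rule.scale!r} in reversal rule")
        out.data[rule.scale] = rule.pivot - out.data[rule.scale]
        d = out.scale_defs[rule.scale]
        flipped = (
            "higher-is-better"
            if d.direction == "higher-is-worse"
            else "higher-is-worse"
        )
        out.scale_defs[rule.scale] = dataclasses.replace(d, direction=flipped)
    return out


def impute_copy_mean(
    table: CohortTable,
    clip: bool = True,
    snap_ordinal: bool = True,
    return_log: bool = False,
    on_all_missing: str = "popmean",
):
    """Fill missing cells by the copy-mean longitudinal rule.

    For a gap strictly between observations at time indices a < t < b::

        imputed(t) = lin_subj(t) + [popmean(t) - lin_pop(t)]

    where ``lin_subj`` interpolates the subject's own observations at a and
    b, and ``lin_pop`` interpolates the population means at a and b — i.e.
    linear interpolation corrected by the curvature of the mean trajectory.
    Leading/trailing gaps anchored at the nearest observation a use::

        imputed(t) = observed(a) + [popmean(t) - popmean(a)]

    Population means use observed values only.  The rule needs at least one
    observation per subject per scale to anchor on; a subject missing a
    scale at every time point falls back to the per-timepoint population
    mean (``on_all_missing="popmean"``, the default) or raises
    (``on_all_missing="error"``).  A scale entirely missing at a time point
    (undefined population mean) always raises.  Imputed cells on ordinal
    scales are snapped to the nearest attainable reporting value by default
    (``snap_ordinal``), so an ordinal scale keeps its level count — and
    hence its ordinal classification downstream — after imputation.
    Imputed values are clipped
    to the declared scale range by default (reflection plus mean shifts can
    exceed the bounds).  With ``return_log`` also returns a frame listing
    each imputed cell and the rule used.
    """
    out = table.copy()
    tps = out.timepoints
    T = len(tps)
    log_rows: list[dict] = []

    def _finalize(val: float, d) -> float:
        if clip:
            val = float(np.clip(val, *d.range))
        if snap_ordinal and d.kind == "ordinal":
            grid = d.attainable_values()
            val = float(grid[np.argmin(np.abs(grid - val))])
        return val
    for scale in out.scales:
        # subjects x timepoints matrix for this scale
        wide = out.data[scale].unstack("timepoint")[tps]
        popmean = wide.mean(axis=0, skipna=True)
        vals = wide.to_numpy(dtype=float)
        if np.isnan(popmean.to_numpy()).any():
            bad = [tps[k] for k in np.flatnonzero(np.isnan(popmean.to_numpy()))]
            raise ValueError(
                f"scale {scale!r} has no observed values at timepoint(s) {bad}"
            )
        pm = popmean.to_numpy()
        for r in range(vals.shape[0]):
            row = vals[r]
            obs = np.flatnonzero(~np.isnan(row))
            if obs.size == 0:
                if on_all_missing == "error":
                    raise ValueError(
                        f"subject {wide.index[r]!r} has no observations on "
                        f"scale {scale!r}"
                    )
                for t in range(T):
                    val = _finalize(pm[t], out.scale_defs[scale])
                    vals[r, t] = val
                    log_rows.append(
                        {
                            "subject_id": wide.index[r],
                            "timepoint": tps[t],
                            "scale": scale,
                            "value": val,
                            "rule": "population-mean",
                        }
                    )
                continue
            if obs.size == T:
                continue
            for t in np.flatnonzero(np.isnan(row)):
                before = obs[obs < t]
                after = obs[obs > t]
                if before.size and after.size:
                    a, b = before[-1], after[0]
                    w = (t - a) / (b - a)
                    lin_subj = row[a] + w * (row[b] - row[a])
                    lin_pop = pm[a] + w * (pm[b] - pm[a])
                    val = lin_subj + (pm[t] - lin_pop)
                    rule = "interior"
                else:
                    a = before[-1] if before.size else after[0]
                    val = row[a] + (pm[t] - pm[a])
                    rule = "copy-edge"
                val = _finalize(val, out.scale_defs[scale])
                vals[r, t] = val
                log_rows.append(
                    {
                        "subject_id": wide.index[r],
                        "timepoint": tps[t],
                        "scale": scale,
                        "value": val,
                        "rule": rule,
                    }
                )
        filled = pd.DataFrame(vals, index=wide.index, columns=tps)
        stacked = filled.stack()
        stacked.index.names = ["subject_id", "timepoint"]
        out.data[scale] = stacked.reindex(out.data.index)
    if return_log:
        return out, pd.DataFrame(
            log_rows, columns=["subject_id", "timepoint", "scale", "value", "rule"]
        )
    return out


def missing_summary(table: CohortTable) -> pd.DataFrame:
    """Per-timepoint missingness: cell fraction and all-missing subjects."""
    rows = []
    for tp in table.timepoints:
        scores = table.scores(tp)
        mask = scores.isna()
        rows.append(
            {
                "timepoint": tp,
                "missing_fraction": float(mask.to_numpy().mean()),
                "subjects_all_missing": int(mask.all(axis=1).sum()),
                "n_subjects": int(len(scores)),
            }
        )
    return pd.DataFrame(rows).set_index("timepoint")
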