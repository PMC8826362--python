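"""Published summary statistics from the BREX early-breast-cancer cohort.

The BREX trial's patient-level questionnaire data are not public; what is
public are the per-scale summary statistics (mean, SD, observed range at
baseline M0 and month 12 M12, with symptom and depression scores reversed
to the higher-is-better orientation) and the Spearman correlations of every
scale with global quality of life (gQoL).  Those published numbers serve
two roles here: as targets for the synthetic-cohort generator's margins,
and as worked-example inputs for the node-selection filter.

Scales come from the EORTC QLQ-C30 core questionnaire, its breast-cancer
module BR23, and the 13-item Beck depression inventory (sum score 0-39).
Single-item EORTC scales attain only 4 reporting values (0, 33.33, 66.67,
100) and are flagged ordinal; multi-item scales are treated as continuous.
"""

from __future__ import annotations

import pandas as pd

from .cohort import ScaleDefinition

__all__ = [
    "brex_scale_table",
    "brex_scale_definitions",
    "brex_screening_correlations",
    "GQOL",
]

GQOL = "global_qol"

# name, ordinal?, (mean, sd) at M0, (mean, sd) at M12, range max (min is 0
# except depression/others noted).  Symptom scales already reversed.
_SCALES = [
    # EORTC QLQ-C30
    ("global_qol",          False, (69.9, 19.0), (74.9, 19.0)),
    ("physical_functioning", False, (82.4, 15.7), (85.0, 15.0)),
    ("role_functioning",    False, (86.7, 19.2), (89.8, 18.0)),
    ("social_functioning",  False, (87.4, 19.4), (93.9, 15.1)),
    ("emotional_functioning", False, (82.4, 17.5), (83.9, 17.6)),
    ("cognitive_functioning", False, (84.6, 19.5), (85.1, 19.2)),
    ("fatigue",             False, (72.6, 18.6), (77.3, 18.9)),
    ("insomnia",            True,  (69.3, 29.2), (73.7, 30.0)),
    ("pain",                False, (83.0, 18.9), (81.6, 22.0)),
    ("nausea_vomiting",     False, (96.8, 9.6),  (98.0, 6.7)),
    ("dyspnea",             True,  (93.6, 14.7), (94.0, 15.8)),
    ("appetite_loss",       True,  (95.0, 14.7), (97.3, 10.1)),
    ("constipation",        True,  (88.9, 19.1), (89.1, 19.7)),
    ("diarrhea",            True,  (94.4, 14.7), (94.7, 14.4)),
    ("financial_difficulties", True, (88.7, 21.9), (94.2, 17.4)),
    # EORTC QLQ-BR23
    ("body_image",          False, (63.7, 27.4), (74.9, 25.7)),
    ("sexual_functioning",  False, (29.7, 26.2), (34.1, 27.5)),
    ("sexual_enjoyment",    True,  (39.5, 36.2), (43.7, 36.2)),
    ("future_perspective",  True,  (55.0, 28.8), (64.2, 26.6)),
    ("systemic_therapy_side_effects", False, (78.4, 13.8), (83.5, 12.0)),
    ("breast_symptoms",     False, (81.4, 16.3), (88.2, 14.2)),
    ("arm_symptoms",        False, (82.0, 18.2), (81.8, 18.7)),
    ("upset_by_hair_loss",  True,  (59.3, 35.5), (92.5, 22.3)),
    # BDI (13 items, sum 0-39, reversed)
    ("depression",          False, (35.4, 3.8),  (35.9, 3.9)),
]

# Spearman rho of each scale with gQoL at (M0, M12) and the published
# significance stars ('' none, '*' <0.05, '**' <0.01, '***' <0.001) from
# the BH-adjusted two-sided t-tests.
_SCREEN = [
    ("physical_functioning", 0.48, "***", 0.53, "***"),
    ("role_functioning",    0.50, "***", 0.52, "***"),
    ("social_functioning",  0.45, "***", 0.45, "***"),
    ("emotional_functioning", 0.45, "***", 0.52, "***"),
    ("cognitive_functioning", 0.38, "***", 0.46, "***"),
    ("fatigue",             0.55, "***", 0.58, "***"),
    ("insomnia",            0.33, "***", 0.33, "***"),
    ("pain",                0.34, "***", 0.54, "***"),
    ("nausea_vomiting",     0.26, "***", 0.30, "***"),
    ("dyspnea",             0.23, "***", 0.25, "***"),
    ("appetite_loss",       0.21, "***", 0.21, "***"),
    ("constipation",        0.14, "*",   0.16, "**"),
    ("diarrhea",            0.07, "",    0.19, "***"),
    ("financial_difficulties", 0.28, "***", 0.34, "***"),
    ("body_image",          0.43, "***", 0.42, "***"),
    ("sexual_functioning",  0.21, "***", 0.31, "***"),
    ("sexual_enjoyment",    0.25, "***", 0.33, "***"),
    ("future_perspective",  0.34, "***", 0.48, "***"),
    ("systemic_therapy_side_effects", 0.35, "***", 0.47, "***"),
    ("breast_symptoms",     0.27, "***", 0.26, "***"),
    ("arm_symptoms",        0.28, "***", 0.39, "***"),
    ("upset_by_hair_loss",  0.16, "",    0.27, "***"),
    ("depression",          0.52, "***", 0.56, "***"),
]


def brex_scale_table() -> pd.DataFrame:
    """Published per-scale means and SDs (reversed orientation) as a frame.

    Columns: ordinal flag, mean/sd at each time point, reporting range.
    """
    rows = []
    for name, ordinal, (m0, s0), (m12, s12) in _SCALES:
        hi = 39.0 if name == "depression" else 100.0
        rows.append(
            {
                "scale": name,
                "ordinal": ordinal,
                "mean_M0": m0,
                "sd_M0": s0,
                "mean_M12": m12,
                "sd_M12": s12,
                "min": 0.0,
                "max": hi,
            }
        )
    return pd.DataFrame(rows).set_index("scale")


def brex_scale_definitions(scales: list[str] | None = None) -> list[ScaleDefinition]:
    """ScaleDefinitions matching the published cohort, for the generator.

    Ordinal (single-item) scales get 4 equispaced levels; target means/SDs
    are per-timepoint dicts so the generator reproduces both columns of the
    published table.  Pass ``scales`` to restrict/reorder.
    """
    tab = brex_scale_table()
    if scales is None:
        scales = list(tab.index)
    defs = []
    for name in scales:
        r = tab.loc[name]
        defs.append(
            ScaleDefinition(
                name=name,
                kind="ordinal" if r["ordinal"] else "continuous",
                levels=4 if r["ordinal"] else None,
                range=(r["min"], r["max"]),
                direction="higher-is-better",
                mean={"M0": float(r["mean_M0"]), "M12": float(r["mean_M12"])},
                sd={"M0": float(r["sd_M0"]), "M12": float(r["sd_M12"])},
            )
        )
    return defs


def brex_screening_correlations() -> pd.DataFrame:
    """Published Spearman correlations of every scale with gQoL.

    One row per non-target scale with ``rho_M0`` / ``rho_M12`` and the
    published significance stars; the standard input to
    :func:`qolnet.screening.select_nodes` for the worked selection example.
    """
    rows = [
        {"scale": n, "rho_M0": r0, "stars_M0": s0, "rho_M12": r12, "stars_M12": s12}
        for n, r0, s0, r12, s12 in _SCREEN
    ]
    df = pd.DataFrame(rows).set_index("scale")
    df["mean_abs_rho"] = (df["rho_M0"].abs() + df["rho_M12"].abs()) / 2.0
    return df
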