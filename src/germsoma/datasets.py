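"""Published lifespan and stress-survival summary tables.

These are the printed per-cohort summary statistics (mean +/- SEM, median,
75th percentile, deaths/enrolled, printed percent extension) of the
germline-ablation study's lifespan assays at 25C and 20C and its arsenite
(AS) / tert-butyl hydroperoxide (TBHP) stress assays.  They serve as
inputs for recomputing the derived arithmetic (percent extension,
summary-cell interaction ANOVA); per-animal records were not published.

``n_deaths``/``n_total`` unpack the printed "x/y" sample sizes, read as
observed deaths over enrolled animals; the means are taken to summarise
the ``n_deaths`` animals that contributed lifespan observations.
"""

from __future__ import annotations

import pandas as pd

_LIFESPAN_COLUMNS = [
    "set",
    "strain",
    "mean",
    "sem",
    "median",
    "p75",
    "n_deaths",
    "n_total",
    "printed_extension",
    "control_strain",
]

# Lifespans (days).  Strains: N2 wild type, skn-1(zu135), glp-1(bn18ts),
# and the glp-1;skn-1 double mutant.  Extension compares glp-1(ts) to its
# matching N2 or skn-1 control.
_LIFESPAN_ROWS = [
    # Composite lifespan at 25C with FUdR (C1)
    ("C1", "N2", 15.40, 0.2, 16, 17, 133, 148, None, None),
    ("C1", "skn-1", 14.66, 0.2, 15, 16, 158, 167, None, None),
    ("C1", "glp-1", 19.94, 0.3, 20, 22, 164, 171, 29.48, "N2"),
    ("C1", "glp-1;skn-1", 15.23, 0.2, 15, 18, 149, 170, 3.89, "skn-1"),
    # Replicate lifespans at 25C with FUdR
    ("#1", "N2", 13.99, 0.4, 14, 17, 40, 55, None, None),
    ("#1", "skn-1", 12.54, 0.3, 13, 14, 41, 50, None, None),
    ("#1", "glp-1", 22.46, 0.8, 25, 27, 50, 55, 60.54, "N2"),
    ("#1", "glp-1;skn-1", 13.29, 0.4, 12, 14, 53, 70, 6.00, "skn-1"),
    ("#2", "N2", 16.07, 0.2, 16, 17, 93, 93, None, None),
    ("#2", "skn-1", 15.42, 0.2, 15, 17, 117, 117, None, None),
    ("#2", "glp-1", 18.86, 0.3, 19, 21, 114, 116, 17.36, "N2"),
    ("#2", "glp-1;skn-1", 16.42, 0.2, 17, 18, 96, 100, 6.49, "skn-1"),
    # Lifespan at 20C without FUdR
    ("#3", "N2", 20.36, 0.6, 18, 21, 42, 50, None, None),
    ("#3", "skn-1", 18.39, 0.5, 18, 18, 27, 47, None, None),
    ("#3", "glp-1", 25.87, 1.3, 24, 33, 35, 66, 27.06, "N2"),
    ("#3", "glp-1;skn-1", 20.02, 0.6, 18, 24, 34, 55, 8.86, "skn-1"),
    # Composite lifespan at 20C with FUdR (C2)
    ("C2", "N2", 20.51, 0.5, 21, 24, 86, 90, None, None),
    ("C2", "skn-1", 17.78, 0.4, 19, 20, 88, 94, None, None),
    ("C2", "glp-1", 24.52, 0.6, 25, 28, 81, 104, 19.55, "N2"),
    ("C2", "glp-1;skn-1", 20.47, 0.5, 20, 24, 91, 98, 15.13, "skn-1"),
    # Replicate lifespans at 20C with FUdR
    ("#4", "N2", 18.09, 0.4, 17, 19, 33, 37, None, None),
    ("#4", "skn-1", 14.78, 0.5, 14, 17, 31, 35, None, None),
    ("#4", "glp-1", 21.79, 1.0, 21, 28, 28, 50, 20.45, "N2"),
    ("#4", "glp-1;skn-1", 16.83, 0.3, 17, 18, 36, 43, 13.87, "skn-1"),
    ("#5", "N2", 22.00, 0.6, 23, 25, 53, 53, None, None),
    ("#5", "skn-1", 19.40, 0.4, 20, 21, 57, 59, None, None),
    ("#5", "glp-1", 25.91, 0.7, 25, 30, 53, 54, 17.77, "N2"),
    ("#5", "glp-1;skn-1", 22.80, 0.6, 24, 26, 55, 55, 17.53, "skn-1"),
]

# Stress-resistance survival (hours) after arsenite or TBHP exposure.
_STRESS_ROWS = [
    ("#1", "N2+vector", 20.20, 1.0, 22.5, 22.5, 122, 122, None, None),
    ("#1", "N2+rme-2", 39.51, 1.1, 47.5, 47.5, 117, 117, 95.59, "N2+vector"),
    ("#2", "N2+vector", 26.82, 1.2, 28.0, 28.0, 57, 57, None, None),
    ("#2", "N2+rme-2", 53.21, 0.9, 52.5, 71.5, 252, 252, 98.44, "N2+vector"),
    ("#2", "glp-1+vector", 53.06, 1.0, 52.5, 71.5, 216, 216, 97.85, "N2+vector"),
    ("#3", "N2+vector", 38.59, 0.6, 47.5, 47.5, 281, 281, None, None),
    ("#3", "N2+rme-2", 63.00, 0.7, 71.5, 71.5, 287, 287, 63.25, "N2+vector"),
    ("#4", "N2+vector", 49.10, 0.8, 46.0, 64.0, 306, 306, None, None),
    ("#4", "N2+vector/skn-1", 32.03, 0.6, 40.0, 40.0, 271, 271, None, None),
    ("#4", "N2+vector/rme-2", 65.38, 1.1, 64.0, 70.0, 361, 361, 33.16, "N2+vector"),
    ("#4", "N2+rme-2/skn-1", 33.76, 0.5, 40.0, 40.0, 409, 409, 5.40, "N2+vector/skn-1"),
    ("#5", "N2+vector", 23.18, 0.5, 22.5, 22.5, 125, 125, None, None),
    ("#5", "N2+lipl-3", 23.04, 0.6, 22.5, 28.0, 139, 139, None, None),
    ("#5", "N2+sbp-1", 11.01, 0.6, 7.5, 22.5, 163, 163, None, None),
    ("#5", "N2+skn-1", 20.88, 0.7, 22.5, 28.0, 115, 115, None, None),
    ("#5", "glp-1+vector", 40.58, 1.1, 47.5, 47.5, 105, 105, 75.05, "N2+vector"),
    ("#5", "glp-1+lipl-3", 28.52, 1.0, 28.0, 32.5, 178, 178, 23.77, "N2+lipl-3"),
    ("#5", "glp-1+sbp-1", 7.50, 0.5, 6.0, 7.5, 138, 138, -31.88, "N2+sbp-1"),
    ("#5", "glp-1+skn-1", 12.90, 0.9, 9.0, 22.5, 129, 129, -38.21, "N2+skn-1"),
    ("#6", "N2+vector", 24.36, 0.8, 22.5, 28.0, 121, 121, None, None),
    ("#6", "N2+fat-6/7", 15.56, 0.8, 22.5, 22.5, 159, 159, None, None),
    ("#6", "N2+skn-1", 20.94, 0.6, 22.5, 22.5, 124, 124, None, None),
    ("#6", "glp-1+vector", 38.49, 1.5, 47.5, 47.5, 98, 98, 58.03, "N2+vector"),
    ("#6", "glp-1+fat-6/7", 12.04, 0.7, 9.0, 22.5, 153, 153, -22.66, "N2+fat-6/7"),
    ("#6", "glp-1+skn-1", 23.69, 0.9, 28.0, 32.5, 116, 116, 13.13, "N2+skn-1"),
    ("#7", "N2+vector", 6.55, 0.3, 7.0, 8.0, 104, 104, None, None),
    ("#7", "N2+skn-1", 5.08, 0.2, 5.0, 7.0, 103, 103, None, None),
    ("#7", "glp-1+vector", 19.36, 0.1, 19.0, 20.0, 97, 97, 195.57, "N2+vector"),
    ("#7", "glp-1+skn-1", 7.86, 0.4, 8.0, 12.0, 100, 100, 54.72, "N2+skn-1"),
    ("#8", "N2+vector", 8.31, 0.4, 9.0, 10.0, 98, 98, None, None),
    ("#8", "N2+skn-1", 6.89, 0.3, 8.0, 9.0, 90, 90, None, None),
    ("#8", "glp-1+vector", 16.95, 1.0, 20.0, 26.0, 81, 81, 103.97, "N2+vector"),
    ("#8", "glp-1+skn-1", 9.90, 0.4, 10.0, 12.0, 91, 91, 43.69, "N2+skn-1"),
    ("#9", "N2+vector", 9.02, 0.3, 9.0, 11.0, 84, 108, None, None),
    ("#9", "N2+skn-1", 6.16, 0.2, 6.0, 7.0, 63, 98, None, None),
    ("#9", "glp-1+vector", 11.62, 0.3, 11.0, 13.0, 61, 61, 28.82, "N2+vector"),
    ("#9", "glp-1+skn-1", 6.48, 0.1, 8.0, 7.0, 63, 65, 5.19, "N2+skn-1"),
    ("#10", "N2", 4.29, 0.2, 4.0, 4.0, 65, 94, None, None),
    ("#10", "skn-1", 4.51, 0.1, 5.0, 3.0, 73, 74, None, None),
    ("#10", "glp-1", 6.25, 0.2, 6.0, 4.0, 73, 74, 45.69, "N2"),
    ("#10", "glp-1;skn-1", 4.78, 0.1, 5.0, 4.0, 73, 75, 5.99, "skn-1"),
]

#: Fold-change screen bookkeeping from the published frequency analysis.
EXPRESSED_GENES = 12595
GENES_FC_ABOVE_4 = 1306
GENES_FC_ABOVE_5 = 615
SKN1_DEPENDENT_GSC_GENES = 87

#: Nuclei counts behind the composition argument.
SOMATIC_NUCLEI = 959
GERMLINE_NUCLEI = 2000

#: Selective-color GFP isolation settings.
SKN1_GFP_TARGET_RGB = (99, 159, 94)
SKN1_GFP_FUZZINESS = 125
DAF16_GFP_TARGET_RGB = (0, 255, 111)
DAF16_GFP_FUZZINESS = 100


def load_lifespan_table() -> pd.DataFrame:
    """Published lifespan summary cells (days)."""
    return pd.DataFrame(_LIFESPAN_ROWS, columns=_LIFESPAN_COLUMNS)


def load_stress_table() -> pd.DataFrame:
    """Published stress-assay survival summary cells (hours)."""
    return pd.DataFrame(_STRESS_ROWS, columns=_LIFESPAN_COLUMNS)


def extension_cells(table: pd.DataFrame) -> pd.DataFrame:
    """Rows with a printed extension, joined to their control-cell mean."""
    rows = []
    for _, row in table.iterrows():
        if pd.isna(row["printed_extension"]):
            continue
        ctrl = table[
            (table["set"] == row["set"]) & (table["strain"] == row["control_strain"])
        ]
        if len(ctrl) != 1:
            raise ValueError(f"ambiguous control for {row['set']}/{row['strain']}")
        rows.append(
            {
                "set": row["set"],
                "strain": row["strain"],
                "mean": row["mean"],
                "control_strain": row["control_strain"],
                "control_mean": float(ctrl["mean"].iloc[0]),
                "printed_extension": float(row["printed_extension"]),
            }
        )
    return pd.DataFrame(rows)


def lifespan_anova_cells(set_id: str):
    """2x2 SummaryCell grid (glp-1 status x skn-1 status) for one lifespan set."""
    from .phenotype import SummaryCell

    table = load_lifespan_table()
    sub = table[table["set"] == set_id].set_index("strain")
    grid = []
    for a_strains in (("N2", "skn-1"), ("glp-1", "glp-1;skn-1")):
        row = []
        for strain in a_strains:
            r = sub.loc[strain]
            row.append(SummaryCell(float(r["mean"]), float(r["sem"]), int(r["n_deaths"])))
        grid.append(row)
    return grid
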