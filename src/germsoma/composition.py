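"""Nuclei-composition model for interpreting fold changes after germline loss.

An adult hermaphrodite has 959 somatic cells and roughly 2000 germline
stem-cell-derived nuclei, so the germline accounts for about two-thirds of
all nuclei.  When the germline is ablated, a transcript expressed only in
the soma rises in *relative* abundance even if its absolute somatic output
is unchanged, simply because the denominator pool shrinks.  This module
quantifies that enrichment, checks it against somatic / germline /
ubiquitous marker panels, and derives the fold-change cutoff above which a
non-somatic-specific gene is called genuinely upregulated in the soma.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class CompositionModel:
    """Two-compartment (soma / germline) transcript-pool model.

    Parameters
    ----------
    n_soma, n_germ : float
        Nuclei counts of the somatic and germline compartments (defaults
        959 and 2000).
    rho : float
        Per-nucleus transcript output of a germline nucleus relative to a
        somatic one (default 1: output proportional to nuclei).
    residual_germline : float
        Fraction of germline output remaining after ablation, in [0, 1).
    """

    n_soma: float = 959.0
    n_germ: float = 2000.0
    rho: float = 1.0
    residual_germline: float = 0.0

    def __post_init__(self) -> None:
        if self.n_soma <= 0 or self.n_germ <= 0:
            raise ValueError("nuclei counts must be positive")
        if self.rho < 0:
            raise ValueError("rho must be >= 0")
        if not 0.0 <= self.residual_germline < 1.0:
            raise ValueError("residual_germline must be in [0, 1)")

    @property
    def germline_share(self) -> float:
        """Fraction of the intact pool produced by the germline."""
        g = self.rho * self.n_germ
        return g / (self.n_soma + g)


def expected_enrichment(model: CompositionModel) -> float:
    """Relative-abundance enrichment of a soma-only transcript on germline loss.

    The intact pool is n_soma + rho*n_germ; after ablation only
    n_soma + rho*n_germ*residual remains, so a somatic transcript's pool
    share is multiplied by their ratio.  With the adult counts and rho = 1,
    residual = 0 this is 2959/959 ~ 3.09 — the "about threefold" enrichment
    predicted from the 2:1 germline-to-soma nuclei proportion.
    """
    g = model.rho * model.n_germ
    return (model.n_soma + g) / (model.n_soma + g * model.residual_germline)


@dataclass
class MarkerPanel:
    """Disjoint somatic-specific / germline-specific / ubiquitous gene lists."""

    somatic: list[str]
    germline: list[str]
    ubiquitous: list[str]

    def __post_init__(self) -> None:
        groups = [set(self.somatic), set(self.germline), set(self.ubiquitous)]
        if any(not g for g in groups):
            raise ValueError("all three marker lists must be non-empty")
        if groups[0] & groups[1] or groups[0] & groups[2] or groups[1] & groups[2]:
            raise ValueError("marker lists must be disjoint")

    @classmethod
    def from_file(cls, path) -> "MarkerPanel":
        """Read a three-section plain-text panel.

        Sections start with ``[somatic]``, ``[germline]`` or
        ``[ubiquitous]``; following non-blank lines are gene ids.
        """
        sections: dict[str, list[str]] = {"somatic": [], "germline": [], "ubiquitous": []}
        current = None
        for line in open(path):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("[") and line.endswith("]"):
                current = line[1:-1]
                if current not in sections:
                    raise ValueError(f"unknown panel section {current!r}")
            elif current is None:
                raise ValueError("gene id before any section header")
            else:
                sections[current].append(line)
        return cls(sections["somatic"], sections["germline"], sections["ubiquitous"])


def calibrate_markers(
    fc_table: pd.Series,
    panel: MarkerPanel,
    reference_tolerance: float = 0.2,
) -> dict:
    """Summarise observed fold changes per marker class.

    ``fc_table`` maps gene id -> linear GSC(-)/WT fold change.  Returns
    per-class median and interquartile range, plus flags for whether the
    ubiquitous references are composition-stable (median FC within
    ``reference_tolerance`` of 1) and germline markers depleted
    (median FC < 1).
    """
    missing = [
        g
        for g in panel.somatic + panel.germline + panel.ubiquitous
        if g not in fc_table.index
    ]
    if missing:
        raise KeyError(f"panel genes missing from fold-change table: {missing}")

    def _stats(genes: list[str]) -> dict:
        vals = fc_table.loc[genes].astype(float)
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        return {"median": float(med), "iqr": (float(q1), float(q3)), "n": len(vals)}

    summary = {
        "somatic": _stats(panel.somatic),
        "germline": _stats(panel.germline),
        "ubiquitous": _stats(panel.ubiquitous),
    }
    summary["reference_stable"] = bool(
        abs(summary["ubiquitous"]["median"] - 1.0) <= reference_tolerance
    )
    summary["germline_depleted"] = bool(summary["germline"]["median"] < 1.0)
    return summary


def call_somatic_upregulated(
    fc_table: pd.Series,
    model: CompositionModel | None = None,
    margin: float = 1.0,
    min_cutoff: float = 4.0,
    exclude: list[str] | pd.Index | None = None,
) -> tuple[pd.Index, float]:
    """Genes called upregulated in the soma, and the cutoff used.

    The cutoff is ``max(min_cutoff, expected_enrichment * margin)``: a gene
    must rise beyond what composition alone predicts (times a safety
    margin) and beyond the published fourfold floor.  Somatic-specific
    panel genes in ``exclude`` are never called, whatever their fold
    change, since their enrichment is expected.
    """
    if margin < 1.0:
        raise ValueError("margin must be >= 1")
    cutoff = min_cutoff
    if model is not None:
        cutoff = max(min_cutoff, expected_enrichment(model) * margin)
    called = fc_table.index[fc_table > cutoff]
    if exclude is not None:
        called = called.difference(pd.Index(exclude), sort=False)
    return called, float(cutoff)
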