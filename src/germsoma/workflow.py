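"""End-to-end expression workflow: counts -> contrasts -> dependency screen.

Convenience layer used by the command-line interface and analysis scripts;
each step delegates to the module that owns it.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .io import CountMatrix
from .linear import ContrastResult, GeneExpressionLM, ModeratedFitResults
from .normalize import cpm_filter, design_matrix, voom_transform
from .screen import DependencyResult, DependencyScreen, SignPattern

#: condition labels as genotype/rnai pairs
WT = "WT/vector"
GSC = "GSC-/vector"
GSC_SKN1 = "GSC-/skn-1"


@dataclass
class StudyResults:
    """Fitted contrasts and the dependency screen for the three-condition design."""

    moderated: ModeratedFitResults
    gsc_vs_wt: ContrastResult
    skn1rnai_vs_gsc: ContrastResult
    screen: DependencyResult

    def summary(self) -> str:
        return "\n\n".join(
            [
                self.moderated.summary(),
                self.gsc_vs_wt.summary(n=5),
                self.skn1rnai_vs_gsc.summary(n=5),
                self.screen.summary(),
            ]
        )


def run_expression_study(
    counts: CountMatrix,
    min_cpm: float = 1.0,
    min_samples: int = 2,
    quantile: bool = True,
    n_null_draws: int = 100_000,
    screen_seed: int = 0,
) -> StudyResults:
    """Filter, normalise, fit and screen the three-condition count matrix.

    Contrasts are GSC(-) vs WT and GSC(-)+skn-1 RNAi vs GSC(-); the screen
    requires up-then-down signs across them.
    """
    filtered = cpm_filter(counts, min_cpm=min_cpm, min_samples=min_samples)
    design = design_matrix(filtered.samples)
    for cond in (WT, GSC, GSC_SKN1):
        if cond not in design.columns:
            raise ValueError(f"condition {cond!r} missing from the sample sheet")
    wle = voom_transform(filtered, design, quantile=quantile)
    moderated = GeneExpressionLM(wle, design).fit().ebayes()

    def _contrast(pos: str, neg: str, name: str) -> ContrastResult:
        c = {pos: 1.0, neg: -1.0}
        return moderated.contrast(c, name=name)

    c1 = _contrast(GSC, WT, "gsc_vs_wt")
    c2 = _contrast(GSC_SKN1, GSC, "skn1rnai_vs_gsc")
    screen = DependencyScreen(
        c1, c2, SignPattern(+1, -1), n_draws=n_null_draws, seed=screen_seed
    ).fit()
    return StudyResults(moderated, c1, c2, screen)
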