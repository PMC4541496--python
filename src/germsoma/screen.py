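"""SKN-1-dependency screen: min-|t| over two contrasts with a sign pattern.

A gene is induced by germline loss in a *skn-1*-dependent way when its
expression is higher in GSC(-) vs WT (contrast 1, t positive) and lower in
GSC(-) + *skn-1* RNAi vs GSC(-) (contrast 2, t negative).  The screen
statistic is the minimum absolute t over the two contrasts when both signs
match the required pattern, and zero otherwise; significance comes from an
empirical null built by applying the same rule to independent randomly
generated t-statistics, followed by Benjamini-Hochberg FDR over all
screened genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .linear import ContrastResult, bh_fdr


@dataclass(frozen=True)
class SignPattern:
    """Required t signs: +1 / -1 per contrast (default up then down)."""

    sign1: int = +1
    sign2: int = -1

    def __post_init__(self) -> None:
        if self.sign1 not in (-1, 1) or self.sign2 not in (-1, 1):
            raise ValueError("signs must be +1 or -1")


def min_t_statistic(
    t1: np.ndarray | float, t2: np.ndarray | float, pattern: SignPattern = SignPattern()
) -> np.ndarray | float:
    """min(|t1|, |t2|) where both signs match the pattern, else 0."""
    t1a, t2a = np.asarray(t1, dtype=float), np.asarray(t2, dtype=float)
    if not (np.all(np.isfinite(t1a)) and np.all(np.isfinite(t2a))):
        raise ValueError("t-statistics must be finite")
    ok = (np.sign(t1a) == pattern.sign1) & (np.sign(t2a) == pattern.sign2)
    T = np.where(ok, np.minimum(np.abs(t1a), np.abs(t2a)), 0.0)
    return T if T.ndim else float(T)


@dataclass
class NullModel:
    """Stored null sample of the screen statistic.

    Generated by drawing random t variates at the stated degrees of
    freedom and applying the min-|t| rule; draws that violate the sign
    pattern contribute zeros (3/4 of them asymptotically when the two t
    are independent), a mass that keeps the resulting p-values
    conservative for sign-violating genes.

    ``correlation`` is the correlation between the two t numerators and
    ``shared_denominator`` states whether one variance estimate scaled
    both statistics — set both to mirror how the observed t pairs were
    produced (contrasts sharing a condition and a moderated variance are
    negatively correlated with a common denominator).
    """

    df1: float
    df2: float
    n_draws: int
    seed: int
    pattern: SignPattern
    values: np.ndarray = field(repr=False)
    correlation: float = 0.0
    shared_denominator: bool = False

    def __post_init__(self) -> None:
        if self.n_draws < 1000:
            raise ValueError("null sample too coarse: need at least 1000 draws")
        if (self.values < 0).any():
            raise ValueError("null statistics must be non-negative")


def sample_null_distribution(
    df1: float,
    df2: float,
    n_draws: int = 100_000,
    seed: int = 0,
    pattern: SignPattern = SignPattern(),
    correlation: float = 0.0,
    shared_denominator: bool = False,
) -> NullModel:
    """Simulate the null distribution of the min-|t| statistic.

    By default the two t variates are independent.  When the observed
    statistics come from two contrasts of one fitted model, pass the
    contrast ``correlation`` (e.g. -0.5 for A-B vs C-A chains under a
    balanced cell-means design) and ``shared_denominator=True`` so a
    single chi-squared variance draw scales both numerators, exactly as
    one moderated variance estimate scales both observed t; ignoring this
    structure makes the null stochastically too small and the p-values
    anti-conservative.
    """
    if df1 <= 0 or df2 <= 0:
        raise ValueError("degrees of freedom must be positive")
    if n_draws < 1000:
        raise ValueError("null sample too coarse: need at least 1000 draws")
    if not -1.0 < correlation < 1.0:
        raise ValueError("correlation must be in (-1, 1)")
    if shared_denominator and df1 != df2:
        raise ValueError("shared denominator requires equal degrees of freedom")
    rng = np.random.default_rng(seed)
    z1 = rng.standard_normal(n_draws)
    z2 = correlation * z1 + np.sqrt(1.0 - correlation**2) * rng.standard_normal(n_draws)
    if shared_denominator:
        v = rng.chisquare(df1, n_draws) / df1 if np.isfinite(df1) else 1.0
        t1, t2 = z1 / np.sqrt(v), z2 / np.sqrt(v)
    else:
        v1 = rng.chisquare(df1, n_draws) / df1 if np.isfinite(df1) else 1.0
        v2 = rng.chisquare(df2, n_draws) / df2 if np.isfinite(df2) else 1.0
        t1, t2 = z1 / np.sqrt(v1), z2 / np.sqrt(v2)
    values = np.asarray(min_t_statistic(t1, t2, pattern))
    return NullModel(
        df1, df2, n_draws, seed, pattern, values, correlation, shared_denominator
    )


def empirical_pvalue(T: np.ndarray | float, null: NullModel) -> np.ndarray | float:
    """p = (1 + #{null >= T}) / (1 + n_draws), add-one corrected."""
    sorted_null = np.sort(null.values)
    Ta = np.atleast_1d(np.asarray(T, dtype=float))
    n_ge = null.n_draws - np.searchsorted(sorted_null, Ta, side="left")
    p = (1.0 + n_ge) / (1.0 + null.n_draws)
    return p if np.ndim(T) else float(p[0])


@dataclass
class DependencyResult:
    """Per-gene screen output: t1, t2, statistic T, empirical p, BH q."""

    table: pd.DataFrame
    null: NullModel

    @property
    def genes(self) -> pd.Index:
        return self.table.index

    def hits(self, alpha: float = 0.05) -> pd.Index:
        return self.table.index[self.table["q"] < alpha]

    def summary(self) -> str:
        return (
            f"min-|t| dependency screen: {len(self.table)} genes, "
            f"{len(self.hits())} at q < 0.05 "
            f"(null: {self.null.n_draws} draws at df ({self.null.df1:g}, {self.null.df2:g}))"
        )

    def write_tsv(self, path) -> None:
        out = self.table.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t")


def contrast_correlation(contrast1: ContrastResult, contrast2: ContrastResult) -> float:
    """Median across genes of the correlation between two contrast estimates.

    Computed from each gene's unscaled coefficient covariance and the two
    contrast vectors; for equal-weight cell-means chains like (B - A,
    C - B) this is exactly -1/2.
    """
    fit = contrast1.extra.get("fit")
    c1 = contrast1.extra.get("contrast_vector")
    c2 = contrast2.extra.get("contrast_vector")
    if fit is None or c1 is None or c2 is None or fit is not contrast2.extra.get("fit"):
        raise ValueError("contrasts must come from the same fitted model")
    cov = fit.cov_unscaled
    num = np.einsum("p,gpq,q->g", c1, cov, c2)
    den = np.sqrt(
        np.einsum("p,gpq,q->g", c1, cov, c1) * np.einsum("p,gpq,q->g", c2, cov, c2)
    )
    return float(np.median(num / den))


class DependencyScreen:
    """Model object combining two fitted contrasts into the min-|t| screen.

    ``correlation='auto'`` (default) recovers the between-contrast
    correlation from the shared fitted model and draws the null with a
    shared variance denominator, mirroring how the observed t pairs were
    produced; pass an explicit float (and ``shared_denominator``) to
    override, or 0.0 for fully independent null t draws.
    """

    def __init__(
        self,
        contrast1: ContrastResult,
        contrast2: ContrastResult,
        pattern: SignPattern = SignPattern(),
        n_draws: int = 100_000,
        seed: int = 0,
        correlation: float | str = "auto",
        shared_denominator: bool | None = None,
    ):
        if not contrast1.genes.equals(contrast2.genes):
            raise ValueError("contrasts must cover the same genes in the same order")
        self.contrast1 = contrast1
        self.contrast2 = contrast2
        self.pattern = pattern
        self.n_draws = n_draws
        self.seed = seed
        if correlation == "auto":
            self.correlation = contrast_correlation(contrast1, contrast2)
            self.shared_denominator = True if shared_denominator is None else shared_denominator
        else:
            self.correlation = float(correlation)
            self.shared_denominator = bool(shared_denominator)

    def fit(self) -> DependencyResult:
        t1 = self.contrast1.table["t"].to_numpy()
        t2 = self.contrast2.table["t"].to_numpy()
        T = np.asarray(min_t_statistic(t1, t2, self.pattern))
        # pooled df: both contrasts share the moderated total df
        null = sample_null_distribution(
            self.contrast1.df_total,
            self.contrast2.df_total,
            n_draws=self.n_draws,
            seed=self.seed,
            pattern=self.pattern,
            correlation=self.correlation,
            shared_denominator=self.shared_denominator,
        )
        p = np.asarray(empirical_pvalue(T, null))
        table = pd.DataFrame(
            {
                "t1": t1,
                "t2": t2,
                "T": T,
                "p": p,
                "q": bh_fdr(p),
                "sign_ok": T > 0,
            },
            index=self.contrast1.genes,
        )
        return DependencyResult(table=table, null=null)


def run_screen(
    contrast1: ContrastResult,
    contrast2: ContrastResult,
    pattern: SignPattern = SignPattern(),
    n_draws: int = 100_000,
    seed: int = 0,
    correlation: float | str = "auto",
) -> DependencyResult:
    return DependencyScreen(
        contrast1, contrast2, pattern, n_draws, seed, correlation=correlation
    ).fit()


def classify_gene_sets(
    fc_gsc_vs_wt: pd.Series,
    fc_skn_vs_gsc: pd.Series,
    p_skn_vs_gsc: pd.Series,
    fc_skn_vs_wt: pd.Series | None = None,
    p_skn_vs_wt: pd.Series | None = None,
    up_threshold: float = 4.0,
    up_threshold_strong: float = 5.0,
    down_threshold: float = 2.0 / 3.0,
    alpha: float = 0.05,
) -> dict[str, pd.Index]:
    """Published fold-change gene-set classifiers (strict inequalities).

    Sets
    ----
    ``GSC_up4`` / ``GSC_up5``
        linear fold change in GSC(-) vs WT above 4 / above 5.
    ``SKN1_up_GSC``
        reduced by *skn-1* RNAi in the GSC(-) background: FC < 2/3 (i.e. a
        >= 33% reduction) with p < alpha.
    ``SKN1_up_WT``
        the same rule in the WT background (only when that contrast is
        supplied).
    ``SKN1_dependent_GSC``
        FC > 4 up in GSC(-) and FC < 2/3 under *skn-1* RNAi — the
        high-confidence skn-1-dependent induction set.
    """
    idx = fc_gsc_vs_wt.index
    fc_skn_vs_gsc = fc_skn_vs_gsc.reindex(idx)
    p_skn_vs_gsc = p_skn_vs_gsc.reindex(idx)
    sets = {
        "GSC_up4": idx[fc_gsc_vs_wt > up_threshold],
        "GSC_up5": idx[fc_gsc_vs_wt > up_threshold_strong],
        "SKN1_up_GSC": idx[(fc_skn_vs_gsc < down_threshold) & (p_skn_vs_gsc < alpha)],
        "SKN1_dependent_GSC": idx[
            (fc_gsc_vs_wt > up_threshold) & (fc_skn_vs_gsc < down_threshold)
        ],
    }
    if fc_skn_vs_wt is not None and p_skn_vs_wt is not None:
        fc_w = fc_skn_vs_wt.reindex(idx)
        p_w = p_skn_vs_wt.reindex(idx)
        sets["SKN1_up_WT"] = idx[(fc_w < down_threshold) & (p_w < alpha)]
    return sets


def write_gene_lists(sets: dict[str, pd.Index], out_dir) -> None:
    """One newline-delimited gene-id file per set."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, genes in sets.items():
        (out / f"{name}.txt").write_text("\n".join(map(str, genes)) + "\n")
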