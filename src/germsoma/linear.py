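"""Gene-wise weighted linear models with empirical-Bayes variance moderation.

The modelling surface follows the statsmodels convention: a
:class:`GeneExpressionLM` model is built from a
:class:`~germsoma.normalize.WeightedLogExpression` and a design matrix;
``fit()`` returns :class:`GeneFitResults` (per-gene weighted-least-squares
estimates), whose ``ebayes()`` shrinks the residual variances towards a
common prior by the closed-form moment method on log-variances and returns
:class:`ModeratedFitResults`, from which ``contrast()`` produces moderated
t-statistics, p-values and BH q-values for a named comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .normalize import WeightedLogExpression, design_matrix


def bh_fdr(pvals: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone-enforced)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


class GeneExpressionLM:
    """Model: one weighted linear model per gene under a shared design."""

    def __init__(self, data: WeightedLogExpression, design: pd.DataFrame | None = None):
        self.data = data
        self.design = data.design if design is None else design
        X = self.design.to_numpy(dtype=float)
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("design matrix is rank deficient")
        if X.shape[0] <= X.shape[1]:
            raise ValueError("fewer samples than coefficients leaves no residual df")
        self.exog_names = list(self.design.columns)

    @classmethod
    def from_counts(cls, counts, design: pd.DataFrame | None = None, **voom_kwargs):
        """Convenience constructor running the voom transform first."""
        from .normalize import voom_transform

        if design is None:
            design = design_matrix(counts.samples)
        return cls(voom_transform(counts, design, **voom_kwargs), design)

    def fit(self) -> "GeneFitResults":
        X = self.design.to_numpy(dtype=float)
        Y = self.data.log_expr.to_numpy(dtype=float)
        W = self.data.weights.to_numpy(dtype=float)
        n, p = X.shape

        # batched weighted normal equations, one p x p system per gene
        xtwx = np.einsum("sp,gs,sq->gpq", X, W, X)
        xtwy = np.einsum("sp,gs,gs->gp", X, W, Y)
        cov_unscaled = np.linalg.inv(xtwx)
        beta = np.einsum("gpq,gq->gp", cov_unscaled, xtwy)

        resid = Y - beta @ X.T
        df_resid = n - p
        sigma2 = np.einsum("gs,gs->g", W, resid**2) / df_resid
        return GeneFitResults(
            model=self,
            coefficients=pd.DataFrame(
                beta, index=self.data.log_expr.index, columns=self.exog_names
            ),
            cov_unscaled=cov_unscaled,
            sigma2=pd.Series(sigma2, index=self.data.log_expr.index, name="sigma2"),
            df_resid=float(df_resid),
        )


@dataclass
class GeneFitResults:
    """Per-gene weighted-least-squares estimates.

    ``cov_unscaled`` holds each gene's unscaled coefficient covariance
    (inverse weighted Gram matrix); multiply by the (moderated) residual
    variance to obtain sampling covariances.
    """

    model: GeneExpressionLM
    coefficients: pd.DataFrame
    cov_unscaled: np.ndarray
    sigma2: pd.Series
    df_resid: float

    @property
    def genes(self) -> pd.Index:
        return self.coefficients.index

    def unscaled_se(self, contrast: np.ndarray) -> np.ndarray:
        c = np.asarray(contrast, dtype=float)
        return np.sqrt(np.einsum("p,gpq,q->g", c, self.cov_unscaled, c))

    def ebayes(self, prior: "EBayesParams | None" = None) -> "ModeratedFitResults":
        """Moderate residual variances towards an empirical prior."""
        s2 = self.sigma2.to_numpy()
        if prior is None:
            prior = estimate_ebayes_params(s2, self.df_resid)
        d0, s02 = prior.df_prior, prior.var_prior
        dg = self.df_resid
        if np.isinf(d0):
            s2_post = np.full_like(s2, s02)
        else:
            s2_post = (d0 * s02 + dg * s2) / (d0 + dg)
        return ModeratedFitResults(
            fit=self,
            params=prior,
            sigma2_post=pd.Series(s2_post, index=self.genes, name="sigma2_post"),
        )

    def ordinary_t(self, contrast: np.ndarray) -> pd.Series:
        """Unmoderated t-statistics for a contrast (d0 = 0 limit)."""
        c = np.asarray(contrast, dtype=float)
        est = self.coefficients.to_numpy() @ c
        se = self.unscaled_se(c) * np.sqrt(self.sigma2.to_numpy())
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, est / se, 0.0)
        return pd.Series(t, index=self.genes, name="t")


@dataclass
class EBayesParams:
    """Prior degrees of freedom d0 (may be inf) and prior variance s0^2."""

    df_prior: float
    var_prior: float

    def __post_init__(self) -> None:
        if not self.df_prior >= 0:
            raise ValueError("df_prior must be non-negative")
        if not self.var_prior > 0:
            raise ValueError("var_prior must be positive")


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) / x < 1e-10:
            break
    return float(x)


def estimate_ebayes_params(sigma2: np.ndarray, df_resid: float | np.ndarray) -> EBayesParams:
    """Moment-match log residual variances against a scaled F distribution.

    Under the hierarchical model s_g^2 ~ s0^2 * F(d_g, d0), the log
    variances satisfy E[log s^2] and Var[log s^2] expressions in digamma /
    trigamma functions of d_g/2 and d0/2; matching the observed moments
    yields closed-form estimates.  Excess variance <= 0 gives d0 = inf
    (all genes share one variance).
    """
    s2 = np.asarray(sigma2, dtype=float)
    dg = np.broadcast_to(np.asarray(df_resid, dtype=float), s2.shape)
    ok = (s2 > 0) & (dg > 0)
    if ok.sum() < 2:
        raise ValueError("need at least two genes with positive residual variance")
    s2, dg = s2[ok], dg[ok]
    z = np.log(s2)
    e = z - special.digamma(dg / 2.0) + np.log(dg / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - np.mean(special.polygamma(1, dg / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s02 = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s02 = float(np.exp(emean))
    return EBayesParams(df_prior=d0, var_prior=s02)


@dataclass
class ModeratedFitResults:
    """Results carrying empirical-Bayes moderated variances."""

    fit: GeneFitResults
    params: EBayesParams
    sigma2_post: pd.Series

    @property
    def df_total(self) -> float:
        return self.params.df_prior + self.fit.df_resid

    def contrast(
        self, contrast: np.ndarray | dict[str, float], name: str = "contrast"
    ) -> "ContrastResult":
        """Moderated t-test of c'beta = 0 for every gene."""
        if isinstance(contrast, dict):
            c = np.array([contrast.get(k, 0.0) for k in self.fit.model.exog_names])
        else:
            c = np.asarray(contrast, dtype=float)
        if c.shape != (self.fit.coefficients.shape[1],):
            raise ValueError("contrast dimension does not match coefficients")
        if np.allclose(c, 0.0):
            raise ValueError("contrast vector is identically zero")
        logfc = self.fit.coefficients.to_numpy() @ c
        se = self.fit.unscaled_se(c) * np.sqrt(self.sigma2_post.to_numpy())
        df = self.df_total
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, logfc / se, 0.0)
        if np.isinf(df):
            p = 2.0 * stats.norm.sf(np.abs(t))
        else:
            p = 2.0 * stats.t.sf(np.abs(t), df)
        p = np.clip(p, np.finfo(float).tiny, 1.0)
        table = pd.DataFrame(
            {
                "logFC": logfc,
                "FC": np.exp2(logfc),
                "t": t,
                "p": p,
                "q": bh_fdr(p),
            },
            index=self.fit.genes,
        )
        return ContrastResult(
            name=name,
            table=table,
            df_total=float(df),
            extra={"contrast_vector": c, "fit": self.fit},
        )

    def summary(self) -> str:
        lines = [
            "Gene-wise weighted linear model, empirical-Bayes moderated",
            f"  genes: {len(self.fit.genes)}",
            f"  residual df per gene: {self.fit.df_resid:g}",
            f"  prior df d0: {self.params.df_prior:g}",
            f"  prior variance s0^2: {self.params.var_prior:.4g}",
            f"  total df: {self.df_total:g}",
        ]
        return "\n".join(lines)


@dataclass
class ContrastResult:
    """Per-gene log2 fold change, moderated t, p and BH q for one contrast."""

    name: str
    table: pd.DataFrame
    df_total: float
    extra: dict = field(default_factory=dict)

    @property
    def genes(self) -> pd.Index:
        return self.table.index

    def top(self, n: int = 10) -> pd.DataFrame:
        return self.table.sort_values("p").head(n)

    def n_significant(self, alpha: float = 0.05) -> int:
        return int((self.table["q"] < alpha).sum())

    def summary(self, n: int = 10) -> str:
        head = (
            f"Contrast {self.name!r}: {len(self.table)} genes, "
            f"df = {self.df_total:g}, "
            f"{self.n_significant()} at q < 0.05"
        )
        return head + "\n" + self.top(n).to_string()

    def write_tsv(self, path) -> None:
        out = self.table.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Functional wrappers mirroring the pipeline vocabulary
# ---------------------------------------------------------------------------


def fit_gene_models(
    wle: WeightedLogExpression, design: pd.DataFrame | None = None
) -> GeneFitResults:
    return GeneExpressionLM(wle, design).fit()


def empirical_bayes_moderate(
    fits: GeneFitResults, params: EBayesParams | None = None
) -> ModeratedFitResults:
    return fits.ebayes(params)


def contrast_test(
    moderated: ModeratedFitResults,
    contrast: np.ndarray | dict[str, float],
    name: str = "contrast",
) -> ContrastResult:
    return moderated.contrast(contrast, name=name)
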