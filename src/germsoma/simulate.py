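"""Synthetic data generators emulating a germline-ablation RNA-seq study.

The expression simulator reproduces the design of the profiling experiment:
three genotypic conditions — wild type (``WT``), germline-stem-cell-ablated
animals (``GSC``, i.e. *glp-1(ts)* at the non-permissive temperature), and
GSC-ablated animals under *skn-1* RNAi (``GSC_skn1``) — each with a small
number of biological replicates.  The key structural feature is a germline
compartment that produces a fraction ``germline_share`` of the wild-type
transcript pool and collapses (down to ``residual_germline``) in the two
GSC-ablated conditions.  Because sequencing measures *relative* abundance,
removing the germline pool inflates the apparent level of every purely
somatic transcript even when its absolute somatic output is unchanged; the
simulator propagates this compositional effect by renormalising expected
pool shares per sample.

Gene classes
------------
``somatic_specific``
    expressed only in the soma; their relative abundance rises on germline
    loss purely through the compositional effect.
``germline_specific``
    expressed only in the germline; depleted to ``residual_germline`` of
    their pool share in GSC-ablated samples.
``ubiquitous``
    expressed in both compartments; approximately composition-stable.
``gsc_induced``
    somatic genes transcriptionally induced (``induction_fc``) by germline
    loss, independent of *skn-1*.
``skn1_dependent``
    somatic genes induced by germline loss whose induction collapses by a
    fraction ``knockdown_reduction`` under *skn-1* RNAi.

Counts are drawn negative-binomially with variance mu + phi*mu**2; phi = 0
degenerates to Poisson.  Every generator is deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CountMatrix

GENE_CLASSES = (
    "somatic_specific",
    "germline_specific",
    "ubiquitous",
    "gsc_induced",
    "skn1_dependent",
)

CONDITIONS = ("WT", "GSC", "GSC_skn1")

#: (genotype, rnai) metadata attached to each condition's samples.
_CONDITION_META = {
    "WT": ("WT", "vector"),
    "GSC": ("GSC-", "vector"),
    "GSC_skn1": ("GSC-", "skn-1"),
}


def _default_class_fractions() -> dict[str, float]:
    # Germline transcripts dominate gene count in gravid adults; the two
    # induced classes together cover roughly the 10% of genes the fold-change
    # screen flags.
    return {
        "somatic_specific": 0.08,
        "germline_specific": 0.25,
        "ubiquitous": 0.562,
        "gsc_induced": 0.10,
        "skn1_dependent": 0.008,
    }


@dataclass
class SimConfig:
    """Parameters of the expression-count simulator.

    Attributes
    ----------
    n_genes : int
        Number of genes (default 12595, the size of the expressed-gene set
        the pipeline is meant to operate on).
    n_replicates : int
        Biological replicates per condition; at least 2 (the expression
        filter requires a count threshold in at least two samples).
    library_size : float
        Expected total reads per sample.
    germline_share : float
        gamma, fraction of the WT transcript pool produced by the germline
        compartment, in [0, 1).  Default 2/3, the share implied by the 2:1
        germline-to-soma nuclei ratio of an adult hermaphrodite.
    residual_germline : float
        Fraction of germline output remaining after genetic GSC ablation
        (GSC number is very low but not zero), in [0, 1).
    class_fractions : dict
        Proportion of genes in each class; must sum to 1.
    induction_fc : float
        Multiplicative somatic induction of gsc_induced / skn1_dependent
        genes in GSC-ablated conditions.
    knockdown_reduction : float
        r, fractional loss of the skn1_dependent induction under skn-1
        RNAi, in [0, 1]; the RNAi-condition somatic multiplier is
        induction_fc * (1 - r).
    nb_dispersion : float
        Negative-binomial dispersion phi (variance mu + phi*mu**2); 0 gives
        Poisson counts.
    baseline_log_mean, baseline_log_sd : float
        Parameters (natural log) of the log-normal baseline expression-rate
        draw.
    seed : int
        Random seed; identical configs with identical seeds reproduce
        identical outputs.
    """

    n_genes: int = 12595
    n_replicates: int = 3
    library_size: float = 1e7
    germline_share: float = 2.0 / 3.0
    residual_germline: float = 0.05
    class_fractions: dict[str, float] = field(default_factory=_default_class_fractions)
    induction_fc: float = 6.0
    knockdown_reduction: float = 0.6
    nb_dispersion: float = 0.05
    baseline_log_mean: float = 0.0
    baseline_log_sd: float = 1.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        if self.library_size <= 0:
            raise ValueError("library_size must be positive")
        if not 0.0 <= self.germline_share < 1.0:
            raise ValueError("germline_share must be in [0, 1)")
        if not 0.0 <= self.residual_germline < 1.0:
            raise ValueError("residual_germline must be in [0, 1)")
        if not 0.0 <= self.knockdown_reduction <= 1.0:
            raise ValueError("knockdown_reduction must be in [0, 1]")
        if self.induction_fc <= 0:
            raise ValueError("induction_fc must be positive")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        unknown = set(self.class_fractions) - set(GENE_CLASSES)
        if unknown:
            raise ValueError(f"unknown gene classes: {sorted(unknown)}")
        fracs = np.array([self.class_fractions.get(c, 0.0) for c in GENE_CLASSES])
        if (fracs < 0).any() or not np.isclose(fracs.sum(), 1.0):
            raise ValueError("class_fractions must be non-negative and sum to 1")


@dataclass
class GeneTruth:
    """Ground truth behind a simulated count matrix.

    ``table`` has one row per gene: the class label, the per-compartment
    baseline rates, and the true expected relative pool share in each
    condition (columns ``share_WT``, ``share_GSC``, ``share_GSC_skn1``;
    each condition's shares sum to 1).
    """

    table: pd.DataFrame

    @property
    def classes(self) -> pd.Series:
        return self.table["gene_class"]

    def genes_of_class(self, gene_class: str) -> pd.Index:
        return self.table.index[self.table["gene_class"] == gene_class]


def _condition_multipliers(config: SimConfig) -> pd.DataFrame:
    """Per-class somatic and germline output multipliers for each condition."""
    r = config.residual_germline
    fc = config.induction_fc
    rnai_fc = config.induction_fc * (1.0 - config.knockdown_reduction)
    rows = []
    for cls in GENE_CLASSES:
        soma = {"WT": 1.0, "GSC": 1.0, "GSC_skn1": 1.0}
        if cls == "gsc_induced":
            soma["GSC"] = soma["GSC_skn1"] = fc
        elif cls == "skn1_dependent":
            soma["GSC"] = fc
            soma["GSC_skn1"] = rnai_fc
        rows.append(
            {
                "gene_class": cls,
                **{f"soma_{c}": soma[c] for c in CONDITIONS},
                **{"germ_WT": 1.0, "germ_GSC": r, "germ_GSC_skn1": r},
            }
        )
    return pd.DataFrame(rows).set_index("gene_class")


def simulate_expression_counts(config: SimConfig) -> tuple[CountMatrix, GeneTruth]:
    """Simulate a gene x sample count matrix with known ground truth.

    Expected counts follow ``library_size * share``, where a gene's pool
    share in a condition is its total output (somatic rate x condition
    somatic multiplier + germline rate x condition germline multiplier)
    renormalised over all genes, so the loss of the germline pool inflates
    every somatic transcript's share.  Counts are negative-binomial around
    the expectation.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    # Class assignment: deterministic counts (largest-remainder rounding),
    # shuffled so class does not correlate with gene order.
    fracs = np.array([config.class_fractions.get(c, 0.0) for c in GENE_CLASSES])
    counts_per_class = np.floor(fracs * config.n_genes).astype(int)
    remainder = config.n_genes - counts_per_class.sum()
    order = np.argsort(-(fracs * config.n_genes - counts_per_class))
    counts_per_class[order[:remainder]] += 1
    labels = np.repeat(np.array(GENE_CLASSES, dtype=object), counts_per_class)
    rng.shuffle(labels)

    n = config.n_genes
    gene_ids = pd.Index([f"gene{i:05d}" for i in range(n)], name="gene_id")

    base = rng.lognormal(config.baseline_log_mean, config.baseline_log_sd, size=n)
    soma_rate = base.copy()
    germ_rate = rng.lognormal(config.baseline_log_mean, config.baseline_log_sd, size=n)
    is_germ_only = labels == "germline_specific"
    soma_only = np.isin(labels, ["somatic_specific", "gsc_induced", "skn1_dependent"])
    soma_rate[is_germ_only] = 0.0
    germ_rate[soma_only] = 0.0

    # Scale germline output so it contributes germline_share of the WT pool.
    soma_total = soma_rate.sum()
    germ_total = germ_rate.sum()
    gamma = config.germline_share
    if gamma == 0.0 or germ_total == 0.0:
        germ_rate[:] = 0.0
    else:
        germ_rate *= (gamma / (1.0 - gamma)) * soma_total / germ_total

    mult = _condition_multipliers(config)
    soma_mult = mult.loc[labels, [f"soma_{c}" for c in CONDITIONS]].to_numpy()
    germ_mult = mult.loc[labels, [f"germ_{c}" for c in CONDITIONS]].to_numpy()

    output = soma_rate[:, None] * soma_mult + germ_rate[:, None] * germ_mult
    shares = output / output.sum(axis=0, keepdims=True)  # genes x conditions

    sample_rows = []
    count_cols = {}
    for j, cond in enumerate(CONDITIONS):
        genotype, rnai = _CONDITION_META[cond]
        for rep in range(1, config.n_replicates + 1):
            sid = f"{cond}_r{rep}"
            mu = config.library_size * shares[:, j]
            count_cols[sid] = _nb_draw(rng, mu, config.nb_dispersion)
            sample_rows.append(
                {"sample_id": sid, "genotype": genotype, "rnai": rnai, "replicate": rep}
            )

    counts = pd.DataFrame(count_cols, index=gene_ids)
    samples = pd.DataFrame(sample_rows).set_index("sample_id")

    truth = pd.DataFrame(
        {
            "gene_class": labels,
            "soma_rate": soma_rate,
            "germ_rate": germ_rate,
            **{f"share_{c}": shares[:, j] for j, c in enumerate(CONDITIONS)},
        },
        index=gene_ids,
    )
    return CountMatrix(counts, samples), GeneTruth(truth)


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, phi: float) -> np.ndarray:
    """Negative-binomial draw with variance mu + phi*mu**2 (phi=0: Poisson)."""
    if phi == 0.0:
        return rng.poisson(mu).astype(np.int64)
    size_param = 1.0 / phi
    p = size_param / (size_param + mu)
    return rng.negative_binomial(size_param, p).astype(np.int64)


# ---------------------------------------------------------------------------
# Survival cohorts
# ---------------------------------------------------------------------------


@dataclass
class SurvivalSimConfig:
    """Parameters for a simulated lifespan cohort.

    ``group_means`` maps group label -> mean lifespan in days (gamma
    distributed with shape ``shape``, so SD = mean/sqrt(shape)); animals are
    independently right-censored with probability ``censor_prob`` at a
    uniform fraction of their nominal lifespan, emulating worms lost to
    crawling off the plate, rupture, or internal hatching.
    """

    group_means: dict[str, float]
    n_per_group: int = 50
    shape: float = 20.0
    censor_prob: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        if not self.group_means:
            raise ValueError("group_means must be non-empty")
        if any(m <= 0 for m in self.group_means.values()):
            raise ValueError("group mean lifespans must be positive")
        if not 0.0 <= self.censor_prob < 1.0:
            raise ValueError("censor_prob must be in [0, 1)")
        if self.shape <= 0:
            raise ValueError("shape must be positive")
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be positive")


def simulate_survival_cohort(config: SurvivalSimConfig) -> pd.DataFrame:
    """Simulate per-animal survival records.

    Returns a DataFrame with columns ``subject``, ``time_days``, ``event``
    (True = death observed, False = censored) and ``group``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    records = []
    for group, mean in config.group_means.items():
        scale = mean / config.shape
        lifespans = rng.gamma(config.shape, scale, size=config.n_per_group)
        censored = rng.random(config.n_per_group) < config.censor_prob
        times = np.where(
            censored, lifespans * rng.uniform(0.2, 1.0, config.n_per_group), lifespans
        )
        for i, (t, c) in enumerate(zip(times, censored)):
            records.append(
                {
                    "subject": f"{group}_{i:03d}",
                    "time_days": float(t),
                    "event": not c,
                    "group": group,
                }
            )
    return pd.DataFrame(records)


# ---------------------------------------------------------------------------
# Categorical score tables and stain images
# ---------------------------------------------------------------------------


def simulate_score_table(
    probs: dict[str, np.ndarray | list[float]],
    n_per_group: dict[str, int] | int,
    seed: int = 0,
    categories: tuple[str, ...] = ("high", "medium", "low"),
) -> pd.DataFrame:
    """Multinomial high/medium/low scoring counts per group.

    ``probs`` maps group label -> per-category probabilities (must sum to
    1); ``n_per_group`` is a common n or a per-group mapping.
    """
    rng = np.random.default_rng(seed)
    rows = {}
    for group, p in probs.items():
        p = np.asarray(p, dtype=float)
        if p.shape != (len(categories),):
            raise ValueError(f"probs for {group!r} must have length {len(categories)}")
        if (p < 0).any() or not np.isclose(p.sum(), 1.0):
            raise ValueError(f"probs for {group!r} must be non-negative and sum to 1")
        n = n_per_group[group] if isinstance(n_per_group, dict) else n_per_group
        rows[group] = rng.multinomial(n, p) if n > 0 else np.zeros(len(p), dtype=int)
    return pd.DataFrame(rows, index=pd.Index(categories, name="score")).T


def simulate_oro_image(
    height: int,
    width: int,
    roi: tuple[int, int, int, int],
    stain_level: float,
    noise_sd: float = 0.0,
    background: float = 120.0,
    seed: int = 0,
) -> np.ndarray:
    """Simulate an RGB micrograph of an oil-red-O-stained animal.

    Inside the rectangular ``roi`` (row0, row1, col0, col1; half-open) the
    red channel exceeds the green channel by ``stain_level`` on average —
    the dye absorbs green light, darkening G relative to R.  Outside, the
    channels are equal on average.  Gaussian pixel noise of SD ``noise_sd``
    is added per channel; values are clipped to [0, 255] uint8.
    """
    if not 0.0 <= stain_level <= 255.0:
        raise ValueError("stain_level must be in [0, 255]")
    r0, r1, c0, c1 = roi
    if not (0 <= r0 < r1 <= height and 0 <= c0 < c1 <= width):
        raise ValueError("roi outside image bounds")
    rng = np.random.default_rng(seed)
    img = np.full((height, width, 3), background, dtype=float)
    img[r0:r1, c0:c1, 1] -= stain_level  # stain attenuates green
    if noise_sd > 0:
        img += rng.normal(0.0, noise_sd, size=img.shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# Named benchmark scenarios
# ---------------------------------------------------------------------------


def calibration_config(n_genes: int = 12000, seed: int = 0, **overrides) -> SimConfig:
    """Composition-calibration scenario: a pure compartment collapse.

    Two-thirds germline share, zero residual germline, no induced gene
    classes — every fold change observed between GSC(-) and WT samples is
    compositional, so the somatic-marker enrichment has the closed form
    1/(1 - gamma) = 3.  Analyse without cross-condition quantile
    normalisation: forcing identical distributions onto samples that lost
    a quarter of their transcriptome erases the very shift being measured.
    """
    params = dict(
        n_genes=n_genes,
        germline_share=2.0 / 3.0,
        residual_germline=0.0,
        class_fractions={
            "somatic_specific": 0.10,
            "germline_specific": 0.25,
            "ubiquitous": 0.65,
            "gsc_induced": 0.0,
            "skn1_dependent": 0.0,
        },
        seed=seed,
    )
    params.update(overrides)
    return SimConfig(**params)


def global_null_config(n_genes: int = 12000, seed: int = 0, **overrides) -> SimConfig:
    """Screen-null scenario: no gene differs between conditions.

    No germline compartment and no induced classes, so both screen
    contrasts are globally null; used to check the dependency screen's
    false-discovery behaviour in isolation from the composition effect.
    """
    params = dict(
        n_genes=n_genes,
        germline_share=0.0,
        residual_germline=0.0,
        class_fractions={
            "somatic_specific": 0.30,
            "germline_specific": 0.0,
            "ubiquitous": 0.70,
            "gsc_induced": 0.0,
            "skn1_dependent": 0.0,
        },
        seed=seed,
    )
    params.update(overrides)
    return SimConfig(**params)


def planted_config(
    n_genes: int = 12000,
    n_planted: int = 100,
    induction_fc: float = 6.0,
    knockdown_reduction: float = 0.6,
    seed: int = 0,
    **overrides,
) -> SimConfig:
    """Planted-effect scenario: the global null plus skn-1-dependent genes.

    ``n_planted`` genes are induced ``induction_fc``-fold by GSC loss and
    lose fraction ``knockdown_reduction`` of that induction under skn-1
    RNAi; everything else is null, so screen recall and false-discovery
    proportion are measured against known truth.
    """
    frac = n_planted / n_genes
    params = dict(
        n_genes=n_genes,
        germline_share=0.0,
        residual_germline=0.0,
        class_fractions={
            "somatic_specific": 0.30,
            "germline_specific": 0.0,
            "ubiquitous": 0.70 - frac,
            "gsc_induced": 0.0,
            "skn1_dependent": frac,
        },
        induction_fc=induction_fc,
        knockdown_reduction=knockdown_reduction,
        seed=seed,
    )
    params.update(overrides)
    return SimConfig(**params)


def roi_mask(height: int, width: int, roi: tuple[int, int, int, int]) -> np.ndarray:
    """Boolean mask for a rectangular (row0, row1, col0, col1) region."""
    mask = np.zeros((height, width), dtype=bool)
    r0, r1, c0, c1 = roi
    mask[r0:r1, c0:c1] = True
    return mask
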