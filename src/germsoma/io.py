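"""Count-matrix container and tab-separated I/O.

The on-disk format is the featureCounts-style matrix the pipeline consumes:
a TSV with a gene-identifier first column and one integer column per sample,
paired with a sample sheet CSV (sample_id, genotype, rnai, replicate).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd


class CountFormatError(ValueError):
    """Counts are malformed (negative, non-integer, duplicated ids)."""


class SampleSheetError(ValueError):
    """Sample sheet does not cover the count-matrix columns."""


REQUIRED_SAMPLE_COLUMNS = ("genotype", "rnai", "replicate")


@dataclass
class CountMatrix:
    """Integer gene x sample counts plus per-sample metadata.

    ``counts`` is a genes x samples DataFrame; ``samples`` is indexed by
    sample id with at least genotype, rnai and replicate columns, one row
    per count column.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise CountFormatError("duplicate gene ids")
        if self.counts.columns.has_duplicates:
            raise CountFormatError("duplicate sample ids")
        values = self.counts.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise CountFormatError("counts must be numeric")
        if (values < 0).any():
            raise CountFormatError("negative counts")
        if not np.array_equal(values, np.rint(values)):
            raise CountFormatError("non-integer counts")
        missing = self.counts.columns.difference(self.samples.index)
        if len(missing):
            raise SampleSheetError(f"sample sheet missing samples: {list(missing)}")
        for col in REQUIRED_SAMPLE_COLUMNS:
            if col not in self.samples.columns:
                raise SampleSheetError(f"sample sheet missing column {col!r}")
        # align metadata to the count columns
        self.samples = self.samples.loc[self.counts.columns]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def condition_labels(self) -> pd.Series:
        """Combined genotype/RNAi condition label per sample."""
        return (
            self.samples["genotype"].astype(str)
            + "/"
            + self.samples["rnai"].astype(str)
        )

    def subset_genes(self, genes: pd.Index) -> "CountMatrix":
        return CountMatrix(self.counts.loc[genes], self.samples.copy())

    def write(self, counts_path: str | Path, sample_sheet_path: str | Path) -> None:
        df = self.counts.copy()
        df.index.name = df.index.name or "gene_id"
        df.to_csv(counts_path, sep="\t")
        self.samples.to_csv(sample_sheet_path)


def load_counts(counts_path: str | Path, sample_sheet_path: str | Path) -> CountMatrix:
    """Read a counts TSV and its sample sheet into a validated CountMatrix."""
    counts_path, sample_sheet_path = Path(counts_path), Path(sample_sheet_path)
    if not counts_path.exists():
        raise FileNotFoundError(counts_path)
    if not sample_sheet_path.exists():
        raise FileNotFoundError(sample_sheet_path)
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    samples = pd.read_csv(sample_sheet_path, index_col=0)
    return CountMatrix(counts, samples)
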