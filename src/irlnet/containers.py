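"""Shared in-memory containers for expression data.

The central object is :class:`ExpressionDataset`, a thin validated wrapper
around a pandas feature x sample matrix of log2 expression values together
with the sample class labels, optional subject pairing (for before/after
contrasts) and the feature biotype (lncRNA vs mRNA).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

LNCRNA = "lncRNA"
MRNA = "mRNA"


@dataclass
class ExpressionDataset:
    """A feature x sample log2 expression matrix with its design.

    Parameters
    ----------
    matrix
        DataFrame of shape (n_features, n_samples), log2 scale, no NaN.
    labels
        Series mapping sample id -> class label (two classes).
    contrast
        ``(positive, baseline)`` pair of class labels; differences and
        statistics are reported as positive-minus-baseline.
    biotype
        Series mapping feature id -> ``"lncRNA"`` or ``"mRNA"``.
    pairing
        Optional Series mapping sample id -> subject id for paired
        (before/after) designs; each subject must appear exactly twice,
        once per class.
    """

    matrix: pd.DataFrame
    labels: pd.Series
    contrast: tuple[str, str]
    biotype: pd.Series
    pairing: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.matrix.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        if not set(self.matrix.columns) <= set(self.labels.index):
            raise ValueError("every sample column needs a class label")
        self.labels = self.labels.loc[self.matrix.columns]
        classes = set(self.labels.unique())
        if classes != set(self.contrast):
            raise ValueError(
                f"labels {sorted(classes)} do not match contrast {self.contrast}"
            )
        counts = self.labels.value_counts()
        if (counts < 3).any():
            raise ValueError("need at least 3 samples per class")
        if not set(self.matrix.index) <= set(self.biotype.index):
            raise ValueError("every feature needs a biotype")
        self.biotype = self.biotype.loc[self.matrix.index]
        bad = set(self.biotype.unique()) - {LNCRNA, MRNA}
        if bad:
            raise ValueError(f"unknown biotypes: {sorted(bad)}")
        if self.pairing is not None:
            self.pairing = self.pairing.loc[self.matrix.columns]
            per_subject = self.pairing.groupby(self.pairing).size()
            if (per_subject != 2).any():
                raise ValueError("paired design requires exactly 2 samples per subject")

    # -- convenience accessors -------------------------------------------------

    @property
    def features(self) -> pd.Index:
        return self.matrix.index

    @property
    def samples(self) -> pd.Index:
        return self.matrix.columns

    def group_columns(self, label: str) -> list[str]:
        return list(self.labels.index[self.labels == label])

    def values_for(self, label: str) -> np.ndarray:
        """Matrix restricted to one class, as an array (features x samples)."""
        return self.matrix[self.group_columns(label)].to_numpy()

    def paired_differences(self) -> pd.DataFrame:
        """Per-subject positive-minus-baseline differences (features x subjects)."""
        if self.pairing is None:
            raise ValueError("dataset has no pairing information")
        pos, base = self.contrast
        diffs = {}
        for subject, cols in self.pairing.groupby(self.pairing).groups.items():
            cols = list(cols)
            pos_col = [c for c in cols if self.labels[c] == pos]
            base_col = [c for c in cols if self.labels[c] == base]
            if len(pos_col) != 1 or len(base_col) != 1:
                raise ValueError(f"subject {subject} lacks one sample per class")
            diffs[subject] = self.matrix[pos_col[0]] - self.matrix[base_col[0]]
        return pd.DataFrame(diffs)

    def subset_features(self, features) -> "ExpressionDataset":
        feats = [f for f in features if f in self.matrix.index]
        return ExpressionDataset(
            matrix=self.matrix.loc[feats],
            labels=self.labels.copy(),
            contrast=self.contrast,
            biotype=self.biotype.loc[feats],
            pairing=None if self.pairing is None else self.pairing.copy(),
        )
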