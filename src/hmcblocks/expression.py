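"""Expression-level classes and developmental gene groups.

Genes are summarized per cohort by the median of their normalized
expression values (linear scale).  Level classes split the non-silent
genes into tertiles of the cohort median; developmental groups I-V
contrast the two cohort medians:

    I   fetal-specific   (expressed in fetal, silent in adult)
    II  fetal-biased     (both expressed, fetal >= fold x adult)
    III non-developmental (both expressed, ratio within (1/fold, fold))
    IV  adult-biased     (both expressed, adult >= fold x fetal)
    V   adult-specific   (expressed in adult, silent in fetal)

Genes silent in both cohorts are 'unassigned'.  "Silent" means cohort
median below a threshold; the default threshold is the 5th percentile of
all cohort medians, but an explicit value is preferred when the platform's
detection limit is known.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

LEVELS = ("silent", "low", "intermediate", "high")
GROUPS = ("I", "II", "III", "IV", "V")

__all__ = [
    "ExpressionMatrix",
    "summarize_cohort",
    "classify_levels",
    "assign_groups",
    "default_silent_threshold",
]


class ExpressionMatrix:
    """Genes x samples matrix of normalized linear-scale expression values."""

    def __init__(self, values: pd.DataFrame, cohorts: dict[str, str]):
        if values.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        if values.index.duplicated().any():
            raise ValueError("duplicate gene ids")
        if (values.to_numpy() < 0).any():
            raise ValueError("negative expression values")
        missing = set(values.columns) - set(cohorts)
        if missing:
            raise ValueError(f"samples without cohort label: {sorted(missing)}")
        self.values = values
        self.cohorts = {s: cohorts[s] for s in values.columns}
        counts = pd.Series(list(self.cohorts.values())).value_counts()
        for cohort, n in counts.items():
            if n < 2:
                raise ValueError(f"cohort {cohort!r} has fewer than 2 samples")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    def cohort_samples(self, cohort: str) -> list[str]:
        return [s for s, c in self.cohorts.items() if c == cohort]

    @classmethod
    def from_tsv(cls, path, manifest: dict[str, str]) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        return cls(df, manifest)

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="gene_id")


def summarize_cohort(expr: ExpressionMatrix, cohort: str) -> pd.Series:
    """Per-gene median over the cohort's samples."""
    samples = expr.cohort_samples(cohort)
    if not samples:
        raise ValueError(f"cohort {cohort!r} not present in expression matrix")
    return expr.values[samples].median(axis=1)


def default_silent_threshold(*median_series: pd.Series, q: float = 0.05) -> float:
    """Silence cutoff as the q-quantile of the pooled cohort medians."""
    pooled = np.concatenate([np.asarray(m, dtype=float) for m in median_series])
    return float(np.quantile(pooled, q))


def classify_levels(medians: pd.Series, silent_threshold: float) -> pd.Series:
    """Classify genes into silent plus low/intermediate/high tertiles.

    Tertiles are taken over the non-silent genes ranked by (median, gene id);
    the stable gene-id tie-break makes equal medians split deterministically
    into near-equal classes (sizes differ by at most 1, extras going to the
    lower classes first).
    """
    medians = medians.astype(float)
    out = pd.Series("silent", index=medians.index, dtype=object)
    nonsilent = medians[medians >= silent_threshold]
    n = len(nonsilent)
    if n < 3:
        raise ValueError("fewer than 3 non-silent genes; cannot form tertiles")
    order = sorted(nonsilent.index, key=lambda g: (nonsilent[g], str(g)))
    base, rem = divmod(n, 3)
    sizes = [base + (1 if i < rem else 0) for i in range(3)]
    lo = order[: sizes[0]]
    mid = order[sizes[0] : sizes[0] + sizes[1]]
    hi = order[sizes[0] + sizes[1] :]
    out[lo] = "low"
    out[mid] = "intermediate"
    out[hi] = "high"
    return out


def assign_groups(
    fetal_medians: pd.Series,
    adult_medians: pd.Series,
    silent_threshold: float,
    fold: float = 2.0,
) -> pd.Series:
    """Assign developmental groups I-V from the two cohort medians."""
    if fold <= 1:
        raise ValueError(f"fold must be > 1, got {fold}")
    if set(fetal_medians.index) != set(adult_medians.index):
        raise ValueError("cohort medians cover different gene universes")
    adult_medians = adult_medians.reindex(fetal_medians.index)
    f = fetal_medians.astype(float)
    a = adult_medians.astype(float)
    f_on = f >= silent_threshold
    a_on = a >= silent_threshold
    out = pd.Series("unassigned", index=f.index, dtype=object)
    out[f_on & ~a_on] = "I"
    out[~f_on & a_on] = "V"
    both = f_on & a_on
    out[both & (f >= fold * a)] = "II"
    out[both & (a >= fold * f)] = "IV"
    out[both & (f < fold * a) & (a < fold * f)] = "III"
    return out
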