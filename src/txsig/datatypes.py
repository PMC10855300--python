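"""Core data model: expression matrices, sample annotations, DEG tables, run config.

All downstream stages consume :class:`ExpressionMatrix` (genes x samples) plus a
:class:`GroupAnnotation`. Validation is total: malformed inputs raise
:class:`ValidationError` with coordinates, never silently coerce.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "Unit",
    "ExpressionMatrix",
    "GroupAnnotation",
    "DEGTable",
    "RunConfig",
    "DEFAULT_GROUPS",
    "DEFAULT_CLASSIFIERS",
    "DEFAULT_OVERSAMPLERS",
    "METRIC_ORDER",
]


class ValidationError(ValueError):
    """Raised for any invariant violation in input data."""


#: Known unit tags for expression values.
Unit = ("read_count", "ct", "log2fc")

DEFAULT_GROUPS = ("Control", "BPS", "DO")

DEFAULT_CLASSIFIERS = (
    "LR", "LDA", "GNB", "SVM", "KNN", "DTC", "GP", "RF", "BC", "ETC", "GBC", "Dummy",
)

DEFAULT_OVERSAMPLERS = ("BorderlineSMOTE", "SVMSMOTE", "RandomOverSampler")

#: Canonical metric order for reporting and the cumulative performance score.
METRIC_ORDER = (
    "F1",
    "Accuracy",
    "Balanced Accuracy",
    "Precision",
    "Recall",
    "Average Precision",
    "ROC-AUC",
)


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: dict[str, int] = {}
    for i in ids:
        seen[i] = seen.get(i, 0) + 1
    dups = sorted(k for k, v in seen.items() if v > 1)
    if dups:
        raise ValidationError(f"duplicate {what} id(s): {', '.join(dups)}")


@dataclass(frozen=True)
class ExpressionMatrix:
    """A genes x samples numeric matrix with a unit tag.

    Parameters
    ----------
    gene_ids : sequence of str
        Unique row identifiers (gene symbols, treated as opaque strings).
    sample_ids : sequence of str
        Unique column identifiers.
    values : ndarray of shape (n_genes, n_samples)
        Finite numeric values. ``read_count`` values must be >= 0.
    unit : str
        One of ``read_count``, ``ct``, ``log2fc``.
    """

    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    values: np.ndarray
    unit: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene_ids", tuple(str(g) for g in self.gene_ids))
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if self.unit not in Unit:
            raise ValidationError(f"unknown unit {self.unit!r}; expected one of {Unit}")
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        if vals.ndim != 2 or vals.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"value matrix shape {vals.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if not np.all(np.isfinite(vals)):
            g, s = np.argwhere(~np.isfinite(vals))[0]
            raise ValidationError(
                f"missing/non-finite value at gene {self.gene_ids[g]!r}, "
                f"sample {self.sample_ids[s]!r} (no imputation is performed)"
            )
        if self.unit == "read_count" and np.any(vals < 0):
            g, s = np.argwhere(vals < 0)[0]
            raise ValidationError(
                f"negative read count at gene {self.gene_ids[g]!r}, "
                f"sample {self.sample_ids[s]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.gene_ids),
                            columns=list(self.sample_ids))

    @classmethod
    def from_frame(cls, df: pd.DataFrame, unit: str) -> "ExpressionMatrix":
        return cls(tuple(map(str, df.index)), tuple(map(str, df.columns)),
                   df.to_numpy(dtype=float), unit)

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        genes = list(genes)
        missing = [g for g in genes if g not in self.gene_ids]
        if missing:
            raise ValidationError(f"gene(s) not in matrix: {', '.join(missing)}")
        idx = [self.gene_ids.index(g) for g in genes]
        return ExpressionMatrix(tuple(genes), self.sample_ids,
                                self.values[idx, :], self.unit)

    def subset_samples(self, samples: Iterable[str]) -> "ExpressionMatrix":
        samples = list(samples)
        missing = [s for s in samples if s not in self.sample_ids]
        if missing:
            raise ValidationError(f"sample(s) not in matrix: {', '.join(missing)}")
        idx = [self.sample_ids.index(s) for s in samples]
        return ExpressionMatrix(self.gene_ids, tuple(samples),
                                self.values[:, idx], self.unit)


class GroupAnnotation:
    """Single-valued mapping sample_id -> group label."""

    def __init__(self, mapping: Mapping[str, str],
                 known_groups: Sequence[str] | None = DEFAULT_GROUPS,
                 extensible: bool = False) -> None:
        if not mapping:
            raise ValidationError("no annotations: the annotation table is empty")
        self._map: dict[str, str] = {}
        for sample, group in mapping.items():
            sample, group = str(sample), str(group)
            if sample in self._map and self._map[sample] != group:
                raise ValidationError(
                    f"sample {sample!r} annotated with conflicting groups "
                    f"{self._map[sample]!r} and {group!r}"
                )
            if known_groups is not None and not extensible and group not in known_groups:
                raise ValidationError(
                    f"unknown group label {group!r} for sample {sample!r}; "
                    f"known labels: {', '.join(known_groups)} "
                    "(pass extensible=True to allow new labels)"
                )
            self._map[sample] = group

    def __len__(self) -> int:
        return len(self._map)

    def __contains__(self, sample: str) -> bool:
        return sample in self._map

    def __getitem__(self, sample: str) -> str:
        return self._map[sample]

    def items(self):
        return self._map.items()

    @property
    def samples(self) -> tuple[str, ...]:
        return tuple(self._map)

    def groups(self) -> tuple[str, ...]:
        """Group labels in first-appearance order."""
        out: list[str] = []
        for g in self._map.values():
            if g not in out:
                out.append(g)
        return tuple(out)

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for g in self._map.values():
            out[g] = out.get(g, 0) + 1
        return out

    def samples_in(self, group: str) -> tuple[str, ...]:
        return tuple(s for s, g in self._map.items() if g == group)

    def labels_for(self, samples: Sequence[str]) -> np.ndarray:
        missing = [s for s in samples if s not in self._map]
        if missing:
            raise ValidationError(
                f"sample(s) present in matrix but absent from annotation: "
                f"{', '.join(missing)}"
            )
        return np.asarray([self._map[s] for s in samples], dtype=object)

    def require_min_per_group(self, n: int) -> None:
        bad = {g: c for g, c in self.counts().items() if c < n}
        if bad:
            raise ValidationError(
                f"group(s) with fewer than {n} samples: "
                + ", ".join(f"{g} ({c})" for g, c in sorted(bad.items()))
            )


@dataclass(frozen=True)
class DEGTable:
    """Differential-expression records: one (gene, log2fc, p_value) row per gene."""

    frame: pd.DataFrame  # columns: gene, log2fc, p_value

    def __post_init__(self) -> None:
        df = self.frame
        required = ["gene", "log2fc", "p_value"]
        if list(df.columns[:3]) != required:
            raise ValidationError(
                f"DEG table must have columns {required}, got {list(df.columns)}"
            )
        _check_unique(list(df["gene"].astype(str)), "DEG gene")
        p = df["p_value"].to_numpy(dtype=float)
        if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
            bad = df["gene"].iloc[int(np.argmax(~((p >= 0) & (p <= 1))))]
            raise ValidationError(f"p_value outside [0,1] for gene {bad!r}")
        if np.any(~np.isfinite(df["log2fc"].to_numpy(dtype=float))):
            raise ValidationError("non-finite log2fc in DEG table")

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(self.frame["gene"].astype(str))

    def significant(self, lfc_threshold: float, p_threshold: float) -> set[str]:
        """Genes with |log2fc| > lfc_threshold and p < p_threshold."""
        df = self.frame
        mask = (df["log2fc"].abs() > lfc_threshold) & (df["p_value"] < p_threshold)
        return set(df.loc[mask, "gene"].astype(str))


@dataclass
class RunConfig:
    """Pipeline configuration mirroring the flat key-value config file."""

    cv_folds: int = 3
    cv_repeats: int = 10
    min_features: int = 3
    lfc_threshold: float = 0.5
    p_threshold: float = 0.05
    oversamplers: tuple[str, ...] = DEFAULT_OVERSAMPLERS
    classifiers: tuple[str, ...] = DEFAULT_CLASSIFIERS
    primary_metric: str = "F1"
    random_seed: int = 0
    # secondary knobs (all defaulted; not every stage reads every field)
    metric_average: str = "macro"      # or "positive" (disease-class F1)
    rfe_mode: str = "global"           # or "per_fold"
    intersect: str = "above-baseline"  # or "all"
    contributor_top_n: int = 4
    direction_filter: bool = True
    kmeans_restarts: int = 25
    param_grids: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.cv_folds < 2:
            raise ValidationError("cv_folds must be >= 2")
        if self.cv_repeats < 1:
            raise ValidationError("cv_repeats must be >= 1")
        if self.min_features < 1:
            raise ValidationError("min_features must be >= 1")
        if self.lfc_threshold <= 0 or self.p_threshold <= 0:
            raise ValidationError("thresholds must be > 0")
        if self.primary_metric not in METRIC_ORDER:
            raise ValidationError(
                f"primary_metric must be one of {METRIC_ORDER}"
            )
        self.oversamplers = tuple(self.oversamplers)
        self.classifiers = tuple(self.classifiers)
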