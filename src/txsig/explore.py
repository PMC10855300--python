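"""Exploratory statistics battery: z-score deviation calls, ECDF, correlation
with significance, normality assessment, and group-difference tests."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import ExpressionMatrix, GroupAnnotation, ValidationError

__all__ = [
    "ZScoreProfile",
    "EcdfCurve",
    "CorrelationReport",
    "zscore_profile",
    "ecdf_curve",
    "ecdf_eval",
    "ecdf_table",
    "correlation_report",
    "normality_assess",
    "group_difference_tests",
]


@dataclass(frozen=True)
class ZScoreProfile:
    """Per-(gene, sample) z-scores with High/Low deviation calls.

    z is standardized per gene across samples with the sample (n-1) sd.
    call is High iff z > 0; z <= 0 is Low (closed boundary for determinism).
    """

    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    z: np.ndarray           # genes x samples
    calls: np.ndarray       # genes x samples, dtype object in {"High","Low"}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, g in enumerate(self.gene_ids):
            for j, s in enumerate(self.sample_ids):
                rows.append((g, s, self.z[i, j], self.calls[i, j]))
        return pd.DataFrame(rows, columns=["gene", "sample", "z", "call"])


@dataclass(frozen=True)
class EcdfCurve:
    """Right-continuous empirical CDF: P(X <= x) at each sorted unique value."""

    values: np.ndarray
    fractions: np.ndarray
    n: int

    def __call__(self, threshold: float) -> float:
        idx = np.searchsorted(self.values, threshold, side="right")
        return 0.0 if idx == 0 else float(self.fractions[idx - 1])


@dataclass(frozen=True)
class CorrelationReport:
    """Gene x gene Pearson r matrix with matching two-sided p-values."""

    gene_ids: tuple[str, ...]
    r: np.ndarray
    p: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, gi in enumerate(self.gene_ids):
            for j, gj in enumerate(self.gene_ids):
                rows.append((gi, gj, self.r[i, j], self.p[i, j],
                             _stars(self.p[i, j])))
        return pd.DataFrame(rows, columns=["gene_a", "gene_b", "r", "p", "signif"])


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def zscore_profile(x: ExpressionMatrix) -> ZScoreProfile:
    """Standardize each gene across samples and call High (z > 0) / Low (z <= 0)."""
    sd = x.values.std(axis=1, ddof=1)
    if np.any(sd == 0):
        bad = x.gene_ids[int(np.argmax(sd == 0))]
        raise ValidationError(f"gene {bad!r} has zero variance; no z-score call possible")
    z = (x.values - x.values.mean(axis=1, keepdims=True)) / sd[:, None]
    calls = np.where(z > 0, "High", "Low").astype(object)
    return ZScoreProfile(x.gene_ids, x.sample_ids, z, calls)


def ecdf_curve(values) -> EcdfCurve:
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValidationError("ECDF of empty input is undefined")
    sorted_vals, counts = np.unique(values, return_counts=True)
    fractions = np.cumsum(counts) / values.size
    return EcdfCurve(sorted_vals, fractions, int(values.size))


def ecdf_eval(values, threshold: float) -> float:
    """Fraction of values <= threshold (weak inequality)."""
    return ecdf_curve(values)(threshold)


def ecdf_table(x: ExpressionMatrix, annotation: GroupAnnotation) -> pd.DataFrame:
    """Per-gene, per-group ECDF curves in long form (plot-ready)."""
    labels = annotation.labels_for(x.sample_ids)
    rows = []
    for gi, gene in enumerate(x.gene_ids):
        for group in annotation.groups():
            vals = x.values[gi, labels == group]
            if vals.size == 0:
                continue
            curve = ecdf_curve(vals)
            for v, f in zip(curve.values, curve.fractions):
                rows.append((gene, group, v, f))
    return pd.DataFrame(rows, columns=["gene", "group", "value", "fraction"])


def correlation_report(x: ExpressionMatrix) -> CorrelationReport:
    """Full symmetric Pearson r and two-sided p matrices over genes.

    p follows the exact t-distribution null for Pearson r with n-2 df;
    the diagonal is (r=1, p=0) by convention.
    """
    if x.n_samples < 3:
        raise ValidationError("correlation requires >= 3 samples")
    sd = x.values.std(axis=1, ddof=1)
    if np.any(sd == 0):
        bad = x.gene_ids[int(np.argmax(sd == 0))]
        raise ValidationError(f"gene {bad!r} has zero variance; correlation undefined")
    r = np.corrcoef(x.values)
    r = np.clip(r, -1.0, 1.0)
    n = x.n_samples
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isclose(np.abs(r), 1.0), 0.0, p)
    np.fill_diagonal(r, 1.0)
    np.fill_diagonal(p, 0.0)
    # enforce exact symmetry against float noise
    r = (r + r.T) / 2.0
    p = (p + p.T) / 2.0
    return CorrelationReport(x.gene_ids, r, p)


def normality_assess(values, alpha: float = 0.05) -> tuple[float, float, str]:
    """Shapiro-Wilk test; verdict is ``normal`` iff p >= alpha."""
    values = np.asarray(values, dtype=float)
    if not (3 <= values.size <= 5000):
        raise ValidationError(
            f"Shapiro-Wilk requires 3 <= n <= 5000, got n={values.size}"
        )
    stat, p = stats.shapiro(values)
    verdict = "normal" if p >= alpha else "non-normal"
    return float(stat), float(p), verdict


def group_difference_tests(x: ExpressionMatrix, annotation: GroupAnnotation,
                           mode: str = "kruskal_wallis_pairwise") -> pd.DataFrame:
    """Per-gene omnibus and pairwise group-difference tests.

    mode ``kruskal_wallis_pairwise``: Kruskal-Wallis omnibus + pairwise
    Mann-Whitney rank-sum with Benjamini-Hochberg adjustment.
    mode ``anova_tukey``: one-way ANOVA + Tukey HSD pairwise.

    Returns a long table: gene, omnibus_statistic, omnibus_p, group_a, group_b,
    pairwise_p, significant (pairwise p < 0.05).
    """
    if mode not in ("kruskal_wallis_pairwise", "anova_tukey"):
        raise ValidationError(f"unknown mode {mode!r}")
    labels = annotation.labels_for(x.sample_ids)
    groups = [g for g in annotation.groups() if (labels == g).sum() > 0]
    if len(groups) < 2:
        raise ValidationError("need >= 2 groups")
    for g in groups:
        if (labels == g).sum() < 2:
            raise ValidationError(f"group {g!r} has < 2 samples")

    pairs = [(groups[i], groups[j]) for i in range(len(groups))
             for j in range(i + 1, len(groups))]
    rows = []
    for gi, gene in enumerate(x.gene_ids):
        per_group = [x.values[gi, labels == g] for g in groups]
        flat = np.concatenate(per_group)
        if np.all(flat == flat[0]):
            # scipy raises on all-identical data; documented boundary:
            stat, p_omni = 0.0, 1.0
            pair_p = [1.0] * len(pairs)
        elif mode == "kruskal_wallis_pairwise":
            stat, p_omni = stats.kruskal(*per_group)
            raw = []
            for a, b in pairs:
                va, vb = x.values[gi, labels == a], x.values[gi, labels == b]
                if np.all(np.concatenate([va, vb]) == va[0]):
                    raw.append(1.0)
                else:
                    raw.append(stats.mannwhitneyu(va, vb, alternative="two-sided").pvalue)
            pair_p = list(multipletests(raw, method="fdr_bh")[1])
        else:
            stat, p_omni = stats.f_oneway(*per_group)
            res = stats.tukey_hsd(*per_group)
            pair_p = [float(res.pvalue[groups.index(a), groups.index(b)])
                      for a, b in pairs]
        for (a, b), pp in zip(pairs, pair_p):
            rows.append((gene, float(stat), float(p_omni), a, b, float(pp), pp < 0.05))
    return pd.DataFrame(rows, columns=[
        "gene", "omnibus_statistic", "omnibus_p", "group_a", "group_b",
        "pairwise_p", "significant",
    ])
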