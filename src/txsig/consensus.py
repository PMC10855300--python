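"""Signature consensus: intersect per-model RFE selections, pull unsupervised
top contributors, and combine both evidence streams into a final marker set."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ExpressionMatrix, GroupAnnotation, ValidationError
from .unsupervised import PcaResult

__all__ = [
    "intersect_selected_features",
    "unsupervised_contributors",
    "consensus_signature",
]


def intersect_selected_features(per_model_sets: list) -> set[str]:
    """Exact intersection of per-model selected-gene sets; empty allowed."""
    if not per_model_sets:
        raise ValidationError("need at least one selected-feature set")
    out = set(per_model_sets[0])
    for s in per_model_sets[1:]:
        out &= set(s)
    if not out:
        warnings.warn("feature-set intersection is empty", stacklevel=2)
    return out


def unsupervised_contributors(pca: PcaResult | pd.DataFrame, top_n: int = 2) -> set[str]:
    """Union of the top_n contributors to the first two dimensions.

    Accepts either a PcaResult or a genes x dimensions contribution table.
    Ties break lexicographically on gene id for determinism.
    """
    if isinstance(pca, PcaResult):
        table = pca.contributions_frame()
    else:
        table = pca
    if top_n > table.shape[0]:
        raise ValidationError(f"top_n={top_n} exceeds panel size {table.shape[0]}")
    if table.shape[1] < 2:
        raise ValidationError("need contributions for at least two dimensions")
    out: set[str] = set()
    for dim in table.columns[:2]:
        col = table[dim]
        ranked = sorted(zip(-col.to_numpy(dtype=float), col.index))
        out.update(g for _, g in ranked[:top_n])
    return out


def _elevated_in_group(x: ExpressionMatrix, annotation: GroupAnnotation,
                       gene: str, group: str, alpha: float = 0.05) -> bool:
    """One-sided Welch t-test: gene mean in ``group`` greater than in the rest."""
    labels = annotation.labels_for(x.sample_ids)
    gi = x.gene_ids.index(gene)
    a = x.values[gi, labels == group]
    b = x.values[gi, labels != group]
    t, p = stats.ttest_ind(a, b, equal_var=False, alternative="greater")
    return bool(p < alpha)


def consensus_signature(supervised_sets, unsupervised: set[str], *,
                        matrix: ExpressionMatrix | None = None,
                        annotation: GroupAnnotation | None = None,
                        disease: str = "BPS",
                        direction_filter: bool = True) -> tuple[set[str], dict]:
    """Intersect the disease-discriminating supervised sets with the
    unsupervised contributor set, optionally keeping only genes elevated in
    the disease group.

    ``supervised_sets`` is either a single gene set or a list of them (e.g.
    the per-task supervised selections for tasks involving the disease).
    Returns (consensus, report) where the report records both evidence streams.
    """
    if isinstance(supervised_sets, (set, frozenset)):
        supervised_sets = [supervised_sets]
    supervised_sets = [set(s) for s in supervised_sets]
    if not supervised_sets or not any(supervised_sets) or not unsupervised:
        raise ValidationError("both supervised and unsupervised inputs must be non-empty")
    supervised = intersect_selected_features(supervised_sets)
    consensus = supervised & set(unsupervised)
    dropped_direction: list[str] = []
    if direction_filter and consensus:
        if matrix is None or annotation is None:
            raise ValidationError(
                "direction filter needs the expression matrix and annotation")
        kept = set()
        for g in sorted(consensus):
            if _elevated_in_group(matrix, annotation, g, disease):
                kept.add(g)
            else:
                dropped_direction.append(g)
        consensus = kept
    report = {
        "supervised": sorted(supervised),
        "unsupervised": sorted(unsupervised),
        "dropped_by_direction_filter": dropped_direction,
        "consensus": sorted(consensus),
    }
    if not consensus:
        warnings.warn(
            "empty consensus signature; supervised="
            f"{report['supervised']}, unsupervised={report['unsupervised']}",
            stacklevel=2,
        )
    return consensus, report
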