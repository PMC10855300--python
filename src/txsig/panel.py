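"""Delta-delta-Ct log2 fold changes and marker-panel selection from DEG tables."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import DEGTable, ExpressionMatrix, GroupAnnotation, RunConfig, ValidationError

__all__ = ["PanelSelection", "compute_log2fc", "select_marker_panel"]


@dataclass(frozen=True)
class PanelSelection:
    """Ordered marker gene list with per-gene selection rationale.

    ``rationale[g]`` is ``exclusive_pass`` for genes passing the exclusivity
    filter and ``manual_addition`` for genes appended by hand.
    """

    genes: tuple[str, ...]
    rationale: dict[str, str]
    lfc_threshold: float
    p_threshold: float

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError("panel contains duplicate genes")

    def __len__(self) -> int:
        return len(self.genes)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "gene": list(self.genes),
            "rationale": [self.rationale[g] for g in self.genes],
            "lfc_threshold": self.lfc_threshold,
            "p_threshold": self.p_threshold,
        })


def compute_log2fc(ct: ExpressionMatrix, annotation: GroupAnnotation,
                   reference_gene: str, control_group: str = "Control") -> ExpressionMatrix:
    """Convert a Ct matrix to log2 fold changes vs. the control-group mean.

    For gene g and sample s, dCt(g, s) = Ct(g, s) - Ct(ref, s). The fold change
    is ``mean over control samples of dCt(g, .) - dCt(g, s)``: lower Ct means
    higher expression, so positive log2FC means expression above the control
    mean. The reference gene is dropped from the output.
    """
    if ct.unit != "ct":
        raise ValidationError(f"expected a ct matrix, got unit {ct.unit!r}")
    if reference_gene not in ct.gene_ids:
        raise ValidationError(f"reference gene {reference_gene!r} not in matrix")
    labels = annotation.labels_for(ct.sample_ids)
    control_mask = labels == control_group
    if not control_mask.any():
        raise ValidationError(f"control group {control_group!r} has no samples")

    ref_idx = ct.gene_ids.index(reference_gene)
    dct = ct.values - ct.values[ref_idx, :]
    control_mean = dct[:, control_mask].mean(axis=1, keepdims=True)
    log2fc = control_mean - dct
    keep = [i for i in range(ct.n_genes) if i != ref_idx]
    return ExpressionMatrix(
        tuple(ct.gene_ids[i] for i in keep), ct.sample_ids, log2fc[keep, :], "log2fc"
    )


def select_marker_panel(deg_primary: DEGTable, deg_other: DEGTable,
                        config: RunConfig | None = None,
                        manual_additions: list[str] | tuple[str, ...] = ()) -> PanelSelection:
    """Apply the exclusivity filter: genes significant in the primary DEG table
    (|log2fc| > threshold and p < threshold) and *not* significant in the other
    table under the same thresholds, ordered by descending |log2fc|, followed by
    manual additions.

    Absence from the other table counts as not significant there.
    """
    config = config or RunConfig()
    lfc_thr, p_thr = config.lfc_threshold, config.p_threshold
    primary_sig = deg_primary.significant(lfc_thr, p_thr)
    other_sig = deg_other.significant(lfc_thr, p_thr)
    exclusive = primary_sig - other_sig

    df = deg_primary.frame
    order = df[df["gene"].isin(exclusive)].copy()
    order["abs_lfc"] = order["log2fc"].abs()
    order = order.sort_values(["abs_lfc", "gene"], ascending=[False, True])
    genes: list[str] = list(order["gene"])
    rationale = {g: "exclusive_pass" for g in genes}

    for g in manual_additions:
        g = str(g)
        if g in rationale:
            warnings.warn(f"manual addition {g!r} already selected; deduplicated",
                          stacklevel=2)
            continue
        genes.append(g)
        rationale[g] = "manual_addition"

    if not genes:
        warnings.warn("panel selection produced an empty panel", stacklevel=2)
    return PanelSelection(tuple(genes), rationale, lfc_thr, p_thr)
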