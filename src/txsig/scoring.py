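"""Multi-metric aggregation: cumulative performance score (radar-polygon area),
model ranking, and spider-table export."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .datatypes import METRIC_ORDER, ValidationError

__all__ = ["ModelScore", "mlcps_score", "rank_models", "spider_table"]


@dataclass
class ModelScore:
    model_id: str
    metrics: dict[str, float]       # the seven metric means
    mlcps: float
    primary: float
    rank: int | None = None


def mlcps_score(metrics: dict[str, float],
                order: tuple[str, ...] = METRIC_ORDER) -> float:
    """Cumulative performance score: shaded radar-polygon area over unit area.

    The metrics sit at equal angles in the canonical order; the polygon area is
    sum_i m_i * m_{i+1} * sin(2*pi/M) / 2 (cyclically), and the score divides
    by the all-ones polygon, reducing to sum_i m_i * m_{i+1} / M. The score is
    invariant under cyclic rotation of the order but not arbitrary permutation,
    so ``order`` is frozen and echoed in outputs.
    """
    try:
        m = [float(metrics[k]) for k in order]
    except KeyError as exc:
        raise ValidationError(f"missing metric {exc.args[0]!r}") from None
    if any(v < 0 or v > 1 for v in m):
        raise ValidationError("metric values must lie in [0, 1]")
    big_m = len(m)
    return sum(m[i] * m[(i + 1) % big_m] for i in range(big_m)) / big_m


def rank_models(scores: list[ModelScore]) -> list[ModelScore]:
    """Descending by primary metric; ties by MLcps, then lexicographic id."""
    if not scores:
        raise ValidationError("no model scores to rank")
    ordered = sorted(scores, key=lambda s: (-s.primary, -s.mlcps, s.model_id))
    for i, s in enumerate(ordered, start=1):
        s.rank = i
    return ordered


def spider_table(scores: list[ModelScore], top: int, bottom: int) -> pd.DataFrame:
    """Metric-per-axis rows for the top/bottom ranked models (radar-plot input)."""
    if top < 0 or bottom < 0:
        raise ValidationError("top/bottom must be non-negative")
    if top + bottom > len(scores):
        raise ValidationError("top + bottom exceeds the number of models")
    ranked = rank_models(list(scores))
    chosen = ranked[:top] + (ranked[-bottom:] if bottom else [])
    rows = []
    for s in chosen:
        for metric in METRIC_ORDER:
            rows.append((s.model_id, s.rank, metric, s.metrics[metric], s.mlcps))
    return pd.DataFrame(rows, columns=["model", "rank", "metric", "value", "mlcps"])
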