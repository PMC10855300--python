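"""Synthetic expression data with planted group structure and ground truth.

Generates QPCR-like log2FC matrices (Gaussian per-group means) and NGS-like
count matrices (negative binomial), sized and structured like the study
cohort: 13 marker genes x 64 samples in groups Control/BPS/DO = 14/28/22,
with per-gene regulation directions. Truth records enable recovery testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datatypes import ExpressionMatrix, GroupAnnotation, ValidationError

__all__ = [
    "PANEL_GENES",
    "DEFAULT_DIRECTIONS",
    "SyntheticConfig",
    "SyntheticTruth",
    "generate_qpcr_like",
    "generate_count_like",
    "planted_signature_config",
]

#: The 13-gene marker panel used as the default roster.
PANEL_GENES = (
    "TPPP3", "FAT1", "SMTN", "ANGPTL7", "CLEC3B", "AIM1", "PALM",
    "NCALD", "P2RX2", "NRXN2", "FAM83A", "MFAP5", "NRXN3",
)

#: Per-gene regulation direction by group (+1 up, -1 down, 0 null), relative
#: to a zero-mean control group.
DEFAULT_DIRECTIONS: dict[str, dict[str, int]] = {
    "TPPP3":   {"BPS": +1, "DO": 0},
    "SMTN":    {"BPS": +1, "DO": 0},
    "ANGPTL7": {"BPS": +1, "DO": 0},
    "CLEC3B":  {"BPS": +1, "DO": 0},
    "PALM":    {"BPS": +1, "DO": 0},
    "NCALD":   {"BPS": +1, "DO": 0},
    "P2RX2":   {"BPS": +1, "DO": 0},
    "NRXN2":   {"BPS": +1, "DO": 0},
    "FAT1":    {"BPS": +1, "DO": -1},
    "AIM1":    {"BPS": -1, "DO": -1},
    "FAM83A":  {"BPS": -1, "DO": 0},
    "NRXN3":   {"BPS": 0,  "DO": +1},
    "MFAP5":   {"BPS": 0,  "DO": 0},
}


@dataclass
class SyntheticConfig:
    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"Control": 14, "BPS": 28, "DO": 22})
    genes: tuple[str, ...] = PANEL_GENES
    directions: dict[str, dict[str, int]] = field(
        default_factory=lambda: {g: dict(d) for g, d in DEFAULT_DIRECTIONS.items()})
    effect_size: float = 1.5
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 2 for n in self.group_sizes.values()):
            raise ValidationError("every group needs >= 2 samples")
        if self.effect_size < 0:
            raise ValidationError("effect size must be >= 0")
        if self.noise_sd <= 0:
            raise ValidationError("noise sd must be > 0")
        missing = [g for g in self.genes if g not in self.directions]
        if missing:
            raise ValidationError(f"no direction entry for gene(s): {', '.join(missing)}")


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted per-gene group means (log2 units) and the informative gene set."""

    group_means: dict[str, dict[str, float]]   # gene -> group -> mean
    informative: tuple[str, ...]
    seed: int


def _truth(config: SyntheticConfig) -> SyntheticTruth:
    groups = list(config.group_sizes)
    means: dict[str, dict[str, float]] = {}
    informative = []
    for g in config.genes:
        dirs = config.directions[g]
        means[g] = {grp: float(dirs.get(grp, 0) * config.effect_size)
                    for grp in groups}
        means[g]["Control"] = 0.0
        if any(d != 0 for d in dirs.values()) and config.effect_size > 0:
            informative.append(g)
    return SyntheticTruth(means, tuple(informative), config.seed)


def _annotation(config: SyntheticConfig) -> GroupAnnotation:
    mapping = {}
    for grp, n in config.group_sizes.items():
        for i in range(1, n + 1):
            mapping[f"{grp}{i}"] = grp
    return GroupAnnotation(mapping, extensible=True)


def generate_qpcr_like(config: SyntheticConfig | None = None
                       ) -> tuple[ExpressionMatrix, GroupAnnotation, SyntheticTruth]:
    """Gaussian log2FC matrix: value(g, s) ~ N(mean(g, group(s)), noise_sd)."""
    config = config or SyntheticConfig()
    truth = _truth(config)
    ann = _annotation(config)
    rng = np.random.default_rng(config.seed)
    samples = ann.samples
    labels = [ann[s] for s in samples]
    values = np.empty((len(config.genes), len(samples)))
    for i, g in enumerate(config.genes):
        mu = np.array([truth.group_means[g][lbl] for lbl in labels])
        values[i] = mu + rng.normal(0.0, config.noise_sd, size=len(samples))
    x = ExpressionMatrix(config.genes, samples, values, "log2fc")
    return x, ann, truth


def generate_count_like(config: SyntheticConfig | None = None,
                        dispersion: float = 0.3, baseline_mean: float = 500.0
                        ) -> tuple[ExpressionMatrix, GroupAnnotation, SyntheticTruth]:
    """Negative-binomial counts with group mean = baseline * 2^(direction*effect).

    var = mu + dispersion * mu^2; draws are integer and non-negative.
    """
    config = config or SyntheticConfig()
    if dispersion <= 0:
        raise ValidationError("dispersion must be > 0")
    if baseline_mean <= 0:
        raise ValidationError("baseline mean must be > 0")
    truth = _truth(config)
    ann = _annotation(config)
    rng = np.random.default_rng(config.seed)
    samples = ann.samples
    labels = [ann[s] for s in samples]
    size = 1.0 / dispersion  # NB shape parameter
    values = np.empty((len(config.genes), len(samples)))
    for i, g in enumerate(config.genes):
        mu = baseline_mean * np.power(
            2.0, [truth.group_means[g][lbl] for lbl in labels])
        p = size / (size + mu)
        values[i] = rng.negative_binomial(size, p)
    x = ExpressionMatrix(config.genes, samples, values, "read_count")
    return x, ann, truth


def planted_signature_config(planted: tuple[str, ...] = ("TPPP3", "FAT1", "NCALD"),
                             effect_size: float = 1.5, seed: int = 0,
                             **kwargs) -> SyntheticConfig:
    """Config with only ``planted`` genes informative (up in BPS), rest null."""
    directions = {g: {"BPS": 0, "DO": 0} for g in PANEL_GENES}
    for g in planted:
        if g not in directions:
            raise ValidationError(f"planted gene {g!r} not in the panel roster")
        directions[g] = {"BPS": +1, "DO": 0}
    return SyntheticConfig(directions=directions, effect_size=effect_size,
                           seed=seed, **kwargs)
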