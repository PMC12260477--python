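"""From model scores to per-species available-habitat rasters.

Distribution-model *fitting* is upstream of this package; what enters here
is either per-model suitability scores (to be thresholded and evaluated) or
already-binary presence maps.  The operations cover the post-modelling
pipeline: pick the presence/absence threshold that balances omission and
commission errors on the ROC curve, gate models on AUC and TSS, average the
survivors into an ensemble, and intersect predicted presence with the
land-cover classes a species' guild can occupy.

Classification convention: a cell is predicted present when its score is
``>= threshold`` (ties count as presences).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .raster import GridRaster

__all__ = [
    "SpeciesProfile",
    "EvaluationResult",
    "GUILD_CLASSES",
    "balanced_threshold",
    "auc",
    "tss",
    "confusion_counts",
    "evaluate_model",
    "ensemble",
    "mask_habitat",
]

#: Land-cover class codes used throughout: 1 = forest, 2 = savanna,
#: 3 = anthropic / other.  A guild admits the classes it can occupy.
FOREST, SAVANNA, ANTHROPIC = 1, 2, 3

GUILD_CLASSES: dict[str, frozenset[int]] = {
    "forest": frozenset({FOREST}),
    "savanna": frozenset({SAVANNA}),
    "both": frozenset({FOREST, SAVANNA}),
}


@dataclass(frozen=True)
class SpeciesProfile:
    name: str
    guild: str
    dispersal_distance_km: float = 1.0

    def __post_init__(self) -> None:
        if self.guild not in GUILD_CLASSES:
            raise ValueError(f"unknown guild {self.guild!r}; expected one of {sorted(GUILD_CLASSES)}")
        if not self.dispersal_distance_km > 0:
            raise ValueError("dispersal_distance_km must be positive")

    @property
    def admissible_classes(self) -> frozenset[int]:
        return GUILD_CLASSES[self.guild]


@dataclass(frozen=True)
class EvaluationResult:
    """Discrimination metrics of one model, gated at 0.7 on both AUC and TSS."""

    auc: float
    tss: float
    threshold: float

    @property
    def passed(self) -> bool:
        return self.auc >= 0.7 and self.tss >= 0.7


def _check_scores(presence_scores, background_scores) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(presence_scores, dtype=float)
    b = np.asarray(background_scores, dtype=float)
    if p.size == 0 or b.size == 0:
        raise ValueError("presence and background score lists must be non-empty")
    for arr, label in ((p, "presence"), (b, "background")):
        if np.any(~np.isfinite(arr)) or np.any((arr < 0) | (arr > 1)):
            raise ValueError(f"{label} scores must be finite and in [0, 1]")
    return p, b


def _sens_spec(p: np.ndarray, b: np.ndarray, t: float) -> tuple[float, float]:
    sens = float(np.mean(p >= t))
    spec = float(np.mean(b < t))
    return sens, spec


def balanced_threshold(
    presence_scores,
    background_scores,
    criterion: str = "balance",
) -> float:
    """ROC-based presence/absence threshold.

    Sensitivity and specificity are step functions of the threshold, so the
    optimum is attained at one of the observed score values; only those are
    scanned.  ``criterion="balance"`` (default) minimizes |sensitivity -
    specificity|; ``criterion="maxsum"`` maximizes sensitivity + specificity
    (the TSS-maximizing point).  Ties are broken toward the lower threshold.
    """
    p, b = _check_scores(presence_scores, background_scores)
    candidates = np.unique(np.concatenate([p, b]))
    best_t, best_key = None, None
    for t in candidates:  # ascending, so strict '<' keeps the lowest tie
        sens, spec = _sens_spec(p, b, t)
        key = abs(sens - spec) if criterion == "balance" else -(sens + spec)
        if best_key is None or key < best_key - 1e-12:
            best_t, best_key = float(t), key
    return best_t


def auc(presence_scores, background_scores) -> float:
    """Rank-based AUC: P(random presence score > random background score),
    ties counted one half.  Equivalent to the Mann-Whitney U statistic
    normalized by the number of pairs."""
    p, b = _check_scores(presence_scores, background_scores)
    greater = (p[:, None] > b[None, :]).sum()
    equal = (p[:, None] == b[None, :]).sum()
    return float((greater + 0.5 * equal) / (p.size * b.size))


def tss(tp: int, fp: int, fn: int, tn: int) -> float:
    """True skill statistic: sensitivity + specificity - 1, in [-1, 1]."""
    if min(tp, fp, fn, tn) < 0:
        raise ValueError("confusion counts must be non-negative")
    if tp + fn == 0 or tn + fp == 0:
        raise ValueError("both margins of the confusion matrix must be non-empty")
    return tp / (tp + fn) + tn / (tn + fp) - 1


def confusion_counts(presence_scores, background_scores, threshold: float) -> tuple[int, int, int, int]:
    """(tp, fp, fn, tn) under the score >= threshold presence rule."""
    p, b = _check_scores(presence_scores, background_scores)
    tp = int(np.sum(p >= threshold))
    fp = int(np.sum(b >= threshold))
    return tp, fp, p.size - tp, b.size - fp


def evaluate_model(presence_scores, background_scores, criterion: str = "balance") -> EvaluationResult:
    """Threshold a model's scores and compute its AUC and TSS in one pass."""
    t = balanced_threshold(presence_scores, background_scores, criterion=criterion)
    tp, fp, fn, tn = confusion_counts(presence_scores, background_scores, t)
    return EvaluationResult(
        auc=auc(presence_scores, background_scores),
        tss=tss(tp, fp, fn, tn),
        threshold=t,
    )


def ensemble(binary_maps: list[GridRaster], evals: list[EvaluationResult]) -> GridRaster:
    """Cell-wise arithmetic mean of the maps whose evaluation passed.

    Maps failing the AUC/TSS gate are excluded; zero passing maps is an
    error (never a silent fallback to all models).  Nodata cells propagate:
    a cell is nodata in the ensemble iff nodata in any passing map.
    """
    if len(binary_maps) != len(evals):
        raise ValueError("one evaluation per map is required")
    passing = [m for m, e in zip(binary_maps, evals) if e.passed]
    if not passing:
        raise ValueError("no model passed the AUC/TSS performance gate")
    ref = passing[0]
    for m in passing[1:]:
        ref.require_same_geometry(m)
    stack = np.stack([np.asarray(m.values, dtype=float) for m in passing])
    mean = stack.mean(axis=0)
    mask = None
    masks = [m.mask for m in passing if m.mask is not None]
    if masks:
        mask = np.any(np.stack(masks), axis=0)
        mean[mask] = 0.0
    return GridRaster(mean, ref.cell_size_km, ref.origin_km, mask, kind="continuous")


def mask_habitat(presence: GridRaster, landcover: GridRaster, profile: SpeciesProfile) -> GridRaster:
    """Available habitat: predicted presence intersected with the land-cover
    classes admissible for the species' guild.  Nodata in either input
    propagates to the output."""
    presence.require_same_geometry(landcover)
    admissible = np.isin(landcover.values, list(profile.admissible_classes))
    habitat = ((np.asarray(presence.values) == 1) & admissible).astype(int)
    mask = None
    masks = [m for m in (presence.mask, landcover.mask) if m is not None]
    if masks:
        mask = np.any(np.stack(masks), axis=0)
        habitat[mask] = 0
    return GridRaster(habitat, presence.cell_size_km, presence.origin_km, mask, kind="binary")
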