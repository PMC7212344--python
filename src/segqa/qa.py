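"""Mathematical core of the segmentation QA method.

Per-slice labels for contour quality assurance are derived from three
co-registered 2D fields: the CT slice, the segmentation probability map
``p(i, j)`` emitted by an upstream segmentation model, and the folded
uncertainty map ``u(i, j) = min(p, 1 - p)``.  Quality is quantified by the
Dice similarity coefficient (DSC) between the ground-truth mask A and the
thresholded prediction B, then either binned into three levels
(good / medium / bad) or discretized into 101 integer classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

__all__ = [
    "GOOD",
    "MEDIUM",
    "BAD",
    "QUALITY_NAMES",
    "SliceRecord",
    "uncertainty_map",
    "slice_dsc",
    "bin_quality",
    "discretize_dsc",
    "undiscretize_dsc",
    "threshold_probability",
    "assemble_channels",
]

GOOD, MEDIUM, BAD = 0, 1, 2
QUALITY_NAMES = {GOOD: "good", MEDIUM: "medium", BAD: "bad"}

#: canonical channel order for QA network inputs
CHANNEL_ORDER = ("ct", "prob", "unc")

# DSC bin edges: good = [0.95, 1], medium = [0.8, 0.95), bad = [0, 0.8)
GOOD_THRESHOLD = 0.95
MEDIUM_THRESHOLD = 0.80

#: probability threshold defining the predicted mask B
PRED_THRESHOLD = 0.5

EmptyRule = Literal["both_empty_one", "paper_literal"]


def _as_2d(a: np.ndarray, name: str) -> np.ndarray:
    a = np.asarray(a)
    if a.ndim != 2:
        raise ValueError(f"{name} must be 2D, got shape {a.shape}")
    return a


def _check_binary(mask: np.ndarray, name: str) -> np.ndarray:
    mask = _as_2d(mask, name)
    if mask.dtype == bool:
        return mask
    vals = np.unique(mask)
    if not np.isin(vals, (0, 1)).all():
        raise ValueError(f"{name} must be binary (0/1), found values {vals[:5]}")
    return mask.astype(bool)


def uncertainty_map(prob: np.ndarray) -> np.ndarray:
    """Fold a probability map into its per-pixel uncertainty.

    ``u = p`` where ``p <= 0.5``, ``u = 1 - p`` where ``0.5 < p < 1`` and
    ``u = 0`` where ``p = 1`` — identically ``u = min(p, 1 - p)``.  The
    maximum value 0.5 is attained exactly on the segmentation model's
    decision boundary, so large values flag pixels the model is unsure
    about.

    Parameters
    ----------
    prob
        2D array of per-pixel foreground probabilities in ``[0, 1]``.

    Returns
    -------
    2D float array with values in ``[0, 0.5]``, same shape as ``prob``.
    """
    p = np.asarray(prob, dtype=np.float64)
    if p.size and (p.min() < 0.0 or p.max() > 1.0):
        raise ValueError(
            f"probability map values must lie in [0, 1]; "
            f"got range [{p.min():.4g}, {p.max():.4g}]"
        )
    return np.minimum(p, 1.0 - p)


def slice_dsc(
    gt_mask: np.ndarray,
    pred_mask: np.ndarray,
    empty_rule: EmptyRule = "both_empty_one",
) -> float:
    """Dice similarity coefficient between two binary masks on one slice.

    ``DSC(A, B) = 2|A ∩ B| / (|A| + |B|)`` with A the ground truth and B
    the thresholded auto-segmentation.  Slices with no contour need a
    convention:

    - ``both_empty_one`` (default): DSC = 1 only when *both* masks are
      empty; when exactly one is empty the formula itself yields 0.
    - ``paper_literal``: DSC = 1 whenever *either* mask is empty.  This
      follows the looser clinical reading in which an absent contour is
      never penalized; it conflicts with treating a missed contour as a
      failure, hence it is not the default.
    """
    a = _check_binary(gt_mask, "gt_mask")
    b = _check_binary(pred_mask, "pred_mask")
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    if empty_rule not in ("both_empty_one", "paper_literal"):
        raise ValueError(f"unknown empty_rule: {empty_rule!r}")

    n_a = int(a.sum())
    n_b = int(b.sum())
    if empty_rule == "paper_literal" and (n_a == 0 or n_b == 0):
        return 1.0
    if n_a == 0 and n_b == 0:
        return 1.0
    inter = int(np.logical_and(a, b).sum())
    return 2.0 * inter / (n_a + n_b)


def bin_quality(dsc: float) -> int:
    """Map a DSC value to a quality level: 0 good, 1 medium, 2 bad.

    good = [0.95, 1], medium = [0.8, 0.95), bad = [0, 0.8).  Shared
    boundary values belong to the higher-quality bin.
    """
    if not 0.0 <= dsc <= 1.0:
        raise ValueError(f"dsc must lie in [0, 1], got {dsc}")
    if dsc >= GOOD_THRESHOLD:
        return GOOD
    if dsc >= MEDIUM_THRESHOLD:
        return MEDIUM
    return BAD


def discretize_dsc(dsc: float) -> int:
    """Discretize a DSC value onto the 101-class grid 0..100 (half-up)."""
    if not 0.0 <= dsc <= 1.0:
        raise ValueError(f"dsc must lie in [0, 1], got {dsc}")
    return min(int(np.floor(100.0 * dsc + 0.5)), 100)


def undiscretize_dsc(dsc_class: int) -> float:
    """Inverse of :func:`discretize_dsc` on the class grid: class / 100."""
    if not 0 <= int(dsc_class) <= 100:
        raise ValueError(f"dsc_class must lie in 0..100, got {dsc_class}")
    return int(dsc_class) / 100.0


def threshold_probability(prob: np.ndarray, threshold: float = PRED_THRESHOLD) -> np.ndarray:
    """Predicted mask B: per-pixel probability >= threshold (default 0.5)."""
    p = np.asarray(prob, dtype=np.float64)
    return (p >= threshold).astype(np.uint8)


@dataclass
class SliceRecord:
    """One training/evaluation unit: the channels and labels of one slice.

    ``dsc``, ``quality_level`` and ``dsc_class`` are computed at
    construction from ``gt_mask`` and the thresholded probability map and
    always satisfy ``quality_level == bin_quality(dsc)`` and
    ``dsc_class == discretize_dsc(dsc)``.
    """

    ct: np.ndarray
    prob: np.ndarray
    gt_mask: np.ndarray
    patient_id: str = ""
    slice_index: int = 0
    empty_rule: EmptyRule = "both_empty_one"
    unc: np.ndarray = field(init=False)
    pred_mask: np.ndarray = field(init=False)
    dsc: float = field(init=False)
    quality_level: int = field(init=False)
    dsc_class: int = field(init=False)

    def __post_init__(self) -> None:
        self.ct = _as_2d(self.ct, "ct")
        self.prob = _as_2d(self.prob, "prob")
        self.gt_mask = _check_binary(self.gt_mask, "gt_mask").astype(np.uint8)
        if not (self.ct.shape == self.prob.shape == self.gt_mask.shape):
            raise ValueError(
                f"channel shapes differ: ct {self.ct.shape}, "
                f"prob {self.prob.shape}, gt {self.gt_mask.shape}"
            )
        self.unc = uncertainty_map(self.prob)
        self.pred_mask = threshold_probability(self.prob)
        self.dsc = slice_dsc(self.gt_mask, self.pred_mask, self.empty_rule)
        self.quality_level = bin_quality(self.dsc)
        self.dsc_class = discretize_dsc(self.dsc)


def assemble_channels(
    record: SliceRecord | dict,
    channel_set: Iterable[str],
    downsampled: dict | None = None,
) -> np.ndarray:
    """Stack the requested channels into a (C, H, W) QA-network input.

    Channels are always stacked in the fixed order (ct, prob, unc)
    restricted to ``channel_set``, so the stack is independent of the
    order the caller names them in.  If ``downsampled`` is given it maps
    channel names to already-resized arrays and takes precedence over the
    record's full-resolution fields.
    """
    requested = set(channel_set)
    if not requested:
        raise ValueError("channel_set must be nonempty")
    unknown = requested - set(CHANNEL_ORDER)
    if unknown:
        raise ValueError(f"unknown channels: {sorted(unknown)}")

    def get(name: str) -> np.ndarray:
        if downsampled is not None and name in downsampled:
            return np.asarray(downsampled[name], dtype=np.float64)
        src = record[name] if isinstance(record, dict) else getattr(record, name)
        return np.asarray(src, dtype=np.float64)

    planes = [get(name) for name in CHANNEL_ORDER if name in requested]
    shapes = {p.shape for p in planes}
    if len(shapes) > 1:
        raise ValueError(f"channel shapes differ: {sorted(shapes)}")
    return np.stack(planes, axis=0)


def parse_channel_set(spec: str | Sequence[str]) -> tuple[str, ...]:
    """Normalize a channel specification like 'ct,prob' to canonical order."""
    if isinstance(spec, str):
        names = [s.strip() for s in spec.replace("+", ",").split(",") if s.strip()]
    else:
        names = list(spec)
    requested = set(names)
    unknown = requested - set(CHANNEL_ORDER)
    if unknown:
        raise ValueError(f"unknown channels: {sorted(unknown)}")
    if not requested:
        raise ValueError("empty channel set")
    return tuple(c for c in CHANNEL_ORDER if c in requested)
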