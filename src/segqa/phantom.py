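"""Synthetic CT phantoms with controllable auto-segmentation quality.

Stands in for a clinical cohort: each "patient" is a stack of 2D slices
holding a soft-tissue body ellipse, a lung-like void, and a breast-like
half-ellipse target whose size follows a smooth per-slice profile (the
target appears, grows, shrinks and disappears along the stack, so stack
ends carry empty ground truth).  A distance-transform perturbation engine
degrades the ground-truth contour into a segmentation probability map with
exactly controllable Dice similarity (DSC): the predicted contour is the
zero level-set of a shifted / dilated / deformed signed distance field,
and the probability map is a logistic profile of that field.  Because the
perturbation acts on a continuous distance field, a bisection search can
calibrate any one perturbation parameter to hit a requested DSC.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage
from scipy.special import expit

from . import qa

__all__ = [
    "PhantomParams",
    "PerturbationConfig",
    "SyntheticDataset",
    "CalibrationError",
    "make_phantom",
    "perturb_segmentation",
    "calibrate_to_dsc",
    "generate_dataset",
]

# -------------------------------------------------------------- phantom ----


@dataclass(frozen=True)
class PhantomParams:
    """Geometry and intensity model of one synthetic patient stack.

    Intensities are HU-like: air background, soft-tissue body, a brighter
    target and a lung-like void, plus Gaussian texture noise.  The
    ``slice_profile`` scales the target semi-axes per slice; entries equal
    to 0 give slices with empty ground truth (the stack ends).
    """

    image_size: int = 512
    body_center: tuple[float, float] = (256.0, 256.0)
    body_semiaxes: tuple[float, float] = (185.0, 150.0)
    target_center: tuple[float, float] = (210.0, 340.0)
    target_semiaxes: tuple[float, float] = (90.0, 55.0)
    void_center: tuple[float, float] = (250.0, 180.0)
    void_semiaxes: tuple[float, float] = (70.0, 55.0)
    intensity_levels: tuple[float, float, float, float] = (-1000.0, 30.0, 120.0, -750.0)
    texture_noise_sd: float = 20.0
    n_slices: int = 20
    slice_profile: tuple[float, ...] | None = None
    area_range: tuple[float, float] = (440.0, 12440.0)
    seed: int = 0

    def profile(self) -> np.ndarray:
        """Per-slice target scale: 0 at both stack ends, smooth in between."""
        if self.slice_profile is not None:
            prof = np.asarray(self.slice_profile, dtype=float)
            if len(prof) != self.n_slices:
                raise ValueError("slice_profile length must equal n_slices")
            return prof
        n = self.n_slices
        prof = np.zeros(n)
        if n > 2:
            # interior slices: sine arc rescaled into [0.35, 1] so every
            # nonempty contour stays inside the configured area range
            t = np.linspace(0.0, np.pi, n - 2 + 2)[1:-1]
            prof[1:-1] = 0.35 + 0.65 * np.sin(t)
        return prof


def _ellipse_mask(
    size: int, center: tuple[float, float], semiaxes: tuple[float, float],
    half: bool = False,
) -> np.ndarray:
    if min(semiaxes) <= 0:
        return np.zeros((size, size), dtype=bool)
    rr, cc = np.ogrid[:size, :size]
    cy, cx = center
    ry, rx = semiaxes
    inside = ((rr - cy) / ry) ** 2 + ((cc - cx) / rx) ** 2 <= 1.0
    if half:
        inside &= rr >= cy  # keep the lower half -> crescent-like target
    return inside


def make_phantom(params: PhantomParams, slice_index: int) -> tuple[np.ndarray, np.ndarray]:
    """Render one CT-like slice and its ground-truth target mask.

    Deterministic for fixed ``(params.seed, slice_index)``.  The target is
    a half-ellipse scaled by the slice profile; its mean CT intensity is
    distinct from the surrounding body so the CT channel carries signal.

    Returns ``(ct_slice, gt_mask)`` as float32 / uint8 arrays.
    """
    if not 0 <= slice_index < params.n_slices:
        raise IndexError(f"slice_index {slice_index} outside stack of {params.n_slices}")
    size = params.image_size
    scale = float(params.profile()[slice_index])
    bg, body_hu, target_hu, void_hu = params.intensity_levels

    body = _ellipse_mask(size, params.body_center, params.body_semiaxes)
    if not body.any() or body[0, :].any() or body[-1, :].any() or body[:, 0].any() or body[:, -1].any():
        raise ValueError("body ellipse must lie strictly inside the image")
    void = _ellipse_mask(size, params.void_center, params.void_semiaxes) & body

    tgt_axes = (params.target_semiaxes[0] * scale, params.target_semiaxes[1] * scale)
    target = _ellipse_mask(size, params.target_center, tgt_axes, half=True)
    if target.any():
        if not (target <= body).all():
            raise ValueError(
                "target region extends outside the body ellipse; "
                "shrink target_semiaxes or recenter the target"
            )
        area = int(target.sum())
        lo, hi = params.area_range
        if not lo <= area <= hi:
            raise ValueError(
                f"ground-truth contour area {area} px outside the allowed "
                f"range [{lo:g}, {hi:g}]; adjust target_semiaxes or slice_profile"
            )
        void &= ~target

    ct = np.full((size, size), bg, dtype=np.float64)
    ct[body] = body_hu
    ct[void] = void_hu
    ct[target] = target_hu
    rng = np.random.default_rng([params.seed, slice_index])
    ct += rng.normal(0.0, params.texture_noise_sd, ct.shape)
    return ct.astype(np.float32), target.astype(np.uint8)


# --------------------------------------------------------- perturbation ----


@dataclass(frozen=True)
class PerturbationConfig:
    """Degradation model applied to a ground-truth contour.

    The predicted contour is the zero level-set of the ground-truth signed
    distance field after a smooth boundary deformation (radial sinusoid of
    amplitude ``deform_amplitude`` px and ``deform_frequency`` cycles per
    contour), a global translation by ``shift`` px along
    ``shift_angle_deg``, and a signed ``dilation`` (positive = uniform
    over-segmentation).  ``boundary_softness_tau`` is the logistic width
    (px) converting signed distance to probability; as tau -> 0 the map
    approaches the binary mask.  ``dropout_prob`` empties the prediction;
    ``spurious_prob`` adds a high-probability false-positive blob disjoint
    from the target.
    """

    shift: float = 0.0
    shift_angle_deg: float = 0.0
    dilation: float = 0.0
    deform_amplitude: float = 0.0
    deform_frequency: float = 3.0
    boundary_softness_tau: float = 1.5
    dropout_prob: float = 0.0
    spurious_prob: float = 0.0
    spurious_radius: float = 14.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.boundary_softness_tau <= 0:
            raise ValueError("boundary_softness_tau must be > 0")
        for name in ("dropout_prob", "spurious_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


class CalibrationError(RuntimeError):
    """Requested DSC unreachable with the given free parameter."""


def _signed_distance(mask: np.ndarray) -> np.ndarray:
    """Signed Euclidean distance: negative inside, positive outside."""
    m = mask.astype(bool)
    return ndimage.distance_transform_edt(~m) - ndimage.distance_transform_edt(m)


def _perturbed_field(gt_mask: np.ndarray, config: PerturbationConfig,
                     base_sdist: np.ndarray | None = None) -> np.ndarray:
    """Signed distance field of the perturbed contour."""
    d = _signed_distance(gt_mask) if base_sdist is None else base_sdist
    if config.deform_amplitude != 0.0:
        rr, cc = np.indices(gt_mask.shape)
        ys, xs = np.nonzero(gt_mask)
        cy, cx = (float(ys.mean()), float(xs.mean())) if ys.size else (0.0, 0.0)
        phase = np.random.default_rng([config.seed, 7]).uniform(0.0, 2.0 * np.pi)
        theta = np.arctan2(rr - cy, cc - cx)
        d = d + config.deform_amplitude * np.sin(config.deform_frequency * theta + phase)
    if config.shift != 0.0:
        ang = np.deg2rad(config.shift_angle_deg)
        dy, dx = config.shift * np.sin(ang), config.shift * np.cos(ang)
        # sampling the field at x - s moves the predicted contour by +s
        d = ndimage.shift(d, (dy, dx), order=1, mode="nearest")
    return d - config.dilation


def _spurious_blob_prob(
    shape: tuple[int, int], avoid_sdist: np.ndarray, config: PerturbationConfig,
    rng: np.random.Generator,
) -> np.ndarray | None:
    """Probability map of a false-positive disk far from the target."""
    r = config.spurious_radius
    candidates = np.argwhere(avoid_sdist > 3.0 * r)
    if candidates.size == 0:
        return None
    cy, cx = candidates[rng.integers(len(candidates))]
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    dist = np.sqrt((rr - cy) ** 2 + (cc - cx) ** 2)
    return expit(-(dist - r) / config.boundary_softness_tau)


def perturb_segmentation(
    gt_mask: np.ndarray, config: PerturbationConfig,
    _base_sdist: np.ndarray | None = None,
) -> np.ndarray:
    """Emulate an auto-segmentation probability map for one slice.

    The map is ``sigmoid(-d / tau)`` with ``d`` the signed distance to the
    perturbed contour, so thresholding at 0.5 recovers exactly the
    perturbed binary mask.  With all perturbation magnitudes at 0 the
    thresholded map equals the ground truth for any tau.  Dropout and
    spurious-blob events are drawn from ``config.seed``.
    """
    gt = np.asarray(gt_mask)
    if gt.ndim != 2:
        raise ValueError(f"gt_mask must be 2D, got shape {gt.shape}")
    rng = np.random.default_rng([config.seed, 13])
    dropped = rng.random() < config.dropout_prob
    add_spurious = rng.random() < config.spurious_prob

    if dropped or not gt.any():
        prob = np.zeros(gt.shape, dtype=np.float64)
        base = None
    else:
        d = _perturbed_field(gt, config, base_sdist=_base_sdist)
        prob = expit(-d / config.boundary_softness_tau)
        base = d
    if add_spurious and not dropped:
        avoid = base if base is not None else np.full(gt.shape, np.inf)
        blob = _spurious_blob_prob(gt.shape, avoid, config, rng)
        if blob is not None:
            prob = np.maximum(prob, blob)
    return np.clip(prob, 0.0, 1.0)


_FREE_PARAMETERS = ("shift", "dilation", "deform_amplitude")


def _dsc_of_magnitude(
    gt: np.ndarray, base_sdist: np.ndarray, config: PerturbationConfig,
    free_parameter: str, magnitude: float, sign: float,
) -> float:
    cfg = replace(config, dropout_prob=0.0, spurious_prob=0.0,
                  **{free_parameter: sign * magnitude})
    d = _perturbed_field(gt, cfg, base_sdist=base_sdist)
    pred = (d <= 0.0).astype(np.uint8)
    return qa.slice_dsc(gt, pred)


def calibrate_to_dsc(
    gt_mask: np.ndarray,
    target_dsc: float,
    free_parameter: str,
    config: PerturbationConfig | None = None,
    tol: float = 0.02,
    max_iter: int = 60,
) -> PerturbationConfig:
    """Find a perturbation magnitude realizing a requested DSC.

    Bisects the magnitude of one free parameter (``shift``, ``dilation``
    or ``deform_amplitude``; DSC is monotone non-increasing in each
    magnitude over the search bracket) until the thresholded probability
    map achieves ``|DSC - target_dsc| <= tol``.  The other perturbation
    parameters of ``config`` are kept; dropout and spurious events are
    disabled during calibration (they are discrete events, not contour
    geometry).  Raises :class:`CalibrationError` when the bracket cannot
    reach the target — e.g. a small mask whose maximal shift cannot push
    the DSC low enough.
    """
    if not 0.0 <= target_dsc <= 1.0:
        raise ValueError(f"target_dsc must lie in [0, 1], got {target_dsc}")
    if free_parameter not in _FREE_PARAMETERS:
        raise ValueError(f"free_parameter must be one of {_FREE_PARAMETERS}")
    config = config or PerturbationConfig()
    gt = np.asarray(gt_mask).astype(bool)
    if not gt.any():
        raise CalibrationError("cannot calibrate on an empty ground-truth mask")

    base = _signed_distance(gt)
    current = getattr(config, free_parameter)
    sign = -1.0 if (free_parameter == "dilation" and current < 0) else 1.0

    def achieved(mag: float) -> float:
        return _dsc_of_magnitude(gt, base, config, free_parameter, mag, sign)

    if achieved(0.0) >= target_dsc - tol and target_dsc >= 1.0 - tol:
        return replace(config, **{free_parameter: 0.0})

    # expand the upper bracket until the DSC falls below the target
    hi, hi_dsc = 2.0, achieved(2.0)
    max_mag = float(max(gt.shape))
    while hi_dsc > target_dsc and hi < max_mag:
        hi *= 2.0
        hi_dsc = achieved(hi)
    if hi_dsc > target_dsc + tol:
        raise CalibrationError(
            f"target DSC {target_dsc:.3f} unreachable via {free_parameter}: "
            f"magnitude {hi:.1f} px still gives DSC {hi_dsc:.3f}"
        )

    lo = 0.0
    best_mag, best_err = hi, abs(hi_dsc - target_dsc)
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        dsc = achieved(mid)
        err = abs(dsc - target_dsc)
        if err < best_err:
            best_mag, best_err = mid, err
        if err <= tol * 0.5:
            break
        if dsc > target_dsc:
            lo = mid
        else:
            hi = mid
    if best_err > tol:
        raise CalibrationError(
            f"bisection did not converge: best |DSC - {target_dsc:.3f}| = {best_err:.3f}"
        )
    return replace(config, **{free_parameter: sign * best_mag})


# -------------------------------------------------------------- dataset ----


@dataclass
class SyntheticDataset:
    """A cohort of synthetic patients with per-slice quality labels.

    ``volumes[pid]`` maps channel name ('ct', 'gt', 'prob') to an
    (H, W, n_slices) array; ``split[pid]`` is 'train', 'val' or 'test'
    (splits are disjoint by patient, never by slice); ``manifest`` has one
    row per slice with the recomputed DSC, quality level, DSC class and
    split.  ``config`` echoes the generator parameters.
    """

    volumes: dict[str, dict[str, np.ndarray]]
    split: dict[str, str]
    manifest: pd.DataFrame
    config: dict

    @property
    def patients(self) -> list[str]:
        return list(self.volumes)

    def save(self, outdir: str | Path) -> None:
        """Write NIfTI volumes, the manifest CSV and a YAML config echo."""
        import nibabel as nib

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        affine = np.eye(4)
        for pid, chans in self.volumes.items():
            nib.save(nib.Nifti1Image(chans["ct"].astype(np.float32), affine),
                     outdir / f"{pid}_ct.nii.gz")
            nib.save(nib.Nifti1Image(chans["gt"].astype(np.uint8), affine),
                     outdir / f"{pid}_gt.nii.gz")
            nib.save(nib.Nifti1Image(chans["prob"].astype(np.float32), affine),
                     outdir / f"{pid}_prob.nii.gz")
        self.manifest.to_csv(outdir / "manifest.csv", index=False)
        with open(outdir / "generator_config.yaml", "w") as fh:
            yaml.safe_dump(self.config, fh, sort_keys=True)

    @classmethod
    def load(cls, outdir: str | Path) -> "SyntheticDataset":
        import nibabel as nib

        outdir = Path(outdir)
        manifest = pd.read_csv(outdir / "manifest.csv", dtype={"patient_id": str})
        with open(outdir / "generator_config.yaml") as fh:
            config = yaml.safe_load(fh)
        volumes: dict[str, dict[str, np.ndarray]] = {}
        split: dict[str, str] = {}
        for pid, grp in manifest.groupby("patient_id", sort=False):
            volumes[pid] = {
                "ct": np.asarray(nib.load(outdir / f"{pid}_ct.nii.gz").dataobj, dtype=np.float32),
                "gt": np.asarray(nib.load(outdir / f"{pid}_gt.nii.gz").dataobj, dtype=np.uint8),
                "prob": np.asarray(nib.load(outdir / f"{pid}_prob.nii.gz").dataobj, dtype=np.float32),
            }
            split[pid] = str(grp["split"].iloc[0])
        return cls(volumes=volumes, split=split, manifest=manifest, config=config)


def _largest_remainder(total: int, fractions: Sequence[float]) -> list[int]:
    fr = np.asarray(fractions, dtype=float)
    raw = fr * total
    counts = np.floor(raw).astype(int)
    rem = total - counts.sum()
    order = np.argsort(-(raw - counts))
    for k in range(rem):
        counts[order[k % len(counts)]] += 1
    return counts.tolist()


def _sample_target_dsc(level: int, rng: np.random.Generator) -> float:
    # keep targets >= 0.025 away from the 0.8 / 0.95 bin edges so the
    # 0.02 calibration tolerance cannot flip the realized quality level
    if level == qa.GOOD:
        return float(rng.uniform(0.975, 1.0))
    if level == qa.MEDIUM:
        return float(rng.uniform(0.825, 0.925))
    return float(rng.uniform(0.40, 0.775))


#: fraction of "bad"-assigned nonempty slices realized as total dropout
DROPOUT_SHARE_OF_BAD = 0.10


def generate_dataset(
    n_patients: int,
    slices_per_patient: int,
    quality_mix: Sequence[float] = (1 / 3, 1 / 3, 1 / 3),
    split_fractions: Sequence[float] = (65 / 85, 10 / 85, 10 / 85),
    seed: int = 0,
    image_size: int = 512,
    tau: float = 1.5,
    progress: Callable[[str], None] | None = None,
) -> SyntheticDataset:
    """Generate a seeded synthetic cohort with a controlled quality mix.

    Slice quality quotas are computed from ``quality_mix`` by largest
    remainder and filled explicitly, so the realized good/medium/bad
    proportions track the request to within calibration tolerance (well
    inside +/-5 points at n >= 500 slices).  Stack-end slices have empty
    ground truth: with an empty prediction they score DSC 1 ("good", the
    both-empty rule); a fraction of them absorb the "bad" quota through
    spurious false-positive blobs (DSC 0).  Within the "bad" quota a
    10% share is realized as prediction dropout (all-zero map).  Fully
    reproducible from ``seed``.
    """
    if n_patients < 1 or slices_per_patient < 1:
        raise ValueError("counts must be >= 1")
    mix = np.asarray(quality_mix, dtype=float)
    if mix.shape != (3,) or not np.isclose(mix.sum(), 1.0) or (mix < 0).any():
        raise ValueError(f"quality_mix must be 3 non-negative proportions summing to 1, got {quality_mix}")
    fr = np.asarray(split_fractions, dtype=float)
    if fr.shape != (3,) or not np.isclose(fr.sum(), 1.0) or (fr < 0).any():
        raise ValueError(f"split_fractions must be 3 proportions summing to 1, got {split_fractions}")

    rng = np.random.default_rng([seed, 1])
    scale = image_size / 512.0
    total = n_patients * slices_per_patient
    quotas = _largest_remainder(total, mix)

    # patient splits (disjoint by patient)
    split_counts = _largest_remainder(n_patients, fr)
    split_names = (["train"] * split_counts[0] + ["val"] * split_counts[1]
                   + ["test"] * split_counts[2])
    perm = rng.permutation(n_patients)
    pids = [f"p{k:03d}" for k in range(n_patients)]
    split = {pids[perm[k]]: split_names[k] for k in range(n_patients)}

    # per-patient phantom geometry with mild jitter
    phantoms: dict[str, PhantomParams] = {}
    for k, pid in enumerate(pids):
        jit = np.random.default_rng([seed, 2, k])
        sa = (90.0 * jit.uniform(0.85, 1.05) * scale, 55.0 * jit.uniform(0.85, 1.05) * scale)
        phantoms[pid] = PhantomParams(
            image_size=image_size,
            body_center=(256 * scale, 256 * scale),
            body_semiaxes=(185 * scale, 150 * scale),
            target_center=(210 * scale + jit.uniform(-8, 8) * scale,
                           330 * scale + jit.uniform(-8, 8) * scale),
            target_semiaxes=sa,
            void_center=(250 * scale, 180 * scale),
            void_semiaxes=(70 * scale, 55 * scale),
            n_slices=slices_per_patient,
            area_range=(440.0 * scale ** 2, 12440.0 * scale ** 2),
            seed=int(jit.integers(2**31)),
        )

    # enumerate slices; stack ends (profile == 0) have empty ground truth
    all_slices = [(pid, s) for pid in pids for s in range(slices_per_patient)]
    empty = [(pid, s) for pid, s in all_slices
             if phantoms[pid].profile()[s] == 0.0]
    nonempty = [t for t in all_slices if t not in set(empty)]

    # fill quotas: empty slices consume the good quota first (both-empty
    # DSC 1); overflow empties become bad via spurious blobs; nonempty
    # slices then fill what remains of each class
    assignment: dict[tuple[str, int], int] = {}
    remaining = list(quotas)
    for t in empty:
        lvl = qa.GOOD if remaining[qa.GOOD] > 0 else qa.BAD
        assignment[t] = lvl
        remaining[lvl] = max(remaining[lvl] - 1, 0)
    order = rng.permutation(len(nonempty))
    fill = [lvl for lvl in (qa.GOOD, qa.MEDIUM, qa.BAD) for _ in range(remaining[lvl])]
    while len(fill) < len(nonempty):  # guard against rounding shortfall
        fill.append(qa.MEDIUM)
    for idx, t_idx in enumerate(order):
        assignment[nonempty[t_idx]] = fill[idx]

    volumes: dict[str, dict[str, np.ndarray]] = {}
    rows = []
    for k, pid in enumerate(pids):
        params = phantoms[pid]
        n = slices_per_patient
        ct_vol = np.zeros((image_size, image_size, n), dtype=np.float32)
        gt_vol = np.zeros((image_size, image_size, n), dtype=np.uint8)
        pr_vol = np.zeros((image_size, image_size, n), dtype=np.float32)
        for s in range(n):
            slice_rng = np.random.default_rng([seed, 3, k, s])
            ct, gt = make_phantom(params, s)
            lvl = assignment[(pid, s)]
            cfg_seed = int(slice_rng.integers(2**31))
            if not gt.any():
                if lvl == qa.BAD:
                    cfg = PerturbationConfig(boundary_softness_tau=tau,
                                             spurious_prob=1.0, seed=cfg_seed,
                                             spurious_radius=14.0 * scale)
                    prob = perturb_segmentation(gt, cfg)
                else:
                    prob = np.zeros_like(ct, dtype=np.float64)
            elif lvl == qa.BAD and slice_rng.random() < DROPOUT_SHARE_OF_BAD:
                cfg = PerturbationConfig(boundary_softness_tau=tau,
                                         dropout_prob=1.0, seed=cfg_seed)
                prob = perturb_segmentation(gt, cfg)
            else:
                target = _sample_target_dsc(lvl, slice_rng)
                free = _FREE_PARAMETERS[slice_rng.integers(3)]
                base_cfg = PerturbationConfig(
                    boundary_softness_tau=tau, seed=cfg_seed,
                    shift_angle_deg=float(slice_rng.uniform(0, 360)),
                    deform_frequency=float(slice_rng.integers(2, 6)),
                )
                # shift and deform act through a continuous field, so one
                # of them can always realize targets that are too coarse
                # for integer-step dilation on small masks
                cfg = None
                for attempt in (free, "shift", "deform_amplitude", "dilation"):
                    try:
                        cfg = calibrate_to_dsc(gt, target, attempt, base_cfg)
                        break
                    except CalibrationError:
                        continue
                if cfg is None:
                    raise CalibrationError(
                        f"slice {pid}/{s}: no free parameter reaches DSC {target:.3f}"
                    )
                prob = perturb_segmentation(gt, cfg)
            ct_vol[:, :, s] = ct
            gt_vol[:, :, s] = gt
            pr_vol[:, :, s] = prob.astype(np.float32)
            dsc = qa.slice_dsc(gt_vol[:, :, s], qa.threshold_probability(pr_vol[:, :, s]))
            rows.append({
                "patient_id": pid, "slice_index": s, "dsc": dsc,
                "quality_level": qa.bin_quality(dsc),
                "dsc_class": qa.discretize_dsc(dsc), "split": split[pid],
            })
        volumes[pid] = {"ct": ct_vol, "gt": gt_vol, "prob": pr_vol}
        if progress is not None:
            progress(f"generated {pid} ({k + 1}/{n_patients})")

    manifest = pd.DataFrame(rows)
    config = {
        "n_patients": n_patients, "slices_per_patient": slices_per_patient,
        "quality_mix": [float(x) for x in mix],
        "split_fractions": [float(x) for x in fr],
        "seed": int(seed), "image_size": int(image_size), "tau": float(tau),
    }
    return SyntheticDataset(volumes=volumes, split=split, manifest=manifest, config=config)
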