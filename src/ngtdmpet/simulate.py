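"""Synthetic dual-time-point PET lesion phantoms.

No patient data accompany the analysis, so cohorts are emulated by
Gaussian-blob phantoms that encode the contrast mechanism the analysis
assumes:

* **malignant** lesions are a single compact focus whose uptake rises
  from the early (~1 h) to the delayed (~3 h) scan (tracer retention)
  and whose delayed appearance is slightly smoother (tumor tissue
  appears coarser late);
* **benign** (inflammatory) lesions are several spatially separated
  small foci inside one nodule envelope, with stable-to-falling delayed
  uptake and a sharper delayed appearance (background and inter-focus
  tissue wash out faster than the foci, so the alternation pattern
  becomes finer) — yielding higher busyness and lower coarseness, more
  so on delayed images.

Early-scan peak SUVs are drawn from truncated normals matching the
malignant 11.22 +/- 6.24 vs benign 6.94 +/- 3.58 g/ml contrast of
FDG-avid solitary pulmonary nodules, so SUVmax alone is a deliberately
imperfect discriminator.  Every generated lesion passes the cohort
inclusion filters (>= 64 mask voxels, early SUVmax >= 2.5) by
construction.  All randomness flows from one seed through per-lesion
spawned streams, so cohorts are reproducible lesion by lesion.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, fields, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage

from .texture import LesionMask, PetVolume

__all__ = [
    "PhantomConfig",
    "LesionSample",
    "SyntheticCohort",
    "default_config",
    "phantom_config_to_json",
    "phantom_config_from_json",
    "generate_lesion",
    "generate_cohort",
    "simulate_reader_scores",
    "fragmentation_phantom",
]


@dataclass(frozen=True)
class PhantomConfig:
    """Generator settings for one lesion phantom.

    Units: spacing in mm (4.25 isotropic mirrors a 128x128 PET matrix),
    SUV in g/ml, focus widths (Gaussian sigma) and radii in voxels.  The
    point-spread sigma 0.8 voxels ~ 3.4 mm approximates an 8-mm-FWHM
    reconstruction filter.  Noise is Gaussian with sd proportional to
    the square root of local activity (Poisson-like counting noise);
    delayed noise is 1.3x early noise (tracer decay).
    """

    kind: str = "malignant"
    grid_shape: tuple[int, int, int] = (32, 32, 32)
    spacing: tuple[float, float, float] = (4.25, 4.25, 4.25)
    n_foci_range: tuple[int, int] = (1, 1)
    focus_sigma_range: tuple[float, float] = (1.6, 2.6)
    envelope_radius_range: tuple[float, float] = (0.0, 0.0)
    peak_suv_mean: float = 11.22
    peak_suv_sd: float = 6.24
    peak_suv_bounds: tuple[float, float] = (3.0, 22.0)
    delayed_uptake_range: tuple[float, float] = (1.10, 1.40)
    focus_shape_power: float = 2.0
    focus_amp_range: tuple[float, float] = (1.0, 1.0)
    delayed_focus_jitter: float = 0.0
    early_texture_sd: float = 0.08
    delayed_texture_sd: float = 0.0
    background_suv: float = 0.4
    background_texture_sd: float = 0.4
    background_texture_scale: float = 1.2
    background_washout: float = 0.8
    psf_sigma: float = 0.8
    delayed_psf_factor: float = 1.0
    noise_sd: float = 0.12
    delayed_noise_factor: float = 1.15
    mask_fraction: float = 0.12
    min_mask_voxels: int = 64
    min_suvmax: float = 2.5

    def __post_init__(self) -> None:
        if self.kind not in ("malignant", "benign"):
            raise ValueError("kind must be 'malignant' or 'benign'")
        if self.kind == "benign" and self.n_foci_range[0] < 2:
            raise ValueError("benign phantoms need >= 2 foci (spatial separation)")
        for rng_ in (
            self.focus_sigma_range,
            self.delayed_uptake_range,
            self.focus_amp_range,
        ):
            if rng_[0] <= 0 or rng_[1] < rng_[0]:
                raise ValueError(f"invalid range {rng_}")
        if not 0 < self.mask_fraction < 1:
            raise ValueError("mask_fraction must be in (0, 1)")


def default_config(kind: str) -> PhantomConfig:
    """Per-class defaults encoding compact-retention vs separated-washout."""
    if kind == "malignant":
        return PhantomConfig(kind="malignant")
    if kind == "benign":
        return PhantomConfig(
            kind="benign",
            n_foci_range=(4, 8),
            focus_sigma_range=(0.55, 0.85),
            envelope_radius_range=(4.5, 6.5),
            peak_suv_mean=6.94,
            peak_suv_sd=3.58,
            peak_suv_bounds=(3.0, 14.0),
            delayed_uptake_range=(0.85, 1.05),
            focus_amp_range=(0.5, 1.0),
            delayed_focus_jitter=0.35,
            psf_sigma=1.1,
            delayed_psf_factor=0.70,
            delayed_noise_factor=1.9,
            delayed_texture_sd=0.15,
            background_washout=1.0,
        )
    raise ValueError("kind must be 'malignant' or 'benign'")


def phantom_config_to_json(config: PhantomConfig, path: str | Path) -> None:
    Path(path).write_text(json.dumps(asdict(config), indent=2, sort_keys=True) + "\n")


def phantom_config_from_json(path: str | Path) -> PhantomConfig:
    """Load a PhantomConfig from a JSON file (unknown keys rejected)."""
    payload = json.loads(Path(path).read_text())
    known = {f.name for f in fields(PhantomConfig)}
    unknown = set(payload) - known
    if unknown:
        raise ValueError(f"unknown PhantomConfig keys: {sorted(unknown)}")
    coerced = {
        k: tuple(v) if isinstance(v, list) else v for k, v in payload.items()
    }
    return PhantomConfig(**coerced)


@dataclass(frozen=True)
class LesionSample:
    """One lesion: early+delayed volumes, a shared mask, the truth label
    and the generator parameters that produced it."""

    lesion_id: str
    label: str
    early: PetVolume
    delayed: PetVolume
    mask: LesionMask
    params: dict


@dataclass(frozen=True)
class SyntheticCohort:
    samples: list[LesionSample]

    @property
    def n_benign(self) -> int:
        return sum(1 for s in self.samples if s.label == "benign")

    @property
    def n_malignant(self) -> int:
        return sum(1 for s in self.samples if s.label == "malignant")


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, bounds: tuple[float, float]
) -> float:
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if bounds[0] <= x <= bounds[1]:
            return float(x)
    return float(np.clip(mean, *bounds))


def _place_foci(
    rng: np.random.Generator,
    n_foci: int,
    envelope_radius: float,
    min_separation: float,
) -> np.ndarray:
    """Focus centers inside a sphere, pairwise separated; the separation
    requirement is relaxed geometrically if packing fails."""
    if n_foci == 1:
        return np.zeros((1, 3))
    sep = min_separation
    for attempt in range(60):
        centers: list[np.ndarray] = []
        for _ in range(500):
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            r = envelope_radius * rng.uniform() ** (1 / 3)
            c = r * u
            if all(np.linalg.norm(c - o) >= sep for o in centers):
                centers.append(c)
                if len(centers) == n_foci:
                    return np.asarray(centers)
        sep *= 0.9
    raise RuntimeError("could not place separated foci")  # pragma: no cover


def _activity(
    grid_shape: tuple[int, int, int],
    center: np.ndarray,
    foci: np.ndarray,
    sigmas: np.ndarray,
    amps: np.ndarray,
    shape_power: float = 2.0,
) -> np.ndarray:
    """Sum of radial foci.  ``shape_power`` 2 is a Gaussian peak; higher
    powers flatten the core (compact uniform uptake) while keeping a
    compact support scale of ~2 sigma."""
    zz, yy, xx = np.meshgrid(*(np.arange(s) for s in grid_shape), indexing="ij")
    out = np.zeros(grid_shape)
    for (dz, dy, dx), sig, amp in zip(foci, sigmas, amps):
        d2 = (
            (zz - (center[0] + dz)) ** 2
            + (yy - (center[1] + dy)) ** 2
            + (xx - (center[2] + dx)) ** 2
        )
        out += amp * np.exp(-((d2 / (2.0 * sig**2)) ** (shape_power / 2.0)))
    return out


def _mask_from_activity(
    smoothed: np.ndarray, fraction: float
) -> np.ndarray:
    """Envelope mask: low-fraction isocontour of the noise-free early
    activity (a generous envelope, as manual nodule segmentation is),
    closed to bridge inter-focus valleys, largest component, holes
    filled."""
    raw = smoothed >= fraction * smoothed.max()
    struct = ndimage.generate_binary_structure(3, 2)
    closed = ndimage.binary_closing(raw, structure=struct, iterations=2)
    filled = ndimage.binary_fill_holes(closed)
    labels, n = ndimage.label(filled)
    if n == 0:  # pragma: no cover
        return filled
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
    return labels == (1 + int(np.argmax(sizes)))


def generate_lesion(
    config: PhantomConfig,
    seed: int | np.random.SeedSequence | np.random.Generator,
    lesion_id: str = "lesion",
) -> LesionSample:
    """One dual-time-point phantom; identical seeds give bit-identical
    volumes.  Configurations yielding a mask below the inclusion floor
    are retried with enlarged foci, erroring after bounded retries."""
    if isinstance(seed, np.random.Generator):
        rng = seed
    else:
        rng = np.random.default_rng(seed)

    cfg = config
    for attempt in range(6):
        sample = _generate_once(cfg, rng, lesion_id)
        if sample is not None:
            return sample
        cfg = replace(
            cfg,
            focus_sigma_range=tuple(1.25 * s for s in cfg.focus_sigma_range),
        )
    raise RuntimeError(f"{lesion_id}: mask below {config.min_mask_voxels} voxels after retries")


def _generate_once(
    cfg: PhantomConfig, rng: np.random.Generator, lesion_id: str
) -> LesionSample | None:
    shape = cfg.grid_shape
    center = np.asarray(shape) / 2.0 - 0.5 + rng.uniform(-1.5, 1.5, size=3)

    n_foci = int(rng.integers(cfg.n_foci_range[0], cfg.n_foci_range[1] + 1))
    sigmas = rng.uniform(*cfg.focus_sigma_range, size=n_foci)
    sigma_eff = float(np.sqrt(np.max(sigmas) ** 2 + cfg.psf_sigma**2))
    envelope = rng.uniform(*cfg.envelope_radius_range) if n_foci > 1 else 0.0
    foci = _place_foci(rng, n_foci, envelope, min_separation=3.6 * sigma_eff)
    amps = rng.uniform(*cfg.focus_amp_range, size=n_foci)

    peak = _truncated_normal(rng, cfg.peak_suv_mean, cfg.peak_suv_sd, cfg.peak_suv_bounds)
    uptake = rng.uniform(*cfg.delayed_uptake_range)
    focus_mult = uptake * (
        1.0 + cfg.delayed_focus_jitter * rng.uniform(-1.0, 1.0, size=n_foci)
    )

    # lung parenchyma is not uniform: a smooth, spatially correlated
    # low-amplitude field keeps surrounding tissue from quantizing to a
    # single flat gray tone
    bg_field = ndimage.gaussian_filter(
        rng.normal(size=shape), cfg.background_texture_scale
    )
    bg_field *= cfg.background_texture_sd / max(bg_field.std(), 1e-12)

    act_early = _activity(shape, center, foci, sigmas, amps, cfg.focus_shape_power)
    smooth_early = ndimage.gaussian_filter(act_early, cfg.psf_sigma)
    scale = (peak - cfg.background_suv) / smooth_early.max()
    clean_early = cfg.background_suv + bg_field + scale * smooth_early
    if cfg.early_texture_sd > 0:
        # the early scan is perfusion-dominated: a mild intensity-
        # proportional mottle (blood-pool heterogeneity) that has
        # cleared by the delayed acquisition
        mottle = ndimage.gaussian_filter(rng.normal(size=shape), 0.7)
        mottle /= max(mottle.std(), 1e-12)
        clean_early = clean_early * (1.0 + cfg.early_texture_sd * mottle)
        np.clip(clean_early, 0.0, None, out=clean_early)

    act_delayed = _activity(
        shape, center, foci, sigmas, amps * focus_mult, cfg.focus_shape_power
    )
    smooth_delayed = ndimage.gaussian_filter(
        act_delayed, cfg.psf_sigma * cfg.delayed_psf_factor
    )
    # normalize the delayed focal amplitude so SUVmax follows the drawn
    # retention/washout multiplier; the delayed PSF then changes only
    # the apparent texture, not the uptake trajectory
    bg_delayed_level = cfg.background_suv * cfg.background_washout
    scale_delayed = (peak * uptake - bg_delayed_level) / smooth_delayed.max()
    clean_delayed = (
        (cfg.background_suv + bg_field) * cfg.background_washout
        + scale_delayed * smooth_delayed
    )
    if cfg.delayed_texture_sd > 0:
        # intensity-proportional fine-grain heterogeneity that emerges on
        # delayed images (e.g. inflammatory tissue after background
        # washout); spatially correlated at ~1 voxel
        fine = ndimage.gaussian_filter(rng.normal(size=shape), 0.7)
        fine /= max(fine.std(), 1e-12)
        clean_delayed = clean_delayed * (1.0 + cfg.delayed_texture_sd * fine)
        np.clip(clean_delayed, 0.0, None, out=clean_delayed)

    member = _mask_from_activity(smooth_early, cfg.mask_fraction)
    if member.sum() < cfg.min_mask_voxels:
        return None

    # Poisson-like statistics: the noise sd scales with the square root
    # of local activity; noise_sd is the coefficient at SUV = 1
    img_early = clean_early + rng.normal(size=shape) * cfg.noise_sd * np.sqrt(
        np.maximum(clean_early, 0.2)
    )
    img_delayed = clean_delayed + rng.normal(size=shape) * (
        cfg.noise_sd * cfg.delayed_noise_factor
    ) * np.sqrt(np.maximum(clean_delayed, 0.2))
    np.clip(img_early, 0.0, None, out=img_early)
    np.clip(img_delayed, 0.0, None, out=img_delayed)
    if img_early[member].max() < cfg.min_suvmax:  # pragma: no cover
        return None

    params = {
        "kind": cfg.kind,
        "n_foci": n_foci,
        "peak_suv_early": peak,
        "delayed_uptake": float(uptake),
        "focus_sigmas": [float(s) for s in sigmas],
        "envelope_radius": float(envelope),
    }
    return LesionSample(
        lesion_id=lesion_id,
        label=cfg.kind,
        early=PetVolume(img_early.astype(np.float32), cfg.spacing, "early"),
        delayed=PetVolume(img_delayed.astype(np.float32), cfg.spacing, "delayed"),
        mask=LesionMask(member),
        params=params,
    )


def generate_cohort(
    n_benign: int = 35,
    n_malignant: int = 81,
    seed: int = 0,
    benign_config: PhantomConfig | None = None,
    malignant_config: PhantomConfig | None = None,
) -> SyntheticCohort:
    """A full dual-time-point cohort (default 35 benign / 81 malignant).

    Each lesion draws from its own spawned random stream, so individual
    lesions are reproducible independently of cohort size or order.
    """
    if n_benign < 1 or n_malignant < 1:
        raise ValueError("need at least one lesion per class")
    benign_config = benign_config or default_config("benign")
    malignant_config = malignant_config or default_config("malignant")
    root = np.random.SeedSequence(seed)
    streams = root.spawn(n_benign + n_malignant)
    samples: list[LesionSample] = []
    for i in range(n_benign):
        samples.append(
            generate_lesion(benign_config, streams[i], lesion_id=f"B{i + 1:03d}")
        )
    for j in range(n_malignant):
        samples.append(
            generate_lesion(
                malignant_config, streams[n_benign + j], lesion_id=f"M{j + 1:03d}"
            )
        )
    return SyntheticCohort(samples=samples)


def simulate_reader_scores(
    feature_values: Sequence[float],
    noise_sd: float,
    seed: int | np.random.Generator = 0,
    n_levels: int = 5,
) -> np.ndarray:
    """Ordinal reader scores correlated with a lesion feature.

    The latent score is the standardized feature plus Gaussian noise,
    discretized by fixed equal-mass quantile cuts into 1..n_levels.
    Standardization is rank-normal (van der Waerden): a reader's
    impression tracks a lesion's standing relative to the cohort, not
    the raw magnitude of a heavy-tailed texture value.  Lower
    ``noise_sd`` models readers who consult the texture values (higher
    correlation with the driving feature).
    """
    from scipy import stats as _sps

    values = np.asarray(feature_values, dtype=float)
    if values.ndim != 1 or values.size < n_levels:
        raise ValueError(f"need a 1-D sample of at least {n_levels} lesions")
    if values.std() == 0:
        raise ValueError("feature has zero variance; scores undefined")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    normal_scores = _sps.norm.ppf(
        (_sps.rankdata(values) - 0.5) / values.size
    )
    latent = normal_scores + rng.normal(0.0, noise_sd, size=values.size)
    cuts = np.quantile(latent, np.linspace(0, 1, n_levels + 1)[1:-1])
    return (np.searchsorted(cuts, latent, side="right") + 1).astype(int)


# ---------------------------------------------------------------------------
# Deterministic fragmentation sweep

_FRAG_DIRECTIONS = {
    1: np.zeros((1, 3)),
    2: np.array([[1.0, 0, 0], [-1.0, 0, 0]]),
    4: np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]]) / np.sqrt(3),
    8: np.array(
        [[sz, sy, sx] for sz in (-1, 1) for sy in (-1, 1) for sx in (-1, 1)]
    )
    / np.sqrt(3),
}


def fragmentation_phantom(
    n_foci: int,
    grid_shape: tuple[int, int, int] = (32, 32, 32),
    sigma: float = 1.2,
    spread: float = 4.5,
    total_peak: float = 8.0,
    background_suv: float = 0.4,
    psf_sigma: float = 0.8,
    mask_radius: float | None = None,
) -> tuple[PetVolume, LesionMask]:
    """Noise-free phantom splitting one blob into 1/2/4/8 equal-activity
    foci at fixed total activity and total volume, inside a FIXED
    spherical mask.  Each fragment keeps the parent's peak amplitude
    while its width shrinks as k^(-1/3), so fragmentation changes only
    the spatial arrangement, not the activity budget."""
    if n_foci not in _FRAG_DIRECTIONS:
        raise ValueError("n_foci must be one of 1, 2, 4, 8")
    center = np.asarray(grid_shape) / 2.0 - 0.5
    foci = _FRAG_DIRECTIONS[n_foci] * spread
    sigma_k = sigma * n_foci ** (-1.0 / 3.0)
    amps = np.ones(n_foci)
    act = _activity(grid_shape, center, foci, np.full(n_foci, sigma_k), amps)
    smooth = ndimage.gaussian_filter(act, psf_sigma)
    img = background_suv + total_peak * smooth

    if mask_radius is None:
        mask_radius = spread + 3.0 * sigma
    zz, yy, xx = np.meshgrid(*(np.arange(s) for s in grid_shape), indexing="ij")
    member = (
        (zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2
    ) <= mask_radius**2
    return (
        PetVolume(img.astype(np.float32), (4.25, 4.25, 4.25), "early"),
        LesionMask(member),
    )
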