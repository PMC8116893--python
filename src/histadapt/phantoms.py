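"""Synthetic domain-shifted 3D phantoms with known labels and priors.

The phantom generator stands in for skull-stripped, atlas-registered brain
MRI: ellipsoidal "structures" (or sparse "lesions" inside a synthetic
white-matter shell) on a textured tissue background, plus a parametric
acquisition shift (gamma, linear contrast/brightness, smooth multiplicative
bias field, additive noise) that produces an unlabelled target domain from
the same anatomy family.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import numpy as np
from scipy.ndimage import gaussian_filter

from .volumes import LabelMap, PriorAtlas, Volume

__all__ = [
    "PhantomObject",
    "PhantomScene",
    "DomainShift",
    "DomainCase",
    "render_phantom",
    "apply_domain_shift",
    "make_domain_pair",
    "default_structure_scene",
    "default_lesion_scene",
]


@dataclass(frozen=True)
class PhantomObject:
    """One ellipsoid: class index, centre (voxels), radii (voxels), intensity."""

    class_index: int
    center: tuple[float, float, float]
    radii: tuple[float, float, float]
    intensity: float


@dataclass(frozen=True)
class PhantomScene:
    """Geometry + intensity model from which one phantom case is rendered.

    ``mode`` is ``"structures"`` (multi-class ellipsoids, anywhere in the
    "brain") or ``"lesions"`` (all objects are class 1 and must sit inside a
    synthetic white-matter shell whose blurred indicator is exported as the
    WM prior channel).
    """

    shape: tuple[int, int, int] = (28, 28, 28)
    mode: str = "structures"
    objects: tuple[PhantomObject, ...] = ()
    tissue_background: tuple[float, float] = (0.35, 0.03)  # (mean, texture sd)
    noise_sd: float = 0.02
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    prior_blur_sd: float = 0.75
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("structures", "lesions"):
            raise ValueError(f"unknown phantom mode {self.mode!r}")
        for obj in self.objects:
            for c, r, n in zip(obj.center, obj.radii, self.shape):
                if c - r < 0 or c + r > n - 1:
                    raise ValueError(f"object at {obj.center} r={obj.radii} exceeds bounds {self.shape}")
            if self.mode == "lesions" and obj.class_index != 1:
                raise ValueError("lesion phantoms use class 1 for every object")

    @property
    def class_count(self) -> int:
        if self.mode == "lesions":
            return 2
        return max((o.class_index for o in self.objects), default=0) + 1


@dataclass(frozen=True)
class DomainShift:
    """Parametric acquisition shift applied to a rendered volume.

    The identity is ``gamma=1, gain=1, offset=0, bias_field_amplitude=0,
    extra_noise_sd=0``.  Gamma acts on intensities rescaled to [0, 1];
    the bias field is a smooth multiplicative map in ``[1-A, 1+A]`` with
    correlation length ``bias_field_smoothness`` (mm).
    """

    gamma: float = 1.0
    gain: float = 1.0
    offset: float = 0.0
    bias_field_amplitude: float = 0.0
    bias_field_smoothness: float = 8.0
    extra_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.gain <= 0:
            raise ValueError("gain must be positive")
        if self.bias_field_amplitude < 0 or self.extra_noise_sd < 0:
            raise ValueError("bias amplitude and noise sd must be non-negative")
        if self.bias_field_smoothness <= 0:
            raise ValueError("bias field smoothness must be positive")

    @property
    def is_identity(self) -> bool:
        return (
            self.gamma == 1.0
            and self.gain == 1.0
            and self.offset == 0.0
            and self.bias_field_amplitude == 0.0
            and self.extra_noise_sd == 0.0
        )


def _ellipsoid_mask(shape, center, radii) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, n) for n in shape)]
    acc = np.zeros(shape, dtype=np.float64)
    for g, c, r in zip(grids, center, radii):
        acc = acc + ((g - c) / r) ** 2
    return acc <= 1.0


def _wm_shell_mask(shape) -> np.ndarray:
    """Synthetic white-matter region: a central ellipsoid filling ~60% of each axis."""
    center = [(n - 1) / 2 for n in shape]
    radii = [0.38 * n for n in shape]
    return _ellipsoid_mask(shape, center, radii)


def render_phantom(scene: PhantomScene) -> tuple[Volume, LabelMap, PriorAtlas]:
    """Render one case: intensity volume, ground-truth labels and blurred priors.

    The prior atlas is built by Gaussian-blurring each class indicator
    (``scene.prior_blur_sd`` voxels) and renormalising per voxel, emulating
    probabilities from a registered population atlas.  In lesion mode the
    atlas channels are (WM, GM, CSF) tissue probabilities instead, with the
    synthetic WM shell as channel 0 so lesion filtering is exercisable.
    """
    rng = np.random.default_rng(scene.seed)
    shape = tuple(scene.shape)
    bg_mean, texture_sd = scene.tissue_background

    label = np.zeros(shape, dtype=np.int32)
    for obj in scene.objects:
        mask = _ellipsoid_mask(shape, obj.center, obj.radii)
        clash = mask & (label != 0) & (label != obj.class_index)
        if clash.any():
            raise ValueError("phantom objects of different classes overlap")
        label[mask] = obj.class_index

    texture = gaussian_filter(rng.standard_normal(shape), sigma=1.0)
    sd = texture.std()
    if sd > 0:
        texture *= texture_sd / sd
    data = bg_mean + texture
    wm_mask = _wm_shell_mask(shape)
    if scene.mode == "lesions":
        # WM shell slightly brighter than surrounding tissue, as on FLAIR.
        data = np.where(wm_mask, data + 0.1, data)
    for obj in scene.objects:
        mask = _ellipsoid_mask(shape, obj.center, obj.radii)
        data[mask] = obj.intensity
    data = data + rng.normal(0.0, scene.noise_sd, size=shape)
    data = np.clip(data, 1e-4, None)  # keep "brain" voxels non-zero for masking

    volume = Volume(data=data.astype(np.float32), spacing=scene.spacing)
    labels = LabelMap(data=label, class_count=max(scene.class_count, int(label.max()) + 1, 2),
                      spacing=scene.spacing)

    if scene.mode == "structures":
        k = labels.class_count
        chans = np.zeros(shape + (k,), dtype=np.float64)
        for c in range(k):
            chans[..., c] = gaussian_filter((label == c).astype(np.float64),
                                            sigma=scene.prior_blur_sd)
        total = chans.sum(axis=-1, keepdims=True)
        total[total == 0] = 1.0
        chans /= total
    else:
        # Tissue priors (WM, GM, CSF): blurred shell, blurred complement, rim.
        wm = gaussian_filter(wm_mask.astype(np.float64), sigma=scene.prior_blur_sd)
        gm = gaussian_filter((~wm_mask).astype(np.float64), sigma=scene.prior_blur_sd)
        csf = np.full(shape, 0.05)
        chans = np.stack([wm, gm, csf], axis=-1)
        chans /= chans.sum(axis=-1, keepdims=True)
    atlas = PriorAtlas(data=np.clip(chans, 0.0, 1.0).astype(np.float32), spacing=scene.spacing)
    return volume, labels, atlas


def _smooth_bias_field(shape, spacing, amplitude, smoothness_mm, rng) -> np.ndarray:
    if amplitude == 0:
        return np.ones(shape)
    sigma_vox = [smoothness_mm / s for s in spacing]
    raw = gaussian_filter(rng.standard_normal(shape), sigma=sigma_vox)
    lo, hi = raw.min(), raw.max()
    if hi - lo < 1e-12:
        return np.ones(shape)
    unit = (raw - lo) / (hi - lo)  # in [0, 1]
    return 1.0 - amplitude + 2.0 * amplitude * unit


def apply_domain_shift(volume: Volume, shift: DomainShift) -> Volume:
    """Apply gamma -> linear contrast/brightness -> bias field -> noise.

    Gamma operates on intensities min-max rescaled to [0, 1] and is undone on
    the original scale, so ``gamma=1`` composed with ``gain``/``offset`` is an
    exact affine map.  Deterministic given ``shift.seed``.
    """
    rng = np.random.default_rng(shift.seed)
    x = volume.data.astype(np.float64)
    lo, hi = x.min(), x.max()
    span = hi - lo
    if span < 1e-12:
        y = x.copy()
    else:
        y = lo + span * ((x - lo) / span) ** shift.gamma
    bias = _smooth_bias_field(x.shape, volume.spacing, shift.bias_field_amplitude,
                              shift.bias_field_smoothness, rng)
    y = shift.gain * bias * y + shift.offset
    if shift.extra_noise_sd > 0:
        y = y + rng.normal(0.0, shift.extra_noise_sd, size=x.shape)
    return Volume(data=y.astype(np.float32), spacing=volume.spacing, affine=volume.affine)


@dataclass
class DomainCase:
    """One rendered case.  Target cases expose no labels; the true labels are
    kept in ``hidden_labels`` for evaluation only."""

    volume: Volume
    priors: PriorAtlas
    labels: LabelMap | None = None
    hidden_labels: LabelMap | None = None
    name: str = ""


def _jitter_scene(template: PhantomScene, rng: np.random.Generator,
                  pos_jitter: float = 1.0, intensity_jitter: float = 0.03) -> PhantomScene:
    objs = []
    for obj in template.objects:
        center = tuple(
            float(np.clip(c + rng.uniform(-pos_jitter, pos_jitter), r + 1, n - r - 2))
            for c, r, n in zip(obj.center, obj.radii, template.shape)
        )
        objs.append(replace(obj, center=center,
                            intensity=obj.intensity + rng.uniform(-intensity_jitter, intensity_jitter)))
    return replace(template, objects=tuple(objs), seed=int(rng.integers(0, 2**31 - 1)))


def make_domain_pair(
    template: PhantomScene,
    n_source: int,
    n_target: int,
    shift: DomainShift,
    seed: int,
) -> tuple[list[DomainCase], list[DomainCase]]:
    """Render labelled source cases and shifted, unlabelled target cases.

    Every case re-draws jittered object positions/intensities from the scene
    template.  Target cases carry the acquisition shift (with per-case seeds)
    and expose only ``hidden_labels`` for evaluation.
    """
    if n_source < 1 or n_target < 1:
        raise ValueError("need at least one source and one target case")
    rng = np.random.default_rng(seed)
    source, target = [], []
    for i in range(n_source):
        scene = _jitter_scene(template, rng)
        vol, lab, atlas = render_phantom(scene)
        source.append(DomainCase(volume=vol, priors=atlas, labels=lab, name=f"source_{i:02d}"))
    for i in range(n_target):
        scene = _jitter_scene(template, rng)
        vol, lab, atlas = render_phantom(scene)
        case_shift = replace(shift, seed=int(rng.integers(0, 2**31 - 1)))
        vol = apply_domain_shift(vol, case_shift)
        target.append(DomainCase(volume=vol, priors=atlas, labels=None,
                                 hidden_labels=lab, name=f"target_{i:02d}"))
    return source, target


def default_structure_scene(shape: tuple[int, int, int] = (28, 28, 28),
                            seed: int = 0) -> PhantomScene:
    """Three bilateral structure analogues with distinct intensities.

    Radii and contrasts are picked so that, at 1 mm isotropic spacing, objects
    span a few hundred voxels each — the scale of small sub-cortical
    structures — with moderate object/background contrast.
    """
    nx, ny, nz = shape
    cx, cy, cz = (nx - 1) / 2, (ny - 1) / 2, (nz - 1) / 2
    dx = 0.26 * nx
    objs = (
        PhantomObject(1, (cx - dx, cy, cz), (0.12 * nx, 0.13 * ny, 0.12 * nz), 0.55),
        PhantomObject(1, (cx + dx, cy, cz), (0.12 * nx, 0.13 * ny, 0.12 * nz), 0.55),
        PhantomObject(2, (cx, cy - 0.28 * ny, cz), (0.10 * nx, 0.10 * ny, 0.13 * nz), 0.70),
        PhantomObject(3, (cx, cy + 0.28 * ny, cz), (0.10 * nx, 0.10 * ny, 0.13 * nz), 0.85),
    )
    return PhantomScene(shape=shape, mode="structures", objects=objs, seed=seed)


def default_lesion_scene(shape: tuple[int, int, int] = (28, 28, 28),
                         seed: int = 0) -> PhantomScene:
    """Sparse bright lesions inside the synthetic white-matter shell."""
    nx, ny, nz = shape
    cx, cy, cz = (nx - 1) / 2, (ny - 1) / 2, (nz - 1) / 2
    r = (0.08 * nx, 0.08 * ny, 0.08 * nz)
    objs = (
        PhantomObject(1, (cx - 0.18 * nx, cy, cz), r, 0.85),
        PhantomObject(1, (cx + 0.15 * nx, cy + 0.12 * ny, cz - 0.1 * nz), r, 0.85),
        PhantomObject(1, (cx, cy - 0.15 * ny, cz + 0.12 * nz),
                      (0.06 * nx, 0.06 * ny, 0.06 * nz), 0.9),
    )
    return PhantomScene(shape=shape, mode="lesions", objects=objs, seed=seed)
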