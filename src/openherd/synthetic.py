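"""Procedural synthetic herd: face-like images with controllable identity similarity.

Real herd face datasets are rarely public, so this module generates stand-in
imagery with the same statistical structure: a modest number of individuals
whose faces are *globally similar* (same species, same coat colour) but carry
identity-specific micro-pattern — marking positions, texture frequency, base
intensity — plus heavy nuisance variation from uncontrolled capture: pose /
orientation, illumination, fog, partially visible faces, occlusion by
neighbours, and apparent head size changing with distance to the camera.

Each identity is a point in a latent pattern space.  All identities share a
herd-mean pattern; the dial ``sigma_id`` scales how far individual patterns
scatter around that mean, i.e. how separable the herd is.  Rendering is fully
analytic in image coordinates, so geometric nuisances (rotation, scale,
partial crop) are applied by transforming the sampling grid — the degenerate
nuisance configuration reproduces the noiseless prototype pixel for pixel.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage

__all__ = [
    "IdentityPrototype",
    "NuisanceConfig",
    "make_identities",
    "render_prototype",
    "render_sample",
    "generate_dataset",
    "load_manifest",
    "count_summary",
    "reference_herd_counts",
]

SESSIONS = ("morning", "noon", "night")

# latent layout: [base_intensity,
#                 amp1, freq1, angle1, phase1,
#                 amp2, freq2, angle2, phase2,
#                 n_markings,
#                 8 x (x, y, rx, ry, angle, contrast)]
_N_MARK_SLOTS = 8
_MARK_DIM = 6
_HEAD_DIM = 10
PARAM_DIM = _HEAD_DIM + _N_MARK_SLOTS * _MARK_DIM

# herd-mean pattern and the per-component scale of identity variation.
_HERD_MEAN = np.zeros(PARAM_DIM)
_HERD_MEAN[0] = 0.55                      # base intensity
_HERD_MEAN[1:5] = [0.10, 3.0, 0.5, 0.0]   # sinusoid 1: amp, freq, angle, phase
_HERD_MEAN[5:9] = [0.08, 5.5, -0.7, 1.0]  # sinusoid 2
_HERD_MEAN[9] = 5.5                       # mean marking count (3..8)
for _i in range(_N_MARK_SLOTS):
    _o = _HEAD_DIM + _i * _MARK_DIM
    _HERD_MEAN[_o:_o + _MARK_DIM] = [0.0, 0.0, 0.22, 0.16, 0.0, 0.0]

_ID_SCALE = np.zeros(PARAM_DIM)
_ID_SCALE[0] = 0.05
_ID_SCALE[1:5] = [0.03, 0.8, 0.5, 1.2]
_ID_SCALE[5:9] = [0.03, 0.8, 0.5, 1.2]
_ID_SCALE[9] = 0.0                        # marking count drawn separately
for _i in range(_N_MARK_SLOTS):
    _o = _HEAD_DIM + _i * _MARK_DIM
    _ID_SCALE[_o:_o + _MARK_DIM] = [0.30, 0.30, 0.06, 0.05, 0.8, 0.18]


@dataclass(frozen=True)
class IdentityPrototype:
    """One individual: a label plus the latent parameters of its face pattern.

    ``pattern_params`` fully determines the noiseless prototype rendering:
    identical parameter vectors yield pixel-identical prototypes.
    """

    id: str
    pattern_params: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.pattern_params, dtype=float)
        if p.shape != (PARAM_DIM,):
            raise ValueError(f"pattern_params must have shape ({PARAM_DIM},), got {p.shape}")
        object.__setattr__(self, "pattern_params", p)


@dataclass(frozen=True)
class NuisanceConfig:
    """Magnitudes of the capture-time nuisance factors.

    rotation_range : max |in-plane rotation| in degrees.
    illumination_range : multiplicative brightness interval (1.0 = unchanged).
    fog_level : blur + additive haze strength in [0, 1].
    partial_crop_prob : probability the face is partially outside the frame.
    occlusion_prob : probability a neighbour occludes part of the face.
    scale_range : apparent head-size interval relative to the frame.
    noise_sd : per-pixel Gaussian intensity noise (images live in [0, 1]).
    """

    rotation_range: float = 15.0
    illumination_range: tuple[float, float] = (0.7, 1.3)
    fog_level: float = 0.2
    partial_crop_prob: float = 0.1
    occlusion_prob: float = 0.1
    scale_range: tuple[float, float] = (0.8, 1.2)
    noise_sd: float = 0.05

    def __post_init__(self) -> None:
        for name in ("partial_crop_prob", "occlusion_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not 0.0 <= self.fog_level <= 1.0:
            raise ValueError(f"fog_level must lie in [0, 1], got {self.fog_level}")
        if self.rotation_range < 0:
            raise ValueError("rotation_range must be nonnegative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        for name in ("illumination_range", "scale_range"):
            lo, hi = getattr(self, name)
            if not (lo <= hi and lo > 0):
                raise ValueError(f"{name} must be a well-ordered positive interval, got ({lo}, {hi})")

    @classmethod
    def degenerate(cls) -> "NuisanceConfig":
        """All nuisance switched off: rendering equals the noiseless prototype."""
        return cls(
            rotation_range=0.0,
            illumination_range=(1.0, 1.0),
            fog_level=0.0,
            partial_crop_prob=0.0,
            occlusion_prob=0.0,
            scale_range=(1.0, 1.0),
            noise_sd=0.0,
        )


def make_identities(n_ids: int, sigma_id: float, seed: int) -> list[IdentityPrototype]:
    """Draw ``n_ids`` identity prototypes around the herd-mean pattern.

    ``sigma_id`` scales the scatter of identity parameters around the herd
    mean, so the expected pairwise parameter distance — and with it visual
    separability — increases monotonically in ``sigma_id``.  Deterministic
    given ``seed``.
    """
    if n_ids < 1:
        raise ValueError(f"n_ids must be >= 1, got {n_ids}")
    if sigma_id < 0:
        raise ValueError(f"sigma_id must be nonnegative, got {sigma_id}")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x1D]))
    protos = []
    for i in range(n_ids):
        z = rng.standard_normal(PARAM_DIM)
        params = _HERD_MEAN + sigma_id * _ID_SCALE * z
        params[9] = rng.integers(3, _N_MARK_SLOTS + 1)  # marking count, identity-specific
        protos.append(IdentityPrototype(id=f"id{i:03d}", pattern_params=params))
    return protos


def _pattern_field(params: np.ndarray, xx: np.ndarray, yy: np.ndarray) -> np.ndarray:
    """Evaluate the analytic face pattern at coordinates (xx, yy) in [-1, 1]^2."""
    img = np.full(xx.shape, params[0])
    for off in (1, 5):
        amp, freq, ang, ph = params[off:off + 4]
        u = xx * np.cos(ang) + yy * np.sin(ang)
        img = img + amp * np.sin(2.0 * np.pi * abs(freq) * u + ph)
    n_mark = int(np.clip(round(params[9]), 0, _N_MARK_SLOTS))
    for i in range(n_mark):
        o = _HEAD_DIM + i * _MARK_DIM
        mx, my, rx, ry, mang, c = params[o:o + _MARK_DIM]
        rx, ry = max(abs(rx), 1e-3), max(abs(ry), 1e-3)
        ca, sa = np.cos(mang), np.sin(mang)
        u = (xx - mx) * ca + (yy - my) * sa
        v = -(xx - mx) * sa + (yy - my) * ca
        img = img + c * np.exp(-((u / rx) ** 2 + (v / ry) ** 2))
    # shared face geometry: an elliptical head mask and a dark muzzle band,
    # common to every identity (this is what makes the herd look alike).
    head = np.exp(-(((xx / 0.85) ** 2 + (yy / 0.95) ** 2) ** 3))
    muzzle = 0.12 * np.exp(-(((xx / 0.45) ** 2 + ((yy - 0.55) / 0.25) ** 2)))
    img = (img - muzzle) * head + 0.15 * (1.0 - head)
    return np.clip(img, 0.0, 1.0)


def render_prototype(proto: IdentityPrototype, size: int = 64) -> np.ndarray:
    """Noiseless rendering of a prototype on a ``size`` x ``size`` grid."""
    if size < 16:
        raise ValueError(f"size must be >= 16, got {size}")
    ax = np.linspace(-1.0, 1.0, size)
    xx, yy = np.meshgrid(ax, ax)
    return _pattern_field(proto.pattern_params, xx, yy)


def render_sample(
    proto: IdentityPrototype,
    nuisance: NuisanceConfig,
    size: int = 64,
    seed: int = 0,
    rgb: bool = False,
) -> np.ndarray:
    """Render one noisy observation of an identity.

    Geometric nuisances (rotation, scale, partial crop) transform the sampling
    grid of the analytic pattern; photometric nuisances (illumination, fog,
    occlusion, sensor noise) act on the rendered pixels.  Values lie in
    [0, 1]; with ``NuisanceConfig.degenerate()`` the output equals
    :func:`render_prototype` exactly, independent of ``seed``.
    """
    if size < 16:
        raise ValueError(f"size must be >= 16, got {size}")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5A]))

    angle = np.deg2rad(rng.uniform(-nuisance.rotation_range, nuisance.rotation_range))
    scale = rng.uniform(*nuisance.scale_range)
    shift = np.zeros(2)
    if rng.random() < nuisance.partial_crop_prob:
        # face partly out of frame: sizeable off-centre shift
        shift = rng.uniform(0.35, 0.7) * _unit_vector(rng)

    ax = np.linspace(-1.0, 1.0, size)
    xx, yy = np.meshgrid(ax, ax)
    ca, sa = np.cos(-angle), np.sin(-angle)
    xr = (xx * ca - yy * sa) / scale + shift[0]
    yr = (xx * sa + yy * ca) / scale + shift[1]
    img = _pattern_field(proto.pattern_params, xr, yr)

    img = img * rng.uniform(*nuisance.illumination_range)

    if nuisance.fog_level > 0:
        img = ndimage.gaussian_filter(img, sigma=2.5 * nuisance.fog_level)
        haze = 0.5 * nuisance.fog_level
        img = (1.0 - haze) * img + haze * 0.8

    if rng.random() < nuisance.occlusion_prob:
        # neighbouring animal: a flat rectangle entering from one edge
        h = rng.integers(size // 5, size // 2)
        w = rng.integers(size // 5, size // 2)
        side = rng.integers(0, 4)
        r0 = 0 if side == 0 else size - h if side == 1 else rng.integers(0, size - h)
        c0 = 0 if side == 2 else size - w if side == 3 else rng.integers(0, size - w)
        img[r0:r0 + h, c0:c0 + w] = 0.35

    if nuisance.noise_sd > 0:
        img = img + rng.normal(0.0, nuisance.noise_sd, img.shape)

    img = np.clip(img, 0.0, 1.0)
    if rgb:
        # warm monochrome tint: colour carries essentially no identity signal
        img = np.stack([img, img * 0.82, img * 0.66], axis=-1)
    return img


def _unit_vector(rng: np.random.Generator) -> np.ndarray:
    theta = rng.uniform(0.0, 2.0 * np.pi)
    return np.array([np.cos(theta), np.sin(theta)])


@dataclass
class DatasetManifest:
    """Image manifest plus per-individual bookkeeping.

    ``frame`` has one row per image with columns
    ``image_path, individual_id, day, session``; paths are relative to
    ``root``.  ``per_individual`` maps each individual to its row count.
    """

    frame: pd.DataFrame
    root: Path
    per_individual: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        counts = self.frame["individual_id"].value_counts()
        self.per_individual = {k: int(v) for k, v in counts.items()}

    @property
    def path(self) -> Path:
        return self.root / "manifest.csv"

    def resolve(self, image_path: str) -> Path:
        return self.root / image_path


def generate_dataset(
    ids: list[IdentityPrototype],
    per_id_per_session: int,
    sessions: tuple[str, ...] = SESSIONS,
    nuisance: NuisanceConfig | None = None,
    out_dir: str | Path = "synthetic_herd",
    seed: int = 0,
    size: int = 64,
    days: tuple[str, ...] = ("day1",),
    rgb: bool = False,
    session_illumination: dict[str, float] | None = None,
) -> DatasetManifest:
    """Render a full dataset to ``out_dir`` and write ``manifest.csv``.

    One image per (identity, day, session, repeat); the manifest has
    ``len(ids) * len(days) * len(sessions) * per_id_per_session`` rows.
    ``session_illumination`` optionally maps session tags to extra brightness
    factors (morning/noon/night light); by default the session tag has no
    effect on the generative distribution.  Byte-identical output given the
    same arguments and ``seed``.
    """
    if per_id_per_session < 1:
        raise ValueError("per_id_per_session must be >= 1")
    if not sessions:
        raise ValueError("sessions must be nonempty")
    nuisance = NuisanceConfig() if nuisance is None else nuisance
    out_dir = Path(out_dir)
    img_dir = out_dir / "images"
    img_dir.mkdir(parents=True, exist_ok=True)

    rows = []
    counter = 0
    for proto in ids:
        for day in days:
            for session in sessions:
                nz = nuisance
                if session_illumination and session in session_illumination:
                    f = session_illumination[session]
                    lo, hi = nuisance.illumination_range
                    nz = replace(nuisance, illumination_range=(lo * f, hi * f))
                for rep in range(per_id_per_session):
                    img_seed = int(
                        np.random.SeedSequence([int(seed), counter]).generate_state(1)[0] % (2**31)
                    )
                    img = render_sample(proto, nz, size=size, seed=img_seed, rgb=rgb)
                    rel = f"images/{proto.id}_{day}_{session}_{rep:04d}.png"
                    _save_png(img, out_dir / rel)
                    rows.append((rel, proto.id, day, session))
                    counter += 1

    frame = pd.DataFrame(rows, columns=["image_path", "individual_id", "day", "session"])
    frame.to_csv(out_dir / "manifest.csv", index=False)
    return DatasetManifest(frame=frame, root=out_dir)


def _save_png(img: np.ndarray, path: Path) -> None:
    arr = np.round(img * 255.0).astype(np.uint8)
    mode = "RGB" if arr.ndim == 3 else "L"
    Image.fromarray(arr, mode=mode).save(path)


def load_image(path: str | Path) -> np.ndarray:
    """Read a PNG/JPEG back to a float array in [0, 1] (grayscale: 2-D)."""
    with Image.open(path) as im:
        arr = np.asarray(im, dtype=float) / 255.0
    return arr


def load_manifest(path: str | Path) -> DatasetManifest:
    """Read a ``manifest.csv`` written by :func:`generate_dataset`."""
    path = Path(path)
    frame = pd.read_csv(path, dtype={"individual_id": str})
    missing = [p for p in frame["image_path"] if not (path.parent / p).is_file()]
    if missing:
        raise FileNotFoundError(f"{len(missing)} manifest images missing, first: {missing[0]}")
    return DatasetManifest(frame=frame, root=path.parent)


def count_summary(manifest: DatasetManifest) -> pd.DataFrame:
    """Per-individual image counts, one column per day — dataset-table shape."""
    tab = manifest.frame.pivot_table(
        index="individual_id", columns="day", aggfunc="size", fill_value=0
    )
    tab.loc["total"] = tab.sum(axis=0)
    return tab


def reference_herd_counts() -> pd.DataFrame:
    """Per-individual image counts of the published 17-head cattle face dataset
    (one training day and two testing days) whose structure the synthetic
    generator emulates.  Columns: ``individual, training, testing_day1,
    testing_day2``."""
    res = importlib.resources.files("openherd") / "data" / "herd_image_counts.csv"
    with importlib.resources.as_file(res) as p:
        return pd.read_csv(p)
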