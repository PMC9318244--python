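"""Synthetic fixtures and simulated lesion photographs.

Two kinds of inputs are generated here:

* **Exact mathematical fixtures** with known fractal dimension — a filled
  square (FD = 2), the Sierpinski carpet (FD = log 8 / log 3 ≈ 1.8928),
  constant fields, checkerboards and fractional-Brownian-motion textures —
  used to anchor the FD estimator.

* **Simulated paired-illumination lesion photographs**: a dark,
  roughly-elliptical lesion with a radial-Fourier irregular border and
  fBm pigment texture on a lighter skin background. Each lesion is
  rendered under two illumination conditions sharing the identical
  boundary and texture fields: the polarized (PL) render as-is, and a
  non-polarized (NPL) render with linearly compressed lesion/background
  contrast plus sparse bright specular speckles, emulating surface
  reflections that polarization would suppress.

All randomness flows from a single integer seed through named
``numpy.random.SeedSequence`` substreams, so every image — and every
cohort — is bit-reproducible.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np

from .image import GrayImage


class Illumination(str, Enum):
    PL = "PL"    # polarized
    NPL = "NPL"  # non-polarized


class FixtureKind(str, Enum):
    FILLED_SQUARE = "filled_square"
    SIERPINSKI_CARPET = "sierpinski_carpet"
    CONSTANT_FIELD = "constant_field"
    FBM_TEXTURE = "fbm_texture"
    CHECKERBOARD = "checkerboard"


@dataclass(frozen=True)
class FractalFixtureSpec:
    """Recipe for an exact test image of known fractal dimension."""

    kind: FixtureKind
    side: int
    depth: int | None = None          # carpet iteration count
    foreground: int = 0
    background: int = 255
    hurst: float | None = None        # fbm only
    seed: int | None = None           # fbm only

    def __post_init__(self) -> None:
        if self.side < 1:
            raise ValueError("side must be positive")
        if self.kind is FixtureKind.SIERPINSKI_CARPET:
            if self.depth is None or self.depth < 1:
                raise ValueError("carpet needs a depth >= 1")
            if self.side != 3**self.depth:
                raise ValueError(
                    f"carpet side must be exactly 3^depth = {3**self.depth}, "
                    f"got {self.side}"
                )
        if self.kind is FixtureKind.FBM_TEXTURE:
            if self.hurst is None or not (0 < self.hurst < 1):
                raise ValueError("fbm texture needs hurst in (0, 1)")
            if self.seed is None:
                raise ValueError("fbm texture needs a seed")


@dataclass(frozen=True)
class SyntheticLesionParams:
    """Controls of the simulated lesion photograph.

    The boundary is r(θ) = base_radius · (1 + irregularity_amplitude ·
    Σ_k a_k cos(kθ + φ_k)) with seeded coefficients decaying as 1/k; the
    lesion interior carries an fBm texture with the given Hurst exponent
    (lower = rougher). The NPL render compresses lesion/background contrast
    by ``npl_contrast_factor`` and adds bright speckles on a
    ``specular_noise_density`` fraction of pixels.
    """

    image_width: int = 640
    image_height: int = 640
    base_radius: float = 200.0
    irregularity_amplitude: float = 0.05
    harmonics: int = 48
    texture_hurst: float = 0.5
    lesion_mean_intensity: int = 70
    background_mean_intensity: int = 200
    illumination: Illumination = Illumination.PL
    npl_contrast_factor: float = 0.55
    specular_noise_density: float = 0.002
    texture_sd: float = 18.0
    background_noise_sd: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.background_mean_intensity <= self.lesion_mean_intensity:
            raise ValueError("lesion must be darker than the skin background")
        if not (0 < self.npl_contrast_factor <= 1):
            raise ValueError("npl_contrast_factor must be in (0, 1]")
        if not (0 < self.texture_hurst < 1):
            raise ValueError("texture_hurst must be in (0, 1)")
        if self.irregularity_amplitude < 0:
            raise ValueError("irregularity_amplitude must be >= 0")
        if not (0 <= self.specular_noise_density <= 1):
            raise ValueError("specular_noise_density must be a pixel fraction")


def _rng(seed: int, stream: str) -> np.random.Generator:
    """Named deterministic substream of the master seed."""
    tag = zlib.crc32(stream.encode())
    return np.random.default_rng(np.random.SeedSequence([int(seed), tag]))


# ---------------------------------------------------------------------------
# exact fixtures


def carpet_mask(depth: int) -> np.ndarray:
    """Boolean foreground mask of the Sierpinski carpet at ``depth``.

    A pixel (x, y) belongs to the background hole iff any base-3 digit
    pair of its coordinates is (1, 1).
    """
    side = 3**depth
    coords = np.arange(side)
    hole = np.zeros((side, side), dtype=bool)
    for k in range(depth):
        d = (coords // 3**k) % 3 == 1
        hole |= d[:, None] & d[None, :]
    return ~hole


def fbm_field(side: int, hurst: float, rng: np.random.Generator) -> np.ndarray:
    """Fractional Brownian field by Fourier spectral synthesis.

    White complex noise is shaped with amplitude ∝ f^-(hurst+1), the 2-D
    spectral envelope of an fBm surface with the given Hurst exponent; the
    zero frequency is suppressed so the field has mean zero.
    """
    fy = np.fft.fftfreq(side)[:, None]
    fx = np.fft.fftfreq(side)[None, :]
    f = np.hypot(fy, fx)
    f[0, 0] = np.inf  # kills the DC term
    amplitude = f ** -(hurst + 1.0)
    noise = rng.standard_normal((side, side)) + 1j * rng.standard_normal((side, side))
    fieldc = np.fft.ifft2(noise * amplitude)
    out = np.real(fieldc)
    out -= out.mean()
    sd = out.std()
    return out / sd if sd > 0 else out


def render_fixture(spec: FractalFixtureSpec) -> GrayImage:
    """Render an exact fixture image per its spec."""
    side = spec.side
    if spec.kind in (FixtureKind.CONSTANT_FIELD, FixtureKind.FILLED_SQUARE):
        return GrayImage(np.full((side, side), spec.foreground, dtype=np.uint8))
    if spec.kind is FixtureKind.CHECKERBOARD:
        yy, xx = np.indices((side, side))
        board = (yy + xx) % 2 == 0
        return GrayImage(np.where(board, spec.foreground, spec.background).astype(np.uint8))
    if spec.kind is FixtureKind.SIERPINSKI_CARPET:
        fg = carpet_mask(spec.depth)
        return GrayImage(np.where(fg, spec.foreground, spec.background).astype(np.uint8))
    if spec.kind is FixtureKind.FBM_TEXTURE:
        rng = _rng(spec.seed, "fbm-fixture")
        f = fbm_field(side, spec.hurst, rng)
        lo, hi = f.min(), f.max()
        scaled = (f - lo) / (hi - lo) * 255.0 if hi > lo else np.zeros_like(f)
        return GrayImage(np.floor(scaled + 0.5).astype(np.uint8))
    raise ValueError(f"unknown fixture kind {spec.kind!r}")


# ---------------------------------------------------------------------------
# simulated lesions


def boundary_radius(params: SyntheticLesionParams, theta: np.ndarray) -> np.ndarray:
    """Analytic lesion boundary r(θ) for the seeded radial-Fourier model.

    Coefficients a_k = g_k / k (g_k standard normal) with uniform phases,
    all drawn from the ``boundary`` substream of the seed, so PL and NPL
    renders of one lesion share the identical curve. The perturbation
    profile is normalised to unit peak, making ``irregularity_amplitude``
    the peak relative radial deviation: any amplitude below 1 yields a
    valid (non-self-intersecting) boundary.
    """
    rng = _rng(params.seed, "boundary")
    k = np.arange(1, params.harmonics + 1)
    a = rng.standard_normal(params.harmonics) / k
    phi = rng.uniform(0, 2 * np.pi, params.harmonics)

    def series(t: np.ndarray) -> np.ndarray:
        return np.sum(a[:, None] * np.cos(k[:, None] * t[None, :] + phi[:, None]), axis=0)

    ref = np.linspace(0.0, 2 * np.pi, 4096, endpoint=False)
    peak = np.max(np.abs(series(ref)))
    pert = series(np.asarray(theta, dtype=float)) / peak if peak > 0 else 0.0
    return params.base_radius * (1.0 + params.irregularity_amplitude * pert)


def lesion_mask_for(params: SyntheticLesionParams) -> np.ndarray:
    """Boolean in-lesion mask implied by the analytic boundary."""
    h, w = params.image_height, params.image_width
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    yy, xx = np.indices((h, w))
    dy, dx = yy - cy, xx - cx
    theta = np.arctan2(dy, dx).ravel()
    r = boundary_radius(params, theta).reshape(h, w)
    if (r <= 0).any():
        raise ValueError(
            "boundary self-intersects (radius <= 0); lower irregularity_amplitude"
        )
    return np.hypot(dy, dx) <= r


def render_lesion(params: SyntheticLesionParams) -> GrayImage:
    """Render a simulated grayscale lesion photograph.

    The PL render places the fBm-textured dark lesion on a noisy light
    background; the NPL render of the same seed reuses the identical
    boundary and texture fields, compresses intensities toward the
    background mean by ``npl_contrast_factor`` and overlays seeded
    specular speckles.
    """
    h, w = params.image_height, params.image_width
    mask = lesion_mask_for(params)

    side = max(h, w)
    texture = fbm_field(side, params.texture_hurst, _rng(params.seed, "texture"))
    texture = texture[:h, :w] * params.texture_sd

    bg_noise = _rng(params.seed, "background").normal(
        0.0, params.background_noise_sd, size=(h, w)
    )
    img = np.where(
        mask,
        params.lesion_mean_intensity + texture,
        params.background_mean_intensity + bg_noise,
    )

    if params.illumination is Illumination.NPL:
        # lower contrast: pull every pixel toward the background mean
        img = params.background_mean_intensity + params.npl_contrast_factor * (
            img - params.background_mean_intensity
        )
        if params.specular_noise_density > 0:
            rng = _rng(params.seed, "specular")
            speckle = rng.random((h, w)) < params.specular_noise_density
            img = np.where(speckle, 255.0, img)

    return GrayImage(np.clip(np.floor(img + 0.5), 0, 255).astype(np.uint8))


def render_lesion_rgb(params: SyntheticLesionParams) -> np.ndarray:
    """RGB variant: a brown-tinted rendering of the grayscale lesion."""
    g = render_lesion(params).pixels.astype(np.float64) / 255.0
    # melanin-like tint: strongest absorption in blue, least in red
    tint = np.array([1.0, 0.82, 0.68])
    rgb = g[..., None] * tint[None, None, :] * 255.0
    return np.clip(np.floor(rgb + 0.5), 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# cohorts


#: Per-group presets: border irregularity and texture roughness increase
#: (Hurst decreases) from benign nevi through dysplastic nevi to melanoma,
#: and melanomas are larger — mirroring the qualitative clinical picture.
DEFAULT_GROUP_PRESETS: dict[str, SyntheticLesionParams] = {
    "BN": SyntheticLesionParams(
        base_radius=170.0, irregularity_amplitude=0.05, texture_hurst=0.60
    ),
    "DN": SyntheticLesionParams(
        base_radius=180.0, irregularity_amplitude=0.15, texture_hurst=0.50
    ),
    "MM": SyntheticLesionParams(
        base_radius=230.0, irregularity_amplitude=0.30, texture_hurst=0.35
    ),
}

#: Study-design group sizes (melanoma / dysplastic / benign = 20/23/54).
DEFAULT_GROUP_SIZES: dict[str, int] = {"MM": 20, "DN": 23, "BN": 54}


@dataclass(frozen=True)
class CohortEntry:
    """One simulated lesion: its parameters and the PL/NPL image pair."""

    lesion_id: str
    group: str
    seed: int
    params: SyntheticLesionParams = field(repr=False)
    pl_image: GrayImage = field(repr=False)
    npl_image: GrayImage = field(repr=False)


def lesion_seed(master_seed: int, group: str, index: int) -> int:
    """Reproducible per-lesion seed derived from the master seed."""
    ss = np.random.SeedSequence([int(master_seed), zlib.crc32(group.encode()), index])
    return int(ss.generate_state(1)[0] % 2**31)


def write_cohort(entries: list["CohortEntry"], directory, mm_per_pixel: float | None = None):
    """Write a cohort as PNGs plus a pipeline-ready manifest CSV.

    One grayscale PNG per illumination per lesion, named
    ``{lesion_id}_{PL|NPL}.png``; returns the manifest path. The manifest
    carries lesion_id, group, illumination, seed, the path and the main
    generator parameters.
    """
    import csv
    from pathlib import Path

    from .image import save_image

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest_path = directory / "manifest.csv"
    with open(manifest_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["lesion_id", "group", "illumination", "path", "seed",
             "base_radius", "irregularity_amplitude", "texture_hurst"]
        )
        for e in entries:
            for illum, img in (("PL", e.pl_image), ("NPL", e.npl_image)):
                path = directory / f"{e.lesion_id}_{illum}.png"
                save_image(img, path)
                writer.writerow(
                    [e.lesion_id, e.group, illum, str(path), e.seed,
                     e.params.base_radius, e.params.irregularity_amplitude,
                     e.params.texture_hurst]
                )
    return manifest_path


def generate_cohort(
    n_per_group: int | dict[str, int],
    group_param_presets: dict[str, SyntheticLesionParams] | None = None,
    seed: int = 0,
) -> list[CohortEntry]:
    """Generate a paired-illumination cohort across lesion groups.

    ``n_per_group`` is either one count for every preset or a per-group
    mapping. Each lesion gets a seed derived deterministically from the
    master seed, and a PL and an NPL render sharing boundary and texture.
    """
    presets = group_param_presets or DEFAULT_GROUP_PRESETS
    if isinstance(n_per_group, int):
        if n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        sizes = {g: n_per_group for g in presets}
    else:
        sizes = dict(n_per_group)
        if any(n < 1 for n in sizes.values()):
            raise ValueError("every group size must be >= 1")
    entries: list[CohortEntry] = []
    for group, preset in presets.items():
        for i in range(sizes[group]):
            s = lesion_seed(seed, group, i)
            base = replace(preset, seed=s, illumination=Illumination.PL)
            pl = render_lesion(base)
            npl = render_lesion(replace(base, illumination=Illumination.NPL))
            entries.append(
                CohortEntry(
                    lesion_id=f"{group}{i:03d}",
                    group=group,
                    seed=s,
                    params=base,
                    pl_image=pl,
                    npl_image=npl,
                )
            )
    return entries
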