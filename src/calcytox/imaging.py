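"""Synthetic fluorescence-image renderer for the image cytometer.

A :class:`~calcytox.assay.WellState` is turned into a single-channel field
image the way the counting-slide workflow does: a Bernoulli subsample of the
well's particles lands in the imaged frame (``sampled_fraction``), each
particle is rendered as an isotropic Gaussian spot whose *integrated* signal
is ``gain × calcein`` counts, and the camera adds Poisson shot noise on
signal + background plus Gaussian read noise before quantization.

Exposure time and optics are not modeled individually: the single ``gain``
constant stands in for exposure × collection efficiency, since only relative
intensities matter to downstream gating.

Ground truth (which particles were rendered, where, and with what noiseless
total signal) is carried alongside the pixels so detection and gating can be
tested against an oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy.special import ndtr

from .assay import WellState, _as_rng
from .errors import InvalidParameterError

__all__ = [
    "ImageSpec",
    "PlacedParticle",
    "FieldImage",
    "sample_field",
    "render_field",
    "acquire_fields",
    "effective_radius_px",
    "write_field",
    "read_field",
    "spot_sigma_px",
]

TRUTH_COLUMNS = ["particle_id", "kind", "x_px", "y_px", "true_total_counts"]

#: Particle centers are kept at least ``PLACEMENT_PADDING x (d_i+d_j)/2``
#: apart. The 50% margin over physical contact keeps the *detection masks*
#: of neighbouring bright spots (which extend past the particle radius by
#: the PSF, ~1.3 mask radii for the brightest cells) from touching, so the
#: declumping-free detector sees them as separate objects — a settled,
#: non-clumped monolayer.
PLACEMENT_PADDING = 1.5


@dataclass
class ImageSpec:
    """Imaging geometry, gain and noise model.

    Parameters
    ----------
    width_px, height_px
        Field dimensions in pixels.
    um_per_px
        Physical pixel pitch (μm/pixel).
    psf_sigma_um
        Lower bound on the Gaussian spot scale (optical blur).
    gain
        Counts of integrated signal per AU of calcein (absorbs exposure time
        and collection optics).
    background_offset
        Mean background level in counts (also Poisson-distributed when shot
        noise is on).
    read_noise_sd
        Gaussian read-noise standard deviation, counts.
    bit_depth
        8 or 16; pixels are quantized and clipped to ``2**bit_depth - 1``.
    sampled_fraction
        Probability that a given particle of the well is imaged at all: the
        fraction of the resuspended pellet loaded onto the counting slide
        and scanned (20 μl imaged of a 50 μl resuspension gives the 0.4
        default). The imaged particles are spread across however many
        frames keep each frame dilute (see ``max_fill_fraction``).
    shot_noise
        Disable to render the noiseless expectation (plus read noise if any);
        used by conservation checks.
    edge_margin_px
        Particle centers are kept at least this far from the frame border so
        spots are not truncated (the analysed counting-frame interior).
    max_fill_fraction
        Ceiling on the fraction of a frame's interior area occupied by
        (padded) particles; :func:`acquire_fields` adds frames until every
        frame is below it, emulating the instrument scanning several fields
        per slide.
    """

    width_px: int = 512
    height_px: int = 512
    um_per_px: float = 2.0
    psf_sigma_um: float = 1.0
    gain: float = 200.0
    background_offset: float = 100.0
    read_noise_sd: float = 3.0
    bit_depth: int = 16
    sampled_fraction: float = 0.4
    shot_noise: bool = True
    edge_margin_px: int = 24
    max_fill_fraction: float = 0.24

    def __post_init__(self) -> None:
        if self.width_px < 1 or self.height_px < 1:
            raise InvalidParameterError("image dimensions must be >= 1 px")
        for name in ("um_per_px", "psf_sigma_um", "gain"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be > 0")
        if self.background_offset < 0 or self.read_noise_sd < 0:
            raise InvalidParameterError(
                "background_offset and read_noise_sd must be >= 0")
        if self.bit_depth not in (8, 16):
            raise InvalidParameterError("bit_depth must be 8 or 16")
        if not (0.0 < self.sampled_fraction <= 1.0):
            raise InvalidParameterError("sampled_fraction must be in (0, 1]")
        if self.edge_margin_px < 0:
            raise InvalidParameterError("edge_margin_px must be >= 0")
        if not (0.0 < self.max_fill_fraction <= 1.0):
            raise InvalidParameterError(
                "max_fill_fraction must be in (0, 1]")

    @property
    def max_count(self) -> int:
        return 2 ** self.bit_depth - 1

    @property
    def dtype(self):
        return np.uint8 if self.bit_depth == 8 else np.uint16

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}

    @classmethod
    def from_dict(cls, d: dict) -> "ImageSpec":
        return cls(**d)

    def replace(self, **kwargs) -> "ImageSpec":
        return replace(self, **kwargs)


@dataclass
class PlacedParticle:
    """A particle assigned a sub-pixel position inside the imaged frame."""

    particle_id: int  # index into WellState.particles
    kind: str
    calcein: float
    diameter_um: float
    row_px: float
    col_px: float


@dataclass
class FieldImage:
    """Rendered field: integer pixels plus the rendering ground truth."""

    pixels: np.ndarray
    spec: ImageSpec
    truth: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=TRUTH_COLUMNS))

    def __post_init__(self) -> None:
        if self.pixels.ndim != 2:
            raise InvalidParameterError("pixels must be a 2-D array")

    def n_rendered(self, kind: str | None = None) -> int:
        if kind is None:
            return len(self.truth)
        return int((self.truth["kind"] == kind).sum())


def spot_sigma_px(diameter_um: float, spec: ImageSpec) -> float:
    """Gaussian spot sigma in pixels: optics floor or particle size/4."""
    return max(spec.psf_sigma_um, diameter_um / 4.0) / spec.um_per_px


def _place_positions(diameters_px: np.ndarray, spec: ImageSpec,
                     rng: np.random.Generator, max_tries: int = 100
                     ) -> np.ndarray:
    """Dart-throwing placement, pairwise distance >= PADDING*(d_i+d_j)/2.

    Particles are placed largest-first on a uniform grid accelerator; if a
    particle cannot be placed within ``max_tries`` attempts (near-jammed
    fields), the last candidate is accepted — dense debris fields degrade
    gracefully instead of failing.
    """
    n = len(diameters_px)
    lo_r = float(spec.edge_margin_px)
    hi_r = float(spec.height_px - 1 - spec.edge_margin_px)
    lo_c = float(spec.edge_margin_px)
    hi_c = float(spec.width_px - 1 - spec.edge_margin_px)
    if hi_r <= lo_r or hi_c <= lo_c:
        raise InvalidParameterError(
            "edge_margin_px leaves no interior to place particles in")

    radii = PLACEMENT_PADDING * diameters_px / 2.0
    order = np.argsort(-diameters_px, kind="stable")
    out = np.empty((n, 2))

    # Large particles (few) are placed first with a vectorized distance
    # test. Their exclusion zones are then rasterized into a boolean mask
    # so that the many small particles (apoptotic bodies) only need an O(1)
    # lookup plus a fine-grid check against other small particles.
    small_cut = 2.5
    is_big = radii > small_cut
    small_rmax = float(radii[~is_big].max(initial=0.0))
    bigs = [idx for idx in order if is_big[idx]]
    smalls = [idx for idx in order if not is_big[idx]]

    big_y = np.empty(len(bigs))
    big_x = np.empty(len(bigs))
    big_r = np.empty(len(bigs))
    n_big = 0
    for idx in bigs:
        ri = radii[idx]
        r = c = 0.0
        for _ in range(max_tries):
            r = rng.uniform(lo_r, hi_r)
            c = rng.uniform(lo_c, hi_c)
            if n_big == 0:
                break
            d2 = (big_y[:n_big] - r) ** 2 + (big_x[:n_big] - c) ** 2
            if (d2 >= (big_r[:n_big] + ri) ** 2).all():
                break
        big_y[n_big], big_x[n_big], big_r[n_big] = r, c, ri
        n_big += 1
        out[idx] = (r, c)

    if not smalls:
        return out

    # conservative raster of big exclusion zones (+1.5 px covers the
    # sub-pixel quantization of the mask lookup)
    forbidden = np.zeros((spec.height_px, spec.width_px), dtype=bool)
    h, w = forbidden.shape
    for j in range(n_big):
        rad = big_r[j] + small_rmax + 1.5
        r0 = max(int(big_y[j] - rad), 0)
        r1 = min(int(big_y[j] + rad) + 2, h)
        c0 = max(int(big_x[j] - rad), 0)
        c1 = min(int(big_x[j] + rad) + 2, w)
        yy, xx = np.ogrid[r0:r1, c0:c1]
        forbidden[r0:r1, c0:c1] |= ((yy - big_y[j]) ** 2
                                    + (xx - big_x[j]) ** 2) <= rad * rad

    cell = max(2.0 * max(small_rmax, 0.5), 1.0)
    grid: dict[tuple, list] = {}
    # pre-drawn candidate batches avoid per-trial scalar RNG calls
    batch = max(4 * len(smalls), 1024)
    cand_r = rng.uniform(lo_r, hi_r, size=batch)
    cand_c = rng.uniform(lo_c, hi_c, size=batch)
    ptr = 0
    for idx in smalls:
        ri = radii[idx]
        r = c = 0.0
        for _ in range(max_tries):
            if ptr >= batch:
                cand_r = rng.uniform(lo_r, hi_r, size=batch)
                cand_c = rng.uniform(lo_c, hi_c, size=batch)
                ptr = 0
            r = cand_r[ptr]
            c = cand_c[ptr]
            ptr += 1
            if forbidden[int(r), int(c)]:
                continue
            gr, gc = int(r // cell), int(c // cell)
            ok = True
            for dg in (-1, 0, 1):
                for dh in (-1, 0, 1):
                    for (pr, pc, prad) in grid.get((gr + dg, gc + dh), ()):
                        dmin = ri + prad
                        if (pr - r) ** 2 + (pc - c) ** 2 < dmin * dmin:
                            ok = False
                            break
                    if not ok:
                        break
                if not ok:
                    break
            if ok:
                break
        grid.setdefault((int(r // cell), int(c // cell)),
                        []).append((r, c, ri))
        out[idx] = (r, c)
    return out


def _place_subset(state: WellState, indices: np.ndarray, spec: ImageSpec,
                  rng: np.random.Generator) -> list[PlacedParticle]:
    particles = state.particles
    if indices.size == 0:
        return []
    diameters_px = np.array(
        [particles[i].diameter_um / spec.um_per_px for i in indices])
    pos = _place_positions(diameters_px, spec, rng)
    return [
        PlacedParticle(
            particle_id=int(i),
            kind=particles[i].kind,
            calcein=particles[i].calcein,
            diameter_um=particles[i].diameter_um,
            row_px=float(pos[j, 0]),
            col_px=float(pos[j, 1]),
        )
        for j, i in enumerate(indices)
    ]


def sample_field(state: WellState, spec: ImageSpec, seed=None
                 ) -> list[PlacedParticle]:
    """Subsample the well onto one imaged frame.

    Each particle is retained independently with probability
    ``sampled_fraction``, then retained particles are placed uniformly
    inside the counting frame with pairwise center distance at least
    ``PLACEMENT_PADDING`` times the mean of the two particle diameters — a
    dilute monolayer of non-touching objects. Resuspension randomizes
    positions, so in-well coordinates do not carry over to the slide.

    This is the single-frame primitive; use :func:`acquire_fields` to image
    a whole sample at instrument-like counting depth.
    """
    rng = _as_rng(seed)
    if not state.particles:
        return []
    keep = rng.random(len(state.particles)) < spec.sampled_fraction
    return _place_subset(state, np.flatnonzero(keep), spec, rng)


def effective_radius_px(diameter_um: float, spec: ImageSpec) -> float:
    """Footprint radius a particle occupies for frame-capacity purposes.

    The padded physical radius, floored at 2 px: even sub-resolution
    particles occupy a PSF-sized detection footprint.
    """
    return max(PLACEMENT_PADDING * diameter_um / spec.um_per_px / 2.0, 2.0)


def acquire_fields(state: WellState, spec: ImageSpec, seed=None
                   ) -> list[FieldImage]:
    """Image one well sample as a set of dilute frames.

    A ``sampled_fraction`` Bernoulli subsample of the well's particles is
    imaged, split uniformly at random across the smallest number of frames
    that keeps each frame's padded-particle area below
    ``max_fill_fraction`` of the frame interior — the counting-slide scan
    of a real image cytometer, which acquires several fields per sample and
    pools their counts.
    """
    rng = _as_rng(seed)
    particles = state.particles
    if not particles:
        return [render_field([], spec, rng)]
    keep = rng.random(len(particles)) < spec.sampled_fraction
    kept = np.flatnonzero(keep)
    if kept.size == 0:
        return [render_field([], spec, rng)]
    radii = np.array([effective_radius_px(particles[i].diameter_um, spec)
                      for i in kept])
    interior = ((spec.height_px - 1 - 2 * spec.edge_margin_px)
                * (spec.width_px - 1 - 2 * spec.edge_margin_px))
    footprint = float(np.pi * (radii ** 2).sum())
    n_frames = max(1, int(np.ceil(
        footprint / (spec.max_fill_fraction * interior))))
    assignment = rng.integers(n_frames, size=kept.size)
    fields = []
    for frame in range(n_frames):
        placed = _place_subset(state, kept[assignment == frame], spec, rng)
        fields.append(render_field(placed, spec, rng))
    return fields


def _accumulate_spot(expected: np.ndarray, total: float, row: float,
                     col: float, sigma: float) -> None:
    """Add an integrated-``total`` Gaussian spot; pixel-integrated kernel."""
    h, w = expected.shape
    half = int(math.ceil(5.0 * sigma))
    r0, r1 = int(math.floor(row)) - half, int(math.floor(row)) + half + 1
    c0, c1 = int(math.floor(col)) - half, int(math.floor(col)) + half + 1
    rows = np.arange(r0, r1)
    cols = np.arange(c0, c1)
    kr = ndtr((rows + 0.5 - row) / sigma) - ndtr((rows - 0.5 - row) / sigma)
    kc = ndtr((cols + 0.5 - col) / sigma) - ndtr((cols - 0.5 - col) / sigma)
    kern = np.outer(kr, kc)
    s = kern.sum()
    if s > 0:
        kern /= s  # window-normalized: the spot carries exactly `total`
    rv = slice(max(r0, 0), min(r1, h))
    cv = slice(max(c0, 0), min(c1, w))
    expected[rv, cv] += total * kern[rv.start - r0: rv.stop - r0,
                                     cv.start - c0: cv.stop - c0]


def _accumulate_spots(expected: np.ndarray, group: list, half: int) -> None:
    """Vectorized spot accumulation for particles sharing a window size.

    Particles whose window would cross the image edge fall back to the
    per-spot path (which clips); the interior majority is rendered in one
    batched erf evaluation and scattered with a single bincount.
    """
    h, w = expected.shape
    rows = np.array([g[0] for g in group])
    cols = np.array([g[1] for g in group])
    sigmas = np.array([g[2] for g in group])
    totals = np.array([g[3] for g in group])
    r0 = np.floor(rows).astype(np.int64) - half
    c0 = np.floor(cols).astype(np.int64) - half
    width = 2 * half + 1
    interior = ((r0 >= 0) & (c0 >= 0)
                & (r0 + width <= h) & (c0 + width <= w))
    for i in np.flatnonzero(~interior):
        _accumulate_spot(expected, totals[i], rows[i], cols[i], sigmas[i])
    if not interior.any():
        return
    r0, c0 = r0[interior], c0[interior]
    rows, cols = rows[interior], cols[interior]
    sigmas, totals = sigmas[interior], totals[interior]
    offs = np.arange(width)
    rr = r0[:, None] + offs
    cc = c0[:, None] + offs
    kr = (ndtr((rr + 0.5 - rows[:, None]) / sigmas[:, None])
          - ndtr((rr - 0.5 - rows[:, None]) / sigmas[:, None]))
    kc = (ndtr((cc + 0.5 - cols[:, None]) / sigmas[:, None])
          - ndtr((cc - 0.5 - cols[:, None]) / sigmas[:, None]))
    kern = kr[:, :, None] * kc[:, None, :]
    mass = kern.sum(axis=(1, 2))
    np.divide(totals, mass, out=totals, where=mass > 0)
    kern *= totals[:, None, None]
    flat = (rr[:, :, None] * w + cc[:, None, :]).ravel()
    expected += np.bincount(flat, weights=kern.ravel(),
                            minlength=h * w).reshape(h, w)


def render_field(placed: list[PlacedParticle], spec: ImageSpec, seed=None
                 ) -> FieldImage:
    """Render placed particles into a quantized camera frame.

    Each particle contributes an isotropic Gaussian spot with integrated
    signal ``gain × calcein`` and sigma ``max(psf_sigma_um, diameter/4)``
    (in pixels). The camera model is Poisson(signal + offset) shot noise
    plus Gaussian read noise, rounded and clipped to the bit depth.
    """
    rng = _as_rng(seed)
    expected = np.zeros((spec.height_px, spec.width_px), dtype=np.float64)
    rows = []
    by_half: dict[int, list] = {}
    for pid, p in enumerate(placed):
        sigma = spot_sigma_px(p.diameter_um, spec)
        total = spec.gain * p.calcein
        half = int(math.ceil(5.0 * sigma))
        by_half.setdefault(half, []).append((p.row_px, p.col_px, sigma, total))
        rows.append((pid, p.kind, p.col_px, p.row_px, total))
    for half, group in by_half.items():
        _accumulate_spots(expected, group, half)

    lam = expected + spec.background_offset
    if spec.shot_noise:
        img = rng.poisson(lam).astype(np.float64)
    else:
        img = lam.copy()
    if spec.read_noise_sd > 0:
        img += rng.normal(0.0, spec.read_noise_sd, size=img.shape)
    img = np.clip(np.rint(img), 0, spec.max_count).astype(spec.dtype)

    truth = pd.DataFrame(rows, columns=TRUTH_COLUMNS)
    return FieldImage(pixels=img, spec=spec, truth=truth)


def write_field(field_image: FieldImage, path) -> Path:
    """Write pixels as single-channel TIFF plus a ``*_truth.csv`` sibling."""
    path = Path(path)
    tifffile.imwrite(path, field_image.pixels)
    truth_path = path.with_name(path.stem + "_truth.csv")
    field_image.truth.to_csv(truth_path, index=False)
    return path


def read_field(path, spec: ImageSpec) -> FieldImage:
    """Read a TIFF written by :func:`write_field`; truth CSV is optional."""
    path = Path(path)
    pixels = tifffile.imread(path)
    truth_path = path.with_name(path.stem + "_truth.csv")
    if truth_path.exists():
        truth = pd.read_csv(truth_path)
    else:
        truth = pd.DataFrame(columns=TRUTH_COLUMNS)
    return FieldImage(pixels=pixels, spec=spec, truth=truth)
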