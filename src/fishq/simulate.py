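"""Synthetic three-channel FISH TMA-core generator with exhaustive ground truth.

The generator renders the image structure the detection pipeline assumes:
round nuclei with a smooth interior plateau and a sigmoidal intensity
falloff at the border on the DAPI channel, and diffraction-limited Gaussian
puncta inside the nuclei on the two probe channels (rhodamine = HER2 = red,
FITC = CEP17 = green).  Each nucleus is planted as either *normal*
(``normal_red``/``normal_green`` spots, default 2/2) or *amplified* (red
count drawn from ``amplified_red_range``); the amplified count per core is
deterministic, ``round(n_nuclei * amplified_frac)``, so recovery tests have
exact expectations.

Optics are emulated, not modelled: a multi-plane stack assigns every nucleus
one sharp plane and blurs it Gaussian-wise elsewhere in proportion to the
plane distance; additive Gaussian camera noise is set from the requested
signal-to-noise ratio.  Everything is driven by one seeded generator, so a
seed fully determines the output byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil
from pathlib import Path

import numpy as np
from lxml import etree
from scipy import ndimage as ndi

from .io_formats import FishqError, _SCHEMA_DIR
from .preprocess import DAPI, FITC, RHODAMINE, ChannelImage, ZStack


class PackingError(FishqError):
    """Requested scene cannot be packed (too many nuclei or spots)."""


@dataclass
class SimParams:
    """Scene parameters for one synthetic TMA core.

    Intensities are relative (fractions of the dynamic range) and quantized
    to ``bit_depth`` on output.  ``snr`` is the ratio of signal amplitude
    (plateau or spot peak above background) to the additive noise sigma.
    Nucleus centers keep a separation of at least ``separation_factor`` times
    the maximum radius; spots within one channel of one nucleus keep
    ``spot_min_sep_px`` so the detector's connected-component logic can
    resolve them.
    """

    image_px: tuple[int, int] = (512, 512)
    n_nuclei: int = 40
    radius_px_range: tuple[float, float] = (12.0, 16.0)
    amplified_frac: float = 0.5
    normal_red: int = 2
    normal_green: int = 2
    amplified_red_range: tuple[int, int] = (6, 9)
    spot_sigma_px: float = 1.5
    snr: float = 10.0
    background_level: float = 0.05
    nucleus_level: float = 0.55
    spot_amplitude: float = 0.5
    border_width_px: float = 1.5
    n_planes: int = 5
    z_step_um: float = 0.8
    defocus_sigma_px: float = 2.0
    separation_factor: float = 3.0
    spot_min_sep_px: float = 6.0
    spot_region_frac: float = 0.8
    bit_depth: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.amplified_frac <= 1.0:
            raise ValueError("amplified_frac must lie in [0, 1]")
        for name, (lo, hi) in (
            ("radius_px_range", self.radius_px_range),
            ("amplified_red_range", self.amplified_red_range),
        ):
            if lo > hi:
                raise ValueError(f"{name} bounds unordered")
        if self.n_planes < 1:
            raise ValueError("n_planes must be >= 1")
        if self.snr <= 0:
            raise ValueError("snr must be positive")


@dataclass
class TrueNucleus:
    """Planted ground truth for one nucleus."""

    label: int
    center: tuple[float, float]      # (row, col)
    radius_px: float
    cls: str                         # "normal" | "amplified"
    red_count: int
    green_count: int
    spots: dict[str, list[tuple[float, float]]]
    sharp_plane: int


@dataclass
class GroundTruth:
    """Exhaustive planted truth for one synthetic core."""

    core_id: str
    seed: int
    nuclei: list[TrueNucleus] = field(default_factory=list)

    @property
    def n_nuclei(self) -> int:
        return len(self.nuclei)

    @property
    def n_amplified(self) -> int:
        return sum(1 for n in self.nuclei if n.cls == "amplified")

    @property
    def n_normal(self) -> int:
        return sum(1 for n in self.nuclei if n.cls == "normal")

    @property
    def total_red(self) -> int:
        return sum(n.red_count for n in self.nuclei)

    @property
    def total_green(self) -> int:
        return sum(n.green_count for n in self.nuclei)


def simulate_core(params: SimParams, core_id: str = "core-1") -> tuple[dict[str, ZStack], GroundTruth]:
    """Render one synthetic core; returns per-channel Z-stacks plus truth.

    Output is ``{"DAPI": ZStack, "FITC": ZStack, "RHODAMINE": ZStack}``.
    Identical parameters (including the seed) give byte-identical stacks.
    """
    rng = np.random.default_rng(params.seed)
    h, w = params.image_px
    r_lo, r_hi = params.radius_px_range

    centers = _place_nuclei(params, rng)
    radii = [float(r) for r in rng.uniform(r_lo, r_hi, size=len(centers))]

    n_amp = round(params.n_nuclei * params.amplified_frac)
    order = rng.permutation(params.n_nuclei)
    amplified = np.zeros(params.n_nuclei, dtype=bool)
    amplified[order[:n_amp]] = True

    truth = GroundTruth(core_id=core_id, seed=params.seed)
    for i, ((cy, cx), radius) in enumerate(zip(centers, radii)):
        if amplified[i]:
            red = int(rng.integers(params.amplified_red_range[0],
                                   params.amplified_red_range[1] + 1))
            cls = "amplified"
        else:
            red = params.normal_red
            cls = "normal"
        green = params.normal_green
        region = params.spot_region_frac * radius
        spots = {
            RHODAMINE: _place_spots(cy, cx, region, red, params.spot_min_sep_px, rng),
            FITC: _place_spots(cy, cx, region, green, params.spot_min_sep_px, rng),
        }
        truth.nuclei.append(TrueNucleus(
            label=i + 1, center=(cy, cx), radius_px=radius, cls=cls,
            red_count=red, green_count=green, spots=spots,
            sharp_plane=int(rng.integers(params.n_planes)),
        ))

    amp = params.nucleus_level - params.background_level
    noise_sigma = amp / params.snr
    spot_noise_sigma = params.spot_amplitude / params.snr

    stacks: dict[str, ZStack] = {}
    for channel in (DAPI, FITC, RHODAMINE):
        planes = []
        for z in range(params.n_planes):
            field_img = np.full((h, w), params.background_level)
            for nuc in truth.nuclei:
                blur = params.defocus_sigma_px * abs(z - nuc.sharp_plane)
                if channel == DAPI:
                    _add_nucleus(field_img, nuc, amp, params.border_width_px, blur)
                else:
                    for (sy, sx) in nuc.spots[channel]:
                        _add_spot(field_img, sy, sx, params.spot_amplitude,
                                  params.spot_sigma_px, blur)
            sigma = noise_sigma if channel == DAPI else spot_noise_sigma
            field_img += rng.normal(0.0, sigma, size=(h, w))
            planes.append(_quantize(field_img, params.bit_depth, channel))
        stacks[channel] = ZStack(planes, channel=channel, z_step_um=params.z_step_um)
    return stacks, truth


def _place_nuclei(params: SimParams, rng: np.random.Generator) -> list[tuple[float, float]]:
    """Jittered-grid placement guaranteeing the separation constraint.

    Grid pitch is ``separation_factor * r_max`` plus twice the jitter
    amplitude, so even worst-case jitter keeps center distances at or above
    ``separation_factor * r_max``.  Raises :class:`PackingError` when the
    field has fewer grid sites than requested nuclei.
    """
    h, w = params.image_px
    r_max = params.radius_px_range[1]
    jitter = 3.0
    pitch = ceil(params.separation_factor * r_max + 2 * jitter)
    margin = ceil(r_max + 2 * jitter + 4)
    rows = np.arange(margin, h - margin + 1e-9, pitch)
    cols = np.arange(margin, w - margin + 1e-9, pitch)
    sites = [(r, c) for r in rows for c in cols]
    if len(sites) < params.n_nuclei:
        raise PackingError(
            f"cannot place {params.n_nuclei} nuclei of radius <= {r_max} "
            f"with separation {params.separation_factor}x on a {h}x{w} field "
            f"({len(sites)} sites available)"
        )
    chosen = rng.choice(len(sites), size=params.n_nuclei, replace=False)
    return [
        (float(sites[i][0] + rng.uniform(-jitter, jitter)),
         float(sites[i][1] + rng.uniform(-jitter, jitter)))
        for i in chosen
    ]


def _place_spots(cy: float, cx: float, region_radius: float, count: int,
                 min_sep: float, rng: np.random.Generator,
                 restarts: int = 200, darts: int = 400) -> list[tuple[float, float]]:
    """Uniform points in a disk with pairwise minimum separation.

    Greedy dart throwing can wedge itself into an unfinishable configuration
    near the packing limit, so failed attempts restart from scratch; only
    after ``restarts`` exhausted attempts is the request declared infeasible.
    """
    for _ in range(restarts):
        pts: list[tuple[float, float]] = []
        for _ in range(darts):
            rad = region_radius * np.sqrt(rng.uniform())
            ang = rng.uniform(0.0, 2.0 * np.pi)
            y, x = cy + rad * np.sin(ang), cx + rad * np.cos(ang)
            if all((y - py) ** 2 + (x - px) ** 2 >= min_sep**2 for py, px in pts):
                pts.append((float(y), float(x)))
                if len(pts) == count:
                    return pts
    raise PackingError(
        f"cannot place {count} spots with separation {min_sep} px "
        f"in a disk of radius {region_radius:.1f} px"
    )


def _patch_window(center: float, half: int, size: int) -> tuple[int, int]:
    lo = max(0, int(np.floor(center)) - half)
    hi = min(size, int(np.ceil(center)) + half + 1)
    return lo, hi


def _add_nucleus(img: np.ndarray, nuc: TrueNucleus, amplitude: float,
                 border_w: float, blur: float) -> None:
    """Render one nucleus (plateau + sigmoidal border), optionally defocused."""
    h, w = img.shape
    half = int(ceil(nuc.radius_px + 4 * border_w + 3 * blur + 2))
    y0, y1 = _patch_window(nuc.center[0], half, h)
    x0, x1 = _patch_window(nuc.center[1], half, w)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    r = np.hypot(yy - nuc.center[0], xx - nuc.center[1])
    patch = amplitude / (1.0 + np.exp((r - nuc.radius_px) / border_w))
    if blur > 0:
        patch = ndi.gaussian_filter(patch, blur, mode="constant")
    img[y0:y1, x0:x1] += patch


def _add_spot(img: np.ndarray, sy: float, sx: float, amplitude: float,
              sigma: float, blur: float) -> None:
    """Render one Gaussian punctum; defocus widens it analytically."""
    sig_eff = np.sqrt(sigma**2 + blur**2)
    amp_eff = amplitude * sigma**2 / sig_eff**2  # energy-preserving widening
    h, w = img.shape
    half = int(ceil(4 * sig_eff + 1))
    y0, y1 = _patch_window(sy, half, h)
    x0, x1 = _patch_window(sx, half, w)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    d2 = (yy - sy) ** 2 + (xx - sx) ** 2
    img[y0:y1, x0:x1] += amp_eff * np.exp(-d2 / (2.0 * sig_eff**2))


def _quantize(field_img: np.ndarray, bit_depth: int, channel: str) -> ChannelImage:
    max_val = 2**bit_depth - 1
    dtype = np.uint8 if bit_depth == 8 else np.uint16
    arr = np.rint(np.clip(field_img, 0.0, 1.0) * max_val).astype(dtype)
    return ChannelImage(arr, bit_depth=bit_depth, channel=channel)


# ---------------------------------------------------------------------------
# Ground-truth XML
# ---------------------------------------------------------------------------

def truth_schema() -> etree.XMLSchema:
    return etree.XMLSchema(etree.parse(str(_SCHEMA_DIR / "truth.xsd")))


def write_ground_truth(gt: GroundTruth, path) -> None:
    """Write planted truth (per-nucleus classes, counts, spot positions) as XML."""
    root = etree.Element(
        "truth",
        core_id=gt.core_id,
        n_nuclei=str(gt.n_nuclei),
        n_normal=str(gt.n_normal),
        n_amplified=str(gt.n_amplified),
        total_red=str(gt.total_red),
        total_green=str(gt.total_green),
        seed=str(gt.seed),
    )
    for nuc in gt.nuclei:
        n_el = etree.SubElement(
            root, "nucleus",
            id=str(nuc.label),
            row=repr(nuc.center[0]), col=repr(nuc.center[1]),
            radius_px=repr(nuc.radius_px),
            red=str(nuc.red_count), green=str(nuc.green_count),
            sharp_plane=str(nuc.sharp_plane),
            **{"class": nuc.cls},
        )
        for channel in (RHODAMINE, FITC):
            for (sy, sx) in nuc.spots.get(channel, []):
                etree.SubElement(n_el, "spot", channel=channel,
                                 row=repr(sy), col=repr(sx))
    truth_schema().assertValid(root)
    etree.ElementTree(root).write(
        str(path), pretty_print=True, xml_declaration=True, encoding="UTF-8"
    )


def read_ground_truth(path) -> GroundTruth:
    path = Path(path)
    root = etree.parse(str(path)).getroot()
    gt = GroundTruth(core_id=root.get("core_id"), seed=int(root.get("seed")))
    for n_el in root.iter("nucleus"):
        spots: dict[str, list[tuple[float, float]]] = {RHODAMINE: [], FITC: []}
        for s_el in n_el.iter("spot"):
            spots[s_el.get("channel")].append(
                (float(s_el.get("row")), float(s_el.get("col"))))
        gt.nuclei.append(TrueNucleus(
            label=int(n_el.get("id")),
            center=(float(n_el.get("row")), float(n_el.get("col"))),
            radius_px=float(n_el.get("radius_px")),
            cls=n_el.get("class"),
            red_count=int(n_el.get("red")),
            green_count=int(n_el.get("green")),
            spots=spots,
            sharp_plane=int(n_el.get("sharp_plane")),
        ))
    return gt
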