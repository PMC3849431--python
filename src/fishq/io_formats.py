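"""File formats: channel TIFF stacks, the MISP profile XML and results XML.

The segmentation profile ("MISP", microscopical image segmentation profile)
collects every tunable of the pipeline: nucleus morphology bounds, contrast
enhancement settings, per-channel spot thresholds and the HER2/CEP17 ratio
cut-offs.  It serializes to a small XML document and round-trips losslessly.

Image input is deliberately plain: single- or multi-page grayscale TIFF
(8- or 16-bit), one file per channel, one page per focus plane.  Results are
written to an XML document with one ``<core>`` element per TMA core and one
``<nucleus>`` child per scored nucleus; the schema ships as an XSD.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile
from lxml import etree

from .preprocess import CHANNELS, ChannelImage, ZStack

logger = logging.getLogger(__name__)

_SCHEMA_DIR = Path(__file__).parent / "schemas"


class FishqError(Exception):
    """Base class for package errors."""


class ImageFormatError(FishqError):
    """The image file is not a grayscale single/multi-page TIFF."""


class ProfileError(FishqError):
    """The MISP profile is malformed or violates an invariant."""


class ResultsError(FishqError):
    """Results are inconsistent or the results XML is malformed."""


# ---------------------------------------------------------------------------
# MISP profile
# ---------------------------------------------------------------------------

@dataclass
class SpotChannelParams:
    """Spot-detection settings for one probe channel.

    ``threshold`` is relative: the binarization cut is
    ``threshold x (99.9th percentile of the amplified nonzero intensities)``,
    so it adapts to slide brightness.  ``area_px2`` bounds the accepted
    component size; components whose centroids fall within ``merge_dist_px``
    are merged into one signal.
    """

    threshold: float = 0.5
    area_px2: tuple[float, float] = (2.0, 60.0)
    merge_dist_px: float = 2.0

    def validate(self) -> None:
        if not 0.0 <= self.threshold <= 1.0:
            raise ProfileError(f"spot threshold {self.threshold} outside [0, 1]")
        lo, hi = self.area_px2
        if lo > hi:
            raise ProfileError(f"spot area bounds {self.area_px2} unordered")
        if self.merge_dist_px < 0:
            raise ProfileError("merge_dist_px must be >= 0")


@dataclass
class MISPProfile:
    """Segmentation profile: every pipeline parameter in one object.

    Shipped defaults are working values for the bundled simulator's imaging
    geometry (40x/0.95 NA-like sampling); they are not canonical clinical
    settings and real slides need their own profile.
    """

    nucleus_radius_px: tuple[float, float] = (8.0, 30.0)
    nucleus_area_px2: tuple[float, float] = (150.0, 3000.0)
    min_circularity: float = 0.75
    min_border_slope: float = 0.02
    contrast_tile_px: int = 64
    contrast_clip: float = 2.0
    spots: dict[str, SpotChannelParams] = field(
        default_factory=lambda: {
            "FITC": SpotChannelParams(),
            "RHODAMINE": SpotChannelParams(),
        }
    )
    ratio_amplified: float = 2.0
    ratio_normal_band: tuple[float, float] = (0.8, 1.25)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name, (lo, hi) in (
            ("nucleus_radius_px", self.nucleus_radius_px),
            ("nucleus_area_px2", self.nucleus_area_px2),
        ):
            if lo > hi:
                raise ProfileError(f"{name} bounds ({lo}, {hi}) unordered")
        if not 0.0 <= self.min_circularity <= 1.0:
            raise ProfileError(
                f"min_circularity {self.min_circularity} outside [0, 1]"
            )
        if self.min_border_slope < 0:
            raise ProfileError("min_border_slope must be >= 0")
        if self.contrast_tile_px < 1:
            raise ProfileError("contrast_tile_px must be a positive integer")
        if not self.contrast_clip > 0:
            raise ProfileError("contrast_clip must be positive")
        for ch, sp in self.spots.items():
            if ch not in ("FITC", "RHODAMINE"):
                raise ProfileError(f"unknown spot channel {ch!r}")
            sp.validate()
        if not self.ratio_amplified > 0:
            raise ProfileError("ratio_amplified must be positive")
        lo, hi = self.ratio_normal_band
        if lo > hi or not (lo <= 1.0 <= hi):
            raise ProfileError(
                f"ratio_normal_band ({lo}, {hi}) must be ordered and contain 1"
            )

    def copy(self, **changes) -> "MISPProfile":
        return replace(self, **changes)


def profile_to_xml(profile: MISPProfile) -> etree._Element:
    root = etree.Element("misp", version="1")
    r0, r1 = profile.nucleus_radius_px
    a0, a1 = profile.nucleus_area_px2
    etree.SubElement(
        root, "nucleus",
        radius_min=repr(r0), radius_max=repr(r1),
        area_min=repr(a0), area_max=repr(a1),
        min_circularity=repr(profile.min_circularity),
        min_border_slope=repr(profile.min_border_slope),
    )
    etree.SubElement(
        root, "contrast",
        tile_px=str(profile.contrast_tile_px),
        clip=repr(profile.contrast_clip),
    )
    spots = etree.SubElement(root, "spots")
    for ch in ("FITC", "RHODAMINE"):
        sp = profile.spots[ch]
        etree.SubElement(
            spots, "channel", name=ch,
            threshold=repr(sp.threshold),
            area_min=repr(sp.area_px2[0]), area_max=repr(sp.area_px2[1]),
            merge_dist_px=repr(sp.merge_dist_px),
        )
    etree.SubElement(
        root, "classify",
        ratio_amplified=repr(profile.ratio_amplified),
        normal_lo=repr(profile.ratio_normal_band[0]),
        normal_hi=repr(profile.ratio_normal_band[1]),
    )
    return root


def write_misp_profile(profile: MISPProfile, path) -> None:
    tree = etree.ElementTree(profile_to_xml(profile))
    tree.write(str(path), pretty_print=True, xml_declaration=True, encoding="UTF-8")


def _attr(el: etree._Element, name: str, default=None, cast=float):
    raw = el.get(name)
    if raw is None:
        if default is None:
            raise ProfileError(
                f"<{el.tag}> is missing required attribute {name!r}"
            )
        return default
    try:
        return cast(raw)
    except ValueError as exc:
        raise ProfileError(f"bad value for {el.tag}/@{name}: {raw!r}") from exc


def read_misp_profile(path) -> MISPProfile:
    """Parse a MISP profile XML file.

    Optional elements take the documented defaults; unknown elements are
    ignored with a logged warning (forward compatibility); a missing
    required element or an out-of-range value raises :class:`ProfileError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        root = etree.parse(str(path)).getroot()
    except etree.XMLSyntaxError as exc:
        raise ProfileError(f"malformed profile XML: {exc}") from exc
    if root.tag != "misp":
        raise ProfileError(f"root element is <{root.tag}>, expected <misp>")

    defaults = MISPProfile()
    kwargs: dict = {}
    spots: dict[str, SpotChannelParams] = {}
    for el in root:
        if el.tag == "nucleus":
            kwargs["nucleus_radius_px"] = (
                _attr(el, "radius_min"), _attr(el, "radius_max"))
            kwargs["nucleus_area_px2"] = (
                _attr(el, "area_min"), _attr(el, "area_max"))
            kwargs["min_circularity"] = _attr(el, "min_circularity")
            kwargs["min_border_slope"] = _attr(
                el, "min_border_slope", defaults.min_border_slope)
        elif el.tag == "contrast":
            kwargs["contrast_tile_px"] = _attr(
                el, "tile_px", defaults.contrast_tile_px, cast=int)
            kwargs["contrast_clip"] = _attr(el, "clip", defaults.contrast_clip)
        elif el.tag == "spots":
            for ch_el in el:
                if ch_el.tag != "channel":
                    logger.warning("ignoring unknown element <%s> in <spots>", ch_el.tag)
                    continue
                name = ch_el.get("name")
                if name not in ("FITC", "RHODAMINE"):
                    raise ProfileError(f"unknown spot channel name {name!r}")
                d = SpotChannelParams()
                spots[name] = SpotChannelParams(
                    threshold=_attr(ch_el, "threshold"),
                    area_px2=(_attr(ch_el, "area_min", d.area_px2[0]),
                              _attr(ch_el, "area_max", d.area_px2[1])),
                    merge_dist_px=_attr(ch_el, "merge_dist_px", d.merge_dist_px),
                )
        elif el.tag == "classify":
            kwargs["ratio_amplified"] = _attr(el, "ratio_amplified")
            kwargs["ratio_normal_band"] = (
                _attr(el, "normal_lo"), _attr(el, "normal_hi"))
        else:
            logger.warning("ignoring unknown profile element <%s>", el.tag)
    if spots:
        for ch in ("FITC", "RHODAMINE"):
            spots.setdefault(ch, SpotChannelParams())
        kwargs["spots"] = spots
    return MISPProfile(**kwargs)


# ---------------------------------------------------------------------------
# Channel images
# ---------------------------------------------------------------------------

def read_channel_stack(path, channel: str, z_step_um: float | None = None) -> ZStack:
    """Read a single- or multi-page grayscale TIFF as a Z-stack.

    Pages become planes in file order; intensities are preserved bit-exactly.
    RGB/multi-sample pages, mixed page dimensions and non-8/16-bit data each
    raise :class:`ImageFormatError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if channel not in CHANNELS:
        raise ValueError(f"unknown channel {channel!r}")
    try:
        with tifffile.TiffFile(str(path)) as tif:
            pages = [p.asarray() for p in tif.pages]
    except (tifffile.TiffFileError, ValueError) as exc:
        raise ImageFormatError(f"{path} is not a readable TIFF: {exc}") from exc
    if not pages:
        raise ImageFormatError(f"{path} contains no pages")
    planes = []
    shape0 = pages[0].shape
    for i, arr in enumerate(pages):
        if arr.ndim != 2:
            raise ImageFormatError(
                f"page {i} of {path} has {arr.ndim} dimensions; "
                "expected single-sample grayscale"
            )
        if arr.shape != shape0:
            raise ImageFormatError(
                f"page {i} of {path} has shape {arr.shape}, expected {shape0}"
            )
        if arr.dtype == np.uint8:
            depth = 8
        elif arr.dtype == np.uint16:
            depth = 16
        else:
            raise ImageFormatError(
                f"page {i} of {path} has dtype {arr.dtype}; expected uint8/uint16"
            )
        planes.append(ChannelImage(arr, bit_depth=depth, channel=channel))
    return ZStack(planes, channel=channel, z_step_um=z_step_um)


def write_channel_stack(stack: ZStack, path) -> None:
    """Write a Z-stack as a multi-page grayscale TIFF (one page per plane)."""
    tifffile.imwrite(str(path), stack.as_array(), photometric="minisblack")


# ---------------------------------------------------------------------------
# Results
# ---------------------------------------------------------------------------

@dataclass
class CoreResult:
    """Per-TMA-core aggregate of the nucleus classification.

    ``std40_*`` re-express the normal/amplified split on the guideline scale
    of 40 evaluated cells per core; they are ``None`` when no nucleus was
    classifiable (all artifact or none detected).
    """

    core_id: str
    n_detected: int
    n_normal: int
    n_amplified: int
    n_artifact: int
    std40_normal: float | None = None
    std40_amplified: float | None = None

    def __post_init__(self) -> None:
        if self.n_normal + self.n_amplified + self.n_artifact != self.n_detected:
            raise ResultsError(
                f"core {self.core_id!r}: class counts "
                f"({self.n_normal}+{self.n_amplified}+{self.n_artifact}) "
                f"do not partition n_detected={self.n_detected}"
            )


def results_schema() -> etree.XMLSchema:
    return etree.XMLSchema(etree.parse(str(_SCHEMA_DIR / "results.xsd")))


def write_results_xml(results, nuclei, path, validate: bool = True) -> None:
    """Write per-core aggregates plus per-nucleus scores to results XML.

    ``results`` is a non-empty list of :class:`CoreResult`; each entry in
    ``nuclei`` (:class:`fishq.scoring.NucleusScore`) must reference a core_id
    present in ``results``.
    """
    if not results:
        raise ResultsError("results list is empty")
    by_core: dict[str, list] = {r.core_id: [] for r in results}
    if len(by_core) != len(results):
        raise ResultsError("duplicate core_id in results")
    for ns in nuclei:
        if ns.core_id not in by_core:
            raise ResultsError(
                f"nucleus {ns.nucleus_label} references unknown core "
                f"{ns.core_id!r}"
            )
        by_core[ns.core_id].append(ns)

    root = etree.Element("fishquant")
    for r in results:
        attrs = {
            "id": r.core_id,
            "n_detected": str(r.n_detected),
            "n_normal": str(r.n_normal),
            "n_amplified": str(r.n_amplified),
            "n_artifact": str(r.n_artifact),
        }
        if r.std40_normal is not None:
            attrs["std40_normal"] = repr(r.std40_normal)
            attrs["std40_amplified"] = repr(r.std40_amplified)
        core_el = etree.SubElement(root, "core", **attrs)
        for ns in by_core[r.core_id]:
            etree.SubElement(
                core_el, "nucleus",
                id=str(ns.nucleus_label),
                cx=repr(float(ns.cx)), cy=repr(float(ns.cy)),
                area=repr(float(ns.area_px2)),
                circularity=repr(float(ns.circularity)),
                red=str(ns.red_count), green=str(ns.green_count),
                **{"class": ns.cls},
            )
    if validate:
        results_schema().assertValid(root)
    etree.ElementTree(root).write(
        str(path), pretty_print=True, xml_declaration=True, encoding="UTF-8"
    )


def read_results_xml(path) -> tuple[list[CoreResult], list]:
    """Parse a results XML back into (CoreResult list, NucleusScore list)."""
    from .scoring import NucleusScore  # deferred: scoring imports this module

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        root = etree.parse(str(path)).getroot()
    except etree.XMLSyntaxError as exc:
        raise ResultsError(f"malformed results XML: {exc}") from exc
    if root.tag != "fishquant":
        raise ResultsError(f"root element is <{root.tag}>, expected <fishquant>")
    results: list[CoreResult] = []
    nuclei: list[NucleusScore] = []
    for core_el in root.iter("core"):
        std40n = core_el.get("std40_normal")
        std40a = core_el.get("std40_amplified")
        cid = core_el.get("id")
        results.append(CoreResult(
            core_id=cid,
            n_detected=int(core_el.get("n_detected")),
            n_normal=int(core_el.get("n_normal")),
            n_amplified=int(core_el.get("n_amplified")),
            n_artifact=int(core_el.get("n_artifact")),
            std40_normal=None if std40n is None else float(std40n),
            std40_amplified=None if std40a is None else float(std40a),
        ))
        for n_el in core_el.iter("nucleus"):
            red = int(n_el.get("red"))
            green = int(n_el.get("green"))
            nuclei.append(NucleusScore(
                nucleus_label=int(n_el.get("id")),
                red_count=red, green_count=green,
                ratio=(red / green) if green else None,
                cls=n_el.get("class"),
                core_id=cid,
                cx=float(n_el.get("cx")), cy=float(n_el.get("cy")),
                area_px2=float(n_el.get("area")),
                circularity=float(n_el.get("circularity")),
            ))
    return results, nuclei
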