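"""End-to-end quantification: stacks in, per-nucleus scores and core result out.

Channel handling follows the asymmetry of the data: the DAPI stack is fused
by local-sharpness selection (preserves nuclear texture) and then contrast
enhanced before segmentation, while the probe channels are fused by
per-pixel maximum (no punctum can be lost) and thresholded on raw fused
intensity, because adaptive equalization would distort relative spot
brightness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .io_formats import CoreResult, MISPProfile
from .nuclei import LabelMask, NucleusObject, segment_nuclei
from .preprocess import DAPI, FITC, RHODAMINE, ZStack, extended_focus, local_contrast_enhance
from .scoring import NucleusScore, score_nuclei, summarize_core
from .spots import Spot, assign_spots, count_spots_per_nucleus, detect_spots


@dataclass
class QuantResult:
    """Everything the pipeline produced for one core."""

    core_id: str
    core_result: CoreResult
    scores: list[NucleusScore]
    mask: LabelMask
    nuclei: list[NucleusObject]
    spots: dict[str, list[Spot]] = field(default_factory=dict)

    def nucleus_table(self) -> pd.DataFrame:
        """Per-nucleus table: label, counts, ratio, class, morphology."""
        rows = [
            {
                "label": s.nucleus_label,
                "red": s.red_count,
                "green": s.green_count,
                "ratio": s.ratio,
                "class": s.cls,
                "cx": s.cx,
                "cy": s.cy,
                "area_px2": s.area_px2,
                "circularity": s.circularity,
            }
            for s in self.scores
        ]
        return pd.DataFrame(
            rows, columns=["label", "red", "green", "ratio", "class",
                           "cx", "cy", "area_px2", "circularity"],
        )

    def spot_table(self) -> pd.DataFrame:
        rows = [
            {
                "channel": s.channel,
                "row": s.centroid[0],
                "col": s.centroid[1],
                "area_px2": s.area_px2,
                "peak_intensity": s.peak_intensity,
                "nucleus_label": s.nucleus_label,
            }
            for ch in sorted(self.spots) for s in self.spots[ch]
        ]
        return pd.DataFrame(
            rows, columns=["channel", "row", "col", "area_px2",
                           "peak_intensity", "nucleus_label"],
        )


def quantify_core(
    stacks: dict[str, ZStack],
    profile: MISPProfile,
    core_id: str = "core-1",
) -> QuantResult:
    """Run the full pipeline on one core's three channel stacks.

    ``stacks`` maps channel names (DAPI, FITC, RHODAMINE) to Z-stacks.
    Only accepted ("ideal") nuclei are scored; rejected candidates remain
    visible in the mask and object list.
    """
    for ch in (DAPI, FITC, RHODAMINE):
        if ch not in stacks:
            raise ValueError(f"missing {ch} stack")

    dapi = extended_focus(stacks[DAPI], method="local_sharpness")
    dapi = local_contrast_enhance(
        dapi, tile_px=profile.contrast_tile_px, clip=profile.contrast_clip
    )
    mask, objects = segment_nuclei(dapi, profile)
    accepted = [o for o in objects if o.accepted]
    labels = [o.label for o in accepted]

    spots: dict[str, list[Spot]] = {}
    for ch in (FITC, RHODAMINE):
        fused = extended_focus(stacks[ch], method="max")
        spots[ch] = assign_spots(detect_spots(fused, ch, profile), mask)

    red = count_spots_per_nucleus(spots[RHODAMINE], labels)
    green = count_spots_per_nucleus(spots[FITC], labels)
    scores = score_nuclei(red, green, profile, core_id=core_id)

    by_label = {o.label: o for o in accepted}
    for s in scores:
        o = by_label[s.nucleus_label]
        s.cy, s.cx = o.centroid
        s.area_px2 = float(o.area_px2)
        s.circularity = o.circularity

    return QuantResult(
        core_id=core_id,
        core_result=summarize_core(scores, core_id),
        scores=scores,
        mask=mask,
        nuclei=objects,
        spots=spots,
    )


#: Outline colors per class, mirroring the review overlay of the original
#: tool: red = amplified, green = normal, white = artifact/unclassified.
_OVERLAY_COLORS = {"amplified": (1.0, 0.15, 0.15), "normal": (0.15, 1.0, 0.15)}


def save_overlay(dapi_fused, result: QuantResult, path) -> None:
    """Write a debug overlay PNG: nucleus outlines colored by class."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from skimage.segmentation import find_boundaries

    cls_by_label = {s.nucleus_label: s.cls for s in result.scores}
    img = dapi_fused.astype_float() / dapi_fused.max_value
    rgb = img[..., None].repeat(3, axis=2)
    for lab in range(1, result.mask.n_labels + 1):
        edge = find_boundaries(result.mask.labels == lab, mode="outer")
        color = _OVERLAY_COLORS.get(cls_by_label.get(lab), (1.0, 1.0, 1.0))
        rgb[edge] = color
    fig, ax = plt.subplots(figsize=(8, 8))
    ax.imshow(rgb)
    ax.set_axis_off()
    fig.savefig(path, bbox_inches="tight", dpi=150)
    plt.close(fig)
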