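"""Per-nucleus HER2/CEP17 classification and per-core aggregation.

Each accepted nucleus carries a red (HER2, rhodamine) and a green (CEP17,
FITC) signal count.  The classification rule follows dual-probe FISH
convention: a nucleus is *amplified* when the red/green ratio exceeds the
amplification cut-off, *normal* when both probes are present and the ratio
sits inside a symmetric band around 1 ("represented equally"), and
*artifact* otherwise — including every nucleus with a missing probe, since
its ratio is undefined.

The amplification cut-off defaults to 2.0, the clinical HER2 FISH decision
line; the looser literal reading "ratio above one" is a single profile edit
(``ratio_amplified=1.0``).

Core-level counts are also re-expressed on a standardized 40-cells-per-core
scale, the number of nuclei a scoring guideline asks a human to enumerate,
so that cores with very different cellularity become comparable.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io_formats import CoreResult, MISPProfile

NORMAL = "normal"
AMPLIFIED = "amplified"
ARTIFACT = "artifact"
CLASSES = (NORMAL, AMPLIFIED, ARTIFACT)


@dataclass
class NucleusScore:
    """Spot counts and HER2 class for one accepted nucleus."""

    nucleus_label: int
    red_count: int
    green_count: int
    ratio: float | None
    cls: str
    core_id: str = ""
    cx: float = 0.0   # centroid column (x)
    cy: float = 0.0   # centroid row (y)
    area_px2: float = 0.0
    circularity: float = 0.0


def classify_nucleus(red: int, green: int, profile: MISPProfile) -> str:
    """Classify one nucleus from its red (HER2) and green (CEP17) counts."""
    if red < 0 or green < 0:
        raise ValueError("spot counts must be non-negative")
    if green >= 1 and red / green > profile.ratio_amplified:
        return AMPLIFIED
    lo, hi = profile.ratio_normal_band
    if green >= 1 and red >= 1 and lo <= red / green <= hi:
        return NORMAL
    return ARTIFACT


def standardize_to_40(n_normal: int, n_amplified: int) -> tuple[float, float]:
    """Rescale the normal/amplified split to a 40-cell core.

    Returns ``(40*n_normal/(n_normal+n_amplified), 40*n_amplified/...)``;
    the components sum to exactly 40.  Artifact nuclei never enter.
    """
    total = n_normal + n_amplified
    if total < 1:
        raise ValueError("need at least one normal or amplified nucleus")
    return 40.0 * n_normal / total, 40.0 * n_amplified / total


def summarize_core(scores: list[NucleusScore], core_id: str) -> CoreResult:
    """Tally class counts for one core and attach the standardized split.

    With no classifiable (normal or amplified) nucleus the standardized
    fields are left unset.
    """
    n_normal = sum(1 for s in scores if s.cls == NORMAL)
    n_amplified = sum(1 for s in scores if s.cls == AMPLIFIED)
    n_artifact = sum(1 for s in scores if s.cls == ARTIFACT)
    std40_n = std40_a = None
    if n_normal + n_amplified > 0:
        std40_n, std40_a = standardize_to_40(n_normal, n_amplified)
    return CoreResult(
        core_id=core_id,
        n_detected=len(scores),
        n_normal=n_normal,
        n_amplified=n_amplified,
        n_artifact=n_artifact,
        std40_normal=std40_n,
        std40_amplified=std40_a,
    )


def score_nuclei(
    red_counts: dict[int, int],
    green_counts: dict[int, int],
    profile: MISPProfile,
    core_id: str = "",
) -> list[NucleusScore]:
    """Build per-nucleus scores from per-label red/green spot tallies."""
    scores = []
    for label in sorted(set(red_counts) | set(green_counts)):
        red = red_counts.get(label, 0)
        green = green_counts.get(label, 0)
        scores.append(NucleusScore(
            nucleus_label=label,
            red_count=red,
            green_count=green,
            ratio=(red / green) if green else None,
            cls=classify_nucleus(red, green, profile),
            core_id=core_id,
        ))
    return scores
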