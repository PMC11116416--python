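"""Deterministic synthetic fixtures: pellet images, score tables, bioassays.

These generators are the package's test and demo data source.  Each is a
pure function of its spec (including the seed), so identical specs give
byte-identical outputs.

* Pellet images are an unantialiased ellipse of a single blend color
  (gray tinted toward pure sRGB yellow) on a removable background, with
  an optional fraction of foreground pixels painted near-black to mimic
  cracks.  The ground-truth yellowness is the exact pixel-fraction-
  weighted closed-form YI of the constituent solid colors, so any
  discrepancy in the analysis pipeline is attributable to the pipeline,
  not to rendering artifacts.

* Score tables realize requested per-score pellet counts as explicit
  yellowing/cracking flags; summarizing the table recovers the counts
  exactly.

* Bioassays draw larval lengths around a probit-shaped dose-response
  with chosen EC50, slope and noise, matching the assay design of the
  analysis modules (control + dilutions 1, 1/3, 1/10, 1/30; replicate
  vials; 35 measured larvae per vial).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
from PIL import Image
from scipy import stats

from .colorimetry import DEFAULT_ILLUMINANT_OBSERVER, IlluminantObserver, yellowness_of_rgb
from .dose_response import CONTROL, BioassayDataset, Vial
from .weathering import PelletObservation

__all__ = [
    "PelletImageSpec",
    "BioassaySimSpec",
    "make_pellet_image",
    "make_score_table",
    "simulate_bioassay",
]

_PURE_YELLOW = np.array([255.0, 255.0, 0.0])
_CRACK_COLOR = (30, 30, 30)


@dataclass(frozen=True)
class PelletImageSpec:
    """Parameters of one synthetic pellet photograph."""

    width: int = 96
    height: int = 96
    base_gray: int = 220
    yellow_tint: float = 0.0  # blend fraction toward pure sRGB yellow
    crack_fraction: float = 0.0  # fraction of foreground painted near-black
    background: str = "alpha"  # "alpha" or "reference" (white background)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.base_gray <= 255):
            raise ValueError("base_gray must be in [0, 255]")
        if not (0.0 <= self.yellow_tint <= 1.0):
            raise ValueError("yellow_tint must be in [0, 1]")
        if not (0.0 <= self.crack_fraction <= 1.0):
            raise ValueError("crack_fraction must be in [0, 1]")
        if self.background not in ("alpha", "reference"):
            raise ValueError("background must be 'alpha' or 'reference'")
        if self.width < 4 or self.height < 4:
            raise ValueError("image too small for a pellet ellipse")


def _blend_color(spec: PelletImageSpec) -> tuple[int, int, int]:
    base = np.full(3, float(spec.base_gray))
    c = np.rint((1.0 - spec.yellow_tint) * base + spec.yellow_tint * _PURE_YELLOW)
    return tuple(int(v) for v in np.clip(c, 0, 255))


def make_pellet_image(
    spec: PelletImageSpec,
    path: str | os.PathLike | None = None,
    io: IlluminantObserver = DEFAULT_ILLUMINANT_OBSERVER,
) -> tuple[Image.Image, float]:
    """Render a pellet image and return it with its ground-truth %YI.

    The pellet is an ellipse inscribed with a small margin, drawn without
    antialiasing.  Ground truth uses the realized pixel counts:
    ``yi = f_crack * YI(crack color) + (1 - f_crack) * YI(blend color)``.
    When ``path`` is given the image is also written there (PNG keeps the
    alpha channel; JPEG requires the reference background).
    """
    w, h = spec.width, spec.height
    yy, xx = np.mgrid[0:h, 0:w]
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    rx, ry = w * 0.42, h * 0.42
    mask = ((xx - cx) / rx) ** 2 + ((yy - cy) / ry) ** 2 <= 1.0
    n_fg = int(mask.sum())
    if n_fg == 0:
        raise ValueError("spec produces zero foreground pixels")

    blend = _blend_color(spec)
    rgb = np.zeros((h, w, 3), dtype=np.uint8)
    rgb[mask] = blend

    rng = np.random.default_rng(spec.seed)
    fg_idx = np.flatnonzero(mask.ravel())
    n_crack = int(round(spec.crack_fraction * n_fg))
    if n_crack > 0:
        chosen = rng.choice(fg_idx, size=n_crack, replace=False)
        flat = rgb.reshape(-1, 3)
        flat[chosen] = _CRACK_COLOR

    f_crack = n_crack / n_fg
    yi_blend = yellowness_of_rgb(blend, io)
    yi_crack = yellowness_of_rgb(_CRACK_COLOR, io)
    ground_truth_yi = f_crack * yi_crack + (1.0 - f_crack) * yi_blend

    if spec.background == "alpha":
        alpha = np.where(mask, 255, 0).astype(np.uint8)
        img = Image.fromarray(np.dstack([rgb, alpha]), mode="RGBA")
    else:
        rgb[~mask] = (255, 255, 255)
        img = Image.fromarray(rgb, mode="RGB")

    if path is not None:
        img.save(path)
    return img, float(ground_truth_yi)


def make_score_table(
    sample_id: str,
    counts: tuple[int, int, int],
    seed: int = 0,
) -> list[PelletObservation]:
    """Observations realizing exact score counts (n1, n2, n3).

    Score-2 pellets alternate yellowing-only / cracking-only; the row
    order is shuffled by the seed (summaries are order-invariant).
    """
    n1, n2, n3 = counts
    if min(n1, n2, n3) < 0 or n1 + n2 + n3 < 1:
        raise ValueError("counts must be non-negative with at least one pellet")
    flags: list[tuple[bool, bool]] = []
    flags += [(False, False)] * n1
    flags += [((i % 2 == 0), (i % 2 == 1)) for i in range(n2)]
    flags += [(True, True)] * n3
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(flags))
    return [
        PelletObservation(
            sample_id=sample_id,
            pellet_id=f"p{i + 1:03d}",
            yellowing=flags[j][0],
            cracking=flags[j][1],
        )
        for i, j in enumerate(order)
    ]


@dataclass(frozen=True)
class BioassaySimSpec:
    """Parameters of one simulated SET bioassay.

    The expected size increase at dilution d follows the probit model
    fitted by the analysis chain: control_mean_um * (1 - Phi(b0 + b1
    log10 d)) with b0 = -b1 log10(ec50); larval lengths are egg_mean_um
    plus a Normal(expected, sigma_um) draw.  Defaults mirror the assay
    design: four dilutions plus control, 35 measured larvae per vial,
    control growth ~20% above the 253 um acceptability floor.
    """

    ec50: float = 0.33
    slope_b1: float = 1.5
    control_mean_um: float = 304.0
    sigma_um: float = 40.0
    egg_mean_um: float = 95.0
    dilutions: tuple[float, ...] = (1.0, 1 / 3, 1 / 10, 1 / 30)
    vials_per_group: int = 4
    larvae_per_vial: int = 35
    fertilization_pct: float = 98.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ec50 <= 0 or self.slope_b1 <= 0:
            raise ValueError("ec50 and slope_b1 must be positive")
        if self.control_mean_um <= 0 or self.egg_mean_um <= 0:
            raise ValueError("control_mean_um and egg_mean_um must be positive")
        if self.sigma_um < 0:
            raise ValueError("sigma_um must be non-negative")
        if any(not (0 < d <= 1) for d in self.dilutions):
            raise ValueError("dilutions must lie in (0, 1]")
        if self.vials_per_group < 1 or self.larvae_per_vial < 1:
            raise ValueError("need at least one vial and one larva per vial")


def expected_inhibition(spec: BioassaySimSpec, d: float) -> float:
    """Model inhibition at dilution d: Phi(b1 (log10 d - log10 ec50))."""
    return float(stats.norm.cdf(spec.slope_b1 * (np.log10(d) - np.log10(spec.ec50))))


def simulate_bioassay(spec: BioassaySimSpec, sample_id: str = "sim") -> BioassayDataset:
    """Draw a reproducible bioassay dataset from the spec.

    With ``sigma_um = 0`` the per-vial means lie exactly on the
    generating curve, so fit + ECx estimation is an exact round trip.
    """
    rng = np.random.default_rng(spec.seed)
    vials: list[Vial] = []
    groups: list[tuple[float | str, float]] = [(CONTROL, spec.control_mean_um)]
    for d in spec.dilutions:
        mean_inc = spec.control_mean_um * (1.0 - expected_inhibition(spec, d))
        groups.append((float(d), mean_inc))
    for treatment, mean_inc in groups:
        for v in range(spec.vials_per_group):
            noise = rng.normal(0.0, spec.sigma_um, size=spec.larvae_per_vial)
            lengths = spec.egg_mean_um + mean_inc + noise
            label = "c" if treatment == CONTROL else f"d{treatment:g}"
            vials.append(
                Vial(
                    vial_id=f"{label}_v{v + 1}",
                    treatment=treatment,
                    lengths_um=np.maximum(lengths, 1.0),
                )
            )
    return BioassayDataset(
        sample_id=sample_id,
        egg_mean_um=spec.egg_mean_um,
        fertilization_pct=spec.fertilization_pct,
        vials=vials,
    )
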