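"""Synthetic microglia silhouettes.

Generates labeled binary cell masks spanning the four canonical
morphologies (ramified/surveillant, hypertrophied, bushy,
amoeboid/reactive), so the whole measurement and classification pipeline
can be exercised without microscope data.  A cell is a soma (elliptical
disk) plus branches grown as discrete random walks: each branch carries a
heading that receives Gaussian jitter at every one-pixel step
(``tortuosity``), a thickness drawn once and decayed multiplicatively per
step (``taper``), and may spawn shorter, thinner secondary branches.

Reproducibility contract: every cell is rendered from a sub-generator
derived from the cohort master seed and the cell index alone, so any cell
can be regenerated in isolation and cohort generation is order-independent.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage
from skimage import draw

from .imaging import DEFAULT_PIXEL_SIZE_UM, BinaryCellImage, outline_of

__all__ = [
    "ArchetypeSpec",
    "CohortEntry",
    "CohortSpec",
    "SyntheticCell",
    "load_presets",
    "default_cohort",
    "render_cell",
    "generate_cohort",
]

ARCHETYPES = ("ramified", "hypertrophied", "bushy", "amoeboid")


class CanvasError(ValueError):
    """A rendered cell does not fit the requested canvas."""


@dataclass(frozen=True)
class ArchetypeSpec:
    """Geometric recipe for one morphological archetype.

    Two-element tuples are (mean, sd) of a normal draw in micrometres.
    ``n_primary`` is an inclusive integer range of primary branch counts.
    ``tortuosity`` is the sd (radians) of the per-step heading jitter and
    ``taper`` the multiplicative thickness loss per one-pixel step.
    ``soma_axis_ratio`` elongates the soma; 1 means circular.
    """

    name: str
    soma_radius_um: tuple[float, float]
    n_primary: tuple[int, int]
    branch_length_um: tuple[float, float]
    branch_thickness_um: tuple[float, float]
    secondary_branch_prob: float
    tortuosity: float
    taper: float
    soma_axis_ratio: tuple[float, float] = (1.0, 0.0)
    thickness_jitter: float = 0.3

    def __post_init__(self) -> None:
        for label, (mean, sd) in (
            ("soma_radius_um", self.soma_radius_um),
            ("branch_length_um", self.branch_length_um),
            ("branch_thickness_um", self.branch_thickness_um),
        ):
            if mean <= 0 or sd < 0:
                raise ValueError(f"{label} must have positive mean and sd >= 0")
        lo, hi = self.n_primary
        if lo < 0 or hi < lo:
            raise ValueError("n_primary range must satisfy 0 <= lo <= hi")
        if not 0.0 <= self.secondary_branch_prob <= 1.0:
            raise ValueError("secondary_branch_prob must lie in [0, 1]")
        if not 0.0 <= self.taper < 1.0:
            raise ValueError("taper must lie in [0, 1)")
        if self.tortuosity < 0:
            raise ValueError("tortuosity must be >= 0")
        if self.thickness_jitter < 0:
            raise ValueError("thickness_jitter must be >= 0")


@dataclass(frozen=True)
class CohortEntry:
    archetype: ArchetypeSpec
    n_cells: int
    region: str = "unspecified"
    treatment: str = "saline"
    time_h: float = 12.0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")


@dataclass(frozen=True)
class CohortSpec:
    """A batch of cells to generate, with per-entry metadata tags."""

    entries: tuple[CohortEntry, ...]
    image_size_px: int = 768
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("cohort has no entries")
        object.__setattr__(self, "entries", tuple(self.entries))
        if self.image_size_px < 16:
            raise ValueError("image_size_px too small")

    @property
    def n_cells(self) -> int:
        return sum(e.n_cells for e in self.entries)


@dataclass(frozen=True)
class SyntheticCell:
    cell_id: str
    image: BinaryCellImage
    archetype: str
    region: str
    treatment: str
    time_h: float
    cell_index: int  # index used to derive this cell's sub-seed


def load_presets() -> dict[str, ArchetypeSpec]:
    """Archetype presets shipped with the package (see ``presets.yaml``)."""
    text = resources.files(__package__).joinpath("presets.yaml").read_text()
    raw = yaml.safe_load(text)
    presets = {}
    for name, p in raw.items():
        presets[name] = ArchetypeSpec(
            name=name,
            soma_radius_um=tuple(p["soma_radius_um"]),
            n_primary=tuple(p["n_primary"]),
            branch_length_um=tuple(p["branch_length_um"]),
            branch_thickness_um=tuple(p["branch_thickness_um"]),
            secondary_branch_prob=p["secondary_branch_prob"],
            tortuosity=p["tortuosity"],
            taper=p["taper"],
            soma_axis_ratio=tuple(p.get("soma_axis_ratio", (1.0, 0.0))),
            thickness_jitter=p.get("thickness_jitter", 0.3),
        )
    return presets


def default_cohort(seed: int = 42, scale: float = 1.0) -> CohortSpec:
    """The standard four-archetype study cohort (160 cells at scale 1).

    Abundances are unequal on purpose — surveillant forms dominate, the
    reactive form is rarest — so the size-ordered cluster numbering is
    stable.  Metadata tags mirror a region x treatment x time design:
    ramified cells stand in for hippocampal saline microglia, hypertrophied
    for hypothalamic saline, bushy and amoeboid for neuraminidase-injected
    tissue.  ``scale`` shrinks every entry proportionally (minimum 2 cells)
    for quick runs.
    """
    presets = load_presets()
    plan = [
        ("ramified", 60, "hippocampus", "saline", 12.0),
        ("bushy", 45, "septofimbrial", "NA", 4.0),
        ("hypertrophied", 35, "hypothalamus", "saline", 12.0),
        ("amoeboid", 20, "hypothalamus", "NA", 12.0),
    ]
    entries = [
        CohortEntry(presets[a], max(2, int(round(n * scale))), region, treatment, t)
        for a, n, region, treatment, t in plan
    ]
    return CohortSpec(entries=tuple(entries), rng_seed=seed)


def _positive_normal(rng: np.random.Generator, mean: float, sd: float, floor: float) -> float:
    return max(floor, float(rng.normal(mean, sd)))


def _stamp_disk(canvas: np.ndarray, r: float, c: float, radius: float) -> None:
    rr, cc = draw.disk((r, c), max(radius, 0.6), shape=canvas.shape)
    canvas[rr, cc] = True
    # a sub-pixel disk at a half-integer center can miss every pixel
    # center; stamping the rounded center keeps thin branches connected
    ri, ci = int(round(r)), int(round(c))
    if 0 <= ri < canvas.shape[0] and 0 <= ci < canvas.shape[1]:
        canvas[ri, ci] = True


def _grow_branch(
    canvas: np.ndarray,
    rng: np.random.Generator,
    start: tuple[float, float],
    heading: float,
    length_px: float,
    radius_px: float,
    tortuosity: float,
    taper: float,
    thickness_jitter: float = 0.0,
) -> list[tuple[float, float, float]]:
    """Random-walk a branch; returns sampled (row, col, heading) anchor points.

    ``thickness_jitter`` perturbs the stamped radius at every step, giving
    the bumpy membrane outline of stained processes; without it the
    silhouette boundary is unrealistically smooth at the pixel scale.
    """
    r, c = start
    anchors = []
    n_steps = max(1, int(round(length_px)))
    for k in range(n_steps):
        heading += rng.normal(0.0, tortuosity)
        r += np.sin(heading)
        c += np.cos(heading)
        step_radius = max(0.6, radius_px * (1.0 + rng.normal(0.0, thickness_jitter)))
        _stamp_disk(canvas, r, c, step_radius)
        radius_px = max(0.6, radius_px * (1.0 - taper))
        if k % 5 == 0:
            anchors.append((r, c, heading))
    return anchors


def render_cell(
    spec: ArchetypeSpec,
    rng: np.random.Generator,
    image_size_px: int = 768,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
) -> BinaryCellImage:
    """Render one binary silhouette; deterministic given (spec, rng state).

    Raises :class:`CanvasError` naming the violated dimension if the cell
    reaches the canvas border.
    """
    px = pixel_size_um
    canvas = np.zeros((image_size_px, image_size_px), bool)
    center = (image_size_px / 2.0, image_size_px / 2.0)

    soma_r = _positive_normal(rng, *spec.soma_radius_um, floor=2 * px) / px
    axis_ratio = max(1.0, float(rng.normal(*spec.soma_axis_ratio)))
    soma_angle = rng.uniform(0, 2 * np.pi)
    rr, cc = draw.ellipse(
        center[0],
        center[1],
        soma_r * np.sqrt(axis_ratio),
        soma_r / np.sqrt(axis_ratio),
        shape=canvas.shape,
        rotation=soma_angle,
    )
    canvas[rr, cc] = True

    n_primary = int(rng.integers(spec.n_primary[0], spec.n_primary[1] + 1))
    if n_primary > 0:
        base = rng.uniform(0, 2 * np.pi)
        for i in range(n_primary):
            heading = base + 2 * np.pi * i / n_primary + rng.normal(0, 0.25)
            length = _positive_normal(rng, *spec.branch_length_um, floor=px) / px
            thickness = _positive_normal(rng, *spec.branch_thickness_um, floor=px) / px
            # grow from the soma center so the walk is connected regardless
            # of soma elongation; the in-soma portion stamps over the soma
            anchors = _grow_branch(
                canvas, rng, center, heading, length + soma_r, thickness / 2.0,
                spec.tortuosity, spec.taper, spec.thickness_jitter,
            )
            anchors = [a for a in anchors if
                       (a[0] - center[0]) ** 2 + (a[1] - center[1]) ** 2 > soma_r**2]
            # secondaries: up to three Bernoulli chances per primary branch,
            # each secondary may itself spawn one shorter tertiary
            n_secondary = int(rng.binomial(3, spec.secondary_branch_prob))
            for _ in range(n_secondary):
                if not anchors:
                    break
                ar, ac, ah = anchors[rng.integers(len(anchors) // 3, len(anchors))]
                side = 1 if rng.random() < 0.5 else -1
                sec_anchors = _grow_branch(
                    canvas, rng, (ar, ac),
                    ah + side * rng.uniform(0.5, 1.2),
                    length * 0.5, thickness * 0.35,
                    spec.tortuosity, spec.taper, spec.thickness_jitter,
                )
                if sec_anchors and rng.random() < spec.secondary_branch_prob:
                    tr, tc, th = sec_anchors[rng.integers(len(sec_anchors))]
                    tside = 1 if rng.random() < 0.5 else -1
                    _grow_branch(
                        canvas, rng, (tr, tc),
                        th + tside * rng.uniform(0.5, 1.2),
                        length * 0.25, thickness * 0.25,
                        spec.tortuosity, spec.taper, spec.thickness_jitter,
                    )

    if canvas[0, :].any() or canvas[-1, :].any():
        raise CanvasError(
            f"cell touches canvas edge along rows (image_size_px={image_size_px})"
        )
    if canvas[:, 0].any() or canvas[:, -1].any():
        raise CanvasError(
            f"cell touches canvas edge along columns (image_size_px={image_size_px})"
        )

    filled = ndimage.binary_fill_holes(canvas)
    return BinaryCellImage(filled, outline_of(filled), pixel_size_um)


def cell_rng(master_seed: int, cell_index: int) -> np.random.Generator:
    """Counter-based sub-generator: derived from (master seed, index) only."""
    return np.random.default_rng(np.random.SeedSequence([master_seed, cell_index]))


def generate_cohort(cohort: CohortSpec) -> tuple[list[SyntheticCell], pd.DataFrame]:
    """Render every cell of the cohort plus the metadata table skeleton.

    The returned frame has one row per cell (cell_id, archetype, region,
    treatment, time_h, seed) in cohort order; descriptor columns are added
    by the measurement stage.
    """
    cells: list[SyntheticCell] = []
    rows = []
    index = 0
    for entry in cohort.entries:
        for _ in range(entry.n_cells):
            rng = cell_rng(cohort.rng_seed, index)
            image = render_cell(
                entry.archetype, rng, cohort.image_size_px, cohort.pixel_size_um
            )
            cid = f"cell_{index:04d}"
            cells.append(
                SyntheticCell(
                    cell_id=cid,
                    image=image,
                    archetype=entry.archetype.name,
                    region=entry.region,
                    treatment=entry.treatment,
                    time_h=entry.time_h,
                    cell_index=index,
                )
            )
            rows.append(
                {
                    "cell_id": cid,
                    "archetype": entry.archetype.name,
                    "region": entry.region,
                    "treatment": entry.treatment,
                    "time_h": entry.time_h,
                    "seed": cohort.rng_seed,
                }
            )
            index += 1
    return cells, pd.DataFrame(rows).set_index("cell_id")
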