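"""Seedable synthetic monocytic-cell image patches, masks and reviewer panels.

Real blood-smear patches of monocytes, promonocytes and blasts are not
publicly available, so this module renders ellipse-based single-cell patches
whose class structure mirrors the morphological criteria hematopathologists
use: the nucleus-to-cell area ratio grows with immaturity (blast >
promonocyte > monocyte), nuclear folding is strongest in mature monocytes,
and chromatin texture runs from coarse/condensed (monocyte) to fine/delicate
(blast).  Every generated patch comes with a background/cytoplasm/nucleus
mask, a patient id (with small per-patient colour offsets), and — via
:func:`simulate_reviewers` — a simulated 5-expert label panel with
class-confusion noise and one repeat labelling.

All generation is a pure function of (parameters, seed).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_erosion, gaussian_filter

CLASSES: tuple[str, str, str] = ("monocyte", "promonocyte", "blast")

# Class presets, maturity-ordered.  Nucleus area fractions are spaced so the
# three distributions have disjoint supports at jitter <= 0.05 (jitter draws
# multiply by 1 + U(-2j, 2j), see MorphologyParams.jitter).
_PRESETS: dict[str, dict] = {
    "monocyte": dict(
        nucleus_to_cell_area_ratio=0.45,
        nucleus_irregularity=0.30,     # deeply folded / indented nucleus
        chromatin_texture_scale=4.0,   # coarse, condensed chromatin
        chromatin_contrast=0.35,
        base_nucleus_color=(110, 70, 160),
        base_cytoplasm_color=(195, 185, 225),
        cell_radius_px=70.0,
    ),
    "promonocyte": dict(
        nucleus_to_cell_area_ratio=0.62,
        nucleus_irregularity=0.18,     # delicate folding
        chromatin_texture_scale=2.5,
        chromatin_contrast=0.22,
        base_nucleus_color=(120, 80, 170),
        base_cytoplasm_color=(190, 180, 222),
        cell_radius_px=75.0,
    ),
    "blast": dict(
        nucleus_to_cell_area_ratio=0.80,
        nucleus_irregularity=0.06,     # round-to-oval nucleus
        chromatin_texture_scale=1.5,   # fine chromatin
        chromatin_contrast=0.12,
        base_nucleus_color=(130, 90, 180),
        base_cytoplasm_color=(185, 178, 220),
        cell_radius_px=78.0,
    ),
}

_BACKGROUND_COLOR = np.array([244.0, 240.0, 236.0])


@dataclass(frozen=True)
class MorphologyParams:
    """Rendering parameters for one cell class.

    ``jitter`` is a per-parameter coefficient of variation: each jittered
    quantity is multiplied by ``1 + U(-2*jitter, 2*jitter)``, i.e. a bounded
    uniform perturbation with standard deviation ``jitter * 2/sqrt(3)`` of
    the mean.  The bounded support makes class separability provable: at
    jitter <= 0.05 the nucleus-area-fraction supports of the three presets
    do not overlap; at large jitter they do (tunable task difficulty).
    """

    class_label: str
    nucleus_to_cell_area_ratio: float
    nucleus_irregularity: float
    chromatin_texture_scale: float
    chromatin_contrast: float
    base_nucleus_color: tuple[float, float, float]
    base_cytoplasm_color: tuple[float, float, float]
    cell_radius_px: float
    jitter: float = 0.05
    patch_size: int = 200

    def __post_init__(self) -> None:
        if self.class_label not in CLASSES:
            raise ValueError(f"unknown class label {self.class_label!r}")
        if not 0.0 < self.nucleus_to_cell_area_ratio < 1.0:
            raise ValueError("nucleus_to_cell_area_ratio must lie in (0, 1)")
        if self.nucleus_irregularity < 0:
            raise ValueError("nucleus_irregularity must be nonnegative")
        if not 0.0 <= self.chromatin_contrast <= 1.0:
            raise ValueError("chromatin_contrast must lie in [0, 1]")
        if self.jitter < 0:
            raise ValueError("jitter must be nonnegative")
        # the nominal cell must fit the patch; jittered draws are clamped
        # to the patch at render time
        if self.cell_radius_px * 1.1 >= self.patch_size / 2:
            raise ValueError(
                f"cell_radius_px {self.cell_radius_px} too large for "
                f"patch_size {self.patch_size}"
            )


def class_preset(class_label: str, jitter: float = 0.05, patch_size: int = 200) -> MorphologyParams:
    """Return the morphology preset for one of the three monocytic classes."""
    if class_label not in _PRESETS:
        raise ValueError(f"unknown class label {class_label!r}")
    preset = dict(_PRESETS[class_label])
    # presets are calibrated for 200 px patches; scale geometry with patch size
    preset["cell_radius_px"] *= patch_size / 200.0
    return MorphologyParams(
        class_label=class_label, jitter=jitter, patch_size=patch_size, **preset
    )


@dataclass
class CellRecord:
    """One cell: image patch, tri-level mask, identity and labels.

    ``mask`` uses 0 = background, 1 = cytoplasm, 2 = nucleus; nucleus pixels
    are a subset of the (single, connected) cell region.
    """

    cell_id: str
    patient_id: str
    image: np.ndarray          # H x W x 3 uint8
    mask: np.ndarray           # H x W uint8 over {0, 1, 2}
    true_label: str
    reviewer_labels: list[str] | None = None
    repeat_label: str | None = None
    consensus_label: str | None = None


@dataclass(frozen=True)
class ReviewerModel:
    """Noise model for a panel of expert reviewers.

    Each reviewer has a row-stochastic confusion matrix P(assigned | true)
    over the maturity-ordered classes.  One designated reviewer labels the
    cells a second time; ``repeat_consistency`` is the probability that the
    second label simply copies the first (otherwise it is redrawn from the
    reviewer's confusion row).
    """

    confusion_matrices: np.ndarray          # n_reviewers x 3 x 3
    repeat_reviewer_index: int = 4
    repeat_consistency: float = 0.9

    def __post_init__(self) -> None:
        cm = np.asarray(self.confusion_matrices, dtype=float)
        if cm.ndim != 3 or cm.shape[1:] != (3, 3):
            raise ValueError("confusion_matrices must have shape (n_reviewers, 3, 3)")
        if np.any(cm < 0) or not np.allclose(cm.sum(axis=2), 1.0, atol=1e-9):
            raise ValueError("each confusion-matrix row must be nonnegative and sum to 1")
        if not 0 <= self.repeat_reviewer_index < cm.shape[0]:
            raise ValueError("repeat_reviewer_index out of range")
        if not 0.0 <= self.repeat_consistency <= 1.0:
            raise ValueError("repeat_consistency must lie in [0, 1]")
        object.__setattr__(self, "confusion_matrices", cm)

    @property
    def n_reviewers(self) -> int:
        return self.confusion_matrices.shape[0]

    @classmethod
    def identity(cls, n_reviewers: int = 5, **kw) -> "ReviewerModel":
        return cls(np.tile(np.eye(3), (n_reviewers, 1, 1)), **kw)

    @classmethod
    def uniform_noise(cls, noise: float, n_reviewers: int = 5, **kw) -> "ReviewerModel":
        """Reviewers correct w.p. 1-noise, otherwise uniform over the other classes."""
        cm = np.full((3, 3), noise / 2.0)
        np.fill_diagonal(cm, 1.0 - noise)
        return cls(np.tile(cm, (n_reviewers, 1, 1)), **kw)


def _jittered(value: float, jitter: float, rng: np.random.Generator) -> float:
    if jitter == 0:
        return value
    return value * (1.0 + rng.uniform(-2.0 * jitter, 2.0 * jitter))


def _texture(shape: tuple[int, int], scale: float, rng: np.random.Generator) -> np.ndarray:
    """Band-limited noise in [-1, 1]: white noise smoothed at the given scale."""
    noise = gaussian_filter(rng.standard_normal(shape), sigma=max(scale, 0.5))
    peak = np.abs(noise).max()
    return noise / peak if peak > 0 else noise


def generate_cell(
    params: MorphologyParams,
    rng_seed: int | np.random.Generator,
    cell_id: str = "cell_0000",
    patient_id: str = "patient_00",
    color_offset: np.ndarray | None = None,
) -> CellRecord:
    """Render one synthetic cell patch with its cytoplasm/nucleus mask.

    The cell is an ellipse; the nucleus boundary is a sinusoidally folded
    closed curve whose enclosed area matches the (jittered) nucleus-to-cell
    area ratio, clipped to the eroded cell so a cytoplasmic rim survives.
    Deterministic given the seed; ``color_offset`` carries per-patient
    illumination/stain shifts (RGB, added before quantisation).
    """
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    size = params.patch_size

    ratio = float(np.clip(_jittered(params.nucleus_to_cell_area_ratio, params.jitter, rng), 0.02, 0.97))
    irregularity = max(_jittered(params.nucleus_irregularity, params.jitter, rng), 0.0)
    tex_scale = max(_jittered(params.chromatin_texture_scale, params.jitter, rng), 0.5)
    contrast = float(np.clip(_jittered(params.chromatin_contrast, params.jitter, rng), 0.0, 1.0))
    radius = min(_jittered(params.cell_radius_px, params.jitter, rng), 0.44 * size)

    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    cx = size / 2 + rng.uniform(-0.03, 0.03) * size
    cy = size / 2 + rng.uniform(-0.03, 0.03) * size

    # cell: mildly eccentric rotated ellipse
    ecc = rng.uniform(0.85, 1.0)
    a, b = radius, radius * ecc
    phi = rng.uniform(0, np.pi)
    xr = (xx - cx) * np.cos(phi) + (yy - cy) * np.sin(phi)
    yr = -(xx - cx) * np.sin(phi) + (yy - cy) * np.cos(phi)
    cell = (xr / a) ** 2 + (yr / b) ** 2 <= 1.0

    # nucleus: folded closed curve r(theta) = r0 * (1 + A sin(k theta + phase)),
    # enclosed area pi r0^2 (1 + A^2/2) solved for r0 to hit the target ratio
    cell_area = cell.sum()
    fold_k = rng.integers(2, 6)
    fold_phase = rng.uniform(0, 2 * np.pi)
    amp = min(irregularity, 0.45)
    r0 = np.sqrt(ratio * cell_area / (np.pi * (1 + amp**2 / 2)))
    ncx = cx + rng.uniform(-0.08, 0.08) * radius
    ncy = cy + rng.uniform(-0.08, 0.08) * radius
    theta = np.arctan2(yy - ncy, xx - ncx)
    r_bound = r0 * (1 + amp * np.sin(fold_k * theta + fold_phase))
    nucleus = (xx - ncx) ** 2 + (yy - ncy) ** 2 <= r_bound**2
    # keep a cytoplasmic rim: clip the nucleus to the eroded cell
    rim = binary_erosion(cell, iterations=2)
    nucleus &= rim
    if not nucleus.any():  # pathological tiny ratio: force one interior pixel
        iy, ix = int(round(ncy)), int(round(ncx))
        nucleus[iy, ix] = rim[iy, ix] if rim.any() else cell[iy, ix]
    cytoplasm = cell & ~nucleus

    image = np.empty((size, size, 3), dtype=float)
    image[:] = _BACKGROUND_COLOR
    image += 3.0 * _texture((size, size), 1.0, rng)[..., None]

    cyto_color = np.asarray(params.base_cytoplasm_color, dtype=float)
    nuc_color = np.asarray(params.base_nucleus_color, dtype=float)
    cyto_tex = _texture((size, size), 3.0, rng) * 10.0
    nuc_tex = _texture((size, size), tex_scale, rng) * contrast
    image[cytoplasm] = cyto_color + cyto_tex[cytoplasm, None]
    image[nucleus] = nuc_color * (1.0 + nuc_tex[nucleus, None])
    if color_offset is not None:
        image += np.asarray(color_offset, dtype=float)
    image += rng.normal(0.0, 1.5, image.shape)  # sensor noise
    image = np.clip(image, 0, 255).round().astype(np.uint8)

    mask = np.zeros((size, size), dtype=np.uint8)
    mask[cytoplasm] = 1
    mask[nucleus] = 2
    return CellRecord(cell_id=cell_id, patient_id=patient_id, image=image, mask=mask,
                      true_label=params.class_label)


def largest_remainder_counts(n: int, proportions: np.ndarray) -> np.ndarray:
    """Apportion ``n`` items to classes by largest remainder.

    Ties on the fractional remainder are broken toward the larger target
    proportion, then toward the earlier class index.
    """
    proportions = np.asarray(proportions, dtype=float)
    quotas = n * proportions
    counts = np.floor(quotas).astype(int)
    order = sorted(
        range(len(proportions)),
        key=lambda j: (-(quotas[j] - counts[j]), -proportions[j], j),
    )
    for j in itertools.islice(itertools.cycle(order), n - counts.sum()):
        counts[j] += 1
    return counts


def generate_dataset(
    n_cells: int,
    class_proportions=(0.45, 0.30, 0.25),
    n_patients: int = 10,
    rng_seed: int = 0,
    jitter: float = 0.05,
    patch_size: int = 200,
) -> list[CellRecord]:
    """Generate a labelled multi-patient dataset of synthetic cells.

    Class counts follow largest-remainder apportionment of the proportions;
    patients are assigned round-robin and carry small per-patient colour and
    brightness offsets so patient-grouped splitting is meaningful.
    Deterministic given the seed.
    """
    proportions = np.asarray(class_proportions, dtype=float)
    if proportions.shape != (3,) or not np.isclose(proportions.sum(), 1.0, atol=1e-6):
        raise ValueError("class_proportions must be 3 values summing to 1")
    if n_cells < len(CLASSES):
        raise ValueError(f"n_cells must be >= {len(CLASSES)}")
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")

    rng = np.random.default_rng(rng_seed)
    counts = largest_remainder_counts(n_cells, proportions)
    labels = np.repeat(np.arange(3), counts)
    rng.shuffle(labels)

    patient_offsets = rng.normal(0.0, 5.0, size=(n_patients, 3))
    patient_offsets += rng.normal(0.0, 4.0, size=(n_patients, 1))  # brightness
    records = []
    for i, lab in enumerate(labels):
        pid = i % n_patients
        params = class_preset(CLASSES[lab], jitter=jitter, patch_size=patch_size)
        records.append(
            generate_cell(
                params,
                rng,
                cell_id=f"cell_{i:04d}",
                patient_id=f"patient_{pid:02d}",
                color_offset=patient_offsets[pid],
            )
        )
    return records


def simulate_reviewers(
    records: list[CellRecord],
    model: ReviewerModel,
    rng_seed: int = 0,
) -> list[CellRecord]:
    """Fill ``reviewer_labels`` (and the repeat label) on each record.

    Each reviewer draws independently from their confusion row for the
    record's true class.  The designated repeat reviewer's second pass
    copies the first label with probability ``repeat_consistency`` and is
    otherwise redrawn from the same confusion row.  Records are modified
    in place and returned; deterministic given the seed.
    """
    rng = np.random.default_rng(rng_seed)
    idx = {c: j for j, c in enumerate(CLASSES)}
    for rec in records:
        if rec.true_label not in idx:
            raise ValueError(f"record {rec.cell_id} has no valid true_label")
        t = idx[rec.true_label]
        labels = [
            CLASSES[rng.choice(3, p=model.confusion_matrices[r, t])]
            for r in range(model.n_reviewers)
        ]
        rec.reviewer_labels = labels
        first = labels[model.repeat_reviewer_index]
        if rng.random() < model.repeat_consistency:
            rec.repeat_label = first
        else:
            rec.repeat_label = CLASSES[
                rng.choice(3, p=model.confusion_matrices[model.repeat_reviewer_index, t])
            ]
    return records
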