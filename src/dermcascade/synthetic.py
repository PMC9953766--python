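"""Seeded synthetic dermoscopy-like cohorts and mock models.

Real cohorts pair RGB dermoscopy images with a binary lesion mask, a binary
irregular pigment-network mask, a lesion identifier (duplicated across images
of the same lesion), and a benign/melanoma label. This module fabricates all
of that at desk scale so the downstream stages — feature extraction, tiled
inference, cascade generalization, evaluation — run with no downloads:

* lesion = a connected, radially perturbed blob on a skin-toned background;
* irregular network = jittered polygonal grid edges of varying width drawn
  inside the lesion, added until a target coverage fraction of the lesion
  area is reached;
* class signal = melanoma records draw a higher mean network coverage;
* duplicate lesion_IDs = the same lesion geometry re-rendered with fresh
  color noise, to exercise grouped splitting;
* mock segmenters (constant / oracle / dark-line heuristic) and a mock
  level-0 classifier with a controlled binormal AUC stand in for the GPU
  networks, honoring the same contracts.

Everything is a pure function of (spec, seed): same spec + same seed gives
bitwise-identical arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter
from scipy.special import expit, ndtri
from skimage.draw import polygon
from skimage.morphology import dilation, disk

from ._seeds import derive_rng

__all__ = [
    "SyntheticLesionSpec",
    "SyntheticCohortSpec",
    "LesionRecord",
    "generate_lesion_record",
    "generate_cohort",
    "make_mock_level0",
    "make_mock_segmenter",
    "MockLevel0",
    "InstrumentedLevel0",
    "ConstantSegmenter",
    "OracleSegmenter",
    "DarkLineSegmenter",
]


# ---------------------------------------------------------------------------
# Records and specs
# ---------------------------------------------------------------------------

@dataclass
class LesionRecord:
    """One image with its lesion mask, network mask, lesion id and label."""

    image_id: str
    lesion_id: str
    image: np.ndarray        # H x W x 3 uint8
    lesion_mask: np.ndarray  # H x W bool
    network_mask: np.ndarray  # H x W bool
    label: int               # 0 = benign, 1 = melanoma

    def __post_init__(self) -> None:
        if self.image.ndim != 3 or self.image.shape[2] != 3:
            raise ValueError("image must be H x W x 3")
        if self.lesion_mask.shape != self.image.shape[:2]:
            raise ValueError("lesion_mask shape does not match image")
        if self.network_mask.shape != self.image.shape[:2]:
            raise ValueError("network_mask shape does not match image")
        if self.label not in (0, 1):
            raise ValueError("label must be 0 (benign) or 1 (melanoma)")


@dataclass(frozen=True)
class SyntheticLesionSpec:
    """Geometry and rendering knobs for one synthetic lesion image.

    Coverage is the fraction of lesion area occupied by network pixels; the
    generator adds grid edges until it is reached, so the realized ratio
    lands within one edge's area of the target.
    """

    image_height: int = 160
    image_width: int = 160
    lesion_radius_range: tuple[float, float] = (40.0, 60.0)
    network_line_width_range: tuple[int, int] = (1, 3)
    network_cell_spacing_range: tuple[int, int] = (8, 13)
    network_coverage_fraction: float = 0.15
    background_color: tuple[int, int, int] = (205, 170, 150)
    lesion_color: tuple[int, int, int] = (150, 100, 80)
    network_color: tuple[int, int, int] = (70, 40, 30)
    color_noise_sd: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("lesion_radius_range", "network_line_width_range",
                     "network_cell_spacing_range"):
            lo, hi = getattr(self, name)
            if lo < 0 or hi < lo:
                raise ValueError(f"{name} must be nonnegative and ordered")
        if not 0.0 <= self.network_coverage_fraction <= 1.0:
            raise ValueError("network_coverage_fraction must be in [0, 1]")
        if self.color_noise_sd < 0:
            raise ValueError("color_noise_sd must be nonnegative")
        if self.image_height < 8 or self.image_width < 8:
            raise ValueError("image dimensions too small")


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """A cohort: class counts, duplicate rate, and the class coverage shift.

    ``class_effect`` is the difference in mean network coverage fraction
    between melanoma and benign records; ``base_coverage``/``coverage_sd``
    set the benign mean and the per-record spread.
    """

    n_melanoma: int = 100
    n_benign: int = 100
    duplicate_lesion_fraction: float = 0.0
    class_effect: float = 0.1
    level0_target_auc: float = 0.85
    seed: int = 0
    base_coverage: float = 0.15
    coverage_sd: float = 0.05
    lesion_spec: SyntheticLesionSpec = field(default_factory=SyntheticLesionSpec)

    def __post_init__(self) -> None:
        if self.n_melanoma < 0 or self.n_benign < 0:
            raise ValueError("class counts must be nonnegative")
        if not 0.0 <= self.duplicate_lesion_fraction <= 1.0:
            raise ValueError("duplicate_lesion_fraction must be in [0, 1]")
        if not 0.5 <= self.level0_target_auc <= 1.0:
            raise ValueError("level0_target_auc must be in [0.5, 1]")


# ---------------------------------------------------------------------------
# Lesion and network geometry
# ---------------------------------------------------------------------------

def _lesion_blob(rng: np.random.Generator, h: int, w: int,
                 radius: float) -> np.ndarray:
    """Connected blob: a polygon with smoothly perturbed polar radius."""
    margin = 4
    if radius > min(h, w) / 2 - margin:
        raise ValueError("lesion radius exceeds image bounds")
    cy = h / 2 + rng.uniform(-0.05, 0.05) * h
    cx = w / 2 + rng.uniform(-0.05, 0.05) * w
    # smooth radial perturbation: noise on 8 control angles, periodic interp
    n_ctrl, n_pts = 8, 96
    ctrl = rng.normal(0.0, 0.12, n_ctrl)
    theta = np.linspace(0, 2 * np.pi, n_pts, endpoint=False)
    ctrl_theta = np.linspace(0, 2 * np.pi, n_ctrl, endpoint=False)
    pert = np.interp(theta, np.concatenate([ctrl_theta, [2 * np.pi]]),
                     np.concatenate([ctrl, [ctrl[0]]]))
    r = radius * (1.0 + pert)
    rr = np.clip(cy + r * np.sin(theta), 0, h - 1)
    cc = np.clip(cx + r * np.cos(theta), 0, w - 1)
    mask = np.zeros((h, w), dtype=bool)
    pr, pc = polygon(rr, cc, shape=(h, w))
    mask[pr, pc] = True
    return mask


def _thick_segment(p0: np.ndarray, p1: np.ndarray, width: float,
                   shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Pixels of a line segment drawn as a rotated rectangle of given width."""
    d = p1 - p0
    norm = np.hypot(*d)
    if norm == 0:
        norm = 1.0
    # unit normal, half-width offset
    nvec = np.array([-d[1], d[0]]) / norm * (width / 2.0)
    corners = np.array([p0 + nvec, p1 + nvec, p1 - nvec, p0 - nvec])
    return polygon(corners[:, 0], corners[:, 1], shape=shape)


def _network_mask(rng: np.random.Generator, lesion: np.ndarray,
                  coverage: float, spacing_range: tuple[int, int],
                  width_range: tuple[int, int]) -> np.ndarray:
    """Reticular mask from jittered grid edges, added until coverage is met.

    Edges are clipped to the lesion dilated by 2 px, so a thin rim of network
    can fall just outside the lesion (as in real masks).
    """
    h, w = lesion.shape
    mask = np.zeros((h, w), dtype=bool)
    if coverage <= 0.0 or not lesion.any():
        return mask
    allowed = dilation(lesion, disk(2))
    lesion_area = int(lesion.sum())

    spacing = int(rng.integers(spacing_range[0], spacing_range[1] + 1))
    spacing = max(spacing, 3)
    rows = np.arange(0, h + spacing, spacing, dtype=float)
    cols = np.arange(0, w + spacing, spacing, dtype=float)
    ny, nx = len(rows), len(cols)
    nodes = np.stack(np.meshgrid(rows, cols, indexing="ij"), axis=-1)
    nodes = nodes + rng.uniform(-0.3 * spacing, 0.3 * spacing, nodes.shape)

    edges = []
    for i in range(ny):
        for j in range(nx):
            if j + 1 < nx:
                edges.append((nodes[i, j], nodes[i, j + 1]))
            if i + 1 < ny:
                edges.append((nodes[i, j], nodes[i + 1, j]))
    # keep edges whose midpoint lies in the lesion
    kept = []
    for p0, p1 in edges:
        mid = np.clip(((p0 + p1) / 2).astype(int), 0, [h - 1, w - 1])
        if allowed[mid[0], mid[1]]:
            kept.append((p0, p1))
    rng.shuffle(kept)

    for p0, p1 in kept:
        width = float(rng.integers(width_range[0], width_range[1] + 1))
        pr, pc = _thick_segment(p0, p1, width, (h, w))
        keep = allowed[pr, pc]
        mask[pr[keep], pc[keep]] = True
        if (mask & lesion).sum() / lesion_area >= coverage:
            break
    return mask


def generate_lesion_record(spec: SyntheticLesionSpec, label: int,
                           lesion_id: str,
                           image_id: str | None = None) -> LesionRecord:
    """Render one synthetic lesion record; deterministic under spec.seed."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_height, spec.image_width
    radius = rng.uniform(*spec.lesion_radius_range)
    lesion = _lesion_blob(rng, h, w, radius)
    network = _network_mask(rng, lesion, spec.network_coverage_fraction,
                            spec.network_cell_spacing_range,
                            spec.network_line_width_range)

    img = np.empty((h, w, 3), dtype=float)
    img[:] = spec.background_color
    img[lesion] = spec.lesion_color
    img[network] = spec.network_color
    if spec.color_noise_sd > 0:
        img += rng.normal(0.0, spec.color_noise_sd, img.shape)
    img = np.clip(np.round(img), 0, 255).astype(np.uint8)

    return LesionRecord(
        image_id=image_id or lesion_id,
        lesion_id=lesion_id,
        image=img,
        lesion_mask=lesion,
        network_mask=network,
        label=int(label),
    )


def generate_cohort(
    spec: SyntheticCohortSpec,
) -> tuple[list[LesionRecord], pd.DataFrame]:
    """Generate a labeled cohort plus its metadata table.

    Melanoma records draw their coverage from N(base + class_effect, sd),
    benign from N(base, sd), clipped away from 0 and 1. A
    ``duplicate_lesion_fraction`` share of each class re-renders an earlier
    record's geometry (same lesion_id, same coverage, fresh color noise).

    Returns the records and a metadata frame with columns
    ``image, lesion_id, diagnosis`` (diagnosis in {MEL, NV}).
    """
    rng = derive_rng(spec.seed, "cohort")
    records: list[LesionRecord] = []
    rows = []
    counter = 0
    for label, n in ((1, spec.n_melanoma), (0, spec.n_benign)):
        n_dup = int(round(spec.duplicate_lesion_fraction * n))
        class_records: list[tuple[LesionRecord, float]] = []
        for k in range(n):
            image_id = f"IMG_{counter:05d}"
            counter += 1
            is_dup = k >= n - n_dup and class_records
            if is_dup:
                orig, coverage = class_records[
                    int(rng.integers(len(class_records)))]
                lesion_id = orig.lesion_id
                # same geometry seed -> same masks; new noise seed via
                # re-render with identical spec but fresh color noise
                base_spec = replace(
                    spec.lesion_spec,
                    network_coverage_fraction=coverage,
                    seed=orig._geom_seed,  # type: ignore[attr-defined]
                )
                rec = generate_lesion_record(base_spec, label, lesion_id,
                                             image_id)
                noise_rng = np.random.default_rng(
                    int(rng.integers(2**31 - 1)))
                img = rec.image.astype(float) + noise_rng.normal(
                    0.0, spec.lesion_spec.color_noise_sd, rec.image.shape)
                rec.image = np.clip(np.round(img), 0, 255).astype(np.uint8)
            else:
                lesion_id = f"LES_{counter:05d}"
                mean_cov = spec.base_coverage + spec.class_effect * label
                coverage = float(np.clip(
                    rng.normal(mean_cov, spec.coverage_sd), 0.02, 0.75))
                geom_seed = int(rng.integers(2**31 - 1))
                rec = generate_lesion_record(
                    replace(spec.lesion_spec,
                            network_coverage_fraction=coverage,
                            seed=geom_seed),
                    label, lesion_id, image_id)
                rec._geom_seed = geom_seed  # type: ignore[attr-defined]
                class_records.append((rec, coverage))
            records.append(rec)
            rows.append({"image": image_id, "lesion_id": lesion_id,
                         "diagnosis": "MEL" if label == 1 else "NV"})
    metadata = pd.DataFrame(rows, columns=["image", "lesion_id", "diagnosis"])
    return records, metadata


# ---------------------------------------------------------------------------
# Mock level-0 classifier
# ---------------------------------------------------------------------------

class MockLevel0:
    """Label-peeking stand-in for a deep level-0 classifier.

    The score for a record is sigmoid(z + d' * (label - 1/2)) with
    z ~ N(0, 1) drawn deterministically from (seed, image_id) and
    d' = sqrt(2) * Phi^-1(AUC): the two class-conditional Gaussians sit
    symmetrically at ±d'/2 (standard signal-detection placement, so the 0.5
    probability threshold is the unbiased operating point) and the empirical
    AUC converges to ``target_auc`` (binormal identity AUC = Phi(d'/sqrt(2))).
    It NEVER looks at pixels: the true label stored on the record drives the
    draw. That makes it test plumbing only — it
    exists so the cascade machinery can be exercised against a level-0 of
    known discrimination, not a model of anything.

    Keying z on (seed, image_id) rather than on the model instance means two
    mocks built with the same seed produce identical scores for the same
    record — emulating the strong correlation between a real classifier's
    fold models.
    """

    def __init__(self, target_auc: float, seed: int):
        if not 0.5 <= target_auc <= 1.0:
            raise ValueError("target_auc must be in [0.5, 1]")
        self.target_auc = target_auc
        self.seed = int(seed)
        self.dprime = (np.inf if target_auc == 1.0
                       else float(np.sqrt(2.0) * ndtri(target_auc)))

    def fit(self, records, labels) -> "MockLevel0":
        self.fit_ids_ = {r.image_id for r in records}
        return self

    def predict_proba(self, records) -> np.ndarray:
        out = np.empty(len(records))
        for i, rec in enumerate(records):
            if np.isinf(self.dprime):
                out[i] = float(rec.label)
                continue
            rng = derive_rng(self.seed, f"mock-level0/{rec.image_id}")
            z = rng.normal()
            out[i] = expit(z + self.dprime * (rec.label - 0.5))
        return out


class InstrumentedLevel0:
    """Wraps a Level0Model, recording fit membership and predict calls.

    Used by leakage tests to prove that no record is ever scored by a model
    that saw it during fitting.
    """

    def __init__(self, inner):
        self.inner = inner
        self.fit_ids_: set[str] = set()
        self.predicted_ids_: list[str] = []

    def fit(self, records, labels):
        self.fit_ids_ = {r.image_id for r in records}
        self.inner.fit(records, labels)
        return self

    def predict_proba(self, records):
        self.predicted_ids_.extend(r.image_id for r in records)
        return self.inner.predict_proba(records)


def make_mock_level0(target_auc: float, seed: int) -> MockLevel0:
    """Mock level-0 classifier with binormal AUC ``target_auc``."""
    if target_auc < 0.5:
        raise ValueError("target_auc must be >= 0.5")
    return MockLevel0(target_auc, seed)


# ---------------------------------------------------------------------------
# Mock segmenters
# ---------------------------------------------------------------------------

class ConstantSegmenter:
    """Outputs a uniform probability c for every pixel."""

    def __init__(self, c: float = 0.5):
        if not 0.0 <= c <= 1.0:
            raise ValueError("c must be in [0, 1]")
        self.c = float(c)

    def predict(self, patch: np.ndarray) -> np.ndarray:
        return np.full(patch.shape[:2], self.c)


class OracleSegmenter:
    """Returns the ground-truth network mask as {0,1} probabilities.

    A patch alone does not identify where in the image it came from, so this
    mock uses the location-aware protocol: the tiled-inference engine sees
    ``requires_location`` and passes the crop origin and the augmentation
    applied, which the oracle applies forward to its truth crop so that
    de-augmentation restores it exactly. Test plumbing only.
    """

    requires_location = True

    def __init__(self, truth_mask: np.ndarray | None):
        if truth_mask is None:
            raise ValueError("oracle segmenter requires a ground-truth mask")
        self.truth = truth_mask.astype(bool)

    def predict(self, patch: np.ndarray, origin: tuple[int, int],
                augmentation) -> np.ndarray:
        from .tta import apply_augmentation, pad_to_min

        size = patch.shape[0]
        padded = pad_to_min(self.truth, size)
        r, c = origin
        crop = padded[r:r + size, c:c + size].astype(float)
        return apply_augmentation(crop, augmentation)


class DarkLineSegmenter:
    """Per-pixel darkness-contrast heuristic.

    Score = (local mean intensity in a square window) − (pixel intensity),
    min-max rescaled to [0,1] per patch; dark thin structures on a lighter
    background score high.
    """

    def __init__(self, window: int = 11):
        self.window = int(window)

    def predict(self, patch: np.ndarray) -> np.ndarray:
        gray = patch.astype(float).mean(axis=2)
        local = uniform_filter(gray, size=self.window, mode="reflect")
        score = local - gray
        lo, hi = score.min(), score.max()
        if hi - lo < 1e-12:
            return np.zeros_like(score)
        return (score - lo) / (hi - lo)


def make_mock_segmenter(kind: str, *, c: float = 0.5,
                        truth_mask: np.ndarray | None = None,
                        window: int = 11):
    """Build a mock segmenter: 'constant', 'oracle' or 'heuristic'."""
    if kind == "constant":
        return ConstantSegmenter(c)
    if kind == "oracle":
        return OracleSegmenter(truth_mask)
    if kind == "heuristic":
        return DarkLineSegmenter(window)
    raise ValueError(f"unknown segmenter kind: {kind!r}")
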