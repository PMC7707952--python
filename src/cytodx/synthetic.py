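"""Synthetic cohorts and rendered nucleus images with analytic ground truth.

The study's patient data are not publicly deposited, so this module emulates
its structure at two levels:

* :func:`simulate_cohort` draws a cohort of patients with the published
  cohort-level shape — 447 cases, 64.4% benign, ~92 measured structures per
  case (~41k structures total) — and class-conditional feature distributions
  with cross-contamination: benign cases contain a small fraction of
  malignant-looking nuclei and malignant cases a substantial fraction of
  benign-looking ones (normal follicular cells, histiocytes and colloid are
  measured from malignant slides too).

* :func:`render_nucleus` rasterizes an ellipse of known size and optical
  density into an RGB patch plus a 256-gon boundary, giving morphometry an
  analytic oracle (area πab, Ramanujan perimeter, axes 2a/2b, OD level).

Every generator is a pure function of (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .morphometry import FEATURE_NAMES, ImagePatch, NucleusBoundary
from .rbf import BENIGN, MALIGNANT

__all__ = [
    "CohortConfig",
    "CaseRecord",
    "simulate_cohort",
    "split_train_test",
    "render_nucleus",
    "cohort_frames",
]

# Size-related features given a mild mutual correlation of 0.3.
_SIZE_FEATURES = (
    "area", "major_axis", "minor_axis", "max_caliper", "min_caliper",
    "mean_caliper", "max_radius", "min_radius", "perimeter",
)

# Baseline (benign) feature location/scale in native units, the sign of the
# malignant shift, and hard validity bounds applied after sampling.
#   name: (base, scale, shift_sign, lo, hi)
_FEATURE_MODEL: dict[str, tuple[float, float, float, float, float]] = {
    "area": (350.0, 120.0, +1, 1.0, math.inf),
    "major_axis": (26.0, 6.0, +1, 0.1, math.inf),
    "minor_axis": (17.0, 4.0, +1, 0.1, math.inf),
    "aspect_ratio": (1.5, 0.25, +1, 1.0, math.inf),
    "max_caliper": (27.0, 6.0, +1, 0.1, math.inf),
    "min_caliper": (16.0, 4.0, +1, 0.1, math.inf),
    "mean_caliper": (21.0, 5.0, +1, 0.1, math.inf),
    "max_radius": (14.0, 3.5, +1, 0.1, math.inf),
    "min_radius": (7.0, 2.0, +1, 0.1, math.inf),
    "radius_ratio": (2.0, 0.4, +1, 1.0, math.inf),
    "perimeter": (72.0, 15.0, +1, 1.0, math.inf),
    "roundness": (0.85, 0.08, -1, 1e-6, 1.0),
    "fractal_dimension": (1.05, 0.04, +1, 1.0, 2.0),
    "iod": (60.0, 25.0, +1, 0.0, math.inf),
    "mean_red": (150.0, 25.0, -1, 0.0, 255.0),
    "mean_green": (120.0, 25.0, -1, 0.0, 255.0),
    "mean_blue": (160.0, 20.0, -1, 0.0, 255.0),
    "mean_od": (0.35, 0.12, +1, 0.0, math.inf),
    "max_od": (0.80, 0.20, +1, 0.0, math.inf),
    "min_od": (0.05, 0.03, +1, 0.0, math.inf),
    "sd_od": (0.15, 0.05, +1, 0.0, math.inf),
    "margination": (0.25, 0.10, +1, 0.0, 1.0),
    "heterogeneity": (0.30, 0.10, +1, 0.0, 1.0),
}

_BENIGN_SUBTYPES = (
    ("goiter", 186), ("nodular hyperplasia-hyperplastic nodule", 37),
    ("adenomatous nodule", 24), ("Hashimoto thyroiditis", 24),
    ("follicular adenoma", 5), ("thyroiditis-nonspecific", 5),
    ("oxyphilic adenoma", 4), ("nodular hyperplasia", 3),
)
_MALIGNANT_SUBTYPES = (
    ("papillary Ca", 126), ("medullary Ca", 20),
    ("follicular Ca", 10), ("anaplastic Ca", 3),
)


@dataclass
class CohortConfig:
    """Generative settings; defaults mirror the published cohort shape."""

    n_cases: int = 447
    benign_case_fraction: float = 0.644
    nuclei_per_case_mean: float = 92.0
    nuclei_per_case_dispersion: float = 10.0  # negative-binomial size r
    contamination_benign: float = 0.01
    contamination_malignant: float = 0.20
    effect_strong: float = 1.5  # SD-unit class shift on area, iod, sd_od
    effect_weak: float = 0.5    # SD-unit class shift on the other features
    strong_features: tuple[str, ...] = ("area", "iod", "sd_od")
    seed: int = 0

    def validate(self) -> None:
        bad = []
        if self.n_cases < 2:
            bad.append("n_cases")
        if not 0.0 <= self.benign_case_fraction <= 1.0:
            bad.append("benign_case_fraction")
        if self.nuclei_per_case_mean < 1:
            bad.append("nuclei_per_case_mean")
        if self.nuclei_per_case_dispersion <= 0:
            bad.append("nuclei_per_case_dispersion")
        if not 0.0 <= self.contamination_benign <= 1.0:
            bad.append("contamination_benign")
        if not 0.0 <= self.contamination_malignant <= 1.0:
            bad.append("contamination_malignant")
        if self.effect_strong < 0 or self.effect_weak < 0:
            bad.append("effect_strong/effect_weak")
        if set(self.strong_features) - set(FEATURE_NAMES):
            bad.append("strong_features")
        if bad:
            raise ValueError(f"invalid CohortConfig field(s): {', '.join(bad)}")


@dataclass
class CaseRecord:
    """One patient: histology truth plus the measured structures."""

    case_id: str
    histology: str  # benign | malignant
    subtype: str
    structures: pd.DataFrame  # structure_id, latent_class, 23 feature columns


def _correlation_cholesky() -> np.ndarray:
    d = len(FEATURE_NAMES)
    corr = np.eye(d)
    size_idx = [FEATURE_NAMES.index(n) for n in _SIZE_FEATURES]
    for i in size_idx:
        for j in size_idx:
            if i != j:
                corr[i, j] = 0.3
    return np.linalg.cholesky(corr)


def _class_shift(config: CohortConfig) -> np.ndarray:
    shift = np.empty(len(FEATURE_NAMES))
    for i, name in enumerate(FEATURE_NAMES):
        eff = config.effect_strong if name in config.strong_features \
            else config.effect_weak
        shift[i] = eff * _FEATURE_MODEL[name][2]
    return shift


def _to_native(z: np.ndarray) -> np.ndarray:
    """Map standardized draws to native feature units and clip to validity."""
    out = np.empty_like(z)
    for i, name in enumerate(FEATURE_NAMES):
        base, scale, _, lo, hi = _FEATURE_MODEL[name]
        out[:, i] = np.clip(base + scale * z[:, i], lo, hi)
    return out


def simulate_cohort(config: CohortConfig | None = None) -> list[CaseRecord]:
    """Draw a full synthetic cohort; reproducible per config.seed."""
    config = config or CohortConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)

    benign_case = rng.random(config.n_cases) < config.benign_case_fraction
    r = config.nuclei_per_case_dispersion
    p = r / (r + config.nuclei_per_case_mean)
    counts = np.maximum(rng.negative_binomial(r, p, size=config.n_cases), 1)

    chol = _correlation_cholesky().T
    shift = _class_shift(config)

    b_names = [s for s, _ in _BENIGN_SUBTYPES]
    b_w = np.array([w for _, w in _BENIGN_SUBTYPES], dtype=float)
    m_names = [s for s, _ in _MALIGNANT_SUBTYPES]
    m_w = np.array([w for _, w in _MALIGNANT_SUBTYPES], dtype=float)

    cases = []
    for i in range(config.n_cases):
        n = int(counts[i])
        histology = BENIGN if benign_case[i] else MALIGNANT
        contam = config.contamination_benign if benign_case[i] \
            else config.contamination_malignant
        flipped = rng.random(n) < contam
        if benign_case[i]:
            latent_mal = flipped
            subtype = b_names[rng.choice(len(b_names), p=b_w / b_w.sum())]
        else:
            latent_mal = ~flipped
            subtype = m_names[rng.choice(len(m_names), p=m_w / m_w.sum())]
        z = rng.standard_normal((n, len(FEATURE_NAMES))) @ chol
        z[latent_mal] += shift
        feats = _to_native(z)
        df = pd.DataFrame(feats, columns=list(FEATURE_NAMES))
        df.insert(0, "structure_id", [f"c{i:04d}s{j:04d}" for j in range(n)])
        df.insert(1, "latent_class",
                  np.where(latent_mal, MALIGNANT, BENIGN))
        cases.append(CaseRecord(
            case_id=f"c{i:04d}", histology=histology, subtype=subtype,
            structures=df,
        ))
    return cases


def split_train_test(
    cases: Sequence[CaseRecord],
    train_fraction: float = 0.5,
    stratified: bool = True,
    seed: int = 0,
) -> tuple[list[CaseRecord], list[CaseRecord]]:
    """Case-level train/test split (nuclei of one patient never straddle sets).

    Stratified by histology: per-class training counts are within one case of
    ``train_fraction``.  Degenerate fractions that would empty either side
    are rejected.
    """
    labels = np.array([c.histology for c in cases])
    for cls in (BENIGN, MALIGNANT):
        if (labels == cls).sum() < 2:
            raise ValueError(f"need at least 2 cases of class {cls!r}")
    rng = np.random.default_rng(seed)
    n = len(cases)
    train_idx: list[int] = []
    if stratified:
        for cls in (BENIGN, MALIGNANT):
            idx = np.flatnonzero(labels == cls)
            n_tr = int(round(train_fraction * len(idx)))
            train_idx.extend(rng.permutation(idx)[:n_tr].tolist())
    else:
        n_tr = int(round(train_fraction * n))
        train_idx = rng.permutation(n)[:n_tr].tolist()
    train_set = set(train_idx)
    if not train_set or len(train_set) == n:
        raise ValueError("train_fraction leaves an empty train or test set")
    train = [cases[i] for i in sorted(train_set)]
    test = [cases[i] for i in range(n) if i not in train_set]
    return train, test


def cohort_frames(
    cases: Sequence[CaseRecord], split: dict[str, str] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flatten a cohort into (cases_df, features_df) tables.

    ``split`` optionally maps case_id → 'train'/'test' and adds a column.
    """
    cases_df = pd.DataFrame({
        "case_id": [c.case_id for c in cases],
        "histology": [c.histology for c in cases],
        "subtype": [c.subtype for c in cases],
    })
    if split is not None:
        cases_df["split"] = cases_df["case_id"].map(split)
    frames = []
    for c in cases:
        df = c.structures.copy()
        df.insert(0, "case_id", c.case_id)
        frames.append(df)
    features_df = pd.concat(frames, ignore_index=True)
    return cases_df, features_df


def _ramanujan_perimeter(a: float, b: float) -> float:
    return math.pi * (3 * (a + b) - math.sqrt((3 * a + b) * (a + 3 * b)))


def _od_to_intensity(od: np.ndarray | float, i0: float = 255.0) -> np.ndarray:
    return np.clip(np.rint((i0 + 1.0) * np.power(10.0, -np.asarray(od)) - 1.0),
                   0, 255).astype(np.uint8)


def render_nucleus(
    a: float,
    b: float,
    rotation: float = 0.0,
    center: tuple[float, float] | None = None,
    od_level: float = 0.3,
    texture: str = "none",
    od_levels: tuple[float, float] = (0.2, 0.4),
    noise_sd: float = 0.05,
    size: tuple[int, int] = (128, 128),
    seed: int = 0,
) -> tuple[ImagePatch, NucleusBoundary, dict]:
    """Rasterize an elliptical nucleus on a white background.

    Pixel intensity encodes the requested optical density (gray RGB against
    I₀ = 255).  ``texture``: 'none' (uniform ``od_level``), 'two_tone'
    (``od_levels`` on either side of the minor axis), or 'noise' (Gaussian OD
    jitter of SD ``noise_sd``).  Returns the patch, a 256-gon boundary on the
    true ellipse, and the analytic truth record.
    """
    h, w = size
    if center is None:
        center = ((w - 1) / 2.0, (h - 1) / 2.0)
    cx, cy = center
    cos_r, sin_r = math.cos(rotation), math.sin(rotation)

    t = np.linspace(0.0, 2.0 * math.pi, 256, endpoint=False)
    ex, ey = a * np.cos(t), b * np.sin(t)
    vx = cx + cos_r * ex - sin_r * ey
    vy = cy + sin_r * ex + cos_r * ey
    if vx.min() < 1 or vy.min() < 1 or vx.max() > w - 2 or vy.max() > h - 2:
        raise ValueError("shape does not fit inside the image")
    boundary = NucleusBoundary(np.column_stack([vx, vy]))

    xs, ys = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
    # rotate pixel centers into the ellipse frame
    u = cos_r * (xs - cx) + sin_r * (ys - cy)
    v = -sin_r * (xs - cx) + cos_r * (ys - cy)
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0 + 1e-12

    od = np.zeros((h, w))
    if texture == "none":
        od[inside] = od_level
    elif texture == "two_tone":
        od[inside & (u <= 0)] = od_levels[0]
        od[inside & (u > 0)] = od_levels[1]
    elif texture == "noise":
        rng = np.random.default_rng(seed)
        od[inside] = np.clip(
            od_level + noise_sd * rng.standard_normal(int(inside.sum())), 0.0, None
        )
    else:
        raise ValueError(f"unknown texture {texture!r}")

    gray = np.full((h, w), 255, dtype=np.uint8)
    gray[inside] = _od_to_intensity(od[inside])
    patch = ImagePatch(np.repeat(gray[:, :, None], 3, axis=2))

    truth = {
        "area": math.pi * a * b,
        "perimeter": _ramanujan_perimeter(a, b),
        "major_axis": 2.0 * max(a, b),
        "minor_axis": 2.0 * min(a, b),
        "od_level": od_level if texture != "two_tone" else od_levels,
        "rotation": rotation,
        "center": center,
    }
    return patch, boundary, truth
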