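"""Synthetic gray-matter cohort generator.

The generator emulates the statistical structure a source-based-morphometry
analysis assumes: each subject's GM volume is a linear mixture of K smooth,
spatially localized sources with per-subject loadings plus i.i.d. Gaussian
voxel noise.  One source is discriminative — its loadings are shifted between
amyloid-beta (Ab) positive and negative subjects — and one source's loadings
track age, so the downstream decomposition, classification, and correlation
stages all have planted ground truth to recover.

Cognitive scores and APOE genotypes are drawn per Ab group from published
cohort summary statistics (memory-clinic population, 45 Ab-positive / 73
Ab-negative), so the subject table has realistic group contrasts: positives
are older, score lower on memory tests, and carry e4 alleles more often.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .volumes import DESK_GRID_SHAPE, GMVolume

__all__ = [
    "SourceMap",
    "CohortConfig",
    "GroundTruth",
    "generate_sources",
    "generate_cohort",
    "cohort_summary",
    "COGNITIVE_VARS",
    "GROUP_SCORE_PARAMS",
    "APOE_FREQS",
    "DIAGNOSIS_GIVEN_LABEL",
]

#: Cognitive variables carried by the subject table, in reporting order.
COGNITIVE_VARS = [
    "MMSE",
    "CDR_global",
    "CDR_sum",
    "FAQ",
    "LM_I",
    "LM_II",
    "ADAS_cog_J",
    "WF_category",
    "WF_initial",
    "TMT_A",
    "TMT_B",
    "JART",
]

# Per-group (mean, SD) of each continuous variable: Ab-positive memory-clinic
# patients are older and perform worse on episodic-memory and global measures.
GROUP_SCORE_PARAMS: dict[str, dict[str, tuple[float, float]]] = {
    "positive": {
        "age": (72.38, 9.09),
        "education": (14.47, 1.85),
        "MMSE": (22.73, 5.96),
        "CDR_global": (0.53, 0.33),
        "CDR_sum": (2.22, 2.38),
        "FAQ": (4.18, 4.44),
        "LM_I": (4.07, 3.58),
        "LM_II": (2.44, 3.58),
        "ADAS_cog_J": (14.94, 9.99),
        "WF_category": (27.98, 13.29),
        "WF_initial": (21.53, 9.24),
        "TMT_A": (153.58, 239.11),
        "TMT_B": (310.22, 326.13),
        "JART": (25.42, 15.21),
    },
    "negative": {
        "age": (67.71, 9.78),
        "education": (14.73, 2.29),
        "MMSE": (27.37, 3.39),
        "CDR_global": (0.23, 0.34),
        "CDR_sum": (0.84, 1.73),
        "FAQ": (1.58, 3.31),
        "LM_I": (10.05, 5.08),
        "LM_II": (8.99, 5.64),
        "ADAS_cog_J": (6.82, 6.68),
        "WF_category": (35.47, 12.83),
        "WF_initial": (24.30, 10.92),
        "TMT_A": (83.79, 156.68),
        "TMT_B": (131.32, 163.87),
        "JART": (32.49, 13.38),
    },
}

# Genotype frequencies per Ab group (counts from the same cohort; e4/4 occurs
# only among positives, e2 alleles only among negatives).
APOE_FREQS: dict[str, dict[str, float]] = {
    "positive": {"e3/e3": 21 / 45, "e3/e4": 18 / 45, "e4/e4": 6 / 45},
    "negative": {
        "e2/e2": 2 / 73,
        "e2/e3": 8 / 73,
        "e3/e3": 47 / 73,
        "e3/e4": 16 / 73,
    },
}

# Clinical diagnosis distribution conditional on Ab label (cohort joint
# counts: e.g. 21 of 24 AD patients were Ab-positive, all PSP were negative).
DIAGNOSIS_GIVEN_LABEL: dict[str, dict[str, float]] = {
    "positive": {"AD": 21 / 45, "MCI": 16 / 45, "FTLD": 1 / 45, "CBS": 2 / 45,
                 "HC": 5 / 45},
    "negative": {"AD": 3 / 73, "MCI": 13 / 73, "FTLD": 11 / 73, "CBS": 1 / 73,
                 "PSP": 3 / 73, "Psychiatric": 5 / 73, "HC": 37 / 73},
}

#: Fraction of men per Ab group.
MALE_FRACTION = {"positive": 0.53, "negative": 0.5479}

# Scores that cannot be negative; TMT-style timings are truncated at 0 from
# below and MMSE is additionally capped at its 30-point ceiling.
_NONNEGATIVE = {"MMSE", "CDR_global", "CDR_sum", "FAQ", "LM_I", "LM_II",
                "ADAS_cog_J", "WF_category", "WF_initial", "TMT_A", "TMT_B",
                "JART"}
_UPPER_CAP = {"MMSE": 30.0}


@dataclass
class SourceMap:
    """One planted spatial source: an isotropic Gaussian blob.

    ``weights`` is the full 3D grid of spatial weights, ``center`` the peak
    voxel, and ``extent`` the Gaussian scale (voxels).
    """

    weights: np.ndarray
    center: tuple[int, int, int]
    extent: float

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("source weights must be finite")
        if np.ptp(self.weights) == 0:
            raise ValueError("source map is constant")


@dataclass
class CohortConfig:
    """Parameters of one synthetic cohort.

    Defaults reproduce the reference study conditions: 118 subjects of whom
    45 (38.1%) are Ab-positive, with the discriminative source's loadings
    shifted down by 1.24 within-group SDs in positives (point-biserial
    r ~= -0.52 against Ab status) and the age-linked source's loadings
    correlated r ~= -0.56 with age.
    """

    n_subjects: int = 118
    grid_shape: tuple[int, int, int] = DESK_GRID_SHAPE
    n_sources: int = 5
    ab_positive_fraction: float = 45 / 118
    discriminative_source_index: int = 0
    loading_shift: float = 1.24
    age_source_index: int = 1
    age_loading_r: float = -0.556
    source_extent: float = 3.0
    noise_sd: float = 0.5
    group_score_params: dict = field(
        default_factory=lambda: {g: dict(v) for g, v in GROUP_SCORE_PARAMS.items()}
    )
    apoe_freqs: dict = field(
        default_factory=lambda: {g: dict(v) for g, v in APOE_FREQS.items()}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.ab_positive_fraction < 1.0:
            raise ValueError("ab_positive_fraction must be in (0, 1)")
        if self.n_sources < 2:
            raise ValueError("n_sources must be >= 2")
        for name in ("discriminative_source_index", "age_source_index"):
            if not 0 <= getattr(self, name) < self.n_sources:
                raise ValueError(f"{name} out of range [0, {self.n_sources})")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for group, freqs in self.apoe_freqs.items():
            total = sum(freqs.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"APOE frequencies for group {group!r} sum to {total}, not 1"
                )

    def replace(self, **kwargs) -> "CohortConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass
class GroundTruth:
    """Planted sources, mixing loadings, labels, and ages of a cohort."""

    sources: list[SourceMap]
    loadings: np.ndarray
    labels: np.ndarray
    ages: np.ndarray

    def __post_init__(self) -> None:
        self.loadings = np.asarray(self.loadings, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.loadings.shape[0] != self.labels.shape[0]:
            raise ValueError("loadings rows must match number of labels")


def _gaussian_blob(grid_shape, center, extent) -> np.ndarray:
    axes = np.ogrid[tuple(slice(0, n) for n in grid_shape)]
    d2 = sum((ax - c) ** 2 for ax, c in zip(axes, center))
    return np.exp(-d2 / (2.0 * extent**2))


def generate_sources(
    n_sources: int,
    grid_shape: tuple[int, int, int] = DESK_GRID_SHAPE,
    extent: float = 3.0,
    seed: int = 0,
) -> list[SourceMap]:
    """Place ``n_sources`` Gaussian blobs with nearly uncorrelated supports.

    Peak voxels are rejection-sampled to keep a minimum pairwise separation
    of 3 x ``extent`` (two isotropic Gaussians that far apart correlate below
    0.2 over the grid), with a one-``extent`` margin from the grid edges.
    Deterministic for a fixed ``seed``.
    """
    if n_sources < 1:
        raise ValueError("n_sources must be >= 1")
    grid_shape = tuple(int(n) for n in grid_shape)
    if any(n < extent for n in grid_shape):
        raise ValueError(
            f"grid {grid_shape} too small for source extent {extent}"
        )
    margin = extent
    lo = [margin] * 3
    hi = [n - 1 - margin for n in grid_shape]
    if any(h < l for l, h in zip(lo, hi)):
        raise ValueError(
            f"grid {grid_shape} leaves no room for sources of extent {extent}"
        )
    min_sep = 3.0 * extent
    rng = np.random.default_rng(seed)
    centers: list[np.ndarray] = []
    attempts = 0
    while len(centers) < n_sources:
        cand = np.array(
            [rng.integers(int(np.ceil(l)), int(np.floor(h)) + 1)
             for l, h in zip(lo, hi)]
        )
        if all(np.linalg.norm(cand - c) >= min_sep for c in centers):
            centers.append(cand)
        attempts += 1
        if attempts > 10000 * n_sources:
            raise ValueError(
                f"cannot place {n_sources} sources of extent {extent} on grid "
                f"{grid_shape}: grid too small for the required separation"
            )
    return [
        SourceMap(
            weights=_gaussian_blob(grid_shape, c, extent),
            center=tuple(int(x) for x in c),
            extent=float(extent),
        )
        for c in centers
    ]


def _draw_truncated(rng, mean, sd, size, lower=None, upper=None):
    x = rng.normal(mean, sd, size)
    if lower is not None:
        x = np.maximum(x, lower)
    if upper is not None:
        x = np.minimum(x, upper)
    return x


def generate_cohort(
    config: CohortConfig,
) -> tuple[list[GMVolume], pd.DataFrame, GroundTruth]:
    """Generate GM volumes, a subject table, and the planted ground truth.

    Every volume is ``sum_k loading[s, k] * source_k + N(0, noise_sd)``.
    Label assignment is deterministic: exactly ``round(n * fraction)``
    subjects are positive, with the positive set shuffled by the seed.
    Positives' discriminative-source loadings are shifted by
    ``-loading_shift`` (in within-group SD units); the age-linked source's
    loadings are built to correlate ``age_loading_r`` with age.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_subjects

    # deterministic label counts, seed-shuffled ordering
    n_pos = int(round(n * cfg.ab_positive_fraction))
    labels = np.array(["positive"] * n_pos + ["negative"] * (n - n_pos))
    rng.shuffle(labels)
    is_pos = labels == "positive"

    sources = generate_sources(
        cfg.n_sources, cfg.grid_shape, cfg.source_extent,
        seed=int(rng.integers(2**31)),
    )

    # covariates drawn per group
    table = pd.DataFrame({
        "subject_id": [f"sub-{i:04d}" for i in range(n)],
        "ab_label": labels,
    })
    for var in ["age", "education", *COGNITIVE_VARS]:
        vals = np.empty(n)
        for group, sel in (("positive", is_pos), ("negative", ~is_pos)):
            mean, sd = cfg.group_score_params[group][var]
            vals[sel] = _draw_truncated(
                rng, mean, sd, int(sel.sum()),
                lower=0.0 if var in _NONNEGATIVE else None,
                upper=_UPPER_CAP.get(var),
            )
        table[var] = vals
    table["age"] = table["age"].round(1)

    sex = np.empty(n, dtype=object)
    apoe = np.empty(n, dtype=object)
    diagnosis = np.empty(n, dtype=object)
    for group, sel in (("positive", is_pos), ("negative", ~is_pos)):
        m = int(sel.sum())
        sex[sel] = np.where(rng.random(m) < MALE_FRACTION[group], "M", "F")
        genotypes = list(cfg.apoe_freqs[group])
        apoe[sel] = rng.choice(
            genotypes, size=m,
            p=[cfg.apoe_freqs[group][g] for g in genotypes],
        )
        diags = list(DIAGNOSIS_GIVEN_LABEL[group])
        diagnosis[sel] = rng.choice(
            diags, size=m,
            p=[DIAGNOSIS_GIVEN_LABEL[group][d] for d in diags],
        )
    table["sex"] = sex
    table["apoe"] = apoe
    table["diagnosis"] = diagnosis

    # mixing loadings: standard normal, with the planted structure
    loadings = rng.normal(0.0, 1.0, (n, cfg.n_sources))
    loadings[is_pos, cfg.discriminative_source_index] -= cfg.loading_shift
    if cfg.age_source_index != cfg.discriminative_source_index:
        age = table["age"].to_numpy(dtype=float)
        age_z = (age - age.mean()) / age.std(ddof=0)
        r = cfg.age_loading_r
        loadings[:, cfg.age_source_index] = (
            r * age_z
            + np.sqrt(max(0.0, 1.0 - r**2))
            * loadings[:, cfg.age_source_index]
        )

    source_stack = np.stack([s.weights for s in sources])  # K x nx x ny x nz
    volumes: list[GMVolume] = []
    for i in range(n):
        vals = np.tensordot(loadings[i], source_stack, axes=1)
        if cfg.noise_sd > 0:
            vals = vals + rng.normal(0.0, cfg.noise_sd, cfg.grid_shape)
        volumes.append(GMVolume(values=vals, subject_id=table["subject_id"][i]))

    truth = GroundTruth(
        sources=sources,
        loadings=loadings,
        labels=labels,
        ages=table["age"].to_numpy(dtype=float),
    )
    return volumes, table, truth


def cohort_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Per-group demographic and clinical summary (n, %, mean +/- SD, counts).

    Continuous variables are summarized as mean and SD (SD is NaN for a
    single-subject group, sample SD with ddof=1 otherwise); categorical
    variables (sex, APOE, diagnosis) as per-level counts.  The returned frame
    has one row per summary quantity and one column per Ab group.
    """
    if "ab_label" not in table.columns:
        raise ValueError("subject table lacks required 'ab_label' column")
    groups = ["positive", "negative"]
    n_total = len(table)
    rows: dict[str, dict[str, object]] = {}
    by = {g: table[table["ab_label"] == g] for g in groups}

    rows["n"] = {g: len(by[g]) for g in groups}
    rows["percent"] = {
        g: round(100.0 * len(by[g]) / n_total, 1) if n_total else float("nan")
        for g in groups
    }
    numeric = [c for c in table.columns
               if c not in ("subject_id", "ab_label", "sex", "apoe", "diagnosis")
               and pd.api.types.is_numeric_dtype(table[c])]
    for var in numeric:
        rows[f"{var}_mean"] = {g: by[g][var].mean() for g in groups}
        rows[f"{var}_sd"] = {
            g: by[g][var].std(ddof=1) if len(by[g]) > 1 else float("nan")
            for g in groups
        }
    for cat in ("sex", "apoe", "diagnosis"):
        if cat not in table.columns:
            continue
        for level in sorted(table[cat].dropna().unique()):
            rows[f"{cat}={level}"] = {
                g: int((by[g][cat] == level).sum()) for g in groups
            }
    return pd.DataFrame.from_dict(rows, orient="index")[groups]
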