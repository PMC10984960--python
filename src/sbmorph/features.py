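"""Feature-matrix assembly for the Ab-positivity classifier.

Feature blocks:

* ``brain`` — the K SBM beta loadings (IC_1 ... IC_K);
* ``demographics`` — age and sex (part of the ALL set only);
* ``cognition`` — the twelve neuropsychological scores;
* ``apoe`` — two derived genotype features, the any-e4-carrier indicator
  ("APOE x/e4") and the e4 allele count ("APOE e4_number").

Named feature sets mirror the ablation rows of the analysis: brain,
cognition, apoe, brain+cognition, brain+apoe, and ALL (brain +
demographics + cognition + APOE).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .decompose import ComponentSet
from .simulate import COGNITIVE_VARS

__all__ = [
    "FeatureSetSpec",
    "FEATURE_SET_NAMES",
    "assemble_features",
    "apoe_features",
]

FEATURE_SET_NAMES = [
    "brain",
    "cognition",
    "apoe",
    "brain+cognition",
    "brain+apoe",
    "ALL",
]

_BLOCKS = {
    "brain": ("brain",),
    "cognition": ("cognition",),
    "apoe": ("apoe",),
    "brain+cognition": ("brain", "cognition"),
    "brain+apoe": ("brain", "apoe"),
    "ALL": ("brain", "demographics", "cognition", "apoe"),
}

DEMOGRAPHIC_VARS = ["age", "sex"]
APOE_DERIVED = ["APOE_any_e4", "APOE_e4_count"]


@dataclass
class FeatureSetSpec:
    """A named recipe resolving to an ordered feature-column list."""

    name: str

    def __post_init__(self) -> None:
        if self.name not in _BLOCKS:
            raise ValueError(
                f"unknown feature set {self.name!r}; expected one of "
                f"{FEATURE_SET_NAMES}"
            )

    @property
    def blocks(self) -> tuple[str, ...]:
        return _BLOCKS[self.name]

    def columns(self, K: int) -> list[str]:
        cols: list[str] = []
        for block in self.blocks:
            if block == "brain":
                cols += [f"IC_{k + 1}" for k in range(K)]
            elif block == "demographics":
                cols += DEMOGRAPHIC_VARS
            elif block == "cognition":
                cols += COGNITIVE_VARS
            elif block == "apoe":
                cols += APOE_DERIVED
        return cols


def apoe_features(genotypes: pd.Series) -> pd.DataFrame:
    """Expand genotype strings ('e3/e4') into carrier and count features."""
    counts = genotypes.map(
        lambda g: sum(a == "e4" for a in str(g).split("/")) if pd.notna(g)
        else np.nan
    )
    return pd.DataFrame(
        {"APOE_any_e4": (counts > 0).astype(float).where(counts.notna()),
         "APOE_e4_count": counts.astype(float)},
        index=genotypes.index,
    )


def assemble_features(
    components: ComponentSet | np.ndarray | None,
    table: pd.DataFrame,
    spec: FeatureSetSpec | str,
) -> pd.DataFrame:
    """Build the feature matrix for ``spec``, aligned to ``table`` rows.

    ``components`` may be a fitted :class:`ComponentSet` (its loadings are
    used, aligned by position), a plain subjects x K loading array, or None
    when the spec uses no brain block.  Raises on a subject-count mismatch.
    Scaling and imputation are deliberately NOT applied here: they are fit
    on training folds at model-fit time.
    """
    if isinstance(spec, str):
        spec = FeatureSetSpec(spec)
    parts: list[pd.DataFrame] = []
    for block in spec.blocks:
        if block == "brain":
            if components is None:
                raise ValueError(
                    f"feature set {spec.name!r} needs component loadings"
                )
            loadings = (
                components.loadings
                if isinstance(components, ComponentSet)
                else np.asarray(components, dtype=float)
            )
            if loadings.shape[0] != len(table):
                raise ValueError(
                    f"loadings rows ({loadings.shape[0]}) do not match the "
                    f"subject table ({len(table)})"
                )
            K = loadings.shape[1]
            parts.append(pd.DataFrame(
                loadings, columns=[f"IC_{k + 1}" for k in range(K)],
                index=table.index,
            ))
        elif block == "demographics":
            demo = table[["age"]].astype(float).copy()
            demo["sex"] = (table["sex"] == "M").astype(float)
            parts.append(demo)
        elif block == "cognition":
            missing = [c for c in COGNITIVE_VARS if c not in table.columns]
            if missing:
                raise ValueError(f"subject table lacks columns {missing}")
            parts.append(table[COGNITIVE_VARS].astype(float))
        elif block == "apoe":
            parts.append(apoe_features(table["apoe"]))
    return pd.concat(parts, axis=1)
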