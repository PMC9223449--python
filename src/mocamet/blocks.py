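"""Concentration-block containers and the deterministic preprocessing steps.

A :class:`ConcentrationBlock` holds one samples x metabolites concentration
matrix (plasma or aorta) together with sample metadata and a validity mask
marking which cells fell inside the assay's dynamic range.  Preprocessing is
the sequence the analysis assumes: drop analytes quantified in too few
samples (strictly more than 70% of values must be in-range), divide aortic
concentrations by the wet weight of the dissected aorta, and impute the
remaining censored cells before multivariate modelling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

import numpy as np
import pandas as pd

from .panel import MetaboliteDescriptor


class Group(str, Enum):
    SHAM = "SHAM"   # standard diet
    HCD = "HCD"     # high-cholesterol diet
    ANG = "ANG"     # high-cholesterol diet + angiotensin II (aneurysm group)


class Tissue(str, Enum):
    PLASMA = "plasma"
    AORTA = "aorta"


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    group: Group
    tissue: Tissue
    aorta_weight: Optional[float] = None  # mg, required iff tissue == aorta

    def __post_init__(self) -> None:
        if self.tissue is Tissue.AORTA:
            if self.aorta_weight is None or not np.isfinite(self.aorta_weight):
                raise ValueError(
                    f"sample {self.sample_id!r}: aorta sample without weight"
                )
            if self.aorta_weight <= 0:
                raise ValueError(
                    f"sample {self.sample_id!r}: non-positive aorta weight "
                    f"{self.aorta_weight}"
                )
        elif self.aorta_weight is not None:
            raise ValueError(
                f"sample {self.sample_id!r}: plasma sample with aorta weight"
            )


@dataclass
class ConcentrationBlock:
    """One tissue block: concentrations (uM), metadata and validity mask."""

    samples: list[SampleMeta]
    metabolites: list[MetaboliteDescriptor]
    values: np.ndarray       # (m, p) float
    valid_mask: np.ndarray   # (m, p) bool; True = inside dynamic range
    weight_normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        m, p = len(self.samples), len(self.metabolites)
        if self.values.shape != (m, p):
            raise ValueError(
                f"values shape {self.values.shape} != ({m}, {p})"
            )
        if self.valid_mask.shape != (m, p):
            raise ValueError(
                f"valid_mask shape {self.valid_mask.shape} != ({m}, {p})"
            )
        if not np.all(np.isfinite(self.values[self.valid_mask])):
            raise ValueError("non-finite concentration marked valid")
        names = [d.name for d in self.metabolites]
        if len(set(names)) != len(names):
            raise ValueError("duplicate metabolite names in block")
        tissues = {s.tissue for s in self.samples}
        if len(tissues) > 1:
            raise ValueError("mixed tissues within one block")

    @property
    def tissue(self) -> Tissue:
        return self.samples[0].tissue

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def metabolite_names(self) -> list[str]:
        return [d.name for d in self.metabolites]

    @property
    def groups(self) -> np.ndarray:
        return np.array([s.group.value for s in self.samples])

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.metabolite_names.index(name)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=[s.sample_id for s in self.samples],
            columns=self.metabolite_names,
        )

    def valid_fractions(self) -> np.ndarray:
        """Per-metabolite fraction of in-range values."""
        return self.valid_mask.mean(axis=0)


@dataclass(frozen=True)
class FilterReport:
    dropped: list[str] = field(default_factory=list)
    valid_fraction: dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "metabolite": self.dropped,
                "valid_fraction": [self.valid_fraction[n] for n in self.dropped],
            }
        )


def filter_dynamic_range(
    block: ConcentrationBlock, min_fraction: float = 0.70
) -> tuple[ConcentrationBlock, FilterReport]:
    """Retain metabolites with *strictly more than* ``min_fraction`` valid values.

    7 valid out of 10 at the default 0.70 is dropped; 8/10 is kept.  Sample
    set and retained values are untouched; the operation is idempotent.
    """
    if not 0 < min_fraction < 1:
        raise ValueError(f"min_fraction must lie in (0, 1), got {min_fraction}")
    if block.n_samples == 0 or not block.metabolites:
        raise ValueError("cannot filter an empty block")
    fractions = block.valid_fractions()
    keep = fractions > min_fraction
    report = FilterReport(
        dropped=[n for n, k in zip(block.metabolite_names, keep) if not k],
        valid_fraction={
            n: float(f)
            for n, f, k in zip(block.metabolite_names, fractions, keep)
            if not k
        },
    )
    filtered = ConcentrationBlock(
        samples=list(block.samples),
        metabolites=[d for d, k in zip(block.metabolites, keep) if k],
        values=block.values[:, keep].copy(),
        valid_mask=block.valid_mask[:, keep].copy(),
        weight_normalized=block.weight_normalized,
    )
    return filtered, report


def normalize_by_weight(block: ConcentrationBlock) -> ConcentrationBlock:
    """Divide every aortic concentration by that sample's aorta wet weight (mg).

    Units become uM per mg of tissue; the extraction volume is constant across
    samples and is not corrected for.  Plasma blocks are rejected.
    """
    if block.tissue is not Tissue.AORTA:
        raise ValueError("weight normalization applies to aorta blocks only")
    if block.weight_normalized:
        raise ValueError("block already weight-normalized")
    weights = np.array([s.aorta_weight for s in block.samples], dtype=float)
    # SampleMeta guarantees positivity, but a block could be built directly
    if np.any(~np.isfinite(weights)) or np.any(weights <= 0):
        raise ValueError("aorta weights must be positive and finite")
    return ConcentrationBlock(
        samples=list(block.samples),
        metabolites=list(block.metabolites),
        values=block.values / weights[:, None],
        valid_mask=block.valid_mask.copy(),
        weight_normalized=True,
    )


def impute_below_lod(
    block: ConcentrationBlock, strategy: str = "half_min"
) -> tuple[ConcentrationBlock, int]:
    """Replace out-of-range cells; returns the block and the imputation count.

    ``half_min`` inserts half the per-metabolite minimum of the in-range
    values (the usual targeted-metabolomics convention for left-censored
    cells); ``zero`` inserts 0.  Assumes the dynamic-range filter already ran,
    so every column has at least one valid value.
    """
    if strategy not in ("half_min", "zero"):
        raise ValueError(f"unknown imputation strategy {strategy!r}")
    values = block.values.copy()
    n_imputed = int((~block.valid_mask).sum())
    if n_imputed == 0:
        return block, 0
    for j in range(values.shape[1]):
        invalid = ~block.valid_mask[:, j]
        if not invalid.any():
            continue
        valid_vals = values[block.valid_mask[:, j], j]
        if valid_vals.size == 0:
            raise ValueError(
                f"metabolite {block.metabolite_names[j]!r} has no valid "
                "values; run filter_dynamic_range first"
            )
        fill = 0.0 if strategy == "zero" else float(valid_vals.min()) / 2.0
        values[invalid, j] = fill
    imputed = ConcentrationBlock(
        samples=list(block.samples),
        metabolites=list(block.metabolites),
        values=values,
        valid_mask=np.ones_like(block.valid_mask),
        weight_normalized=block.weight_normalized,
    )
    return imputed, n_imputed
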