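"""Reading and writing wide concentration tables.

The on-disk dialect is a Biocrates-style wide export: one row per sample,
metadata columns (``sample_id``, ``group``, and ``aorta_weight_mg`` for
tissue blocks) followed by one column per metabolite.  Cells hold a decimal
concentration in uM or a below-LOD sentinel (``<LOD``, ``< LOD``, ``NA`` or
an empty cell), which is recorded as out-of-dynamic-range in the block's
validity mask.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from .blocks import ConcentrationBlock, Group, SampleMeta, Tissue
from .panel import build_panel

LOD_SENTINELS = {"<LOD", "< LOD", "NA", ""}
_META_COLUMNS = {"sample_id", "group", "tissue", "aorta_weight_mg"}


def _sep_for(path: str | Path) -> str:
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


def read_block(path: str | Path, tissue: Tissue | str) -> ConcentrationBlock:
    """Read one wide concentration table into a :class:`ConcentrationBlock`."""
    tissue = Tissue(tissue)
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str, keep_default_na=False)
    for required in ("sample_id", "group"):
        if required not in df.columns:
            raise ValueError(f"{path}: missing metadata column {required!r}")
    if tissue is Tissue.AORTA and "aorta_weight_mg" not in df.columns:
        raise ValueError(f"{path}: aorta table without aorta_weight_mg column")
    metabolite_cols = [c for c in df.columns if c not in _META_COLUMNS]
    if len(set(metabolite_cols)) != len(metabolite_cols):
        raise ValueError(f"{path}: duplicate metabolite columns")
    metabolites = build_panel(metabolite_cols)

    samples = []
    for _, row in df.iterrows():
        weight = None
        if tissue is Tissue.AORTA:
            weight = float(row["aorta_weight_mg"])
        samples.append(
            SampleMeta(
                sample_id=str(row["sample_id"]),
                group=Group(row["group"]),
                tissue=tissue,
                aorta_weight=weight,
            )
        )

    m, p = len(samples), len(metabolite_cols)
    values = np.full((m, p), np.nan)
    mask = np.zeros((m, p), dtype=bool)
    for j, col in enumerate(metabolite_cols):
        for i, cell in enumerate(df[col]):
            cell = cell.strip()
            if cell in LOD_SENTINELS:
                continue
            try:
                values[i, j] = float(cell)
            except ValueError as exc:
                raise ValueError(
                    f"{path}: non-numeric cell {cell!r} for metabolite "
                    f"{col!r}, sample {samples[i].sample_id!r}"
                ) from exc
            mask[i, j] = True
    return ConcentrationBlock(samples, metabolites, values, mask)


def write_block(block: ConcentrationBlock, path: str | Path) -> None:
    """Write a block back to the wide delimited format (``<LOD`` at invalid cells).

    Valid concentrations are written with ``repr`` round-trip precision, so a
    read -> write -> read cycle reproduces the block exactly.
    """
    path = Path(path)
    os.makedirs(path.parent, exist_ok=True)
    out = {"sample_id": [s.sample_id for s in block.samples],
           "group": [s.group.value for s in block.samples]}
    if block.tissue is Tissue.AORTA:
        out["aorta_weight_mg"] = [repr(s.aorta_weight) for s in block.samples]
    for j, name in enumerate(block.metabolite_names):
        col = []
        for i in range(block.n_samples):
            if block.valid_mask[i, j]:
                col.append(repr(float(block.values[i, j])))
            else:
                col.append("<LOD")
        out[name] = col
    pd.DataFrame(out).to_csv(path, sep=_sep_for(path), index=False)
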