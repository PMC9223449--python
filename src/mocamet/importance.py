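"""Rank-based variable importance against the first joint component.

For each metabolite the Kendall tau-b rank correlation between its
concentration profile and the shared risk score t_j,1 is computed together
with a two-sided p-value; Benjamini-Hochberg step-up selection at q = 0.05
flags the significant analytes.  The (loading, tau, -log10 p) triples are the
coordinates of the 3D volcano display: x = loading on t_j,1, y = tau,
z = -log10 p, colored by metabolite class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .blocks import ConcentrationBlock
from .moca import MocaModel

#: Volcano display color key per metabolite class.
CLASS_COLORS = {
    "phosphatidylcholine": "red",
    "sphingomyelin": "yellow",
    "lysophosphatidylcholine": "blue",
    "acylcarnitine": "violet",
    "aminoacid": "green",
    "biogenic_amine": "green",
    "hexose": "orange",
}


def kendall_tau(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Kendall tau-b with a two-sided p-value for H0: tau = 0.

    The tie-corrected tau-b variant is used because LOD imputation produces
    tied concentrations.  The p-value comes from exact enumeration of rank
    permutations for n <= 9 without ties, otherwise from the normal
    approximation with tie-corrected variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if x.size < 3:
        raise ValueError(f"need at least 3 observations, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Kendall tau undefined for a constant vector")
    has_ties = (np.unique(x).size < x.size) or (np.unique(y).size < y.size)
    method = "exact" if (x.size <= 9 and not has_ties) else "asymptotic"
    res = stats.kendalltau(x, y, method=method)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class BhResult:
    q: float
    alpha_threshold: float  # largest admissible sorted p; 0 when none pass
    n_significant: int


def bh_select(p_values: np.ndarray, q: float = 0.05) -> tuple[BhResult, np.ndarray]:
    """Benjamini-Hochberg step-up selection at FDR level ``q``.

    Returns the result summary and a boolean mask flagging the k smallest
    p-values, where k = max{i : p_(i) <= i q / m} over the ascending sort.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    admissible = np.flatnonzero(sorted_p <= (np.arange(1, m + 1) * q / m))
    if admissible.size == 0:
        return BhResult(q=q, alpha_threshold=0.0, n_significant=0), np.zeros(m, bool)
    k = int(admissible[-1]) + 1
    threshold = float(sorted_p[k - 1])
    mask = p <= threshold
    return BhResult(q=q, alpha_threshold=threshold, n_significant=int(mask.sum())), mask


def importance_table(
    block: ConcentrationBlock,
    model: MocaModel,
    block_name: str,
    q: float = 0.05,
) -> pd.DataFrame:
    """Per-metabolite loading, tau against t_j,1, p-value and BH significance.

    Tau is computed between each metabolite's concentration vector and the
    shared score vector across mice (rank-based, hence identical on raw or
    UV-scaled concentrations); BH runs over all p-values of this block.
    """
    if not model.oriented:
        raise ValueError("orient the model (orient_model) before ranking")
    names = block.metabolite_names
    if names != model.metabolite_names[block_name]:
        raise ValueError(
            f"block/model metabolite mismatch for {block_name!r}"
        )
    t1 = model.joint_scores[:, 0]
    loadings = model.joint_loadings[block_name][:, 0]
    taus = np.empty(len(names))
    pvals = np.empty(len(names))
    for j in range(len(names)):
        taus[j], pvals[j] = kendall_tau(block.values[:, j], t1)
    bh, mask = bh_select(pvals, q=q)
    with np.errstate(divide="ignore"):
        neg_log10 = -np.log10(pvals)
    table = pd.DataFrame(
        {
            "metabolite": names,
            "class": [d.metabolite_class.value for d in block.metabolites],
            "loading": loadings,
            "tau": taus,
            "p_value": pvals,
            "neg_log10_p": neg_log10,
            "significant": mask,
        }
    )
    table.attrs["bh"] = bh
    return table


def volcano_coordinates(records: pd.DataFrame) -> pd.DataFrame:
    """3D-volcano coordinate table: (loading, tau, -log10 p) plus color key."""
    out = records[
        ["metabolite", "loading", "tau", "neg_log10_p", "significant"]
    ].copy()
    out.insert(4, "color", records["class"].map(CLASS_COLORS))
    return out
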