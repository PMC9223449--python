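"""Group comparisons, biochemical class sums/ratios, and ROC biomarker scoring.

Pairwise group differences use the Mann-Whitney-Wilcoxon test with
Benjamini-Hochberg correction over the tested family.  Candidate biomarkers
are single features — metabolites, class sums (BCAA, PC, SM, total
carnitine, long-chain acylcarnitines) or ratios (BCAA/Gly, BCAA/Gln,
LysoPC/PC, PC/SM, unsaturated/saturated lysoPC) — scored by the area under
the ROC curve with a DeLong 95% confidence interval and the AUC >= 0.80
"good classifier" convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Callable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .blocks import ConcentrationBlock
from .importance import bh_select
from .panel import MetaboliteClass, MetaboliteDescriptor

# ---------------------------------------------------------------------------
# class sums and ratios

Rule = Union[str, Sequence[str], Callable[[MetaboliteDescriptor], bool]]

#: Named sum rules over the panel taxonomy.
NAMED_RULES: dict[str, Callable[[MetaboliteDescriptor], bool]] = {
    "BCAA": lambda d: d.name in ("Leu", "Ile", "Val"),
    "PC": lambda d: d.metabolite_class is MetaboliteClass.PHOSPHATIDYLCHOLINE,
    "SM": lambda d: d.metabolite_class is MetaboliteClass.SPHINGOMYELIN,
    "LysoPC": lambda d: (
        d.metabolite_class is MetaboliteClass.LYSOPHOSPHATIDYLCHOLINE
    ),
    # total carnitine content: free carnitine (C0) plus every acylcarnitine
    "total_carnitine": lambda d: (
        d.metabolite_class is MetaboliteClass.ACYLCARNITINE
    ),
    # long-chain acylcarnitines: acyl moiety of strictly more than 12 carbons
    "LCAC": lambda d: (
        d.metabolite_class is MetaboliteClass.ACYLCARNITINE
        and d.acyl_carbons is not None
        and d.acyl_carbons > 12
    ),
    "C2+C3": lambda d: d.name in ("C2", "C3"),
    "LysoPC_unsaturated": lambda d: (
        d.metabolite_class is MetaboliteClass.LYSOPHOSPHATIDYLCHOLINE
        and d.is_saturated is False
    ),
    "LysoPC_saturated": lambda d: (
        d.metabolite_class is MetaboliteClass.LYSOPHOSPHATIDYLCHOLINE
        and d.is_saturated is True
    ),
}


def _resolve_rule(rule: Rule) -> Callable[[MetaboliteDescriptor], bool]:
    if callable(rule):
        return rule
    if isinstance(rule, str):
        if rule in NAMED_RULES:
            return NAMED_RULES[rule]
        return lambda d: d.name == rule
    names = set(rule)
    return lambda d: d.name in names


def class_sum(block: ConcentrationBlock, rule: Rule) -> np.ndarray:
    """Per-sample sum of the metabolites selected by ``rule``."""
    predicate = _resolve_rule(rule)
    mask = np.array([predicate(d) for d in block.metabolites])
    if not mask.any():
        raise ValueError(f"rule {rule!r} matches no metabolite in the block")
    return block.values[:, mask].sum(axis=1)


@dataclass(frozen=True)
class RatioSpec:
    name: str
    numerator: Rule
    denominator: Rule


#: The candidate biomarker ratios of interest.
DEFAULT_RATIO_SPECS = (
    RatioSpec("BCAA", "BCAA", None),   # plain sum, no denominator
    RatioSpec("BCAA/Gly", "BCAA", "Gly"),
    RatioSpec("BCAA/Gln", "BCAA", "Gln"),
    RatioSpec("LysoPC/PC", "LysoPC", "PC"),
    RatioSpec("PC/SM", "PC", "SM"),
    RatioSpec("LysoPC U/S", "LysoPC_unsaturated", "LysoPC_saturated"),
)


def ratio_statistic(block: ConcentrationBlock, spec: RatioSpec) -> np.ndarray:
    """Per-sample numerator-sum over denominator-sum (or plain sum)."""
    numerator = class_sum(block, spec.numerator)
    if spec.denominator is None:
        return numerator
    denominator = class_sum(block, spec.denominator)
    zero = np.flatnonzero(denominator <= 0)
    if zero.size:
        ids = [block.samples[i].sample_id for i in zero]
        raise ValueError(
            f"{spec.name}: non-positive denominator for samples {ids}"
        )
    return numerator / denominator


# ---------------------------------------------------------------------------
# nonparametric group comparisons


def mannwhitney_pairwise(
    values: np.ndarray, groups: Sequence[str]
) -> dict[tuple[str, str], tuple[float, float]]:
    """Two-sided Mann-Whitney U per group pair: {(g1, g2): (U, p)}.

    Exact enumeration when min(n1, n2) <= 8 without ties, otherwise the
    normal approximation with tie correction (and continuity correction).
    U is reported for the first group of the pair.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = list(dict.fromkeys(groups))
    if len(levels) < 2:
        raise ValueError("need at least two groups")
    out = {}
    for g1, g2 in combinations(levels, 2):
        x, y = values[groups == g1], values[groups == g2]
        if min(x.size, y.size) < 2:
            raise ValueError(f"group {g1 if x.size < 2 else g2!r} has < 2 samples")
        pooled = np.concatenate([x, y])
        has_ties = np.unique(pooled).size < pooled.size
        method = (
            "exact" if (min(x.size, y.size) <= 8 and not has_ties)
            else "asymptotic"
        )
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
        out[(g1, g2)] = (float(res.statistic), float(res.pvalue))
    return out


def group_comparison_table(
    block: ConcentrationBlock, q: float = 0.05
) -> pd.DataFrame:
    """Pairwise Mann-Whitney for every metabolite, BH over metabolite x pair."""
    rows = []
    for j, name in enumerate(block.metabolite_names):
        for (g1, g2), (u, p) in mannwhitney_pairwise(
            block.values[:, j], block.groups
        ).items():
            rows.append((name, g1, g2, u, p))
    table = pd.DataFrame(rows, columns=["metabolite", "group1", "group2", "U", "p_value"])
    _, mask = bh_select(table["p_value"].to_numpy(), q=q)
    table["significant"] = mask
    return table


# ---------------------------------------------------------------------------
# ROC / AUC with DeLong confidence interval


@dataclass(frozen=True)
class RocResult:
    auc: float
    ci_low: float
    ci_high: float
    n_pos: int
    n_neg: int
    good_classifier: bool   # AUC >= cutoff (default 0.80)

    def ci_includes(self, value: float) -> bool:
        return self.ci_low <= value <= self.ci_high


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def roc_auc_delong(
    scores: np.ndarray,
    labels: np.ndarray,
    cutoff: float = 0.80,
    level: float = 0.95,
) -> RocResult:
    """AUC by pair counting (ties count 1/2) with DeLong's variance estimate.

    The AUC equals U / (n_pos * n_neg) for the Mann-Whitney statistic of the
    score; the variance comes from the placement values of each class
    (DeLong's structural-components estimator), giving a normal-theory
    confidence interval clipped to [0, 1].
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    pos, neg = scores[labels], scores[~labels]
    n_pos, n_neg = pos.size, neg.size
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    all_ranks = _midrank(scores)
    pos_ranks = _midrank(pos)
    neg_ranks = _midrank(neg)
    # placement values: fraction of the other class each observation beats
    v10 = (all_ranks[labels] - pos_ranks) / n_neg          # per positive
    v01 = 1.0 - (all_ranks[~labels] - neg_ranks) / n_pos   # per negative
    auc = float(v10.mean())
    if n_pos > 1 and n_neg > 1:
        var = v10.var(ddof=1) / n_pos + v01.var(ddof=1) / n_neg
    else:
        var = 0.0
    z = stats.norm.ppf(0.5 + level / 2)
    half = z * np.sqrt(var)
    return RocResult(
        auc=auc,
        ci_low=float(np.clip(auc - half, 0.0, 1.0)),
        ci_high=float(np.clip(auc + half, 0.0, 1.0)),
        n_pos=n_pos,
        n_neg=n_neg,
        good_classifier=bool(auc >= cutoff),
    )


#: Contrast name -> (positive groups, negative groups)
DEFAULT_CONTRASTS: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {
    "ANG_vs_rest": (("ANG",), ("SHAM", "HCD")),
    "HCD_vs_ANG": (("ANG",), ("HCD",)),
    "SHAM_vs_HCD": (("HCD",), ("SHAM",)),
}


def evaluate_biomarkers(
    block: ConcentrationBlock,
    specs: Sequence[RatioSpec] = DEFAULT_RATIO_SPECS,
    contrasts: Optional[dict[str, tuple[tuple[str, ...], tuple[str, ...]]]] = None,
    cutoff: float = 0.80,
) -> pd.DataFrame:
    """Score each candidate ratio on each contrast; AUC reported >= 0.5.

    The orientation making AUC >= 0.5 is used (and recorded in ``flipped``)
    because discriminative performance, not direction, is being evaluated.
    ``lci_includes_cutoff`` flags intervals whose lower bound does not clear
    the 0.80 line even when the point estimate does.
    """
    contrasts = DEFAULT_CONTRASTS if contrasts is None else contrasts
    groups = block.groups
    rows = []
    for spec in specs:
        feature = ratio_statistic(block, spec)
        for contrast, (pos_groups, neg_groups) in contrasts.items():
            keep = np.isin(groups, pos_groups + neg_groups)
            if not np.isin(groups, pos_groups).any() or not np.isin(
                groups, neg_groups
            ).any():
                raise ValueError(f"contrast {contrast!r} has an empty side")
            labels = np.isin(groups[keep], pos_groups)
            scores = feature[keep]
            roc = roc_auc_delong(scores, labels, cutoff=cutoff)
            flipped = roc.auc < 0.5
            if flipped:
                roc = roc_auc_delong(-scores, labels, cutoff=cutoff)
            rows.append(
                (
                    spec.name, contrast, roc.auc, roc.ci_low, roc.ci_high,
                    roc.n_pos, roc.n_neg, roc.good_classifier, flipped,
                    roc.ci_low < cutoff <= roc.ci_high,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "spec", "contrast", "auc", "ci_low", "ci_high", "n_pos",
            "n_neg", "good_classifier", "flipped", "lci_includes_cutoff",
        ],
    )


# ---------------------------------------------------------------------------
# clinical-chemistry helper


def friedewald_ldl(ct: float, hdl: float, tg: float, tg_warn: float = 4.5) -> float:
    """LDL cholesterol (mmol/L) = total cholesterol - HDL - triglycerides/2.2.

    Valid for fasting samples with moderate triglycerides; a warning is
    emitted above ``tg_warn`` mmol/L where the formula is unreliable.
    """
    for label, v in (("ct", ct), ("hdl", hdl), ("tg", tg)):
        if v < 0:
            raise ValueError(f"{label} must be nonnegative, got {v}")
    if tg > tg_warn:
        warnings.warn(
            f"triglycerides {tg} mmol/L exceed the Friedewald validity "
            f"bound {tg_warn}",
            stacklevel=2,
        )
    return ct - hdl - tg / 2.2
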