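"""Synthetic two-block cohorts with known ground truth.

The generator emulates the statistical structure the pipeline assumes: a
three-group design (SHAM n=11, HCD n=10, ANG n=10) driven by one latent
"aneurysmal risk" factor whose group means increase from control to
high-cholesterol diet to diet-plus-angiotensin-II; a p180-like 188-analyte
panel measured in plasma and aorta; block-specific unique factors; lognormal
concentration noise with class-specific baselines spanning several orders of
magnitude (hexose >> amino acids >> lysoPC); a planted signature giving
selected metabolites a fixed correlation sign with risk; and below-LOD
censoring of the lowest tail of each analyte.

On the log scale each standardized column decomposes as

    z = sqrt(f_j) * s * risk  +  sqrt(f_u) * unique  +  sqrt(f_n) * eps

with variance fractions (f_j, f_u, f_n) defaulting to (0.4, 0.3, 0.3) and the
sign/magnitude ``s`` random (+-1) except where the signature pins it.  The
block-unique factor loads the polar LC panel common-mode — like the shared
per-sample derivatization/dilution efficiency of a targeted kit, it moves
all amino acids and biogenic amines of a block in the same direction, so
ratios of polar analytes cancel it — and the remaining analytes with random
sign.  Realized factors are
standardized so the planted fractions hold in-sample; concentrations are
``baseline * exp(log_sigma * z)``, and the aorta's structure is planted on
the weight-normalized scale (the raw export multiplies the weights back in).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .blocks import ConcentrationBlock, Group, SampleMeta, Tissue
from .panel import MetaboliteClass, MetaboliteDescriptor, default_panel

#: Typical concentration scale (uM) per class, log-uniform jitter around it.
CLASS_BASELINES = {
    MetaboliteClass.HEXOSE: 8000.0,
    MetaboliteClass.AMINOACID: 200.0,
    MetaboliteClass.BIOGENIC_AMINE: 5.0,
    MetaboliteClass.PHOSPHATIDYLCHOLINE: 30.0,
    MetaboliteClass.LYSOPHOSPHATIDYLCHOLINE: 8.0,
    MetaboliteClass.SPHINGOMYELIN: 40.0,
    MetaboliteClass.ACYLCARNITINE: 1.0,
}


#: Joint-loading multipliers for the named signature hits.  Two tiers: the
#: decreased polar protectives and the top aortic discriminators are
#: near-perfect markers (a magnitude-4 column is ~91% joint variance), while
#: the secondary hits — including the branched-chain amino acids, whose
#: standalone classifier is only marginal — carry a modest boost.  Bulk
#: columns keep the default 0.4/0.3/0.3 split.
STRONG_MAGNITUDE = 4.0
MODEST_MAGNITUDE = 1.5


def default_signature() -> dict[str, dict[str, float]]:
    """Planted signed effect with risk, per block and metabolite.

    Values are signed joint-loading multipliers: the sign is the direction of
    association with aneurysmal risk, the magnitude scales the column's joint
    loading relative to the bulk panel.  Plasma: branched-chain amino acids
    rise with risk while glycine, glutamine, taurine, free carnitine and the
    shortest acylcarnitines fall steeply — so BCAA/Gly and BCAA/Gln ratios
    combine opposing effects into strong classifiers while BCAA alone stays
    marginal.  Aorta: ADMA, polyamine precursors and collagen-turnover
    markers rise while PC/SM species, hexose and the same polar protectives
    fall.  Class-level entries are written ``class:<name>`` (direction only,
    magnitude 1) and expanded against the panel.
    """
    s, w = STRONG_MAGNITUDE, MODEST_MAGNITUDE
    plasma = {
        "Leu": w, "Ile": w, "Val": w,
        "Phe": w, "Trp": w, "Thr": w, "Met": w,
        "alpha-AAA": w, "Putrescine": w,
        "Gly": -s, "Gln": -s, "Taurine": -s,
        "C0": -s, "C2": -s, "C3": -s,
        "class:phosphatidylcholine": 1.0,
        "class:sphingomyelin": 1.0,
        "class:lysophosphatidylcholine": 1.0,
    }
    aorta = {
        "ADMA": s, "Putrescine": s, "Orn": s,
        "Lys": w, "alpha-AAA": w, "t4-OH-Pro": w, "Cit": w, "Trp": w,
        "His": w, "Spermidine": w,
        "Taurine": -s, "Gly": -s, "C0": -s, "C2": -s,
        "H1": -s, "Carnosine": -s,
        "class:phosphatidylcholine": -1.0,
        "class:sphingomyelin": -1.0,
    }
    return {"plasma": plasma, "aorta": aorta}


@dataclass(frozen=True)
class CohortSpec:
    """Study-design parameters of the synthetic cohort."""

    n_sham: int = 11
    n_hcd: int = 10
    n_ang: int = 10
    joint_effect: tuple[float, float, float] = (-1.0, 0.0, 1.0)
    joint_frac: float = 0.4
    unique_frac: float = 0.3
    noise_frac: float = 0.3
    within_group_sd: float = 0.5
    log_sigma: float = 0.25
    lod_quantile: float = 0.02
    aorta_weight_mean: float = 5.0   # mg
    aorta_weight_log_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        total = self.joint_frac + self.unique_frac + self.noise_frac
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"variance fractions must sum to 1, got {total}")
        if min(self.joint_frac, self.unique_frac, self.noise_frac) < 0:
            raise ValueError("variance fractions must be nonnegative")
        if not (self.joint_effect[0] <= self.joint_effect[1] <= self.joint_effect[2]):
            raise ValueError("group means of the risk factor must be monotone")
        if not 0 <= self.lod_quantile < 0.5:
            raise ValueError("lod_quantile must lie in [0, 0.5)")

    @property
    def n_total(self) -> int:
        return self.n_sham + self.n_hcd + self.n_ang


@dataclass
class GroundTruth:
    """What the generator planted, for recovery checks."""

    risk: np.ndarray                                # (m,) latent factor
    unique_factors: dict[str, np.ndarray]           # block -> (m,)
    signature_effects: dict[str, dict[str, float]]  # block -> name -> signed magnitude
    joint_signs: dict[str, np.ndarray]              # block -> (p,) all columns
    uncensored: dict[str, np.ndarray]               # block -> (m, p) values
    censoring_mask: dict[str, np.ndarray]           # block -> (m, p) bool valid


def _zscore(v: np.ndarray) -> np.ndarray:
    return (v - v.mean()) / v.std(ddof=0)


def _expand_signature(
    signature: dict[str, float], panel: list[MetaboliteDescriptor]
) -> dict[str, float]:
    expanded: dict[str, float] = {}
    names = {d.name for d in panel}
    for key, sign in signature.items():
        if key.startswith("class:"):
            cls = MetaboliteClass(key.split(":", 1)[1])
            for d in panel:
                if d.metabolite_class is cls:
                    expanded.setdefault(d.name, sign)
        else:
            if key not in names:
                raise ValueError(f"signature metabolite {key!r} not in panel")
            expanded[key] = sign
    return expanded


def _simulate_block(
    spec: CohortSpec,
    panel: list[MetaboliteDescriptor],
    risk_std: np.ndarray,
    signature: dict[str, float],
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    m, p = risk_std.size, len(panel)
    unique = _zscore(rng.standard_normal(m))
    signs = np.where(rng.random(p) < 0.5, -1.0, 1.0)
    for j, d in enumerate(panel):
        if d.name in signature:
            signs[j] = signature[d.name]
    # the unique factor loads the polar LC panel (amino acids + biogenic
    # amines) common-mode — a shared per-sample derivatization/dilution
    # efficiency, the variation that ratios of polar analytes cancel — and
    # the remaining analytes with random sign (generic block-specific
    # structure that stays near-orthogonal to the planted risk loadings)
    polar = (MetaboliteClass.AMINOACID, MetaboliteClass.BIOGENIC_AMINE)
    u_signs = np.where(rng.random(p) < 0.5, -1.0, 1.0)
    for j, d in enumerate(panel):
        if d.metabolite_class in polar:
            u_signs[j] = 1.0
    z = (
        np.sqrt(spec.joint_frac) * np.outer(risk_std, signs)
        + np.sqrt(spec.unique_frac) * np.outer(unique, u_signs)
        + np.sqrt(spec.noise_frac) * rng.standard_normal((m, p))
    )
    baselines = np.array(
        [
            CLASS_BASELINES[d.metabolite_class]
            * np.exp(rng.uniform(-1.0, 1.0))
            for d in panel
        ]
    )
    values = baselines * np.exp(spec.log_sigma * z)
    return values, unique, signs


def _censor(values: np.ndarray, lod_quantile: float) -> np.ndarray:
    """Mark the k = round(q*m) lowest entries of each column out-of-range."""
    m, p = values.shape
    k = int(round(lod_quantile * m))
    mask = np.ones((m, p), dtype=bool)
    if k > 0:
        order = np.argsort(values, axis=0)
        for j in range(p):
            mask[order[:k, j], j] = False
    return mask


def generate_cohort(
    spec: CohortSpec,
    panel: Optional[list[MetaboliteDescriptor]] = None,
    signature: Optional[dict[str, dict[str, float]]] = None,
) -> tuple[ConcentrationBlock, ConcentrationBlock, GroundTruth]:
    """Generate matched plasma and aorta blocks plus the planted ground truth.

    Deterministic in ``spec.seed``: the same spec yields bit-identical
    output.  Censored cells carry NaN in the blocks; the uncensored values
    live in the returned :class:`GroundTruth`.
    """
    panel = default_panel() if panel is None else panel
    signature = default_signature() if signature is None else signature
    rng = np.random.default_rng(spec.seed)

    group_sizes = {"SHAM": spec.n_sham, "HCD": spec.n_hcd, "ANG": spec.n_ang}
    group_means = dict(zip(("SHAM", "HCD", "ANG"), spec.joint_effect))
    groups = [g for g, n in group_sizes.items() for _ in range(n)]
    risk = np.array(
        [group_means[g] + spec.within_group_sd * rng.standard_normal()
         for g in groups]
    )
    risk_std = _zscore(risk)

    expanded = {
        b: _expand_signature(signature.get(b, {}), panel)
        for b in ("plasma", "aorta")
    }
    values, unique_factors, joint_signs = {}, {}, {}
    for b in ("plasma", "aorta"):
        values[b], unique_factors[b], joint_signs[b] = _simulate_block(
            spec, panel, risk_std, expanded[b], rng
        )
    weights = spec.aorta_weight_mean * np.exp(
        spec.aorta_weight_log_sd * rng.standard_normal(spec.n_total)
        - spec.aorta_weight_log_sd**2 / 2
    )
    # the aorta's systematic structure lives on the weight-normalized scale
    # (uM per mg); the raw export is back-computed so that dividing by the
    # recorded weight recovers the planted structure exactly
    values["aorta"] = values["aorta"] * weights[:, None]

    masks = {b: _censor(values[b], spec.lod_quantile) for b in ("plasma", "aorta")}
    truth = GroundTruth(
        risk=risk,
        unique_factors=unique_factors,
        signature_effects=expanded,
        joint_signs=joint_signs,
        uncensored={b: values[b].copy() for b in ("plasma", "aorta")},
        censoring_mask={b: masks[b].copy() for b in ("plasma", "aorta")},
    )

    blocks = {}
    for b, tissue in (("plasma", Tissue.PLASMA), ("aorta", Tissue.AORTA)):
        samples = [
            SampleMeta(
                sample_id=f"m{i + 1:02d}",
                group=Group(groups[i]),
                tissue=tissue,
                aorta_weight=float(weights[i]) if tissue is Tissue.AORTA else None,
            )
            for i in range(spec.n_total)
        ]
        vals = values[b].copy()
        vals[~masks[b]] = np.nan
        blocks[b] = ConcentrationBlock(samples, list(panel), vals, masks[b])
    return blocks["plasma"], blocks["aorta"], truth


def null_cohort(
    spec: CohortSpec,
    panel: Optional[list[MetaboliteDescriptor]] = None,
) -> tuple[ConcentrationBlock, ConcentrationBlock, GroundTruth]:
    """Cohort under the global null: no joint and no unique structure.

    Every systematic variance fraction is reassigned to noise, so each
    analyte is independent lognormal jitter around its baseline.  This is
    the reference distribution for false-discovery-rate and permutation-null
    checks: correlating analytes against a score fitted on the same data is
    only calibrated when no systematic structure exists at all — a cohort
    that kept block-unique factors would make t_j,1 partially capture them,
    and analytes would then be *truly* correlated with the realized score
    (see the methods note on this caveat).
    """
    null_spec = replace(
        spec,
        joint_frac=0.0,
        unique_frac=0.0,
        noise_frac=1.0,
    )
    return generate_cohort(null_spec, panel=panel, signature={})
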