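"""Two-block joint/unique component decomposition (O2PLS/OnPLS family).

Given two mean-centered, unit-variance blocks measured on the same animals
(plasma ``X_pl`` and aorta ``X_ao``), the model splits each block into three
parts::

    X_b = T_j P_b' + U_b Q_b' + E_b

where the *joint* scores ``T_j`` (columns t_j,1, t_j,2, ...) are shared by
both blocks — a single realization per mouse — the *unique* scores ``U_b``
capture systematic structure present in one block only, and ``E_b`` is
residual noise.  The construction:

1. the leading singular-vector pair of the cross-product ``X_pl' X_ao`` gives
   per-block candidate scores ``t_pl = X_pl w_pl`` and ``t_ao = X_ao w_ao``;
2. after sign-aligning ``t_ao`` to ``t_pl``, the consensus joint score is the
   leading left singular vector of ``[t_pl | t_ao]`` (unit norm);
3. each block is deflated by least-squares projection onto the consensus
   score, and steps 1-3 repeat for the requested number of joint components;
4. unique components per block are the leading principal components of that
   block's deflated residual, re-orthogonalized against all joint scores;
5. variance bookkeeping: captured sum of squares over the total sum of
   squares of the scaled block, so joint + unique + residual R2 = 1.

Because both candidate scores live in the column spaces of the deflated
blocks, successive joint scores are mutually orthogonal, and the
decomposition reconstructs the scaled input exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .blocks import ConcentrationBlock

BLOCKS = ("plasma", "aorta")


@dataclass(frozen=True)
class ScalingSpec:
    center: bool = True
    unit_variance: bool = True


@dataclass
class ScalingRealization:
    """Column means and standard deviations actually applied to one block."""

    means: np.ndarray
    sds: np.ndarray


@dataclass
class MocaModel:
    joint_scores: np.ndarray                       # (m, A_j), unit-norm columns
    joint_loadings: dict[str, np.ndarray]          # block -> (p_b, A_j)
    unique_scores: dict[str, np.ndarray]           # block -> (m, A_u,b)
    unique_loadings: dict[str, np.ndarray]         # block -> (p_b, A_u,b)
    r2_joint_components: dict[str, np.ndarray]     # block -> (A_j,)
    r2_unique_components: dict[str, np.ndarray]    # block -> (A_u,b,)
    r2_residual: dict[str, float]
    scaling: dict[str, ScalingRealization]
    metabolite_names: dict[str, list[str]]
    oriented: bool = False

    @property
    def n_joint(self) -> int:
        return self.joint_scores.shape[1]

    def r2_joint(self, block: str) -> float:
        return float(self.r2_joint_components[block].sum())

    def r2_unique(self, block: str) -> float:
        return float(self.r2_unique_components[block].sum())

    def reconstruct(self, block: str) -> np.ndarray:
        """Joint part + unique part (scaled units); add nothing for residual."""
        rec = self.joint_scores @ self.joint_loadings[block].T
        if self.unique_scores[block].shape[1]:
            rec = rec + self.unique_scores[block] @ self.unique_loadings[block].T
        return rec


def scale_blocks(
    blocks: dict[str, Union[ConcentrationBlock, np.ndarray]],
    spec: ScalingSpec = ScalingSpec(),
) -> tuple[dict[str, np.ndarray], dict[str, ScalingRealization]]:
    """Mean-center and scale each column to unit variance (sample sd, m-1).

    Accepts either :class:`ConcentrationBlock` objects or plain arrays.
    Raises on constant columns (naming them) and on mismatched sample counts.
    """
    matrices: dict[str, np.ndarray] = {}
    names: dict[str, list[str]] = {}
    for key, b in blocks.items():
        if isinstance(b, ConcentrationBlock):
            if not b.valid_mask.all():
                raise ValueError(
                    f"block {key!r} still has out-of-range cells; impute first"
                )
            matrices[key] = np.asarray(b.values, dtype=float)
            names[key] = b.metabolite_names
        else:
            matrices[key] = np.asarray(b, dtype=float)
            names[key] = [f"var{j}" for j in range(matrices[key].shape[1])]
    m_counts = {X.shape[0] for X in matrices.values()}
    if len(m_counts) != 1:
        raise ValueError(f"blocks have mismatched sample counts: {m_counts}")

    scaled: dict[str, np.ndarray] = {}
    realizations: dict[str, ScalingRealization] = {}
    for key, X in matrices.items():
        means = X.mean(axis=0) if spec.center else np.zeros(X.shape[1])
        centered = X - means
        if spec.unit_variance:
            sds = centered.std(axis=0, ddof=1)
            constant = np.flatnonzero(sds == 0)
            if constant.size:
                bad = [names[key][j] for j in constant]
                raise ValueError(f"block {key!r}: constant columns {bad}")
        else:
            sds = np.ones(X.shape[1])
        scaled[key] = centered / sds
        realizations[key] = ScalingRealization(means=means, sds=sds)
    return scaled, realizations


def _leading_pair(cross: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    u, s, vt = np.linalg.svd(cross, full_matrices=False)
    return u[:, 0], vt[0, :], float(s[0])


def _residual_pca(
    residual: np.ndarray,
    joint_scores: np.ndarray,
    n_unique: int,
    tol: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray]:
    """Leading PCs of a deflated residual, re-orthogonalized to joint scores."""
    scores = []
    loadings = []
    R = residual.copy()
    scale = np.linalg.norm(residual) + 1.0
    for _ in range(n_unique):
        u, s, vt = np.linalg.svd(R, full_matrices=False)
        if s[0] < tol * scale:
            break
        t = u[:, 0] * s[0]
        # deflation already keeps R orthogonal to joint scores; re-project to
        # guard against numerical drift
        t = t - joint_scores @ (joint_scores.T @ t)
        for prev in scores:
            t = t - prev * (prev @ t)
        norm = np.linalg.norm(t)
        if norm < tol * scale:
            break
        t = t / norm
        p = R.T @ t
        scores.append(t)
        loadings.append(p)
        R = R - np.outer(t, p)
    if not scores:
        m, p = residual.shape
        return np.zeros((m, 0)), np.zeros((p, 0))
    return np.column_stack(scores), np.column_stack(loadings)


def select_n_unique(
    residual: np.ndarray,
    n_permutations: int = 99,
    quantile: float = 0.95,
    max_components: int = 5,
    rng: Optional[np.random.Generator] = None,
) -> int:
    """Permutation-null eigenvalue rule for the number of unique components.

    Counts leading singular values of the residual exceeding the ``quantile``
    of the largest singular value obtained after independently permuting each
    column (which destroys inter-column structure but keeps marginals).
    """
    rng = np.random.default_rng() if rng is None else rng
    s = np.linalg.svd(residual, compute_uv=False)
    null_top = np.empty(n_permutations)
    for b in range(n_permutations):
        perm = np.empty_like(residual)
        for j in range(residual.shape[1]):
            perm[:, j] = rng.permutation(residual[:, j])
        null_top[b] = np.linalg.svd(perm, compute_uv=False)[0]
    threshold = np.quantile(null_top, quantile)
    count = int(np.sum(s[:max_components] > threshold))
    return count


def fit_moca(
    Xpl: np.ndarray,
    Xao: np.ndarray,
    n_joint: int = 2,
    n_unique_pl: Union[int, str] = "auto",
    n_unique_ao: Union[int, str] = "auto",
    metabolite_names: Optional[dict[str, list[str]]] = None,
    scaling: Optional[dict[str, ScalingRealization]] = None,
    rng: Optional[np.random.Generator] = None,
) -> MocaModel:
    """Fit the two-block joint/unique decomposition on pre-scaled matrices.

    ``n_unique_*`` may be an integer or ``"auto"`` (permutation-null
    eigenvalue rule at the 95th percentile on the deflated residual).
    """
    Xpl = np.asarray(Xpl, dtype=float)
    Xao = np.asarray(Xao, dtype=float)
    if Xpl.shape[0] != Xao.shape[0]:
        raise ValueError(
            f"row mismatch: {Xpl.shape[0]} plasma vs {Xao.shape[0]} aorta "
            "samples (blocks must share mice in matched order)"
        )
    if n_joint < 1:
        raise ValueError("n_joint must be at least 1")
    rank = np.linalg.matrix_rank(Xpl.T @ Xao)
    if n_joint > rank:
        raise ValueError(
            f"n_joint={n_joint} exceeds the rank {rank} of the cross-product"
        )
    rng = np.random.default_rng(0) if rng is None else rng

    X = {"plasma": Xpl.copy(), "aorta": Xao.copy()}
    tss = {b: float(np.sum(X[b] ** 2)) for b in BLOCKS}

    joint_scores = []
    joint_loadings = {b: [] for b in BLOCKS}
    R = {b: X[b].copy() for b in BLOCKS}
    for _ in range(n_joint):
        w_pl, w_ao, _ = _leading_pair(R["plasma"].T @ R["aorta"])
        t_pl = R["plasma"] @ w_pl
        t_ao = R["aorta"] @ w_ao
        if t_pl @ t_ao < 0:
            t_ao = -t_ao
        T = np.column_stack([t_pl, t_ao])
        u, s, _ = np.linalg.svd(T, full_matrices=False)
        t_j = u[:, 0]
        # fix an arbitrary SVD sign so the fit is deterministic; the
        # scientific orientation is applied later by orient_model
        if t_j @ t_pl < 0:
            t_j = -t_j
        joint_scores.append(t_j)
        for b in BLOCKS:
            p_b = R[b].T @ t_j  # t_j has unit norm
            joint_loadings[b].append(p_b)
            R[b] = R[b] - np.outer(t_j, p_b)
    T_j = np.column_stack(joint_scores)
    P = {b: np.column_stack(joint_loadings[b]) for b in BLOCKS}

    requested = {"plasma": n_unique_pl, "aorta": n_unique_ao}
    U, Q = {}, {}
    for b in BLOCKS:
        n_u = requested[b]
        if n_u == "auto":
            n_u = select_n_unique(R[b], rng=rng)
        U[b], Q[b] = _residual_pca(R[b], T_j, int(n_u))
        R[b] = R[b] - U[b] @ Q[b].T

    r2_joint = {
        b: np.array([float(p @ p) / tss[b] for p in P[b].T]) for b in BLOCKS
    }
    r2_unique = {
        b: np.array([float(q @ q) / tss[b] for q in Q[b].T]) for b in BLOCKS
    }
    r2_residual = {b: float(np.sum(R[b] ** 2)) / tss[b] for b in BLOCKS}

    return MocaModel(
        joint_scores=T_j,
        joint_loadings=P,
        unique_scores=U,
        unique_loadings=Q,
        r2_joint_components=r2_joint,
        r2_unique_components=r2_unique,
        r2_residual=r2_residual,
        scaling=scaling
        or {b: ScalingRealization(np.zeros(X[b].shape[1]), np.ones(X[b].shape[1]))
            for b in BLOCKS},
        metabolite_names=metabolite_names
        or {b: [f"var{j}" for j in range(X[b].shape[1])] for b in BLOCKS},
    )


def variance_table(model: MocaModel) -> pd.DataFrame:
    """Per-component, per-block variance explained (R2, percent)."""
    rows = []
    for b in BLOCKS:
        for a, r2 in enumerate(model.r2_joint_components[b], start=1):
            rows.append((f"joint {a}", b, 100.0 * r2))
        for a, r2 in enumerate(model.r2_unique_components[b], start=1):
            rows.append((f"unique {a}", b, 100.0 * r2))
        rows.append(("residual", b, 100.0 * model.r2_residual[b]))
    table = pd.DataFrame(rows, columns=["component", "block", "r2_percent"])
    for b in BLOCKS:
        total = table.loc[table["block"] == b, "r2_percent"].sum()
        if abs(total - 100.0) > 1e-6:
            raise AssertionError(f"variance bookkeeping broken for {b}: {total}")
    return table


def orient_model(model: MocaModel, groups: Sequence[str]) -> MocaModel:
    """Fix the sign of t_j,1 so the aneurysm group scores positive.

    The singular-vector sign is arbitrary; the display convention puts the
    ANG group at positive coordinates and SHAM at negative ones.  Flipping
    negates the first joint score column and both blocks' first-component
    loadings, leaving every variance quantity and downstream p-value intact.
    """
    groups = np.asarray(groups)
    for required in ("SHAM", "ANG"):
        if required not in groups:
            raise ValueError(f"group {required!r} absent; cannot orient")
    t1 = model.joint_scores[:, 0]
    flip = t1[groups == "ANG"].mean() < t1[groups == "SHAM"].mean()
    joint_scores = model.joint_scores.copy()
    loadings = {b: model.joint_loadings[b].copy() for b in BLOCKS}
    if flip:
        joint_scores[:, 0] = -joint_scores[:, 0]
        for b in BLOCKS:
            loadings[b][:, 0] = -loadings[b][:, 0]
    return MocaModel(
        joint_scores=joint_scores,
        joint_loadings=loadings,
        unique_scores={b: model.unique_scores[b].copy() for b in BLOCKS},
        unique_loadings={b: model.unique_loadings[b].copy() for b in BLOCKS},
        r2_joint_components={
            b: model.r2_joint_components[b].copy() for b in BLOCKS
        },
        r2_unique_components={
            b: model.r2_unique_components[b].copy() for b in BLOCKS
        },
        r2_residual=dict(model.r2_residual),
        scaling=model.scaling,
        metabolite_names=model.metabolite_names,
        oriented=True,
    )


def save_model(model: MocaModel, out_dir: str | Path) -> None:
    """Serialize scores/loadings/variance to delimited tables plus metadata."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        model.joint_scores,
        columns=[f"t_j{a}" for a in range(1, model.n_joint + 1)],
    ).to_csv(out / "scores.tsv", sep="\t", index=False)
    for b in BLOCKS:
        cols = {
            f"p_j{a}": model.joint_loadings[b][:, a - 1]
            for a in range(1, model.n_joint + 1)
        }
        for a in range(model.unique_loadings[b].shape[1]):
            cols[f"p_u{a + 1}"] = model.unique_loadings[b][:, a]
        pd.DataFrame(
            {"metabolite": model.metabolite_names[b], **cols}
        ).to_csv(out / f"loadings_{b}.tsv", sep="\t", index=False)
    variance_table(model).to_csv(out / "variance.tsv", sep="\t", index=False)
    with open(out / "model_info.txt", "w") as fh:
        fh.write(f"n_joint\t{model.n_joint}\n")
        for b in BLOCKS:
            fh.write(f"n_unique_{b}\t{model.unique_scores[b].shape[1]}\n")
        fh.write(f"oriented\t{model.oriented}\n")
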