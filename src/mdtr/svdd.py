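"""One-class SVDD with RBF kernel and the two-stage Dual-SVDD procedure.

Support Vector Data Description (Tax & Duin) fits the minimal hypersphere
enclosing a training cloud in RBF feature space; a sample outside the sphere
(decision value f(x) > 0) is an outlier. Dual-SVDD applies this twice:

* stage 1 (drug-effect boundary) is trained on DMSO vehicle samples; any
  drug-treated sample with f_DE(x) > 0 carries a detectable drug effect;
* stage 2 (toxic-effect boundary) is trained on the non-toxic drug-treated
  samples outside the first boundary (X_NT); toxic-treated samples outside
  BOTH boundaries are the "potentially toxic" (PT) set.

The canonical SVDD dual
``min_a  a' K a - sum_i a_i K_ii   s.t.  sum a = 1,  0 <= a_i <= 1/(n nu)``
is solved through the nu-one-class-SVM quadratic program (with a
unit-diagonal RBF kernel the two duals coincide after rescaling alpha by
``1/(n nu)``); ``nu`` upper-bounds the training outlier fraction and
lower-bounds the support-vector fraction.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.metrics.pairwise import rbf_kernel as _sk_rbf
from sklearn.svm import OneClassSVM

from .io import ExpressionDataset, SampleTable

logger = logging.getLogger(__name__)

_ALPHA_TOL = 1e-8


def scale_gamma(values: np.ndarray | ExpressionDataset) -> float:
    """RBF width ``gamma = 1 / (n_genes * var)`` for an expression matrix.

    ``var`` is the variance over all matrix entries pooled together.
    """
    if isinstance(values, ExpressionDataset):
        values = values.values
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty expression matrix")
    n_genes = values.shape[0] if values.ndim == 2 else len(values)
    var = float(np.var(values))
    if var <= 0:
        raise ValueError("zero-variance expression matrix: gamma undefined")
    return 1.0 / (n_genes * var)


def rbf_kernel(u: np.ndarray, v: np.ndarray, gamma: float) -> float:
    """``exp(-gamma * ||u - v||^2)`` for a single pair of profiles."""
    u = np.asarray(u, dtype=float).ravel()
    v = np.asarray(v, dtype=float).ravel()
    if u.shape != v.shape:
        raise ValueError(f"profile lengths differ: {u.shape} vs {v.shape}")
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    d2 = float(np.sum((u - v) ** 2))
    return float(np.exp(-gamma * d2))


def rbf_kernel_matrix(U: np.ndarray, V: np.ndarray, gamma: float) -> np.ndarray:
    """Pairwise RBF kernel matrix between row-sample matrices."""
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    U = np.atleast_2d(np.asarray(U, dtype=float))
    V = np.atleast_2d(np.asarray(V, dtype=float))
    if U.shape[1] != V.shape[1]:
        raise ValueError(f"feature dimensions differ: {U.shape[1]} vs {V.shape[1]}")
    return _sk_rbf(U, V, gamma=gamma)


@dataclass
class SVDDModel:
    """A fitted SVDD hypersphere.

    ``alphas`` follow the canonical scaling (nonnegative, summing to 1,
    bounded by ``1/(n nu)``); ``center_norm_sq`` is the feature-space squared
    norm of the sphere center (``a' K a``); ``bias`` is the constant
    ``1 + a' K a`` so that ``f(x) = -2 sum_j a_j k(x_j, x) + bias - r^2``
    (self-term absorbed: k(x, x) = 1 for the RBF kernel).
    """

    support_sample_ids: list[str]
    support_vectors: np.ndarray  # (n_sv, n_genes)
    alphas: np.ndarray  # (n_sv,), canonical scaling
    gamma: float
    nu: float
    center_norm_sq: float
    radius_sq: float
    n_training: int
    training_sample_ids: list[str] = field(default_factory=list)

    @property
    def bias(self) -> float:
        return 1.0 + self.center_norm_sq

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        """``f(x) = ||phi(x) - center||^2 - r^2`` per row of ``X``; f > 0 is
        outside the boundary, f <= 0 inside."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.support_vectors.shape[1]:
            raise ValueError(
                f"profile has {X.shape[1]} genes, model expects "
                f"{self.support_vectors.shape[1]}"
            )
        k = rbf_kernel_matrix(X, self.support_vectors, self.gamma)
        return -2.0 * (k @ self.alphas) + self.bias - self.radius_sq

    def decision_value(self, x: np.ndarray) -> float:
        return float(self.decision_values(np.atleast_2d(x))[0])

    def to_dict(self) -> dict:
        return {
            "support_sample_ids": self.support_sample_ids,
            "support_vectors": self.support_vectors.tolist(),
            "alphas": self.alphas.tolist(),
            "gamma": self.gamma,
            "nu": self.nu,
            "center_norm_sq": self.center_norm_sq,
            "radius_sq": self.radius_sq,
            "n_training": self.n_training,
            "training_sample_ids": self.training_sample_ids,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SVDDModel":
        return cls(
            support_sample_ids=list(d["support_sample_ids"]),
            support_vectors=np.asarray(d["support_vectors"], dtype=float),
            alphas=np.asarray(d["alphas"], dtype=float),
            gamma=float(d["gamma"]),
            nu=float(d["nu"]),
            center_norm_sq=float(d["center_norm_sq"]),
            radius_sq=float(d["radius_sq"]),
            n_training=int(d["n_training"]),
            training_sample_ids=list(d.get("training_sample_ids", [])),
        )


def fit_svdd(
    X: np.ndarray,
    gamma: float,
    nu: float = 0.1,
    sample_ids: list[str] | None = None,
) -> SVDDModel:
    """Fit the canonical SVDD dual on ``X`` (samples as rows).

    The radius is set by the squared feature-space distance of the unbounded
    support vectors (``0 < alpha_i < 1/(n nu)``) from the center; when every
    support vector sits at the box bound (degenerate data), the largest
    training distance is used so all training points are enclosed.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 training samples")
    if not 0 < nu < 1:
        raise ValueError(f"nu must be in (0, 1), got {nu}")
    if nu < 1.0 / n:
        raise ValueError(f"nu={nu} < 1/n={1.0 / n:.4g}: box constraint infeasible")
    if sample_ids is None:
        sample_ids = [str(i) for i in range(n)]

    oc = OneClassSVM(kernel="rbf", gamma=gamma, nu=nu, tol=1e-9, shrinking=False)
    oc.fit(X)
    if oc.fit_status_ != 0:
        raise ArithmeticError(
            f"one-class QP did not converge (libsvm status {oc.fit_status_})"
        )
    alphas_full = np.zeros(n)
    alphas_full[oc.support_] = oc.dual_coef_[0]
    total = alphas_full.sum()  # == n * nu up to solver tolerance
    alphas_full /= total

    K = rbf_kernel_matrix(X, X, gamma)
    center_norm_sq = float(alphas_full @ K @ alphas_full)
    # squared feature-space distance of each training point from the center
    dist_sq = 1.0 - 2.0 * (K @ alphas_full) + center_norm_sq
    box = 1.0 / (n * nu)
    unbounded = (alphas_full > _ALPHA_TOL) & (alphas_full < box * (1 - 1e-6))
    if unbounded.any():
        # exact solutions place every unbounded SV on the sphere; under
        # solver slack their distances spread slightly, and taking the max
        # keeps all of them inside-or-on as the KKT conditions require
        radius_sq = float(np.max(dist_sq[unbounded]))
    else:  # degenerate: enclose everything
        radius_sq = float(dist_sq.max())
    radius_sq = max(radius_sq, 0.0)

    sv = alphas_full > _ALPHA_TOL
    return SVDDModel(
        support_sample_ids=[sample_ids[i] for i in np.flatnonzero(sv)],
        support_vectors=X[sv].copy(),
        alphas=alphas_full[sv].copy(),
        gamma=float(gamma),
        nu=float(nu),
        center_norm_sq=center_norm_sq,
        radius_sq=radius_sq,
        n_training=n,
        training_sample_ids=list(sample_ids),
    )


def decision_value(model: SVDDModel, x: np.ndarray) -> float:
    """Decision value f(x) of one profile (see :meth:`SVDDModel.decision_values`)."""
    return model.decision_value(x)


@dataclass
class DualBoundary:
    """The two fitted boundaries plus the sample partition they induce."""

    drug_effect_model: SVDDModel
    toxic_effect_model: SVDDModel
    nt_sample_ids: list[str]  # X_NT: non-toxic samples with f_DE > 0
    t_sample_ids: list[str]  # X_T: toxic samples with f_DE > 0
    pt_sample_ids: list[str]  # X_PT: X_T members with f_TE > 0
    f_de: dict[str, float]
    f_te: dict[str, float]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "drug_effect_model": self.drug_effect_model.to_dict(),
            "toxic_effect_model": self.toxic_effect_model.to_dict(),
            "nt_sample_ids": self.nt_sample_ids,
            "t_sample_ids": self.t_sample_ids,
            "pt_sample_ids": self.pt_sample_ids,
            "f_de": self.f_de,
            "f_te": self.f_te,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path: str | Path) -> "DualBoundary":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            drug_effect_model=SVDDModel.from_dict(d["drug_effect_model"]),
            toxic_effect_model=SVDDModel.from_dict(d["toxic_effect_model"]),
            nt_sample_ids=list(d["nt_sample_ids"]),
            t_sample_ids=list(d["t_sample_ids"]),
            pt_sample_ids=list(d["pt_sample_ids"]),
            f_de={k: float(v) for k, v in d["f_de"].items()},
            f_te={k: float(v) for k, v in d["f_te"].items()},
        )


def fit_dual_boundaries(
    expr: ExpressionDataset,
    meta: SampleTable,
    nu: float = 0.1,
    gamma: float | str = "scale",
    min_nt: int = 5,
) -> DualBoundary:
    """Run the two-stage Dual-SVDD procedure.

    Stage 1 fits the drug-effect boundary on DMSO samples; X_NT (non-toxic,
    f_DE > 0) and X_T (toxic, f_DE > 0) are collected; stage 2 fits the
    toxic-effect boundary on X_NT; PT = members of X_T with f_TE > 0.

    ``gamma`` is either ``"scale"`` (recomputed per stage from that stage's
    training matrix via :func:`scale_gamma`) or a fixed positive float used
    for both stages. Boundary values of exactly 0 count as inside.
    """
    dmso_ids = meta.ids_in_group("DMSO")
    nontoxic_ids = meta.ids_in_group("NONTOXIC")
    toxic_ids = meta.ids_in_group("TOXIC")
    if len(dmso_ids) < 2 or len(nontoxic_ids) < 2:
        raise ValueError("need >= 2 DMSO and >= 2 non-toxic samples")

    X_dmso = expr.sample_matrix(dmso_ids)
    gamma_de = scale_gamma(X_dmso.T) if gamma == "scale" else float(gamma)
    logger.info("drug-effect boundary: n=%d gamma=%.4g nu=%.3g",
                len(dmso_ids), gamma_de, nu)
    de_model = fit_svdd(X_dmso, gamma_de, nu, sample_ids=dmso_ids)

    all_ids = expr.sample_ids
    f_de_all = de_model.decision_values(expr.sample_matrix())
    f_de = dict(zip(all_ids, map(float, f_de_all)))

    nt_ids = [s for s in nontoxic_ids if f_de[s] > 0]
    t_ids = [s for s in toxic_ids if f_de[s] > 0]
    logger.info("|X_NT|=%d of %d non-toxic; |X_T|=%d of %d toxic",
                len(nt_ids), len(nontoxic_ids), len(t_ids), len(toxic_ids))
    if len(nt_ids) < min_nt:
        raise RuntimeError(
            f"only {len(nt_ids)} non-toxic samples fall outside the drug-effect "
            f"boundary (need >= {min_nt}); consider raising nu or revisiting gamma"
        )

    X_nt = expr.sample_matrix(nt_ids)
    gamma_te = scale_gamma(X_nt.T) if gamma == "scale" else float(gamma)
    logger.info("toxic-effect boundary: n=%d gamma=%.4g nu=%.3g",
                len(nt_ids), gamma_te, nu)
    te_model = fit_svdd(X_nt, gamma_te, nu, sample_ids=nt_ids)

    f_te_all = te_model.decision_values(expr.sample_matrix())
    f_te = dict(zip(all_ids, map(float, f_te_all)))
    pt_ids = [s for s in t_ids if f_te[s] > 0]
    logger.info("|X_PT|=%d potentially toxic samples", len(pt_ids))

    return DualBoundary(
        drug_effect_model=de_model,
        toxic_effect_model=te_model,
        nt_sample_ids=nt_ids,
        t_sample_ids=t_ids,
        pt_sample_ids=pt_ids,
        f_de=f_de,
        f_te=f_te,
    )


def identify_pt_samples(boundary: DualBoundary) -> set[str]:
    """The potentially-toxic sample ids selected by the dual boundaries."""
    return set(boundary.pt_sample_ids)
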