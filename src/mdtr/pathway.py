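"""Per-pathway toxicity kernel spaces and weighted pathway-level distances.

For each pathway p with l_p genes present in the expression matrix, a kernel
PCA embedding (RBF kernel, gamma = 1/l_p) is fitted on the potentially-toxic
(PT) samples restricted to those genes; the latent dimension is
``clamp(floor(0.1 * l_p), 1, 3)``. All samples are mapped into this
"toxicity kernel space", where a squared Mahalanobis distance to the pooled
embedded distribution (mean mu_p, ridge-regularised covariance S_p) scores
how far each sample sits from the cohort. Distances are min-max normalised
to [0, 1] across the cohort, and each sample receives a weight derived from
an F-distribution null fitted by maximum likelihood to the normalised
distances of the non-PT samples: by default the significance of
dysregulation ``w(p, x) = -log(1 - F_cdf(d))``, with a ``cdf`` mode giving
the literal ``-log I_{d1 d/(d1 d + d2)}(d1/2, d2/2) = -log F_cdf(d)`` form
instead (that form decreases as dysregulation grows).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import special, stats
from sklearn.decomposition import KernelPCA

from .io import ExpressionDataset, Pathway, SampleTable, intersect_pathway

logger = logging.getLogger(__name__)

#: -log of the smallest positive double; weights are clamped here when the
#: F CDF (or survival function) underflows to 0
W_MAX = 700.0
_EIG_TOL = 1e-10
_ZERO_FLOOR = 1e-9


def latent_dim(l_p: int) -> int:
    """Latent dimensionality ``clamp(floor(0.1 * l_p), 1, 3)``."""
    return int(np.clip(int(np.floor(0.1 * l_p)), 1, 3))


class DegenerateSpaceError(ArithmeticError):
    """All kernel-PCA eigenvalues vanished (e.g. identical PT profiles)."""


@dataclass
class PathwayToxicitySpace:
    """A fitted per-pathway kernel-PCA embedding with scoring statistics.

    The embedding itself (training PT matrix, gamma, kept components) is
    fitted by :func:`build_toxicity_space`; the Mahalanobis reference
    (mu_p, S_p), normalisation bounds and F-null degrees of freedom are
    attached by :func:`compute_pathway_distances`.
    """

    pathway_id: str
    gene_subset: list[str]
    gamma: float
    training_matrix: np.ndarray  # PT samples x pathway genes
    kpca: KernelPCA
    eigenvalues: np.ndarray
    dim: int
    mu: np.ndarray | None = None
    cov: np.ndarray | None = None
    norm_min: float | None = None
    norm_max: float | None = None
    f_d1: float | None = None
    f_d2: float | None = None
    f_scale: float = 1.0

    def to_dict(self) -> dict:
        return {
            "pathway_id": self.pathway_id,
            "gene_subset": self.gene_subset,
            "training_matrix": self.training_matrix.tolist(),
            "mu": None if self.mu is None else self.mu.tolist(),
            "cov": None if self.cov is None else self.cov.tolist(),
            "norm_min": self.norm_min,
            "norm_max": self.norm_max,
            "f_d1": self.f_d1,
            "f_d2": self.f_d2,
            "f_scale": self.f_scale,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PathwayToxicitySpace":
        pathway = Pathway(d["pathway_id"], d["pathway_id"], frozenset(d["gene_subset"]))
        space = build_toxicity_space(
            np.asarray(d["training_matrix"], dtype=float), pathway,
            gene_subset=list(d["gene_subset"]),
        )
        if d.get("mu") is not None:
            space.mu = np.asarray(d["mu"], dtype=float)
            space.cov = np.asarray(d["cov"], dtype=float)
            space.norm_min = d["norm_min"]
            space.norm_max = d["norm_max"]
            space.f_d1 = d["f_d1"]
            space.f_d2 = d["f_d2"]
            space.f_scale = float(d.get("f_scale", 1.0))
        return space


def build_toxicity_space(
    pt_matrix: np.ndarray,
    pathway: Pathway,
    gene_subset: list[str] | None = None,
) -> PathwayToxicitySpace:
    """Fit the kernel-PCA toxicity space for one pathway from PT profiles.

    ``pt_matrix`` holds PT samples as rows over the pathway's intersected
    genes. gamma is 1/l_p; components with eigenvalue <= 1e-10 are dropped
    (reducing the latent dimension, never below 1 — if every component
    vanishes a :class:`DegenerateSpaceError` is raised).
    """
    pt_matrix = np.atleast_2d(np.asarray(pt_matrix, dtype=float))
    n_pt, l_p = pt_matrix.shape
    if n_pt < 2:
        raise ValueError(f"pathway {pathway.pathway_id}: need >= 2 PT samples")
    if gene_subset is not None and len(gene_subset) != l_p:
        raise ValueError("gene_subset length does not match matrix width")
    gamma = 1.0 / l_p
    d = min(latent_dim(l_p), n_pt - 1)
    kpca = KernelPCA(n_components=d, kernel="rbf", gamma=gamma)
    kpca.fit(pt_matrix)
    eig = np.asarray(kpca.eigenvalues_, dtype=float)
    keep = eig > _EIG_TOL
    if not keep.any():
        raise DegenerateSpaceError(
            f"pathway {pathway.pathway_id}: all kernel-PCA eigenvalues <= {_EIG_TOL}"
        )
    if not keep.all():
        logger.warning(
            "pathway %s: dropping %d near-zero kernel-PCA components",
            pathway.pathway_id, int((~keep).sum()),
        )
        d = int(keep.sum())
        kpca = KernelPCA(n_components=d, kernel="rbf", gamma=gamma)
        kpca.fit(pt_matrix)
        eig = np.asarray(kpca.eigenvalues_, dtype=float)
    return PathwayToxicitySpace(
        pathway_id=pathway.pathway_id,
        gene_subset=list(gene_subset) if gene_subset is not None else
        [f"g{i}" for i in range(l_p)],
        gamma=gamma,
        training_matrix=pt_matrix.copy(),
        kpca=kpca,
        eigenvalues=eig,
        dim=d,
    )


def embed_samples(space: PathwayToxicitySpace, profiles: np.ndarray) -> np.ndarray:
    """Out-of-sample kernel-PCA projection (rows = samples over the
    space's gene subset, in the same order)."""
    profiles = np.atleast_2d(np.asarray(profiles, dtype=float))
    if profiles.shape[1] != space.training_matrix.shape[1]:
        raise ValueError(
            f"profiles have {profiles.shape[1]} genes, space expects "
            f"{space.training_matrix.shape[1]}"
        )
    return space.kpca.transform(profiles)


def fit_reference(
    space: PathwayToxicitySpace, embedded_all: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Mean and ridge-regularised sample covariance of all embedded samples.

    The ridge ``1e-6 * mean(diag)`` guarantees positive-definiteness on
    degenerate data. Requires at least d + 2 samples.
    """
    Z = np.atleast_2d(np.asarray(embedded_all, dtype=float))
    n, d = Z.shape
    if n < d + 2:
        raise ValueError(f"need >= {d + 2} embedded samples to fit a reference, got {n}")
    mu = Z.mean(axis=0)
    cov = np.cov(Z, rowvar=False, ddof=1).reshape(d, d)
    ridge = 1e-6 * float(np.mean(np.diag(cov)))
    if ridge <= 0:
        ridge = 1e-12
    cov = cov + ridge * np.eye(d)
    return mu, cov


def mahalanobis_sq(z: np.ndarray, mu: np.ndarray, cov: np.ndarray) -> float | np.ndarray:
    """Squared Mahalanobis distance ``(z - mu)' S^{-1} (z - mu)``.

    Accepts a single latent vector or a matrix of row vectors.
    """
    z = np.asarray(z, dtype=float)
    mu = np.asarray(mu, dtype=float)
    cov = np.asarray(cov, dtype=float)
    single = z.ndim == 1
    Z = np.atleast_2d(z) - mu
    if Z.shape[1] != mu.shape[0] or cov.shape != (mu.shape[0], mu.shape[0]):
        raise ValueError("latent dimension mismatch")
    try:
        sol = np.linalg.solve(cov, Z.T)
    except np.linalg.LinAlgError as exc:
        raise ArithmeticError(f"singular covariance: {exc}") from None
    d2 = np.einsum("ij,ji->i", Z, sol)
    d2 = np.maximum(d2, 0.0)
    return float(d2[0]) if single else d2


def min_max_normalize(values: np.ndarray) -> np.ndarray:
    """Scale to [0, 1] via (v - min) / (max - min); constant input maps to 0."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("no values to normalize")
    if not np.all(np.isfinite(v)):
        raise ValueError("values must be finite")
    lo, hi = float(v.min()), float(v.max())
    if hi == lo:
        return np.zeros_like(v)
    return (v - lo) / (hi - lo)


def fit_f_null(
    nonpt_distances: np.ndarray, fit_scale: bool = True
) -> tuple[float, float, float]:
    """Maximum-likelihood F-distribution null for the non-PT normalised
    distances: degrees of freedom (d1, d2) plus a scale, location fixed at 0.

    The scale is fitted by default (min-max normalisation concentrates the
    null well below 1, which a unit-scale F cannot represent, flattening the
    weights); ``fit_scale=False`` pins it at 1 for the strictly unscaled
    variant. Zeros are lifted to a floor of 1e-9 so the log-likelihood is
    finite.
    """
    x = np.asarray(nonpt_distances, dtype=float)
    if x.size < 10:
        raise ValueError(f"need >= 10 non-PT distances to fit the null, got {x.size}")
    if np.any(x < 0) or not np.all(np.isfinite(x)):
        raise ValueError("distances must be finite and nonnegative")
    if np.all(x <= _ZERO_FLOOR):
        raise ArithmeticError("all non-PT distances are ~0: degenerate null")
    x = np.maximum(x, _ZERO_FLOOR)
    if fit_scale:
        d1, d2, loc, scale = stats.f.fit(x, floc=0)
    else:
        d1, d2, loc, scale = stats.f.fit(x, floc=0, fscale=1)
    if not (
        np.isfinite(d1) and np.isfinite(d2) and np.isfinite(scale)
        and d1 > 0 and d2 > 0 and scale > 0
    ):
        raise ArithmeticError(
            f"F-distribution fit did not converge: d1={d1}, d2={d2}, scale={scale}"
        )
    return float(d1), float(d2), float(scale)


def pathway_weight(
    dp: float | np.ndarray,
    d1: float,
    d2: float,
    scale: float = 1.0,
    tail: str = "survival",
) -> float | np.ndarray:
    """Pathway weight from the fitted F(d1, d2) null at the normalised
    distance dp (rescaled by the null's fitted scale).

    ``tail="survival"`` (default): ``-log(1 - F_cdf(dp/scale))`` — minus the
    log upper-tail probability, the significance of the dysregulation, which
    grows with dp. ``tail="cdf"`` gives the literal
    ``-log I_{d1 dp/(d1 dp + d2)}(d1/2, d2/2)`` form (minus the log CDF via
    the regularised incomplete beta function), which decreases with dp.
    Results are clamped to [0, 700].
    """
    if d1 <= 0 or d2 <= 0:
        raise ValueError("degrees of freedom must be positive")
    if scale <= 0:
        raise ValueError("scale must be positive")
    dp_arr = np.asarray(dp, dtype=float) / scale
    if not np.all(np.isfinite(dp_arr)) or np.any(dp_arr < 0):
        raise ValueError("normalized distances must be finite and >= 0")
    if tail == "cdf":
        cdf = special.betainc(d1 / 2.0, d2 / 2.0, d1 * dp_arr / (d1 * dp_arr + d2))
        with np.errstate(divide="ignore"):
            w = -np.log(cdf)
    elif tail == "survival":
        # sf computed directly for accuracy deep in the tail
        with np.errstate(divide="ignore"):
            w = -np.log(stats.f.sf(dp_arr, d1, d2))
    else:
        raise ValueError(f"unknown weight tail {tail!r}")
    w = np.clip(w, 0.0, W_MAX)
    return float(w) if np.isscalar(dp) or np.ndim(dp) == 0 else w


@dataclass
class PathwayDistanceResult:
    """Per-sample scores for one pathway: raw squared Mahalanobis distance,
    min-max normalised distance in [0, 1], and F-null weight."""

    pathway_id: str
    sample_ids: list[str]
    raw: np.ndarray
    normalized: np.ndarray
    weights: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample_id": self.sample_ids, "raw": self.raw,
             "normalized": self.normalized, "weight": self.weights}
        )

    def value_for(self, sample_id: str) -> tuple[float, float]:
        i = self.sample_ids.index(sample_id)
        return float(self.normalized[i]), float(self.weights[i])


def compute_pathway_distances(
    space: PathwayToxicitySpace,
    expr: ExpressionDataset,
    meta: SampleTable,
    pt_ids: set[str] | list[str],
    weight_tail: str = "survival",
    fit_scale: bool = True,
) -> PathwayDistanceResult:
    """Score every sample of ``expr`` against one pathway's toxicity space.

    Embeds all samples, fits the Mahalanobis reference (mu_p, S_p) on the
    pooled embedding, min-max normalises the squared distances across the
    cohort, fits the F null on the non-PT samples' normalised distances and
    assigns weights. The fitted statistics are stored back on ``space``.
    """
    pt_ids = set(pt_ids)
    sub = expr.subset_genes(space.gene_subset)
    Z = embed_samples(space, sub.sample_matrix())
    mu, cov = fit_reference(space, Z)
    raw = np.asarray(mahalanobis_sq(Z, mu, cov), dtype=float)
    normalized = min_max_normalize(raw)
    nonpt_mask = np.array([s not in pt_ids for s in expr.sample_ids])
    if nonpt_mask.sum() < 10:
        raise ValueError(
            f"pathway {space.pathway_id}: only {int(nonpt_mask.sum())} non-PT "
            "samples; cannot fit the F null"
        )
    d1, d2, scale = fit_f_null(normalized[nonpt_mask], fit_scale=fit_scale)
    weights = pathway_weight(normalized, d1, d2, scale=scale, tail=weight_tail)
    space.mu, space.cov = mu, cov
    space.norm_min, space.norm_max = float(raw.min()), float(raw.max())
    space.f_d1, space.f_d2, space.f_scale = d1, d2, scale
    logger.info(
        "pathway %s: l_p=%d d=%d F-null (d1=%.3g, d2=%.3g, scale=%.3g)",
        space.pathway_id, len(space.gene_subset), space.dim, d1, d2, scale,
    )
    return PathwayDistanceResult(
        pathway_id=space.pathway_id,
        sample_ids=list(expr.sample_ids),
        raw=raw,
        normalized=normalized,
        weights=np.asarray(weights, dtype=float),
    )


def build_spaces(
    expr: ExpressionDataset,
    pathways: list[Pathway],
    pt_ids: list[str],
    min_genes: int = 3,
) -> dict[str, PathwayToxicitySpace]:
    """Build toxicity spaces for every pathway with enough genes present.

    Pathways whose intersection with the expression matrix falls below
    ``min_genes`` are skipped (logged); the caller sees them as absent keys.
    """
    spaces: dict[str, PathwayToxicitySpace] = {}
    pt_list = list(pt_ids)
    for pw in pathways:
        subset = intersect_pathway(pw, expr.gene_ids, min_genes=min_genes)
        if subset is None:
            continue
        pt_matrix = expr.subset_genes(subset).sample_matrix(pt_list)
        try:
            spaces[pw.pathway_id] = build_toxicity_space(pt_matrix, pw, subset)
        except DegenerateSpaceError as exc:
            logger.warning("skipping pathway %s: %s", pw.pathway_id, exc)
    return spaces


def save_spaces(spaces: dict[str, PathwayToxicitySpace], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump({pid: s.to_dict() for pid, s in spaces.items()}, fh)


def load_spaces(path: str | Path) -> dict[str, PathwayToxicitySpace]:
    with open(path) as fh:
        raw = json.load(fh)
    return {pid: PathwayToxicitySpace.from_dict(d) for pid, d in raw.items()}
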