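"""Evaluation protocols: dose-distance correlation, raw-gene-space baseline
distances, and toxic vs non-toxic group comparison.

The dose-dependence protocol groups samples into series by (drug, cell line,
time), keeps series with at least ``min_dose_points`` distinct doses, and
computes a rank correlation between dose and distance per series; the
positive ratio is the fraction of series with a positive correlation.
Baselines measure each sample's full-gene-vector distance to the DMSO
centroid (cosine / Euclidean / shrunk-covariance Mahalanobis).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.covariance import LedoitWolf

from .io import GROUP_DMSO, ExpressionDataset, MDTRProfile, SampleTable

BASELINE_METHODS = ("cosine", "euclidean", "mahalanobis")


def baseline_distance(
    expr: ExpressionDataset, meta: SampleTable, method: str = "euclidean"
) -> pd.Series:
    """Distance of each sample's full gene vector to the DMSO centroid.

    ``mahalanobis`` shrinks the DMSO covariance (Ledoit-Wolf) so it stays
    invertible when genes far outnumber samples. Returns a Series indexed by
    sample id.
    """
    if method not in BASELINE_METHODS:
        raise ValueError(f"unknown baseline method {method!r}")
    dmso_ids = meta.ids_in_group(GROUP_DMSO)
    if len(dmso_ids) < 2:
        raise ValueError("need >= 2 DMSO samples for the reference")
    X = expr.sample_matrix()  # samples x genes
    D = expr.sample_matrix(dmso_ids)
    centroid = D.mean(axis=0)
    diff = X - centroid
    if method == "euclidean":
        vals = np.linalg.norm(diff, axis=1)
    elif method == "cosine":
        num = X @ centroid
        denom = np.linalg.norm(X, axis=1) * np.linalg.norm(centroid)
        with np.errstate(invalid="ignore", divide="ignore"):
            cos = np.where(denom > 0, num / denom, 1.0)
        vals = 1.0 - cos
        # a sample exactly at the centroid has cosine distance 0
        vals[np.linalg.norm(diff, axis=1) == 0] = 0.0
    else:
        lw = LedoitWolf().fit(D)
        prec = lw.precision_
        vals = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", diff, prec, diff), 0.0))
    return pd.Series(vals, index=expr.sample_ids, name=method)


@dataclass
class DoseSeries:
    """One (drug, cell line, time) dose-escalation series."""

    drug: str
    cell_line: str
    time_h: float
    doses: np.ndarray
    distances: np.ndarray
    rho: float
    p_value: float


@dataclass
class CorrelationReport:
    """Per-series dose-distance correlations and the positive ratio."""

    series: list[DoseSeries]
    n_excluded: int
    correlation: str

    @property
    def n_series(self) -> int:
        return len(self.series)

    @property
    def positive_ratio(self) -> float:
        if not self.series:
            return float("nan")
        return sum(1 for s in self.series if s.rho > 0) / len(self.series)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"drug": s.drug, "cell_line": s.cell_line, "time_h": s.time_h,
                 "n_doses": len(s.doses), "rho": s.rho, "p_value": s.p_value}
                for s in self.series
            ]
        )


def profiles_to_distance(
    profiles: list[MDTRProfile], selector: str = "max_mechanism"
) -> pd.Series:
    """Reduce ruler profiles to one scalar per sample.

    ``max_mechanism`` takes the per-sample maximum over mechanism distances;
    ``mechanism:<name>`` selects a single axis.
    """
    if selector == "max_mechanism":
        vals = {p.sample_id: p.max_distance for p in profiles}
    elif selector.startswith("mechanism:"):
        mech = selector.split(":", 1)[1]
        try:
            vals = {p.sample_id: p.mechanism_distances[mech] for p in profiles}
        except KeyError:
            raise ValueError(f"mechanism {mech!r} not present in profiles") from None
    else:
        raise ValueError(f"unknown selector {selector!r}")
    return pd.Series(vals, name="distance")


def dose_distance_correlation(
    distances: pd.Series,
    meta: SampleTable,
    min_dose_points: int = 5,
    correlation: str = "spearman",
) -> CorrelationReport:
    """Correlate dose with distance within each (drug, cell line, time) series.

    Only drug-treated samples (dose > 0) enter; series with fewer than
    ``min_dose_points`` distinct doses are excluded but counted. Spearman
    rank correlation is the default (ties handled by average ranks);
    ``correlation="pearson"`` is available.
    """
    if correlation not in ("spearman", "pearson"):
        raise ValueError(f"unknown correlation {correlation!r}")
    df = meta.table.copy()
    df = df[df["dose_um"] > 0]
    df["distance"] = df["sample_id"].map(distances)
    if df["distance"].isna().any():
        missing = df.loc[df["distance"].isna(), "sample_id"].tolist()
        raise ValueError(f"no distance for samples: {missing[:5]}")
    series: list[DoseSeries] = []
    n_excluded = 0
    for (drug, cell, time_h), grp in df.groupby(["drug", "cell_line", "time_h"]):
        if grp["dose_um"].nunique() < min_dose_points:
            n_excluded += 1
            continue
        doses = grp["dose_um"].to_numpy(dtype=float)
        dist = grp["distance"].to_numpy(dtype=float)
        if correlation == "spearman":
            rho, p = stats.spearmanr(doses, dist)
        else:
            rho, p = stats.pearsonr(doses, dist)
        series.append(
            DoseSeries(drug=str(drug), cell_line=str(cell), time_h=float(time_h),
                       doses=doses, distances=dist, rho=float(rho), p_value=float(p))
        )
    if not series:
        raise ValueError(
            f"all series excluded (min_dose_points={min_dose_points}); nothing to report"
        )
    return CorrelationReport(series=series, n_excluded=n_excluded,
                             correlation=correlation)


def group_comparison(
    distances: pd.Series, meta: SampleTable, groups: tuple[str, str] = ("TOXIC", "NONTOXIC")
) -> tuple[float, float, dict[str, float]]:
    """Two-sided Mann-Whitney U between two sample groups' distances.

    Exact p-value for group sizes <= 20 without ties, otherwise the normal
    approximation with tie correction. Returns (U statistic, p-value,
    per-group mean distances).
    """
    a_ids = meta.ids_in_group(groups[0])
    b_ids = meta.ids_in_group(groups[1])
    if len(a_ids) < 3 or len(b_ids) < 3:
        raise ValueError("need >= 3 samples per group")
    a = distances.loc[a_ids].to_numpy(dtype=float)
    b = distances.loc[b_ids].to_numpy(dtype=float)
    means = {groups[0]: float(a.mean()), groups[1]: float(b.mean())}
    if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
        # identical constant groups: no evidence of difference
        return float(len(a) * len(b) / 2), 1.0, means
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (max(len(a), len(b)) <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue), means
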