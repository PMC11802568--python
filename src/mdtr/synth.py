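"""Synthetic LINCS-like cohorts with known ground truth.

Emulates replicate-collapsed differential-expression signatures (z-scores
relative to vehicle controls) for three sample groups — DMSO vehicle,
non-toxic drug-treated, toxic drug-treated — together with a pathway / five-
mechanism annotation layout, dose and time metadata, and a per-sample ground
truth record. Toxic samples carry a dose-dependent z-shift on the genes of
one target mechanism; the dose response is either monotone in log-dose or
hormetic (U-shaped).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import (
    GROUP_DMSO,
    GROUP_NONTOXIC,
    GROUP_TOXIC,
    ExpressionDataset,
    MechanismMap,
    Pathway,
    SampleTable,
)
import pandas as pd

#: the five hepatotoxicity mechanisms used as radar axes, with their
#: pathway counts (6 + 3 + 13 + 2 + 2 = 26 pathways)
DEFAULT_MECHANISMS: list[tuple[str, int]] = [
    ("Oxidative stress", 6),
    ("Immunological response", 3),
    ("Altered lipid metabolism", 13),
    ("Mitochondrial dysfunction", 2),
    ("Bile acids accumulation", 2),
]

_SIZE_CYCLE = (25, 20, 16, 12, 10)


def default_pathway_sizes(n_pathways: int = 26) -> list[int]:
    """Deterministic KEGG-like pathway sizes cycling over a small palette."""
    return [_SIZE_CYCLE[i % len(_SIZE_CYCLE)] for i in range(n_pathways)]


def default_mechanism_layout() -> dict[str, list[int]]:
    """Mechanism -> pathway-index layout mirroring the five-axis design."""
    layout: dict[str, list[int]] = {}
    start = 0
    for name, count in DEFAULT_MECHANISMS:
        layout[name] = list(range(start, start + count))
        start += count
    return layout


class ConfigError(ValueError):
    """Inconsistent synthetic-cohort configuration."""


@dataclass
class SynthConfig:
    """Study conditions for one synthetic cohort.

    ``effect_size`` is the z-score shift per decade of dose applied to the
    perturbed mechanism's genes in toxic samples; ``noise_sd`` is the DMSO
    noise standard deviation (1.0 matches the z-score scale of the input
    data regime). Doses are in uM.
    """

    n_genes: int = 3000
    pathway_sizes: list[int] = field(default_factory=default_pathway_sizes)
    mechanism_layout: dict[str, list[int]] = field(
        default_factory=default_mechanism_layout
    )
    n_dmso: int = 30
    n_nontoxic: int = 30
    n_toxic: int = 30
    doses: tuple[float, ...] = (0.1, 0.37, 1.11, 3.33, 10.0)
    effect_size: float = 3.0
    noise_sd: float = 1.0
    response_model: str = "monotone"  # or "hormetic"
    perturbed_mechanism: str = "Oxidative stress"
    # fraction of non-target genes shifted in each non-toxic sample; the
    # per-gene shift magnitude is <= 0.25 * effect_size by construction
    nontoxic_gene_fraction: float = 0.2
    # per-gene response heterogeneity on the perturbed mechanism: each target
    # gene g gets a fixed coefficient u_g with |u_g| ~ Uniform(lo, hi); the
    # applied shift on g is u_g * dose_response_shift(dose). (1, 1) with
    # signed_response=False gives a homogeneous all-positive shift.
    gene_response: tuple[float, float] = (0.15, 0.7)
    signed_response: bool = True
    # co-expression structure: genes outside the annotated pathways load
    # latent_rank global factors (the dominant co-regulated programs of the
    # cell line); each pathway's genes share pathway_factors factors of
    # their own (pathways are co-expression modules, independent across
    # pathways so that mechanism attribution stays identifiable). A gene's
    # noise is sqrt(f)*<loading, h> + sqrt(1-f)*eps with
    # f = latent_var_fraction and unit-norm per-gene loadings, so every
    # gene keeps marginal variance noise_sd**2. Setting both ranks to 0
    # gives fully independent gene noise.
    latent_rank: int = 2
    pathway_factors: int = 2
    latent_var_fraction: float = 0.98
    overlap_fraction: float = 0.0
    time_h: float = 24.0
    cell_line: str = "HEPG2"
    seed: int = 0

    def validate(self) -> None:
        counts = (self.n_dmso, self.n_nontoxic, self.n_toxic, self.n_genes)
        if any(c < 1 for c in counts):
            raise ConfigError("all counts must be >= 1")
        if not self.pathway_sizes or any(s < 1 for s in self.pathway_sizes):
            raise ConfigError("pathway sizes must be positive")
        if sum(self.pathway_sizes) > self.n_genes:
            raise ConfigError(
                f"pathway sizes sum to {sum(self.pathway_sizes)} > n_genes={self.n_genes}"
            )
        if len(self.doses) < 1 or any(d <= 0 for d in self.doses):
            raise ConfigError("doses must be positive")
        if list(self.doses) != sorted(set(self.doses)):
            raise ConfigError("doses must be strictly increasing")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be positive")
        if self.response_model not in ("monotone", "hormetic"):
            raise ConfigError(f"unknown response model {self.response_model!r}")
        if self.perturbed_mechanism not in self.mechanism_layout:
            raise ConfigError(
                f"perturbed mechanism {self.perturbed_mechanism!r} not in layout"
            )
        n_pw = len(self.pathway_sizes)
        for name, idxs in self.mechanism_layout.items():
            if not idxs:
                raise ConfigError(f"mechanism {name!r} has no pathways")
            if any(i < 0 or i >= n_pw for i in idxs):
                raise ConfigError(f"mechanism {name!r} references unknown pathway index")
        if not 0 <= self.overlap_fraction < 1:
            raise ConfigError("overlap_fraction must be in [0, 1)")
        lo, hi = self.gene_response
        if not (0 <= lo <= hi):
            raise ConfigError("gene_response bounds must satisfy 0 <= lo <= hi")
        if self.latent_rank < 0 or self.pathway_factors < 0:
            raise ConfigError("latent_rank and pathway_factors must be >= 0")
        if not 0 <= self.latent_var_fraction < 1:
            raise ConfigError("latent_var_fraction must be in [0, 1)")


@dataclass
class GroundTruth:
    """What the generator actually did, for recovery checks."""

    toxic_flags: dict[str, bool]
    shift_magnitudes: dict[str, float]
    perturbed_pathway_ids: list[str]


def dose_response_shift(dose: float, config: SynthConfig) -> float:
    """Mean z-shift applied at ``dose`` (uM) under the configured response.

    Monotone: ``beta * log10(dose / min_dose)`` — zero at the lowest dose and
    non-decreasing. Hormetic: ``beta * log10(dose / d_mid)**2`` with ``d_mid``
    the middle configured dose, giving a U-shape whose minimum sits at an
    interior dose.
    """
    if dose <= 0:
        raise ValueError(f"dose must be positive, got {dose}")
    beta = config.effect_size
    if config.response_model == "monotone":
        return beta * np.log10(dose / min(config.doses))
    d_mid = config.doses[len(config.doses) // 2]
    return beta * np.log10(dose / d_mid) ** 2


def _build_annotation(
    config: SynthConfig, rng: np.random.Generator
) -> tuple[list[Pathway], MechanismMap]:
    """Assign genes to pathways (disjoint by default, optional overlap)."""
    gene_ids = [f"G{i:04d}" for i in range(config.n_genes)]
    pathways: list[Pathway] = []
    cursor = 0
    for i, size in enumerate(config.pathway_sizes):
        core = gene_ids[cursor : cursor + size]
        cursor += size
        genes = list(core)
        n_overlap = int(round(config.overlap_fraction * size))
        if n_overlap and cursor < config.n_genes:
            pool = [g for g in gene_ids if g not in core]
            extra = rng.choice(len(pool), size=n_overlap, replace=False)
            genes.extend(pool[j] for j in extra)
        pathways.append(Pathway(f"pw{i:03d}", f"synthetic pathway {i}", frozenset(genes)))
    mechanisms = [
        (name, [pathways[i].pathway_id for i in idxs])
        for name, idxs in config.mechanism_layout.items()
    ]
    return pathways, MechanismMap(mechanisms)


def generate_cohort(
    config: SynthConfig | None = None,
) -> tuple[ExpressionDataset, SampleTable, list[Pathway], MechanismMap, GroundTruth]:
    """Generate one cohort under ``config`` (deterministic for a fixed seed).

    DMSO samples are pure Gaussian noise. Non-toxic samples add a small
    random shift (|shift| <= 0.25 * effect_size per gene) on a random subset
    of non-target genes — a generic, non-toxic drug effect. Toxic samples add
    ``u_g * dose_response_shift(dose)`` to each gene g of the perturbed
    mechanism's pathways, where the fixed per-gene response coefficients u_g
    emulate heterogeneous within-pathway responsiveness (see
    ``SynthConfig.gene_response``). The random stream is split hierarchically
    per group, so sample counts in one group do not change another group's
    draws.
    """
    if config is None:
        config = SynthConfig()
    config.validate()
    root = np.random.SeedSequence(config.seed)
    ss_layout, ss_dmso, ss_nt, ss_tox = root.spawn(4)

    layout_rng = np.random.default_rng(ss_layout)
    pathways, mech_map = _build_annotation(config, layout_rng)
    gene_ids = [f"G{i:04d}" for i in range(config.n_genes)]
    gene_index = {g: i for i, g in enumerate(gene_ids)}

    target_pids = mech_map.pathways_of(config.perturbed_mechanism)
    target_genes = sorted(
        {g for p in pathways if p.pathway_id in target_pids for g in p.genes}
    )
    target_rows = np.array([gene_index[g] for g in target_genes])
    nontarget_rows = np.array(
        [i for i in range(config.n_genes) if i not in set(target_rows)]
    )
    lo, hi = config.gene_response
    response = layout_rng.uniform(lo, hi, size=len(target_rows))
    if config.signed_response:
        response *= layout_rng.choice([-1.0, 1.0], size=len(target_rows))

    f = config.latent_var_fraction
    k_g = config.latent_rank
    k_p = config.pathway_factors
    use_latent = f > 0 and (k_g > 0 or k_p > 0)
    if use_latent:
        # per-gene loadings: global-factor columns for every gene, plus
        # own-pathway factor columns for pathway genes; rows unit-normalised
        global_load = np.zeros((config.n_genes, max(k_g, 1)))
        pathway_load = np.zeros((config.n_genes, max(k_p, 1)))
        pathway_of_gene = np.full(config.n_genes, -1)
        if k_p:
            for j, p in enumerate(pathways):
                rows = sorted(gene_index[g] for g in p.genes)
                pathway_load[rows] = layout_rng.normal(size=(len(rows), k_p))
                pathway_of_gene[rows] = j
        if k_g:
            free = pathway_of_gene < 0
            global_load[free] = layout_rng.normal(size=(int(free.sum()), k_g))
        norms = np.sqrt(
            np.sum(global_load**2, axis=1) + np.sum(pathway_load**2, axis=1)
        )
        norms[norms == 0] = 1.0  # genes in no factor block keep iid noise
        global_load /= norms[:, None]
        pathway_load /= norms[:, None]
        has_no_factor = (
            np.sum(global_load**2, axis=1) + np.sum(pathway_load**2, axis=1)
        ) < 0.5

    def background(rng: np.random.Generator) -> np.ndarray:
        """Gaussian background with marginal sd noise_sd per gene and the
        configured shared co-expression components."""
        eps = rng.normal(0.0, 1.0, config.n_genes)
        if not use_latent:
            return config.noise_sd * eps
        x = np.sqrt(1 - f) * eps
        shared = np.zeros(config.n_genes)
        if k_g:
            shared += global_load[:, :k_g] @ rng.normal(0.0, 1.0, k_g)
        if k_p:
            h_pw = rng.normal(0.0, 1.0, (len(pathways), k_p))
            in_pw = pathway_of_gene >= 0
            shared[in_pw] += np.einsum(
                "ij,ij->i", pathway_load[in_pw, :k_p], h_pw[pathway_of_gene[in_pw]]
            )
        x = x + np.sqrt(f) * shared
        x[has_no_factor] = eps[has_no_factor]
        return config.noise_sd * x

    cols: list[np.ndarray] = []
    meta_rows: list[dict] = []
    toxic_flags: dict[str, bool] = {}
    shifts: dict[str, float] = {}
    n_doses = len(config.doses)

    rng = np.random.default_rng(ss_dmso)
    for i in range(config.n_dmso):
        sid = f"DMSO_{i:03d}"
        cols.append(background(rng))
        meta_rows.append(
            dict(sample_id=sid, drug="DMSO", dose_um=0.0, time_h=config.time_h,
                 cell_line=config.cell_line, group=GROUP_DMSO)
        )
        toxic_flags[sid] = False
        shifts[sid] = 0.0

    rng = np.random.default_rng(ss_nt)
    max_nt_shift = 0.25 * config.effect_size
    for i in range(config.n_nontoxic):
        sid = f"NT_{i:03d}"
        drug = f"ntdrug-{i // n_doses + 1:02d}"
        dose = config.doses[i % n_doses]
        x = background(rng)
        n_shift = int(round(config.nontoxic_gene_fraction * len(nontarget_rows)))
        if n_shift and max_nt_shift > 0:
            hit = rng.choice(nontarget_rows, size=n_shift, replace=False)
            magnitude = max_nt_shift * rng.uniform(0.6, 1.0, n_shift)
            sign = rng.choice([-1.0, 1.0], n_shift)
            x[hit] += sign * magnitude
        cols.append(x)
        meta_rows.append(
            dict(sample_id=sid, drug=drug, dose_um=dose, time_h=config.time_h,
                 cell_line=config.cell_line, group=GROUP_NONTOXIC)
        )
        toxic_flags[sid] = False
        shifts[sid] = 0.0

    rng = np.random.default_rng(ss_tox)
    for i in range(config.n_toxic):
        sid = f"TOX_{i:03d}"
        drug = f"toxdrug-{i // n_doses + 1:02d}"
        dose = config.doses[i % n_doses]
        shift = dose_response_shift(dose, config)
        x = background(rng)
        x[target_rows] += response * shift
        cols.append(x)
        meta_rows.append(
            dict(sample_id=sid, drug=drug, dose_um=dose, time_h=config.time_h,
                 cell_line=config.cell_line, group=GROUP_TOXIC)
        )
        toxic_flags[sid] = True
        shifts[sid] = float(shift)

    sample_ids = [m["sample_id"] for m in meta_rows]
    expr = ExpressionDataset(gene_ids, sample_ids, np.column_stack(cols))
    meta = SampleTable(pd.DataFrame(meta_rows))
    truth = GroundTruth(toxic_flags, shifts, list(target_pids))
    return expr, meta, pathways, mech_map, truth
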