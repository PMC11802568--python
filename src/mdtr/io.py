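"""Data model and readers/writers for the MDTR pipeline.

Core containers: :class:`ExpressionDataset` (genes x samples z-score matrix),
:class:`SampleTable` (per-sample treatment annotations), :class:`Pathway`
(gene set), :class:`MechanismMap` (ordered mechanism -> pathway assignment)
and :class:`MDTRProfile` (per-sample ruler output).

Formats: GCT 1.3 text (expression, with a plain genes-as-rows TSV fallback),
GMT (gene sets), TSV (sample metadata), JSON/YAML (mechanism map) and
TSV + JSON sidecar (profiles out).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

GROUP_DMSO = "DMSO"
GROUP_NONTOXIC = "NONTOXIC"
GROUP_TOXIC = "TOXIC"
VALID_GROUPS = (GROUP_DMSO, GROUP_NONTOXIC, GROUP_TOXIC)

#: metadata TSV column order
META_COLUMNS = ["sample_id", "drug", "dose_um", "time_h", "cell_line", "group"]


class FormatError(ValueError):
    """Malformed input file (bad header, non-numeric cell, short line...)."""


class ValidationError(ValueError):
    """Structurally parseable input violating a model invariant."""


class ResolutionError(ValueError):
    """A referenced identifier does not resolve to a loaded object."""


# ---------------------------------------------------------------------------
# Expression data


@dataclass
class ExpressionDataset:
    """Genes x samples matrix of z-scores relative to vehicle controls."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray  # shape (n_genes, n_samples), float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("expression values must be a 2-D matrix")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        for label, ids in (("gene", self.gene_ids), ("sample", self.sample_ids)):
            if len(set(ids)) != len(ids):
                dupes = sorted({i for i in ids if ids.count(i) > 1})
                raise ValidationError(f"duplicate {label} ids: {dupes[:5]}")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("expression values must be finite")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionDataset":
        """Row-subset in the given gene order (genes must all be present)."""
        index = {g: i for i, g in enumerate(self.gene_ids)}
        try:
            rows = [index[g] for g in genes]
        except KeyError as exc:
            raise KeyError(f"gene {exc.args[0]!r} not in dataset") from None
        return ExpressionDataset(list(genes), list(self.sample_ids), self.values[rows])

    def sample_matrix(self, sample_ids: Sequence[str] | None = None) -> np.ndarray:
        """Samples-as-rows matrix (n_samples x n_genes) for model fitting."""
        if sample_ids is None:
            return self.values.T.copy()
        index = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            cols = [index[s] for s in sample_ids]
        except KeyError as exc:
            raise KeyError(f"sample {exc.args[0]!r} not in dataset") from None
        return self.values[:, cols].T.copy()


def load_expression_gct(path: str | Path) -> ExpressionDataset:
    """Read a GCT 1.3 text file (or a plain genes-as-rows TSV fallback).

    The GCT layout is ``#1.3``, a dimensions line
    ``n_genes<TAB>n_samples[<TAB>n_row_meta<TAB>n_col_meta]``, a column-header
    line starting with the id column, then one row per gene. Row metadata
    columns (if declared) are skipped. A file whose first line is not a GCT
    version tag is read as a TSV with gene ids in the first column and sample
    ids in the header.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().rstrip("\n")
    if first.startswith("#1."):
        if first.strip() != "#1.3":
            raise FormatError(f"{path}: unsupported GCT version line {first!r}")
        return _load_gct13(path)
    return _load_plain_tsv(path)


def _load_gct13(path: Path) -> ExpressionDataset:
    with open(path) as fh:
        fh.readline()
        dims_line = fh.readline().rstrip("\n")
        dims = dims_line.split("\t")
        if len(dims) not in (2, 4):
            raise FormatError(f"{path}: malformed GCT dimensions line {dims_line!r}")
        try:
            parsed = [int(x) for x in dims]
        except ValueError:
            raise FormatError(
                f"{path}: non-integer GCT dimensions line {dims_line!r}"
            ) from None
        n_genes, n_samples = parsed[0], parsed[1]
        n_row_meta = parsed[2] if len(parsed) == 4 else 1  # classic "Description"
        header = fh.readline().rstrip("\n").split("\t")
        expected_cols = 1 + n_row_meta + n_samples
        if len(header) != expected_cols:
            raise FormatError(
                f"{path}: GCT header has {len(header)} columns, expected {expected_cols}"
            )
        sample_ids = header[1 + n_row_meta :]
        gene_ids: list[str] = []
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=4):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != expected_cols:
                raise FormatError(
                    f"{path}:{lineno}: row has {len(fields)} columns, expected {expected_cols}"
                )
            gene_ids.append(fields[0])
            try:
                rows.append([float(v) for v in fields[1 + n_row_meta :]])
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-numeric expression value"
                ) from None
    if len(gene_ids) != n_genes:
        raise FormatError(
            f"{path}: header declares {n_genes} genes but {len(gene_ids)} data rows found"
        )
    return ExpressionDataset(gene_ids, sample_ids, np.array(rows, dtype=float))


def _load_plain_tsv(path: Path) -> ExpressionDataset:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from None
    return ExpressionDataset(
        [str(g) for g in df.index], [str(s) for s in df.columns], values
    )


def write_expression_gct(dataset: ExpressionDataset, path: str | Path) -> None:
    """Write a GCT 1.3 file with an empty Description metadata column."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("#1.3\n")
        fh.write(f"{dataset.n_genes}\t{dataset.n_samples}\t1\t0\n")
        fh.write("id\tDescription\t" + "\t".join(dataset.sample_ids) + "\n")
        for gene, row in zip(dataset.gene_ids, dataset.values):
            fh.write(gene + "\t\t" + "\t".join(repr(float(v)) for v in row) + "\n")


# ---------------------------------------------------------------------------
# Sample metadata


@dataclass
class SampleTable:
    """Per-sample treatment annotations.

    One row per sample: drug name (``DMSO`` for vehicle), dose in uM
    (0 for DMSO), treatment time in hours, cell line, and toxicity group
    label (``DMSO`` / ``NONTOXIC`` / ``TOXIC``).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table
        missing = [c for c in META_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"sample table missing columns: {missing}")
        df = df[META_COLUMNS].copy()
        df["sample_id"] = df["sample_id"].astype(str)
        if df["sample_id"].duplicated().any():
            dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValidationError(f"duplicate sample ids: {dupes[:5]}")
        bad_group = sorted(set(df["group"]) - set(VALID_GROUPS))
        if bad_group:
            raise ValidationError(f"unknown group labels: {bad_group}")
        dmso_mismatch = (df["group"] == GROUP_DMSO) != (df["drug"] == "DMSO")
        if dmso_mismatch.any():
            raise ValidationError(
                "group is DMSO iff drug is DMSO; offending samples: "
                f"{df.loc[dmso_mismatch, 'sample_id'].tolist()[:5]}"
            )
        if (df["dose_um"].astype(float) < 0).any():
            raise ValidationError("doses must be nonnegative")
        if (df["time_h"].astype(float) <= 0).any():
            raise ValidationError("treatment times must be positive")
        self.table = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return self.table["sample_id"].tolist()

    def ids_in_group(self, group: str) -> list[str]:
        if group not in VALID_GROUPS:
            raise ValueError(f"unknown group {group!r}")
        return self.table.loc[self.table["group"] == group, "sample_id"].tolist()

    def row(self, sample_id: str) -> pd.Series:
        match = self.table[self.table["sample_id"] == sample_id]
        if match.empty:
            raise KeyError(sample_id)
        return match.iloc[0]


def load_sample_table(path: str | Path) -> SampleTable:
    df = pd.read_csv(path, sep="\t")
    return SampleTable(df)


def write_sample_table(table: SampleTable, path: str | Path) -> None:
    table.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Gene sets and mechanism map


@dataclass(frozen=True)
class Pathway:
    """A named gene set (e.g. one KEGG pathway)."""

    pathway_id: str
    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if len(self.genes) < 1:
            raise ValidationError(f"pathway {self.pathway_id}: empty gene set")


def load_gene_sets_gmt(path: str | Path) -> list[Pathway]:
    """Read a GMT file: ``id<TAB>description<TAB>gene1<TAB>gene2...`` per line."""
    path = Path(path)
    pathways: list[Pathway] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, need >= 3"
                )
            pid, name, genes = fields[0], fields[1], [g for g in fields[2:] if g]
            if pid in seen:
                raise ValidationError(f"{path}:{lineno}: duplicate pathway id {pid!r}")
            seen.add(pid)
            if not genes:
                raise FormatError(f"{path}:{lineno}: pathway {pid!r} lists no genes")
            if len(set(genes)) != len(genes):
                logger.warning(
                    "%s:%d: pathway %s has duplicate genes; deduplicating",
                    path, lineno, pid,
                )
            pathways.append(Pathway(pid, name, frozenset(genes)))
    return pathways


def write_gene_sets_gmt(pathways: Sequence[Pathway], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in pathways:
            fh.write("\t".join([p.pathway_id, p.name, *sorted(p.genes)]) + "\n")


@dataclass
class MechanismMap:
    """Ordered assignment of pathways to toxicity mechanisms (radar axes)."""

    mechanisms: list[tuple[str, list[str]]]

    def __post_init__(self) -> None:
        names = [m for m, _ in self.mechanisms]
        if len(set(names)) != len(names):
            raise ValidationError("mechanism names must be unique")
        for name, pids in self.mechanisms:
            if not pids:
                raise ValidationError(f"mechanism {name!r} has no pathways")

    @property
    def mechanism_names(self) -> list[str]:
        return [m for m, _ in self.mechanisms]

    def pathways_of(self, mechanism: str) -> list[str]:
        for name, pids in self.mechanisms:
            if name == mechanism:
                return list(pids)
        raise KeyError(mechanism)

    @property
    def all_pathway_ids(self) -> list[str]:
        out: list[str] = []
        for _, pids in self.mechanisms:
            out.extend(p for p in pids if p not in out)
        return out

    def validate_against(self, pathways: Iterable[Pathway]) -> None:
        known = {p.pathway_id for p in pathways}
        missing = [pid for pid in self.all_pathway_ids if pid not in known]
        if missing:
            raise ResolutionError(f"unresolved pathway ids: {missing}")


def load_mechanism_map(
    path: str | Path, pathways: Iterable[Pathway] | None = None
) -> MechanismMap:
    """Load a JSON or YAML mechanism -> pathway-id mapping, order-preserving.

    If ``pathways`` is given, every referenced id must resolve against it.
    """
    path = Path(path)
    with open(path) as fh:
        if path.suffix.lower() in (".yaml", ".yml"):
            raw = yaml.safe_load(fh)
        else:
            raw = json.load(fh)
    if not isinstance(raw, Mapping):
        raise FormatError(f"{path}: mechanism map must be a mapping")
    mm = MechanismMap([(str(k), [str(p) for p in v]) for k, v in raw.items()])
    if pathways is not None:
        mm.validate_against(pathways)
    return mm


def write_mechanism_map(mm: MechanismMap, path: str | Path) -> None:
    path = Path(path)
    data = {name: pids for name, pids in mm.mechanisms}
    with open(path, "w") as fh:
        if path.suffix.lower() in (".yaml", ".yml"):
            yaml.safe_dump(data, fh, sort_keys=False)
        else:
            json.dump(data, fh, indent=1)


def intersect_pathway(
    pathway: Pathway, gene_ids: Sequence[str], min_genes: int = 3
) -> list[str] | None:
    """Pathway genes present in the expression matrix, in matrix row order.

    Genes missing from the matrix are dropped with a warning; if fewer than
    ``min_genes`` remain the pathway is skipped (returns ``None``).
    """
    present = [g for g in gene_ids if g in pathway.genes]
    dropped = len(pathway.genes) - len(present)
    if dropped:
        logger.warning(
            "pathway %s: %d/%d genes absent from the expression matrix",
            pathway.pathway_id, dropped, len(pathway.genes),
        )
    if len(present) < min_genes:
        logger.warning(
            "pathway %s skipped: %d genes present < min_genes=%d",
            pathway.pathway_id, len(present), min_genes,
        )
        return None
    return present


# ---------------------------------------------------------------------------
# Ruler output


@dataclass
class MDTRProfile:
    """Per-sample ruler output: five mechanism distances plus pathway detail."""

    sample_id: str
    mechanism_distances: dict[str, float]
    pathway_distances: dict[str, float] = field(default_factory=dict)
    pathway_weights: dict[str, float] = field(default_factory=dict)
    missing_mechanisms: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for pid, d in self.pathway_distances.items():
            if not (-1e-9 <= d <= 1 + 1e-9):
                raise ValidationError(
                    f"{self.sample_id}: pathway {pid} distance {d} outside [0, 1]"
                )
        for pid, w in self.pathway_weights.items():
            if not (w >= 0 and np.isfinite(w)):
                raise ValidationError(
                    f"{self.sample_id}: pathway {pid} weight {w} invalid"
                )

    @property
    def max_distance(self) -> float:
        return max(self.mechanism_distances.values())


def write_mdtr_profiles(
    profiles: Sequence[MDTRProfile], path: str | Path
) -> None:
    """Write profiles as a TSV (one row per sample, one column per mechanism,
    plus ``max_distance``) with a JSON sidecar carrying per-pathway detail."""
    if not profiles:
        raise ValidationError("no profiles to write")
    path = Path(path)
    mechanisms = list(profiles[0].mechanism_distances)
    rows = []
    for p in profiles:
        if list(p.mechanism_distances) != mechanisms:
            raise ValidationError("profiles have inconsistent mechanism axes")
        rows.append(
            {"sample_id": p.sample_id, **p.mechanism_distances,
             "max_distance": p.max_distance}
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.12g")
    sidecar = path.with_suffix(path.suffix + ".json")
    detail = {
        p.sample_id: {
            "mechanism_distances": p.mechanism_distances,
            "pathway_distances": p.pathway_distances,
            "pathway_weights": p.pathway_weights,
            "missing_mechanisms": p.missing_mechanisms,
        }
        for p in profiles
    }
    with open(sidecar, "w") as fh:
        json.dump(detail, fh, indent=1)


def load_mdtr_profiles(path: str | Path) -> list[MDTRProfile]:
    """Read back profiles written by :func:`write_mdtr_profiles`."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    sidecar = path.with_suffix(path.suffix + ".json")
    detail: dict = {}
    if sidecar.exists():
        with open(sidecar) as fh:
            detail = json.load(fh)
    mechanisms = [c for c in df.columns if c not in ("sample_id", "max_distance")]
    profiles = []
    for _, row in df.iterrows():
        sid = str(row["sample_id"])
        extra = detail.get(sid, {})
        profiles.append(
            MDTRProfile(
                sample_id=sid,
                mechanism_distances={m: float(row[m]) for m in mechanisms},
                pathway_distances=extra.get("pathway_distances", {}),
                pathway_weights=extra.get("pathway_weights", {}),
                missing_mechanisms=extra.get("missing_mechanisms", []),
            )
        )
    return profiles
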