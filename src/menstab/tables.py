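"""Abundance, taxonomy, metadata and environment tables, plus network export.

The central container is :class:`AbundanceTable`, a taxa-by-samples count
matrix (rows = zOTUs/taxa, columns = samples) with optional per-sample group
labels and per-taxon ranked lineages.  All tables travel as TSV; networks are
exported as GraphML (with a plain edge-list TSV as a secondary format).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from math import ceil
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "AbundanceTable",
    "EnvTable",
    "read_abundance_table",
    "write_abundance_table",
    "read_env_table",
    "write_env_table",
    "read_metadata",
    "read_taxonomy",
    "filter_low_abundance",
    "filter_prevalence",
    "relative_abundance",
    "aggregate_taxa",
    "write_network_graphml",
    "read_network_graphml",
    "write_network_edgelist",
]

#: canonical rank order used when parsing lineage strings
RANKS = ("phylum", "class", "order", "family", "genus")


class TableValidationError(ValueError):
    """Raised when a table violates a structural invariant."""


@dataclass
class AbundanceTable:
    """Taxa × samples non-negative abundance matrix.

    Parameters
    ----------
    taxa_ids
        Unique taxon identifiers (row labels).
    sample_ids
        Unique sample identifiers (column labels).
    counts
        ``(n_taxa, n_samples)`` array of non-negative reals.
    group_of
        Optional map ``sample_id -> group label``.
    lineage_of
        Optional map ``taxon_id -> ordered rank list`` (phylum … genus).
    """

    taxa_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    group_of: dict[str, str] | None = None
    lineage_of: dict[str, list[str]] | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2:
            raise TableValidationError("counts must be a 2-D matrix")
        if self.counts.shape != (len(self.taxa_ids), len(self.sample_ids)):
            raise TableValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.taxa_ids)} taxa × {len(self.sample_ids)} samples"
            )
        if len(set(self.taxa_ids)) != len(self.taxa_ids):
            dup = _first_duplicate(self.taxa_ids)
            raise TableValidationError(f"duplicate taxon ID: {dup!r}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dup = _first_duplicate(self.sample_ids)
            raise TableValidationError(f"duplicate sample ID: {dup!r}")
        if np.any(self.counts < 0):
            i, j = np.argwhere(self.counts < 0)[0]
            raise TableValidationError(
                f"negative count at taxon {self.taxa_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )
        if not np.all(np.isfinite(self.counts)):
            raise TableValidationError("counts contain non-finite values")
        if self.group_of is not None:
            unknown = set(self.group_of) - set(self.sample_ids)
            if unknown:
                raise TableValidationError(
                    f"group labels for unknown samples: {sorted(unknown)}"
                )

    @property
    def n_taxa(self) -> int:
        return len(self.taxa_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.taxa_ids, columns=self.sample_ids)

    def taxa_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def sample_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def groups(self) -> dict[str, list[str]]:
        """Sample IDs per group label (empty if no labels attached)."""
        out: dict[str, list[str]] = {}
        if self.group_of:
            for s in self.sample_ids:
                g = self.group_of.get(s)
                if g is not None:
                    out.setdefault(g, []).append(s)
        return out

    def select_samples(self, sample_ids: Sequence[str]) -> "AbundanceTable":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return replace(
            self,
            sample_ids=list(sample_ids),
            counts=self.counts[:, idx],
            group_of=(
                {s: self.group_of[s] for s in sample_ids if s in self.group_of}
                if self.group_of
                else None
            ),
        )

    def select_taxa(self, keep: np.ndarray) -> "AbundanceTable":
        """Subset rows by a boolean mask or index array (order preserved)."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        taxa = [self.taxa_ids[i] for i in keep]
        return replace(
            self,
            taxa_ids=taxa,
            counts=self.counts[keep, :],
            lineage_of=(
                {t: self.lineage_of[t] for t in taxa if t in self.lineage_of}
                if self.lineage_of
                else None
            ),
        )


@dataclass
class EnvTable:
    """Samples × environmental-variables matrix (soil physicochemistry)."""

    sample_ids: list[str]
    variable_names: list[str]
    values: np.ndarray
    units: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.variable_names)):
            raise TableValidationError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples × {len(self.variable_names)} variables"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise TableValidationError("duplicate sample IDs in EnvTable")
        if np.any(~np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise TableValidationError(
                f"missing/non-finite value for sample {self.sample_ids[i]!r}, "
                f"variable {self.variable_names[j]!r}; missing values are not imputed"
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.sample_ids, columns=self.variable_names
        )


def _first_duplicate(items: Sequence[str]) -> str:
    seen: set[str] = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    return ""


# ---------------------------------------------------------------------------
# I/O


def _read_numeric_tsv(path: str | Path, what: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"{what} file not found: {path}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    out = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.to_numpy().argmax()]
            raise TableValidationError(
                f"malformed numeric cell in {path.name} at row {row!r}, "
                f"column {col!r}: {df.loc[row, col]!r}"
            )
        out[col] = converted
    return out


def read_abundance_table(
    path: str | Path,
    metadata: str | Path | None = None,
    taxonomy: str | Path | None = None,
    transposed: bool = False,
) -> AbundanceTable:
    """Read a taxa × samples TSV (first column = taxon IDs, header = sample IDs).

    ``transposed=True`` declares that the file stores samples as rows; the
    orientation is never guessed from the data.
    """
    df = _read_numeric_tsv(path, "abundance")
    if transposed:
        df = df.T
    table = AbundanceTable(
        taxa_ids=[str(t) for t in df.index],
        sample_ids=[str(s) for s in df.columns],
        counts=df.to_numpy(dtype=float),
    )
    if metadata is not None:
        table.group_of = read_metadata(metadata)
        unknown = set(table.group_of) - set(table.sample_ids)
        if unknown:
            raise TableValidationError(
                f"metadata refers to unknown samples: {sorted(unknown)}"
            )
    if taxonomy is not None:
        table.lineage_of = read_taxonomy(taxonomy)
    return table


def write_abundance_table(table: AbundanceTable, path: str | Path) -> None:
    df = table.to_frame()
    # preserve integer formatting for count tables
    if np.allclose(df.to_numpy(), np.round(df.to_numpy())):
        df = df.astype(np.int64)
    df.to_csv(path, sep="\t", index_label="taxon_id")


def read_metadata(path: str | Path) -> dict[str, str]:
    """Read a sample → group-label TSV (two columns, header required)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"metadata file not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise TableValidationError("metadata needs ≥ 2 columns (sample, group)")
    samples = df.iloc[:, 0].astype(str)
    if samples.duplicated().any():
        raise TableValidationError("duplicate sample IDs in metadata")
    return dict(zip(samples, df.iloc[:, 1].astype(str)))


def read_taxonomy(path: str | Path) -> dict[str, list[str]]:
    """Read taxon → lineage TSV; lineage either one ';'-joined column or one
    column per rank."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"taxonomy file not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str, index_col=0)
    out: dict[str, list[str]] = {}
    for taxon, row in df.iterrows():
        vals = [v for v in row.tolist() if isinstance(v, str) and v.strip()]
        if len(vals) == 1 and ";" in vals[0]:
            vals = [p.strip() for p in vals[0].split(";")]
        out[str(taxon)] = vals
    return out


def read_env_table(path: str | Path) -> EnvTable:
    """Read a samples × variables TSV of soil properties; missing cells error."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"environment file not found: {path}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    return EnvTable(
        sample_ids=[str(s) for s in df.index],
        variable_names=[str(v) for v in df.columns],
        values=df.to_numpy(dtype=float),
    )


def write_env_table(env: EnvTable, path: str | Path) -> None:
    env.to_frame().to_csv(path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# Filters and transforms


def filter_low_abundance(table: AbundanceTable, min_total: int = 8) -> AbundanceTable:
    """Drop taxa whose total count across samples is below ``min_total``.

    The removal rule is a strict ``<``: a taxon with total exactly equal to
    ``min_total`` is retained.  The default of 8 matches the denoising
    convention of discarding zOTUs with fewer than 8 supporting sequences.
    """
    if min_total < 0:
        raise ValueError("min_total must be ≥ 0")
    keep = table.taxa_totals() >= min_total
    if not keep.any():
        warnings.warn("filter_low_abundance removed every taxon", stacklevel=2)
    return table.select_taxa(keep)


def filter_prevalence(table: AbundanceTable, min_fraction: float) -> AbundanceTable:
    """Keep taxa detected (count > 0) in ≥ ceil(min_fraction × n_samples) samples."""
    if not 0.0 <= min_fraction <= 1.0:
        raise ValueError("min_fraction must lie in [0, 1]")
    required = ceil(min_fraction * table.n_samples)
    keep = (table.counts > 0).sum(axis=1) >= required
    return table.select_taxa(keep)


def relative_abundance(table: AbundanceTable) -> AbundanceTable:
    """Normalise each sample (column) to sum to 1."""
    totals = table.sample_totals()
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValueError(
            f"sample {table.sample_ids[zero[0]]!r} has zero total; cannot normalise"
        )
    return replace(table, counts=table.counts / totals)


def aggregate_taxa(table: AbundanceTable, rank: str) -> AbundanceTable:
    """Sum taxa into groups at a taxonomic rank; unlabelled taxa pool into
    ``"Unclassified"``.  Per-sample totals are conserved exactly."""
    if table.lineage_of is None:
        raise ValueError("aggregate_taxa requires lineage_of")
    rank = rank.lower()
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
    level = RANKS.index(rank)
    labels = []
    for t in table.taxa_ids:
        lin = (table.lineage_of or {}).get(t, [])
        labels.append(lin[level] if level < len(lin) and lin[level] else "Unclassified")
    order: list[str] = []
    rows: dict[str, np.ndarray] = {}
    for lab, row in zip(labels, table.counts):
        if lab not in rows:
            order.append(lab)
            rows[lab] = row.astype(float).copy()
        else:
            rows[lab] += row
    return AbundanceTable(
        taxa_ids=order,
        sample_ids=list(table.sample_ids),
        counts=np.vstack([rows[lab] for lab in order]) if order else
        np.empty((0, table.n_samples)),
        group_of=dict(table.group_of) if table.group_of else None,
    )


# ---------------------------------------------------------------------------
# Network export


def write_network_graphml(net, path: str | Path) -> None:
    """Export a signed network to GraphML.

    Node attributes (module ID, Zi, Pi, role) are written when present on the
    graph; edges always carry ``sign`` (+1/−1) and ``weight``.
    """
    g = net.graph if hasattr(net, "graph") else net
    nx.write_graphml(g, str(path))


def read_network_graphml(path: str | Path):
    from .network import SignedNetwork

    g = nx.read_graphml(str(path))
    g = nx.relabel_nodes(g, {n: str(n) for n in g.nodes})
    for _, _, d in g.edges(data=True):
        d["sign"] = int(d.get("sign", 1))
        d["weight"] = float(d.get("weight", 1.0))
    threshold = float(g.graph.get("threshold_used", 0.0))
    return SignedNetwork(graph=g, threshold_used=threshold)


def write_network_edgelist(net, path: str | Path) -> None:
    """Secondary export: TSV with columns taxon_a, taxon_b, sign, weight."""
    g = net.graph if hasattr(net, "graph") else net
    rows = [
        {"taxon_a": u, "taxon_b": v, "sign": d["sign"], "weight": d["weight"]}
        for u, v, d in g.edges(data=True)
    ]
    pd.DataFrame(rows, columns=["taxon_a", "taxon_b", "sign", "weight"]).to_csv(
        path, sep="\t", index=False
    )
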