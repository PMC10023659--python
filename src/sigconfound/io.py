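"""Readers and writers for external formats, plus the run manifest.

Counts come in as genes x samples TSV (gene ids in the first column, sample
ids in the header) or MatrixMarket MTX accompanied by ``<stem>.genes.txt``
and ``<stem>.samples.txt`` index files.  Sample metadata is a TSV with one
row per sample.  Gene sets are GMT; orthology is a strict one-to-one
two-column TSV.

Gene identifiers are treated as opaque strings: no case normalization or
symbol matching is ever performed, and cross-dataset gene matching goes
exclusively through an :class:`OrthologyMap`.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

logger = logging.getLogger(__name__)

DIAGNOSIS_LEVELS = ("control", "case")
TOX_GROUP_LEVELS = ("neg", "atypical", "typical", "mixed", "none")

#: columns read_metadata requires, with their kind
METADATA_COLUMNS = {
    "sample_id": "id",
    "diagnosis": "categorical",
    "tox_group": "categorical",
    "sex": "categorical",
    "age": "numeric",
    "rin": "numeric",
    "pmi": "numeric",
    "ph": "numeric",
    "batch": "categorical",
    "effective_mapping_rate": "numeric",
    "intergenic_rate": "numeric",
}


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: dict[str, int] = {}
    dups = []
    for x in ids:
        seen[x] = seen.get(x, 0) + 1
        if seen[x] == 2:
            dups.append(x)
    if dups:
        raise ValueError(f"duplicate {what} identifiers: {sorted(dups)}")


@dataclass
class CountMatrix:
    """Genes x samples non-negative integer counts with stable identifiers."""

    gene_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if counts.shape[0] < 2 or counts.shape[1] < 2:
            raise ValueError("need at least 2 genes and 2 samples")
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        if np.issubdtype(counts.dtype, np.floating):
            if not np.all(np.isfinite(counts)) or np.any(counts != np.round(counts)):
                raise ValueError("counts must be integers")
        counts = counts.astype(np.int64)
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        self.counts = counts

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    @property
    def library_sizes(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CountMatrix":
        return cls(list(frame.index), list(frame.columns), frame.to_numpy())

    def subset_genes(self, keep: np.ndarray) -> "CountMatrix":
        keep = np.asarray(keep)
        genes = [g for g, k in zip(self.gene_ids, keep) if k] if keep.dtype == bool else [
            self.gene_ids[i] for i in keep
        ]
        idx = np.where(keep)[0] if keep.dtype == bool else keep
        return CountMatrix(genes, list(self.sample_ids), self.counts[idx])

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in sample_ids]
        return CountMatrix(list(self.gene_ids), list(sample_ids), self.counts[:, idx])


@dataclass
class SampleTable:
    """Validated per-sample metadata (diagnosis, toxicology group, covariates)."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        missing = [c for c in METADATA_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"metadata missing required columns: {missing}")
        df = df.copy()
        df["sample_id"] = df["sample_id"].astype(str)
        _check_unique(list(df["sample_id"]), "sample")
        bad = set(df["diagnosis"]) - set(DIAGNOSIS_LEVELS)
        if bad:
            raise ValueError(f"invalid diagnosis levels: {sorted(bad)}")
        bad = set(df["tox_group"]) - set(TOX_GROUP_LEVELS)
        if bad:
            raise ValueError(f"invalid tox_group levels: {sorted(bad)}")
        none_on_case = df[(df["tox_group"] == "none") & (df["diagnosis"] == "case")]
        if len(none_on_case):
            raise ValueError(
                "tox_group 'none' is permitted only for controls; offending samples: "
                f"{list(none_on_case['sample_id'])}"
            )
        for col, (lo, hi) in {
            "age": (0.0, np.inf),
            "rin": (0.0, 10.0),
            "effective_mapping_rate": (0.0, 1.0),
            "intergenic_rate": (0.0, 1.0),
        }.items():
            vals = pd.to_numeric(df[col])
            if (vals <= lo).any() if col == "age" else ((vals < lo) | (vals > hi)).any():
                raise ValueError(f"column {col!r} out of range [{lo}, {hi}]")
            df[col] = vals
        for col in ("pmi", "ph"):
            df[col] = pd.to_numeric(df[col])
        self.frame = df.set_index("sample_id", drop=False)

    def aligned_to(self, sample_ids: Sequence[str]) -> "SampleTable":
        """Join metadata onto the count matrix's sample order (never the reverse)."""
        missing = [s for s in sample_ids if s not in self.frame.index]
        if missing:
            raise ValueError(f"samples present in counts but absent from metadata: {missing}")
        return SampleTable(self.frame.loc[list(sample_ids)].reset_index(drop=True))

    def __len__(self) -> int:
        return len(self.frame)


@dataclass
class GeneSetCollection:
    """Named, non-empty gene sets with optional descriptions."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)


@dataclass
class OrthologyMap:
    """Strict one-to-one gene-identifier pairs between two datasets."""

    pairs: list[tuple[str, str]]

    def __post_init__(self) -> None:
        a_ids = [a for a, _ in self.pairs]
        b_ids = [b for _, b in self.pairs]
        _check_unique(a_ids, "dataset-A")
        _check_unique(b_ids, "dataset-B")

    @property
    def a_to_b(self) -> dict[str, str]:
        return dict(self.pairs)

    @property
    def b_to_a(self) -> dict[str, str]:
        return {b: a for a, b in self.pairs}

    def __len__(self) -> int:
        return len(self.pairs)


def read_counts(path: str | Path, format: str | None = None) -> CountMatrix:
    """Read a counts file (TSV or MTX triplet).

    TSV: genes in rows, first column gene ids, header row of sample ids.
    MTX: genes x samples sparse matrix plus ``<stem>.genes.txt`` and
    ``<stem>.samples.txt`` (one identifier per line).
    """
    path = Path(path)
    if format is None:
        format = "mtx" if path.suffix == ".mtx" else "tsv"
    if format == "tsv":
        if path.stat().st_size == 0:
            raise ValueError(f"empty counts file: {path}")
        df = pd.read_csv(path, sep="\t", index_col=0)
        if df.empty:
            raise ValueError(f"counts file has no data rows: {path}")
        df.index = df.index.astype(str)
        return CountMatrix(list(df.index), [str(c) for c in df.columns], df.to_numpy())
    if format == "mtx":
        mat = scipy.io.mmread(path)
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        stem = path.with_suffix("")
        genes = Path(f"{stem}.genes.txt").read_text().split()
        samples = Path(f"{stem}.samples.txt").read_text().split()
        return CountMatrix(genes, samples, np.asarray(mat))
    raise ValueError(f"unknown counts format {format!r}")


def write_counts(cm: CountMatrix, path: str | Path) -> None:
    cm.to_frame().to_csv(path, sep="\t", index_label="gene_id")


def read_metadata(path: str | Path) -> SampleTable:
    """Read and validate the sample metadata TSV (see METADATA_COLUMNS)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "batch": str})
    return SampleTable(df)


def write_metadata(table: SampleTable, path: str | Path) -> None:
    table.frame.to_csv(path, sep="\t", index=False)


def read_gene_sets(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: name <tab> description <tab> member [<tab> member ...]."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: malformed GMT line (<3 fields)")
            name, desc, *members = fields
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            # dedupe while preserving first-seen order
            members = list(dict.fromkeys(m for m in members if m))
            if not members:
                raise ValueError(f"{path}:{lineno}: gene set {name!r} has no members")
            sets[name] = members
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gene_sets(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *members]) + "\n")


def read_orthology(path: str | Path) -> OrthologyMap:
    """Read a two-column TSV of ortholog pairs; rows violating one-to-one-ness
    (any identifier seen more than once) are dropped with a logged count."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"orthology file {path} needs two columns")
    a_counts = df[0].value_counts()
    b_counts = df[1].value_counts()
    ok = df[0].map(a_counts).eq(1) & df[1].map(b_counts).eq(1)
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.warning("dropped %d orthology rows violating one-to-one-ness", n_dropped)
    kept = df[ok]
    if len(kept) < 1:
        raise ValueError(f"orthology file {path} has no valid one-to-one pairs")
    return OrthologyMap([(a, b) for a, b in zip(kept[0], kept[1])])


def write_orthology(omap: OrthologyMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        for a, b in omap.pairs:
            fh.write(f"{a}\t{b}\n")


def write_table(frame: pd.DataFrame, path: str | Path, index: bool = True,
                index_label: str | None = None) -> None:
    """Write a TSV with floats at 6 significant digits (diff-able outputs)."""
    frame.to_csv(path, sep="\t", index=index, index_label=index_label,
                 float_format="%.6g")


def file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Reproducibility record: config snapshot, seed, digests, stage dimensions."""

    config: Mapping
    seed: int
    version: str
    input_digests: dict[str, str] = field(default_factory=dict)
    stage_shapes: dict[str, list[int]] = field(default_factory=dict)
    output_digests: dict[str, str] = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)

    def record_stage(self, name: str, shape: Sequence[int]) -> None:
        self.stage_shapes[name] = [int(x) for x in shape]

    def record_output(self, name: str, path: str | Path) -> None:
        self.output_digests[name] = file_digest(path)

    def to_json(self) -> str:
        payload = {
            "config": self.config,
            "seed": self.seed,
            "version": self.version,
            "input_digests": self.input_digests,
            "stage_shapes": self.stage_shapes,
            "output_digests": self.output_digests,
            "notes": self.notes,
        }
        return json.dumps(payload, indent=2, sort_keys=True, default=str)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json() + "\n")
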