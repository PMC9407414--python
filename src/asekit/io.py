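"""Count-table and ortholog-map readers, joint-matrix assembly, result writers.

Gene identity across files is by exact string match — the two parental
reference assemblies use distinct naming systems, so no prefix stripping or
normalisation is ever applied. Parsing is label-driven, never order-driven.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "ParseError",
    "CountMatrix",
    "OrthologMap",
    "JointCounts",
    "RunConfig",
    "read_count_table",
    "read_ortholog_map",
    "build_joint_counts",
    "write_results",
    "read_results",
]

FEATURECOUNTS_ANNOTATION = ("Chr", "Start", "End", "Strand", "Length")


class ParseError(ValueError):
    """Malformed input file; the message names the offending line."""


@dataclass(frozen=True)
class CountMatrix:
    """Integer read counts, genes in rows, samples in columns.

    ``counts`` is a DataFrame indexed by unique gene identifiers with one
    integer column per sample.
    """

    counts: pd.DataFrame

    def __post_init__(self):
        if self.counts.index.has_duplicates:
            dups = self.counts.index[self.counts.index.duplicated()].unique()
            raise ParseError(f"duplicate gene ids: {list(dups[:5])}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_labels(self) -> list[str]:
        return list(self.counts.columns)

    def __len__(self) -> int:
        return len(self.counts)


@dataclass(frozen=True)
class OrthologMap:
    """Strictly one-to-one pairing of gene ids between two assemblies."""

    pairs: pd.DataFrame  # columns: gene_a, gene_b

    def __post_init__(self):
        for col in ("gene_a", "gene_b"):
            dup = self.pairs[col][self.pairs[col].duplicated()]
            if len(dup):
                raise ParseError(
                    f"ortholog map is not 1:1 — duplicated {col} ids: "
                    f"{sorted(dup.unique())[:10]}"
                )

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class JointCounts:
    """Ortholog-paired count matrix: parents plus per-backcross alleles.

    ``data`` is indexed by the pair id ``"<gene_a>|<gene_b>"`` and holds the
    columns ``gene_a``, ``gene_b``, ``parent_A``, ``parent_B`` and, for each
    backcross label ``bc``, ``"{bc}_A"`` and ``"{bc}_B"``. Column suffix A
    refers to the first parent's (recurrent-genome) allele throughout.
    """

    data: pd.DataFrame
    backcrosses: tuple[str, ...]
    normalized: bool = False

    @property
    def count_columns(self) -> list[str]:
        cols = ["parent_A", "parent_B"]
        for bc in self.backcrosses:
            cols += [f"{bc}_A", f"{bc}_B"]
        return cols

    @property
    def counts(self) -> pd.DataFrame:
        return self.data[self.count_columns]

    def parent_pair(self) -> pd.DataFrame:
        return self.data[["parent_A", "parent_B"]]

    def hybrid_pair(self, backcross: str) -> pd.DataFrame:
        if backcross not in self.backcrosses:
            raise KeyError(f"unknown backcross {backcross!r}; have {self.backcrosses}")
        return self.data[[f"{backcross}_A", f"{backcross}_B"]]

    def with_counts(self, counts: pd.DataFrame, normalized: bool) -> "JointCounts":
        data = self.data.copy()
        data[counts.columns] = counts
        return replace(self, data=data, normalized=normalized)

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class RunConfig:
    """Thresholds and study constants for one analysis run.

    Attributes
    ----------
    alpha_regdiv : float
        FDR threshold for the cis/trans classification (0.005, i.e. the
        conservative FDR < 0.5% assignment).
    alpha_ase : float
        FDR threshold for per-backcross allelic-imbalance calls (0.05).
    alpha_joint : float
        FDR threshold for the cross-backcross joint/switching stage (0.005).
    lfc_threshold : float
        Biological |log2 fold-change| threshold for a directional call.
    min_total : int
        Minimum two-column total (after zero->1 pseudocounting) for a gene
        pair to be retained.
    genomic_prop : mapping
        Expected recurrent-parent (allele A) genome fraction per backcross:
        0.875 after two backcrosses, 0.9375 after three.
    n_genome : mapping
        Gene-universe size per backcross used by the incongruence z-test.
    seed : int
        Seed for any randomised step.
    """

    alpha_regdiv: float = 0.005
    alpha_ase: float = 0.05
    alpha_joint: float = 0.005
    lfc_threshold: float = 1.0
    min_total: int = 20
    genomic_prop: Mapping[str, float] = field(
        default_factory=lambda: {"BC2": 0.875, "BC3": 0.9375}
    )
    n_genome: Mapping[str, int] = field(
        default_factory=lambda: {"BC2": 33511, "BC3": 33394}
    )
    seed: int = 0

    def __post_init__(self):
        for name in ("alpha_regdiv", "alpha_ase", "alpha_joint"):
            a = getattr(self, name)
            if not 0 < a < 1:
                raise ValueError(f"{name} must lie in (0, 1), got {a}")
        if self.min_total < 0:
            raise ValueError("min_total must be >= 0")
        for bc, gp in self.genomic_prop.items():
            if not 0 < gp < 1:
                raise ValueError(f"genomic_prop[{bc!r}] must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path) -> None:
        payload = {
            "alpha_regdiv": self.alpha_regdiv,
            "alpha_ase": self.alpha_ase,
            "alpha_joint": self.alpha_joint,
            "lfc_threshold": self.lfc_threshold,
            "min_total": self.min_total,
            "genomic_prop": dict(self.genomic_prop),
            "n_genome": dict(self.n_genome),
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)


def _validate_int_frame(df: pd.DataFrame, path, line_offset: int) -> pd.DataFrame:
    """Coerce string cells to integers, reporting the 1-based source line."""
    out = {}
    for col in df.columns:
        series = df[col].astype(str).str.strip()
        numeric = pd.to_numeric(series, errors="coerce")
        bad = numeric.isna() | (numeric != numeric.round()) | (numeric < 0)
        if bad.any():
            pos = int(bad.to_numpy().argmax())
            raise ParseError(
                f"{path}: line {line_offset + pos + 1}: column {col!r} has "
                f"non-integer or negative count {series.iloc[pos]!r}"
            )
        out[col] = numeric.astype("int64")
    return pd.DataFrame(out, index=df.index)


def read_count_table(path, dialect: str = "plain_tsv") -> CountMatrix:
    """Read a gene x sample count table.

    Parameters
    ----------
    path : str or Path
        Tab-separated file.
    dialect : {"plain_tsv", "featurecounts"}
        ``plain_tsv``: header row, first column gene id, remaining columns
        integer counts. ``featurecounts``: '#'-prefixed comment lines, then
        a header with Geneid, Chr, Start, End, Strand, Length and one column
        per sample; the annotation columns are dropped.
    """
    path = Path(path)
    if dialect not in ("plain_tsv", "featurecounts"):
        raise ValueError(f"unknown dialect {dialect!r}")
    with open(path) as fh:
        lines = fh.readlines()
    n_comment = 0
    if dialect == "featurecounts":
        while n_comment < len(lines) and lines[n_comment].startswith("#"):
            n_comment += 1
    body = lines[n_comment:]
    if not body:
        raise ParseError(f"{path}: no header line found")
    header = body[0].rstrip("\n").split("\t")
    rows = [ln.rstrip("\n").split("\t") for ln in body[1:] if ln.strip()]
    for i, row in enumerate(rows):
        if len(row) != len(header):
            raise ParseError(
                f"{path}: line {n_comment + i + 2}: expected "
                f"{len(header)} fields, found {len(row)}"
            )
    df = pd.DataFrame(rows, columns=header)
    gene_col = header[0]
    df = df.set_index(gene_col)
    df.index.name = "gene_id"
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()]
        first = dup[0]
        where = [i for i, r in enumerate(rows) if r[0] == first]
        raise ParseError(
            f"{path}: line {n_comment + where[1] + 2}: duplicate gene id {first!r}"
        )
    if dialect == "featurecounts":
        drop = [c for c in FEATURECOUNTS_ANNOTATION if c in df.columns]
        df = df.drop(columns=drop)
    counts = _validate_int_frame(df, path, line_offset=n_comment + 1)
    return CountMatrix(counts)


def read_ortholog_map(path) -> OrthologMap:
    """Read a two-column TSV of 1:1 ortholog gene-id pairs.

    An optional single header line is detected heuristically: the first
    non-comment line is treated as a header when neither of its two fields
    contains a digit and neither reappears in its column. Duplicated ids in
    either column violate the 1:1 invariant and raise :class:`ParseError`.
    """
    path = Path(path)
    with open(path) as fh:
        rows = [
            ln.rstrip("\n").split("\t")
            for ln in fh
            if ln.strip() and not ln.startswith("#")
        ]
    if not rows:
        logger.warning("%s: empty ortholog map", path)
        return OrthologMap(pd.DataFrame(columns=["gene_a", "gene_b"]))
    for i, row in enumerate(rows):
        if len(row) != 2:
            raise ParseError(
                f"{path}: line {i + 1}: expected 2 tab-separated fields, "
                f"found {len(row)}"
            )
    first = rows[0]
    col_a = {r[0] for r in rows[1:]}
    col_b = {r[1] for r in rows[1:]}
    looks_like_header = (
        not any(ch.isdigit() for ch in first[0] + first[1])
        and first[0] not in col_a
        and first[1] not in col_b
    )
    if looks_like_header and len(rows) > 1:
        rows = rows[1:]
    df = pd.DataFrame(rows, columns=["gene_a", "gene_b"])
    return OrthologMap(df)


def build_joint_counts(
    parent_a: CountMatrix,
    parent_b: CountMatrix,
    bc_counts: Mapping[str, tuple[CountMatrix, CountMatrix]],
    ortholog_map: OrthologMap,
) -> JointCounts:
    """Assemble the ortholog-paired joint count matrix.

    ``bc_counts`` maps each backcross label to the pair (A-allele matrix,
    B-allele matrix), where the A-allele matrix uses parent A's gene-id
    space and the B-allele matrix parent B's. Each matrix must carry exactly
    one sample column (the study design pools replicates into one library
    per genotype). Rows are the ortholog pairs present in every matrix;
    pairs whose counts are zero across all columns are removed at assembly,
    before any normalisation.
    """
    matrices_a = {"parent_A": parent_a}
    matrices_b = {"parent_B": parent_b}
    for bc, (ma, mb) in bc_counts.items():
        matrices_a[f"{bc}_A"] = ma
        matrices_b[f"{bc}_B"] = mb
    for name, m in {**matrices_a, **matrices_b}.items():
        if len(m.sample_labels) != 1:
            raise ValueError(
                f"{name}: expected exactly one sample column, "
                f"got {m.sample_labels}"
            )

    pairs = ortholog_map.pairs
    keep = pd.Series(True, index=pairs.index)
    for name, m in matrices_a.items():
        keep &= pairs["gene_a"].isin(m.gene_ids)
    for name, m in matrices_b.items():
        keep &= pairs["gene_b"].isin(m.gene_ids)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info(
            "build_joint_counts: %d ortholog pairs absent from at least one "
            "matrix were excluded",
            n_dropped,
        )
    pairs = pairs[keep]
    if pairs.empty:
        raise ValueError(
            "no ortholog pair is present in every input matrix "
            "(empty intersection — check gene-id naming)"
        )

    data = pairs.reset_index(drop=True).copy()
    backcrosses = tuple(bc_counts)
    for name, m in matrices_a.items():
        data[name] = m.counts.iloc[:, 0].reindex(data["gene_a"]).to_numpy()
    for name, m in matrices_b.items():
        data[name] = m.counts.iloc[:, 0].reindex(data["gene_b"]).to_numpy()
    data.index = pd.Index(
        data["gene_a"] + "|" + data["gene_b"], name="pair_id"
    )

    count_cols = [c for c in data.columns if c not in ("gene_a", "gene_b")]
    nonzero = data[count_cols].sum(axis=1) > 0
    n_zero = int((~nonzero).sum())
    if n_zero:
        logger.info(
            "build_joint_counts: removed %d all-zero ortholog pairs", n_zero
        )
    data = data[nonzero]
    if data.empty:
        raise ValueError("all ortholog pairs had zero total counts")
    return JointCounts(data=data, backcrosses=backcrosses, normalized=False)


def write_results(table: pd.DataFrame, path) -> None:
    """Write a result table as TSV: stable column order, floats at 6
    significant digits, one row per gene; round-trips through
    :func:`read_results`."""
    table.to_csv(path, sep="\t", float_format="%.6g", index=True)


def read_results(path, index_col: int = 0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)
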