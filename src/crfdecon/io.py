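"""Shared data model and tab-separated I/O.

Every stage of the pipeline consumes and produces plain TSV tables
(tab-delimited, UTF-8, Unix newlines).  Missing values are serialized as the
literal ``NA`` — a zero is always data ("no change"), never missingness;
this distinction matters because the carbon response factor must separate
"not measured in a reference contrast" from "measured, did not respond".

Gene identifiers are matched by exact string equality after upper-casing
(AGI-style locus tags are case-insensitive in the wild).
"""

from __future__ import annotations

import dataclasses
import io as _io
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "Thresholds",
    "CountMatrix",
    "BINMap",
    "ContrastResult",
    "read_count_matrix",
    "read_gene_lengths",
    "read_response_panel",
    "read_contrast_result",
    "read_binmap",
    "read_table",
    "write_table",
]

GENOTYPES = ("iTPS", "alcR")
TREATMENTS = ("ethanol", "water")

NA_REP = "NA"
#: significant digits used when serializing floats; round-tripping a table
#: reproduces every value to this precision.
FLOAT_FMT = "%.9g"


class FormatError(ValueError):
    """A malformed input table (never silently coerced)."""


def _norm_gene_ids(ids: Iterable[str]) -> pd.Index:
    return pd.Index([str(g).strip().upper() for g in ids], name="gene_id")


@dataclasses.dataclass(frozen=True)
class Thresholds:
    """DEG-calling thresholds.

    fdr            -- FDR (BH q-value) cutoff, default 0.05
    log2_fc_strict -- |log2 FC| for the strict filter (2-fold), default 1.0
    log2_fc_relaxed-- |log2 FC| for the relaxed filter, default 0.2
    """

    fdr: float = 0.05
    log2_fc_strict: float = 1.0
    log2_fc_relaxed: float = 0.2


@dataclasses.dataclass
class CountMatrix:
    """Replicated gene x sample read counts with a sample sheet.

    counts        -- non-negative integer DataFrame, genes x samples
    samples       -- per-sample records indexed by sample_id with columns
                     genotype, treatment, timepoint, replicate
    library_sizes -- total mapped reads per sample (>= column sums; the
                     matrix rows are a subset of all mapped reads)
    """

    counts: pd.DataFrame
    samples: pd.DataFrame
    library_sizes: pd.Series

    def __post_init__(self) -> None:
        self.counts.index = _norm_gene_ids(self.counts.index)
        if self.counts.index.duplicated().any():
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise FormatError(f"duplicate gene_id {dup!r} in count matrix")
        missing = [s for s in self.counts.columns if s not in self.samples.index]
        if missing:
            raise FormatError(
                f"sample(s) {missing} present in count matrix but absent from sample sheet"
            )
        self.samples = self.samples.loc[list(self.counts.columns)]
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            frac = vals - np.floor(vals)
            if np.any(frac != 0) or np.any(~np.isfinite(vals)):
                r, c = np.argwhere((frac != 0) | ~np.isfinite(vals))[0]
                raise FormatError(
                    f"non-integer count at gene {self.counts.index[r]!r}, "
                    f"sample {self.counts.columns[c]!r}"
                )
            self.counts = self.counts.astype(np.int64)
            vals = self.counts.to_numpy()
        if (vals < 0).any():
            r, c = np.argwhere(vals < 0)[0]
            raise FormatError(
                f"negative count at gene {self.counts.index[r]!r}, "
                f"sample {self.counts.columns[c]!r}"
            )
        self.library_sizes = self.library_sizes.loc[list(self.counts.columns)].astype(np.int64)
        if (self.library_sizes <= 0).any():
            bad = self.library_sizes.index[self.library_sizes <= 0][0]
            raise FormatError(f"non-positive library size for sample {bad!r}")
        colsum = self.counts.sum(axis=0)
        if (self.library_sizes < colsum).any():
            bad = self.library_sizes.index[self.library_sizes < colsum][0]
            raise FormatError(
                f"library size for sample {bad!r} is smaller than its column sum"
            )

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    def select(self, **cell: str) -> list[str]:
        """Sample ids matching a (genotype, treatment, timepoint, ...) cell."""
        mask = pd.Series(True, index=self.samples.index)
        for key, value in cell.items():
            if key not in self.samples.columns:
                raise KeyError(f"unknown sample-sheet column {key!r}")
            mask &= self.samples[key].astype(str) == str(value)
        return list(self.samples.index[mask])


@dataclasses.dataclass
class ContrastResult:
    """Per-gene differential-expression result for one contrast.

    ``table`` columns: mean_expr_treated, mean_expr_control (RPKM), log2_fc,
    stat, p_value, q_value, testable, passes_strict, passes_relaxed.
    Untestable genes (all counts zero in both cells) carry stat 0, p 1 and no
    flags, and are excluded from the BH family.
    """

    table: pd.DataFrame
    thresholds: Thresholds = dataclasses.field(default_factory=Thresholds)

    COLUMNS = (
        "mean_expr_treated",
        "mean_expr_control",
        "log2_fc",
        "stat",
        "p_value",
        "q_value",
        "testable",
        "passes_strict",
        "passes_relaxed",
    )

    def __post_init__(self) -> None:
        self.table.index = _norm_gene_ids(self.table.index)
        missing = [c for c in self.COLUMNS if c not in self.table.columns]
        if missing:
            raise FormatError(f"contrast table missing column(s) {missing}")

    @property
    def log2_fc(self) -> pd.Series:
        return self.table["log2_fc"]

    def passing(self, which: str) -> pd.Index:
        """Gene ids passing the ``strict`` or ``relaxed`` filter."""
        if which not in ("strict", "relaxed"):
            raise ValueError(f"unknown filter {which!r}")
        return self.table.index[self.table[f"passes_{which}"].astype(bool)]


@dataclasses.dataclass
class BINMap:
    """Gene -> hierarchical functional category mapping (MapMan dialect).

    A gene may map to several categories; category codes are dot-separated
    integers forming a prefix tree ("1.3" is implicitly the parent of
    "1.3.4").  ``assignments`` has one row per (bincode, gene_id) pair.
    """

    assignments: pd.DataFrame  # columns: bincode, gene_id
    names: dict[str, str] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.assignments.empty:
            raise FormatError("empty BIN mapping")
        self.assignments = self.assignments.copy()
        self.assignments["gene_id"] = [
            str(g).strip().upper() for g in self.assignments["gene_id"]
        ]
        self.assignments["bincode"] = self.assignments["bincode"].astype(str)
        for code in self.assignments["bincode"]:
            parts = code.split(".")
            if not all(p.isdigit() for p in parts):
                raise FormatError(f"malformed BIN code {code!r}")

    def all_codes(self) -> list[str]:
        """Every category code, including implicit ancestors, in code order."""
        codes: set[str] = set()
        for code in self.assignments["bincode"].unique():
            parts = code.split(".")
            for i in range(1, len(parts) + 1):
                codes.add(".".join(parts[:i]))
        return sorted(codes, key=lambda c: tuple(int(p) for p in c.split(".")))

    def members(self, code: str, cumulative: bool = True) -> pd.Index:
        """Genes assigned to ``code`` (and, if cumulative, its descendants)."""
        bc = self.assignments["bincode"]
        if cumulative:
            mask = (bc == code) | bc.str.startswith(code + ".")
        else:
            mask = bc == code
        return pd.Index(sorted(set(self.assignments.loc[mask, "gene_id"])), name="gene_id")

    def genes(self) -> pd.Index:
        return pd.Index(sorted(set(self.assignments["gene_id"])), name="gene_id")


# ---------------------------------------------------------------------------
# readers


def _read_tsv(path, **kw) -> pd.DataFrame:
    return pd.read_csv(
        path,
        sep="\t",
        comment="#",
        na_values=[NA_REP],
        keep_default_na=False,
        **kw,
    )


def read_count_matrix(path, sample_sheet_path) -> CountMatrix:
    """Read a gene x sample count TSV plus its sample sheet.

    The count matrix has a header row of sample ids with gene ids in the
    first column.  The sheet requires columns genotype, treatment, timepoint
    and replicate; if a library_size column is absent, library sizes default
    to the column sums of the matrix.
    """
    counts = _read_tsv(path, index_col=0)
    sheet = _read_tsv(sample_sheet_path)
    required = {"sample_id", "genotype", "treatment", "timepoint", "replicate"}
    missing = required - set(sheet.columns)
    if missing:
        raise FormatError(f"sample sheet missing column(s) {sorted(missing)}")
    sheet = sheet.set_index("sample_id")
    if sheet.index.duplicated().any():
        dup = sheet.index[sheet.index.duplicated()][0]
        raise FormatError(f"duplicate sample_id {dup!r} in sample sheet")
    if "library_size" in sheet.columns and sheet["library_size"].notna().all():
        libs = sheet["library_size"].astype(np.int64)
    else:
        libs = counts.sum(axis=0).astype(np.int64)
        libs.name = "library_size"
    return CountMatrix(counts=counts, samples=sheet, library_sizes=libs)


def read_gene_lengths(path) -> pd.Series:
    """Read gene_id -> transcript length (bp) from a two-column TSV."""
    tab = _read_tsv(path)
    if tab.shape[1] < 2:
        raise FormatError("gene length table needs columns gene_id, length")
    lengths = pd.Series(
        tab.iloc[:, 1].to_numpy(), index=_norm_gene_ids(tab.iloc[:, 0]), name="length"
    )
    if lengths.index.duplicated().any():
        dup = lengths.index[lengths.index.duplicated()][0]
        raise FormatError(f"duplicate gene_id {dup!r} in gene lengths")
    if (lengths <= 0).any() or lengths.isna().any():
        bad = lengths.index[(lengths <= 0) | lengths.isna()][0]
        raise FormatError(f"non-positive length for gene {bad!r}")
    return lengths.astype(np.int64)


def read_response_panel(path) -> pd.DataFrame:
    """Read the reference response panel: gene x contrast log2 FC, NaN = missing."""
    panel = _read_tsv(path, index_col=0)
    panel.index = _norm_gene_ids(panel.index)
    if panel.index.duplicated().any():
        dup = panel.index[panel.index.duplicated()][0]
        raise FormatError(f"duplicate gene_id {dup!r} in response panel")
    if panel.shape[1] < 1:
        raise FormatError("response panel needs at least one contrast column")
    return panel.astype(float)


def read_contrast_result(path, thresholds: Thresholds | None = None) -> ContrastResult:
    tab = _read_tsv(path, index_col=0)
    for col in ("testable", "passes_strict", "passes_relaxed"):
        if col in tab.columns:
            tab[col] = tab[col].astype(bool)
    return ContrastResult(table=tab, thresholds=thresholds or Thresholds())


def read_external_vector(path) -> pd.Series:
    """Read an external (gene, log2FC) response vector."""
    tab = _read_tsv(path)
    if tab.shape[1] < 2:
        raise FormatError("external vector needs columns gene_id, log2_fc")
    vec = pd.Series(
        tab.iloc[:, 1].astype(float).to_numpy(),
        index=_norm_gene_ids(tab.iloc[:, 0]),
        name="log2_fc",
    )
    if vec.index.duplicated().any():
        dup = vec.index[vec.index.duplicated()][0]
        raise FormatError(f"duplicate gene_id {dup!r} in external vector")
    return vec


def read_binmap(path) -> BINMap:
    """Read a MapMan-dialect mapping: BINCODE (quoted dot-code), NAME,
    IDENTIFIER, DESCRIPTION; one row per (gene, category) pair."""
    tab = _read_tsv(path, dtype=str)
    cols = {c.strip().upper(): c for c in tab.columns}
    for req in ("BINCODE", "IDENTIFIER"):
        if req not in cols:
            raise FormatError(f"BIN mapping missing column {req}")
    codes = tab[cols["BINCODE"]].astype(str).str.strip().str.strip("'\"")
    genes = tab[cols["IDENTIFIER"]].astype(str).str.strip()
    keep = genes.notna() & (genes != "") & (genes.str.upper() != NA_REP)
    assignments = pd.DataFrame({"bincode": codes[keep], "gene_id": genes[keep]})
    names: dict[str, str] = {}
    if "NAME" in cols:
        for code, name in zip(codes, tab[cols["NAME"]].astype(str)):
            names.setdefault(code, name)
    return BINMap(assignments=assignments.reset_index(drop=True), names=names)


def read_table(path, index_col: int | None = 0) -> pd.DataFrame:
    """Generic reader for any table produced by :func:`write_table`."""
    return _read_tsv(path, index_col=index_col)


# ---------------------------------------------------------------------------
# writer


def write_table(records, path, header_comments: Sequence[str] = ()) -> None:
    """Write a result table as TSV with a fixed column order.

    Floats are serialized with 9 significant digits so a write/read
    round-trip reproduces values to well beyond 6 significant digits; NaN is
    serialized as ``NA``.  An empty table produces a header-only file.
    ``header_comments`` lines are prefixed with ``#`` and skipped by all
    readers in this module.
    """
    if isinstance(records, (ContrastResult,)):
        frame = records.table
    elif isinstance(records, BINMap):
        frame = records.assignments
    elif isinstance(records, pd.Series):
        frame = records.to_frame()
    else:
        frame = records
    if not isinstance(frame, pd.DataFrame):
        raise TypeError(f"cannot serialize object of type {type(records).__name__}")
    path = Path(path)
    buf = _io.StringIO()
    for line in header_comments:
        buf.write(f"# {line}\n")
    frame.to_csv(buf, sep="\t", na_rep=NA_REP, float_format=FLOAT_FMT, lineterminator="\n")
    try:
        path.write_text(buf.getvalue(), encoding="utf-8", newline="\n")
    except OSError as exc:
        raise OSError(f"cannot write table to {path}: {exc}") from exc
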