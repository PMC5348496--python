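"""File formats: paired count matrices with a mouse-by-site design,
taxonomy tables (two-column and NCBI-dump dialects), BLAST-tabular hit
tables, PSM tables, and the two-block differential-result table.

All tabular I/O goes through pandas; readers validate hard and report the
offending row/column. Writers and readers are mutual inverses on valid
data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .taxonomy import TaxonomyTree

CECUM = "CC"
FECES = "F"

BLAST6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


class FormatError(ValueError):
    pass


# ----------------------------------------------------------------------
# design
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class SampleDesign:
    """Maps each sample id to its (mouse, site) cell of the paired design."""

    mouse: Mapping[str, str]
    site: Mapping[str, str]

    def __post_init__(self):
        if set(self.mouse) != set(self.site):
            raise FormatError("design mouse/site maps cover different samples")
        for s, site in self.site.items():
            if site not in (CECUM, FECES):
                raise FormatError(f"sample {s!r}: site must be CC or F, got {site!r}")
        seen: dict[tuple[str, str], str] = {}
        for s in self.mouse:
            key = (self.mouse[s], self.site[s])
            if key in seen:
                raise FormatError(
                    f"mouse {key[0]!r} has two {key[1]} samples: {seen[key]!r}, {s!r}"
                )
            seen[key] = s
        for m in set(self.mouse.values()):
            if (m, CECUM) not in seen or (m, FECES) not in seen:
                raise FormatError(f"mouse {m!r} is unpaired (needs one CC and one F)")

    @property
    def samples(self) -> list[str]:
        return list(self.mouse)

    @property
    def mice(self) -> list[str]:
        return sorted(set(self.mouse.values()))

    def sample_of(self, mouse: str, site: str) -> str:
        for s in self.mouse:
            if self.mouse[s] == mouse and self.site[s] == site:
                return s
        raise KeyError((mouse, site))


def read_design(path: str | Path) -> SampleDesign:
    """Read a design TSV with columns sample, mouse, site."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample", "mouse", "site"}
    if not required.issubset(df.columns):
        raise FormatError(f"design file needs columns {sorted(required)}")
    return SampleDesign(
        mouse=dict(zip(df["sample"], df["mouse"])),
        site=dict(zip(df["sample"], df["site"])),
    )


def write_design(design: SampleDesign, path: str | Path) -> None:
    pd.DataFrame(
        {
            "sample": design.samples,
            "mouse": [design.mouse[s] for s in design.samples],
            "site": [design.site[s] for s in design.samples],
        }
    ).to_csv(path, sep="\t", index=False)


# ----------------------------------------------------------------------
# paired count matrix
# ----------------------------------------------------------------------

class PairedCountMatrix:
    """Integer counts for features across paired (mouse x site) samples.

    Wraps a features-by-samples DataFrame plus the design; caches per-sample
    totals. Non-integer abundances (e.g. scaled NSAF) must be rounded
    half-to-even before construction — use :meth:`from_abundances`.
    """

    def __init__(self, counts: pd.DataFrame, design: SampleDesign) -> None:
        missing = set(counts.columns) - set(design.samples)
        if missing:
            raise FormatError(f"samples absent from design: {sorted(missing)}")
        undesigned = set(design.samples) - set(counts.columns)
        if undesigned:
            raise FormatError(f"design samples absent from matrix: {sorted(undesigned)}")
        arr = counts.to_numpy()
        if np.any(arr < 0):
            r, c = np.argwhere(arr < 0)[0]
            raise FormatError(
                f"negative count at feature {counts.index[r]!r}, sample {counts.columns[c]!r}"
            )
        frac = np.modf(np.asarray(arr, dtype=float))[0]
        if np.any(frac != 0):
            r, c = np.argwhere(frac != 0)[0]
            raise FormatError(
                f"non-integer count at feature {counts.index[r]!r}, "
                f"sample {counts.columns[c]!r}"
            )
        self.counts = counts.astype(np.int64).rename_axis("feature")
        self.design = design
        self.totals: pd.Series = self.counts.sum(axis=0)

    @classmethod
    def from_abundances(cls, abundances: pd.DataFrame, design: SampleDesign):
        """Round half-to-even to integers, then construct."""
        rounded = abundances.astype(float).round(0)
        return cls(rounded, design)

    @property
    def features(self) -> list[str]:
        return list(self.counts.index)

    @property
    def n_pairs(self) -> int:
        return len(self.design.mice)

    def paired_arrays(self):
        """(cecum, feces, cecum_totals, feces_totals) with features on rows
        and mice on columns, in ``design.mice`` order."""
        mice = self.design.mice
        cc_cols = [self.design.sample_of(m, CECUM) for m in mice]
        f_cols = [self.design.sample_of(m, FECES) for m in mice]
        cec = self.counts[cc_cols].to_numpy()
        fec = self.counts[f_cols].to_numpy()
        C = self.totals[cc_cols].to_numpy(dtype=float)
        F = self.totals[f_cols].to_numpy(dtype=float)
        return cec, fec, C, F

    def subset(self, features) -> "PairedCountMatrix":
        return PairedCountMatrix(self.counts.loc[list(features)], self.design)


def read_count_matrix(path: str | Path, design: SampleDesign) -> PairedCountMatrix:
    """Read a features-by-samples TSV (first column = feature id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[~df[col].astype(str).str.fullmatch(r"-?\d+")].index
            raise FormatError(
                f"non-numeric count in sample {col!r}, feature(s) {list(bad[:3])!r}"
            )
    return PairedCountMatrix(df, design)


def write_count_matrix(matrix: PairedCountMatrix, path: str | Path) -> None:
    matrix.counts.rename_axis("feature").to_csv(path, sep="\t")


# ----------------------------------------------------------------------
# taxonomy
# ----------------------------------------------------------------------

def read_taxonomy(path: str | Path, names_path: str | Path | None = None) -> TaxonomyTree:
    """Read a taxonomy in either supported dialect.

    A single path is treated as a child->parent TSV with columns
    (child, parent[, rank[, name]]). Two paths are treated as NCBI-style
    ``nodes.dmp`` / ``names.dmp`` dumps (fields separated by ``\\t|\\t``).
    """
    if names_path is not None:
        return _read_ncbi_dumps(path, names_path)
    df = pd.read_csv(path, sep="\t", dtype=str, header=0)
    cols = list(df.columns)
    if len(cols) < 2:
        raise FormatError("taxonomy table needs at least child and parent columns")
    parent = dict(zip(df[cols[0]], df[cols[1]]))
    rank = dict(zip(df[cols[0]], df[cols[2]])) if len(cols) > 2 else None
    name = dict(zip(df[cols[0]], df[cols[3]])) if len(cols) > 3 else None
    return TaxonomyTree(parent, rank, name)


def _read_ncbi_dumps(nodes_path, names_path) -> TaxonomyTree:
    parent: dict[str, str] = {}
    rank: dict[str, str] = {}
    for line in Path(nodes_path).read_text().splitlines():
        if not line.strip():
            continue
        fields = [f.strip() for f in line.rstrip("|").split("\t|\t")]
        if len(fields) < 3:
            raise FormatError(f"malformed nodes.dmp line: {line!r}")
        parent[fields[0]] = fields[1]
        rank[fields[0]] = fields[2]
    name: dict[str, str] = {}
    for line in Path(names_path).read_text().splitlines():
        if not line.strip():
            continue
        fields = [f.strip() for f in line.rstrip("\t|").split("\t|\t")]
        if len(fields) >= 4 and fields[3] == "scientific name":
            name[fields[0]] = fields[1]
        elif fields[0] not in name and len(fields) >= 2:
            name.setdefault(fields[0], fields[1])
    return TaxonomyTree(parent, rank, name)


def write_taxonomy_child_parent(tree: TaxonomyTree, path: str | Path) -> None:
    rows = tree.to_child_parent()
    pd.DataFrame(rows, columns=["child", "parent", "rank", "name"]).to_csv(
        path, sep="\t", index=False
    )


def write_taxonomy_ncbi_dumps(tree: TaxonomyTree, nodes_path, names_path) -> None:
    with open(nodes_path, "w") as fh:
        for child, par, rank, _ in tree.to_child_parent():
            fh.write(f"{child}\t|\t{par}\t|\t{rank}\t|\n")
    with open(names_path, "w") as fh:
        for child, _, _, name in tree.to_child_parent():
            fh.write(f"{child}\t|\t{name}\t|\t\t|\tscientific name\t|\n")


# ----------------------------------------------------------------------
# BLAST-tabular hit tables
# ----------------------------------------------------------------------

def read_hit_table(path: str | Path) -> pd.DataFrame:
    """Read a 12-column BLAST outfmt-6-style TSV.

    The subject field encodes the taxon id as ``taxid|<id>``; a ``taxid``
    column is added. Returns one row per hit.
    """
    df = pd.read_csv(path, sep="\t", header=None, names=BLAST6_COLUMNS, dtype={1: str})
    if df.shape[1] != 12:
        raise FormatError("hit table must have 12 tab-separated columns")
    taxid = df["sseqid"].str.extract(r"taxid\|([^|]+)", expand=False)
    if taxid.isna().any():
        bad = df.loc[taxid.isna(), "sseqid"].iloc[0]
        raise FormatError(f"subject id without taxid tag: {bad!r}")
    df["taxid"] = taxid
    return df


def write_hit_table(hits: pd.DataFrame, path: str | Path) -> None:
    hits[BLAST6_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


# ----------------------------------------------------------------------
# PSM tables
# ----------------------------------------------------------------------

def read_psm_table(path: str | Path) -> pd.DataFrame:
    """Read a PSM TSV (accession, length_aa, one count column per sample)."""
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "accession" or df.columns[1] != "length_aa":
        raise FormatError("PSM table must start with accession, length_aa columns")
    if (df["length_aa"] < 1).any():
        bad = df.loc[df["length_aa"] < 1, "accession"].iloc[0]
        raise FormatError(f"protein {bad!r} has non-positive length")
    samples = list(df.columns[2:])
    if not samples:
        raise FormatError("PSM table has no sample columns")
    if (df[samples] < 0).to_numpy().any():
        raise FormatError("negative spectral count")
    return df


def write_psm_table(psm: pd.DataFrame, path: str | Path) -> None:
    psm.to_csv(path, sep="\t", index=False)


# ----------------------------------------------------------------------
# differential-result table
# ----------------------------------------------------------------------

DIFF_COLUMNS = [
    "feature", "phylum", "raw_p", "adjusted_p",
    "mean_fc", "sem_fc", "filtered", "declared",
]


def sort_diff_rows(rows: pd.DataFrame) -> pd.DataFrame:
    """Two-block layout: higher-in-cecum (positive FC) rows first, each
    block by ascending adjusted p-value."""
    key = rows.assign(_neg=(rows["mean_fc"] < 0).astype(int))
    return (
        key.sort_values(["_neg", "adjusted_p", "feature"], kind="stable")
        .drop(columns="_neg")
        .reset_index(drop=True)
    )


def write_diff_table(rows: pd.DataFrame, path: str | Path) -> None:
    out = rows.reindex(columns=[c for c in DIFF_COLUMNS if c in rows.columns])
    sort_diff_rows(out).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_diff_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def round_half_even(x) -> np.ndarray:
    """Round to nearest integer, ties to even (numpy's default rounding)."""
    return np.asarray(np.round(np.asarray(x, dtype=float)), dtype=np.int64)


def _isclose(a: float, b: float, tol: float = 1e-12) -> bool:
    return math.isclose(a, b, rel_tol=tol, abs_tol=tol)
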