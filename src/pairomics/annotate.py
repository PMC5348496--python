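"""LCA taxonomic assignment and construction of feature-level paired count
matrices (taxon, function-by-phylum, pathway-by-phylum), including the
within-phylum renormalization used to separate a function's own shift from
the shift of its whole phylum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import FormatError, PairedCountMatrix, SampleDesign, round_half_even
from .taxonomy import TaxonomyTree

__all__ = [
    "LcaParams",
    "lca_assign",
    "annotate_hits",
    "build_feature_matrix",
    "normalize_within_phylum",
]

LEVELS = ("taxon", "function-phylum", "pathway-phylum")


@dataclass(frozen=True)
class LcaParams:
    """Hit-filtering parameters of the LCA classifier.

    ``min_score`` drops weak hits outright; ``top_percent`` keeps only hits
    scoring within that percentage of the best surviving hit; assignments
    supported by fewer than ``min_support`` reads are discarded at the
    summarization step (1 disables the rule).
    """

    min_score: float = 50.0
    top_percent: float = 10.0
    min_support: int = 1

    def __post_init__(self):
        if self.min_score < 0:
            raise ValueError("min_score must be non-negative")
        if not (0 < self.top_percent <= 100):
            raise ValueError("top_percent must lie in (0, 100]")
        if self.min_support < 1:
            raise ValueError("min_support must be a positive integer")


def lca_assign(
    hits,
    tree: TaxonomyTree,
    params: LcaParams = LcaParams(),
    on_unknown_taxon: str = "skip",
) -> str | None:
    """Assign one read from its (taxon id, bitscore) hit list.

    Hits below ``min_score`` are dropped; of the survivors only those with
    score >= (1 - top_percent/100) * best score are kept; the read is
    assigned the lowest common ancestor of the kept taxa, or None
    (unassigned) if nothing survives. Hit taxa absent from the tree are
    skipped with a warning by default (``on_unknown_taxon="error"`` raises).
    """
    if on_unknown_taxon not in ("skip", "error"):
        raise ValueError("on_unknown_taxon must be 'skip' or 'error'")
    known = []
    for taxid, score in hits:
        if taxid not in tree:
            if on_unknown_taxon == "error":
                raise KeyError(f"hit taxon {taxid!r} not in taxonomy")
            warnings.warn(f"hit taxon {taxid!r} not in taxonomy; skipped", stacklevel=2)
            continue
        known.append((taxid, float(score)))
    survivors = [(t, s) for t, s in known if s >= params.min_score]
    if not survivors:
        return None
    best = max(s for _, s in survivors)
    cutoff = (1.0 - params.top_percent / 100.0) * best
    kept = [t for t, s in survivors if s >= cutoff]
    return tree.lca(kept)


def annotate_hits(
    hits: pd.DataFrame,
    tree: TaxonomyTree,
    params: LcaParams = LcaParams(),
    sample_of_read=None,
    function_of_read=None,
    pathway_of_function=None,
    weight_of_read=None,
) -> pd.DataFrame:
    """Per-read annotation table from a BLAST-tabular hit frame.

    Groups hits by ``qseqid``, runs the LCA classifier on each group and
    derives the rank-phylum ancestor. The optional mappings attach sample,
    function (KO-style), pathway and weight to each read; weight defaults
    to 1 (one count per read).
    """
    records = []
    for read, grp in hits.groupby("qseqid", sort=True):
        taxon = lca_assign(
            list(zip(grp["taxid"], grp["bitscore"])), tree, params
        )
        phylum = tree.phylum_of(taxon) if taxon is not None else None
        func = function_of_read(read) if function_of_read else None
        records.append(
            {
                "seq_id": read,
                "sample": sample_of_read(read) if sample_of_read else "S1",
                "taxon_id": taxon,
                "phylum": phylum,
                "function_id": func,
                "pathway_id": pathway_of_function(func)
                if (pathway_of_function and func is not None)
                else None,
                "weight": weight_of_read(read) if weight_of_read else 1.0,
            }
        )
    df = pd.DataFrame.from_records(records)
    if params.min_support > 1 and len(df):
        support = df.groupby("taxon_id")["seq_id"].transform("size")
        df.loc[support < params.min_support, ["taxon_id", "phylum"]] = None
    return df


def _feature_key(annotations: pd.DataFrame, level: str) -> pd.Series:
    if level == "taxon":
        return annotations["taxon_id"]
    if level == "function-phylum":
        ok = annotations["function_id"].notna() & annotations["phylum"].notna()
        key = annotations["function_id"].astype("string") + "|" + annotations[
            "phylum"
        ].astype("string")
        return key.where(ok)
    if level == "pathway-phylum":
        if "pathway_id" not in annotations or annotations["pathway_id"].isna().all():
            raise FormatError("level requires pathway annotations but none present")
        ok = annotations["pathway_id"].notna() & annotations["phylum"].notna()
        key = annotations["pathway_id"].astype("string") + "|" + annotations[
            "phylum"
        ].astype("string")
        return key.where(ok)
    raise ValueError(f"unknown level {level!r}; expected one of {LEVELS}")


def build_feature_matrix(
    annotations: pd.DataFrame, level: str, design: SampleDesign
) -> PairedCountMatrix:
    """Aggregate per-sequence weights into a paired feature-by-sample
    count matrix at the requested level.

    Sequences lacking either component of a combination key (e.g. a read
    with a function but no phylum) are excluded from that matrix. Weights
    are summed per (feature, sample) and rounded half-to-even, so both raw
    read counts and scaled-NSAF abundances are accepted.
    """
    ann = annotations.copy()
    ann["_key"] = _feature_key(ann, level)
    ann = ann[ann["_key"].notna()]
    pivot = (
        ann.pivot_table(
            index="_key", columns="sample", values="weight", aggfunc="sum", fill_value=0.0
        )
        .reindex(columns=design.samples, fill_value=0.0)
        .rename_axis(index="feature", columns=None)
    )
    return PairedCountMatrix.from_abundances(pivot, design)


def normalize_within_phylum(
    matrix: PairedCountMatrix, phylum_totals: pd.Series
) -> PairedCountMatrix:
    """Rescale each sample's counts by its phylum total.

    Each count is divided by the total abundance of the phylum in its
    sample and multiplied by the across-sample mean phylum total, then
    rounded half-to-even, restoring integer counts on a common phylum
    scale. This removes the phylum's own cecum/feces shift so that only
    within-phylum redistribution of functions remains testable.
    """
    totals = phylum_totals.reindex(matrix.counts.columns)
    zero = totals[totals.isna() | (totals <= 0)]
    if len(zero):
        raise FormatError(
            f"zero/missing phylum total in sample(s) {list(zero.index)!r}"
        )
    mean_total = float(totals.mean())
    scaled = matrix.counts / totals.to_numpy() * mean_total
    rounded = pd.DataFrame(
        np.stack([round_half_even(scaled[c]) for c in scaled.columns], axis=1),
        index=scaled.index,
        columns=scaled.columns,
    )
    return PairedCountMatrix(rounded, matrix.design)
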