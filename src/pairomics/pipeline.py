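"""End-to-end orchestration: per-feature paired beta-binomial tests, SGoF
adjustment across the matrix, signed fold-changes, the missing-value
filter, and the within-phylum re-analysis, producing two-block result
tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotate import normalize_within_phylum
from .io import PairedCountMatrix, sort_diff_rows
from .stats import ibb_test, missing_value_filter, paired_fold_change, sgof_adjust

log = logging.getLogger(__name__)

__all__ = ["DiffParams", "run_differential", "run_phylum_normalized"]


@dataclass(frozen=True)
class DiffParams:
    """Knobs of the differential pipeline: raw-p threshold ``alpha`` and
    metatest level ``gamma`` of SGoF, and the fold-change correction
    factor ``cf``."""

    alpha: float = 0.05
    gamma: float = 0.05
    cf: float = 2.0


def run_differential(
    matrix: PairedCountMatrix,
    params: DiffParams = DiffParams(),
    feature_phylum: pd.Series | None = None,
    level: str = "",
) -> pd.DataFrame:
    """Full differential analysis of one paired count matrix.

    Per feature: paired beta-binomial likelihood-ratio test; then SGoF
    across all features of the matrix; then signed fold-change with the
    correction factor and the missing-value filter. A row is ``declared``
    when SGoF selects it and the filter does not remove it. Rows come back
    in the two-block order (higher-in-cecum first, ascending adjusted p).
    """
    cec, fec, C, F = matrix.paired_arrays()
    feats = matrix.features
    raw_p = np.empty(len(feats))
    r_hat = np.empty(len(feats))
    fcs, sems, filtered = [], [], []
    for i, feat in enumerate(feats):
        res = ibb_test(cec[i], fec[i], C, F)
        raw_p[i] = res.p_value
        r_hat[i] = res.r_hat
        fc = paired_fold_change(cec[i], fec[i], C, F, cf=params.cf)
        fcs.append(fc.mean_fc_signed)
        sems.append(fc.sem)
        filtered.append(missing_value_filter(cec[i], fec[i], fc))
    sgof = sgof_adjust(raw_p, alpha=params.alpha, gamma=params.gamma)
    rows = pd.DataFrame(
        {
            "feature": feats,
            "phylum": (
                feature_phylum.reindex(feats).to_numpy()
                if feature_phylum is not None
                else [f.split("|")[-1] if "|" in f else "" for f in feats]
            ),
            "raw_p": raw_p,
            "adjusted_p": sgof.adjusted_p,
            "r_hat": r_hat,
            "mean_fc": fcs,
            "sem_fc": sems,
            "n_pairs": matrix.n_pairs,
            "filtered": filtered,
            "declared": sgof.declared & ~np.asarray(filtered),
            "level": level,
        }
    )
    log.info(
        "differential: %d features, R=%d, K=%d, declared=%d",
        len(feats), sgof.R, sgof.K, int(rows["declared"].sum()),
    )
    return sort_diff_rows(rows)


def run_phylum_normalized(
    matrix: PairedCountMatrix,
    phylum: str,
    feature_phylum: pd.Series,
    params: DiffParams = DiffParams(),
) -> pd.DataFrame:
    """Within-phylum re-analysis of one phylum's features.

    Subsets the matrix to the phylum, renormalizes every sample by its
    phylum total (restoring integer counts on the mean-total scale) and
    reruns the differential analysis, so that functions merely tracking the
    phylum's overall cecum/feces shift are no longer declared.
    """
    members = [f for f in matrix.features if feature_phylum.get(f) == phylum]
    if not members:
        raise ValueError(f"no features belong to phylum {phylum!r}")
    sub = matrix.subset(members)
    totals = sub.counts.sum(axis=0)
    norm = normalize_within_phylum(sub, totals)
    out = run_differential(
        norm, params, feature_phylum=feature_phylum, level=f"normalized:{phylum}"
    )
    return out
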