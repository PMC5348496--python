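"""NSAF protein quantification from spectral counts.

The spectral abundance factor (SAF) of a protein is its spectral count
divided by its length in amino acids; NSAF divides each SAF by the sample's
SAF sum, so NSAF values sum to one per sample. Scaled NSAF multiplies by a
single dataset-wide factor — the mean number of spectra identified per
sample — so that values are integer-sized and comparable across samples.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["compute_saf", "compute_nsaf", "scale_nsaf", "nsaf_table"]


def compute_saf(spectral_count, length_aa):
    """SAF = spectral_count / length_aa (elementwise)."""
    counts = np.asarray(spectral_count, dtype=float)
    lengths = np.asarray(length_aa, dtype=float)
    if np.any(lengths < 1):
        raise ValueError("protein length must be >= 1 amino acid")
    if np.any(counts < 0):
        raise ValueError("spectral counts must be non-negative")
    return counts / lengths


def compute_nsaf(saf):
    """Normalize SAF values of one sample to sum to one."""
    saf = np.asarray(saf, dtype=float)
    total = saf.sum()
    if total <= 0:
        raise ValueError("all SAF values are zero; nothing identified in sample")
    return saf / total


def scale_nsaf(nsaf, scale_factor: float):
    """Multiply NSAF values by the dataset-wide scale factor."""
    if scale_factor <= 0:
        raise ValueError("scale factor must be positive")
    return np.asarray(nsaf, dtype=float) * scale_factor


def nsaf_table(psm: pd.DataFrame) -> pd.DataFrame:
    """Long-format quantification of a PSM table.

    ``psm`` has columns (accession, length_aa, <sample>...). Returns one row
    per (protein, sample) with spectral_count, saf, nsaf and scaled_nsaf.
    The scale factor is the arithmetic mean over samples of the per-sample
    spectral-count totals, applied uniformly to every sample. Proteins with
    zero spectra in a sample keep nsaf = 0 and stay in the output.
    """
    samples = [c for c in psm.columns if c not in ("accession", "length_aa")]
    if not samples:
        raise ValueError("PSM table has no sample columns")
    scale = float(psm[samples].to_numpy().sum(axis=0).mean())
    frames = []
    for s in samples:
        saf = compute_saf(psm[s], psm["length_aa"])
        nsaf = compute_nsaf(saf)
        frames.append(
            pd.DataFrame(
                {
                    "accession": psm["accession"],
                    "sample": s,
                    "spectral_count": psm[s].astype(np.int64),
                    "length_aa": psm["length_aa"].astype(np.int64),
                    "saf": saf,
                    "nsaf": nsaf,
                    "scaled_nsaf": scale_nsaf(nsaf, scale),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
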