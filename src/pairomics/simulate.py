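"""Synthetic paired cecum/feces data with known ground truth.

Generates every input the pipeline consumes: paired count matrices with
planted fold-changes and beta-binomial-style overdispersion, a toy
taxonomy with per-read hit tables for the LCA classifier, and PSM tables
for NSAF quantification.

Generative model for counts
---------------------------
Each feature g has a baseline relative abundance ``b_g`` (lognormal,
moderately skewed). A fraction of features is planted differential with
fold ratio ``r_g`` (cecum relative to feces) cycled from ``fold_set``;
planted baselines are rescaled by ``2 / (1 + r_g)`` so every planted
feature carries the same cross-site mean mass — with a reciprocal-closed
fold set the planted mass gained in cecum equals the mass lost, keeping
the compositional background of the null features undistorted.

Dependence structure: each (feature, mouse) carries a shared gamma latent
(mean 1, variance ``dispersion``) that scales both sites of the mouse and
induces the paired dependence; each (feature, sample) additionally carries
a site-level gamma latent with the same variance. The shared latent
cancels when conditioning on the pair total, so it is the site-level
latent that gives the conditional cecum-given-total law its beta-binomial
overdispersion — without it ``dispersion`` would be inert for any
conditional paired test. Feces expected proportions are proportional to
``b_g * lam_shared * lam_site``, cecum additionally to ``r_g``, and counts
are drawn multinomially per sample at its lognormal depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from .io import CECUM, FECES, SampleDesign, PairedCountMatrix
from .taxonomy import STANDARD_RANKS, TaxonomyTree

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_paired_counts",
    "simulate_taxonomy_and_hits",
    "simulate_psm_table",
    "write_simulation",
]

_PHYLA = ("Firmicutes", "Bacteroidetes", "Proteobacteria", "Actinobacteria")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of a simulated paired experiment.

    Defaults mirror the emulated study: three mice sampled at two sites,
    sequencing depths around 10^6 with the reported order-of-magnitude
    spread, and mild overdispersion.
    """

    n_pairs: int = 3
    n_features: int = 2000
    frac_differential: float = 0.1
    fold_set: tuple[float, ...] = (8.0, 0.125)
    dispersion: float = 0.05
    depth_mean: float = 1e6
    depth_cv: float = 0.6
    baseline_sigma: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_pairs < 1 or self.n_features < 1:
            raise ValueError("n_pairs and n_features must be positive")
        if not (0.0 <= self.frac_differential <= 1.0):
            raise ValueError("frac_differential must lie in [0, 1]")
        if any(r <= 0 for r in self.fold_set):
            raise ValueError("all folds must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be positive")


@dataclass
class SimTruth:
    """Ground truth of one simulated experiment."""

    fold: pd.Series  # per-feature true fold ratio r_g (1 for null features)
    phylum: pd.Series
    function: pd.Series
    depths: pd.Series  # realized per-sample totals requested from the multinomial
    differential: pd.Series = field(init=False)

    def __post_init__(self):
        self.differential = self.fold != 1.0


def _design(n_pairs: int) -> SampleDesign:
    mouse, site = {}, {}
    for i in range(1, n_pairs + 1):
        for s in (CECUM, FECES):
            name = f"M{i}_{s}"
            mouse[name] = f"M{i}"
            site[name] = s
    return SampleDesign(mouse=mouse, site=site)


def _lognormal_with_mean(rng, mean: float, cv: float, size) -> np.ndarray:
    if cv <= 0:
        return np.full(size, mean)
    sigma2 = np.log1p(cv**2)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mean=mu, sigma=np.sqrt(sigma2), size=size)


def simulate_paired_counts(config: SimConfig) -> tuple[PairedCountMatrix, SimTruth]:
    """Draw one paired count matrix and its ground truth. Deterministic
    given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    G, n = config.n_features, config.n_pairs
    features = [f"feat{g:05d}" for g in range(G)]

    base = rng.lognormal(mean=0.0, sigma=config.baseline_sigma, size=G)
    fold = np.ones(G)
    n_diff = int(round(config.frac_differential * G))
    if n_diff > 0:
        planted = rng.choice(G, size=n_diff, replace=False)
        folds = np.array(
            [config.fold_set[j % len(config.fold_set)] for j in range(n_diff)]
        )
        fold[planted] = folds
        # equalize cross-site mean mass of planted features (see module doc)
        base[planted] *= 2.0 / (1.0 + folds)
        # then balance exactly in this realization: scale the up-planted
        # baselines so the planted mass gained in cecum equals the mass lost
        up = planted[folds > 1]
        down = planted[folds < 1]
        gain = float(np.sum(base[up] * (fold[up] - 1.0)))
        loss = float(-np.sum(base[down] * (fold[down] - 1.0)))
        if gain > 0 and loss > 0:
            base[up] *= loss / gain

    if config.dispersion > 0:
        # shared per-(feature, mouse) latent: marginal pair dependence
        lam = rng.gamma(
            shape=1.0 / config.dispersion, scale=config.dispersion, size=(G, n)
        )
        # site-level latents (same shape-1/phi convention as the shared
        # one): these survive conditioning on the pair total, so the
        # conditional cecum share of a pair is Beta(1/phi, 1/phi) at equal
        # depths — genuine beta-binomial overdispersion of order phi/2.
        k_site = 1.0 / config.dispersion
        lam_cc = rng.gamma(shape=k_site, scale=1.0 / k_site, size=(G, n))
        lam_f = rng.gamma(shape=k_site, scale=1.0 / k_site, size=(G, n))
    else:
        lam = lam_cc = lam_f = np.ones((G, n))

    design = _design(n)
    depths = {
        s: max(1, int(round(d)))
        for s, d in zip(
            design.samples,
            _lognormal_with_mean(rng, config.depth_mean, config.depth_cv, 2 * n),
        )
    }

    counts = {}
    for i in range(n):
        shared = base * lam[:, i]
        for s, w in (
            (design.sample_of(f"M{i+1}", CECUM), shared * lam_cc[:, i] * fold),
            (design.sample_of(f"M{i+1}", FECES), shared * lam_f[:, i]),
        ):
            if w.sum() <= 0:
                raise ValueError("degenerate all-zero abundance vector")
            counts[s] = rng.multinomial(depths[s], w / w.sum())

    matrix = PairedCountMatrix(
        pd.DataFrame(counts, index=features).reindex(columns=design.samples), design
    )
    truth = SimTruth(
        fold=pd.Series(fold, index=features, name="fold"),
        phylum=pd.Series(
            rng.choice(_PHYLA, size=G), index=features, name="phylum"
        ),
        function=pd.Series(
            [f"K{g % max(G // 4, 1):05d}" for g in range(G)],
            index=features,
            name="function",
        ),
        depths=pd.Series(depths, name="depth"),
    )
    return matrix, truth


# ----------------------------------------------------------------------
# taxonomy + hit tables
# ----------------------------------------------------------------------

def _path_intersection_lca(tree: TaxonomyTree, taxa) -> str:
    # ancestor-set intersection, deepest common node; the generator's own
    # truth computation, independent of TaxonomyTree.lca
    common = None
    for t in taxa:
        anc = set(tree.path_to_root(t))
        common = anc if common is None else (common & anc)
    assert common
    return max(common, key=tree.depth)


def simulate_taxonomy_and_hits(
    n_taxa: int,
    n_reads: int,
    seed: int = 0,
    min_score: float = 50.0,
    top_percent: float = 10.0,
):
    """Toy taxonomy plus per-read hit lists with known correct LCA.

    The tree has ranks domain -> ... -> species; each non-root node attaches
    to a random shallower node. Reads receive 1-5 hits with bitscores that
    exercise both the ``min_score`` and ``top_percent`` filters; the
    recorded truth is the path-intersection LCA of the hits that survive
    those filters (None when nothing survives).

    Returns ``(tree, hits_df, truth)`` where ``truth`` maps read id to the
    expected assignment.
    """
    if n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    rng = np.random.default_rng(seed)
    parent = {"t1": "t1"}
    rank = {"t1": STANDARD_RANKS[0]}
    attachable = ["t1"]
    for i in range(2, n_taxa + 1):
        node = f"t{i}"
        par = attachable[rng.integers(len(attachable))]
        parent[node] = par
        r_idx = STANDARD_RANKS.index(rank[par]) + 1
        rank[node] = STANDARD_RANKS[r_idx]
        if r_idx < len(STANDARD_RANKS) - 1:
            attachable.append(node)
    tree = TaxonomyTree(parent, rank, {t: f"{rank[t]} {t}" for t in parent})

    taxa = np.array(sorted(tree.nodes(), key=lambda t: -tree.depth(t)))
    deep = taxa[: max(1, len(taxa) // 2)]  # prefer deeper nodes as hit targets

    rows, truth = [], {}
    for j in range(n_reads):
        read = f"read{j:05d}"
        k = int(rng.integers(1, 6))
        anchor = deep[rng.integers(len(deep))]
        hit_taxa = [anchor]
        for _ in range(k - 1):
            if rng.random() < 0.6:  # a relative: some ancestor's other line
                hit_taxa.append(taxa[rng.integers(len(taxa))])
            else:
                hit_taxa.append(anchor)
        best = float(rng.uniform(60, 120))
        scores = [best] + [
            float(best * rng.uniform(0.6, 1.0)) if rng.random() < 0.8
            else float(rng.uniform(20, 49))  # below min_score
            for _ in range(k - 1)
        ]
        # truth must be computed from the scores as written to disk
        scores = [round(s, 1) for s in scores]
        surviving = [t for t, s in zip(hit_taxa, scores) if s >= min_score]
        best_surv = max(
            (s for s in scores if s >= min_score), default=None
        )
        if best_surv is not None:
            cutoff = (1 - top_percent / 100.0) * best_surv
            kept = [
                t
                for t, s in zip(hit_taxa, scores)
                if s >= min_score and s >= cutoff
            ]
            truth[read] = _path_intersection_lca(tree, kept)
        else:
            truth[read] = None
        for t, s in zip(hit_taxa, scores):
            aln = int(rng.integers(50, 200))
            rows.append(
                {
                    "qseqid": read,
                    "taxid": t,
                    "sseqid": f"taxid|{t}",
                    "pident": round(float(rng.uniform(60, 100)), 2),
                    "length": aln,
                    "mismatch": int(rng.integers(0, 20)),
                    "gapopen": int(rng.integers(0, 4)),
                    "qstart": 1,
                    "qend": aln,
                    "sstart": 1,
                    "send": aln,
                    "evalue": float(10.0 ** -rng.uniform(5, 50)),
                    "bitscore": round(s, 1),
                }
            )
    return tree, pd.DataFrame(rows), truth


# ----------------------------------------------------------------------
# PSM tables
# ----------------------------------------------------------------------

def simulate_psm_table(
    n_proteins: int, n_samples: int, seed: int = 0, mean_count: float = 20.0
) -> pd.DataFrame:
    """Toy PSM table: lengths uniform on [100, 1000] aa, Poisson-lognormal
    spectral counts, at least one nonzero count per sample."""
    if n_proteins < 1 or n_samples < 1:
        raise ValueError("need at least one protein and one sample")
    rng = np.random.default_rng(seed)
    lengths = rng.integers(100, 1001, size=n_proteins)
    abundance = rng.lognormal(mean=0.0, sigma=1.0, size=n_proteins)
    abundance /= abundance.mean()
    counts = rng.poisson(
        lam=np.outer(abundance, rng.uniform(0.5, 1.5, size=n_samples)) * mean_count
    )
    for j in range(n_samples):
        if counts[:, j].sum() == 0:
            counts[int(np.argmax(abundance)), j] = 1
    df = pd.DataFrame({"accession": [f"P{i:05d}" for i in range(n_proteins)],
                       "length_aa": lengths})
    for j in range(n_samples):
        df[f"S{j+1}"] = counts[:, j]
    return df


# ----------------------------------------------------------------------
# file output
# ----------------------------------------------------------------------

def write_simulation(config: SimConfig, outdir: str | Path) -> None:
    """Write one full simulated dataset (counts, truth, design, taxonomy in
    both dialects, hit table, PSM table) under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    matrix, truth = simulate_paired_counts(config)
    pio.write_count_matrix(matrix, outdir / "counts.tsv")
    pio.write_design(matrix.design, outdir / "design.tsv")
    pd.DataFrame(
        {
            "feature": truth.fold.index,
            "fold": truth.fold.values,
            "phylum": truth.phylum.values,
            "function": truth.function.values,
        }
    ).to_csv(outdir / "truth.tsv", sep="\t", index=False)

    tree, hits, lca_truth = simulate_taxonomy_and_hits(
        n_taxa=50, n_reads=500, seed=config.seed + 1
    )
    pio.write_taxonomy_child_parent(tree, outdir / "taxonomy.tsv")
    pio.write_taxonomy_ncbi_dumps(
        tree, outdir / "nodes.dmp", outdir / "names.dmp"
    )
    pio.write_hit_table(hits, outdir / "hits.tsv")
    pd.Series(lca_truth, name="lca").rename_axis("read").to_csv(
        outdir / "lca_truth.tsv", sep="\t"
    )
    pio.write_psm_table(
        simulate_psm_table(200, 2 * config.n_pairs, seed=config.seed + 2),
        outdir / "psm.tsv",
    )
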