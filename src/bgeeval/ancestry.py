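"""Local-ancestry-stratified imputation accuracy.

Each compared genotype (one sample at one site) is assigned to the
unordered pair of ancestry labels of the sample's two haplotypes at that
position — its *diploid background* (e.g. ``AFR|AFR`` homozygous or
``AFR|EUR`` heterozygous background) — and the pooled concordance
metrics are then computed within each background and MAF bin.
Stratification is per-genotype, not per-SNP: one SNP contributes
genotypes to several backgrounds, which is what rescues rare SNPs whose
few minor-allele copies happen to sit on one background.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .concordance import MafBinScheme, _binned_pearson, count_pairs, \
    nonref_concordance
from .io_formats import MISSING, AncestryTractSet


def canonical_background(label_a: str, label_b: str) -> str:
    """Order-free diploid background label, e.g. ``AFR|EUR``."""
    return "|".join(sorted((label_a, label_b)))


def background_at(tracts: AncestryTractSet, sample: str, position: int):
    """Diploid background of one sample at one position, or None when a
    haplotype is uncovered there (half-open tract convention)."""
    i = tracts.samples.index(sample)
    codes = tracts.hap_codes(np.array([position]))[i, 0]
    if (codes < 0).any():
        return None
    labels = tracts.labels
    return canonical_background(labels[int(codes[0])], labels[int(codes[1])])


def background_matrix(tracts: AncestryTractSet, positions):
    """Per-genotype background index matrix.

    Returns ``(bg_idx, names)``: an ``(n_samples, n_sites)`` int array of
    indices into ``names`` (-1 where a haplotype is uncovered), with
    ``names`` the sorted canonical background labels.
    """
    codes = tracts.hap_codes(positions)  # (n, m, 2)
    labels = tracts.labels
    lo = np.minimum(codes[..., 0], codes[..., 1])
    hi = np.maximum(codes[..., 0], codes[..., 1])
    n_anc = max(labels) + 1
    pair_id = lo.astype(np.int32) * n_anc + hi
    pair_id[(lo < 0) | (hi < 0)] = -1
    ids = np.unique(pair_id[pair_id >= 0])
    names = [canonical_background(labels[int(i) // n_anc], labels[int(i) % n_anc])
             for i in ids]
    remap = np.full(n_anc * n_anc, -1, dtype=np.int32)
    remap[ids] = np.arange(len(ids))
    bg_idx = np.where(pair_id >= 0, remap[np.clip(pair_id, 0, None)], -1)
    return bg_idx, names


def stratified_metrics(truth: np.ndarray, dosage: np.ndarray,
                       hard_calls: np.ndarray, tracts: AncestryTractSet,
                       positions, maf, bins: MafBinScheme | None = None,
                       backgrounds: str = "all") -> pd.DataFrame:
    """Aggregate R² and aggregate non-ref concordance per (background, bin).

    ``backgrounds="homozygous_only"`` restricts to same-ancestry diploid
    backgrounds (main-figure style); ``"all"`` keeps heterozygous
    backgrounds as first-class strata.  Every non-missing compared
    genotype lands in exactly one stratum, so per-stratum genotype
    counts sum to the unstratified count.
    """
    bins = bins or MafBinScheme()
    bg_idx, names = background_matrix(tracts, positions)
    bin_idx = bins.assign(maf)
    truth = np.asarray(truth)
    dosage = np.asarray(dosage, dtype=float)
    hard_calls = np.asarray(hard_calls)
    rows = []
    for s, name in enumerate(names):
        if backgrounds == "homozygous_only":
            a, b = name.split("|")
            if a != b:
                continue
        in_stratum = bg_idx == s
        pair_bin = np.broadcast_to(bin_idx[None, :], truth.shape).copy()
        pair_bin[~in_stratum | (truth == MISSING) | np.isnan(dosage)] = -1
        r2, n = _binned_pearson(truth.ravel().astype(float), dosage.ravel(),
                                pair_bin.ravel(), bins.n_bins)
        for b in range(bins.n_bins):
            cols = bin_idx == b
            mask = in_stratum[:, cols]
            c = count_pairs(np.where(mask, truth[:, cols], MISSING),
                            np.where(mask, hard_calls[:, cols], MISSING))
            rows.append((name, bins.edges[b], bins.edges[b + 1], r2[b],
                         nonref_concordance(c), int(n[b])))
    return pd.DataFrame(rows, columns=["background", "bin_lo", "bin_hi",
                                       "aggregate_r2", "aggregate_nrc",
                                       "n_genotypes"])


def reference_panel_prefilter(fractions, min_fraction: float = 0.9) -> np.ndarray:
    """Indices of reference samples whose target-ancestry global fraction
    is at least ``min_fraction`` (admixed reference samples degrade local
    ancestry inference and are excluded)."""
    fr = np.asarray(fractions, dtype=float)
    return np.flatnonzero(fr >= min_fraction)
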