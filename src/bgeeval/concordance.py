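"""Imputation-accuracy metrics against array truth.

Two families of statistics are computed per minor-allele-frequency bin:

* **Non-reference concordance** — ``TP / (TP + FP + FN)`` over genotype
  comparisons, crediting only agreement on non-reference genotypes.  In
  *aggregate* mode the TP/FP/FN counts of every genotype of every SNP in
  a bin are pooled before taking the ratio; this avoids the deflation
  that per-SNP averaging suffers for rare SNPs, where the few copies of
  the minor allele may by chance all sit in one subset and leave zeros
  elsewhere.
* **Aggregate R²** — the squared Pearson correlation between the stacked
  (vectorised) truth genotype calls and imputed dosages of all SNPs in a
  bin.

Genotype pairs are classified as: missing either side → MISSING;
truth non-reference and equal → TP; truth non-reference and unequal
(including the het/hom-alt mismatch) → FN; truth reference and test
non-reference → FP; both reference → TN.  Counting the 1↔2 mismatch as a
single FN (rather than FP+FN) keeps every compared genotype contributing
exactly one count.  The alternative convention is available via
``mismatch_mode="fp_fn"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import MISSING, ParameterError

log = logging.getLogger(__name__)

DEFAULT_BIN_EDGES = (0.0, 0.005, 0.01, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5)


@dataclass
class MafBinScheme:
    """MAF binning: edges ascending from 0 to 0.5; bins are (lo, hi]
    except the first, which is [0, hi].  ``maf_of`` assigns bin indices;
    -1 marks values outside [0, 0.5] (never produced by a valid MAF)."""

    edges: tuple = DEFAULT_BIN_EDGES

    def __post_init__(self):
        e = np.asarray(self.edges, dtype=float)
        if e.size < 2 or np.any(np.diff(e) <= 0):
            raise ParameterError("bin edges must be strictly ascending")
        if e[0] != 0.0 or e[-1] != 0.5:
            raise ParameterError("bin edges must start at 0 and end at 0.5")

    @property
    def n_bins(self) -> int:
        return len(self.edges) - 1

    def assign(self, maf) -> np.ndarray:
        maf = np.asarray(maf, dtype=float)
        idx = np.searchsorted(self.edges, maf, side="left") - 1
        idx[maf <= self.edges[1]] = 0  # first bin closed on both ends
        idx[(maf < 0) | (maf > 0.5) | np.isnan(maf)] = -1
        return idx

    def labels(self) -> pd.DataFrame:
        return pd.DataFrame({"bin_lo": self.edges[:-1], "bin_hi": self.edges[1:]})


@dataclass
class ConcordanceCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0
    missing: int = 0

    def __add__(self, other):
        return ConcordanceCounts(self.tp + other.tp, self.fp + other.fp,
                                 self.fn + other.fn, self.tn + other.tn,
                                 self.missing + other.missing)

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn + self.missing


def hard_call(dosage=None, gp=None, rule: str = "argmax_gp",
              gp_threshold: float | None = None):
    """Reduce dosages/GP triples to hard genotype calls.

    ``argmax_gp`` takes the most probable genotype, returning missing
    where the winning probability is below ``gp_threshold``; ``round_ds``
    rounds the dosage to the nearest integer (ties to even).
    """
    if rule == "argmax_gp":
        if gp is None:
            raise ParameterError("argmax_gp rule requires GP")
        gp = np.asarray(gp, dtype=float)
        calls = np.argmax(gp, axis=-1).astype(np.int8)
        best = np.max(gp, axis=-1)
        miss = np.isnan(best)
        if gp_threshold is not None:
            miss |= best < gp_threshold
        calls = np.where(miss, MISSING, calls).astype(np.int8)
        return calls
    if rule == "round_ds":
        if dosage is None:
            raise ParameterError("round_ds rule requires dosages")
        d = np.asarray(dosage, dtype=float)
        calls = np.rint(d).astype(np.int8)  # numpy rint rounds ties to even
        return np.where(np.isnan(d), MISSING, calls).astype(np.int8)
    raise ParameterError(f"unknown hard-call rule: {rule!r}")


_CLASSES = ("TP", "FP", "FN", "TN", "MISSING")


def classify_pair(truth: int, test: int, mismatch_mode: str = "fn") -> str:
    """Classify one (truth, test) genotype pair.

    ``mismatch_mode="fn"`` (default) counts the het vs hom-alt mismatch
    as FN only; ``"fp_fn"`` counts it as both FP and FN (returned as
    the compound label ``"FP+FN"``).
    """
    if truth == MISSING or test == MISSING:
        return "MISSING"
    if truth > 0:
        if test == truth:
            return "TP"
        if test > 0 and mismatch_mode == "fp_fn":
            return "FP+FN"
        return "FN"
    return "FP" if test > 0 else "TN"


def count_pairs(truth: np.ndarray, test: np.ndarray,
                mismatch_mode: str = "fn") -> ConcordanceCounts:
    """Vectorised ConcordanceCounts over aligned genotype arrays."""
    truth = np.asarray(truth)
    test = np.asarray(test)
    miss = (truth == MISSING) | (test == MISSING)
    tp = (~miss) & (truth > 0) & (test == truth)
    fn = (~miss) & (truth > 0) & (test != truth)
    fp = (~miss) & (truth == 0) & (test > 0)
    tn = (~miss) & (truth == 0) & (test == 0)
    extra_fp = 0
    if mismatch_mode == "fp_fn":
        extra_fp = int(((~miss) & (truth > 0) & (test > 0)
                        & (test != truth)).sum())
    return ConcordanceCounts(tp=int(tp.sum()), fp=int(fp.sum()) + extra_fp,
                             fn=int(fn.sum()), tn=int(tn.sum()),
                             missing=int(miss.sum()))


def nonref_concordance(counts: ConcordanceCounts) -> float:
    """TP / (TP + FP + FN); NaN when no non-reference comparisons exist."""
    denom = counts.tp + counts.fp + counts.fn
    if denom == 0:
        return float("nan")
    return counts.tp / denom


def per_snp_nonref_concordance(truth: np.ndarray, test: np.ndarray,
                               mismatch_mode: str = "fn") -> np.ndarray:
    """Per-SNP non-reference concordance (NaN where truth is all-reference
    or counts are empty), matching the per-SNP exclusion rule."""
    n_sites = truth.shape[1]
    out = np.full(n_sites, np.nan)
    for j in range(n_sites):
        c = count_pairs(truth[:, j], test[:, j], mismatch_mode)
        out[j] = nonref_concordance(c)
    return out


def aggregate_nonref_concordance(truth: np.ndarray, test: np.ndarray,
                                 maf: np.ndarray,
                                 bins: MafBinScheme | None = None,
                                 mismatch_mode: str = "fn") -> pd.DataFrame:
    """Pooled non-reference concordance per MAF bin.

    TP/FP/FN counts of every genotype of every SNP in the bin are summed
    before the ratio; SNPs whose truth column is all-reference still
    contribute their genotypes to the pool.  Empty bins yield NaN.
    """
    bins = bins or MafBinScheme()
    bin_idx = bins.assign(maf)
    rows = []
    for b in range(bins.n_bins):
        cols = np.flatnonzero(bin_idx == b)
        if cols.size == 0:
            rows.append((np.nan, 0, 0))
            continue
        c = count_pairs(truth[:, cols], test[:, cols], mismatch_mode)
        rows.append((nonref_concordance(c), c.total - c.missing, cols.size))
    out = bins.labels()
    out[["aggregate_nrc", "n_genotypes", "n_snps"]] = rows
    return out


def _binned_pearson(x, y, bin_of_pair, n_bins):
    """Per-bin squared Pearson r via sufficient statistics (no copies of
    the stacked vectors)."""
    ok = bin_of_pair >= 0
    b = bin_of_pair[ok]
    x = x[ok]
    y = y[ok]
    n = np.bincount(b, minlength=n_bins).astype(float)
    sx = np.bincount(b, weights=x, minlength=n_bins)
    sy = np.bincount(b, weights=y, minlength=n_bins)
    sxx = np.bincount(b, weights=x * x, minlength=n_bins)
    syy = np.bincount(b, weights=y * y, minlength=n_bins)
    sxy = np.bincount(b, weights=x * y, minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        vx = sxx - sx * sx / n
        vy = syy - sy * sy / n
        cov = sxy - sx * sy / n
        r2 = np.where((vx > 0) & (vy > 0), cov ** 2 / (vx * vy), np.nan)
    r2[n < 2] = np.nan
    return r2, n.astype(int)


def aggregate_r2(truth: np.ndarray, dosage: np.ndarray, maf: np.ndarray,
                 bins: MafBinScheme | None = None,
                 gp: np.ndarray | None = None,
                 gp_threshold: float | None = None) -> pd.DataFrame:
    """Squared Pearson correlation of stacked truth calls vs dosages per bin.

    Pairs with missing truth or dosage are dropped from the stack; with
    ``gp_threshold`` set, genotypes whose maximum GP falls below it are
    dropped too.  Bins with zero variance in either stack come back NaN.
    """
    bins = bins or MafBinScheme()
    truth = np.asarray(truth)
    dosage = np.asarray(dosage, dtype=float)
    bin_idx = bins.assign(maf)
    pair_bin = np.broadcast_to(bin_idx[None, :], truth.shape).copy()
    bad = (truth == MISSING) | np.isnan(dosage)
    if gp_threshold is not None:
        if gp is None:
            raise ParameterError("gp_threshold requires GP")
        bad |= np.max(gp, axis=-1) < gp_threshold
    pair_bin[bad] = -1
    r2, n = _binned_pearson(truth.ravel().astype(float), dosage.ravel(),
                            pair_bin.ravel(), bins.n_bins)
    out = bins.labels()
    out["aggregate_r2"] = r2
    out["n_genotypes"] = n
    snp_counts = np.bincount(bin_idx[bin_idx >= 0], minlength=bins.n_bins)
    out["n_snps"] = snp_counts
    return out


def info_from_gp(gp: np.ndarray) -> np.ndarray:
    """Per-site imputation INFO score from genotype posteriors.

    Ratio-of-variances estimate: with per-genotype posterior mean
    ``e = P(1) + 2 P(2)`` and second moment ``f = P(1) + 4 P(2)``,

        INFO = 1 - sum(f - e^2) / (2 n theta (1 - theta)),

    where ``theta`` is the posterior allele frequency ``sum(e) / 2n``.
    Monomorphic sites (theta of 0 or 1) get NaN.  Genotypes with missing
    posteriors are excluded from the sums.
    """
    gp = np.asarray(gp, dtype=float)
    e = gp[..., 1] + 2.0 * gp[..., 2]
    f = gp[..., 1] + 4.0 * gp[..., 2]
    ok = ~np.isnan(e)
    n = ok.sum(axis=0)
    e = np.where(ok, e, 0.0)
    f = np.where(ok, f, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = e.sum(axis=0) / (2.0 * n)
        denom = 2.0 * n * theta * (1.0 - theta)
        info = 1.0 - (f - e ** 2).sum(axis=0) / denom
    return np.where(denom > 0, info, np.nan)


def info_filter(sites: pd.DataFrame, min_info: float = 0.8,
                bins: MafBinScheme | None = None):
    """Retain sites with INFO >= ``min_info`` (inclusive).

    Returns (index of retained sites, histogram of dropped sites by MAF
    bin).  Sites with missing INFO are dropped and logged.
    """
    bins = bins or MafBinScheme()
    info = sites["info"].to_numpy(dtype=float)
    keep = info >= min_info
    n_missing = int(np.isnan(info).sum())
    if n_missing:
        log.warning("%d sites with missing INFO dropped", n_missing)
    dropped = sites.loc[~keep]
    hist = bins.labels()
    if len(dropped):
        bin_idx = bins.assign(dropped["maf"].to_numpy())
        hist["n_dropped"] = np.bincount(bin_idx[bin_idx >= 0],
                                        minlength=bins.n_bins)
    else:
        hist["n_dropped"] = 0
    return np.flatnonzero(keep), hist


def gp_filter_sweep(truth: np.ndarray, dosage: np.ndarray, gp: np.ndarray,
                    maf: np.ndarray, thresholds,
                    bins: MafBinScheme | None = None) -> pd.DataFrame:
    """Aggregate R² per bin at a sweep of max-GP thresholds.

    Reports, per (threshold, bin): R², genotype count, and the fraction
    of otherwise-comparable genotypes the threshold drops.
    """
    bins = bins or MafBinScheme()
    base = aggregate_r2(truth, dosage, maf, bins)
    frames = []
    for t in thresholds:
        res = aggregate_r2(truth, dosage, maf, bins, gp=gp,
                           gp_threshold=(None if t <= 0 else t))
        res["gp_threshold"] = t
        with np.errstate(invalid="ignore", divide="ignore"):
            res["fraction_dropped"] = np.where(
                base["n_genotypes"] > 0,
                1.0 - res["n_genotypes"] / base["n_genotypes"], np.nan)
        frames.append(res)
    return pd.concat(frames, ignore_index=True)
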