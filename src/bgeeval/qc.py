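"""Exome and array quality-control filters.

Implements the deep-exome genotype and site filters, per-sample coverage
and contamination cutoffs, strata-wise outlier removal on sample QC
metrics, X-chromosome sex inference, PCA-based ancestry assignment, and
the staged SNP-array QC (call rate, |FHET|, differential missingness,
Hardy-Weinberg exact test).

Threshold conventions (all configurable):

* genotype: drop if DP < 10, GQ < 20, het allele balance outside
  [0.2, 0.8], or hom-alt allele balance < 0.8;
* sample: drop if fraction of exome at >=10x < 0.90, WGS coverage < 1x,
  or chimera/contamination rate > 0.05;
* metric outliers: |x - mean| > 4 MAD within each ancestry-by-cohort
  stratum (MAD about the median; the mean centre is deliberate, with a
  ``center="median"`` switch for the fully robust variant);
* sex: X inbreeding coefficient F < 0.6 female, > 0.6 male, exactly 0.6
  (or too few sites) undetermined;
* ancestry: assign the modal label of the k=50 nearest reference samples
  in top-10 PC space when its vote fraction reaches 0.7.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .io_formats import MISSING, ParameterError

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Genotype- and site-level filters
# ---------------------------------------------------------------------------

@dataclass
class GenotypeQCThresholds:
    min_dp: int = 10
    min_gq: int = 20
    het_ab_range: tuple = (0.2, 0.8)
    homalt_ab_min: float = 0.8

    def __post_init__(self):
        lo, hi = self.het_ab_range
        if not (0 <= lo <= hi <= 1) or not 0 <= self.homalt_ab_min <= 1:
            raise ParameterError("allele-balance bounds must lie in [0, 1]")
        if self.min_dp < 0 or self.min_gq < 0:
            raise ParameterError("min_dp and min_gq must be >= 0")


def filter_genotypes(genotypes, dp, gq, ad_ref, ad_alt,
                     thresholds: GenotypeQCThresholds | None = None):
    """Mask genotype calls failing depth/quality/allele-balance rules.

    Returns ``(masked genotypes, report)`` where the report counts
    genotypes removed by each rule (a genotype may count under several)
    and genotypes whose AB rules could not be evaluated for missing AD.
    """
    t = thresholds or GenotypeQCThresholds()
    g = np.array(genotypes, dtype=np.int8, copy=True)
    dp = np.asarray(dp, dtype=float)
    gq = np.asarray(gq, dtype=float)
    ad_ref = np.asarray(ad_ref, dtype=float)
    ad_alt = np.asarray(ad_alt, dtype=float)
    called = g != MISSING

    low_dp = called & (dp < t.min_dp)
    low_gq = called & (gq < t.min_gq)
    total = ad_ref + ad_alt
    ad_ok = ~np.isnan(total) & (total > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ab = np.where(ad_ok, ad_alt / total, np.nan)
    het_bad = called & (g == 1) & ad_ok & \
        ((ab < t.het_ab_range[0]) | (ab > t.het_ab_range[1]))
    hom_bad = called & (g == 2) & ad_ok & (ab < t.homalt_ab_min)
    ad_missing = called & (g >= 1) & ~ad_ok

    report = {
        "low_dp": int(low_dp.sum()),
        "low_gq": int(low_gq.sum()),
        "het_allele_balance": int(het_bad.sum()),
        "homalt_allele_balance": int(hom_bad.sum()),
        "ab_unevaluated_missing_ad": int(ad_missing.sum()),
    }
    g[low_dp | low_gq | het_bad | hom_bad] = MISSING
    report["removed_total"] = int((called & (g == MISSING)).sum())
    return g, report


def filter_sites(sites: pd.DataFrame, n_alleles, vqsr_pass, in_lcr, in_target):
    """Site filter: drop sites with >6 alleles, VQSR failure, inside a
    low-complexity region, or outside the capture target (any condition
    removes the site).  Returns (retained table, boolean keep mask)."""
    n_alleles = np.asarray(n_alleles)
    vqsr_pass = np.asarray(vqsr_pass, dtype=bool)
    in_lcr = np.asarray(in_lcr, dtype=bool)
    in_target = np.asarray(in_target, dtype=bool)
    keep = (n_alleles <= 6) & vqsr_pass & ~in_lcr & in_target
    return sites.loc[keep].reset_index(drop=True), keep


# ---------------------------------------------------------------------------
# Sample-level filters
# ---------------------------------------------------------------------------

SAMPLE_QC_METRICS = ("n_singletons", "n_insertions", "n_deletions",
                     "n_transitions", "n_transversions", "het_ratio",
                     "titv_ratio", "insdel_ratio")


@dataclass
class SampleCoverageThresholds:
    min_exome_fraction_10x: float = 0.90
    min_wgs_coverage: float = 1.0
    max_chimera_rate: float = 0.05
    max_contamination_rate: float = 0.05


def filter_sample_coverage(records: pd.DataFrame,
                           thresholds: SampleCoverageThresholds | None = None
                           ) -> pd.DataFrame:
    """Pass/fail per sample on coverage, chimera and contamination rates.

    ``records`` needs columns exome_fraction_10x, wgs_coverage,
    chimera_rate, contamination_rate.  Returns a frame with ``passed``
    and a semicolon-joined ``reasons`` column (strict inequalities on the
    failing side: 0.90 and 1x pass; 0.05 rates pass).
    """
    t = thresholds or SampleCoverageThresholds()
    checks = [
        ("exome_fraction", records["exome_fraction_10x"] < t.min_exome_fraction_10x),
        ("wgs_coverage", records["wgs_coverage"] < t.min_wgs_coverage),
        ("chimera", records["chimera_rate"] > t.max_chimera_rate),
        ("contamination", records["contamination_rate"] > t.max_contamination_rate),
    ]
    reasons = []
    for i in range(len(records)):
        reasons.append(";".join(name for name, bad in checks if bool(bad.iloc[i])))
    out = records.copy()
    out["reasons"] = reasons
    out["passed"] = [r == "" for r in reasons]
    return out


def mad_outlier_filter(metrics: pd.DataFrame, strata, k: float = 4.0,
                       center: str = "mean", min_stratum: int = 10):
    """Strata-wise metric-outlier filter.

    Within each stratum and for each metric column, samples with
    ``|x - centre| > k * MAD`` are flagged, where MAD is the median
    absolute deviation about the median and the centre defaults to the
    stratum mean.  Strata smaller than ``min_stratum`` are skipped, as
    are metrics with zero MAD (both logged).

    Returns ``(passed boolean Series, per-metric flag DataFrame)``.
    """
    if center not in ("mean", "median"):
        raise ParameterError("center must be 'mean' or 'median'")
    strata = pd.Series(np.asarray(strata), index=metrics.index)
    flags = pd.DataFrame(False, index=metrics.index, columns=metrics.columns)
    for stratum, idx in metrics.groupby(strata).groups.items():
        sub = metrics.loc[idx]
        if len(sub) < min_stratum:
            log.warning("stratum %r has %d < %d samples; skipped",
                        stratum, len(sub), min_stratum)
            continue
        for col in metrics.columns:
            x = sub[col].to_numpy(dtype=float)
            mad = np.median(np.abs(x - np.median(x)))
            if mad == 0:
                log.warning("metric %r has zero MAD in stratum %r; skipped",
                            col, stratum)
                continue
            c = x.mean() if center == "mean" else np.median(x)
            flags.loc[idx, col] = np.abs(x - c) > k * mad
    return ~flags.any(axis=1), flags


def infer_sex(x_genotypes: np.ndarray, site_afs: np.ndarray,
              female_max_f: float = 0.6, min_sites: int = 20):
    """Sex from the X-chromosome inbreeding coefficient.

    ``F = 1 - O_het / E_het`` per sample over called non-PAR X sites,
    with ``E_het = sum 2 p (1-p)``.  F below the threshold is female,
    above is male; exactly at the threshold, or with fewer than
    ``min_sites`` called sites, the sample is undetermined.

    Returns ``(F array, label array)``.
    """
    g = np.asarray(x_genotypes)
    if g.shape[1] == 0:
        raise ParameterError("no X-chromosome sites provided")
    p = np.asarray(site_afs, dtype=float)
    called = g != MISSING
    n_called = called.sum(axis=1)
    o_het = (g == 1).sum(axis=1)
    e_het = (called * (2.0 * p * (1.0 - p))[None, :]).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = 1.0 - o_het / e_het
    labels = np.where(f < female_max_f, "female",
                      np.where(f > female_max_f, "male", "undetermined"))
    labels = np.where((n_called < min_sites) | ~np.isfinite(f),
                      "undetermined", labels)
    return f, labels.astype(object)


# ---------------------------------------------------------------------------
# PCA, LD pruning, ancestry assignment
# ---------------------------------------------------------------------------

def hwe_normalized_pca(genotypes: np.ndarray, n_pcs: int = 10):
    """PCA on HWE-variance-normalised genotypes.

    Each entry is normalised to ``(g - 2p) / sqrt(2 p (1-p))`` with
    ``p`` the in-sample AF from called genotypes; missing entries become
    0 after centering.  Constant sites are dropped (counted).  Component
    signs are fixed so each loading vector's largest-magnitude entry is
    positive, making scores deterministic.

    Returns ``(scores, loadings, eigenvalues, n_dropped_sites)``.
    """
    g = np.asarray(genotypes, dtype=float)
    g = np.where(g == MISSING, np.nan, g)
    p = np.nanmean(g, axis=0) / 2.0
    keep = (p > 0) & (p < 1) & ~np.isnan(p)
    n_dropped = int((~keep).sum())
    g = g[:, keep]
    p = p[keep]
    x = (g - 2 * p) / np.sqrt(2 * p * (1 - p))
    x = np.where(np.isnan(x), 0.0, x)
    rank = min(x.shape)
    if n_pcs > rank:
        log.warning("n_pcs=%d exceeds rank %d; truncating", n_pcs, rank)
        n_pcs = rank
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    u, s, vt = u[:, :n_pcs], s[:n_pcs], vt[:n_pcs]
    sign = np.sign(vt[np.arange(n_pcs), np.argmax(np.abs(vt), axis=1)])
    sign[sign == 0] = 1.0
    u *= sign
    vt *= sign[:, None]
    scores = u * s
    eigvals = s ** 2 / max(x.shape[0] - 1, 1)
    return scores, vt.T, eigvals, n_dropped


def ld_prune(genotypes: np.ndarray, positions: np.ndarray,
             window_bp: int = 500_000, r2_max: float = 0.2) -> np.ndarray:
    """Greedy left-to-right LD pruning.

    Scanning sites in position order, a site is dropped when its genotype
    r² with any retained site within ``window_bp`` upstream exceeds
    ``r2_max``.  Returns the retained site indices.
    """
    g = np.asarray(genotypes, dtype=float)
    g = np.where(g == MISSING, np.nan, g)
    positions = np.asarray(positions)
    col_mean = np.nanmean(g, axis=0)
    gc = np.where(np.isnan(g), 0.0, g - col_mean)
    norms = np.sqrt((gc ** 2).sum(axis=0))
    kept = []
    for j in range(g.shape[1]):
        if norms[j] == 0:
            continue
        drop = False
        for i in reversed(kept):
            if window_bp <= 0 or positions[j] - positions[i] > window_bp:
                break
            r = gc[:, i] @ gc[:, j] / (norms[i] * norms[j])
            if r * r > r2_max:
                drop = True
                break
        if not drop:
            kept.append(j)
    return np.asarray(kept, dtype=int)


def assign_ancestry(sample_pcs: np.ndarray, reference_pcs: np.ndarray,
                    reference_labels, threshold: float = 0.7,
                    k: int = 50, n_pcs: int = 10):
    """k-NN ancestry vote in principal-component space.

    For each sample, the assignment probability is the fraction of the
    ``k`` nearest reference samples (Euclidean, top ``n_pcs`` PCs)
    sharing the modal label; the modal label is assigned when that
    fraction reaches ``threshold``, else the sample is unassigned.

    Returns a DataFrame with columns ``label`` (None when unassigned),
    ``modal_label`` and ``probability``.
    """
    ref = np.asarray(reference_pcs, dtype=float)[:, :n_pcs]
    qry = np.asarray(sample_pcs, dtype=float)[:, :n_pcs]
    labels = np.asarray(reference_labels, dtype=object)
    if len(ref) < k:
        log.warning("only %d reference samples; k reduced from %d", len(ref), k)
        k = len(ref)
    d2 = ((qry[:, None, :] - ref[None, :, :]) ** 2).sum(axis=2)
    nn = np.argpartition(d2, kth=k - 1, axis=1)[:, :k]
    rows = []
    for i in range(len(qry)):
        votes = pd.Series(labels[nn[i]]).value_counts()
        modal = votes.index[0]
        prob = votes.iloc[0] / k
        rows.append((modal if prob >= threshold else None, modal, float(prob)))
    return pd.DataFrame(rows, columns=["label", "modal_label", "probability"])


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test and array QC
# ---------------------------------------------------------------------------

def hwe_exact_test(n_het: int, n_hom_rare: int, n_hom_common: int) -> float:
    """Exact Hardy-Weinberg p-value (two-sided, probability-mass method).

    The p-value sums the probabilities of all heterozygote counts, given
    the observed allele counts, whose conditional probability does not
    exceed that of the observed count (Wigginton-style recurrence; no
    mid-p adjustment).
    """
    if min(n_het, n_hom_rare, n_hom_common) < 0:
        raise ParameterError("genotype counts must be nonnegative")
    n = n_het + n_hom_rare + n_hom_common
    if n == 0:
        return 1.0
    # fold to the minor allele so the support is 0..rare heterozygotes
    rare = min(2 * n_hom_rare + n_het, 2 * n_hom_common + n_het)
    n_het_obs = n_het
    mid = rare * (2 * n - rare) // (2 * n)
    if (mid % 2) != (rare % 2):
        mid += 1
    probs = np.zeros(rare + 1)
    probs[mid] = 1.0
    # downward recurrence: P(h-2)/P(h) = h(h-1) / ((rare-h+2)(2n-rare-h+2))
    h = mid
    while h > 1:
        probs[h - 2] = probs[h] * h * (h - 1) / \
            ((rare - h + 2) * (2 * n - rare - h + 2))
        h -= 2
    h = mid
    while h <= rare - 2:
        probs[h + 2] = probs[h] * (rare - h) * (2 * n - rare - h) / \
            ((h + 2) * (h + 1))
        h += 2
    probs /= probs.sum()
    p_obs = probs[n_het_obs]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def hwe_exact_test_bruteforce(n_het, n_hom_rare, n_hom_common) -> float:
    """Direct enumeration oracle for the exact HWE test (small n only)."""
    n = n_het + n_hom_rare + n_hom_common
    rare = min(2 * n_hom_rare + n_het, 2 * n_hom_common + n_het)
    hets = np.arange(rare % 2, rare + 1, 2)
    logp = (gammaln(n + 1) - gammaln((rare - hets) / 2 + 1) - gammaln(hets + 1)
            - gammaln(n - (rare + hets) / 2 + 1) + hets * np.log(2)
            + gammaln(rare + 1) + gammaln(2 * n - rare + 1) - gammaln(2 * n + 1))
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    p_obs = probs[list(hets).index(n_het)]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


@dataclass
class ArrayQCThresholds:
    min_snp_call_rate_1: float = 0.95
    min_sample_call_rate: float = 0.98
    max_abs_fhet: float = 0.20
    min_snp_call_rate_2: float = 0.98
    max_diff_missingness: float = 0.02
    hwe_p_controls: float = 1e-6
    hwe_p_cases: float = 1e-10


def _fhet(genotypes: np.ndarray) -> np.ndarray:
    """Per-sample autosomal inbreeding coefficient 1 - O_het/E_het."""
    g = np.asarray(genotypes, dtype=float)
    g = np.where(g == MISSING, np.nan, g)
    p = np.nanmean(g, axis=0) / 2.0
    exp_het = 2.0 * p * (1.0 - p)
    called = ~np.isnan(g)
    o = (g == 1).sum(axis=1)
    e = (called * exp_het[None, :]).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return 1.0 - o / e


def array_qc(genotypes: np.ndarray, is_case=None,
             reported_sex=None, inferred_sex=None,
             thresholds: ArrayQCThresholds | None = None):
    """Staged SNP-array QC.

    Order of operations: SNP call rate >= 0.95; then sample filters
    (call rate >= 0.98, |FHET| < 0.20, reported/inferred sex concordance
    when both are given); then SNP call rate >= 0.98; then, when
    case/control labels are present, differential missingness <= 0.02 and
    the Hardy-Weinberg exact test at 1e-6 in controls and 1e-10 in cases.

    Returns ``(sample keep mask, site keep mask, report dict)``.
    """
    t = thresholds or ArrayQCThresholds()
    g = np.asarray(genotypes)
    n_samples, n_sites = g.shape
    site_keep = np.ones(n_sites, dtype=bool)
    sample_keep = np.ones(n_samples, dtype=bool)
    report = {}

    called = g != MISSING
    snp_cr = called.mean(axis=0)
    site_keep &= snp_cr >= t.min_snp_call_rate_1
    report["snp_call_rate_95"] = int((~site_keep).sum())

    sub = g[:, site_keep]
    sample_cr = (sub != MISSING).mean(axis=1) if sub.shape[1] else \
        np.ones(n_samples)
    fhet = _fhet(sub) if sub.shape[1] else np.zeros(n_samples)
    bad_cr = sample_cr < t.min_sample_call_rate
    bad_fhet = np.abs(fhet) >= t.max_abs_fhet
    bad_sex = np.zeros(n_samples, dtype=bool)
    if reported_sex is not None and inferred_sex is not None:
        rep = np.asarray(reported_sex, dtype=object)
        inf = np.asarray(inferred_sex, dtype=object)
        bad_sex = (inf != "undetermined") & (rep != inf)
    sample_keep = ~(bad_cr | bad_fhet | bad_sex)
    report["sample_call_rate"] = int(bad_cr.sum())
    report["sample_fhet"] = int(bad_fhet.sum())
    report["sample_sex_discordant"] = int(bad_sex.sum())

    g2 = g[sample_keep]
    called2 = g2 != MISSING
    with np.errstate(invalid="ignore"):
        snp_cr2 = called2.mean(axis=0) if g2.shape[0] else np.zeros(n_sites)
    drop = site_keep & (snp_cr2 < t.min_snp_call_rate_2)
    report["snp_call_rate_98"] = int(drop.sum())
    site_keep &= ~drop

    if is_case is not None:
        case = np.asarray(is_case, dtype=bool)[sample_keep]
        if case.any() and (~case).any():
            miss_case = 1.0 - called2[case].mean(axis=0)
            miss_ctrl = 1.0 - called2[~case].mean(axis=0)
            drop = site_keep & (np.abs(miss_case - miss_ctrl)
                                > t.max_diff_missingness)
            report["differential_missingness"] = int(drop.sum())
            site_keep &= ~drop
        for label, mask, cut in (("controls", ~case, t.hwe_p_controls),
                                 ("cases", case, t.hwe_p_cases)):
            if not mask.any():
                continue
            gg = g2[mask]
            drop = np.zeros(n_sites, dtype=bool)
            for j in np.flatnonzero(site_keep):
                col = gg[:, j]
                col = col[col != MISSING]
                n_het = int((col == 1).sum())
                n_alt = int((col == 2).sum())
                n_ref = int((col == 0).sum())
                if n_het + n_alt + n_ref == 0:
                    continue
                hom_rare, hom_common = ((n_alt, n_ref)
                                        if n_alt <= n_ref else (n_ref, n_alt))
                if hwe_exact_test(n_het, hom_rare, hom_common) < cut:
                    drop[j] = True
            report[f"hwe_{label}"] = int(drop.sum())
            site_keep &= ~drop
    return sample_keep, site_keep, report
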