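"""Merge per-batch imputation outputs into cohort-level summaries.

Low-pass imputation is run on randomized batches of samples; the merged
cohort callset must then carry allele frequencies and INFO scores that
reflect the full sample size rather than any single batch.  With batch
sample counts :math:`N_i`, batch allele frequencies :math:`AF_i` and
batch INFO scores :math:`I_i`:

.. math::

    AF_c = \\frac{\\sum_i AF_i N_i}{\\sum_i N_i}

.. math::

    I_c = 1 - \\frac{\\sum_i (1 - I_i)\\, 2 N_i AF_i (1 - AF_i)}
                    {2 \\left(\\sum_i N_i\\right) AF_c (1 - AF_c)}

The INFO correction is the ratio of summed per-batch imputation variances
to the pooled binomial variance; when every batch has the same AF it
reduces to the :math:`N_i`-weighted mean of the batch INFO scores.  A
batch monomorphic at a site (:math:`AF_i \\in \\{0, 1\\}`) contributes
zero to the numerator, so its (undefined) INFO score is irrelevant and is
treated as 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import io_formats
from .io_formats import ParameterError

log = logging.getLogger(__name__)


@dataclass
class BatchSiteSummary:
    """One batch's per-site summary: sample count, AF, INFO."""

    batch_id: str
    n: int
    af: float
    info: float | None = None

    def __post_init__(self):
        if self.n < 1:
            raise ParameterError(f"batch {self.batch_id}: n must be >= 1")
        if not 0.0 <= self.af <= 1.0:
            raise ParameterError(f"batch {self.batch_id}: AF outside [0, 1]")
        if self.info is not None and not 0.0 <= self.info <= 1.0:
            raise ParameterError(f"batch {self.batch_id}: INFO outside [0, 1]")


def merge_af(batches) -> float:
    """Sample-size-weighted mean of batch allele frequencies."""
    if not batches:
        raise ParameterError("merge_af requires at least one batch")
    n = np.array([b.n for b in batches], dtype=float)
    af = np.array([b.af for b in batches], dtype=float)
    return float((af * n).sum() / n.sum())


def merge_info(batches) -> float:
    """Cohort INFO score from batch INFO scores and AFs.

    Returns NaN when the cohort is monomorphic (pooled binomial variance
    zero).  A batch with a missing INFO score at a polymorphic batch AF
    is an error; monomorphic batches may omit INFO.
    """
    if not batches:
        raise ParameterError("merge_info requires at least one batch")
    af_c = merge_af(batches)
    n_total = sum(b.n for b in batches)
    denom = 2.0 * n_total * af_c * (1.0 - af_c)
    if denom == 0.0:
        return float("nan")
    num = 0.0
    for b in batches:
        var_b = 2.0 * b.n * b.af * (1.0 - b.af)
        if var_b == 0.0:
            continue
        if b.info is None or (isinstance(b.info, float) and np.isnan(b.info)):
            raise ParameterError(
                f"batch {b.batch_id}: INFO missing at a polymorphic site")
        num += (1.0 - b.info) * var_b
    return float(1.0 - num / denom)


def merge_site_tables(site_tables, batch_sizes, batch_ids=None) -> pd.DataFrame:
    """Vectorised merge of aligned per-batch site tables.

    All tables must share (chrom, pos, ref, alt) row for row.  Returns a
    cohort site table with merged ``af``/``info`` and ``n_total``.
    """
    ids = batch_ids or [f"batch{i}" for i in range(len(site_tables))]
    n = np.asarray(batch_sizes, dtype=float)
    af = np.stack([t["af"].to_numpy(dtype=float) for t in site_tables])
    info = np.stack([t["info"].to_numpy(dtype=float) for t in site_tables])
    af_c = (af * n[:, None]).sum(axis=0) / n.sum()
    var_b = 2.0 * n[:, None] * af * (1.0 - af)
    bad = np.isnan(info) & (var_b > 0)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ParameterError(
            f"batch {ids[i]}: INFO missing at polymorphic site row {j}")
    num = np.where(var_b > 0, (1.0 - np.where(np.isnan(info), 1.0, info)) * var_b,
                   0.0).sum(axis=0)
    denom = 2.0 * n.sum() * af_c * (1.0 - af_c)
    with np.errstate(invalid="ignore", divide="ignore"):
        info_c = np.where(denom > 0, 1.0 - num / denom, np.nan)
    out = site_tables[0][["chrom", "pos", "ref", "alt"]].copy()
    out["af"] = af_c
    out["info"] = info_c
    out["maf"] = np.minimum(af_c, 1.0 - af_c)
    out["n_total"] = int(n.sum())
    return out


def dosage_af(dosages: np.ndarray) -> np.ndarray:
    """Estimated alt AF per site from dosages: mean dosage / 2 over
    non-missing entries."""
    d = np.asarray(dosages, dtype=float)
    return np.nanmean(d, axis=0) / 2.0


def merge_callsets(batch_paths, out_path=None):
    """Merge per-batch imputed VCFs into one cohort callset.

    Batches are intersected on (chrom, pos, ref, alt) when site lists
    differ (logged); genotype columns are concatenated batch by batch;
    the cohort AF and INFO fields are recomputed with the batch-merge
    formulas.  Duplicate sample IDs across batches are an error.

    Returns ``(dosages, gp, cohort site table, samples)`` and, when
    ``out_path`` is given, also writes the merged VCF.
    """
    mats, gps, tables, sample_lists = [], [], [], []
    for path in batch_paths:
        ds, sites, samples = io_formats.read_genotype_vcf(path, "DS")
        gp, _, _ = io_formats.read_genotype_vcf(path, "GP")
        mats.append(ds)
        gps.append(gp)
        tables.append(sites)
        sample_lists.append(samples)
    all_samples = [s for lst in sample_lists for s in lst]
    if len(set(all_samples)) != len(all_samples):
        raise ParameterError("duplicate sample IDs across batches")

    keys = [list(zip(t["chrom"], t["pos"], t["ref"], t["alt"])) for t in tables]
    common = set(keys[0])
    for k in keys[1:]:
        common &= set(k)
    if any(len(k) != len(common) for k in keys):
        log.warning("batch site lists differ; intersecting to %d sites",
                    len(common))
    if not common:
        log.warning("no overlapping sites across batches; empty merge")
    aligned_tables, aligned_mats, aligned_gps = [], [], []
    for t, m, g, k in zip(tables, mats, gps, keys):
        idx = [i for i, key in enumerate(k) if key in common]
        aligned_tables.append(t.iloc[idx].reset_index(drop=True))
        aligned_mats.append(m[:, idx])
        aligned_gps.append(g[:, idx])
    sizes = [len(s) for s in sample_lists]
    if common:
        cohort_sites = merge_site_tables(aligned_tables, sizes)
    else:
        cohort_sites = aligned_tables[0].copy()
        cohort_sites["n_total"] = 0
    dosages = np.concatenate(aligned_mats, axis=0) if common else \
        np.empty((sum(sizes), 0))
    gp = np.concatenate(aligned_gps, axis=0) if common else \
        np.empty((sum(sizes), 0, 3))
    if out_path is not None:
        io_formats.write_imputed_vcf(out_path, dosages, gp, cohort_sites,
                                     all_samples)
    return dosages, gp, cohort_sites, all_samples
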