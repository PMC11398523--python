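"""Exonic CNV benchmarking against a gold-standard callset.

A *site* is a cluster of same-type calls across samples (single-linkage
on reciprocal bp overlap >= 0.5 by default).  A truth site is *recalled*
when at least 50% of its carriers have a same-type test call covering at
least 50% of the truth call's exons; PPV applies the same rule with the
roles of truth and test swapped, so swapping the callsets swaps the two
metrics exactly.  Both recall and PPV are reported as a function of a
minimum exon count, since exon-resolution is the natural unit of a
capture-based CNV caller.

Quality filters mirror the evaluation protocol: calls must have quality
score QS > 200 (strict) and site carrier frequency < 1% within each
ancestry group; samples carrying more than 10 rare high-quality CNVs are
removed outright.

De novo screening over quartet pedigrees marks a child call de novo when
no same-type call in either parent has reciprocal overlap >= 0.5 with it.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .io_formats import ParameterError

log = logging.getLogger(__name__)


def annotate_exons(calls: pd.DataFrame, exons: pd.DataFrame) -> pd.DataFrame:
    """Add ``exon_count``: number of exon intervals a call overlaps >= 1 bp.

    ``exons`` must be sorted and merged (1-based half-open).  Calls ending
    exactly where an exon starts do not count that exon.
    """
    calls = calls.copy()
    counts = np.zeros(len(calls), dtype=int)
    for chrom, grp in exons.groupby("chrom"):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        on = calls["chrom"] == chrom
        if not on.any():
            continue
        c_start = calls.loc[on, "start"].to_numpy()
        c_end = calls.loc[on, "end"].to_numpy()
        # exons with exon.start < call.end and exon.end > call.start
        first = np.searchsorted(ends, c_start, side="right")
        last = np.searchsorted(starts, c_end, side="left")
        counts[np.flatnonzero(on)] = np.maximum(last - first, 0)
    calls["exon_count"] = counts
    return calls


def _exon_ids(call_start, call_end, starts, ends):
    """Indices of exons overlapped >= 1 bp by [call_start, call_end)."""
    first = int(np.searchsorted(ends, call_start, side="right"))
    last = int(np.searchsorted(starts, call_end, side="left"))
    return range(first, max(first, last))


def reciprocal_overlap(a_start, a_end, b_start, b_end) -> float:
    """min(overlap/len(a), overlap/len(b)) for half-open bp intervals."""
    ov = min(a_end, b_end) - max(a_start, b_start)
    if ov <= 0:
        return 0.0
    return ov / max(a_end - a_start, b_end - b_start)


def cluster_sites(calls: pd.DataFrame,
                  min_recip_overlap: float = 0.5) -> pd.DataFrame:
    """Single-linkage clustering of same-type calls into sites.

    Adds ``site_id`` per call; returns the annotated call table.  Use
    :func:`site_summary` for per-site carriers and frequency.
    """
    calls = calls.copy().reset_index(drop=True)
    parent = np.arange(len(calls))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for (_chrom, _type), grp in calls.groupby(["chrom", "type"]):
        idx = grp.sort_values("start").index.to_numpy()
        starts = calls.loc[idx, "start"].to_numpy()
        ends = calls.loc[idx, "end"].to_numpy()
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                if starts[b] >= ends[a]:
                    break
                ro = reciprocal_overlap(starts[a], ends[a], starts[b], ends[b])
                if ro >= min_recip_overlap:
                    ra, rb = find(idx[a]), find(idx[b])
                    if ra != rb:
                        parent[rb] = ra
    roots = np.array([find(i) for i in range(len(calls))])
    _, site_ids = np.unique(roots, return_inverse=True)
    calls["site_id"] = site_ids
    return calls


def site_summary(calls: pd.DataFrame, cohort_size: int) -> pd.DataFrame:
    """Per-site summary: type, union interval, carriers, carrier frequency."""
    rows = []
    for site_id, grp in calls.groupby("site_id"):
        carriers = sorted(set(grp["sample"]))
        rows.append({
            "site_id": site_id,
            "chrom": grp["chrom"].iloc[0],
            "type": grp["type"].iloc[0],
            "start": int(grp["start"].min()),
            "end": int(grp["end"].max()),
            "n_carriers": len(carriers),
            "carriers": carriers,
            "frequency": len(carriers) / cohort_size,
            "exon_count": int(grp["exon_count"].max())
            if "exon_count" in grp else np.nan,
        })
    return pd.DataFrame(rows)


def filter_calls(calls: pd.DataFrame, cohort_size: int,
                 ancestry_labels: dict | None = None,
                 min_qs: float = 200.0, max_frequency: float = 0.01,
                 max_rare_cnvs_per_sample: int = 10,
                 min_recip_overlap: float = 0.5):
    """Apply sample and call quality filters.

    First, samples carrying more than ``max_rare_cnvs_per_sample`` rare
    (carrier frequency < ``max_frequency``) high-quality (QS >
    ``min_qs``, strict) calls are removed.  Then calls are kept when
    QS > ``min_qs`` and their site's carrier frequency within the
    sample's ancestry group (whole cohort when no labels are given) is
    below ``max_frequency``.

    Returns ``(filtered calls, removed sample list)``.
    """
    calls = cluster_sites(calls, min_recip_overlap)
    groups = {}
    if ancestry_labels:
        for s, lab in ancestry_labels.items():
            groups.setdefault(lab, set()).add(s)
    else:
        groups = {"cohort": set(calls["sample"])}

    def site_freq(sub: pd.DataFrame, denom: int) -> pd.Series:
        per_site = sub.groupby("site_id")["sample"].nunique() / max(denom, 1)
        return sub["site_id"].map(per_site)

    freq_cohort = site_freq(calls, cohort_size)
    hq = calls["qs"] > min_qs
    rare = freq_cohort < max_frequency
    per_sample = calls.loc[hq & rare].groupby("sample").size()
    removed = sorted(per_sample[per_sample > max_rare_cnvs_per_sample].index)
    if removed:
        log.info("removed %d samples with >%d rare high-quality CNVs",
                 len(removed), max_rare_cnvs_per_sample)
    calls = calls.loc[~calls["sample"].isin(removed)].copy()

    keep = np.zeros(len(calls), dtype=bool)
    for lab, members in groups.items():
        on = calls["sample"].isin(members)
        if not on.any():
            continue
        denom = sum(1 for s in members) if ancestry_labels else cohort_size
        fr = site_freq(calls.loc[on], denom)
        keep[np.flatnonzero(on)] = (calls.loc[on, "qs"] > min_qs) & \
            (fr < max_frequency)
    return calls.loc[keep].reset_index(drop=True), removed


def _carrier_matched(truth_call, candidate_calls, exons_by_chrom,
                     min_exon_fraction: float) -> bool:
    """Does any same-sample/same-type test call cover >= the required
    fraction of the truth call's exons?"""
    starts, ends = exons_by_chrom.get(truth_call.chrom, (None, None))
    if starts is None:
        return False
    t_exons = set(_exon_ids(truth_call.start, truth_call.end, starts, ends))
    if not t_exons:
        return False
    for cand in candidate_calls.itertuples(index=False):
        c_exons = set(_exon_ids(cand.start, cand.end, starts, ends))
        if len(t_exons & c_exons) / len(t_exons) >= min_exon_fraction:
            return True
    return False


def _score_one_way(ref_calls: pd.DataFrame, other_calls: pd.DataFrame,
                   exons: pd.DataFrame, carrier_fraction: float,
                   min_interval_overlap: float, cohort_size: int):
    """Fraction of ref sites 'hit' by other calls, per site; returns the
    per-site table with a ``recalled`` flag."""
    ref = cluster_sites(annotate_exons(ref_calls, exons))
    other = annotate_exons(other_calls, exons)
    exons_by_chrom = {
        chrom: (grp["start"].to_numpy(), grp["end"].to_numpy())
        for chrom, grp in exons.groupby("chrom")
    }
    by_sample_type = dict(tuple(other.groupby(["sample", "type"])))
    sites = site_summary(ref, cohort_size)
    hits = []
    for site in sites.itertuples(index=False):
        member = ref.loc[ref["site_id"] == site.site_id]
        n_matched = 0
        for call in member.itertuples(index=False):
            cand = by_sample_type.get((call.sample, call.type))
            if cand is not None and _carrier_matched(
                    call, cand, exons_by_chrom, min_interval_overlap):
                n_matched += 1
        hits.append(n_matched / site.n_carriers >= carrier_fraction)
    sites["recalled"] = hits
    return sites


def match_and_score(truth_calls: pd.DataFrame, test_calls: pd.DataFrame,
                    exons: pd.DataFrame, min_exons=(1, 2, 3, 4, 5, 10),
                    carrier_fraction: float = 0.5,
                    min_interval_overlap: float = 0.5,
                    cohort_size: int | None = None) -> pd.DataFrame:
    """Recall and PPV per minimum exon count.

    Recall: fraction of truth sites (exon_count >= min_exons) whose
    carriers are matched at the carrier-fraction rule.  PPV: the same
    computation with truth and test swapped.  Thresholds are inclusive.
    Empty callsets yield NaN metrics.
    """
    cohort_size = cohort_size or max(
        len(set(truth_calls["sample"]) | set(test_calls["sample"])), 1)
    rows = []
    if len(truth_calls) == 0 or len(test_calls) == 0:
        log.warning("empty truth or test callset; metrics undefined")
        return pd.DataFrame(
            [(m, 0, np.nan, 0, np.nan) for m in min_exons],
            columns=["min_exons", "n_truth_sites", "recall",
                     "n_test_sites", "ppv"])
    truth_sites = _score_one_way(truth_calls, test_calls, exons,
                                 carrier_fraction, min_interval_overlap,
                                 cohort_size)
    test_sites = _score_one_way(test_calls, truth_calls, exons,
                                carrier_fraction, min_interval_overlap,
                                cohort_size)
    for m in min_exons:
        t = truth_sites.loc[truth_sites["exon_count"] >= m]
        s = test_sites.loc[test_sites["exon_count"] >= m]
        rows.append((m, len(t),
                     t["recalled"].mean() if len(t) else np.nan,
                     len(s),
                     s["recalled"].mean() if len(s) else np.nan))
    return pd.DataFrame(rows, columns=["min_exons", "n_truth_sites", "recall",
                                       "n_test_sites", "ppv"])


def de_novo_check(calls: pd.DataFrame, pedigree: pd.DataFrame,
                  parent_overlap: float = 0.5) -> pd.DataFrame:
    """De novo CNVs in children of complete trios/quartets.

    A child call is de novo when neither parent has a same-type call with
    reciprocal overlap >= ``parent_overlap``.  Opposite-type parental
    calls at the same locus do not rescue it.  Children lacking either
    parent in the pedigree are skipped (logged).
    """
    parents_of = {}
    members = set(pedigree["sample"])
    for row in pedigree.itertuples(index=False):
        if row.father != "0" and row.mother != "0":
            if row.father in members and row.mother in members:
                parents_of[row.sample] = (row.father, row.mother)
            else:
                log.warning("child %s lacks both parents in pedigree; skipped",
                            row.sample)
    by_sample = dict(tuple(calls.groupby("sample")))
    out = []
    for child, (father, mother) in parents_of.items():
        child_calls = by_sample.get(child)
        if child_calls is None:
            continue
        parent_calls = pd.concat(
            [by_sample.get(p, calls.iloc[0:0]) for p in (father, mother)])
        for call in child_calls.itertuples(index=False):
            same = parent_calls.loc[
                (parent_calls["type"] == call.type)
                & (parent_calls["chrom"] == call.chrom)]
            inherited = any(
                reciprocal_overlap(call.start, call.end, p.start, p.end)
                >= parent_overlap
                for p in same.itertuples(index=False))
            if not inherited:
                out.append({"sample": child, "chrom": call.chrom,
                            "start": call.start, "end": call.end,
                            "type": call.type,
                            "qs": getattr(call, "qs", np.nan)})
    return pd.DataFrame(out, columns=["sample", "chrom", "start", "end",
                                      "type", "qs"])
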