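"""Readers and writers for the external formats the pipeline touches.

All genomic coordinates are held internally as 1-based, half-open
``[start, end)`` intervals; conversions to and from the 0-based half-open
BED convention and the 1-based closed Picard interval_list convention
happen only at the I/O boundary.

Genotypes are encoded as the count of alternate alleles in ``{0, 1, 2}``
with ``-1`` for missing.  Dosages are the expected alternate-allele count
in ``[0, 2]``; genotype probabilities (GP) are triples over the diploid
genotypes summing to one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

MISSING = -1

SITE_COLUMNS = ["chrom", "pos", "ref", "alt", "af", "info", "maf"]
CNV_COLUMNS = ["sample", "chrom", "start", "end", "type", "qs"]
PED_COLUMNS = ["fam_id", "sample", "father", "mother", "sex", "phenotype"]


class FormatError(ValueError):
    """Malformed or unsupported input file content."""


class ParameterError(ValueError):
    """Invalid parameter or configuration value."""


def make_site_table(chrom, pos, ref=None, alt=None, af=None, info=None) -> pd.DataFrame:
    """Assemble a per-site metadata table (chrom/pos/ref/alt/af/info/maf).

    ``maf`` is derived as ``min(af, 1 - af)``.  Missing INFO scores are
    held as NaN.
    """
    pos = np.asarray(pos, dtype=np.int64)
    n = pos.size
    if np.any(pos < 1):
        raise FormatError("positions must be 1-based (>= 1)")
    chrom = np.broadcast_to(np.asarray(chrom, dtype=object), (n,)).copy()
    if ref is None:
        ref = np.full(n, "A", dtype=object)
    if alt is None:
        alt = np.full(n, "C", dtype=object)
    af = np.full(n, np.nan) if af is None else np.asarray(af, dtype=float)
    info = np.full(n, np.nan) if info is None else np.asarray(info, dtype=float)
    maf = np.minimum(af, 1.0 - af)
    return pd.DataFrame(
        {"chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
         "af": af, "info": info, "maf": maf}
    )


# ---------------------------------------------------------------------------
# Ancestry tracts
# ---------------------------------------------------------------------------

@dataclass
class AncestryTractSet:
    """Per-sample, per-haplotype ancestry tracts on one chromosome.

    ``tracts[i]`` is a pair (haplotype 0, haplotype 1); each haplotype is a
    tuple of numpy arrays ``(starts, ends, codes)`` describing sorted,
    non-overlapping half-open intervals labelled with integer ancestry
    codes.  ``code_map`` maps ancestry label to code.
    """

    chrom: str
    samples: list
    code_map: dict
    tracts: list = field(repr=False)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def labels(self) -> dict:
        """Inverse of ``code_map``: integer code -> ancestry label."""
        return {v: k for k, v in self.code_map.items()}

    def hap_codes(self, positions) -> np.ndarray:
        """Ancestry code of each haplotype at each position.

        Returns an ``(n_samples, n_positions, 2)`` int16 array; positions
        outside every tract get -1.
        """
        positions = np.asarray(positions, dtype=np.int64)
        out = np.full((self.n_samples, positions.size, 2), -1, dtype=np.int16)
        for i, (hap0, hap1) in enumerate(self.tracts):
            for h, (starts, ends, codes) in enumerate((hap0, hap1)):
                idx = np.searchsorted(starts, positions, side="right") - 1
                ok = (idx >= 0) & (positions < ends[np.clip(idx, 0, len(ends) - 1)])
                out[i, ok, h] = codes[idx[ok]]
        return out

    def equals(self, other: "AncestryTractSet") -> bool:
        if (self.chrom != other.chrom or self.samples != other.samples
                or self.code_map != other.code_map):
            return False
        for (a0, a1), (b0, b1) in zip(self.tracts, other.tracts):
            for a, b in ((a0, b0), (a1, b1)):
                if not all(np.array_equal(x, y) for x, y in zip(a, b)):
                    return False
        return True


def _merge_consecutive(starts, ends, codes):
    """Merge runs of adjacent intervals sharing the same code."""
    starts, ends, codes = (np.asarray(a) for a in (starts, ends, codes))
    if starts.size == 0:
        return starts, ends, codes
    keep = np.ones(starts.size, dtype=bool)
    keep[1:] = (codes[1:] != codes[:-1]) | (starts[1:] != ends[:-1])
    out_starts = starts[keep]
    out_codes = codes[keep]
    # each merged tract ends where the next kept tract starts (or at the last end)
    idx = np.flatnonzero(keep)
    out_ends = np.append(starts[idx[1:]], ends[-1]) if idx.size > 1 else ends[-1:]
    return out_starts, out_ends, out_codes


def read_msp(path) -> AncestryTractSet:
    """Read an RFMix2-style ``msp.tsv`` local-ancestry table.

    Expects a first comment line carrying the subpopulation code map
    (``label=code`` pairs), a header line ``#chm spos epos sgpos egpos
    n snps`` followed by two columns per sample, then one row per window.
    Windows with identical consecutive codes are merged into tracts;
    positions are treated as half-open ``[spos, epos)``.
    """
    with open(path) as fh:
        first = fh.readline().rstrip("\n")
        header = fh.readline().rstrip("\n")
        body = pd.read_csv(fh, sep="\t", header=None)
    code_map = {}
    for tok in first.split(":", 1)[-1].replace(",", "\t").split():
        if "=" in tok:
            label, code = tok.split("=")
            code_map[label] = int(code)
    cols = header.lstrip("#").split("\t")
    hap_cols = cols[6:]
    if len(hap_cols) % 2:
        raise FormatError(
            f"msp file has {len(hap_cols)} haplotype columns; an even count "
            "(two per sample) is required"
        )
    samples = [c[:-2] for c in hap_cols[0::2]]
    chrom = str(body.iloc[0, 0])
    spos = body.iloc[:, 1].to_numpy(np.int64)
    epos = body.iloc[:, 2].to_numpy(np.int64)
    tracts = []
    for i in range(len(samples)):
        haps = []
        for h in range(2):
            codes = body.iloc[:, 6 + 2 * i + h].to_numpy(np.int16)
            haps.append(_merge_consecutive(spos, epos, codes))
        tracts.append(tuple(haps))
    return AncestryTractSet(chrom=chrom, samples=samples, code_map=code_map,
                            tracts=tracts)


def write_msp(tracts: AncestryTractSet, path) -> None:
    """Write tracts as an RFMix2-style msp.tsv (windows = union of breakpoints)."""
    cuts = np.unique(np.concatenate(
        [np.concatenate([h[0] for pair in tracts.tracts for h in pair]),
         np.concatenate([h[1] for pair in tracts.tracts for h in pair])]
    ))
    spos, epos = cuts[:-1], cuts[1:]
    mids = spos  # code of the tract containing the window start
    cols = []
    for hap0, hap1 in tracts.tracts:
        for starts, ends, codes in (hap0, hap1):
            idx = np.searchsorted(starts, mids, side="right") - 1
            cols.append(codes[np.clip(idx, 0, len(codes) - 1)])
    order = sorted(tracts.code_map.items(), key=lambda kv: kv[1])
    with open(path, "w") as fh:
        fh.write("#Subpopulation order/codes: "
                 + "\t".join(f"{k}={v}" for k, v in order) + "\n")
        hap_names = [f"{s}.{h}" for s in tracts.samples for h in (0, 1)]
        fh.write("#chm\tspos\tepos\tsgpos\tegpos\tn snps\t"
                 + "\t".join(hap_names) + "\n")
        cm = 1e-6  # nominal 1 cM/Mb genetic positions
        for w in range(spos.size):
            row = [tracts.chrom, str(spos[w]), str(epos[w]),
                   f"{spos[w] * cm:.2f}", f"{epos[w] * cm:.2f}", "1"]
            row += [str(c[w]) for c in cols]
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# Intervals (BED / interval_list)
# ---------------------------------------------------------------------------

def merge_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Sort and merge overlapping or abutting half-open intervals."""
    out = []
    for chrom, grp in df.groupby("chrom", sort=True):
        grp = grp.sort_values("start")
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        cur_s, cur_e = starts[0], ends[0]
        for s, e in zip(starts[1:], ends[1:]):
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                out.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        out.append((chrom, cur_s, cur_e))
    return pd.DataFrame(out, columns=["chrom", "start", "end"])


def read_intervals(path, dialect: str = "bed") -> pd.DataFrame:
    """Read BED (0-based half-open) or interval_list (1-based closed) intervals.

    Returns a merged, sorted DataFrame (chrom, start, end) in the internal
    1-based half-open convention.
    """
    if dialect not in ("bed", "interval_list"):
        raise ParameterError(f"unknown interval dialect: {dialect!r}")
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "@", "track", "browser")):
                continue
            parts = line.split("\t")
            chrom, a, b = parts[0], int(parts[1]), int(parts[2])
            if dialect == "bed":
                start, end = a + 1, b + 1
            else:
                start, end = a, b + 1
            if end < start:
                raise FormatError(f"{path}:{lineno}: interval end < start")
            rows.append((chrom, start, end))
    if not rows:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    return merge_intervals(pd.DataFrame(rows, columns=["chrom", "start", "end"]))


def write_bed(intervals: pd.DataFrame, path) -> None:
    """Write internal 1-based half-open intervals as 0-based half-open BED."""
    with open(path, "w") as fh:
        for row in intervals.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start - 1}\t{row.end - 1}\n")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_genotype_vcf(path, fmt: str = "GT"):
    """Read a biallelic-SNP VCF into a matrix plus site table and samples.

    ``fmt`` selects GT (hard calls as alt-allele counts), DS (dosage,
    clipped to [0,2]; derived from GP as ``GP1 + 2*GP2`` when DS is
    absent), or GP (the probability triples).  Multi-allelic records are
    skipped with a logged count.  GP triples whose sum deviates from 1 by
    more than 1e-3 mark the genotype missing; within tolerance they are
    renormalised.
    """
    from cyvcf2 import VCF

    if fmt not in ("GT", "DS", "GP"):
        raise ParameterError(f"unsupported FORMAT field: {fmt!r}")
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, chroms, poss, refs, alts, afs, infos = [], [], [], [], [], [], []
    n_multi = 0
    last = None
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        key = (var.CHROM, var.POS)
        if last is not None and last[0] == var.CHROM and var.POS < last[1]:
            raise FormatError(f"{path}: unsorted VCF at {var.CHROM}:{var.POS}")
        last = key
        chroms.append(var.CHROM)
        poss.append(var.POS)
        refs.append(var.REF)
        alts.append(var.ALT[0])
        afs.append(_info_float(var, "AF"))
        infos.append(_info_float(var, "INFO"))
        rows.append(_extract_format(var, fmt, len(samples), path))
    vcf.close()
    if n_multi:
        log.info("skipped %d multi-allelic records in %s", n_multi, path)
    sites = make_site_table(chroms, poss or [1], refs or None, alts or None,
                            afs or None, infos or None) if poss else \
        pd.DataFrame(columns=SITE_COLUMNS)
    if not rows:
        shape = (0, len(samples), 3) if fmt == "GP" else (0, len(samples))
        return np.empty(shape), sites, samples
    mat = np.stack(rows)
    if fmt == "GT":
        mat = mat.astype(np.int8).T
    elif fmt == "GP":
        mat = np.transpose(mat, (1, 0, 2))
    else:
        mat = mat.T
    return mat, sites, samples


def _info_float(var, key):
    val = var.INFO.get(key)
    if val is None:
        return np.nan
    return float(val[0] if isinstance(val, tuple) else val)


def _normalize_gp(gp):
    """Renormalise GP rows within 1e-3 of summing to one; else mark missing."""
    gp = np.array(gp, dtype=float)
    s = gp.sum(axis=-1)
    bad = np.abs(s - 1.0) > 1e-3
    safe = np.where(s > 0, s, 1.0)
    gp = gp / safe[..., None]
    gp[bad] = np.nan
    return gp, int(bad.sum())


def _format_or_none(var, key):
    try:
        return var.format(key)
    except KeyError:
        return None


def _extract_format(var, fmt, n_samples, path):
    if fmt == "GT":
        gt = np.asarray(var.genotype.array())[:, :2]
        missing = (gt < 0).any(axis=1)
        out = np.where(missing, MISSING, (gt > 0).sum(axis=1))
        return out
    gp_raw = _format_or_none(var, "GP")
    if fmt == "GP":
        if gp_raw is None:
            raise FormatError(f"{path}: FORMAT field GP absent at {var.POS}")
        gp, n_bad = _normalize_gp(gp_raw)
        if n_bad:
            log.warning("%d GP triples off-simplex at %s:%d set missing",
                        n_bad, var.CHROM, var.POS)
        return gp
    ds = _format_or_none(var, "DS")
    if ds is not None:
        return np.clip(np.asarray(ds, dtype=float)[:, 0], 0.0, 2.0)
    if gp_raw is None:
        raise FormatError(f"{path}: neither DS nor GP present at {var.POS}")
    gp, _ = _normalize_gp(gp_raw)
    return np.clip(gp[:, 1] + 2.0 * gp[:, 2], 0.0, 2.0)


def _vcf_header(samples, extra_meta=(), contigs=()):
    lines = ["##fileformat=VCFv4.2"]
    lines += [f"##contig=<ID={c}>" for c in contigs]
    lines += list(extra_meta)
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples))
    return lines


_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_genotype_vcf(path, genotypes, sites: pd.DataFrame, samples) -> None:
    """Write hard-call genotypes (samples x sites, {0,1,2,-1}) as a GT VCF."""
    genotypes = np.asarray(genotypes)
    meta = ['##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
            '##INFO=<ID=AF,Number=A,Type=Float,Description="Allele frequency">']
    contigs = pd.unique(sites["chrom"])
    with open(path, "w") as fh:
        fh.write("\n".join(_vcf_header(samples, meta, contigs)) + "\n")
        for j, row in enumerate(sites.itertuples(index=False)):
            info = "." if np.isnan(row.af) else f"AF={row.af:.6g}"
            cells = [_GT_STR[int(g)] for g in genotypes[:, j]]
            fh.write(f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\t."
                     f"\t{info}\tGT\t" + "\t".join(cells) + "\n")


def write_imputed_vcf(path, dosages, gp, sites: pd.DataFrame, samples) -> None:
    """Write imputed dosages (+ optional GP triples) with per-site AF/INFO.

    DS and GP are written to 3 decimals; INFO fields AF and INFO come from
    the site table.
    """
    dosages = np.asarray(dosages)
    meta = [
        '##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">',
        '##FORMAT=<ID=GP,Number=G,Type=Float,Description="Genotype probability">',
        '##INFO=<ID=AF,Number=A,Type=Float,Description="Allele frequency">',
        '##INFO=<ID=INFO,Number=1,Type=Float,Description="Imputation INFO score">',
    ]
    fmt = "DS:GP" if gp is not None else "DS"
    contigs = pd.unique(sites["chrom"])
    with open(path, "w") as fh:
        fh.write("\n".join(_vcf_header(samples, meta, contigs)) + "\n")
        for j, row in enumerate(sites.itertuples(index=False)):
            parts = []
            if not np.isnan(row.af):
                parts.append(f"AF={row.af:.6g}")
            if not np.isnan(row.info):
                parts.append(f"INFO={row.info:.6g}")
            info = ";".join(parts) or "."
            cells = []
            for i in range(len(samples)):
                cell = f"{dosages[i, j]:.3f}"
                if gp is not None:
                    # round so the triple sums to exactly 1.000 at 3 decimals
                    p0 = round(float(gp[i, j, 0]), 3)
                    p1 = round(float(gp[i, j, 1]), 3)
                    p2 = max(round(1.0 - p0 - p1, 3), 0.0)
                    cell += f":{p0:.3f},{p1:.3f},{p2:.3f}"
                cells.append(cell)
            fh.write(f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\t."
                     f"\t{info}\t{fmt}\t" + "\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# PED / CNV tables
# ---------------------------------------------------------------------------

def read_ped(path) -> pd.DataFrame:
    """Read a 6-column whitespace-delimited PED pedigree file."""
    df = pd.read_csv(path, sep=r"\s+", header=None, names=PED_COLUMNS,
                     dtype=str, comment="#")
    df["sex"] = df["sex"].astype(int)
    df["phenotype"] = df["phenotype"].astype(int)
    return df


def write_ped(pedigree: pd.DataFrame, path) -> None:
    pedigree[PED_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_cnv_tsv(path) -> pd.DataFrame:
    """Read a CNV call table (sample, chrom, start, end, type, qs)."""
    df = pd.read_csv(path, sep="\t")
    missing = set(CNV_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: CNV table missing columns {sorted(missing)}")
    bad = df["end"] <= df["start"]
    if bad.any():
        raise FormatError(f"{path}: CNV call with end <= start "
                          f"(row {int(np.flatnonzero(bad)[0])})")
    if not df["type"].isin(["DEL", "DUP"]).all():
        raise FormatError(f"{path}: CNV type must be DEL or DUP")
    return df


def write_cnv_tsv(calls: pd.DataFrame, path) -> None:
    cols = [c for c in calls.columns if c in CNV_COLUMNS + ["exon_count", "site_id"]]
    calls[cols].to_csv(path, sep="\t", index=False)
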