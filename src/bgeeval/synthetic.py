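"""Synthetic admixed-cohort generator with known truth.

Every downstream stage of the evaluation pipeline (batch merging,
concordance metrics, local-ancestry stratification, CNV benchmarking)
is exercised against cohorts produced here, so planted parameters can be
recovered and compared.

The generative model, in order:

1. **Population allele frequencies** — a Balding–Nichols model: each
   ancestry's AF at a site is drawn ``Beta(p(1-F)/F, (1-p)(1-F)/F)``
   around an ancestral frequency ``p``, so the per-ancestry divergence is
   controlled by a single drift parameter ``F`` per ancestry.
2. **Ancestry tracts** — admixed haplotypes as a Markov tract process:
   breakpoints follow a Poisson process with rate ``g`` per Morgan
   (uniform 1 cM/Mb map), tract labels drawn i.i.d. from the admixture
   proportions.  This emulates the output of a local-ancestry caller on
   a population ``g`` generations past admixture.
3. **Truth genotypes** — each haplotype allele is Bernoulli with the AF
   of its local ancestry; the diploid genotype is the haplotype sum.
   Sites are then polarised so the alternate allele is the cohort minor
   allele, as allele-order harmonisation (e.g. conform-gt) produces.
4. **Low-pass dosages** — a read-resampling model: read depth is
   Poisson(``mean_coverage``), alternate reads Binomial with genotype-
   dependent rate, and the genotype posterior is computed against a
   Hardy–Weinberg prior at the cohort AF.  GP is that posterior; the
   dosage is its mean.  At zero depth the posterior equals the prior, so
   dosage = 2·AF exactly.
5. **Array genotypes** — truth perturbed by independent genotyping error
   and missingness, standing in for SNP-array ground truth.
6. **CNV quartets** — rare exonic deletions/duplications planted in
   quartet families (two parents, two children) with configurable
   carrier drop-out and boundary jitter, for recall/PPV and de novo
   benchmarking.

Sites are independent given local ancestry: no linkage disequilibrium is
simulated, which is irrelevant for the metrics evaluated here (they are
per-genotype) but means the generator cannot exercise an imputation
engine itself.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import MISSING, AncestryTractSet, ParameterError, make_site_table

log = logging.getLogger(__name__)

BP_PER_MORGAN = 100_000_000  # uniform 1 cM/Mb recombination map


def substream(seed: int, stream: int) -> np.random.Generator:
    """Independent generator for operation ``stream`` of a seeded run."""
    return np.random.default_rng(np.random.SeedSequence((int(seed), int(stream))))


@dataclass
class CohortConfig:
    """Parameters of one synthetic admixed cohort.

    Defaults describe a mid-sized admixed cohort genotyped on one
    chromosome: 3-way AFR/EUR/AMR admixture ~10 generations old,
    Balding–Nichols drift F=0.1 per ancestry, low-pass coverage 1x with
    1% base error, array error 0.2% and missingness 1%, split into 2
    imputation batches.
    """

    n_samples: int = 200
    n_sites: int = 2000
    chrom: str = "chr1"
    chrom_length_bp: int = BP_PER_MORGAN
    ancestries: tuple = ("AFR", "EUR", "AMR")
    admixture_proportions: tuple = (0.45, 0.35, 0.2)
    generations_since_admixture: float = 10.0
    divergence_fst: tuple = (0.1, 0.1, 0.1)
    ancestral_af_range: tuple = (0.01, 0.99)
    mean_coverage: float = 1.0
    base_error: float = 0.01
    array_error_rate: float = 0.002
    array_missing_rate: float = 0.01
    n_batches: int = 2
    seed: int = 0

    def __post_init__(self):
        props = np.asarray(self.admixture_proportions, dtype=float)
        if len(props) != len(self.ancestries):
            raise ParameterError("one admixture proportion per ancestry required")
        if abs(props.sum() - 1.0) > 1e-12:
            raise ParameterError("admixture_proportions must sum to 1")
        if np.any(props < 0):
            raise ParameterError("admixture_proportions must be nonnegative")
        fst = np.asarray(self.divergence_fst, dtype=float)
        if len(fst) != len(self.ancestries):
            raise ParameterError("one divergence_fst per ancestry required")
        if np.any((fst <= 0) | (fst >= 1)):
            raise ParameterError("divergence_fst values must lie in (0, 1)")
        if self.n_samples < 1 or self.n_sites < 1:
            raise ParameterError("n_samples and n_sites must be >= 1")
        if self.generations_since_admixture <= 0:
            raise ParameterError("generations_since_admixture must be > 0")
        if self.mean_coverage < 0:
            raise ParameterError("mean_coverage must be >= 0")
        if not 0 <= self.base_error < 0.5:
            raise ParameterError("base_error must lie in [0, 0.5)")
        for name in ("array_error_rate", "array_missing_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ParameterError(f"{name} must lie in [0, 1]")

    @property
    def sample_ids(self):
        return [f"S{i:05d}" for i in range(self.n_samples)]


@dataclass
class TruthBundle:
    """Everything the generator knows to be true about one cohort."""

    true_genotypes: np.ndarray          # (n_samples, n_sites) int8
    true_haplotypes: tuple              # two (n_samples, n_sites) int8 matrices
    tracts: AncestryTractSet
    per_ancestry_afs: np.ndarray        # (n_ancestries, n_sites)
    sites: pd.DataFrame
    samples: list = field(default_factory=list)


def simulate_population_afs(config: CohortConfig,
                            rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw per-ancestry allele frequencies under Balding–Nichols drift.

    The ancestral AF ``p`` is uniform on ``config.ancestral_af_range``;
    each ancestry's AF is Beta(p(1-F)/F, (1-p)(1-F)/F), giving mean ``p``
    and variance ``F p (1-p)``.
    """
    rng = rng or substream(config.seed, 1)
    lo, hi = config.ancestral_af_range
    p = rng.uniform(lo, hi, size=config.n_sites)
    afs = np.empty((len(config.ancestries), config.n_sites))
    for k, f in enumerate(config.divergence_fst):
        scale = (1.0 - f) / f
        afs[k] = rng.beta(p * scale, (1.0 - p) * scale)
    return np.clip(afs, 1e-9, 1.0 - 1e-9)


def simulate_tracts(config: CohortConfig,
                    rng: np.random.Generator | None = None) -> AncestryTractSet:
    """Simulate per-haplotype ancestry tracts.

    Breakpoints are a Poisson process at rate ``g`` per Morgan on a
    uniform map; each tract's ancestry is i.i.d. from the admixture
    proportions.  Tracts tile ``[1, chrom_length_bp + 1)``.
    """
    rng = rng or substream(config.seed, 2)
    g = config.generations_since_admixture
    length_morgans = config.chrom_length_bp / BP_PER_MORGAN
    props = np.asarray(config.admixture_proportions, dtype=float)
    n_anc = len(props)
    tracts = []
    for _ in range(config.n_samples):
        haps = []
        for _h in range(2):
            n_breaks = rng.poisson(g * length_morgans)
            breaks = np.sort(rng.integers(2, config.chrom_length_bp + 1,
                                          size=n_breaks))
            starts = np.concatenate(([1], breaks)).astype(np.int64)
            ends = np.concatenate((breaks, [config.chrom_length_bp + 1])).astype(np.int64)
            codes = rng.choice(n_anc, size=starts.size, p=props).astype(np.int16)
            haps.append(_dedup(starts, ends, codes))
        tracts.append(tuple(haps))
    code_map = {label: k for k, label in enumerate(config.ancestries)}
    return AncestryTractSet(chrom=config.chrom, samples=config.sample_ids,
                            code_map=code_map, tracts=tracts)


def _dedup(starts, ends, codes):
    """Drop zero-length tracts and merge same-code neighbours."""
    keep = ends > starts
    starts, ends, codes = starts[keep], ends[keep], codes[keep]
    if starts.size == 0:
        return starts, ends, codes
    new = np.ones(starts.size, dtype=bool)
    new[1:] = codes[1:] != codes[:-1]
    idx = np.flatnonzero(new)
    out_starts = starts[idx]
    out_codes = codes[idx]
    out_ends = np.append(starts[idx[1:]], ends[-1]) if idx.size > 1 else ends[-1:]
    return out_starts, out_ends, out_codes


def simulate_truth(config: CohortConfig) -> TruthBundle:
    """Simulate truth haplotypes, genotypes and site metadata.

    Haplotype alleles are Bernoulli with the AF of the haplotype's local
    ancestry at the site.  After drawing, sites where the cohort ALT
    frequency exceeds 0.5 are re-polarised (allele labels swapped) so the
    alternate allele is the cohort minor allele throughout.
    """
    afs = simulate_population_afs(config)
    tracts = simulate_tracts(config)
    rng = substream(config.seed, 3)
    positions = site_positions(config)
    hap_codes = tracts.hap_codes(positions)  # (n_samples, n_sites, 2)
    haps = []
    for h in range(2):
        p = afs[hap_codes[:, :, h], np.arange(config.n_sites)[None, :]]
        haps.append((rng.random(p.shape) < p).astype(np.int8))
    genotypes = (haps[0] + haps[1]).astype(np.int8)

    af = genotypes.mean(axis=0) / 2.0
    flip = af > 0.5
    if flip.any():
        for h in range(2):
            haps[h][:, flip] = 1 - haps[h][:, flip]
        genotypes[:, flip] = 2 - genotypes[:, flip]
        afs[:, flip] = 1.0 - afs[:, flip]
        af = genotypes.mean(axis=0) / 2.0

    sites = make_site_table(config.chrom, positions, af=af)
    return TruthBundle(true_genotypes=genotypes, true_haplotypes=tuple(haps),
                       tracts=tracts, per_ancestry_afs=afs, sites=sites,
                       samples=config.sample_ids)


def site_positions(config: CohortConfig) -> np.ndarray:
    """Evenly spaced site positions along the chromosome (1-based)."""
    step = max(config.chrom_length_bp // (config.n_sites + 1), 1)
    return (np.arange(1, config.n_sites + 1, dtype=np.int64) * step)


def genotype_posteriors(depth: np.ndarray, alt_reads: np.ndarray,
                        site_af: np.ndarray, base_error: float) -> np.ndarray:
    """Posterior over {0,1,2} from read counts against an HWE prior.

    Likelihood of ``a`` alternate reads out of ``c`` is Binomial with
    success rate ε, 0.5, or 1-ε for genotypes 0, 1, 2; the prior is
    Hardy–Weinberg at the site's cohort AF.
    """
    eps = base_error
    c = depth.astype(np.float64)
    a = alt_reads.astype(np.float64)
    r = c - a
    with np.errstate(divide="ignore", invalid="ignore"):
        loglik = np.stack([
            a * np.log(eps) + r * np.log1p(-eps),
            (a + r) * np.log(0.5),
            a * np.log1p(-eps) + r * np.log(eps),
        ], axis=-1)
    loglik = np.where(np.isnan(loglik), -np.inf, loglik)
    # zero reads of a class contribute log(rate)*0 = 0 even when rate = 0
    loglik[..., 0] = np.where((a == 0) & (eps == 0), 0.0, loglik[..., 0])
    loglik[..., 2] = np.where((r == 0) & (eps == 0), 0.0, loglik[..., 2])
    p = site_af[None, :]
    prior = np.stack([(1 - p) ** 2, 2 * p * (1 - p), p ** 2], axis=-1)
    with np.errstate(divide="ignore"):
        logpost = loglik + np.log(prior)
    logpost -= logpost.max(axis=-1, keepdims=True)
    post = np.exp(logpost)
    post /= post.sum(axis=-1, keepdims=True)
    return post


@dataclass
class DosageMatrix:
    """Imputed-style output: dosages in [0,2] with GP triples."""

    dosages: np.ndarray   # (n_samples, n_sites)
    gp: np.ndarray        # (n_samples, n_sites, 3)
    sites: pd.DataFrame
    samples: list


def simulate_lowpass_dosages(truth: TruthBundle, config: CohortConfig,
                             coverage: np.ndarray | float | None = None,
                             chunk_sites: int = 4000) -> DosageMatrix:
    """Simulate low-pass posterior dosages from the truth genotypes.

    ``coverage`` may be a scalar (defaults to ``config.mean_coverage``) or
    a per-genotype matrix of Poisson depth means, which lets tests plant
    coverage differences between local-ancestry backgrounds.  Sites that
    are monomorphic in the cohort get a degenerate HWE prior; their
    dosage is the prior mean (a logged condition).
    """
    rng = substream(config.seed, 4)
    g = truth.true_genotypes
    n, m = g.shape
    lam = config.mean_coverage if coverage is None else coverage
    lam_mat = np.broadcast_to(np.asarray(lam, dtype=float), (n, m))
    af = truth.sites["af"].to_numpy()
    mono = (af <= 0) | (af >= 1)
    if mono.any():
        log.warning("%d monomorphic sites: prior-only dosages returned",
                    int(mono.sum()))
    af = np.clip(af, 1e-12, 1 - 1e-12)
    mu = np.array([config.base_error, 0.5, 1.0 - config.base_error])
    dosages = np.empty((n, m))
    gp = np.empty((n, m, 3), dtype=np.float32)
    for j0 in range(0, m, chunk_sites):
        j1 = min(j0 + chunk_sites, m)
        depth = rng.poisson(lam_mat[:, j0:j1])
        alt = rng.binomial(depth, mu[g[:, j0:j1]])
        post = genotype_posteriors(depth, alt, af[j0:j1], config.base_error)
        gp[:, j0:j1] = post
        dosages[:, j0:j1] = post[..., 1] + 2.0 * post[..., 2]
    sites = truth.sites.copy()
    return DosageMatrix(dosages=dosages, gp=gp, sites=sites,
                        samples=list(truth.samples))


def simulate_array_genotypes(truth: TruthBundle,
                             config: CohortConfig) -> np.ndarray:
    """Array-style hard calls: truth with genotyping error and missingness.

    Each genotype is independently set missing with ``array_missing_rate``,
    else replaced by a uniformly random *different* genotype with
    ``array_error_rate``.
    """
    rng = substream(config.seed, 5)
    g = truth.true_genotypes.copy()
    shape = g.shape
    u = rng.random(shape)
    err = (u >= config.array_missing_rate) & \
          (u < config.array_missing_rate + config.array_error_rate)
    shift = rng.integers(1, 3, size=int(err.sum()))
    g[err] = ((g[err] + shift) % 3).astype(np.int8)
    g[u < config.array_missing_rate] = MISSING
    return g


def batch_assignments(config: CohortConfig) -> np.ndarray:
    """Deterministic round-robin split of samples into imputation batches."""
    return np.arange(config.n_samples) % config.n_batches


# ---------------------------------------------------------------------------
# CNV quartet fixtures
# ---------------------------------------------------------------------------

@dataclass
class CnvPlantSpec:
    """What to plant in the quartet CNV fixture.

    ``n_transmitted_*`` sites each get ``carrier_families`` families where
    one parent and one child both carry the event; ``n_denovo_*`` events
    occur in exactly one child with neither parent carrying.  The test
    callset reproduces truth calls with probability ``1 - dropout``, with
    endpoints jittered by up to ``jitter_exons`` whole exons.

    ``dropout_mode`` controls the unit of drop-out: ``"carrier"`` drops
    each carrier's call independently, ``"site"`` drops all carriers of
    an event together.  Site-level drop-out makes the benchmark's
    site-level recall equal ``1 - dropout`` in expectation regardless of
    per-site carrier counts, which is what planted-parameter recovery
    tests need; carrier-level drop-out instead thins carriers, which the
    50%-of-carriers matching rule largely absorbs.
    """

    n_transmitted_del: int = 20
    n_transmitted_dup: int = 20
    n_denovo_del: int = 6
    n_denovo_dup: int = 5
    carrier_families: int = 2
    span_exons: tuple = (5, 10)
    dropout: float = 0.0
    dropout_mode: str = "carrier"
    jitter_exons: int = 0
    qs_range: tuple = (250.0, 1000.0)

    def __post_init__(self):
        if self.dropout_mode not in ("carrier", "site"):
            raise ParameterError("dropout_mode must be 'carrier' or 'site'")
        if not 0.0 <= self.dropout < 1.0:
            raise ParameterError("dropout must lie in [0, 1)")


def make_exon_intervals(n_exons: int = 3000, chrom: str = "chr1",
                        exon_bp: int = 150, gap_bp: int = 5000) -> pd.DataFrame:
    """Evenly spaced synthetic exons (1-based half-open internal convention)."""
    starts = 1 + np.arange(n_exons, dtype=np.int64) * (exon_bp + gap_bp)
    return pd.DataFrame({"chrom": chrom, "start": starts,
                         "end": starts + exon_bp})


def quartet_pedigree(n_families: int) -> pd.DataFrame:
    """PED table for ``n_families`` quartets (father, mother, two children)."""
    rows = []
    for f in range(n_families):
        fam = f"F{f:03d}"
        fa, mo = f"{fam}_fa", f"{fam}_mo"
        rows.append((fam, fa, "0", "0", 1, 1))
        rows.append((fam, mo, "0", "0", 2, 1))
        for c in (1, 2):
            rows.append((fam, f"{fam}_c{c}", fa, mo, c, 2))
    return pd.DataFrame(rows, columns=["fam_id", "sample", "father", "mother",
                                       "sex", "phenotype"])


def plant_cnv_quartets(n_families: int, exon_intervals: pd.DataFrame,
                       spec: CnvPlantSpec, seed: int = 0):
    """Plant rare CNVs in quartet families; return (truth, test, pedigree).

    Truth calls sit on disjoint runs of consecutive exons so sites do not
    overlap one another.  Raises if the requested events do not fit in
    the available exons.
    """
    rng = substream(seed, 6)
    ped = quartet_pedigree(n_families)
    exons = exon_intervals.sort_values("start").reset_index(drop=True)
    n_events = (spec.n_transmitted_del + spec.n_transmitted_dup
                + spec.n_denovo_del + spec.n_denovo_dup)
    slot = spec.span_exons[1] + 2 * spec.jitter_exons + 1  # +1 exon spacer
    if n_events * slot > len(exons):
        raise ParameterError(
            f"{n_events} events of up to {slot - 1} exons do not fit in "
            f"{len(exons)} exons")

    types = (["DEL"] * spec.n_transmitted_del + ["DUP"] * spec.n_transmitted_dup
             + ["DEL"] * spec.n_denovo_del + ["DUP"] * spec.n_denovo_dup)
    denovo_flags = ([False] * (spec.n_transmitted_del + spec.n_transmitted_dup)
                    + [True] * (spec.n_denovo_del + spec.n_denovo_dup))
    children = ped.loc[ped["father"] != "0"]
    truth_rows = []
    for e, (cnv_type, is_denovo) in enumerate(zip(types, denovo_flags)):
        first = e * slot + (0 if spec.jitter_exons == 0 else spec.jitter_exons)
        span = int(rng.integers(spec.span_exons[0], spec.span_exons[1] + 1))
        start = int(exons.loc[first, "start"])
        end = int(exons.loc[first + span - 1, "end"])
        chrom = exons.loc[first, "chrom"]
        if is_denovo:
            child = children.iloc[int(rng.integers(len(children)))]
            carriers = [child["sample"]]
        else:
            fams = rng.choice(n_families, size=min(spec.carrier_families,
                                                   n_families), replace=False)
            carriers = []
            for f in fams:
                fam = f"F{f:03d}"
                parent = fam + ("_fa" if rng.random() < 0.5 else "_mo")
                child = fam + f"_c{int(rng.integers(1, 3))}"
                carriers += [parent, child]
        for s in carriers:
            truth_rows.append((s, chrom, start, end, cnv_type,
                               float(rng.uniform(*spec.qs_range)),
                               is_denovo, e))
    truth = pd.DataFrame(truth_rows, columns=["sample", "chrom", "start", "end",
                                              "type", "qs", "is_denovo",
                                              "event_id"])

    exon_starts = exons["start"].to_numpy()
    exon_ends = exons["end"].to_numpy()
    dropped_events = {e for e in range(n_events)
                      if spec.dropout_mode == "site"
                      and rng.random() < spec.dropout}
    test_rows = []
    for row in truth.itertuples(index=False):
        if spec.dropout_mode == "site":
            if row.event_id in dropped_events:
                continue
        elif rng.random() < spec.dropout:
            continue
        i0 = int(np.searchsorted(exon_starts, row.start))
        i1 = int(np.searchsorted(exon_ends, row.end))
        if spec.jitter_exons:
            i0 = max(0, i0 + int(rng.integers(-spec.jitter_exons,
                                              spec.jitter_exons + 1)))
            i1 = min(len(exons) - 1,
                     max(i0, i1 + int(rng.integers(-spec.jitter_exons,
                                                   spec.jitter_exons + 1))))
        test_rows.append((row.sample, row.chrom, int(exon_starts[i0]),
                          int(exon_ends[i1]), row.type,
                          float(rng.uniform(*spec.qs_range))))
    test = pd.DataFrame(test_rows, columns=["sample", "chrom", "start", "end",
                                            "type", "qs"])
    return truth, test, ped
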