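"""Scalar statistics over Pack-TIR sets and population panels.

Covers the contingency tests and regression used on genome-wide counts,
the allele-frequency spectrum of segregating insertions, sliding-window
nucleotide diversity, the matched-resampling selective-sweep test, and
region-wise synonymous/nonsynonymous substitution enrichment with
NG86-style site counting.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import VariantPanel

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# contingency and regression
# ---------------------------------------------------------------------------

def fisher_exact(table, sided: str = "two") -> float:
    """Fisher's exact test on a 2x2 table.

    Two-sided p sums the point probabilities of all tables (fixed margins)
    no more likely than the observed one; one-sided takes the tail in the
    observed direction of association.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a non-negative 2x2 table")
    if t.sum() == 0:
        raise ValueError("empty table")
    if sided == "two":
        alternative = "two-sided"
    elif sided == "one":
        a, b = t[0]
        c, d = t[1]
        # tail of the observed direction of association
        alternative = "greater" if a * d >= b * c else "less"
    else:
        raise ValueError("sided must be 'one' or 'two'")
    return float(stats.fisher_exact(t, alternative=alternative).pvalue)


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    f_stat: float
    p_value: float
    n: int


def fit_count_regression(x, y) -> RegressionResult:
    """Ordinary least squares of capture counts on TE counts, with the
    F-test (1, n-2 d.f.) for the slope."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.allclose(x, x[0]):
        raise ValueError("zero variance in x")
    res = stats.linregress(x, y)
    # F with (1, n-2) d.f. for simple regression is the squared slope t
    t = res.slope / res.stderr if res.stderr > 0 else np.inf
    f = float(t * t)
    return RegressionResult(float(res.slope), float(res.intercept),
                            float(res.rvalue ** 2), f, float(res.pvalue),
                            int(x.size))


# ---------------------------------------------------------------------------
# allele frequency spectrum
# ---------------------------------------------------------------------------

@dataclass
class FrequencySpectrum:
    frequencies: pd.Series        # per insertion, carriers / non-missing lines
    carrier_counts: pd.Series
    n_lines: int
    singleton_fraction: float


def allele_frequency_spectrum(presence: pd.DataFrame) -> FrequencySpectrum:
    """Per-insertion carrier frequency and the singleton fraction.

    ``presence`` is lines x insertions with entries 0/1 (NaN allowed for
    missing genotyping); insertions with zero carriers are excluded with a
    logged count.
    """
    carriers = presence.sum(axis=0, skipna=True)
    informative = presence.notna().sum(axis=0)
    zero = carriers == 0
    if zero.any():
        logger.warning("excluding %d insertions with zero carriers",
                       int(zero.sum()))
    carriers = carriers[~zero]
    informative = informative[~zero]
    freq = carriers / informative
    singleton = float((carriers == 1).mean()) if len(carriers) else 0.0
    return FrequencySpectrum(freq, carriers.astype(int),
                             presence.shape[0], singleton)


# ---------------------------------------------------------------------------
# windowed nucleotide diversity
# ---------------------------------------------------------------------------

@dataclass
class DiversityWindow:
    chrom: str
    start: int
    end: int
    group: str
    pi: float
    n_snps: int


def per_site_pi(genotypes: np.ndarray) -> np.ndarray:
    """Unbiased per-site diversity 2a(k-a)/(k(k-1)) for haploid genotypes
    (rows sites, cols lines; -1 missing).  Sites with < 2 calls give 0."""
    g = np.asarray(genotypes)
    called = g >= 0
    k = called.sum(axis=1)
    a = np.where(called, g, 0).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        pi = 2.0 * a * (k - a) / (k * (k - 1.0))
    pi[k < 2] = 0.0
    return pi


def windowed_pi(panel: VariantPanel, chrom: str,
                span: tuple[int, int] | None = None,
                window: int = 1000, step: int = 500,
                group_mask: np.ndarray | None = None,
                group: str = "all") -> list[DiversityWindow]:
    """Sliding-window nucleotide diversity (pi per site).

    Window pi is the sum of per-site pi over SNPs in the window divided by
    the window length; monomorphic windows report 0.
    """
    sel = panel.site_mask(chrom)
    pos = panel.positions[sel]
    geno = panel.genotypes[sel]
    if group_mask is not None:
        geno = geno[:, group_mask]
    pis = per_site_pi(geno)
    if span is None:
        span = (0, int(pos.max()) + 1 if len(pos) else window)
    out = []
    start = span[0]
    while start < span[1]:
        end = start + window
        lo = np.searchsorted(pos, start, side="left")
        hi = np.searchsorted(pos, end, side="left")
        out.append(DiversityWindow(chrom, start, end, group,
                                   float(pis[lo:hi].sum()) / window,
                                   int(hi - lo)))
        start += step
    return out


def _span_pi_sum(pos: np.ndarray, pis: np.ndarray,
                 span: tuple[int, int], window: int, step: int) -> float:
    """Sum of window pi over sliding windows covering a span (vectorized)."""
    starts = np.arange(span[0], span[1], step)
    lo = np.searchsorted(pos, starts, side="left")
    hi = np.searchsorted(pos, starts + window, side="left")
    cum = np.concatenate([[0.0], np.cumsum(pis)])
    return float((cum[hi] - cum[lo]).sum()) / window


# ---------------------------------------------------------------------------
# matched-resampling sweep test
# ---------------------------------------------------------------------------

@dataclass
class SweepTestResult:
    locus: int
    affected_span: tuple[int, int]
    observed_ratio: float
    n_reps: int
    n_le: int
    seed: int
    n_eligible: int

    @property
    def empirical_p(self) -> float:
        return self.n_le / self.n_reps


def sweep_empirical_pvalue(panel: VariantPanel, chrom: str,
                           carrier_lines: list[str],
                           affected_span: tuple[int, int],
                           locus: int | None = None,
                           n_reps: int = 1000,
                           matching: tuple[float, float] = (0.95, 1.05),
                           window: int = 1000, step: int = 500,
                           seed: int = 0) -> SweepTestResult:
    """Empirical p-value for carrier-linked diversity reduction.

    The observed statistic is the ratio of summed window pi (carriers /
    noncarriers) over the affected span.  Each replicate resamples a
    synonymous site on the same chromosome with carrier frequency and
    recombination rate each within the matching band of the focal values,
    splits lines by that site's allele, and recomputes the same ratio over
    an equal-length span centered on the site (clipped identically at
    chromosome ends).  The empirical p is the exact fraction of replicate
    ratios <= the observed ratio.
    """
    if panel.is_synonymous is None:
        raise ValueError("panel lacks synonymous-site flags")
    rng = np.random.default_rng(seed)
    sel = panel.site_mask(chrom)
    pos = panel.positions[sel]
    geno = panel.genotypes[sel]
    syn = panel.is_synonymous[sel]
    rr = panel.recomb_rate[sel] if panel.recomb_rate is not None else None

    line_index = {l: i for i, l in enumerate(panel.line_ids)}
    car = np.zeros(panel.n_lines, dtype=bool)
    car[[line_index[l] for l in carrier_lines]] = True
    if locus is None:
        locus = (affected_span[0] + affected_span[1]) // 2
    span_len = affected_span[1] - affected_span[0]
    focal_freq = car.mean()

    chrom_end = int(pos.max()) + 1 if len(pos) else span_len

    def ratio_for(mask: np.ndarray, span: tuple[int, int]) -> float:
        pc = _span_pi_sum(pos, per_site_pi(geno[:, mask]), span, window, step)
        pn = _span_pi_sum(pos, per_site_pi(geno[:, ~mask]), span, window, step)
        return pc / pn if pn > 0 else np.inf

    observed = ratio_for(car, _clip_span(affected_span, chrom_end))

    counts = (geno == 1).sum(axis=1)
    called = (geno >= 0).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        freqs = counts / called
    ok = syn & (freqs >= matching[0] * focal_freq) \
        & (freqs <= matching[1] * focal_freq)
    if rr is not None:
        focal_rr = float(np.median(rr))
        ok &= (rr >= matching[0] * focal_rr) & (rr <= matching[1] * focal_rr)
    eligible = np.nonzero(ok)[0]
    if len(eligible) == 0:
        raise ValueError("no eligible matched synonymous sites")
    replace = len(eligible) < n_reps
    if replace:
        logger.warning("only %d eligible matched sites for %d replicates; "
                       "sampling with replacement", len(eligible), n_reps)
    picks = rng.choice(eligible, size=n_reps, replace=True)
    n_le = 0
    for i in picks:
        center = int(pos[i])
        span = _clip_span((center - span_len // 2, center + span_len -
                           span_len // 2), chrom_end)
        mask = geno[i] == 1
        if mask.sum() < 2 or (~mask).sum() < 2:
            continue
        if ratio_for(mask, span) <= observed:
            n_le += 1
    return SweepTestResult(locus, affected_span, float(observed),
                           n_reps, n_le, seed, len(eligible))


def _clip_span(span: tuple[int, int], chrom_end: int) -> tuple[int, int]:
    lo, hi = max(0, span[0]), min(chrom_end, span[1])
    return lo, hi


# ---------------------------------------------------------------------------
# region-wise substitution counting (NG86-style)
# ---------------------------------------------------------------------------

_CODON_TABLE = {}


def _codon_table() -> dict[str, str]:
    if not _CODON_TABLE:
        from Bio.Data.CodonTable import standard_dna_table
        _CODON_TABLE.update(standard_dna_table.forward_table)
        for stop in standard_dna_table.stop_codons:
            _CODON_TABLE[stop] = "*"
    return _CODON_TABLE


def codon_site_counts(codon: str) -> tuple[float, float]:
    """NG86 synonymous/nonsynonymous site counts for one codon: each of the
    9 single-nucleotide changes contributes 1/3 of a site, synonymous iff
    the amino acid is conserved (changes to stops count nonsynonymous)."""
    table = _codon_table()
    aa = table[codon]
    syn = 0.0
    for i in range(3):
        for b in "ACGT":
            if b == codon[i]:
                continue
            mut = codon[:i] + b + codon[i + 1:]
            if table[mut] == aa and aa != "*":
                syn += 1.0 / 3.0
    return syn, 3.0 - syn


def _pathway_counts(c1: str, c2: str) -> tuple[float, float]:
    """Observed syn/nonsyn differences between two codons, averaging over
    all shortest mutational pathways through sense codons (NG86)."""
    table = _codon_table()
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    totals = []
    for order in itertools.permutations(diff):
        syn = non = 0.0
        cur = c1
        dead = False
        for i in order:
            nxt = cur[:i] + c2[i] + cur[i + 1:]
            if table[nxt] == "*" and len(diff) > 1:
                dead = True
                break
            if table[nxt] == table[cur]:
                syn += 1
            else:
                non += 1
            cur = nxt
        if not dead:
            totals.append((syn, non))
    if not totals:           # all pathways pass through stops; fall back
        totals = [(0.0, float(len(diff)))]
    s = np.mean([t[0] for t in totals])
    n = np.mean([t[1] for t in totals])
    return float(s), float(n)


@dataclass
class RegionChangeCounts:
    regions: list[str]
    obs_syn: dict[str, float]
    obs_nonsyn: dict[str, float]
    exp_syn_prop: dict[str, float]
    exp_nonsyn_prop: dict[str, float]
    p_syn: dict[str, float]
    p_nonsyn: dict[str, float]
    total_syn_sites: float
    total_nonsyn_sites: float


def region_substitution_test(codon_alignment: dict[str, str],
                             outgroup_id: str,
                             region_map: list[str]) -> RegionChangeCounts:
    """Region-wise enrichment of synonymous/nonsynonymous changes.

    ``codon_alignment`` maps sequence id to an in-frame gapped nucleotide
    string; ``region_map`` assigns each codon column to one region.  Every
    ingroup difference from the outgroup codon is classified by pathway
    averaging; expected per-region proportions come from the outgroup's
    NG86 site counts; the one-sided binomial proportion test asks whether a
    region's observed count exceeds its expected share.
    """
    out_seq = codon_alignment[outgroup_id]
    if len(out_seq) % 3:
        raise ValueError("alignment length not a multiple of 3")
    n_codons = len(out_seq) // 3
    if len(region_map) != n_codons:
        raise ValueError("region_map must have one region per codon")
    regions = sorted(set(region_map))
    table = _codon_table()

    site_syn = {r: 0.0 for r in regions}
    site_non = {r: 0.0 for r in regions}
    obs_syn = {r: 0.0 for r in regions}
    obs_non = {r: 0.0 for r in regions}

    for ci in range(n_codons):
        codon = out_seq[3 * ci:3 * ci + 3]
        if "-" in codon:
            if codon != "---":
                raise ValueError(f"frame-breaking gap at codon {ci + 1}")
            continue
        if codon not in table:
            continue
        s, n = codon_site_counts(codon)
        site_syn[region_map[ci]] += s
        site_non[region_map[ci]] += n

    for sid, seq in codon_alignment.items():
        if sid == outgroup_id:
            continue
        if len(seq) != len(out_seq):
            raise ValueError("alignment sequences differ in length")
        for ci in range(n_codons):
            c1 = out_seq[3 * ci:3 * ci + 3]
            c2 = seq[3 * ci:3 * ci + 3]
            if "-" in c1 or "-" in c2:
                if (c1 != "---" and "-" in c1) or (c2 != "---" and "-" in c2):
                    raise ValueError(f"frame-breaking gap at codon {ci + 1}")
                continue
            if c1 not in table or c2 not in table:
                continue
            s, n = _pathway_counts(c1, c2)
            obs_syn[region_map[ci]] += s
            obs_non[region_map[ci]] += n

    tot_s_sites = sum(site_syn.values())
    tot_n_sites = sum(site_non.values())
    exp_s = {r: site_syn[r] / tot_s_sites for r in regions}
    exp_n = {r: site_non[r] / tot_n_sites for r in regions}
    tot_s_obs = sum(obs_syn.values())
    tot_n_obs = sum(obs_non.values())

    def pval(obs, total, prop) -> float:
        n = int(round(total))
        if n < 1:
            return float("nan")
        k = min(int(round(obs)), n)
        return float(stats.binomtest(k, n, prop,
                                     alternative="greater").pvalue)

    p_syn = {r: pval(obs_syn[r], tot_s_obs, exp_s[r]) for r in regions}
    p_non = {r: pval(obs_non[r], tot_n_obs, exp_n[r]) for r in regions}
    return RegionChangeCounts(regions, obs_syn, obs_non, exp_s, exp_n,
                              p_syn, p_non, tot_s_sites, tot_n_sites)


# ---------------------------------------------------------------------------
# locus summaries
# ---------------------------------------------------------------------------

def gc_content(seq: str) -> float:
    acgt = sum(seq.count(b) for b in "ACGT")
    return (seq.count("G") + seq.count("C")) / acgt if acgt else float("nan")


def locus_summaries(candidates, families, proximity_bp: int = 15_000
                    ) -> tuple[pd.DataFrame, dict]:
    """Per-candidate location/length/GC summaries and their aggregates.

    Distance to parent is the gap between the internal span and the parent
    span (0 if touching); interchromosomal parents get no distance.  The
    aggregate includes the intrachromosomal and <15 kb proximity
    proportions, median distance and internal length, and a Wilcoxon
    rank-sum comparison of internal GC between multicopy and single-copy
    candidates (normal approximation with tie correction for n >= 8 per
    group, exact enumeration otherwise).
    """
    multicopy_ids = set()
    for f in families:
        if f.classification == "multicopy":
            multicopy_ids.update(f.member_ids)
    rows = []
    for c in candidates:
        if not c.passed or c.parent is None:
            continue
        dist = c.parent.distance_to_candidate
        intra = dist != "interchromosomal"
        rows.append({
            "id": c.id, "chrom": c.chrom,
            "internal_len": len(c.internal_seq),
            "gc_pct": 100.0 * gc_content(c.internal_seq),
            "intrachromosomal": intra,
            "distance_bp": dist if intra else np.nan,
            "proximal": bool(intra and dist < proximity_bp),
            "multicopy": c.id in multicopy_ids,
        })
    df = pd.DataFrame(rows)
    agg: dict = {}
    if len(df):
        agg["n"] = len(df)
        agg["intrachromosomal_prop"] = float(df.intrachromosomal.mean())
        agg["proximal_prop"] = float(df.proximal.mean())
        agg["median_distance_bp"] = float(df.distance_bp.median())
        agg["median_internal_len"] = float(df.internal_len.median())
        mc = df[df.multicopy].gc_pct
        sc = df[~df.multicopy].gc_pct
        if len(mc) >= 1 and len(sc) >= 1:
            method = "asymptotic" if min(len(mc), len(sc)) >= 8 else "exact"
            res = stats.mannwhitneyu(mc, sc, alternative="two-sided",
                                     method=method)
            agg["gc_multicopy_vs_single_p"] = float(res.pvalue)
    return df, agg
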