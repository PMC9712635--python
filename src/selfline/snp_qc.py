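"""SNP quality-control cascade, relatedness pruning and the F_IS filter.

The cascade mirrors a capture-seq filtering recipe for a mixed-mating conifer
population: VCFtools-style basic filters (call rate, site quality, mean
depth), an allele-balance window over pooled heterozygote reads, an
HDplot-style read-ratio deviation score D to catch collapsed paralogs, exact
excess-heterozygosity and Hardy-Weinberg tests, a bespoke inbreeding filter
F_IS = 1 - (H_O/H_E)(1 - F_eq) that removes loci more heterozygous than the
mixed-mating equilibrium F_eq = 0.17 allows, MAF/MAC thresholds, greedy LD
pruning, and VanRaden genomic-relationship sample exclusion.

Filters report per-locus removal reasons (first filter that removed a locus)
and obey the conservation invariant: loci in = loci out + sum of removals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Callable, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .io_formats import HET, HOM_ALT, HOM_REF, MISSING, DepthTable, GenotypeTable

__all__ = [
    "LocusQC",
    "FilterStep",
    "FilterReport",
    "compute_locus_qc",
    "hwe_exact",
    "filter_basic",
    "filter_allele_balance",
    "read_ratio_deviation",
    "filter_het_excess",
    "fis_filter",
    "filter_maf_mac",
    "ld_prune",
    "grm_vanraden",
    "exclude_related",
    "run_filter_cascade",
    "DEFAULT_F_EQ",
]

#: Equilibrium fixation index used by the F_IS filter: s/(2-s) at the
#: species' selfing rate 0.3 (outcrossing 0.7), truncated to two decimals.
DEFAULT_F_EQ = 0.17


@dataclass
class LocusQC:
    """Per-locus QC statistics driving the filter cascade.

    ``stats`` has one row per locus with columns: call_rate, mean_depth,
    h_obs, h_exp, p_ref, maf, mac, n_called, allele_balance (NaN without
    heterozygous calls), d_score (NaN likewise), p_hwe, p_excess_het, f_is.
    """

    stats: pd.DataFrame
    f_eq: float = DEFAULT_F_EQ

    def __getitem__(self, col: str) -> np.ndarray:
        return self.stats[col].to_numpy()


def compute_locus_qc(
    table: GenotypeTable,
    depths: DepthTable | None = None,
    f_eq: float = DEFAULT_F_EQ,
) -> LocusQC:
    """Compute every per-locus statistic used by the cascade.

    All statistics are over called genotypes only.  H_E is the plug-in
    2*p*(1-p) with p the sample reference-allele frequency (no small-sample
    correction, matching the ratio form of the F_IS filter).  Allele balance
    is the pooled alternate-read fraction over heterozygous calls; the
    read-ratio deviation D = (sum_ref - sum_alt)/sqrt(sum_ref + sum_alt) over
    the same pooled reads.
    """
    g = table.genotypes
    if depths is not None and depths.total.shape != g.shape:
        raise ValueError("depth table dimensions do not match genotype table")

    called = g != MISSING
    n_called = called.sum(axis=0)
    n_het = (g == HET).sum(axis=0)
    n_hom_ref = (g == HOM_REF).sum(axis=0)
    n_hom_alt = (g == HOM_ALT).sum(axis=0)
    n_samples = g.shape[0]

    call_rate = n_called / n_samples if n_samples else np.zeros(g.shape[1])
    with np.errstate(invalid="ignore", divide="ignore"):
        h_obs = np.where(n_called > 0, n_het / np.maximum(n_called, 1), np.nan)
        ref_alleles = 2 * n_hom_ref + n_het
        p_ref = np.where(n_called > 0, ref_alleles / np.maximum(2 * n_called, 1), np.nan)
    h_exp = 2.0 * p_ref * (1.0 - p_ref)
    maf = np.minimum(p_ref, 1.0 - p_ref)
    mac = np.minimum(ref_alleles, 2 * n_called - ref_alleles)

    if depths is not None:
        mean_depth = depths.total.mean(axis=0)
        het_mask = g == HET
        ref_het = np.where(het_mask, depths.ref, 0).sum(axis=0)
        alt_het = np.where(het_mask, depths.alt, 0).sum(axis=0)
        tot_het = ref_het + alt_het
        with np.errstate(invalid="ignore", divide="ignore"):
            allele_balance = np.where(tot_het > 0, alt_het / np.maximum(tot_het, 1), np.nan)
            d_score = np.where(
                tot_het > 0,
                (ref_het - alt_het) / np.sqrt(np.maximum(tot_het, 1)),
                np.nan,
            )
    else:
        mean_depth = np.full(g.shape[1], np.nan)
        allele_balance = np.full(g.shape[1], np.nan)
        d_score = np.full(g.shape[1], np.nan)

    p_hwe = np.ones(g.shape[1])
    p_excess = np.ones(g.shape[1])
    variant = table.variant_mask()
    for j in np.flatnonzero(variant):
        p_hwe[j], p_excess[j] = hwe_exact(
            int(n_het[j]), int(n_hom_ref[j]), int(n_hom_alt[j])
        )

    with np.errstate(invalid="ignore", divide="ignore"):
        f_is = np.where(h_exp > 0, 1.0 - (h_obs / np.where(h_exp > 0, h_exp, 1)) * (1.0 - f_eq), np.nan)
    bad = (h_exp == 0) & (h_obs > 0)
    if bad.any():
        raise ValueError(
            f"{bad.sum()} locus/loci with H_E = 0 but H_O > 0 (inconsistent counts)"
        )

    stats = pd.DataFrame(
        {
            "call_rate": call_rate,
            "mean_depth": mean_depth,
            "h_obs": h_obs,
            "h_exp": h_exp,
            "p_ref": p_ref,
            "maf": maf,
            "mac": mac,
            "n_called": n_called,
            "allele_balance": allele_balance,
            "d_score": d_score,
            "p_hwe": p_hwe,
            "p_excess_het": p_excess,
            "f_is": f_is,
        }
    )
    return LocusQC(stats=stats, f_eq=f_eq)


def hwe_exact(n_het: int, n_hom_ref: int, n_hom_alt: int) -> tuple[float, float]:
    """Exact Hardy-Weinberg test by full enumeration of heterozygote counts.

    Conditions on the observed allele counts and enumerates every possible
    heterozygote count of matching parity.  Returns (two-sided p, one-sided
    excess-heterozygosity p).  The two-sided p sums outcomes no more probable
    than the observed configuration; the excess p sums outcomes with at least
    the observed number of heterozygotes.  No mid-p adjustment.
    """
    n = n_het + n_hom_ref + n_hom_alt
    if n == 0:
        return 1.0, 1.0
    n_a = 2 * n_hom_ref + n_het  # reference allele count
    n_rare = min(n_a, 2 * n - n_a)
    if n_rare == 0:
        return 1.0, 1.0

    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    hom_rare = (n_rare - hets) // 2
    hom_common = n - hets - hom_rare
    # P(het | n, n_rare) = n! / (h_r! h_c! het!) * 2^het * n_rare! n_common! / (2n)!
    logp = (
        gammaln(n + 1)
        - gammaln(hom_rare + 1)
        - gammaln(hom_common + 1)
        - gammaln(hets + 1)
        + hets * np.log(2.0)
        + gammaln(n_rare + 1)
        + gammaln(2 * n - n_rare + 1)
        - gammaln(2 * n + 1)
    )
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    obs = np.searchsorted(hets, n_het)
    p_obs = probs[obs]
    p_two = float(probs[probs <= p_obs * (1 + 1e-12)].sum())
    p_excess = float(probs[hets >= n_het].sum())
    return min(p_two, 1.0), min(p_excess, 1.0)


# ---------------------------------------------------------------------------
# Individual filters: each returns a boolean retain mask over all loci.
# Invariant sites pass every SNP-specific filter; the basic filter applies to
# them without the site-quality condition.
# ---------------------------------------------------------------------------

def filter_basic(
    table: GenotypeTable,
    qc: LocusQC,
    max_missing: float = 0.95,
    min_q: float = 30.0,
    min_mean_dp: float = 15.0,
    max_mean_dp: float = 60.0,
) -> np.ndarray:
    """Call rate >= max_missing, QUAL >= min_q (variants only, skipped when
    absent), min_mean_dp <= mean depth <= max_mean_dp (bounds inclusive)."""
    retain = qc["call_rate"] >= max_missing
    depth = qc["mean_depth"]
    has_depth = ~np.isnan(depth)
    retain &= ~has_depth | ((depth >= min_mean_dp) & (depth <= max_mean_dp))
    qual = table.loci["qual"].to_numpy(dtype=float)
    variant = table.variant_mask()
    has_qual = ~np.isnan(qual)
    retain &= ~(variant & has_qual & (qual < min_q))
    return retain


def filter_allele_balance(
    table: GenotypeTable,
    qc: LocusQC,
    lo: float = 0.2,
    hi: float = 0.8,
    ref_only: float = 0.01,
) -> np.ndarray:
    """Retain loci with allele balance strictly inside (lo, hi) or below
    ref_only; loci with no heterozygous calls pass vacuously."""
    ab = qc["allele_balance"]
    no_het = np.isnan(ab)
    keep = ((ab > lo) & (ab < hi)) | (ab < ref_only)
    return no_het | keep | ~table.variant_mask()


def read_ratio_deviation(
    table: GenotypeTable,
    depths: DepthTable,
    max_abs_d: float = 5.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Pooled read-ratio deviation D per locus and its retain mask |D| <= 5.

    D = (sum_ref - sum_alt) / sqrt(sum_ref + sum_alt) over reads of
    heterozygous calls; a binomial(1/2) z-score whose large values betray
    paralog-collapsed "heterozygotes".  Loci with no het calls pass.
    """
    qc = compute_locus_qc(table, depths)
    d = qc["d_score"]
    retain = np.isnan(d) | (np.abs(d) <= max_abs_d) | ~table.variant_mask()
    return d, retain


def _d_filter(table: GenotypeTable, qc: LocusQC, max_abs_d: float = 5.0) -> np.ndarray:
    d = qc["d_score"]
    return np.isnan(d) | (np.abs(d) <= max_abs_d) | ~table.variant_mask()


def filter_het_excess(
    table: GenotypeTable,
    qc: LocusQC,
    max_het: float = 0.55,
    p_excess: float = 0.05,
    p_hwe: float = 1e-5,
) -> np.ndarray:
    """Remove loci with H_O > max_het, exact excess-het p < p_excess, or
    two-sided exact HWE p < p_hwe (computed on the reference population)."""
    h_obs = qc["h_obs"]
    bad = (
        (h_obs > max_het)
        | (qc["p_excess_het"] < p_excess)
        | (qc["p_hwe"] < p_hwe)
    )
    bad &= table.variant_mask()
    bad &= ~np.isnan(h_obs)
    return ~bad


def fis_filter(
    table: GenotypeTable,
    qc: LocusQC,
    f_eq: float = DEFAULT_F_EQ,
) -> np.ndarray:
    """Remove loci with F_IS = 1 - (H_O/H_E)(1 - f_eq) strictly negative.

    A locus exactly at the mixed-mating equilibrium heterozygosity has
    F_IS = f_eq; F_IS < 0 marks more heterozygosity than even Hardy-Weinberg
    proportions inflated by 1/(1-f_eq) allow.  Monomorphic loci (H_E = 0,
    H_O = 0, F_IS undefined) pass.
    """
    h_obs, h_exp = qc["h_obs"], qc["h_exp"]
    with np.errstate(invalid="ignore", divide="ignore"):
        f_is = np.where(h_exp > 0, 1.0 - (h_obs / np.where(h_exp > 0, h_exp, 1.0)) * (1.0 - f_eq), np.nan)
    bad = (f_is < 0) & table.variant_mask()
    return ~bad


def filter_maf_mac(
    table: GenotypeTable,
    qc: LocusQC,
    maf: float | None = None,
    mac: int | None = None,
) -> np.ndarray:
    """Retain variant loci with MAF >= maf or MAC >= mac (exactly one given).

    Invariant sites are untouched (they are not SNPs); monomorphic variant
    records fail either threshold.
    """
    if (maf is None) == (mac is None):
        raise ValueError("give exactly one of maf or mac")
    variant = table.variant_mask()
    if maf is not None:
        ok = qc["maf"] >= maf
    else:
        ok = qc["mac"] >= mac
    return ok | ~variant


def ld_prune(
    table: GenotypeTable,
    r2_max: float = 0.1,
    window_bp: float = 2.17e6,
    candidate_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Greedy LD pruning: scan each scaffold in position order and drop any
    locus whose dosage r^2 with an already-retained locus within ``window_bp``
    exceeds ``r2_max``.  Deterministic given input order.  Returns the retain
    mask (invariant sites always retained)."""
    from .diversity_ld import pairwise_r2_dosage

    dosage = table.dosage()
    variant = table.variant_mask()
    retain = np.ones(table.n_loci, dtype=bool)
    consider = variant if candidate_mask is None else (variant & candidate_mask)
    pos = table.loci["pos"].to_numpy()
    for scaf, idx in table.loci.groupby("scaffold", sort=False).indices.items():
        kept: list[int] = []
        for j in idx:
            if not consider[j]:
                continue
            drop = False
            for k in reversed(kept):
                if pos[j] - pos[k] > window_bp:
                    break
                r2 = pairwise_r2_dosage(dosage[:, j], dosage[:, k])
                if r2 is not None and r2 > r2_max:
                    drop = True
                    break
            if drop:
                retain[j] = False
            else:
                kept.append(j)
    return retain


# ---------------------------------------------------------------------------
# Relatedness
# ---------------------------------------------------------------------------

def grm_vanraden(table: GenotypeTable) -> np.ndarray:
    """VanRaden genomic relationship matrix A = Z Z' / (2 sum p(1-p)).

    Z is the reference-allele dosage matrix centred by 2p per locus; missing
    dosages are imputed to 2p (a zero in Z).  Monomorphic loci contribute
    nothing to the numerator; if every locus is monomorphic the denominator
    is zero and an error is raised.
    """
    if table.n_samples < 2:
        raise ValueError("need at least two samples")
    dosage = table.dosage()[:, table.variant_mask()]
    with np.errstate(invalid="ignore"):
        p = np.nanmean(dosage, axis=0) / 2.0
    usable = ~np.isnan(p)
    dosage, p = dosage[:, usable], p[usable]
    denom = 2.0 * np.sum(p * (1.0 - p))
    if denom == 0:
        raise ValueError("all loci monomorphic: relationship matrix undefined")
    z = dosage - 2.0 * p
    z[np.isnan(z)] = 0.0
    return z @ z.T / denom


def exclude_related(
    grm: np.ndarray,
    sample_ids: Sequence[str],
    max_rel: float = 0.2,
) -> list[str]:
    """Minimal greedy exclusion so no retained pair exceeds ``max_rel``.

    Repeatedly drops the sample involved in the most violating pairs; ties
    broken by higher mean relatedness, then input order.
    """
    grm = np.asarray(grm, dtype=float)
    n = grm.shape[0]
    active = np.ones(n, dtype=bool)
    off = grm.copy()
    np.fill_diagonal(off, np.nan)
    mean_rel = np.nanmean(off, axis=1)
    excluded: list[str] = []
    while True:
        viol = (off > max_rel) & active[:, None] & active[None, :]
        counts = viol.sum(axis=1)
        if counts.max(initial=0) == 0:
            break
        top = counts.max()
        cand = np.flatnonzero((counts == top) & active)
        worst = cand[np.argmax(mean_rel[cand])]
        active[worst] = False
        excluded.append(sample_ids[worst])
    return excluded


# ---------------------------------------------------------------------------
# Cascade
# ---------------------------------------------------------------------------

@dataclass
class FilterStep:
    name: str
    params: dict[str, Any]
    n_in: int
    n_removed: int
    n_out: int


@dataclass
class FilterReport:
    """Ordered record of a filter cascade run.

    ``removal_reason[j]`` names the first filter that removed locus j (None
    for retained loci); conservation holds by construction:
    ``n_in`` of the first step = ``n_out`` of the last + total removals.
    """

    steps: list[FilterStep] = field(default_factory=list)
    removal_reason: np.ndarray | None = None
    retained: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "filter": s.name,
                    "params": ";".join(f"{k}={v}" for k, v in s.params.items()),
                    "loci_in": s.n_in,
                    "loci_removed": s.n_removed,
                    "loci_out": s.n_out,
                }
                for s in self.steps
            ]
        )

    def check_conservation(self) -> bool:
        if not self.steps:
            return True
        total_removed = sum(s.n_removed for s in self.steps)
        return self.steps[0].n_in == self.steps[-1].n_out + total_removed


#: Default cascade order, following the filtering narrative: basic ->
#: allele balance -> D -> het/HWE -> F_IS -> MAF/MAC -> LD prune.
DEFAULT_ORDER = (
    "basic",
    "allele_balance",
    "read_ratio_deviation",
    "het_excess",
    "fis",
    "maf_mac",
    "ld_prune",
)


def run_filter_cascade(
    table: GenotypeTable,
    depths: DepthTable | None = None,
    *,
    order: Sequence[str] = DEFAULT_ORDER,
    params: dict[str, dict[str, Any]] | None = None,
    f_eq: float = DEFAULT_F_EQ,
) -> tuple[GenotypeTable, DepthTable | None, FilterReport]:
    """Run the configured filter cascade and return the filtered tables.

    ``params`` overrides per-step keyword arguments, keyed by step name.
    Steps absent from ``order`` are skipped; ``maf_mac`` and ``ld_prune`` are
    skipped by default unless parameters are supplied for them (they apply to
    analysis-specific SNP subsets rather than the core panel).
    """
    params = dict(params or {})
    qc = compute_locus_qc(table, depths, f_eq=f_eq)

    steps: list[FilterStep] = []
    reason = np.full(table.n_loci, None, dtype=object)
    retained = np.ones(table.n_loci, dtype=bool)

    def apply(name: str, mask_fn: Callable[[], np.ndarray], p: dict[str, Any]) -> None:
        nonlocal retained
        n_in = int(retained.sum())
        mask = mask_fn()
        newly_removed = retained & ~mask
        reason[newly_removed] = name
        retained = retained & mask
        steps.append(FilterStep(name, p, n_in, int(newly_removed.sum()), int(retained.sum())))

    for name in order:
        p = params.get(name, {})
        if name == "basic":
            apply(name, lambda: filter_basic(table, qc, **p), p)
        elif name == "allele_balance":
            apply(name, lambda: filter_allele_balance(table, qc, **p), p)
        elif name == "read_ratio_deviation":
            if depths is None:
                continue
            apply(name, lambda: _d_filter(table, qc, **p), p)
        elif name == "het_excess":
            apply(name, lambda: filter_het_excess(table, qc, **p), p)
        elif name == "fis":
            apply(name, lambda: fis_filter(table, qc, f_eq=f_eq, **p), p)
        elif name == "maf_mac":
            if not p:
                continue
            apply(name, lambda: filter_maf_mac(table, qc, **p), p)
        elif name == "ld_prune":
            if not p:
                continue
            apply(
                name,
                lambda: ld_prune(table, candidate_mask=retained, **p) | ~retained,
                p,
            )
        else:
            raise ValueError(f"unknown filter step {name!r}")

    report = FilterReport(steps=steps, removal_reason=reason, retained=retained)
    out_table = table.subset(locus_mask=retained)
    out_depths = depths.subset(cols=retained) if depths is not None else None
    return out_table, out_depths, report
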