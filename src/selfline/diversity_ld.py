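"""Missing-data-aware diversity statistics and LD decay-model fitting.

Nucleotide diversity here follows the ratio-of-sums estimator: per site the
number of pairwise allele differences and the number of pairwise allele
comparisons among called alleles are accumulated separately, and pi is their
ratio over a region.  Keeping invariant sites in the denominator and letting
missing genotypes shrink the comparison count (rather than the estimate)
avoids the downward bias of filling missing data with reference alleles.

LD decay uses the sample-size-adjusted drift-recombination expectation of
r^2 as a function of C = rho * distance (rho = 4*Ne*r), fitted to observed
(distance, r^2) pairs by bounded nonlinear least squares.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io_formats import GenotypeTable, HET, HOM_ALT, HOM_REF, MISSING

__all__ = [
    "DiversityWindow",
    "SiteDegeneracy",
    "LDDecayFit",
    "allele_counts",
    "pi_region",
    "pi_windows",
    "dxy_region",
    "classify_degeneracy",
    "pi_by_degeneracy",
    "folded_sfs",
    "pairwise_r2_dosage",
    "pairwise_r2",
    "all_pairs_within_scaffold",
    "ld_expectation",
    "fit_ld_decay",
]


@dataclass
class DiversityWindow:
    """Summed pairwise differences/comparisons over a region.

    ``pi`` is None when no comparisons were possible (the estimate is
    absent, not zero).
    """

    region: tuple[str, int, int] | str | None
    n_diffs: float
    n_comparisons: float
    n_sites_used: int

    @property
    def pi(self) -> float | None:
        if self.n_comparisons == 0:
            return None
        return self.n_diffs / self.n_comparisons


def _region_mask(table: GenotypeTable, region: tuple[str, int, int] | None) -> np.ndarray:
    if region is None:
        return np.ones(table.n_loci, dtype=bool)
    scaf, start, end = region
    loci = table.loci
    return (
        (loci["scaffold"] == scaf) & (loci["pos"] >= start) & (loci["pos"] <= end)
    ).to_numpy()


def allele_counts(
    table: GenotypeTable, samples: Sequence[str] | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus (n_ref, n_alt) allele counts among called genotypes."""
    sub = table.subset(samples=samples) if samples is not None else table
    g = sub.genotypes
    n_ref = 2 * (g == HOM_REF).sum(axis=0) + (g == HET).sum(axis=0)
    n_alt = 2 * (g == HOM_ALT).sum(axis=0) + (g == HET).sum(axis=0)
    return n_ref, n_alt


def pi_region(
    table: GenotypeTable,
    samples: Sequence[str] | None = None,
    region: tuple[str, int, int] | None = None,
    locus_mask: np.ndarray | None = None,
) -> DiversityWindow:
    """Nucleotide diversity over a region, invariant sites included.

    Per site with m called alleles, comparisons += C(m, 2) and differences +=
    n_ref * n_alt; pi is the ratio of the sums.  Sites absent from the table
    contribute nothing (the caller controls which invariant sites are
    represented).
    """
    if samples is not None and len(samples) == 0:
        raise ValueError("empty sample set")
    mask = _region_mask(table, region)
    if locus_mask is not None:
        mask = mask & np.asarray(locus_mask, dtype=bool)
    sub = table.subset(samples=samples, locus_mask=mask) if samples is not None else table.subset(locus_mask=mask)
    n_ref, n_alt = allele_counts(sub)
    m = n_ref + n_alt
    comps = m * (m - 1) / 2.0
    diffs = n_ref * n_alt
    return DiversityWindow(
        region=region,
        n_diffs=float(diffs.sum()),
        n_comparisons=float(comps.sum()),
        n_sites_used=int((m >= 2).sum()),
    )


def pi_windows(
    table: GenotypeTable,
    samples: Sequence[str] | None = None,
    window_bp: int = 10_000,
) -> pd.DataFrame:
    """Non-overlapping windowed pi per scaffold (window size 10 kb default)."""
    sub = table.subset(samples=samples) if samples is not None else table
    n_ref, n_alt = allele_counts(sub)
    m = n_ref + n_alt
    comps = m * (m - 1) / 2.0
    diffs = (n_ref * n_alt).astype(float)
    loci = sub.loci
    win = ((loci["pos"] - 1) // window_bp).to_numpy()
    df = pd.DataFrame(
        {
            "scaffold": loci["scaffold"],
            "window": win,
            "diffs": diffs,
            "comps": comps,
            "used": (m >= 2).astype(int),
        }
    )
    agg = df.groupby(["scaffold", "window"], sort=True).sum().reset_index()
    agg["start"] = agg["window"] * window_bp + 1
    agg["end"] = (agg["window"] + 1) * window_bp
    with np.errstate(invalid="ignore", divide="ignore"):
        agg["pi"] = np.where(agg["comps"] > 0, agg["diffs"] / agg["comps"], np.nan)
    return agg[["scaffold", "start", "end", "diffs", "comps", "used", "pi"]].rename(
        columns={"diffs": "n_diffs", "comps": "n_comparisons", "used": "n_sites_used"}
    )


def dxy_region(
    table: GenotypeTable,
    pop_a: Sequence[str],
    pop_b: Sequence[str],
    region: tuple[str, int, int] | None = None,
) -> DiversityWindow:
    """Absolute divergence d_XY: cross-population allele pairs only.

    Per site, comparisons += m_A * m_B and differences += n_refA * n_altB +
    n_altA * n_refB over called alleles; sites where either population is
    entirely missing contribute no comparisons.
    """
    if set(pop_a) & set(pop_b):
        raise ValueError("populations overlap")
    mask = _region_mask(table, region)
    sub = table.subset(locus_mask=mask)
    ra, aa = allele_counts(sub, samples=list(pop_a))
    rb, ab = allele_counts(sub, samples=list(pop_b))
    ma, mb = ra + aa, rb + ab
    comps = (ma * mb).astype(float)
    diffs = (ra * ab + aa * rb).astype(float)
    return DiversityWindow(
        region=region,
        n_diffs=float(diffs.sum()),
        n_comparisons=float(comps.sum()),
        n_sites_used=int(((ma > 0) & (mb > 0)).sum()),
    )


# ---------------------------------------------------------------------------
# Codon degeneracy
# ---------------------------------------------------------------------------

@dataclass
class SiteDegeneracy:
    """Per-CDS-site degeneracy classes.

    ``table`` has columns scaffold, pos (1-based), gene, fold (0, 2, 3 or 4);
    ``skipped_genes`` lists CDSs rejected for internal stops or length not a
    multiple of three.
    """

    table: pd.DataFrame
    skipped_genes: list[str] = field(default_factory=list)

    def positions(self, fold: int) -> set[tuple[str, int]]:
        sel = self.table[self.table["fold"] == fold]
        return set(zip(sel["scaffold"], sel["pos"]))

    def mask_for(self, table: GenotypeTable, fold: int) -> np.ndarray:
        pos = self.positions(fold)
        keys = zip(table.loci["scaffold"], table.loci["pos"])
        return np.fromiter((k in pos for k in keys), dtype=bool, count=table.n_loci)


def classify_degeneracy(
    cds_records: Iterable[tuple[str, str, list[tuple[int, int]], str]],
    sequences: Mapping[str, str],
) -> SiteDegeneracy:
    """Classify CDS sites as 0/2/3/4-fold degenerate (standard codon table).

    ``cds_records`` yields (gene_id, scaffold, [(start, end), ...], strand)
    with 1-based inclusive exon spans in genomic order; minus-strand CDSs are
    reverse-complemented before codon reading.  A site is 4-fold when every
    nucleotide at its codon position yields the same amino acid and 0-fold
    when every change is nonsynonymous.  Stop codons are excluded; a CDS with
    an internal stop (or a length not divisible by three) is skipped and
    reported in ``skipped_genes``.
    """
    from Bio.Data.CodonTable import standard_dna_table
    from Bio.Seq import Seq

    fwd = standard_dna_table.forward_table
    stops = set(standard_dna_table.stop_codons)
    bases = "ACGT"

    def aa(codon: str) -> str | None:
        return None if codon in stops else fwd.get(codon)

    rows = []
    skipped: list[str] = []
    for gene_id, scaffold, spans, strand in cds_records:
        seq = "".join(
            str(sequences[scaffold][start - 1 : end]) for start, end in spans
        ).upper()
        positions = [p for start, end in spans for p in range(start, end + 1)]
        if strand == "-":
            seq = str(Seq(seq).reverse_complement())
            positions = positions[::-1]
        if len(seq) % 3 != 0:
            skipped.append(gene_id)
            continue
        codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
        if any(c in stops for c in codons[:-1]):
            skipped.append(gene_id)
            continue
        gene_rows = []
        ok = True
        for ci, codon in enumerate(codons):
            if codon in stops:
                continue  # terminal stop: excluded
            if aa(codon) is None or any(b not in bases for b in codon):
                ok = False
                break
            for offset in range(3):
                same = sum(
                    1
                    for b in bases
                    if aa(codon[:offset] + b + codon[offset + 1 :]) == aa(codon)
                )
                fold = {1: 0, 2: 2, 3: 3, 4: 4}[same]
                gene_rows.append(
                    {
                        "scaffold": scaffold,
                        "pos": positions[3 * ci + offset],
                        "gene": gene_id,
                        "fold": fold,
                    }
                )
        if ok:
            rows.extend(gene_rows)
        else:
            skipped.append(gene_id)
    return SiteDegeneracy(
        table=pd.DataFrame(rows, columns=["scaffold", "pos", "gene", "fold"]),
        skipped_genes=skipped,
    )


def pi_by_degeneracy(
    table: GenotypeTable,
    degeneracy: SiteDegeneracy,
    samples: Sequence[str] | None = None,
) -> tuple[float | None, float | None, float | None]:
    """(pi_0, pi_4, pi_0/pi_4) over 0- and 4-fold degenerate sites.

    The ratio indexes the strength of purifying selection on amino-acid
    changes; it is absent when pi_4 is zero or undefined.
    """
    pi0 = pi_region(table, samples=samples, locus_mask=degeneracy.mask_for(table, 0)).pi
    pi4 = pi_region(table, samples=samples, locus_mask=degeneracy.mask_for(table, 4)).pi
    ratio = None
    if pi0 is not None and pi4 not in (None, 0.0):
        ratio = pi0 / pi4
    return pi0, pi4, ratio


# ---------------------------------------------------------------------------
# Folded SFS
# ---------------------------------------------------------------------------

def folded_sfs(
    table: GenotypeTable,
    samples: Sequence[str] | None = None,
    projection: int | None = None,
) -> np.ndarray:
    """Folded site-frequency spectrum over biallelic variant loci.

    Without projection, only fully called loci contribute (complete-case) and
    bins run 0..n_samples by minor-allele count.  With ``projection`` m, each
    locus with at least m called alleles adds its hypergeometric projection
    mass to bins 0..floor(m/2); loci with fewer called alleles are dropped.
    """
    sub = table.subset(samples=samples) if samples is not None else table
    sub = sub.subset(locus_mask=sub.variant_mask())
    n_ref, n_alt = allele_counts(sub)
    m_avail = n_ref + n_alt
    n_total = 2 * sub.n_samples

    if projection is None:
        full = m_avail == n_total
        minor = np.minimum(n_ref, n_alt)[full]
        sfs = np.zeros(n_total // 2 + 1)
        np.add.at(sfs, minor, 1.0)
        return sfs

    if projection < 2 or projection > n_total:
        raise ValueError("projection size out of range")
    sfs = np.zeros(projection // 2 + 1)
    usable = m_avail >= projection
    for na, m in zip(n_alt[usable], m_avail[usable]):
        j = np.arange(projection + 1)
        pmf = stats.hypergeom.pmf(j, m, na, projection)
        folded = np.minimum(j, projection - j)
        np.add.at(sfs, folded, pmf)
    return sfs


# ---------------------------------------------------------------------------
# Linkage disequilibrium
# ---------------------------------------------------------------------------

def pairwise_r2_dosage(x: np.ndarray, y: np.ndarray) -> float | None:
    """Squared Pearson correlation of two dosage vectors over samples called
    at both loci (composite LD); None when under two shared calls or either
    locus has zero variance."""
    both = ~(np.isnan(x) | np.isnan(y))
    if both.sum() < 2:
        return None
    xv, yv = x[both], y[both]
    sx, sy = xv.std(), yv.std()
    if sx == 0 or sy == 0:
        return None
    r = ((xv - xv.mean()) * (yv - yv.mean())).mean() / (sx * sy)
    return float(r * r)


def pairwise_r2(table: GenotypeTable, locus_i: int, locus_j: int) -> float | None:
    dosage = table.dosage()
    return pairwise_r2_dosage(dosage[:, locus_i], dosage[:, locus_j])


def all_pairs_within_scaffold(
    table: GenotypeTable,
    maf: float = 0.05,
    max_pairs: int | None = None,
) -> np.ndarray:
    """All same-scaffold (distance, r^2) pairs among variant loci with
    MAF >= ``maf`` (no distance cap).  Returns an (n_pairs, 2) array."""
    from .snp_qc import compute_locus_qc

    qc = compute_locus_qc(table)
    ok = table.variant_mask() & (qc["maf"] >= maf)
    dosage = table.dosage()
    pos = table.loci["pos"].to_numpy()
    out: list[tuple[float, float]] = []
    for scaf, idx in table.loci.groupby("scaffold", sort=False).indices.items():
        idx = [j for j in idx if ok[j]]
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                i, j = idx[a], idx[b]
                r2 = pairwise_r2_dosage(dosage[:, i], dosage[:, j])
                if r2 is None:
                    continue
                out.append((abs(float(pos[j] - pos[i])), r2))
                if max_pairs is not None and len(out) >= max_pairs:
                    return np.asarray(out)
    return np.asarray(out) if out else np.empty((0, 2))


def ld_expectation(
    c: float | np.ndarray, n: int, adjusted: bool = True
) -> float | np.ndarray:
    """Expected r^2 under drift-recombination equilibrium at C = rho * d.

    ``adjusted=True`` (default) applies the sample-size/low-mutation
    correction:

        E(r^2) = [(10+C) / ((2+C)(11+C))] *
                 [1 + ((3+C)(12+12C+C^2)) / (n(2+C)(11+C))]

    and tends to 1/n for large C; ``adjusted=False`` gives the bare
    1/(1+C).
    """
    if n < 2:
        raise ValueError("sample size n must be at least 2")
    c = np.asarray(c, dtype=float)
    if (c < 0).any():
        raise ValueError("C must be non-negative")
    if not adjusted:
        out = 1.0 / (1.0 + c)
    else:
        # clamp to avoid float overflow far out on the curve; the expectation
        # is already within ~1e-9 of its 1/n asymptote there
        c = np.minimum(c, 1e9)
        first = (10.0 + c) / ((2.0 + c) * (11.0 + c))
        second = 1.0 + ((3.0 + c) * (12.0 + 12.0 * c + c**2)) / (
            n * (2.0 + c) * (11.0 + c)
        )
        out = first * second
    return float(out) if out.ndim == 0 else out


@dataclass
class LDDecayFit:
    """Fitted LD decay curve r^2(d) = E(r^2)(C_hat * d, n).

    ``c_per_bp`` is the recombination-scale parameter per base pair
    (C at distance d is c_per_bp * d).  Derived distances are solved on the
    fitted curve and are None when the target level is outside its range;
    ``half_decay_bp`` is where the curve falls to half the 90th percentile of
    the observed r^2 values.
    """

    c_per_bp: float
    n: int
    rss: float
    n_pairs: int
    r2_p90: float
    half_decay_bp: float | None
    d_at_r2: dict[float, float | None]

    def predict(self, d: float | np.ndarray) -> float | np.ndarray:
        return ld_expectation(self.c_per_bp * np.asarray(d, dtype=float), self.n)


def _solve_distance(c_per_bp: float, n: int, level: float) -> float | None:
    """Distance where the fitted curve crosses ``level`` (bisection)."""
    if c_per_bp <= 0:
        return None
    top = ld_expectation(0.0, n)
    if level >= top:
        return None
    lo, hi = 1e-9, 1.0
    for _ in range(200):
        if ld_expectation(c_per_bp * hi, n) < level:
            break
        hi *= 2.0
    else:
        return None
    return float(optimize.brentq(
        lambda d: ld_expectation(c_per_bp * d, n) - level, lo, hi, xtol=1e-6
    ))


def fit_ld_decay(
    pairs: np.ndarray,
    n: int,
    thresholds: Sequence[float] = (0.2, 0.1),
    min_pairs: int = 50,
) -> LDDecayFit:
    """Least-squares fit of the adjusted decay expectation to (d, r^2) pairs.

    Unweighted nonlinear least squares over c_per_bp >= 0 with multi-start on
    a log grid 1e-8..1e-4 (plus a moment-style start), converged to relative
    SSE 1e-10.  Raises on fewer than ``min_pairs`` usable pairs or if every
    start fails.
    """
    pairs = np.asarray(pairs, dtype=float)
    pairs = pairs[pairs[:, 0] > 0]
    if len(pairs) < min_pairs:
        raise ValueError(f"need at least {min_pairs} pairs with positive distance")
    d, r2 = pairs[:, 0], pairs[:, 1]

    def residuals(log_c: np.ndarray) -> np.ndarray:
        return ld_expectation(np.exp(log_c[0]) * d, n) - r2

    best: tuple[float, float] | None = None  # (sse, c)
    starts = list(np.log(np.logspace(-8, -4, 9)))
    for x0 in starts:
        try:
            sol = optimize.least_squares(
                residuals, x0=[x0], method="lm", xtol=1e-14, ftol=1e-14, gtol=1e-14
            )
        except Exception:
            continue
        sse = float(np.sum(sol.fun**2))
        if best is None or sse < best[0] * (1 - 1e-10) :
            best = (sse, float(np.exp(sol.x[0])))
    if best is None:
        raise RuntimeError("LD decay fit failed from every start")
    sse, c_hat = best

    # a flat curve (c -> 0) can win when data carry no decay signal
    flat_sse = float(np.sum((ld_expectation(0.0, n) - r2) ** 2))
    if flat_sse < sse:
        sse, c_hat = flat_sse, 0.0

    p90 = float(np.percentile(r2, 90))
    return LDDecayFit(
        c_per_bp=c_hat,
        n=n,
        rss=sse,
        n_pairs=len(pairs),
        r2_p90=p90,
        half_decay_bp=_solve_distance(c_hat, n, 0.5 * p90),
        d_at_r2={float(x): _solve_distance(c_hat, n, float(x)) for x in thresholds},
    )
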