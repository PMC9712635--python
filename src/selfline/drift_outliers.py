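"""Drift-deviation outlier test for selfing-line fixation patterns.

Under pure drift a locus heterozygous in the FS founder has probability
(1/2)^t of still being heterozygous after t generations of selfing, the
remainder splitting evenly between fixation for either allele — at S4:
6.25% heterozygous and 46.875% fixed for each homozygote.  Each selfing line
is an independent replicate; a chi-square goodness-of-fit test per locus
(df = 2, lines with data in at least three lines) against these proportions,
Benjamini-Hochberg corrected across tested loci, flags loci whose fixation
behaviour drift cannot explain.  Fisher's exact test then asks whether
annotation categories are enriched among the significant loci.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import (
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    AnnotationTable,
    PedigreeTable,
)
from .selfing_lines import CorrectedLineGenotypes

__all__ = [
    "FixationCounts",
    "expected_fixation_proportions",
    "tabulate_fixation",
    "chi2_drift_test",
    "exact_multinomial_test",
    "bh_fdr",
    "fisher_enrichment",
]


def expected_fixation_proportions(t: int) -> tuple[float, float, float]:
    """(P(het), P(fixed ref), P(fixed alt)) after t selfed generations.

    P(het) = (1/2)^t; the complement splits evenly between the homozygotes.
    t = 4 gives (0.0625, 0.46875, 0.46875).
    """
    if t < 0:
        raise ValueError("generation index must be non-negative")
    p_het = 0.5**t
    p_fix = (1.0 - p_het) / 2.0
    return (p_het, p_fix, p_fix)


@dataclass
class FixationCounts:
    """Per-locus S4 fixation tallies over FS-heterozygous lines.

    One row per tested locus: locus index into the corrected table, k (lines
    contributing: FS heterozygous and a non-missing call at the target
    generation), and counts n_het, n_hom_ref, n_hom_alt at that generation.
    """

    counts: pd.DataFrame
    generation: str
    t: int


def tabulate_fixation(
    corrected: CorrectedLineGenotypes,
    ped: PedigreeTable | None = None,
    generation: str = "S4",
    min_lines: int = 3,
) -> FixationCounts:
    """Tally S4 fixation categories over lines whose FS call is heterozygous.

    Only FS-heterozygous line x locus cells contribute; loci with fewer than
    ``min_lines`` contributing lines are excluded from testing.  S5 is never
    substituted for a missing S4.
    """
    data = corrected.kept()
    if generation not in data.generations:
        raise ValueError(f"generation {generation!r} absent from corrected data")
    gi = data.generations.index(generation)
    fs = data.genotypes[:, 0, :]  # FS is the first generation by construction
    target = data.genotypes[:, gi, :]

    eligible = (fs == HET) & (target != MISSING)
    n_het = ((target == HET) & eligible).sum(axis=0)
    n_ref = ((target == HOM_REF) & eligible).sum(axis=0)
    n_alt = ((target == HOM_ALT) & eligible).sum(axis=0)
    k = eligible.sum(axis=0)

    tested = k >= min_lines
    df = pd.DataFrame(
        {
            "locus": np.flatnonzero(tested),
            "scaffold": data.loci.loc[tested, "scaffold"].to_numpy(),
            "pos": data.loci.loc[tested, "pos"].to_numpy(),
            "k": k[tested],
            "n_het": n_het[tested],
            "n_hom_ref": n_ref[tested],
            "n_hom_alt": n_alt[tested],
        }
    )
    return FixationCounts(counts=df, generation=generation,
                          t=int(generation[1:]) if generation != "FS" else 0)


def chi2_drift_test(
    fix: FixationCounts,
    t: int | None = None,
    fdr: float = 0.05,
    exact: bool = False,
) -> pd.DataFrame:
    """Chi-square goodness-of-fit of fixation counts to drift proportions.

    chi^2 = sum (obs - exp)^2 / exp over the three categories with expected
    counts k * expected_fixation_proportions(t), df = 2, no continuity
    correction, upper-tail asymptotic p (used even at small k, matching the
    study procedure; ``exact=True`` swaps in an exact multinomial test).
    BH q-values and the FDR rejection set are appended across tested loci;
    direction flags mark categories with observed > expected counts.
    """
    if t is None:
        t = fix.t
    p_het, p_ref, p_alt = expected_fixation_proportions(t)
    df = fix.counts.copy()
    if df.empty:
        for col in ("exp_het", "exp_hom_ref", "exp_hom_alt", "chi2", "p", "q",
                    "significant", "excess_het", "excess_fix_ref", "excess_fix_alt"):
            df[col] = pd.Series(dtype=float)
        return df
    k = df["k"].to_numpy(dtype=float)
    exp = np.column_stack([p_het * k, p_ref * k, p_alt * k])
    obs = df[["n_het", "n_hom_ref", "n_hom_alt"]].to_numpy(dtype=float)
    chi2 = ((obs - exp) ** 2 / exp).sum(axis=1)
    if exact:
        pvals = np.array([
            exact_multinomial_test(o.astype(int), (p_het, p_ref, p_alt))
            for o in obs
        ])
    else:
        pvals = stats.chi2.sf(chi2, df=2)
    q, reject = bh_fdr(pvals, q=fdr)
    df["exp_het"], df["exp_hom_ref"], df["exp_hom_alt"] = exp.T
    df["chi2"] = chi2
    df["p"] = pvals
    df["q"] = q
    df["significant"] = reject
    df["excess_het"] = obs[:, 0] > exp[:, 0]
    df["excess_fix_ref"] = obs[:, 1] > exp[:, 1]
    df["excess_fix_alt"] = obs[:, 2] > exp[:, 2]
    return df


def exact_multinomial_test(
    observed: np.ndarray, probs: tuple[float, float, float]
) -> float:
    """Exact multinomial goodness-of-fit p: total probability of outcomes no
    more likely than the observed triple (small-k alternative to chi-square)."""
    observed = np.asarray(observed, dtype=int)
    k = int(observed.sum())
    p = np.asarray(probs, dtype=float)
    p_obs = stats.multinomial.pmf(observed, k, p)
    total = 0.0
    for a in range(k + 1):
        for b in range(k - a + 1):
            c = k - a - b
            pm = stats.multinomial.pmf([a, b, c], k, p)
            if pm <= p_obs * (1 + 1e-12):
                total += pm
    return min(total, 1.0)


def bh_fdr(pvalues: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: returns (q-values, rejection mask)."""
    pvalues = np.asarray(pvalues, dtype=float)
    if pvalues.size == 0:
        return pvalues.copy(), np.zeros(0, dtype=bool)
    reject, qvals, _, _ = multipletests(pvalues, alpha=q, method="fdr_bh")
    return qvals, reject


def fisher_enrichment(
    categories: pd.Series,
    significant: np.ndarray,
) -> pd.DataFrame:
    """Per-category 2x2 Fisher's exact test of enrichment among outliers.

    ``categories`` holds one label per tested locus (NaN = unannotated,
    skipped); ``significant`` is the outlier mask over the same loci.  For
    each observed category the table (in category x significant) is tested
    two-sided; the odds ratio reports direction (>1 over-represented among
    significant loci).
    """
    categories = pd.Series(categories).reset_index(drop=True)
    significant = np.asarray(significant, dtype=bool)
    if len(categories) != len(significant):
        raise ValueError("categories and significance mask lengths differ")
    annotated = categories.notna().to_numpy()
    rows = []
    for cat in sorted(categories.dropna().unique()):
        in_cat = (categories == cat).to_numpy() & annotated
        a = int((in_cat & significant).sum())
        b = int((in_cat & ~significant).sum())
        c = int((~in_cat & annotated & significant).sum())
        d = int((~in_cat & annotated & ~significant).sum())
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        rows.append(
            {"category": cat, "n_significant": a, "n_not_significant": b,
             "n_other_significant": c, "n_other_not": d,
             "odds_ratio": odds, "p": p}
        )
    return pd.DataFrame(rows)
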