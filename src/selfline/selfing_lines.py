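"""Selfing-line genotype correction, imputation and inbreeding trajectories.

Under single-seed descent a homozygote breeds true and a heterozygote child
requires a heterozygote parent.  Two correction rules follow: (1) two
consecutive identical homozygous calls force that homozygote for every later
generation; (2) two consecutive heterozygous calls force heterozygosity for
every earlier generation back to the founding FS outcross.  Loci where the
rules contradict each other cannot be explained by any selfing history and
are removed.  The same logic imputes a missing S3 generation from S2/S4 where
only one genotype is possible.

Trajectories: observed per-locus heterozygosity per generation is compared
with the halving expectation (half the previous generation's observed value),
and per-sample inbreeding F_UNI (correlation between uniting gametes) with
the complete-selfing recurrence F_{t+1} = (1 + F_t)/2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import (
    GENERATIONS,
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    GenotypeTable,
    PedigreeTable,
)

__all__ = [
    "PROV_OBSERVED",
    "PROV_CORRECTED",
    "PROV_IMPUTED",
    "PROV_MISSING",
    "CorrectedLineGenotypes",
    "correct_line",
    "correct_vectors",
    "impute_s3_vector",
    "correct_panel",
    "heterozygosity_trajectory",
    "f_uni",
    "expected_f_trajectory",
]

# provenance codes
PROV_OBSERVED, PROV_CORRECTED, PROV_IMPUTED, PROV_MISSING = 0, 1, 2, 3

_UNSET = -2  # internal marker: no rule assignment


def correct_vectors(v: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised correction of (N, T) generation-ordered genotype vectors.

    Applies both rules using the observed calls only (a single scan; no
    re-triggering on corrected values, so correction is idempotent by
    construction).  MISSING entries neither trigger nor block a rule but are
    overwritten when a rule covers their slot.

    Returns (corrected, provenance, removed) where ``removed`` marks vectors
    whose rule assignments contradict each other.
    """
    v = np.asarray(v, dtype=np.int8)
    squeeze = v.ndim == 1
    if squeeze:
        v = v[None, :]
    n, t = v.shape
    assigned = np.full((n, t), _UNSET, dtype=np.int8)
    conflict = np.zeros(n, dtype=bool)

    def assign(mask: np.ndarray, slot: int, value: np.ndarray) -> None:
        nonlocal conflict
        cur = assigned[:, slot]
        clash = mask & (cur != _UNSET) & (cur != value)
        conflict |= clash
        write = mask & (cur == _UNSET)
        assigned[write, slot] = value[write] if value.ndim else value

    for i in range(t - 1):
        a, b = v[:, i], v[:, i + 1]
        hom_pair = (a == b) & ((a == HOM_REF) | (a == HOM_ALT))
        if hom_pair.any():
            for slot in range(i, t):  # trigger slots and all subsequent
                assign(hom_pair, slot, a)
        het_pair = (a == HET) & (b == HET)
        if het_pair.any():
            het_val = np.full(n, HET, dtype=np.int8)
            for slot in range(0, i + 2):  # all preceding slots and the trigger
                assign(het_pair, slot, het_val)

    corrected = np.where(assigned != _UNSET, assigned, v).astype(np.int8)
    provenance = np.full((n, t), PROV_OBSERVED, dtype=np.int8)
    provenance[(assigned != _UNSET) & (v == MISSING)] = PROV_IMPUTED
    provenance[(assigned != _UNSET) & (v != MISSING) & (assigned != v)] = PROV_CORRECTED
    provenance[corrected == MISSING] = PROV_MISSING
    # removed vectors keep their observed values
    corrected[conflict] = v[conflict]
    provenance[conflict] = np.where(
        v[conflict] == MISSING, PROV_MISSING, PROV_OBSERVED
    ).astype(np.int8)
    if squeeze:
        return corrected[0], provenance[0], conflict[0]
    return corrected, provenance, conflict


def correct_line(vector: np.ndarray) -> tuple[np.ndarray, str]:
    """Correct one FS->Sn genotype vector; returns (vector, status).

    Vectors shorter than two generations cannot trigger a rule and come back
    unchanged with status ``"kept"``.
    """
    v = np.asarray(vector, dtype=np.int8)
    if v.size < 2:
        return v.copy(), "kept"
    corrected, _, removed = correct_vectors(v)
    if removed:
        return v.copy(), "removed_uncorrectable"
    return corrected, "kept"


def impute_s3_vector(
    s2: np.ndarray, s4: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Impute S3 from corrected S2/S4 calls under selfing constraints.

    Returns (s3, impossible): S3 is forced when no other genotype is possible
    (identical flanking homozygotes, or a heterozygous S4 which requires a
    heterozygous parent); a heterozygous S2 with homozygous S4 leaves two
    possibilities and stays MISSING; contradictory flanks (different
    homozygotes, or homozygous S2 with heterozygous S4) are impossible under
    selfing and flag the locus for removal.
    """
    s2 = np.asarray(s2, dtype=np.int8)
    s4 = np.asarray(s4, dtype=np.int8)
    s3 = np.full(s2.shape, MISSING, dtype=np.int8)
    s2_hom = (s2 == HOM_REF) | (s2 == HOM_ALT)
    s4_hom = (s4 == HOM_REF) | (s4 == HOM_ALT)
    s3[(s4 == HET) & ~s2_hom] = HET
    same_hom = s2_hom & s4_hom & (s2 == s4)
    s3[same_hom] = s2[same_hom]
    impossible = (s2_hom & (s4 == HET)) | (s2_hom & s4_hom & (s2 != s4))
    return s3, impossible


@dataclass
class CorrectedLineGenotypes:
    """Corrected selfing-line genotypes with per-entry provenance.

    ``genotypes`` and ``provenance`` have shape (n_lines, n_generations,
    n_loci); ``generations`` is the ordered global label list (FS first);
    ``locus_kept`` is False for loci removed as uncorrectable in any line.
    """

    line_ids: list[str]
    generations: list[str]
    loci: pd.DataFrame
    genotypes: np.ndarray
    provenance: np.ndarray
    locus_kept: np.ndarray

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def kept(self) -> "CorrectedLineGenotypes":
        m = self.locus_kept
        return CorrectedLineGenotypes(
            line_ids=self.line_ids,
            generations=self.generations,
            loci=self.loci.loc[m].reset_index(drop=True),
            genotypes=self.genotypes[:, :, m],
            provenance=self.provenance[:, :, m],
            locus_kept=np.ones(int(m.sum()), dtype=bool),
        )

    def to_genotype_table(self, ped: PedigreeTable) -> GenotypeTable:
        """Flatten back to a GenotypeTable of the pedigree's samples (kept loci)."""
        kept = self.kept()
        sample_ids: list[str] = []
        rows: list[np.ndarray] = []
        for li, line in enumerate(self.line_ids):
            for gi, gen in enumerate(self.generations):
                sample = ped.sample_for(line, gen)
                if sample is None:
                    continue
                sample_ids.append(sample)
                rows.append(kept.genotypes[li, gi])
        geno = np.stack(rows) if rows else np.empty((0, kept.n_loci), dtype=np.int8)
        return GenotypeTable(sample_ids=sample_ids, loci=kept.loci.copy(), genotypes=geno)


def correct_panel(
    table: GenotypeTable,
    ped: PedigreeTable,
    impute_s3: bool = True,
    remove_per_line: bool = False,
) -> CorrectedLineGenotypes:
    """Apply the correction rules to every line of a selfing panel.

    A rule conflict removes the locus globally across all lines (removal is
    per-SNP, not per cell) unless ``remove_per_line`` is set, in which case
    only the conflicting line's vector reverts to its observed calls.  Lines
    without an S3 sample get S3 imputed from S2/S4 when ``impute_s3``.
    """
    max_gen = 0
    for line in ped.line_ids():
        for gen in ped.generations_present(line):
            max_gen = max(max_gen, GENERATIONS.index(gen))
    gens = list(GENERATIONS[: max_gen + 1])
    line_ids = ped.line_ids()
    n_lines, n_gens, n_loci = len(line_ids), len(gens), table.n_loci

    geno = np.full((n_lines, n_gens, n_loci), MISSING, dtype=np.int8)
    has_sample = np.zeros((n_lines, n_gens), dtype=bool)
    for li, line in enumerate(line_ids):
        for gi, gen in enumerate(gens):
            sample = ped.sample_for(line, gen)
            if sample is not None and sample in table.sample_ids:
                geno[li, gi] = table.genotypes[table.sample_index(sample)]
                has_sample[li, gi] = True

    flat = geno.transpose(0, 2, 1).reshape(n_lines * n_loci, n_gens)
    corrected, prov, removed = correct_vectors(flat)
    corrected = corrected.reshape(n_lines, n_loci, n_gens).transpose(0, 2, 1)
    prov = prov.reshape(n_lines, n_loci, n_gens).transpose(0, 2, 1)
    removed = removed.reshape(n_lines, n_loci)

    if impute_s3 and "S3" in gens and "S4" in gens:
        gi3, gi2, gi4 = gens.index("S3"), gens.index("S2"), gens.index("S4")
        for li in range(n_lines):
            if has_sample[li, gi3]:
                continue
            s3, impossible = impute_s3_vector(corrected[li, gi2], corrected[li, gi4])
            fill = (corrected[li, gi3] == MISSING) & (s3 != MISSING)
            corrected[li, gi3, fill] = s3[fill]
            prov[li, gi3, fill] = PROV_IMPUTED
            removed[li] |= impossible

    if remove_per_line:
        bad = removed
        for li in range(n_lines):
            mask = bad[li]
            corrected[li][:, mask] = geno[li][:, mask]
            prov[li][:, mask] = np.where(
                geno[li][:, mask] == MISSING, PROV_MISSING, PROV_OBSERVED
            )
        locus_kept = np.ones(n_loci, dtype=bool)
    else:
        locus_kept = ~removed.any(axis=0)

    return CorrectedLineGenotypes(
        line_ids=line_ids,
        generations=gens,
        loci=table.loci.copy(),
        genotypes=corrected,
        provenance=prov,
        locus_kept=locus_kept,
    )


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------

def expected_f_trajectory(f0: float, n_generations: int) -> np.ndarray:
    """Iterate F_{t+1} = (1 + F_t)/2 from F0; closed form 1 - (1-F0)/2^t.

    Returns the expected inbreeding coefficient at generations 1..n.
    """
    if not -1.0 <= f0 <= 1.0:
        raise ValueError("F0 must be in [-1, 1]")
    t = np.arange(1, n_generations + 1)
    return 1.0 - (1.0 - f0) / 2.0**t


def f_uni(table: GenotypeTable, allele_freq: np.ndarray | None = None) -> pd.Series:
    """Per-sample inbreeding from the correlation between uniting gametes.

    For dosage x in {0,1,2} and population reference-allele frequency p the
    per-locus term is (x^2 - (1+2p)x + 2p^2) / (2p(1-p)); the sample value is
    its mean over non-missing polymorphic loci.  ``allele_freq`` defaults to
    the plug-in frequency of the same table.
    """
    dosage = table.dosage()
    variant = table.variant_mask()
    if allele_freq is None:
        with np.errstate(invalid="ignore"):
            p = np.nanmean(dosage, axis=0) / 2.0
    else:
        p = np.asarray(allele_freq, dtype=float)
    usable = variant & ~np.isnan(p) & (p > 0) & (p < 1)
    x = dosage[:, usable]
    pu = p[usable]
    with np.errstate(invalid="ignore"):
        term = (x**2 - (1 + 2 * pu) * x + 2 * pu**2) / (2 * pu * (1 - pu))
    f = np.nanmean(term, axis=1)
    n_used = (~np.isnan(term)).sum(axis=1)
    f = np.where(n_used > 0, f, np.nan)
    return pd.Series(f, index=table.sample_ids, name="f_uni")


def heterozygosity_trajectory(
    corrected: CorrectedLineGenotypes,
    ped: PedigreeTable,
    f_by_sample: pd.Series | None = None,
) -> pd.DataFrame:
    """Observed vs expected heterozygosity and inbreeding per generation.

    Per generation and locus, H is the fraction of heterozygous lines among
    lines with a non-missing call; the expectation at generation g is half
    the previous generation's observed H at the same locus (per-locus first,
    then averaged).  A two-sided exact sign test compares per-locus observed
    and expected H (ties dropped); a one-sample t-test compares the
    generation's per-sample F_UNI with the complete-selfing recurrence value
    seeded at the FS mean.

    Returns one row per generation with columns: generation, n_lines,
    mean_h_obs, median_h_obs, mean_h_exp, median_h_exp, sign_test_p,
    mean_f, expected_f, t_test_p.
    """
    data = corrected.kept()
    geno = data.genotypes  # (lines, gens, loci)
    gens = data.generations

    het = geno == HET
    called = geno != MISSING
    n_called = called.sum(axis=0)  # (gens, loci)
    with np.errstate(invalid="ignore", divide="ignore"):
        h_obs = np.where(n_called > 0, het.sum(axis=0) / np.maximum(n_called, 1), np.nan)

    if f_by_sample is None and ped is not None:
        f_by_sample = f_uni(data.to_genotype_table(ped))

    f0 = np.nan
    if f_by_sample is not None:
        fs_samples = [
            ped.sample_for(line, "FS")
            for line in data.line_ids
            if ped.sample_for(line, "FS") in f_by_sample.index
        ]
        if fs_samples:
            f0 = float(np.nanmean(f_by_sample.loc[fs_samples]))
    exp_f = (
        expected_f_trajectory(f0, len(gens) - 1)
        if np.isfinite(f0)
        else np.full(len(gens) - 1, np.nan)
    )

    rows = []
    for gi, gen in enumerate(gens):
        obs = h_obs[gi]
        row: dict[str, object] = {
            "generation": gen,
            "n_lines": int(called[:, gi, :].any(axis=1).sum()),
            "mean_h_obs": float(np.nanmean(obs)) if np.isfinite(obs).any() else np.nan,
            "median_h_obs": float(np.nanmedian(obs)) if np.isfinite(obs).any() else np.nan,
        }
        if gi == 0:
            row.update(mean_h_exp=np.nan, median_h_exp=np.nan, sign_test_p=np.nan)
        else:
            exp = 0.5 * h_obs[gi - 1]
            both = np.isfinite(obs) & np.isfinite(exp)
            row["mean_h_exp"] = float(np.nanmean(exp[both])) if both.any() else np.nan
            row["median_h_exp"] = float(np.nanmedian(exp[both])) if both.any() else np.nan
            diff = obs[both] - exp[both]
            nz = diff[diff != 0]
            if nz.size:
                res = stats.binomtest(int((nz > 0).sum()), nz.size, 0.5)
                row["sign_test_p"] = float(res.pvalue)
            else:
                row["sign_test_p"] = 1.0 if both.any() else np.nan

        f_gen = np.nan
        t_p = np.nan
        if f_by_sample is not None:
            samples = [
                ped.sample_for(line, gen)
                for line in data.line_ids
                if ped.sample_for(line, gen) in f_by_sample.index
            ]
            vals = f_by_sample.loc[samples].dropna().to_numpy() if samples else np.array([])
            if vals.size:
                f_gen = float(vals.mean())
                if gi > 0 and np.isfinite(exp_f[gi - 1]) and vals.size > 1 and np.ptp(vals) > 0:
                    t_p = float(stats.ttest_1samp(vals, exp_f[gi - 1]).pvalue)
        row["mean_f"] = f_gen
        row["expected_f"] = float(exp_f[gi - 1]) if gi > 0 else f0
        row["t_test_p"] = t_p
        rows.append(row)
    return pd.DataFrame(rows)
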