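"""Shared data model and readers/writers for the formats the pipeline touches.

The common currency of every stage is a :class:`GenotypeTable`: a samples x loci
matrix of diploid genotype codes plus per-locus metadata.  Invariant sites
(records with no alternate allele) travel in the same table with
``is_variant=False`` so that diversity denominators can stream one structure.

Genotype codes are small integers (``HOM_REF``/``HET``/``HOM_ALT``/``MISSING``)
stored in an int8 matrix; the reference-allele dosage x in {0, 1, 2} used by
inbreeding and relatedness estimators is derived from them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

# Genotype codes. MISSING is negative so that ``codes >= 0`` masks called cells.
HOM_REF: int = 0
HET: int = 1
HOM_ALT: int = 2
MISSING: int = -1

GENOTYPE_CODES = (HOM_REF, HET, HOM_ALT, MISSING)

#: Ordered generation labels of a selfing line: the initial full-sib outcross
#: followed by up to five generations of single-seed-descent selfing.
GENERATIONS: tuple[str, ...] = ("FS", "S1", "S2", "S3", "S4", "S5")

# Reference-allele dosage per code; MISSING maps to NaN.
_DOSAGE = {HOM_REF: 2.0, HET: 1.0, HOM_ALT: 0.0, MISSING: np.nan}


class VcfParseError(ValueError):
    """Malformed VCF input; the message names the offending record."""


class PloidyError(ValueError):
    """A genotype call was not diploid."""


@dataclass
class GenotypeTable:
    """Samples x loci matrix of diploid genotype codes with locus metadata.

    Parameters
    ----------
    sample_ids
        Unique sample identifiers, one per matrix row.
    loci
        DataFrame with one row per matrix column and columns ``scaffold``
        (str), ``pos`` (1-based int), ``ref``, ``alt`` (single-character
        nucleotides; ``alt`` empty for invariant sites), ``is_variant``
        (bool) and optional ``qual`` (site quality, NaN when absent).
    genotypes
        int8 matrix of genotype codes, shape (n_samples, n_loci).
    """

    sample_ids: list[str]
    loci: pd.DataFrame
    genotypes: np.ndarray

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.sample_ids), len(self.loci)):
            raise ValueError(
                f"genotype matrix shape {self.genotypes.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.loci)} loci"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample_ids are not unique")
        if "qual" not in self.loci.columns:
            self.loci = self.loci.assign(qual=np.nan)
        self.loci = self.loci.reset_index(drop=True)
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        """Enforce the table invariants; raise ``ValueError`` on violation."""
        if not np.isin(self.genotypes, GENOTYPE_CODES).all():
            raise ValueError("genotype matrix contains codes outside the vocabulary")
        key = list(zip(self.loci["scaffold"], self.loci["pos"]))
        if len(set(key)) != len(key):
            raise ValueError("duplicate (scaffold, position) pairs")
        pos_sorted = self.loci.groupby("scaffold", sort=False)["pos"].apply(
            lambda s: s.is_monotonic_increasing
        )
        if not pos_sorted.all():
            raise ValueError("positions not sorted within scaffold")
        inv = ~self.loci["is_variant"].to_numpy(dtype=bool)
        if inv.any():
            bad = np.isin(self.genotypes[:, inv], (HET, HOM_ALT)).any()
            if bad:
                raise ValueError("invariant locus carries HET/HOM_ALT codes")

    # -- conveniences -------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def sample_index(self, sample_id: str) -> int:
        return self.sample_ids.index(sample_id)

    def dosage(self) -> np.ndarray:
        """Reference-allele dosage matrix in {0, 1, 2}; MISSING -> NaN."""
        out = np.empty(self.genotypes.shape, dtype=float)
        for code, d in _DOSAGE.items():
            out[self.genotypes == code] = d
        return out

    def subset(
        self,
        samples: Sequence[str] | None = None,
        locus_mask: np.ndarray | None = None,
    ) -> "GenotypeTable":
        """Return a new table restricted to the given samples and/or loci."""
        rows = (
            [self.sample_index(s) for s in samples]
            if samples is not None
            else list(range(self.n_samples))
        )
        if locus_mask is None:
            locus_mask = np.ones(self.n_loci, dtype=bool)
        locus_mask = np.asarray(locus_mask)
        if locus_mask.dtype != bool:
            idx = np.zeros(self.n_loci, dtype=bool)
            idx[locus_mask] = True
            locus_mask = idx
        return GenotypeTable(
            sample_ids=[self.sample_ids[i] for i in rows],
            loci=self.loci.loc[locus_mask].reset_index(drop=True),
            genotypes=self.genotypes[np.ix_(rows, np.flatnonzero(locus_mask))],
        )

    def variant_mask(self) -> np.ndarray:
        return self.loci["is_variant"].to_numpy(dtype=bool)


@dataclass
class DepthTable:
    """Per sample x locus read depths aligned with a :class:`GenotypeTable`."""

    total: np.ndarray
    ref: np.ndarray
    alt: np.ndarray

    def __post_init__(self) -> None:
        self.total = np.asarray(self.total, dtype=np.int32)
        self.ref = np.asarray(self.ref, dtype=np.int32)
        self.alt = np.asarray(self.alt, dtype=np.int32)
        if not (self.total.shape == self.ref.shape == self.alt.shape):
            raise ValueError("depth matrices have mismatched shapes")
        if (self.total < 0).any() or (self.ref < 0).any() or (self.alt < 0).any():
            raise ValueError("negative read depths")
        if (self.ref + self.alt > self.total).any():
            raise ValueError("ref_depth + alt_depth exceeds total_depth")

    def subset(self, rows: Sequence[int] | None = None, cols: np.ndarray | None = None) -> "DepthTable":
        r = np.asarray(rows) if rows is not None else np.arange(self.total.shape[0])
        if cols is None:
            c = np.arange(self.total.shape[1])
        else:
            cols = np.asarray(cols)
            c = np.flatnonzero(cols) if cols.dtype == bool else cols
        ix = np.ix_(r, c)
        return DepthTable(self.total[ix], self.ref[ix], self.alt[ix])


class PedigreeError(ValueError):
    """Invalid pedigree structure (duplicate slot or unknown generation)."""


@dataclass
class PedigreeTable:
    """Selfing-line structure: line id -> generation label -> sample id.

    Each sample occupies at most one (line, generation) slot and generation
    labels come from the fixed ordered set ``FS, S1..S5``.
    """

    lines: dict[str, dict[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: dict[str, tuple[str, str]] = {}
        for line_id, gens in self.lines.items():
            for gen, sample in gens.items():
                if gen not in GENERATIONS:
                    raise PedigreeError(f"unknown generation label {gen!r} in line {line_id!r}")
                if sample in seen:
                    raise PedigreeError(
                        f"sample {sample!r} assigned to both {seen[sample]} and ({line_id}, {gen})"
                    )
                seen[sample] = (line_id, gen)
            # keep generations in canonical order
            self.lines[line_id] = {g: gens[g] for g in GENERATIONS if g in gens}

    def line_ids(self) -> list[str]:
        return list(self.lines)

    def sample_for(self, line_id: str, generation: str) -> str | None:
        return self.lines.get(line_id, {}).get(generation)

    def generations_present(self, line_id: str) -> list[str]:
        return list(self.lines[line_id])

    def samples(self) -> list[str]:
        return [s for gens in self.lines.values() for s in gens.values()]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (line, gen, sample)
            for line, gens in self.lines.items()
            for gen, sample in gens.items()
        ]
        return pd.DataFrame(rows, columns=["line_id", "generation", "sample_id"])


@dataclass
class AnnotationTable:
    """Per-locus consequence annotation (VEP-style), one row per locus key.

    ``consequence`` values are free-form category labels (missense,
    synonymous, intergenic, ...); ``gene`` and ``go_ids`` are optional.
    """

    table: pd.DataFrame  # columns: scaffold, pos, consequence, gene, go_ids

    def __post_init__(self) -> None:
        required = {"scaffold", "pos", "consequence"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"annotation table missing columns {required - set(self.table.columns)}")
        for col in ("gene", "go_ids"):
            if col not in self.table.columns:
                self.table[col] = ""

    def consequence_for(self, table: GenotypeTable) -> pd.Series:
        """Consequence label per locus of ``table`` (NaN where unannotated)."""
        key = pd.MultiIndex.from_frame(table.loci[["scaffold", "pos"]])
        ann = self.table.set_index(["scaffold", "pos"])["consequence"]
        ann = ann[~ann.index.duplicated()]
        return pd.Series(ann.reindex(key).to_numpy(), index=range(len(key)))


# ---------------------------------------------------------------------------
# VCF reading / writing
# ---------------------------------------------------------------------------

def read_vcf(
    path: str | Path,
    region: tuple[str, int, int] | None = None,
    multiallelic: str = "skip",
) -> tuple[GenotypeTable, DepthTable]:
    """Read a VCF 4.x file into a genotype and depth table.

    GT is mapped ``0/0 -> HOM_REF``, ``0/1``/``1/0`` -> ``HET``, ``1/1 ->
    HOM_ALT``, anything containing a missing allele -> ``MISSING`` (half-calls
    are treated as missing).  Phase is ignored.  Records with no alternate
    allele are flagged ``is_variant=False``.  Multi-allelic records are
    skipped with a warning (``multiallelic="skip"``) or raise
    (``multiallelic="error"``); the number skipped is logged and stored on the
    returned table as ``table.n_skipped_multiallelic``.

    Parameters
    ----------
    region
        Optional (scaffold, start, end) filter, 1-based inclusive.
    """
    from cyvcf2 import VCF

    if multiallelic not in ("skip", "error"):
        raise ValueError("multiallelic must be 'skip' or 'error'")

    try:
        vcf = VCF(str(path), gts012=False)
    except Exception as exc:  # htslib reports the offending line itself
        raise VcfParseError(f"cannot parse VCF {path}: {exc}") from exc

    sample_ids = list(vcf.samples)
    scaffolds: list[str] = []
    positions: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    is_variant: list[bool] = []
    quals: list[float] = []
    geno_rows: list[np.ndarray] = []
    dp_rows: list[np.ndarray] = []
    ad_ref_rows: list[np.ndarray] = []
    ad_alt_rows: list[np.ndarray] = []
    n_skipped = 0

    n = len(sample_ids)
    for var in vcf:
        if region is not None:
            scaf, start, end = region
            if var.CHROM != scaf or not (start <= var.POS <= end):
                continue
        if len(var.ALT) > 1:
            if multiallelic == "error":
                raise VcfParseError(
                    f"multi-allelic record at {var.CHROM}:{var.POS} (ALT={var.ALT})"
                )
            n_skipped += 1
            continue
        variant = len(var.ALT) == 1
        codes = np.full(n, MISSING, dtype=np.int8)
        for i, g in enumerate(var.genotypes):
            alleles = g[:-1]
            if len(alleles) != 2:
                raise PloidyError(
                    f"non-diploid call ({len(alleles)} alleles) at "
                    f"{var.CHROM}:{var.POS} sample {sample_ids[i]}"
                )
            a, b = alleles
            if a < 0 or b < 0:
                codes[i] = MISSING
            else:
                codes[i] = a + b  # 0/0->0, 0/1->1, 1/1->2
        if not variant:
            codes[codes > 0] = MISSING  # defensive; GT should be 0/0 or ./.

        def fmt(tag: str):
            try:
                return var.format(tag)
            except KeyError:  # tag absent from the header
                return None

        dp = fmt("DP")
        dp_row = (
            np.maximum(dp[:, 0], 0).astype(np.int32)
            if dp is not None
            else np.zeros(n, dtype=np.int32)
        )
        ad = fmt("AD")
        if ad is not None:
            ad = np.maximum(ad, 0)
            ref_row = ad[:, 0].astype(np.int32)
            alt_row = ad[:, 1].astype(np.int32) if ad.shape[1] > 1 else np.zeros(n, np.int32)
        else:
            ref_row = np.zeros(n, dtype=np.int32)
            alt_row = np.zeros(n, dtype=np.int32)
        if dp is None and ad is not None:
            dp_row = ref_row + alt_row

        scaffolds.append(var.CHROM)
        positions.append(var.POS)
        refs.append(var.REF)
        alts.append(var.ALT[0] if variant else "")
        is_variant.append(variant)
        quals.append(var.QUAL if var.QUAL is not None else np.nan)
        geno_rows.append(codes)
        dp_rows.append(np.maximum(dp_row, ref_row + alt_row))
        ad_ref_rows.append(ref_row)
        ad_alt_rows.append(alt_row)

    if n_skipped:
        logger.warning("skipped %d multi-allelic record(s) in %s", n_skipped, path)

    loci = pd.DataFrame(
        {
            "scaffold": scaffolds,
            "pos": positions,
            "ref": refs,
            "alt": alts,
            "is_variant": is_variant,
            "qual": quals,
        }
    )
    geno = (
        np.stack(geno_rows, axis=1) if geno_rows else np.empty((n, 0), dtype=np.int8)
    )
    table = GenotypeTable(sample_ids=sample_ids, loci=loci, genotypes=geno)
    table.n_skipped_multiallelic = n_skipped  # type: ignore[attr-defined]
    depths = DepthTable(
        total=np.stack(dp_rows, axis=1) if dp_rows else np.empty((n, 0), np.int32),
        ref=np.stack(ad_ref_rows, axis=1) if ad_ref_rows else np.empty((n, 0), np.int32),
        alt=np.stack(ad_alt_rows, axis=1) if ad_alt_rows else np.empty((n, 0), np.int32),
    )
    return table, depths


_GT_STRING = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}


def write_vcf(
    table: GenotypeTable,
    depths: DepthTable | None,
    path: str | Path,
) -> None:
    """Write the table as an uncompressed VCF 4.2 file.

    Round-trip contract: ``read_vcf(write_vcf(T))`` reproduces genotype codes,
    positions and alleles exactly.  Invariant sites are written with
    ``ALT=.``; missing genotypes as ``./.``.
    """
    table.validate()
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        for scaf in dict.fromkeys(table.loci["scaffold"]):
            fh.write(f"##contig=<ID={scaf}>\n")
        cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
        fh.write("\t".join(cols + table.sample_ids) + "\n")
        fmt = "GT:AD:DP" if depths is not None else "GT"
        for j in range(table.n_loci):
            row = table.loci.iloc[j]
            alt = row["alt"] if row["is_variant"] else "."
            qual = "." if pd.isna(row["qual"]) else f"{row['qual']:g}"
            fields = [
                str(row["scaffold"]),
                str(int(row["pos"])),
                ".",
                row["ref"],
                alt,
                qual,
                "PASS",
                ".",
                fmt,
            ]
            for i in range(table.n_samples):
                gt = _GT_STRING[int(table.genotypes[i, j])]
                if depths is not None:
                    fields.append(
                        f"{gt}:{depths.ref[i, j]},{depths.alt[i, j]}:{depths.total[i, j]}"
                    )
                else:
                    fields.append(gt)
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# Pedigree / annotation TSV
# ---------------------------------------------------------------------------

def read_pedigree(path: str | Path) -> PedigreeTable:
    """Read a pedigree TSV with columns line_id, generation, sample_id."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"line_id", "generation", "sample_id"}
    if not required.issubset(df.columns):
        raise PedigreeError(f"pedigree TSV missing columns {required - set(df.columns)}")
    lines: dict[str, dict[str, str]] = {}
    for line_id, gen, sample in df[["line_id", "generation", "sample_id"]].itertuples(index=False):
        slot = lines.setdefault(line_id, {})
        if gen in slot:
            raise PedigreeError(f"duplicate slot ({line_id}, {gen})")
        slot[gen] = sample
    return PedigreeTable(lines=lines)


def write_pedigree(ped: PedigreeTable, path: str | Path) -> None:
    ped.to_frame().to_csv(path, sep="\t", index=False)


def read_annotation(path: str | Path) -> AnnotationTable:
    """Read an annotation TSV (scaffold, pos, consequence[, gene, go_ids])."""
    df = pd.read_csv(path, sep="\t", dtype={"scaffold": str, "pos": int})
    return AnnotationTable(table=df)
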