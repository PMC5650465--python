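"""Data model and I/O for genotypes, pedigrees, sample metadata.

Coordinates are 1-based and inclusive throughout (VCF convention and the
convention of printed genome-browser intervals such as ``9:5360823-7243520``).
Genotype calls are encoded as integers: ``0`` hom-ref, ``1`` het, ``2``
hom-alt, ``-1`` missing.  Missing genotypes are never silently imputed by
any reader or filter in this package.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

HOM_REF: int = 0
HET: int = 1
HOM_ALT: int = 2
MISSING: int = -1

#: sentinel used for an unknown/absent parent in pedigree files
FOUNDER_SENTINEL = "0"


class Cohort(str, Enum):
    MODEL_PEDIGREE = "model_pedigree"
    AFFECTED_PETS = "affected_pets"
    CONTROL_PETS_1 = "control_pets_1"
    CONTROL_PETS_2 = "control_pets_2"
    EXTERNAL_CONTROL = "external_control"


class SryStatus(str, Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"
    UNTESTED = "untested"


class PhenotypeCode(str, Enum):
    UNAFFECTED = "unaffected"
    XX_DSD = "xx_dsd"
    XY_MALE = "xy_male"
    UNKNOWN = "unknown"


class GonadClass(str, Enum):
    OV = "ov"
    OVT_LT_HALF_T = "ovt_lt_half_t"
    OVT_GT_HALF_T = "ovt_gt_half_t"
    T = "t"
    NONE_RECORDED = "none_recorded"


class CoreIOError(Exception):
    """Base class for malformed inputs."""


class VcfParseError(CoreIOError):
    pass


class ReconciliationError(CoreIOError):
    """Sample sets of two inputs that must describe the same cohort differ."""


@dataclass(frozen=True)
class VariantSite:
    """One biallelic site; ``pos`` is the 1-based VCF POS."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt must differ at {self.chrom}:{self.pos}")

    @property
    def vtype(self) -> str:
        return "snp" if len(self.ref) == 1 and len(self.alt) == 1 else "indel"

    @property
    def key(self) -> tuple[str, int]:
        return (self.chrom, self.pos)


@dataclass(frozen=True)
class GenomicInterval:
    """1-based inclusive interval, e.g. the 1.9 Mb candidate segment."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"start > end: {self}")

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end

    def jaccard(self, other: "GenomicInterval") -> float:
        """Overlap / union in bp; 0 for intervals on different chromosomes."""
        if self.chrom != other.chrom:
            return 0.0
        inter = min(self.end, other.end) - max(self.start, other.start) + 1
        if inter <= 0:
            return 0.0
        union = max(self.end, other.end) - min(self.start, other.start) + 1
        return inter / union


@dataclass
class SampleRecord:
    """Metadata for one dog: parentage, breed, cohort, SRY assay, phenotype.

    Diagnostic invariants: an XX DSD diagnosis requires an SRY-negative
    assay, and an XY male classification requires SRY-positive.
    """

    sample_id: str
    sire_id: str = FOUNDER_SENTINEL
    dam_id: str = FOUNDER_SENTINEL
    breed: str = ""
    cohort: Cohort = Cohort.MODEL_PEDIGREE
    sry_status: SryStatus = SryStatus.UNTESTED
    phenotype_code: PhenotypeCode = PhenotypeCode.UNKNOWN
    gonad_class: GonadClass = GonadClass.NONE_RECORDED

    def __post_init__(self) -> None:
        if (
            self.phenotype_code is PhenotypeCode.XX_DSD
            and self.sry_status is not SryStatus.NEGATIVE
        ):
            raise ValueError(
                f"{self.sample_id}: xx_dsd phenotype requires sry_status=negative"
            )
        if (
            self.phenotype_code is PhenotypeCode.XY_MALE
            and self.sry_status is not SryStatus.POSITIVE
        ):
            raise ValueError(
                f"{self.sample_id}: xy_male phenotype requires sry_status=positive"
            )

    @property
    def is_founder(self) -> bool:
        return self.sire_id == FOUNDER_SENTINEL and self.dam_id == FOUNDER_SENTINEL


class PedigreeGraph:
    """Sire/dam DAG with founder breed labels.

    The expected fraction of a founder breed carried by any individual is
    the mean of its parents' fractions; founders contribute 1 for their own
    breed and 0 otherwise.  An unknown parent (sentinel ``"0"``) contributes
    0 to every named breed.
    """

    def __init__(
        self,
        parents: Mapping[str, tuple[str, str]],
        founder_breed: Mapping[str, str],
    ) -> None:
        self.parents: dict[str, tuple[str, str]] = {
            k: (s, d) for k, (s, d) in parents.items()
        }
        self.founder_breed: dict[str, str] = dict(founder_breed)
        self._check_acyclic()
        self._frac_cache: dict[tuple[str, str], float] = {}

    @classmethod
    def from_samples(cls, records: Iterable[SampleRecord]) -> "PedigreeGraph":
        parents = {}
        founder_breed = {}
        for r in records:
            if r.is_founder:
                founder_breed[r.sample_id] = r.breed
            else:
                parents[r.sample_id] = (r.sire_id, r.dam_id)
        return cls(parents, founder_breed)

    @property
    def nodes(self) -> list[str]:
        seen = dict.fromkeys(self.founder_breed)
        for child, (s, d) in self.parents.items():
            for n in (s, d, child):
                if n != FOUNDER_SENTINEL:
                    seen.setdefault(n)
        return list(seen)

    @property
    def founders(self) -> list[str]:
        return [n for n in self.nodes if n not in self.parents]

    def _check_acyclic(self) -> None:
        WHITE, GREY, BLACK = 0, 1, 2
        state: dict[str, int] = {}

        def visit(node: str, stack: list[str]) -> None:
            state[node] = GREY
            for p in self.parents.get(node, ()):  # founders have no entry
                if p == FOUNDER_SENTINEL:
                    continue
                st = state.get(p, WHITE)
                if st == GREY:
                    raise ValueError(f"pedigree cycle through {p}")
                if st == WHITE:
                    visit(p, stack + [p])
            state[node] = BLACK

        for n in list(self.parents):
            if state.get(n, WHITE) == WHITE:
                visit(n, [n])

    def breed_fraction(self, sample_id: str, breed: str) -> float:
        """Expected genome fraction of ``breed`` background for ``sample_id``."""
        key = (sample_id, breed)
        if key in self._frac_cache:
            return self._frac_cache[key]
        if sample_id == FOUNDER_SENTINEL:
            out = 0.0
        elif sample_id not in self.parents:
            out = 1.0 if self.founder_breed.get(sample_id) == breed else 0.0
        else:
            sire, dam = self.parents[sample_id]
            out = 0.5 * (self.breed_fraction(sire, breed) + self.breed_fraction(dam, breed))
        self._frac_cache[key] = out
        return out

    def topological_order(self) -> list[str]:
        """Parents before offspring."""
        order: list[str] = []
        done: set[str] = set()

        def visit(n: str) -> None:
            if n in done or n == FOUNDER_SENTINEL:
                return
            for p in self.parents.get(n, ()):  # founders first
                visit(p)
            done.add(n)
            order.append(n)

        for n in self.nodes:
            visit(n)
        return order


@dataclass
class GenotypeMatrix:
    """Samples x biallelic sites with integer calls.

    ``calls`` has shape ``(n_samples, n_sites)`` and dtype int8 with values
    in ``{0, 1, 2, -1}``.
    """

    sites: list[VariantSite]
    samples: list[str]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.sites)):
            raise ValueError(
                f"calls shape {self.calls.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(self.sites)} sites"
            )
        bad = ~np.isin(self.calls, (HOM_REF, HET, HOM_ALT, MISSING))
        if bad.any():
            raise ValueError("calls must be in {0,1,2,-1}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def call_rate(self) -> np.ndarray:
        """Per-site fraction of non-missing calls."""
        if self.n_samples == 0:
            return np.zeros(self.n_sites)
        return (self.calls != MISSING).mean(axis=0)

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.samples.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample {sample_id!r}") from None

    def site_index(self, chrom: str, pos: int) -> int:
        for i, s in enumerate(self.sites):
            if s.chrom == chrom and s.pos == pos:
                return i
        raise KeyError(f"no site at {chrom}:{pos}")

    def subset_sites(self, indices: Sequence[int]) -> "GenotypeMatrix":
        idx = np.asarray(indices, dtype=int)
        return GenotypeMatrix(
            [self.sites[i] for i in idx], list(self.samples), self.calls[:, idx]
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.sample_index(s) for s in sample_ids]
        return GenotypeMatrix(list(self.sites), list(sample_ids), self.calls[idx, :])

    def dosage(self, mean_impute: bool = False) -> np.ndarray:
        """Float alt-dosage matrix; missing as NaN, or column-mean imputed."""
        d = self.calls.astype(float)
        d[self.calls == MISSING] = np.nan
        if mean_impute:
            col_mean = np.nanmean(np.where(np.isnan(d), np.nan, d), axis=0)
            col_mean = np.nan_to_num(col_mean)
            nan_r, nan_c = np.nonzero(np.isnan(d))
            d[nan_r, nan_c] = col_mean[nan_c]
        return d

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.sites == other.sites
            and self.samples == other.samples
            and np.array_equal(self.calls, other.calls)
        )


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read genotypes (GT only) from a VCF v4.x file.

    Multi-allelic records are split into one biallelic site per alternate
    allele (warning logged); in each split record alleles belonging to a
    different alternate are counted as reference.  Half-calls and ``./.``
    become missing.
    """
    from cyvcf2 import VCF

    path = Path(path)
    with open(path, "rt") as fh:
        first = fh.readline()
    if not first.startswith("##fileformat=VCF"):
        raise VcfParseError(
            f"{path}: line 1 is not a VCF header ('##fileformat=VCF...'): {first[:60]!r}"
        )
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    sites: list[VariantSite] = []
    columns: list[np.ndarray] = []
    for var in vcf:
        alts = var.ALT
        if len(alts) > 1:
            log.warning(
                "splitting multi-allelic record %s:%d into %d biallelic sites",
                var.CHROM, var.POS, len(alts),
            )
        gts = var.genotypes  # [allele0, allele1, phased] per sample
        for ai, alt in enumerate(alts, start=1):
            col = np.full(len(samples), MISSING, dtype=np.int8)
            for si, g in enumerate(gts):
                a0, a1 = g[0], g[1]
                if a0 < 0 or a1 < 0:
                    continue  # missing or half-call
                col[si] = int(a0 == ai) + int(a1 == ai)
            sites.append(VariantSite(var.CHROM, var.POS, var.REF, alt))
            columns.append(col)
    calls = (
        np.stack(columns, axis=1)
        if columns
        else np.zeros((len(samples), 0), dtype=np.int8)
    )
    return GenotypeMatrix(sites, samples, calls)


_GT_STR = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}


def write_vcf(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal VCF v4.2 with GT fields, bit-stably for fixed input."""
    path = Path(path)
    chroms = list(dict.fromkeys(s.chrom for s in matrix.sites))
    with open(path, "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=caninedsd\n")
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.samples)
            + "\n"
        )
        for j, site in enumerate(matrix.sites):
            gts = "\t".join(_GT_STR[int(c)] for c in matrix.calls[:, j])
            fh.write(
                f"{site.chrom}\t{site.pos}\t.\t{site.ref}\t{site.alt}\t.\tPASS\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# PLINK text PED/MAP
# ---------------------------------------------------------------------------

def read_plink_text(
    ped_path: str | Path,
    map_path: str | Path,
    ref_alleles: Sequence[str] | None = None,
) -> tuple[GenotypeMatrix, list[SampleRecord]]:
    """Read whitespace-delimited PLINK text PED/MAP.

    PLINK text carries no reference designation: unless ``ref_alleles`` is
    supplied, the first non-missing allele seen at each site defines ref.
    The allele code ``0`` is missing.  The PED phenotype column is read
    (1 -> unaffected, 2 -> xx_dsd) but the sample table remains the
    phenotype authority downstream.
    """
    map_rows = []
    with open(map_path) as fh:
        for line in fh:
            if line.strip():
                map_rows.append(line.split())
    n_sites = len(map_rows)
    samples: list[str] = []
    records: list[SampleRecord] = []
    allele_rows: list[list[tuple[str, str]]] = []
    with open(ped_path) as fh:
        for line in fh:
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 6 + 2 * n_sites:
                raise CoreIOError(
                    f"PED row has {len(parts)} columns; MAP implies "
                    f"{6 + 2 * n_sites} (6 + 2 x {n_sites} sites)"
                )
            _fid, iid, sire, dam, _sex, pheno = parts[:6]
            samples.append(iid)
            if pheno == "2":
                code, sry = PhenotypeCode.XX_DSD, SryStatus.NEGATIVE
            elif pheno == "1":
                code, sry = PhenotypeCode.UNAFFECTED, SryStatus.UNTESTED
            else:
                code, sry = PhenotypeCode.UNKNOWN, SryStatus.UNTESTED
            records.append(
                SampleRecord(iid, sire, dam, phenotype_code=code, sry_status=sry)
            )
            alleles = parts[6:]
            allele_rows.append(
                [(alleles[2 * j], alleles[2 * j + 1]) for j in range(n_sites)]
            )

    calls = np.full((len(samples), n_sites), MISSING, dtype=np.int8)
    sites: list[VariantSite] = []
    for j, row in enumerate(map_rows):
        chrom, _snp_id, _cm, pos = row[0], row[1], row[2], int(row[3])
        ref = ref_alleles[j] if ref_alleles is not None else None
        alt = None
        for i in range(len(samples)):
            a, b = allele_rows[i][j]
            if a == "0" or b == "0":
                continue
            for allele in (a, b):
                if ref is None:
                    ref = allele
                elif alt is None and allele != ref:
                    alt = allele
            calls[i, j] = int(a != ref) + int(b != ref)
        if ref is None:
            ref = "N"
        if alt is None:
            alt = "."  # monomorphic in this file
        sites.append(VariantSite(chrom, pos, ref, alt))
    return GenotypeMatrix(sites, samples, calls), records


def write_plink_text(
    matrix: GenotypeMatrix,
    ped_path: str | Path,
    map_path: str | Path,
    records: Sequence[SampleRecord] | None = None,
) -> None:
    """Write PLINK text PED/MAP (ref/alt letters of each site as alleles)."""
    rec_by_id = {r.sample_id: r for r in records} if records else {}
    with open(map_path, "wt") as fh:
        for s in matrix.sites:
            fh.write(f"{s.chrom}\t{s.chrom}:{s.pos}\t0\t{s.pos}\n")
    with open(ped_path, "wt") as fh:
        for i, sid in enumerate(matrix.samples):
            r = rec_by_id.get(sid)
            sire = r.sire_id if r else FOUNDER_SENTINEL
            dam = r.dam_id if r else FOUNDER_SENTINEL
            pheno = {
                PhenotypeCode.UNAFFECTED: "1",
                PhenotypeCode.XX_DSD: "2",
            }.get(r.phenotype_code if r else PhenotypeCode.UNKNOWN, "0")
            fields = ["FAM", sid, sire, dam, "0", pheno]
            for j, site in enumerate(matrix.sites):
                c = int(matrix.calls[i, j])
                if c == MISSING:
                    fields += ["0", "0"]
                elif c == HOM_REF:
                    fields += [site.ref, site.ref]
                elif c == HET:
                    fields += [site.ref, site.alt]
                else:
                    fields += [site.alt, site.alt]
            fh.write(" ".join(fields) + "\n")


# ---------------------------------------------------------------------------
# Sample / pedigree metadata TSV
# ---------------------------------------------------------------------------

SAMPLE_TABLE_COLUMNS = [
    "sample_id", "sire", "dam", "breed", "cohort", "sry", "phenotype", "gonad",
]

_PHENO_OUT = {
    PhenotypeCode.UNAFFECTED: "1",
    PhenotypeCode.XX_DSD: "2",
    PhenotypeCode.XY_MALE: "xy_male",
    PhenotypeCode.UNKNOWN: "unknown",
}
_PHENO_IN = {v: k for k, v in _PHENO_OUT.items()}


def write_sample_table(records: Sequence[SampleRecord], path: str | Path) -> None:
    with open(path, "wt") as fh:
        fh.write("\t".join(SAMPLE_TABLE_COLUMNS) + "\n")
        for r in records:
            fh.write(
                "\t".join(
                    [
                        r.sample_id, r.sire_id, r.dam_id, r.breed,
                        r.cohort.value, r.sry_status.value,
                        _PHENO_OUT[r.phenotype_code], r.gonad_class.value,
                    ]
                )
                + "\n"
            )


def read_sample_table(path: str | Path) -> list[SampleRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing_cols = set(SAMPLE_TABLE_COLUMNS) - set(df.columns)
    if missing_cols:
        raise CoreIOError(f"sample table missing columns: {sorted(missing_cols)}")
    out = []
    for row in df.itertuples(index=False):
        out.append(
            SampleRecord(
                sample_id=row.sample_id,
                sire_id=row.sire or FOUNDER_SENTINEL,
                dam_id=row.dam or FOUNDER_SENTINEL,
                breed=row.breed,
                cohort=Cohort(row.cohort),
                sry_status=SryStatus(row.sry),
                phenotype_code=_PHENO_IN[row.phenotype],
                gonad_class=GonadClass(row.gonad),
            )
        )
    return out


def reconcile_samples(
    matrix: GenotypeMatrix, records: Sequence[SampleRecord]
) -> None:
    """Raise unless the genotype matrix and metadata cover the same samples."""
    m, r = set(matrix.samples), {x.sample_id for x in records}
    if m != r:
        raise ReconciliationError(
            f"sample mismatch: only-in-genotypes={sorted(m - r)[:5]}, "
            f"only-in-metadata={sorted(r - m)[:5]}"
        )


# ---------------------------------------------------------------------------
# Genotype summaries
# ---------------------------------------------------------------------------

def allele_frequency(
    hom_ref: float,
    het: float,
    hom_alt: float,
    other: float = 0.0,
    third_allele_policy: str = "non_carrier",
) -> float:
    """Alt-allele frequency from genotype-class tallies (counts or fractions).

    ``other`` tallies samples carrying a third, non-insertion allele at the
    locus.  Under the default ``"non_carrier"`` policy they contribute two
    non-alternate alleles to the denominator; under ``"exclude"`` they are
    dropped from numerator and denominator.
    """
    if third_allele_policy not in ("non_carrier", "exclude"):
        raise ValueError(f"unknown third_allele_policy {third_allele_policy!r}")
    denom_classes = hom_ref + het + hom_alt
    if third_allele_policy == "non_carrier":
        denom_classes += other
    if denom_classes <= 0:
        raise ValueError("undefined allele frequency: zero genotyped samples")
    return (2.0 * hom_alt + het) / (2.0 * denom_classes)


def allele_frequency_from_fractions(f_het: float, f_hom_alt: float) -> float:
    """AF from genotype-class fractions of all genotyped samples.

    The remainder ``1 - f_het - f_hom_alt`` is treated as carrying two
    non-alternate alleles, so ``AF = f_hom_alt + f_het / 2``.  With the
    published cohort percentages this reproduces the printed frequencies
    exactly (e.g. het 75%, hom 3% -> 0.405).
    """
    if f_het < 0 or f_hom_alt < 0 or f_het + f_hom_alt > 1 + 1e-12:
        raise ValueError("fractions must be nonnegative and sum to <= 1")
    return f_hom_alt + f_het / 2.0


def call_rate_filter(
    matrix: GenotypeMatrix, min_rate: float
) -> tuple[GenotypeMatrix, list[VariantSite]]:
    """Drop sites whose call rate is below ``min_rate``; order preserved."""
    if not 0 <= min_rate <= 1:
        raise ValueError("min_rate must be in [0, 1]")
    rates = matrix.call_rate()
    keep = np.nonzero(rates >= min_rate)[0]
    dropped = [matrix.sites[i] for i in np.nonzero(rates < min_rate)[0]]
    return matrix.subset_sites(keep), dropped


# ---------------------------------------------------------------------------
# Packaged reference table
# ---------------------------------------------------------------------------

def load_model_pedigree_genotypes() -> pd.DataFrame:
    """Curated genotype-histology table for the XX DSD model pedigree.

    Sanger-confirmed genotypes at the CFA9:6048201 guanine-insertion locus
    for the affected dogs of the ACS/BGL model pedigree plus the five
    breeding-stock dams with female external genitalia that produced
    affected offspring (``breeding_stock == 1``).
    """
    with resources.files("caninedsd.data").joinpath(
        "model_pedigree_insertion_genotypes.tsv"
    ).open() as fh:
        df = pd.read_csv(fh, sep="\t", dtype={"breeding_stock": int})
    return df
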