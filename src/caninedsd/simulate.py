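"""Forward simulator for pedigrees, genotypes, phenotypes, crosses, cohorts
and expression tables.

The generator emulates the statistical structure of the XX DSD mapping
study: a two-founder-breed pedigree (a carrier-breed sire crossed to
non-carrier dams, with intercross and backcross generations), a biallelic
causal insertion transmitted inside a non-recombining linked variant
cluster, genotype-by-background penetrance restricted to SRY-negative
females, genotype-by-background embryonic lethality in crosses, three pet
cohorts with an allele-frequency gradient, and FPKM expression tables with
planted fold-changes.

All randomness flows from a single top-level seed; every stochastic
operation derives a named substream, so outputs are reproducible
bit-for-bit and independent of each other.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .association import CohortCounts, bh_adjust
from .core_io import (
    FOUNDER_SENTINEL,
    HET,
    HOM_ALT,
    HOM_REF,
    Cohort,
    GenomicInterval,
    GenotypeMatrix,
    PedigreeGraph,
    PhenotypeCode,
    SampleRecord,
    SryStatus,
    VariantSite,
    write_sample_table,
    write_vcf,
)
from .expression import log2_fold_change
from .lethality import CrossOutcome, mendelian_class_probabilities
from .segscan import SegregationPattern


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, reproducible child RNG of the top-level seed."""
    tag = int.from_bytes(hashlib.sha256(name.encode()).digest()[:4], "big")
    return np.random.default_rng(np.random.SeedSequence([int(seed), tag]))


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class PenetranceParams:
    """P(affected | genotype, background).

    For an SRY-negative female with carrier-breed background fraction b:
    hom-alt   -> clamp(pi_hom_max - background_coefficient * (1 - b), 0, 1)
    het       -> pi_het * b
    hom-ref   -> 0.
    """

    pi_hom_max: float = 0.9
    pi_het: float = 0.1
    background_coefficient: float = 0.8


@dataclass
class LethalityRule:
    """Conceptuses of ``genotype`` with ``breed`` background fraction >=
    ``min_background`` survive with probability ``survival``."""

    genotype: int = HOM_ALT
    breed: str = "GSHP"
    min_background: float = 0.5
    survival: float = 0.0


@dataclass
class CrossSpec:
    sire_gt: int
    dam_gt: int
    n_conceptuses: int
    background_fraction: float
    label: str = ""


@dataclass
class PedigreeParams:
    n_founder_dams: int = 3
    generations: int = 5
    matings_per_generation: int = 6
    offspring_per_mating: int = 5
    backcross_prob: float = 0.4
    fresh_dam_prob: float = 0.2


@dataclass
class ExpressionParams:
    n_genes: int = 10_000
    group_sizes: tuple[int, int] = (6, 6)  # (cases, controls)
    ages: tuple[str, ...] = ("d37_39", "d42_44")
    log_fpkm_mu: float = 1.5
    log_fpkm_mu_sd: float = 1.5
    sigma: float = 0.3
    n_planted: int = 300
    planted_fold: float = 0.25  # 4-fold down in cases
    # planted DE genes emulate expressed pathway genes, not the genome-wide
    # abundance distribution (a silent gene cannot show a fold change)
    planted_log_fpkm_mu: float = 3.0
    planted_log_fpkm_sd: float = 0.8
    planted_interval: GenomicInterval | None = None
    n_ovary_pathway: int = 10


@dataclass
class CohortParams:
    n_per_cohort: int = 60
    afs: tuple[float, float, float] = (0.405, 0.292, 0.175)


@dataclass
class SimConfig:
    seed: int = 0
    n_chromosomes: int = 5
    chrom_length_bp: int = 50_000_000
    n_background_variants: int = 20_000
    causal_interval: GenomicInterval = field(
        default_factory=lambda: GenomicInterval("chr3", 5_360_823, 7_243_520)
    )
    causal_pos: int = 6_048_201
    n_linked_variants: int = 244
    carrier_breed: str = "ACS"
    other_breed: str = "BGL"
    breed_divergence: float = 0.1
    recomb_block_prob: float = 0.0
    pedigree: PedigreeParams = field(default_factory=PedigreeParams)
    penetrance: PenetranceParams = field(default_factory=PenetranceParams)
    lethality: LethalityRule = field(default_factory=LethalityRule)
    crosses: list[CrossSpec] = field(
        default_factory=lambda: [
            CrossSpec(HET, HET, 17, 1.0, "gshp_intercross"),
            CrossSpec(HOM_ALT, HET, 22, 0.75, "model_sire_x_gshp_dam"),
        ]
    )
    expression: ExpressionParams = field(default_factory=ExpressionParams)
    cohorts: CohortParams = field(default_factory=CohortParams)

    @property
    def chromosomes(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]

    @property
    def genome_bp(self) -> float:
        return float(self.n_chromosomes * self.chrom_length_bp)

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: self.chrom_length_bp for c in self.chromosomes}

    def validate(self) -> None:
        p = self.penetrance
        for name, v in (
            ("pi_hom_max", p.pi_hom_max),
            ("pi_het", p.pi_het),
            ("lethality.survival", self.lethality.survival),
            ("lethality.min_background", self.lethality.min_background),
            ("recomb_block_prob", self.recomb_block_prob),
        ):
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        ci = self.causal_interval
        if ci.chrom not in self.chromosomes or ci.end > self.chrom_length_bp:
            raise ValueError("causal_interval outside the simulated genome")
        if not ci.contains(ci.chrom, self.causal_pos):
            raise ValueError("causal_pos outside causal_interval")
        if self.pedigree.n_founder_dams < 1:
            raise ValueError("impossible design: need at least one founder dam")


@dataclass
class SimTruth:
    causal_site_index: int
    block_site_indices: list[int]
    carrier_dosage: dict[str, int]
    affected: set[str] = field(default_factory=set)
    lethal_counts: dict[str, int] = field(default_factory=dict)
    planted_genes: list[str] = field(default_factory=list)
    ovary_genes: list[str] = field(default_factory=list)


@dataclass
class SimulatedStudy:
    config: SimConfig
    pedigree: PedigreeGraph
    records: list[SampleRecord]
    matrix: GenotypeMatrix
    crosses: list[CrossOutcome]
    cohort_counts: dict[str, CohortCounts]
    expression: pd.DataFrame
    truth: SimTruth

    def write(self, outdir: str | Path) -> dict[str, str]:
        """Write VCF/TSV artifacts; returns {relative path: sha256}."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_vcf(self.matrix, outdir / "genotypes.vcf")
        write_sample_table(self.records, outdir / "samples.tsv")
        with open(outdir / "crosses.tsv", "wt") as fh:
            fh.write("label\tsire_gt\tdam_gt\tn_homref\tn_het\tn_homalt\tbackground_fraction\n")
            for c in self.crosses:
                fh.write(
                    f"{c.label}\t{c.sire_gt}\t{c.dam_gt}\t"
                    f"{c.observed.get(HOM_REF, 0)}\t{c.observed.get(HET, 0)}\t"
                    f"{c.observed.get(HOM_ALT, 0)}\t{c.background_fraction}\n"
                )
        self.expression.to_csv(outdir / "expression.tsv", sep="\t", index=False)
        truth = {
            "causal_site_index": self.truth.causal_site_index,
            "causal_chrom": self.config.causal_interval.chrom,
            "causal_pos": self.config.causal_pos,
            "affected": sorted(self.truth.affected),
            "lethal_counts": self.truth.lethal_counts,
            "planted_genes": self.truth.planted_genes,
            "ovary_genes": self.truth.ovary_genes,
        }
        with open(outdir / "truth.json", "wt") as fh:
            json.dump(truth, fh, indent=1, sort_keys=True)
        manifest = {}
        for f in sorted(outdir.iterdir()):
            if f.is_file() and f.name != "manifest.json":
                manifest[f.name] = hashlib.sha256(f.read_bytes()).hexdigest()
        return manifest


# ---------------------------------------------------------------------------
# Pedigree
# ---------------------------------------------------------------------------

def simulate_pedigree(config: SimConfig) -> tuple[PedigreeGraph, list[SampleRecord], dict[str, str]]:
    """Two-founder-breed pedigree with intercross/backcross structure.

    A carrier-breed founder sire is mated to non-carrier founder dams; each
    later generation mates a male of the previous generation (or the founder
    sire, a backcross) to a previous-generation or fresh non-carrier female.
    Sexes are assigned 1:1 from a seeded draw.  Returns the graph, sample
    records (phenotypes set later by :func:`apply_penetrance`) and a
    sample -> sex ("M"/"F") map.
    """
    config.validate()
    rng = substream(config.seed, "pedigree")
    p = config.pedigree
    parents: dict[str, tuple[str, str]] = {}
    founder_breed: dict[str, str] = {}
    sex: dict[str, str] = {}

    sire0 = f"{config.carrier_breed}1"
    founder_breed[sire0] = config.carrier_breed
    sex[sire0] = "M"
    dams = []
    for i in range(p.n_founder_dams):
        d = f"{config.other_breed}_D{i + 1}"
        founder_breed[d] = config.other_breed
        sex[d] = "F"
        dams.append(d)

    counter = 0
    prev_gen: list[str] = []
    for d in dams:
        for _ in range(p.offspring_per_mating):
            counter += 1
            cid = f"G1_{counter:03d}"
            parents[cid] = (sire0, d)
            sex[cid] = "M" if rng.random() < 0.5 else "F"
            prev_gen.append(cid)

    fresh = 0
    for g in range(2, p.generations + 1):
        males = [s for s in prev_gen if sex[s] == "M"]
        females = [s for s in prev_gen if sex[s] == "F"]
        new_gen: list[str] = []
        for _ in range(p.matings_per_generation):
            if males and rng.random() >= p.backcross_prob:
                sire = males[rng.integers(len(males))]
            else:
                sire = sire0
            if females and rng.random() >= p.fresh_dam_prob:
                dam = females[rng.integers(len(females))]
            else:
                fresh += 1
                dam = f"{config.other_breed}_F{fresh}"
                founder_breed[dam] = config.other_breed
                sex[dam] = "F"
            for _ in range(p.offspring_per_mating):
                counter += 1
                cid = f"G{g}_{counter:03d}"
                parents[cid] = (sire, dam)
                sex[cid] = "M" if rng.random() < 0.5 else "F"
                new_gen.append(cid)
        prev_gen = new_gen

    graph = PedigreeGraph(parents, founder_breed)
    records = []
    for sid in graph.nodes:
        if sid in founder_breed:
            breed = founder_breed[sid]
        else:
            breed = f"{config.carrier_breed}/{config.other_breed}"
        if sex[sid] == "M":
            pheno, sry = PhenotypeCode.XY_MALE, SryStatus.POSITIVE
        else:
            pheno, sry = PhenotypeCode.UNAFFECTED, SryStatus.NEGATIVE
        sire_id, dam_id = parents.get(sid, (FOUNDER_SENTINEL, FOUNDER_SENTINEL))
        records.append(
            SampleRecord(
                sid, sire_id, dam_id, breed,
                cohort=Cohort.MODEL_PEDIGREE, sry_status=sry, phenotype_code=pheno,
            )
        )
    return graph, records, sex


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

def simulate_genotypes(
    pedigree: PedigreeGraph, config: SimConfig
) -> tuple[GenotypeMatrix, SimTruth]:
    """Drop founder haplotypes through the pedigree with exact Mendelian
    transmission.

    Background variants transmit independently; the causal insertion and
    its linked cluster transmit as one block (optionally recombining at a
    random interior breakpoint with probability ``recomb_block_prob`` per
    meiosis).  Carrier-breed founders are homozygous for the whole block;
    other-breed founders are homozygous reference there.
    """
    config.validate()
    rng = substream(config.seed, "genotypes")

    # --- site map ---------------------------------------------------------
    n_bg = config.n_background_variants
    chrom_idx = rng.integers(config.n_chromosomes, size=n_bg)
    bg_pos = rng.integers(1, config.chrom_length_bp + 1, size=n_bg)
    ci = config.causal_interval
    block_pos = np.sort(
        rng.choice(
            np.arange(ci.start, ci.end + 1), size=config.n_linked_variants - 1, replace=False
        )
    )
    block_pos = np.unique(np.concatenate([block_pos, [config.causal_pos]]))

    entries: list[tuple[str, int, bool]] = [
        (config.chromosomes[c], int(p), False) for c, p in zip(chrom_idx, bg_pos)
    ] + [(ci.chrom, int(p), True) for p in block_pos]
    # drop duplicate positions (keep block entries over background ones)
    entries.sort(key=lambda e: (e[0], e[1], not e[2]))
    dedup: list[tuple[str, int, bool]] = []
    for e in entries:
        if dedup and dedup[-1][0] == e[0] and dedup[-1][1] == e[1]:
            continue
        dedup.append(e)
    sites = []
    block_mask = np.zeros(len(dedup), dtype=bool)
    causal_index = -1
    for i, (chrom, pos, is_block) in enumerate(dedup):
        if is_block and pos == config.causal_pos and chrom == ci.chrom:
            sites.append(VariantSite(chrom, pos, "C", "CG"))  # the insertion
            causal_index = i
        else:
            sites.append(VariantSite(chrom, pos, "A", "C"))
        block_mask[i] = is_block
    block_idx = np.nonzero(block_mask)[0]
    bg_idx = np.nonzero(~block_mask)[0]
    n_sites = len(sites)

    # --- founder allele frequencies --------------------------------------
    base_af = rng.uniform(0.05, 0.95, size=n_sites)
    breed_af = {}
    for breed in (config.carrier_breed, config.other_breed):
        shift = rng.normal(0.0, config.breed_divergence, size=n_sites)
        breed_af[breed] = np.clip(base_af + shift, 0.01, 0.99)

    # --- founder haplotypes ----------------------------------------------
    order = pedigree.topological_order()
    H: dict[str, np.ndarray] = {}
    for sid in order:
        if sid in pedigree.parents:
            continue
        breed = pedigree.founder_breed.get(sid, config.other_breed)
        af = breed_af.get(breed, breed_af[config.other_breed])
        h = (rng.random((2, n_sites)) < af).astype(np.int8)
        carrier = breed == config.carrier_breed
        h[:, block_idx] = 1 if carrier else 0
        H[sid] = h

    # --- gene dropping -----------------------------------------------------
    def gamete(h: np.ndarray) -> np.ndarray:
        g = np.empty(n_sites, dtype=np.int8)
        pick = rng.integers(0, 2, size=bg_idx.size)
        g[bg_idx] = h[pick, bg_idx]
        c = int(rng.integers(0, 2))
        if config.recomb_block_prob > 0 and rng.random() < config.recomb_block_prob:
            k = int(rng.integers(1, block_idx.size))
            g[block_idx[:k]] = h[c, block_idx[:k]]
            g[block_idx[k:]] = h[1 - c, block_idx[k:]]
        else:
            g[block_idx] = h[c, block_idx]
        return g

    for sid in order:
        if sid not in pedigree.parents:
            continue
        sire, dam = pedigree.parents[sid]
        H[sid] = np.stack([gamete(H[sire]), gamete(H[dam])])

    samples = list(order)
    calls = np.stack([H[s].sum(axis=0) for s in samples]).astype(np.int8)
    matrix = GenotypeMatrix(sites, samples, calls)
    truth = SimTruth(
        causal_site_index=causal_index,
        block_site_indices=[int(i) for i in block_idx],
        carrier_dosage={s: int(calls[i, causal_index]) for i, s in enumerate(samples)},
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

def penetrance_probability(call: int, background: float, params: PenetranceParams) -> float:
    """P(XX DSD | genotype, carrier-breed background fraction b)."""
    if call == HOM_ALT:
        return float(np.clip(params.pi_hom_max - params.background_coefficient * (1 - background), 0, 1))
    if call == HET:
        return float(np.clip(params.pi_het * background, 0, 1))
    return 0.0


def apply_penetrance(
    records: Sequence[SampleRecord],
    matrix: GenotypeMatrix,
    pedigree: PedigreeGraph,
    config: SimConfig,
    truth: SimTruth,
) -> list[SampleRecord]:
    """Draw XX DSD phenotypes for SRY-negative samples; others unchanged.

    Returns new records with realized phenotypes and fills
    ``truth.affected``.
    """
    rng = substream(config.seed, "penetrance")
    out = []
    for r in records:
        if r.sry_status is not SryStatus.NEGATIVE:
            out.append(r)
            continue
        call = truth.carrier_dosage.get(r.sample_id, HOM_REF)
        b = pedigree.breed_fraction(r.sample_id, config.carrier_breed)
        p = penetrance_probability(call, b, config.penetrance)
        affected = rng.random() < p
        code = PhenotypeCode.XX_DSD if affected else PhenotypeCode.UNAFFECTED
        if affected:
            truth.affected.add(r.sample_id)
        out.append(
            SampleRecord(
                r.sample_id, r.sire_id, r.dam_id, r.breed, r.cohort,
                SryStatus.NEGATIVE, code, r.gonad_class,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Crosses and lethality
# ---------------------------------------------------------------------------

def apply_lethality(
    conceptus_calls: np.ndarray,
    background_fraction: float,
    rule: LethalityRule,
    rng: np.random.Generator,
) -> tuple[np.ndarray, int]:
    """Remove conceptuses matching the lethality rule; returns survivors and
    the lethal count."""
    calls = np.asarray(conceptus_calls)
    if background_fraction < rule.min_background:
        return calls.copy(), 0
    at_risk = calls == rule.genotype
    survive = rng.random(calls.size) < rule.survival
    keep = ~at_risk | survive
    return calls[keep], int((~keep).sum())


def simulate_crosses(config: SimConfig, truth: SimTruth | None = None) -> list[CrossOutcome]:
    """Mendelian conceptus draws per configured cross, then lethality."""
    config.validate()
    rng = substream(config.seed, "crosses")
    out = []
    for spec in config.crosses:
        probs = mendelian_class_probabilities(spec.sire_gt, spec.dam_gt)
        classes = sorted(probs)
        draws = rng.choice(classes, size=spec.n_conceptuses, p=[probs[c] for c in classes])
        born, n_lethal = apply_lethality(
            draws, spec.background_fraction, config.lethality, rng
        )
        observed = {c: int((born == c).sum()) for c in classes}
        out.append(
            CrossOutcome(
                spec.sire_gt, spec.dam_gt, observed,
                label=spec.label, background_fraction=spec.background_fraction,
            )
        )
        if truth is not None:
            truth.lethal_counts[spec.label or f"cross{len(out)}"] = n_lethal
    return out


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

def simulate_cohorts(config: SimConfig) -> dict[str, CohortCounts]:
    """Three pet cohorts with genotype counts drawn from Hardy-Weinberg
    proportions at the configured insertion allele frequencies."""
    rng = substream(config.seed, "cohorts")
    names = ("affected_pets", "control_pets_1", "control_pets_2")
    out = {}
    for name, af in zip(names, config.cohorts.afs):
        probs = [(1 - af) ** 2, 2 * af * (1 - af), af**2]
        n_ref, n_het, n_alt = rng.multinomial(config.cohorts.n_per_cohort, probs)
        out[name] = CohortCounts(hom_alt=int(n_alt), het=int(n_het), hom_ref=int(n_ref))
    return out


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def simulate_expression(
    config: SimConfig, truth: SimTruth | None = None
) -> pd.DataFrame:
    """Per-gene FPKM table with planted fold-changes and stand-in q-values.

    FPKM ~ lognormal(mu_g, sigma) per sample; planted genes are multiplied
    by the configured fold-change in the affected group (both age groups).
    q-values come from a two-sample t-test on log FPKM followed by
    Benjamini-Hochberg — a documented stand-in for the cuffdiff statistic,
    present only so the downstream filter is exercisable.
    """
    config.validate()
    rng = substream(config.seed, "expression")
    xp = config.expression
    n = xp.n_genes
    gene_ids = [f"GENE{i + 1:05d}" for i in range(n)]
    mu = rng.normal(xp.log_fpkm_mu, xp.log_fpkm_mu_sd, size=n)

    n_planted = min(xp.n_planted, n)
    planted = np.zeros(n, dtype=bool)
    planted[:n_planted] = True
    if n_planted:
        mu[planted] = rng.normal(
            xp.planted_log_fpkm_mu, xp.planted_log_fpkm_sd, size=n_planted
        )
    chroms = np.array(config.chromosomes)[rng.integers(config.n_chromosomes, size=n)]
    starts = rng.integers(1, config.chrom_length_bp + 1, size=n)
    if xp.planted_interval is not None:
        pi = xp.planted_interval
        chroms[planted] = pi.chrom
        starts[planted] = rng.integers(pi.start, pi.end + 1, size=xp.n_planted)

    ovary = [f"OVARY{i + 1:02d}" for i in range(min(xp.n_ovary_pathway, n_planted))]
    for i, g in enumerate(ovary):
        gene_ids[i] = g  # designated ovary-pathway genes are planted genes

    n_case, n_ctrl = xp.group_sizes
    if min(n_case, n_ctrl) < 2:
        raise ValueError("group sizes must be >= 2")
    df = pd.DataFrame({"gene_id": gene_ids, "chrom": chroms, "start": starts})
    log_fold = np.where(planted, np.log(xp.planted_fold), 0.0)
    for age in xp.ages:
        case = np.exp(rng.normal(mu[:, None] + log_fold[:, None], xp.sigma, size=(n, n_case)))
        ctrl = np.exp(rng.normal(mu[:, None], xp.sigma, size=(n, n_ctrl)))
        mean_case = case.mean(axis=1)
        mean_ctrl = ctrl.mean(axis=1)
        lfc = np.array(
            [log2_fold_change(a, b) for a, b in zip(mean_case, mean_ctrl)]
        )
        with np.errstate(invalid="ignore", divide="ignore"):
            t = stats.ttest_ind(np.log(case), np.log(ctrl), axis=1)
        p = np.nan_to_num(t.pvalue, nan=1.0)
        p = np.clip(p, np.finfo(float).tiny, 1.0)
        q = bh_adjust(p)
        df[f"mean_fpkm_case_{age}"] = mean_case
        df[f"mean_fpkm_ctrl_{age}"] = mean_ctrl
        df[f"log2fc_{age}"] = lfc
        df[f"q_{age}"] = q
    if truth is not None:
        truth.planted_genes = [gene_ids[i] for i in np.nonzero(planted)[0]]
        truth.ovary_genes = ovary
    return df


# ---------------------------------------------------------------------------
# Whole-study assembly
# ---------------------------------------------------------------------------

def simulate_study(config: SimConfig) -> SimulatedStudy:
    """Run every generator stage and bundle the results with the truth."""
    pedigree, records, _sex = simulate_pedigree(config)
    matrix, truth = simulate_genotypes(pedigree, config)
    records = apply_penetrance(records, matrix, pedigree, config, truth)
    crosses = simulate_crosses(config, truth)
    cohorts = simulate_cohorts(config)
    expression = simulate_expression(config, truth)
    return SimulatedStudy(config, pedigree, records, matrix, crosses, cohorts, expression, truth)


def reference_pattern(study: SimulatedStudy) -> SegregationPattern:
    """Pick the four informative animals for the recessive pattern from a
    simulated study: two affected homozygotes, one unaffected SRY-negative
    heterozygote (carrier), one homozygous wild-type female control."""
    dosage = study.truth.carrier_dosage
    affected_hom = [s for s in sorted(study.truth.affected) if dosage[s] == HOM_ALT]
    females = [
        r.sample_id
        for r in study.records
        if r.sry_status is SryStatus.NEGATIVE and r.sample_id not in study.truth.affected
    ]
    carriers = [s for s in females if dosage[s] == HET]
    controls = [s for s in females if dosage[s] == HOM_REF]
    if len(affected_hom) < 2 or not carriers or not controls:
        raise ValueError(
            "study lacks the informative animals for the recessive pattern "
            f"(affected hom: {len(affected_hom)}, carriers: {len(carriers)}, "
            f"controls: {len(controls)})"
        )
    return SegregationPattern.recessive(affected_hom[:2], carriers[:1], controls[:1])


# --- small generators used for method calibration -------------------------

def simulate_unrelated(
    n_samples: int,
    n_sites: int,
    seed: int,
    af_range: tuple[float, float] = (0.1, 0.9),
    name: str = "unrelated",
) -> GenotypeMatrix:
    """Unrelated samples, independent sites in Hardy-Weinberg proportions."""
    rng = substream(seed, name)
    af = rng.uniform(*af_range, size=n_sites)
    calls = rng.binomial(2, af, size=(n_samples, n_sites)).astype(np.int8)
    sites = [VariantSite("chr1", j + 1, "A", "C") for j in range(n_sites)]
    return GenotypeMatrix(sites, [f"S{i + 1:04d}" for i in range(n_samples)], calls)


def simulate_two_populations(
    n_per_pop: int,
    n_sites: int,
    seed: int,
    divergence: float = 0.2,
) -> tuple[GenotypeMatrix, np.ndarray]:
    """Two diverged populations; returns the matrix and 0/1 labels."""
    rng = substream(seed, "two_pops")
    base = rng.uniform(0.2, 0.8, size=n_sites)
    af = np.stack([
        np.clip(base + rng.normal(0, divergence, n_sites), 0.01, 0.99),
        np.clip(base - rng.normal(0, divergence, n_sites), 0.01, 0.99),
    ])
    labels = np.repeat([0, 1], n_per_pop)
    calls = np.vstack([
        rng.binomial(2, af[lab], size=n_sites) for lab in labels
    ]).astype(np.int8)
    sites = [VariantSite("chr1", j + 1, "A", "C") for j in range(n_sites)]
    return GenotypeMatrix(sites, [f"P{i + 1:04d}" for i in range(2 * n_per_pop)], calls), labels
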