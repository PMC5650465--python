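"""Candidate-locus cohort association.

Genotype count tables at a focal site, contingency chi-squared tests under
collapsed genetic models (dominant / recessive / allelic / genotypic),
Bonferroni and Benjamini-Hochberg multiple-testing control, the
allele-frequency-gradient check across the three pet cohorts, and the
heavy SNP prefilter used before the small-sample array association stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .core_io import (
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    GenotypeMatrix,
    allele_frequency,
)


@dataclass
class CohortCounts:
    """Genotype-class tallies for one cohort at the focal site."""

    hom_alt: int = 0
    het: int = 0
    hom_ref: int = 0
    other: int = 0  # third (non-insertion) allele carriers

    @property
    def n(self) -> int:
        return self.hom_alt + self.het + self.hom_ref + self.other

    def allele_frequency(self, third_allele_policy: str = "non_carrier") -> float:
        return allele_frequency(
            self.hom_ref, self.het, self.hom_alt, self.other,
            third_allele_policy=third_allele_policy,
        )


@dataclass
class AssociationResult:
    model: str
    statistic: float
    df: int
    p: float
    yates: bool = False


def genotype_count_table(
    matrix: GenotypeMatrix,
    chrom: str,
    pos: int,
    cohort_of: Mapping[str, str],
    other_allele_samples: Sequence[str] = (),
) -> tuple[dict[str, CohortCounts], list[str]]:
    """Per-cohort genotype tallies at one site; missing calls are excluded.

    Samples listed in ``other_allele_samples`` carry a third allele at the
    locus (e.g. the CT SNP dogs) and are tallied separately.  Cohorts with
    zero genotyped samples are flagged (second return value), not fatal.
    """
    j = matrix.site_index(chrom, pos)
    other = set(other_allele_samples)
    out: dict[str, CohortCounts] = {}
    for sid in matrix.samples:
        cohort = cohort_of.get(sid)
        if cohort is None:
            continue
        cc = out.setdefault(cohort, CohortCounts())
        if sid in other:
            cc.other += 1
            continue
        call = int(matrix.calls[matrix.sample_index(sid), j])
        if call == MISSING:
            continue
        if call == HOM_ALT:
            cc.hom_alt += 1
        elif call == HET:
            cc.het += 1
        else:
            cc.hom_ref += 1
    for cohort in set(cohort_of.values()):
        out.setdefault(cohort, CohortCounts())
    flagged = sorted(c for c, cc in out.items() if cc.n == 0)
    return out, flagged


def contingency_chisq(
    table: Sequence[Sequence[float]] | np.ndarray,
    yates: bool = False,
    model: str = "contingency",
) -> AssociationResult:
    """Pearson chi-squared test of independence on an r x c count table.

    Expected counts come from the margins; the Yates continuity correction
    (subtract 0.5 from each |O - E|) applies only when df = 1 and
    ``yates`` is set.  The p-value is the chi-squared upper tail.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("table must be at least 2x2")
    if (obs < 0).any():
        raise ValueError("cell counts must be nonnegative")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    if (row == 0).any() or (col == 0).any():
        zr = [f"row {i}" for i in np.nonzero(row == 0)[0]]
        zc = [f"col {j}" for j in np.nonzero(col == 0)[0]]
        raise ValueError(f"degenerate margins: {', '.join(zr + zc)}")
    total = obs.sum()
    expected = np.outer(row, col) / total
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    dev = np.abs(obs - expected)
    if yates and df == 1:
        dev = np.maximum(dev - 0.5, 0.0)
    stat = float((dev**2 / expected).sum())
    p = float(stats.chi2.sf(stat, df))
    return AssociationResult(model, stat, df, max(p, np.finfo(float).tiny), yates and df == 1)


def genetic_model_collapse(
    case: CohortCounts, control: CohortCounts, model: str
) -> np.ndarray:
    """Collapse two cohorts' genotype tallies into a test table.

    dominant: carriers (hom_alt + het) vs hom_ref; recessive: hom_alt vs
    rest; allelic: alt vs ref allele counts; genotypic: the full 2x3.
    Third-allele carriers are excluded under the default policy.
    """
    rows = []
    for cc in (case, control):
        if model == "dominant":
            rows.append([cc.hom_alt + cc.het, cc.hom_ref])
        elif model == "recessive":
            rows.append([cc.hom_alt, cc.het + cc.hom_ref])
        elif model == "allelic":
            rows.append([2 * cc.hom_alt + cc.het, 2 * cc.hom_ref + cc.het])
        elif model == "genotypic":
            rows.append([cc.hom_alt, cc.het, cc.hom_ref])
        else:
            raise ValueError(f"unknown model {model!r}")
    return np.asarray(rows, dtype=float)


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise significance threshold alpha / m."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, original order restored.

    adj_(i) = min_{j >= i} m * p_(j) / j over the sorted p-values, capped at
    1; ties share their adjusted value.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adj_sorted = np.minimum(adj_sorted, 1.0)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


@dataclass
class GradientResult:
    afs: tuple[float, float, float]  # affected, control1, control2
    gradient: bool
    pairwise: dict[str, AssociationResult]


def af_gradient_check(
    affected: CohortCounts,
    control1: CohortCounts,
    control2: CohortCounts,
    yates: bool = False,
    third_allele_policy: str = "non_carrier",
) -> GradientResult:
    """Check the predicted allele-frequency gradient across the pet cohorts.

    The common-ancestral-variant hypothesis predicts AF(affected pets) >
    AF(breed-matched controls) > AF(unaffected breeds).  Pairwise allelic
    chi-squared tests are attached.
    """
    cohorts = {"affected": affected, "control1": control1, "control2": control2}
    for name, cc in cohorts.items():
        if cc.n == 0:
            raise ValueError(f"empty cohort: {name}")
    afs = tuple(cc.allele_frequency(third_allele_policy) for cc in cohorts.values())
    gradient = afs[0] > afs[1] > afs[2]
    pairwise = {}
    for a, b in (("affected", "control1"), ("affected", "control2"), ("control1", "control2")):
        tab = genetic_model_collapse(cohorts[a], cohorts[b], "allelic")
        pairwise[f"{a}_vs_{b}"] = contingency_chisq(tab, yates=yates, model="allelic")
    return GradientResult(afs, gradient, pairwise)  # type: ignore[arg-type]


def gwas_snp_prefilter(
    matrix: GenotypeMatrix,
    maf_min: float = 0.3,
    thin_every: int = 10,
    thin_keep: bool = True,
) -> tuple[GenotypeMatrix, dict[str, int]]:
    """Heavy SNP prefilter for the under-powered array association stage.

    Applied in order: (1) drop sites with any missing call; (2) drop sites
    with minor allele frequency below ``maf_min``; (3) thin — with
    ``thin_keep`` retain every ``thin_every``-th surviving site (1st,
    (1+k)-th, ...), otherwise drop every ``thin_every``-th.
    """
    if thin_every < 1:
        raise ValueError("thin_every must be >= 1")
    n0 = matrix.n_sites
    no_missing = np.nonzero((matrix.calls != MISSING).all(axis=0))[0]
    m1 = matrix.subset_sites(no_missing)
    if m1.n_sites:
        af = m1.calls.mean(axis=0) / 2.0
        maf = np.minimum(af, 1 - af)
        keep = np.nonzero(maf >= maf_min)[0]
    else:
        keep = np.arange(0)
    m2 = m1.subset_sites(keep)
    if thin_keep:
        idx = np.arange(0, m2.n_sites, thin_every)
    else:
        mask = np.ones(m2.n_sites, dtype=bool)
        mask[thin_every - 1 :: thin_every] = False
        idx = np.nonzero(mask)[0]
    m3 = m2.subset_sites(idx)
    info = {
        "input": n0,
        "after_missing": m1.n_sites,
        "after_maf": m2.n_sites,
        "after_thin": m3.n_sites,
    }
    return m3, info
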