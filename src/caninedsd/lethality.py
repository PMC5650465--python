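"""Mendelian expected counts and segregation-distortion testing.

A genotype class that should appear among live-born offspring under simple
Mendelian inheritance but never does — with a significant goodness-of-fit
chi-squared deficit — is the classic signature of genotype-specific
embryonic lethality, here the hom-insertion class in crosses onto the GSHP
background.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .core_io import HET, HOM_ALT, HOM_REF

#: gamete allele distribution per parental genotype (alt-allele count)
_GAMETES: dict[int, dict[int, float]] = {
    HOM_REF: {0: 1.0},
    HET: {0: 0.5, 1: 0.5},
    HOM_ALT: {1: 1.0},
}

CLASS_NAMES = {HOM_REF: "hom_ref", HET: "het", HOM_ALT: "hom_alt"}


@dataclass
class CrossOutcome:
    """Parental genotypes and observed offspring genotype-class counts.

    ``observed`` maps offspring call (0/1/2) to a count; ``pooled`` marks an
    outcome aggregated over several same-type matings.
    ``background_fraction`` is the offspring's expected fraction of the
    lethality-relevant breed background (mean of the parents').
    """

    sire_gt: int
    dam_gt: int
    observed: dict[int, int]
    label: str = ""
    pooled: bool = False
    background_fraction: float = 0.0

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.observed.values()):
            raise ValueError("observed counts must be >= 0")
        possible = set(mendelian_class_probabilities(self.sire_gt, self.dam_gt))
        impossible = {k for k, v in self.observed.items() if v > 0} - possible
        if impossible:
            raise ValueError(
                f"observed classes {sorted(impossible)} are Mendelian-impossible "
                f"for parents ({self.sire_gt}, {self.dam_gt})"
            )

    @property
    def n(self) -> int:
        return sum(self.observed.values())


def mendelian_class_probabilities(sire_gt: int, dam_gt: int) -> dict[int, float]:
    """Offspring genotype-class probabilities from the Punnett rules."""
    for gt, name in ((sire_gt, "sire"), (dam_gt, "dam")):
        if gt not in _GAMETES:
            raise ValueError(f"{name} genotype must be 0/1/2 (non-missing), got {gt}")
    probs: dict[int, float] = {}
    for a, pa in _GAMETES[sire_gt].items():
        for b, pb in _GAMETES[dam_gt].items():
            probs[a + b] = probs.get(a + b, 0.0) + pa * pb
    return probs


def mendelian_expected(sire_gt: int, dam_gt: int, n: int) -> dict[int, float]:
    """Expected offspring counts per genotype class for ``n`` offspring."""
    if n < 0:
        raise ValueError("n must be >= 0")
    return {k: n * p for k, p in mendelian_class_probabilities(sire_gt, dam_gt).items()}


def gof_chisq(
    observed: Mapping[int, float],
    expected: Mapping[int, float],
    yates_if_df1: bool = True,
) -> tuple[float, int, float]:
    """Goodness-of-fit chi-squared over identical class sets; df = classes - 1.

    With one degree of freedom and ``yates_if_df1`` the continuity
    correction subtracts 0.5 from each |O - E|.
    """
    if set(observed) != set(expected):
        raise ValueError("observed and expected must cover identical classes")
    classes = sorted(expected)
    e = np.array([expected[c] for c in classes], dtype=float)
    o = np.array([observed[c] for c in classes], dtype=float)
    if (e <= 0).any():
        zero = [CLASS_NAMES.get(classes[i], classes[i]) for i in np.nonzero(e <= 0)[0]]
        raise ValueError(
            f"expected count is zero for class(es) {zero}; merge classes before testing"
        )
    df = len(classes) - 1
    if df < 1:
        raise ValueError("need at least two classes")
    dev = np.abs(o - e)
    if df == 1 and yates_if_df1:
        dev = np.maximum(dev - 0.5, 0.0)
    stat = float((dev**2 / e).sum())
    p = float(stats.chi2.sf(stat, df))
    return stat, df, p


@dataclass
class CrossTest:
    cross: CrossOutcome
    expected: dict[int, float]
    statistic: float
    df: int
    p: float


@dataclass
class LethalityReport:
    per_cross: list[CrossTest]
    pooled_observed: dict[int, float]
    pooled_expected: dict[int, float]
    pooled_statistic: float
    pooled_df: int
    pooled_p: float
    flagged: list[int]  # genotype classes consistent with embryonic lethality


def lethality_screen(
    crosses: Sequence[CrossOutcome],
    alpha: float = 0.01,
    expected_min: float = 5.0,
    yates_if_df1: bool = True,
) -> LethalityReport:
    """Flag genotype classes whose total absence indicates embryonic lethality.

    Observed and Mendelian-expected counts are pooled class-wise across
    crosses; a class is flagged when it was never observed, its pooled
    expectation is at least ``expected_min`` (chi-squared validity gate),
    and the pooled goodness-of-fit test rejects at ``alpha``.  Per-cross
    tests are always reported alongside the pooled one.
    """
    if not crosses:
        raise ValueError("need at least one cross")
    per_cross: list[CrossTest] = []
    pooled_obs: dict[int, float] = {}
    pooled_exp: dict[int, float] = {}
    for cross in crosses:
        exp = mendelian_expected(cross.sire_gt, cross.dam_gt, cross.n)
        obs = {c: float(cross.observed.get(c, 0)) for c in exp}
        if len(exp) >= 2:
            stat, df, p = gof_chisq(obs, exp, yates_if_df1)
        else:  # fixed cross (single Mendelian class): nothing to test
            stat, df, p = 0.0, 0, 1.0
        per_cross.append(CrossTest(cross, exp, stat, df, p))
        for c in exp:
            pooled_obs[c] = pooled_obs.get(c, 0.0) + obs[c]
            pooled_exp[c] = pooled_exp.get(c, 0.0) + exp[c]
    if len(pooled_exp) >= 2:
        stat, df, p = gof_chisq(pooled_obs, pooled_exp, yates_if_df1)
    else:
        stat, df, p = 0.0, 0, 1.0
    flagged = sorted(
        c
        for c in pooled_exp
        if pooled_obs[c] == 0 and pooled_exp[c] >= expected_min and p < alpha
    )
    return LethalityReport(per_cross, pooled_obs, pooled_exp, stat, df, p, flagged)


# ---------------------------------------------------------------------------
# TSV interface
# ---------------------------------------------------------------------------

def read_crosses_tsv(path) -> list[CrossOutcome]:
    """Read `sire_gt dam_gt n_homref n_het n_homalt` rows."""
    out = []
    with open(path) as fh:
        header = fh.readline().split()
        for line in fh:
            if not line.strip():
                continue
            vals = dict(zip(header, line.split()))
            out.append(
                CrossOutcome(
                    sire_gt=int(vals["sire_gt"]),
                    dam_gt=int(vals["dam_gt"]),
                    observed={
                        HOM_REF: int(vals["n_homref"]),
                        HET: int(vals["n_het"]),
                        HOM_ALT: int(vals["n_homalt"]),
                    },
                    label=vals.get("label", ""),
                    background_fraction=float(vals.get("background_fraction", 0.0)),
                )
            )
    return out


def write_report_tsv(report: LethalityReport, path, alpha: float = 0.01) -> None:
    with open(path, "wt") as fh:
        fh.write("cross\tclass\tobserved\texpected\tstatistic\tdf\tp\tflag\n")
        for ct in report.per_cross:
            for c in sorted(ct.expected):
                fh.write(
                    f"{ct.cross.label or 'cross'}\t{CLASS_NAMES[c]}\t"
                    f"{ct.cross.observed.get(c, 0)}\t{ct.expected[c]:.4g}\t"
                    f"{ct.statistic:.6g}\t{ct.df}\t{ct.p:.4g}\t\n"
                )
        for c in sorted(report.pooled_expected):
            flag = "lethal_candidate" if c in report.flagged else ""
            fh.write(
                f"pooled\t{CLASS_NAMES[c]}\t{report.pooled_observed[c]:.4g}\t"
                f"{report.pooled_expected[c]:.4g}\t{report.pooled_statistic:.6g}\t"
                f"{report.pooled_df}\t{report.pooled_p:.4g}\t{flag}\n"
            )
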