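"""Stringent differential-expression filtering over FPKM tables.

The stringent-DE rule keeps a gene only when the group q-value is
significant, the between-group change is at least two-fold
(|log2FC| >= 1), and at least one comparison arm is meaningfully expressed
(group mean FPKM >= 4).  Retained genes are categorised by fold change,
binned into fixed genomic intervals, and summarised over curated
sex-determination pathway gene sets.

Expected table schema (TSV with header): ``gene_id``, ``chrom``, ``start``,
then per age group ``mean_fpkm_case_<age>``, ``mean_fpkm_ctrl_<age>``,
``log2fc_<age>``, ``q_<age>``.  Functions operating on a single comparison
take the plain column names ``mean_fpkm_case``, ``mean_fpkm_ctrl``,
``log2fc``, ``q_value``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: pseudocount used for log2FC when a group mean is zero
PSEUDOCOUNT_FPKM = 0.1

#: |log2FC| boundaries of the verbal fold categories (config defaults,
#: printed in report headers): >=1 -> ">2-fold", [0.9, 1) -> "~2-fold",
#: [0.4, 0.9) -> "<2-fold", < 0.4 -> "<<2-fold".  The 1.0 boundary is closed.
FOLD_CATEGORY_THRESHOLDS = (1.0, 0.9, 0.4)


def log2_fold_change(
    mean_case: float, mean_ctrl: float, pseudocount: float = PSEUDOCOUNT_FPKM
) -> float:
    """log2(case / control) with a pseudocount when a group mean is zero."""
    a = mean_case if mean_case > 0 else pseudocount
    b = mean_ctrl if mean_ctrl > 0 else pseudocount
    return float(np.log2(a / b))


def stringent_de_filter(
    records: pd.DataFrame,
    q_max: float = 0.05,
    min_abs_log2fc: float = 1.0,
    min_group_fpkm: float = 4.0,
) -> pd.DataFrame:
    """Apply the triple gate; adds a ``direction`` column (up/down in cases).

    Retain iff ``q_value <= q_max`` AND ``|log2fc| >= min_abs_log2fc`` AND
    ``max(group mean FPKM) >= min_group_fpkm``.
    """
    required = {"gene_id", "mean_fpkm_case", "mean_fpkm_ctrl", "log2fc", "q_value"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"records missing columns: {sorted(missing)}")
    keep = (
        (records["q_value"] <= q_max)
        & (records["log2fc"].abs() >= min_abs_log2fc)
        & (records[["mean_fpkm_case", "mean_fpkm_ctrl"]].max(axis=1) >= min_group_fpkm)
    )
    out = records.loc[keep].copy()
    out["direction"] = np.where(out["log2fc"] > 0, "up", "down")
    out["fold_category"] = out["log2fc"].map(fold_category)
    return out


def fold_category(
    log2fc: float,
    thresholds: tuple[float, float, float] = FOLD_CATEGORY_THRESHOLDS,
) -> str:
    """Verbal fold-change category from |log2FC|."""
    if not np.isfinite(log2fc):
        raise ValueError("log2fc must be finite")
    hi, mid, lo = thresholds
    mag = abs(log2fc)
    if mag >= hi:
        return ">2-fold"
    if mag >= mid:
        return "~2-fold"
    if mag >= lo:
        return "<2-fold"
    return "<<2-fold"


def genomic_binning(
    de_genes: pd.DataFrame,
    chrom_lengths: Mapping[str, int],
    bin_bp: int = 10_000_000,
) -> pd.DataFrame:
    """Count DE genes (up/down) per fixed genomic bin.

    A gene belongs to bin ``floor((start - 1) / bin_bp)`` of its chromosome
    (start coordinate only).  Returns one row per bin of every declared
    chromosome with columns chrom, bin, start, end, n_up, n_down.
    """
    rows = []
    for chrom, length in chrom_lengths.items():
        n_bins = int(np.ceil(length / bin_bp))
        for b in range(n_bins):
            rows.append(
                {
                    "chrom": chrom,
                    "bin": b,
                    "start": b * bin_bp + 1,
                    "end": min((b + 1) * bin_bp, length),
                    "n_up": 0,
                    "n_down": 0,
                }
            )
    bins = pd.DataFrame(rows)
    index = {(r.chrom, r.bin): i for i, r in enumerate(bins.itertuples(index=False))}
    for r in de_genes.itertuples(index=False):
        if r.chrom not in chrom_lengths:
            raise KeyError(f"unknown chromosome {r.chrom!r} for gene {r.gene_id}")
        b = (int(r.start) - 1) // bin_bp
        i = index[(r.chrom, b)]
        col = "n_up" if r.direction == "up" else "n_down"
        bins.loc[i, col] += 1
    return bins


def argmax_bin(bins: pd.DataFrame, direction: str = "down") -> tuple[str, int]:
    """Bin with the most DE genes of a direction; ties break lexicographically
    by (chrom, bin)."""
    col = f"n_{direction}"
    best = bins.sort_values(["chrom", "bin"]).sort_values(col, ascending=False, kind="mergesort")
    top = best.iloc[0]
    return str(top["chrom"]), int(top["bin"])


def pathway_summary(
    records: pd.DataFrame,
    pathways: Mapping[str, str] | pd.DataFrame,
    ages: Sequence[str] = ("d37_39", "d42_44"),
    q_max: float = 0.05,
) -> pd.DataFrame:
    """Per-gene report over curated pathway gene sets (ovary/testis/...).

    ``records`` uses the per-age schema.  Each pathway gene gets a row with
    its direction (from the most significant age), fold category, and a
    significance class in {both ages, one age, neither}; genes absent from
    the records are reported as ``not measured``.
    """
    if isinstance(pathways, pd.DataFrame):
        pathways = dict(zip(pathways["gene_id"], pathways["pathway"]))
    by_gene = records.set_index("gene_id")
    rows = []
    for gene, pathway in pathways.items():
        if gene not in by_gene.index:
            rows.append(
                {
                    "gene_id": gene, "pathway": pathway, "direction": "not measured",
                    "fold_category": "", "significance": "not measured",
                }
            )
            continue
        rec = by_gene.loc[gene]
        sig_ages = [a for a in ages if rec[f"q_{a}"] <= q_max]
        if len(sig_ages) == len(ages):
            sig = "both ages"
        elif sig_ages:
            sig = f"{sig_ages[0]} only"
        else:
            sig = "neither"
        ref_age = sig_ages[0] if sig_ages else ages[0]
        # most significant age defines the reported change
        if sig_ages:
            ref_age = min(sig_ages, key=lambda a: rec[f"q_{a}"])
        fc = float(rec[f"log2fc_{ref_age}"])
        rows.append(
            {
                "gene_id": gene,
                "pathway": pathway,
                "direction": "up" if fc > 0 else "down",
                "fold_category": fold_category(fc),
                "significance": sig,
            }
        )
    report = pd.DataFrame(rows)
    return report


def pathway_counts(report: pd.DataFrame) -> pd.DataFrame:
    """Summary counts per pathway x direction (measured genes only)."""
    measured = report[report["direction"] != "not measured"]
    return (
        measured.groupby(["pathway", "direction"]).size().rename("n_genes").reset_index()
    )


# ---------------------------------------------------------------------------
# TSV interface
# ---------------------------------------------------------------------------

def read_expression_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_expression_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def single_age_view(records: pd.DataFrame, age: str) -> pd.DataFrame:
    """Project the per-age schema onto the single-comparison column names."""
    out = records[["gene_id", "chrom", "start"]].copy()
    out["mean_fpkm_case"] = records[f"mean_fpkm_case_{age}"]
    out["mean_fpkm_ctrl"] = records[f"mean_fpkm_ctrl_{age}"]
    out["log2fc"] = records[f"log2fc_{age}"]
    out["q_value"] = records[f"q_{age}"]
    return out
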