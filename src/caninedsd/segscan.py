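"""Segregation-pattern variant filtering, enrichment scanning, homozygosity mapping.

This is the whole-genome fine-mapping core: keep only variants whose calls in
a handful of informative pedigree members match the genotype vector predicted
by the inheritance model (two affected homozygotes, an obligate carrier
heterozygote, a homozygous wild-type control for the default recessive
model), then locate the genomic interval where the surviving variants pile up
far above the genome-wide density, and corroborate it by homozygosity /
haplotype-block mapping with breed-sharing scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .core_io import (
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    GenomicInterval,
    GenotypeMatrix,
    VariantSite,
)

_CALL_NAMES = {"hom_ref": HOM_REF, "het": HET, "hom_alt": HOM_ALT}
_NAME_BY_CALL = {v: k for k, v in _CALL_NAMES.items()}


@dataclass
class SegregationPattern:
    """Required genotype per informative sample under the inheritance model.

    ``missing_policy`` controls how a missing call in a patterned sample is
    treated: ``"fail_match"`` (default, conservative — a missing call cannot
    confirm the pattern) rejects the site; ``"ignore_sample"`` lets the
    remaining samples decide.
    """

    required: dict[str, int]
    missing_policy: str = "fail_match"

    def __post_init__(self) -> None:
        if self.missing_policy not in ("fail_match", "ignore_sample"):
            raise ValueError(f"unknown missing_policy {self.missing_policy!r}")
        for s, c in self.required.items():
            if c not in (HOM_REF, HET, HOM_ALT):
                raise ValueError(f"required call for {s} must be 0/1/2, got {c}")

    @classmethod
    def recessive(
        cls,
        affected_hom: Sequence[str],
        carrier_het: Sequence[str],
        control_hom_ref: Sequence[str],
        missing_policy: str = "fail_match",
    ) -> "SegregationPattern":
        req: dict[str, int] = {}
        req.update({s: HOM_ALT for s in affected_hom})
        req.update({s: HET for s in carrier_het})
        req.update({s: HOM_REF for s in control_hom_ref})
        return cls(req, missing_policy)

    @classmethod
    def from_tsv(cls, path: str | Path, missing_policy: str = "fail_match") -> "SegregationPattern":
        req = {}
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("sample_id"):
                    continue
                sid, name = line.split()
                req[sid] = _CALL_NAMES[name]
        return cls(req, missing_policy)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "wt") as fh:
            fh.write("sample_id\trequired_genotype\n")
            for sid, call in self.required.items():
                fh.write(f"{sid}\t{_NAME_BY_CALL[call]}\n")


def segregation_pattern_filter(
    matrix: GenotypeMatrix, pattern: SegregationPattern
) -> tuple[list[VariantSite], np.ndarray]:
    """Sites whose calls match the predicted segregation pattern.

    Returns the retained sites sorted by (chrom, pos) together with their
    column indices into ``matrix`` in the same order.
    """
    unknown = sorted(set(pattern.required) - set(matrix.samples))
    if unknown:
        raise KeyError(f"pattern samples not in matrix: {unknown}")
    ok = np.ones(matrix.n_sites, dtype=bool)
    for sid, req in pattern.required.items():
        row = matrix.calls[matrix.sample_index(sid)]
        match = row == req
        if pattern.missing_policy == "ignore_sample":
            match |= row == MISSING
        ok &= match
    idx = np.nonzero(ok)[0]
    order = sorted(range(len(idx)), key=lambda i: matrix.sites[idx[i]].key)
    idx = idx[order]
    return [matrix.sites[i] for i in idx], idx


# ---------------------------------------------------------------------------
# Density enrichment
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentWindow:
    """Variant-density window: fold = (k/w) / (K/G)."""

    interval: GenomicInterval
    k: int
    K: int
    w: int
    G: float
    fold: float


@dataclass
class ScanResult:
    windows: list[EnrichmentWindow]
    segments: list[EnrichmentWindow]

    @property
    def top_segment(self) -> EnrichmentWindow | None:
        return self.segments[0] if self.segments else None


def fold_enrichment(k: float, w_bp: float, K: float, G_bp: float) -> float:
    """Local over genome-wide density of pattern-matching variants."""
    if K <= 0:
        raise ValueError("undefined enrichment: K (genome-wide count) must be > 0")
    if w_bp <= 0:
        raise ValueError("window length must be > 0")
    if G_bp < w_bp:
        raise ValueError("genome length must be >= window length")
    return (k / w_bp) / (K / G_bp)


def enrichment_scan(
    sites: Sequence[VariantSite],
    window_bp: int = 1_000_000,
    step_bp: int = 100_000,
    genome_bp: float = 2.392e9,
    fold_threshold: float = 5.0,
    refine_factor: int = 10,
    min_segment_sites: int = 3,
) -> ScanResult:
    """Slide fixed windows over the retained sites and merge enriched ones.

    Windows with ``fold >= fold_threshold`` that overlap are merged into
    maximal segments.  A coarse window can reach up to one window length
    beyond the dense cluster that made it pass, so each merged span is
    refined with windows ``refine_factor`` times smaller (same fold
    threshold) to settle the boundary (``refine_factor=1`` disables this).
    The reported segment interval spans the first to the last retained
    variant inside it, and its fold is recomputed on that trimmed span.
    Segments with fewer than ``min_segment_sites`` variants are dropped:
    one or two chance-matching neighbours can produce an extreme density
    on a trimmed span without constituting a cluster.  Windows are ranked
    by (fold desc, chrom, start); segments likewise.
    """
    if not sites:
        raise ValueError("enrichment_scan requires at least one retained site")
    K = len(sites)
    by_chrom: dict[str, np.ndarray] = {}
    for s in sites:
        by_chrom.setdefault(s.chrom, [])
    for s in sites:
        by_chrom[s.chrom].append(s.pos)  # type: ignore[union-attr]
    windows: list[EnrichmentWindow] = []
    for chrom in by_chrom:
        pos = np.sort(np.asarray(by_chrom[chrom], dtype=np.int64))
        by_chrom[chrom] = pos
        starts = np.arange(1, pos[-1] + 1, step_bp, dtype=np.int64)
        ends = starts + window_bp - 1
        k = np.searchsorted(pos, ends, side="right") - np.searchsorted(
            pos, starts, side="left"
        )
        for st, en, kk in zip(starts, ends, k):
            if kk == 0:
                continue
            windows.append(
                EnrichmentWindow(
                    GenomicInterval(chrom, int(st), int(en)),
                    int(kk), K, window_bp, genome_bp,
                    fold_enrichment(int(kk), window_bp, K, genome_bp),
                )
            )
    windows.sort(key=lambda w: (-w.fold, w.interval.chrom, w.interval.start))

    # merge passing windows into maximal segments per chromosome
    passing = [w for w in windows if w.fold >= fold_threshold]
    passing.sort(key=lambda w: (w.interval.chrom, w.interval.start))
    segments: list[EnrichmentWindow] = []
    i = 0
    while i < len(passing):
        chrom = passing[i].interval.chrom
        seg_start = passing[i].interval.start
        seg_end = passing[i].interval.end
        j = i + 1
        while (
            j < len(passing)
            and passing[j].interval.chrom == chrom
            and passing[j].interval.start <= seg_end + 1
        ):
            seg_end = max(seg_end, passing[j].interval.end)
            j += 1
        pos = by_chrom[chrom]
        if refine_factor > 1:
            seg_start, seg_end = _refine_span(
                pos, seg_start, seg_end,
                max(window_bp // refine_factor, 1),
                max(step_bp // refine_factor, 1),
                K, genome_bp, fold_threshold,
            )
        lo = np.searchsorted(pos, seg_start, side="left")
        hi = np.searchsorted(pos, seg_end, side="right")
        if hi - lo >= min_segment_sites:
            first, last = int(pos[lo]), int(pos[hi - 1])
            w = last - first + 1
            k_seg = int(hi - lo)
            segments.append(
                EnrichmentWindow(
                    GenomicInterval(chrom, first, last),
                    k_seg, K, w, genome_bp,
                    fold_enrichment(k_seg, w, K, genome_bp),
                )
            )
        i = j
    segments.sort(key=lambda w: (-w.fold, w.interval.chrom, w.interval.start))
    return ScanResult(windows, segments)


def _refine_span(
    pos: np.ndarray,
    seg_start: int,
    seg_end: int,
    window_bp: int,
    step_bp: int,
    K: int,
    genome_bp: float,
    fold_threshold: float,
) -> tuple[int, int]:
    """Trim a merged coarse span to the union of passing fine windows.

    A fine window needs at least two variants to pass: a single variant
    carries no clustering evidence, and at fine scale one stray site can
    otherwise clear the fold threshold.  Falls back to the coarse span when
    no fine window passes (a diffuse segment denser than the genome but
    below threshold at fine scale).
    """
    starts = np.arange(seg_start, seg_end + 1, step_bp, dtype=np.int64)
    ends = np.minimum(starts + window_bp - 1, seg_end)
    k = np.searchsorted(pos, ends, side="right") - np.searchsorted(pos, starts, side="left")
    with np.errstate(invalid="ignore"):
        fold = (k / np.maximum(ends - starts + 1, 1)) / (K / genome_bp)
    passing = (fold >= fold_threshold) & (k >= 2)
    if not passing.any():
        return seg_start, seg_end
    return int(starts[passing].min()), int(ends[passing].max())


def write_windows_tsv(
    result: ScanResult, path: str | Path, bed_strict: bool = False
) -> None:
    """BED-like TSV (chrom, start, end, k, fold).

    Default coordinates are 1-based inclusive to match printed browser
    intervals; ``bed_strict`` emits true BED (0-based half-open).
    """
    off = 1 if bed_strict else 0
    with open(path, "wt") as fh:
        fh.write("#chrom\tstart\tend\tk\tfold\n")
        for w in result.segments + result.windows:
            fh.write(
                f"{w.interval.chrom}\t{w.interval.start - off}\t{w.interval.end}"
                f"\t{w.k}\t{w.fold:.6g}\n"
            )


# ---------------------------------------------------------------------------
# Homozygosity / haplotype-block mapping
# ---------------------------------------------------------------------------

@dataclass
class HaplotypeBlock:
    """Maximal run of sites hom-alt in every case and hom-ref in every control."""

    interval: GenomicInterval
    site_indices: list[int]
    status: bool = True  # all-cases-hom-alt AND all-controls-hom-ref


def homozygosity_blocks(
    matrix: GenotypeMatrix,
    case_ids: Sequence[str],
    control_ids: Sequence[str],
    min_sites: int = 2,
    max_violations: int = 0,
) -> list[HaplotypeBlock]:
    """Find runs of consecutive sites homozygous-alternate in all cases and
    homozygous-reference in all controls.

    Site qualification is strict (a missing call disqualifies).  Runs
    shorter than ``min_sites`` are dropped.  ``max_violations > 0`` allows
    that many interior non-qualifying sites to bridge adjacent runs.
    """
    if not case_ids or not control_ids:
        raise ValueError("case and control sets must both be non-empty")
    overlap = set(case_ids) & set(control_ids)
    if overlap:
        raise ValueError(f"cases and controls overlap: {sorted(overlap)}")
    case_rows = matrix.calls[[matrix.sample_index(s) for s in case_ids]]
    ctrl_rows = matrix.calls[[matrix.sample_index(s) for s in control_ids]]
    qual = (case_rows == HOM_ALT).all(axis=0) & (ctrl_rows == HOM_REF).all(axis=0)

    blocks: list[HaplotypeBlock] = []
    order = sorted(range(matrix.n_sites), key=lambda i: matrix.sites[i].key)
    runs: list[list[int]] = []
    cur: list[int] | None = None
    cur_chrom: str | None = None
    budget = max_violations
    pending = 0  # non-qualifying sites seen since the last qualifying one
    for i in order:
        chrom = matrix.sites[i].chrom
        if cur is not None and chrom != cur_chrom:
            runs.append(cur)
            cur = None
        if qual[i]:
            if cur is not None and pending <= budget:
                budget -= pending
                cur.append(i)
            else:
                if cur is not None:
                    runs.append(cur)
                cur = [i]
                budget = max_violations
            pending = 0
            cur_chrom = chrom
        elif cur is not None:
            pending += 1
    if cur is not None:
        runs.append(cur)
    for run in runs:
        if len(run) < min_sites:
            continue
        sites = [matrix.sites[i] for i in run]
        blocks.append(
            HaplotypeBlock(
                GenomicInterval(sites[0].chrom, sites[0].pos, sites[-1].pos), run
            )
        )
    return blocks


def breed_sharing_table(
    matrix: GenotypeMatrix,
    block: HaplotypeBlock,
    breed_of: Mapping[str, str],
    affected: Iterable[str],
) -> tuple[dict[str, dict[str, int]], int]:
    """Per-breed counts of affected dogs homozygous-alternate across a block.

    A breed *segregates* with the phenotype when at least one affected dog
    of that breed is hom-alt at every site of the block.  Returns the
    per-breed tally and the number of segregating breeds.
    """
    affected = set(affected)
    table: dict[str, dict[str, int]] = {}
    for sid in matrix.samples:
        breed = breed_of.get(sid)
        if breed is None:
            continue
        row = table.setdefault(breed, {"n_affected": 0, "n_affected_hom_alt": 0})
        if sid not in affected:
            continue
        row["n_affected"] += 1
        calls = matrix.calls[matrix.sample_index(sid), block.site_indices]
        if (calls == HOM_ALT).all():
            row["n_affected_hom_alt"] += 1
    n_segregating = sum(1 for r in table.values() if r["n_affected_hom_alt"] >= 1)
    return table, n_segregating
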