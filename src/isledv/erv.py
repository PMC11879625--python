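"""Post-processing of MELT-style polymorphic ERV insertion calls.

Endogenous retroviruses segregate as presence/absence insertion polymorphisms;
calls arrive as a multi-sample VCF with per-call evidence annotations.  This
module resolves multi-family overlapping calls (the same breakpoint claimed by
more than one ERV consensus), applies evidence/quality/missingness filters,
and counts homozygous non-reference insertions per individual — the quantity
expected to accumulate in small populations where selection against mildly
deleterious insertions is weak.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence

from cyvcf2 import VCF

from .genotype_io import Genotype, _FROM_CYVCF2


@dataclass
class ERVCall:
    """One putative polymorphic insertion: position (1-based), source ERV
    family, percent divergence from the family consensus, MELT ASSESS
    evidence flag, FILTER status and per-sample genotypes."""

    chrom: str
    pos: int
    family: str
    divergence: float
    assess: int
    filter_status: str
    genotypes: List[Genotype]

    def missing_fraction(self) -> float:
        if not self.genotypes:
            return 0.0
        return sum(g == Genotype.MISSING for g in self.genotypes) / len(self.genotypes)


@dataclass(frozen=True)
class ERVFilterConfig:
    """Post-filters: drop calls with ASSESS >= ``max_assess``, a non-PASS
    FILTER (when ``require_pass``), or more than ``max_missing_fraction`` of
    sample genotypes missing; ``overlap_radius`` is the +/- window within
    which calls from different families are considered the same breakpoint."""

    max_assess: int = 3
    require_pass: bool = True
    max_missing_fraction: float = 0.25
    overlap_radius: int = 100

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_missing_fraction <= 1.0:
            raise ValueError("max_missing_fraction must be in [0, 1]")
        if self.overlap_radius < 0:
            raise ValueError("overlap_radius must be non-negative")


@dataclass
class ERVSummary:
    sample: str
    n_hom_nonref: int
    n_het: int
    n_polymorphic_total: int


@dataclass
class ERVFilterStats:
    n_seen: int = 0
    n_kept: int = 0
    removed_overlap: int = 0
    removed_assess: int = 0
    removed_filter: int = 0
    removed_missing: int = 0

    def as_dict(self) -> Dict[str, int]:
        return dict(self.__dict__)


def read_erv_vcf(path: str) -> tuple[List[ERVCall], List[str]]:
    """Read a MELT-style VCF: INFO keys FAMILY (string), DIV (percent float),
    ASSESS (int); standard FILTER column; GT per sample."""
    vcf = VCF(path)
    samples = list(vcf.samples)
    calls: List[ERVCall] = []
    for rec in vcf:
        gts = [_FROM_CYVCF2[g] for g in rec.gt_types]
        calls.append(
            ERVCall(
                chrom=rec.CHROM,
                pos=rec.POS,
                family=str(rec.INFO.get("FAMILY", "")),
                divergence=float(rec.INFO.get("DIV", 0.0)),
                assess=int(rec.INFO.get("ASSESS", 0)),
                filter_status=rec.FILTER or "PASS",
                genotypes=gts,
            )
        )
    return calls, samples


def resolve_overlaps(
    calls: Sequence[ERVCall],
    radius: int = 100,
    stats: Optional[ERVFilterStats] = None,
) -> List[ERVCall]:
    """Collapse multi-family overlapping calls to the most similar consensus.

    Calls on one chromosome whose positions chain within ``radius`` bp form a
    single-linkage cluster.  A cluster containing more than one family keeps
    only the call with minimum divergence (ties: earlier position, then
    lexicographic family); single-family clusters are left untouched.  Input
    must be sorted by (chrom, pos).
    """
    for a, b in zip(calls, calls[1:]):
        if (a.chrom, a.pos) > (b.chrom, b.pos):
            raise ValueError("ERV calls must be sorted by (chrom, pos)")
    out: List[ERVCall] = []
    cluster: List[ERVCall] = []

    def flush() -> None:
        if not cluster:
            return
        families = {c.family for c in cluster}
        if len(families) > 1:
            best = min(cluster, key=lambda c: (c.divergence, c.pos, c.family))
            if stats is not None:
                stats.removed_overlap += len(cluster) - 1
            out.append(best)
        else:
            out.extend(cluster)
        cluster.clear()

    for c in calls:
        if cluster and (c.chrom != cluster[-1].chrom or c.pos - cluster[-1].pos > radius):
            flush()
        cluster.append(c)
    flush()
    return out


def filter_calls(
    calls: Iterable[ERVCall],
    cfg: ERVFilterConfig = ERVFilterConfig(),
    stats: Optional[ERVFilterStats] = None,
) -> List[ERVCall]:
    """Apply the evidence/quality/missingness filters; removal counts per
    rule are tallied (a call is charged to the first rule it fails)."""
    if stats is None:
        stats = ERVFilterStats()
    kept: List[ERVCall] = []
    for c in calls:
        stats.n_seen += 1
        if c.assess >= cfg.max_assess:
            stats.removed_assess += 1
        elif cfg.require_pass and c.filter_status != "PASS":
            stats.removed_filter += 1
        elif c.missing_fraction() > cfg.max_missing_fraction:
            stats.removed_missing += 1
        else:
            stats.n_kept += 1
            kept.append(c)
    return kept


def count_hom_nonref(
    calls: Sequence[ERVCall],
    sample: str,
    samples: Sequence[str],
) -> ERVSummary:
    """Count homozygous non-reference (insertion/insertion) genotypes for one
    individual over the filtered call set; raw counts, no missing-data
    adjustment."""
    try:
        i = list(samples).index(sample)
    except ValueError:
        raise ValueError(f"unknown sample id {sample!r}") from None
    n_hom = sum(c.genotypes[i] == Genotype.HOM_ALT for c in calls)
    n_het = sum(c.genotypes[i] == Genotype.HET for c in calls)
    return ERVSummary(sample, n_hom, n_het, len(calls))


def write_summary_csv(summaries: Sequence[ERVSummary], path: str) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["sample", "n_hom_nonref", "n_het", "n_polymorphic_total"])
        for s in summaries:
            w.writerow([s.sample, s.n_hom_nonref, s.n_het, s.n_polymorphic_total])
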