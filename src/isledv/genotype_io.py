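"""Reading all-sites VCFs and applying site/genotype quality filters.

The pipeline consumes an "all-sites" VCF: one record per genotyped position,
variant and invariant alike, so that per-site heterozygosity has a correct
denominator.  Filtering follows the standard VCFtools-style site/genotype
split: a site is dropped outright when its QUAL or mean depth fails, while an
individual genotype failing GQ/DP is set to missing but the site survives for
the other samples.
"""

from __future__ import annotations

import csv
import enum
import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Tuple

import numpy as np
from cyvcf2 import VCF

logger = logging.getLogger("isledv")

# cyvcf2 gt_types codes
_CY_HOM_REF, _CY_HET, _CY_UNKNOWN, _CY_HOM_ALT = 0, 1, 2, 3


class Genotype(enum.IntEnum):
    """Unphased diploid genotype state."""

    HOM_REF = 0
    HET = 1
    HOM_ALT = 2
    MISSING = 3


_FROM_CYVCF2 = {
    _CY_HOM_REF: Genotype.HOM_REF,
    _CY_HET: Genotype.HET,
    _CY_UNKNOWN: Genotype.MISSING,
    _CY_HOM_ALT: Genotype.HOM_ALT,
}


@dataclass
class SampleCall:
    """One sample's diploid call at one site.

    ``gq`` and ``dp`` are ``None`` when the field is absent or undefined in
    the record (or the genotype itself is missing).
    """

    genotype: Genotype
    gq: Optional[float] = None
    dp: Optional[int] = None


@dataclass
class GenotypeSite:
    """One genomic position (1-based, VCF convention) with per-sample calls."""

    chrom: str
    pos: int
    site_qual: Optional[float]
    ref: str
    alts: Tuple[str, ...]
    per_sample: List[SampleCall]
    is_multiallelic: bool = False

    @property
    def is_invariant(self) -> bool:
        return len(self.alts) == 0


@dataclass(frozen=True)
class FilterConfig:
    """Site/genotype quality thresholds (phred units for quals, reads for depth).

    Defaults: site QUAL >= 20, genotype GQ >= 20, depth in [5, mean 30].
    """

    min_site_qual: float = 20.0
    min_gq: float = 20.0
    min_dp: int = 5
    max_mean_dp: float = 30.0

    def __post_init__(self) -> None:
        if min(self.min_site_qual, self.min_gq, self.min_dp, self.max_mean_dp) < 0:
            raise ValueError("filter thresholds must be non-negative")
        if self.min_dp > self.max_mean_dp:
            raise ValueError("min_dp must not exceed max_mean_dp")


@dataclass
class FilterStats:
    """Tallies of records dropped / genotypes masked, by rule."""

    n_sites_seen: int = 0
    n_sites_kept: int = 0
    dropped_site_qual: int = 0
    dropped_mean_dp: int = 0
    masked_gq: int = 0
    masked_dp: int = 0

    def as_dict(self) -> Dict[str, int]:
        return dict(self.__dict__)

    def write_csv(self, path: str) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["rule", "count"])
            for k, v in self.as_dict().items():
                w.writerow([k, v])


class VCFParseError(ValueError):
    pass


def read_sites(vcf_source: str, snps_only: bool = False) -> Iterator[GenotypeSite]:
    """Stream :class:`GenotypeSite` records from a VCF 4.x file.

    Invariant records (no ALT, or a symbolic ``<NON_REF>`` ALT) are emitted
    like any other site.  Multiallelic records are flagged, not dropped; with
    ``snps_only`` records carrying a non-symbolic ALT longer than one base
    (indels) are skipped.
    """
    try:
        vcf = VCF(vcf_source)
    except Exception as exc:  # pragma: no cover - htslib error paths
        raise VCFParseError(f"cannot open VCF {vcf_source!r}: {exc}") from exc
    n_samples = len(vcf.samples)
    recno = 0
    try:
        for rec in vcf:
            recno += 1
            alts = tuple(a for a in (rec.ALT or []) if a not in (".", "<NON_REF>", "<*>"))
            if snps_only and any(len(a) != 1 or len(rec.REF) != 1 for a in alts):
                continue
            gts = rec.gt_types
            gqs = rec.gt_quals
            dps = rec.format("DP")
            calls: List[SampleCall] = []
            for i in range(n_samples):
                g = _FROM_CYVCF2[gts[i]]
                gq = float(gqs[i]) if gqs is not None and gqs[i] >= 0 else None
                dp = None
                if dps is not None:
                    d = int(dps[i][0])
                    if d >= 0:
                        dp = d
                calls.append(SampleCall(g, gq, dp))
            yield GenotypeSite(
                chrom=rec.CHROM,
                pos=rec.POS,
                site_qual=rec.QUAL,
                ref=rec.REF,
                alts=alts,
                per_sample=calls,
                is_multiallelic=len(alts) > 1,
            )
    except VCFParseError:
        raise
    except Exception as exc:
        raise VCFParseError(
            f"malformed VCF record near data line {recno + 1} of {vcf_source!r}: {exc}"
        ) from exc


def site_mean_dp(site: GenotypeSite) -> Optional[float]:
    """Mean DP across samples with a non-missing call and a defined DP."""
    dps = [c.dp for c in site.per_sample if c.genotype != Genotype.MISSING and c.dp is not None]
    if not dps:
        return None
    return float(np.mean(dps))


def apply_filters(
    sites: Iterable[GenotypeSite],
    cfg: FilterConfig = FilterConfig(),
    stats: Optional[FilterStats] = None,
) -> Iterator[GenotypeSite]:
    """Apply site-level and genotype-level filters.

    A site is dropped iff its QUAL is below ``min_site_qual`` or its mean DP
    across non-missing samples exceeds ``max_mean_dp``.  On surviving sites a
    sample call is set missing iff its GQ or DP fails.  A call with an
    undefined GQ or DP (on a called genotype) is treated as failing —
    conservative and reproducible.  Sites with an undefined QUAL pass the
    QUAL test, mirroring VCFtools' treatment of '.' QUAL.
    """
    if stats is None:
        stats = FilterStats()
    for site in sites:
        stats.n_sites_seen += 1
        if site.site_qual is not None and site.site_qual < cfg.min_site_qual:
            stats.dropped_site_qual += 1
            continue
        mean_dp = site_mean_dp(site)
        if mean_dp is not None and mean_dp > cfg.max_mean_dp:
            stats.dropped_mean_dp += 1
            continue
        for call in site.per_sample:
            if call.genotype == Genotype.MISSING:
                continue
            if call.gq is None or call.gq < cfg.min_gq:
                call.genotype = Genotype.MISSING
                call.gq = None
                call.dp = None
                stats.masked_gq += 1
            elif call.dp is None or call.dp < cfg.min_dp:
                call.genotype = Genotype.MISSING
                call.gq = None
                call.dp = None
                stats.masked_dp += 1
        stats.n_sites_kept += 1
        yield site


# ---------------------------------------------------------------------------
# Callable mask
# ---------------------------------------------------------------------------


@dataclass
class CallableMask:
    """Per-sample sets of disjoint genomic intervals (0-based, half-open)
    covering every position with a non-missing post-filter genotype."""

    samples: List[str]
    # sample -> chrom -> (n, 2) int array of [start, end)
    intervals: Dict[str, Dict[str, np.ndarray]] = field(default_factory=dict)

    def total_length(self, sample: str) -> int:
        per_chrom = self.intervals.get(sample, {})
        return int(sum((iv[:, 1] - iv[:, 0]).sum() for iv in per_chrom.values()))

    def write_bed(self, sample: str, path: str) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self.intervals.get(sample, {})):
                for start, end in self.intervals[sample][chrom]:
                    fh.write(f"{chrom}\t{start}\t{end}\n")


def _runs_from_positions(pos0: np.ndarray) -> np.ndarray:
    """Merge sorted, unique 0-based positions into maximal [start, end) runs."""
    if pos0.size == 0:
        return np.empty((0, 2), dtype=np.int64)
    breaks = np.nonzero(np.diff(pos0) > 1)[0]
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [pos0.size - 1]))
    return np.stack([pos0[starts], pos0[ends] + 1], axis=1)


def build_callable_mask(
    sites: Iterable[GenotypeSite],
    chrom_lengths: Dict[str, int],
    samples: Optional[Sequence[str]] = None,
) -> CallableMask:
    """Build the per-sample callable mask from filtered sites.

    Input must be sorted by (chrom, pos); adjacent genotyped positions merge
    into maximal intervals.  Raises on unsorted input or positions beyond the
    declared chromosome length.
    """
    per_sample_pos: Dict[int, Dict[str, list]] = {}
    names: Optional[List[str]] = list(samples) if samples is not None else None
    chrom_order: List[str] = []
    last: Tuple[str, int] = ("", 0)
    for site in sites:
        if names is None:
            names = [f"sample{i}" for i in range(len(site.per_sample))]
        if site.chrom not in chrom_lengths:
            raise ValueError(f"chromosome {site.chrom!r} not in chrom_lengths")
        if site.pos > chrom_lengths[site.chrom]:
            raise ValueError(
                f"position {site.chrom}:{site.pos} beyond chromosome length"
            )
        if site.chrom != last[0]:
            if site.chrom in chrom_order:
                raise ValueError("input not sorted: chromosome repeats non-contiguously")
            chrom_order.append(site.chrom)
        elif site.pos <= last[1]:
            raise ValueError(
                f"input not sorted at {site.chrom}:{site.pos} (previous {last[1]})"
            )
        last = (site.chrom, site.pos)
        for i, call in enumerate(site.per_sample):
            if call.genotype != Genotype.MISSING:
                per_sample_pos.setdefault(i, {}).setdefault(site.chrom, []).append(
                    site.pos - 1
                )
    if names is None:
        names = []
    mask = CallableMask(samples=names)
    for i, name in enumerate(names):
        mask.intervals[name] = {}
        for chrom, positions in per_sample_pos.get(i, {}).items():
            mask.intervals[name][chrom] = _runs_from_positions(
                np.asarray(positions, dtype=np.int64)
            )
    return mask
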