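"""Synthetic archipelago generator with known ground truth.

Emulates the study design this pipeline targets: one sequenced diploid
individual per island, island area acting as a proxy for effective population
size (ne = c * area^b).  For each island it produces

* an all-sites VCF whose heterozygous-site density scales with Ne, built from
  a tract model of the diploid genome: tract lengths are independent
  exponentials (shared ancestry blocks), each tract draws a pairwise TMRCA
  T ~ Exp(rate 1/(2 Ne)) generations, and heterozygous sites fall as a
  Poisson process at per-site probability min(2 mu_g T, 1).  Expected
  heterozygosity is therefore theta = 4 Ne mu_g, and low-TMRCA tracts create
  the multi-window homozygous stretches the ROH caller detects;
* planted quality failures (site QUAL, GQ, DP low/high, missing genotypes) at
  known positions, so the filter stage can be checked against ground truth;
* a MELT-style insertion-polymorphism VCF from per-island Wright-Fisher
  drift with genic selection against the insertion allele;
* MSMC2-format scaled trajectories (the exact inverse of the demography
  module's unscaling, plus optional log-normal noise on lambda);
* island metadata, a ground-truth JSON and a checksummed manifest.

The tract model is not a sequential coalescent: tracts are independent, there
is no recombination-driven correlation between adjacent tracts and no gene
flow between islands.
"""

from __future__ import annotations

import hashlib
import json
import math
import os
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .demography import DemographicEpoch, ScalingParams, rescale

# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


def default_islands(n: int = 8, area_min: float = 10.0, area_max: float = 4000.0) -> List[Tuple[str, float]]:
    """Log-spaced island areas (km^2), the span of a small oceanic archipelago."""
    areas = area_min * (area_max / area_min) ** (np.arange(n) / (n - 1))
    return [(f"Isl{i+1:02d}", float(round(a, 2))) for i, a in enumerate(areas)]


@dataclass
class ArchipelagoConfig:
    """Study-condition defaults for the synthetic archipelago.

    ``ne_model``: ne = ne_per_km2 * area^area_exponent (default 100/km^2,
    exponent 1, so 10-4000 km^2 spans Ne 1e3-4e5).  The genome is 2 x 500 kb
    — 40 full 25-kb windows per individual, enough to resolve the
    diversity/ROH gradient at desk scale.  Quality-failure rates are small
    but nonzero so every filter rule is exercised.
    """

    islands: List[Tuple[str, float]] = field(default_factory=default_islands)
    ne_per_km2: float = 100.0
    area_exponent: float = 1.0
    mu_per_year: float = 3.16e-9
    generation_time_years: float = 1.0
    genome: List[Tuple[str, int]] = field(
        default_factory=lambda: [("chr1", 500_000), ("chr2", 500_000)]
    )
    tract_mean_bp: float = 50_000.0
    missing_rate: float = 0.02
    qual_fail_rates: Dict[str, float] = field(
        default_factory=lambda: {
            "site_qual": 0.02,
            "gq": 0.03,
            "low_dp": 0.02,
            "high_dp": 0.01,
        }
    )
    msmc_noise_sd: float = 0.05
    msmc_n_epochs: int = 16
    erv: "ERVSimConfig" = field(default_factory=lambda: ERVSimConfig())
    master_seed: int = 42

    def __post_init__(self) -> None:
        if any(a <= 0 for _, a in self.islands):
            raise ValueError("island areas must be positive")
        if any(l <= 0 for _, l in self.genome):
            raise ValueError("genome lengths must be positive")
        rates = [self.missing_rate, *self.qual_fail_rates.values()]
        if any(not 0 <= r <= 1 for r in rates):
            raise ValueError("rates must be in [0, 1]")
        if self.tract_mean_bp <= 0:
            raise ValueError("tract_mean_bp must be positive")

    def ne_for_area(self, area_km2: float) -> float:
        return self.ne_per_km2 * area_km2 ** self.area_exponent

    @property
    def mu_per_generation(self) -> float:
        return self.mu_per_year * self.generation_time_years

    @property
    def scaling(self) -> ScalingParams:
        return ScalingParams(self.mu_per_year, self.generation_time_years)


@dataclass
class ERVSimConfig:
    """Wright-Fisher drift/selection settings for insertion polymorphisms.

    ``s`` is the genic selection coefficient against the insertion allele
    (<= 0 for deleterious).  Populations larger than ``wf_cap`` are simulated
    at the cap with s rescaled to conserve 2*Ne*s (same selection-drift
    balance, desk-scale runtime); set ``rescale_capped=False`` to error
    instead.  Fractions control planted filter failures and multi-family
    overlap duplicates in the emitted MELT-style VCF.
    """

    n_loci: int = 500
    s: float = -0.001
    q0: float = 0.25
    generations: int = 1000
    wf_cap: int = 10_000
    rescale_capped: bool = True
    n_families: int = 10
    fail_assess_fraction: float = 0.05
    fail_filter_fraction: float = 0.05
    fail_missing_fraction: float = 0.05
    overlap_fraction: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 <= self.q0 <= 1.0:
            raise ValueError("q0 must be in [0, 1]")
        if self.generations < 0:
            raise ValueError("generations must be >= 0")


# ---------------------------------------------------------------------------
# Genotype simulation (tract TMRCA model)
# ---------------------------------------------------------------------------


@dataclass
class SimulatedChrom:
    name: str
    length: int
    het_pos: np.ndarray           # 0-based het positions before quality failures
    fail_pos: Dict[str, np.ndarray]  # rule -> 0-based positions (disjoint)

    def all_fail_pos(self) -> np.ndarray:
        arrs = [v for v in self.fail_pos.values() if v.size]
        return np.sort(np.concatenate(arrs)) if arrs else np.empty(0, dtype=np.int64)

    def callable_het_pos(self) -> np.ndarray:
        return np.setdiff1d(self.het_pos, self.all_fail_pos(), assume_unique=False)

    def callable_pos_mask(self) -> np.ndarray:
        mask = np.ones(self.length, dtype=bool)
        fp = self.all_fail_pos()
        mask[fp] = False
        return mask


@dataclass
class SimulatedIndividual:
    island: str
    ne: float
    chroms: List[SimulatedChrom]

    def n_callable(self) -> int:
        return int(sum(c.length - c.all_fail_pos().size for c in self.chroms))

    def n_het_callable(self) -> int:
        return int(sum(c.callable_het_pos().size for c in self.chroms))

    def genotyped_positions(self) -> Dict[str, np.ndarray]:
        return {c.name: np.nonzero(c.callable_pos_mask())[0] for c in self.chroms}

    def het_positions(self) -> Dict[str, np.ndarray]:
        return {c.name: c.callable_het_pos() for c in self.chroms}

    def planted_counts(self) -> Dict[str, int]:
        out: Dict[str, int] = {}
        for c in self.chroms:
            for rule, pos in c.fail_pos.items():
                out[rule] = out.get(rule, 0) + int(pos.size)
        return out


def sample_tract_tmrca(rng: np.random.Generator, ne: float, n: int) -> np.ndarray:
    """Pairwise TMRCA (generations) for ``n`` tracts under constant Ne:
    T ~ Exp(mean 2*Ne)."""
    return rng.exponential(2.0 * ne, size=n)


_FAIL_RULES = ("missing", "site_qual", "gq", "low_dp", "high_dp")


def simulate_genotypes(
    island: str,
    ne: float,
    cfg: ArchipelagoConfig,
    rng: np.random.Generator,
) -> SimulatedIndividual:
    """Simulate one diploid individual's all-sites genotypes for one island."""
    if cfg.tract_mean_bp <= 0:
        raise ValueError("tract_mean_bp must be positive")
    mu_g = cfg.mu_per_generation
    chroms: List[SimulatedChrom] = []
    for chrom, length in cfg.genome:
        # tract boundaries
        n_guess = max(4, int(length / cfg.tract_mean_bp * 3))
        lens = rng.exponential(cfg.tract_mean_bp, n_guess)
        while lens.sum() < length:
            lens = np.concatenate([lens, rng.exponential(cfg.tract_mean_bp, n_guess)])
        ends = np.minimum(np.cumsum(lens), length).astype(np.int64)
        k = int(np.searchsorted(ends, length)) + 1
        ends = ends[:k]
        ends[-1] = length
        starts = np.concatenate(([0], ends[:-1]))
        tract_len = ends - starts
        # het sites per tract
        T = sample_tract_tmrca(rng, ne, k)
        p = np.minimum(2.0 * mu_g * T, 1.0)
        n_het = rng.poisson(tract_len * p)
        het_chunks = [
            starts[i] + rng.integers(0, tract_len[i], size=int(n_het[i]))
            for i in range(k)
            if n_het[i] > 0
        ]
        het_pos = (
            np.unique(np.concatenate(het_chunks)) if het_chunks else np.empty(0, np.int64)
        )
        # planted quality failures: disjoint position sets per rule
        probs = [cfg.missing_rate] + [
            cfg.qual_fail_rates.get(r, 0.0) for r in _FAIL_RULES[1:]
        ]
        counts = rng.multinomial(length, probs + [max(0.0, 1 - sum(probs))])[:-1]
        total = int(counts.sum())
        fail_all = rng.choice(length, size=total, replace=False) if total else np.empty(0, np.int64)
        fail_pos: Dict[str, np.ndarray] = {}
        off = 0
        for rule, c in zip(_FAIL_RULES, counts):
            fail_pos[rule] = np.sort(fail_all[off : off + int(c)].astype(np.int64))
            off += int(c)
        chroms.append(SimulatedChrom(chrom, length, het_pos, fail_pos))
    return SimulatedIndividual(island, ne, chroms)


_VCF_HEADER = """##fileformat=VCFv4.2
##source=isledv-simulate
{contigs}##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}
"""

_BASES = "ACGT"


def write_individual_vcf(ind: SimulatedIndividual, path: str) -> None:
    """Write the all-sites VCF (one record per position, invariant sites
    included) with QUAL/GQ/DP fields realising the planted failures."""
    contigs = "".join(
        f"##contig=<ID={c.name},length={c.length}>\n" for c in ind.chroms
    )
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER.format(contigs=contigs, sample=ind.island))
        for c in ind.chroms:
            qual = np.full(c.length, 60, dtype=np.int16)
            gq = np.full(c.length, 60, dtype=np.int16)
            dp = np.full(c.length, 20, dtype=np.int16)
            state = np.zeros(c.length, dtype=np.int8)  # 0 hom_ref, 1 het, 2 missing
            state[c.het_pos] = 1
            qual[c.fail_pos["site_qual"]] = 10
            gq[c.fail_pos["gq"]] = 10
            dp[c.fail_pos["low_dp"]] = 3
            dp[c.fail_pos["high_dp"]] = 40
            state[c.fail_pos["missing"]] = 2
            name = c.name
            lines = []
            append = lines.append
            for pos in range(c.length):
                ref = _BASES[pos & 3]
                st = state[pos]
                if st == 0:
                    append(
                        f"{name}\t{pos+1}\t.\t{ref}\t.\t{qual[pos]}\t.\t.\tGT:GQ:DP\t0/0:{gq[pos]}:{dp[pos]}"
                    )
                elif st == 1:
                    alt = _BASES[(pos + 1) & 3]
                    append(
                        f"{name}\t{pos+1}\t.\t{ref}\t{alt}\t{qual[pos]}\t.\t.\tGT:GQ:DP\t0/1:{gq[pos]}:{dp[pos]}"
                    )
                else:
                    append(
                        f"{name}\t{pos+1}\t.\t{ref}\t.\t{qual[pos]}\t.\t.\tGT:GQ:DP\t./.:.:."
                    )
                if len(lines) == 100_000:
                    fh.write("\n".join(lines) + "\n")
                    lines = []
                    append = lines.append
            if lines:
                fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# ERV Wright-Fisher simulation
# ---------------------------------------------------------------------------


def wf_frequencies(
    ne: float,
    s: float,
    q0: float,
    n_loci: int,
    generations: int,
    rng: np.random.Generator,
    wf_cap: int = 10_000,
    rescale_capped: bool = True,
) -> np.ndarray:
    """Final insertion-allele frequencies after discrete Wright-Fisher
    sampling of 2N gametes with genic selection ``s`` on the insertion.

    Populations above ``wf_cap`` are simulated at N = wf_cap with s scaled by
    ne/wf_cap (conserving 2*Ne*s); with ``rescale_capped=False`` such a
    population raises instead.
    """
    n_eff = ne
    s_eff = s
    if ne > wf_cap:
        if not rescale_capped:
            raise ValueError(
                f"2*ne = {2*ne:.0f} exceeds the Wright-Fisher cap {2*wf_cap}; "
                "enable rescale_capped to simulate at the cap with 2*Ne*s conserved"
            )
        s_eff = s * ne / wf_cap
        n_eff = wf_cap
    two_n = max(2, int(round(2 * n_eff)))
    q = np.full(n_loci, q0, dtype=float)
    for _ in range(generations):
        # genic selection then binomial drift
        q_sel = q * (1 + s_eff) / (1 + q * s_eff)
        q_sel = np.clip(q_sel, 0.0, 1.0)
        q = rng.binomial(two_n, q_sel) / two_n
    return q


@dataclass
class ERVGroundTruth:
    n_clean_loci: int
    n_planted_assess: int
    n_planted_filter: int
    n_planted_missing: int
    n_planted_overlap: int
    fixation_count: Dict[str, int]       # island -> loci at q == 1 (clean loci)
    hom_nonref: Dict[str, int]           # island -> emitted hom-insertion genotypes, clean loci


def simulate_erv_archipelago(
    islands: Sequence[Tuple[str, float]],
    cfg: ERVSimConfig,
    rng: np.random.Generator,
) -> Tuple[str, ERVGroundTruth]:
    """Simulate insertion polymorphisms across islands and render them as a
    combined MELT-style multi-sample VCF (returned as text).

    Each clean locus drifts independently within each island from a shared
    initial frequency.  Planted extras exercise the downstream filters:
    ASSESS >= 3 calls, non-PASS calls, high-missingness calls, and
    multi-family duplicate calls within +/-100 bp of a clean call (higher
    divergence, so overlap resolution must discard them).
    """
    names = [n for n, _ in islands]
    n_isl = len(names)
    n = cfg.n_loci
    freqs = np.empty((n_isl, n))
    for i, (_, ne) in enumerate(islands):
        freqs[i] = wf_frequencies(
            ne, cfg.s, cfg.q0, n, cfg.generations, rng, cfg.wf_cap, cfg.rescale_capped
        )
    # genotype one diploid per island at each clean locus
    geno = rng.binomial(2, freqs)  # (n_isl, n): copies of insertion allele
    n_assess = int(round(cfg.fail_assess_fraction * n))
    n_filter = int(round(cfg.fail_filter_fraction * n))
    n_missing = int(round(cfg.fail_missing_fraction * n))
    n_overlap = int(round(cfg.overlap_fraction * n))

    spacing = 2_000
    records: List[Tuple[int, str]] = []  # (pos, line)
    families = [f"ERV{k+1}" for k in range(cfg.n_families)]

    def gt_str(g: int) -> str:
        return ("0/0", "0/1", "1/1")[g]

    def line(pos: int, fam: str, div: float, assess: int, filt: str, gts: List[str]) -> str:
        info = f"FAMILY={fam};DIV={div:.2f};ASSESS={assess}"
        return (
            f"chr1\t{pos}\t.\tA\t<INS:ME:ERV>\t.\t{filt}\t{info}\tGT\t" + "\t".join(gts)
        )

    divs = np.round(rng.uniform(1.0, 15.0, size=n), 2)
    assess_clean = rng.integers(0, 3, size=n)
    for j in range(n):
        pos = spacing * (j + 1)
        fam = families[j % len(families)]
        gts = [gt_str(int(geno[i, j])) for i in range(n_isl)]
        records.append((pos, line(pos, fam, float(divs[j]), int(assess_clean[j]), "PASS", gts)))
        if j < n_overlap:
            # duplicate call from a different family, worse divergence
            fam2 = families[(j + 1) % len(families)]
            records.append(
                (pos + 40, line(pos + 40, fam2, float(divs[j]) + 5.0, int(assess_clean[j]), "PASS", gts))
            )
    base = spacing * (n + 2)
    gts_q0 = lambda: [gt_str(int(g)) for g in rng.binomial(2, cfg.q0, size=n_isl)]
    for j in range(n_assess):
        records.append((base + spacing * j, line(base + spacing * j, families[0], 8.0, 3 + int(rng.integers(0, 3)), "PASS", gts_q0())))
    base2 = base + spacing * (n_assess + 1)
    for j in range(n_filter):
        records.append((base2 + spacing * j, line(base2 + spacing * j, families[1], 8.0, 1, "lc", gts_q0())))
    base3 = base2 + spacing * (n_filter + 1)
    for j in range(n_missing):
        gts = gts_q0()
        k_miss = int(math.floor(0.25 * n_isl)) + 1  # strictly more than 25%
        for idx in rng.choice(n_isl, size=min(k_miss, n_isl), replace=False):
            gts[idx] = "./."
        records.append((base3 + spacing * j, line(base3 + spacing * j, families[2], 8.0, 1, "PASS", gts)))

    records.sort(key=lambda t: t[0])
    header = (
        "##fileformat=VCFv4.2\n"
        "##source=isledv-simulate-erv\n"
        f"##contig=<ID=chr1,length={records[-1][0] + spacing}>\n"
        '##INFO=<ID=FAMILY,Number=1,Type=String,Description="ERV consensus family">\n'
        '##INFO=<ID=DIV,Number=1,Type=Float,Description="Percent divergence from consensus">\n'
        '##INFO=<ID=ASSESS,Number=1,Type=Integer,Description="Evidence quality flag">\n'
        '##FILTER=<ID=lc,Description="Low complexity / failed internal filters">\n'
        '##ALT=<ID=INS:ME:ERV,Description="ERV insertion">\n'
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(names) + "\n"
    )
    text = header + "\n".join(l for _, l in records) + "\n"
    truth = ERVGroundTruth(
        n_clean_loci=n,
        n_planted_assess=n_assess,
        n_planted_filter=n_filter,
        n_planted_missing=n_missing,
        n_planted_overlap=n_overlap,
        fixation_count={names[i]: int((freqs[i] == 1.0).sum()) for i in range(n_isl)},
        hom_nonref={names[i]: int((geno[i] == 2).sum()) for i in range(n_isl)},
    )
    return text, truth


# ---------------------------------------------------------------------------
# MSMC-format trajectories
# ---------------------------------------------------------------------------


def constant_trajectory(ne: float, n_epochs: int = 16, t_max: float = 2_000_000.0) -> List[DemographicEpoch]:
    """A constant-Ne trajectory discretised into log-spaced epochs (the shape
    a coalescent HMM reports), final epoch unbounded."""
    bounds = np.concatenate(([0.0], np.geomspace(1_000.0, t_max, n_epochs - 1)))
    epochs = []
    for i in range(len(bounds)):
        t0 = bounds[i]
        t1 = bounds[i + 1] if i + 1 < len(bounds) else math.inf
        epochs.append(DemographicEpoch(t0, t1, ne))
    return epochs


def simulate_msmc_output(
    trajectory: Sequence[DemographicEpoch],
    p: ScalingParams,
    noise_sd: float = 0.0,
    rng: Optional[np.random.Generator] = None,
) -> str:
    """Render a trajectory as MSMC2 ``.final.txt`` text — the exact inverse
    of :func:`isledv.demography.unscale`, with optional multiplicative
    log-normal noise on lambda (``noise_sd`` on the log scale)."""
    scaled = rescale(trajectory, p)
    lines = ["time_index\tleft_time_boundary\tright_time_boundary\tlambda"]
    for e in scaled:
        lam = e.lam
        if noise_sd > 0:
            if rng is None:
                raise ValueError("rng required when noise_sd > 0")
            lam *= float(np.exp(rng.normal(0.0, noise_sd)))
        right = "inf" if math.isinf(e.right_time) else repr(float(e.right_time))
        lines.append(f"{e.index}\t{float(e.left_time)!r}\t{right}\t{float(lam)!r}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Archipelago assembly
# ---------------------------------------------------------------------------


def _rng_for(cfg_seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(cfg_seed, spawn_key=key))


def build_archipelago(
    cfg: ArchipelagoConfig,
    out_dir: str,
    overwrite: bool = False,
) -> Dict[str, object]:
    """Write the full synthetic data set and return its ground truth.

    Deterministic under ``cfg.master_seed``: per-island, per-component random
    streams are derived through ``numpy`` SeedSequence spawn keys, so the
    same seed yields byte-identical files.  A manifest records sha256
    checksums of every file.
    """
    manifest_path = os.path.join(out_dir, "manifest.json")
    if os.path.exists(manifest_path) and not overwrite:
        raise FileExistsError(
            f"{out_dir!r} already holds an archipelago (pass overwrite=True)"
        )
    os.makedirs(out_dir, exist_ok=True)
    truth: Dict[str, object] = {"islands": {}, "config": {
        "ne_per_km2": cfg.ne_per_km2,
        "area_exponent": cfg.area_exponent,
        "mu_per_year": cfg.mu_per_year,
        "generation_time_years": cfg.generation_time_years,
        "genome": cfg.genome,
        "tract_mean_bp": cfg.tract_mean_bp,
        "master_seed": cfg.master_seed,
    }}
    files: Dict[str, str] = {}

    with open(os.path.join(out_dir, "islands.csv"), "w") as fh:
        fh.write("sample,island,area_km2,group\n")
        for name, area in cfg.islands:
            fh.write(f"{name},{name},{area},synthetic\n")
    files["islands.csv"] = ""

    mu_g = cfg.mu_per_generation
    for i, (name, area) in enumerate(cfg.islands):
        ne = cfg.ne_for_area(area)
        ind = simulate_genotypes(name, ne, cfg, _rng_for(cfg.master_seed, i, 0))
        vcf_name = f"{name}.vcf"
        write_individual_vcf(ind, os.path.join(out_dir, vcf_name))
        files[vcf_name] = ""
        traj = constant_trajectory(ne, cfg.msmc_n_epochs)
        msmc_name = f"{name}.final.txt"
        with open(os.path.join(out_dir, msmc_name), "w") as fh:
            fh.write(
                simulate_msmc_output(
                    traj, cfg.scaling, cfg.msmc_noise_sd, _rng_for(cfg.master_seed, i, 1)
                )
            )
        files[msmc_name] = ""
        truth["islands"][name] = {
            "area_km2": area,
            "ne": ne,
            "expected_het": 4.0 * ne * mu_g,
            "n_callable": ind.n_callable(),
            "n_het_callable": ind.n_het_callable(),
            "planted_fail_counts": ind.planted_counts(),
            "trajectory": [[e.t_start, e.t_end if math.isfinite(e.t_end) else None, e.ne] for e in traj],
        }

    erv_rng = _rng_for(cfg.master_seed, 1_000)
    melt_text, erv_truth = simulate_erv_archipelago(
        [(n, cfg.ne_for_area(a)) for n, a in cfg.islands], cfg.erv, erv_rng
    )
    with open(os.path.join(out_dir, "melt.vcf"), "w") as fh:
        fh.write(melt_text)
    files["melt.vcf"] = ""
    truth["erv"] = {
        "n_clean_loci": erv_truth.n_clean_loci,
        "n_planted_assess": erv_truth.n_planted_assess,
        "n_planted_filter": erv_truth.n_planted_filter,
        "n_planted_missing": erv_truth.n_planted_missing,
        "n_planted_overlap": erv_truth.n_planted_overlap,
        "fixation_count": erv_truth.fixation_count,
        "hom_nonref": erv_truth.hom_nonref,
    }

    with open(os.path.join(out_dir, "ground_truth.json"), "w") as fh:
        json.dump(truth, fh, indent=2)
    files["ground_truth.json"] = ""

    for fname in files:
        with open(os.path.join(out_dir, fname), "rb") as fh:
            files[fname] = hashlib.sha256(fh.read()).hexdigest()
    with open(manifest_path, "w") as fh:
        json.dump({"files": files, "master_seed": cfg.master_seed}, fh, indent=2, sort_keys=True)
    return truth
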