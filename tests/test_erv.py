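"""ERV insertion-call overlap resolution, filtering and counting."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from isledv import (
    ERVCall,
    ERVFilterConfig,
    Genotype,
    count_hom_nonref,
    filter_calls,
    resolve_overlaps,
    wf_frequencies,
)

HOM, HET, REF, MISS = Genotype.HOM_ALT, Genotype.HET, Genotype.HOM_REF, Genotype.MISSING


def call(pos, family="A", div=5.0, assess=1, filt="PASS", gts=None, chrom="chr1"):
    return ERVCall(chrom, pos, family, div, assess, filt, gts or [REF, REF, REF, REF])


class TestOverlapResolution:
    def test_keeps_most_similar_family_within_radius(self):
        kept = resolve_overlaps([call(1_000, "A", 5.0), call(1_050, "B", 8.0)], 100)
        assert [(c.pos, c.family) for c in kept] == [(1_000, "A")]

    def test_distant_calls_both_kept(self):
        kept = resolve_overlaps([call(1_000, "A", 5.0), call(1_300, "B", 8.0)], 100)
        assert len(kept) == 2

    def test_same_family_cluster_untouched(self):
        kept = resolve_overlaps([call(1_000, "A", 5.0), call(1_050, "A", 8.0)], 100)
        assert len(kept) == 2

    def test_transitive_chaining(self):
        # A-B within 100, B-C within 100, A-C 160 apart: one cluster
        kept = resolve_overlaps(
            [call(1_000, "A", 5.0), call(1_080, "B", 3.0), call(1_160, "C", 9.0)], 100
        )
        assert [(c.pos, c.family) for c in kept] == [(1_080, "B")]

    def test_unsorted_input_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            resolve_overlaps([call(1_300), call(1_000)], 100)

    def test_matches_quadratic_clustering_oracle(self):
        rng = np.random.default_rng(23)
        n = 300
        chroms = np.sort(rng.integers(0, 2, size=n))
        pos = np.empty(n, dtype=int)
        for c in (0, 1):
            k = int((chroms == c).sum())
            pos[chroms == c] = np.sort(rng.integers(0, 12_000, size=k))
        fams = rng.integers(0, 5, size=n)
        divs = rng.random(n) * 15  # continuous: ties absent a.s.
        calls = [
            call(int(p), f"F{f}", float(d), chrom=f"chr{c+1}")
            for p, f, d, c in zip(pos, fams, divs, chroms)
        ]
        kept = resolve_overlaps(calls, 100)

        # O(n^2) single-linkage oracle
        parent = list(range(n))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(n):
            for j in range(i + 1, n):
                if calls[i].chrom == calls[j].chrom and abs(calls[i].pos - calls[j].pos) <= 100:
                    parent[find(i)] = find(j)
        clusters = {}
        for i in range(n):
            clusters.setdefault(find(i), []).append(calls[i])
        expected = []
        for members in clusters.values():
            if len({m.family for m in members}) > 1:
                expected.append(min(members, key=lambda c: (c.divergence, c.pos, c.family)))
            else:
                expected.extend(members)
        key = lambda cs: sorted((c.chrom, c.pos, c.family) for c in cs)
        assert key(kept) == key(expected)


class TestFilters:
    def test_assess_boundary(self):
        assert filter_calls([call(1, assess=3)]) == []
        assert len(filter_calls([call(1, assess=2)])) == 1

    def test_non_pass_removed(self):
        assert filter_calls([call(1, filt="lc")]) == []
        kept = filter_calls([call(1, filt="lc")], ERVFilterConfig(require_pass=False))
        assert len(kept) == 1

    def test_missing_fraction_boundary(self):
        gts16 = [REF] * 11 + [MISS] * 5  # 5/16 = 0.3125 > 0.25
        assert filter_calls([call(1, gts=gts16)]) == []
        gts16 = [REF] * 12 + [MISS] * 4  # exactly 0.25: kept
        assert len(filter_calls([call(1, gts=gts16)])) == 1

    def test_ten_call_rule_enumeration(self):
        calls = [call(i * 1_000, assess=1) for i in range(1, 8)]  # 7 clean
        calls.append(call(8_000, assess=4))
        calls.append(call(9_000, filt="lc"))
        calls.append(call(10_000, gts=[MISS, MISS, REF, REF]))
        kept = filter_calls(calls)
        assert len(kept) == 7

    def test_order_invariance_when_clusters_filter_homogeneously(self):
        # overlap resolution and filtering commute (absent divergence ties)
        # whenever each overlap cluster passes or fails the filters as a
        # whole; removing part of a cluster can otherwise re-chain it
        rng = np.random.default_rng(31)
        positions = np.sort(rng.integers(0, 5_000, size=60))
        calls = [
            call(int(p), family=f"F{rng.integers(0, 3)}", div=float(rng.random() * 15))
            for p in positions
        ]
        # single-linkage clusters at radius 100 on the sorted positions
        cluster_of, cid = [], 0
        for i, c in enumerate(calls):
            if i and c.pos - calls[i - 1].pos > 100:
                cid += 1
            cluster_of.append(cid)
        failing = {k for k in range(cid + 1) if rng.random() < 0.3}
        for c, k in zip(calls, cluster_of):
            c.assess = 5 if k in failing else 1
        a = filter_calls(resolve_overlaps(calls, 100))
        b = resolve_overlaps(filter_calls(calls), 100)
        key = lambda cs: sorted((c.pos, c.family) for c in cs)
        assert key(a) == key(b)


class TestCount:
    GTS = [HOM, HOM, HOM, HET, HET, MISS]

    def test_all_hom_ref_gives_zero(self):
        s = count_hom_nonref([call(1)], "s1", ["s1", "s2", "s3", "s4"])
        assert s.n_hom_nonref == 0

    def test_counts_hom_alt_only(self):
        calls = [call(i * 1_000, gts=[g]) for i, g in enumerate(self.GTS, start=1)]
        s = count_hom_nonref(calls, "s1", ["s1"])
        assert (s.n_hom_nonref, s.n_het, s.n_polymorphic_total) == (3, 2, 6)

    def test_unknown_sample_raises(self):
        with pytest.raises(ValueError, match="unknown sample"):
            count_hom_nonref([call(1)], "nope", ["s1", "s2", "s3", "s4"])

    def test_monotone_in_missingness_threshold(self):
        rng = np.random.default_rng(41)
        calls = []
        for i in range(50):
            gts = [
                [REF, HET, HOM, MISS][rng.integers(0, 4)] for _ in range(8)
            ]
            calls.append(call((i + 1) * 1_000, gts=gts))
        counts = []
        for mx in (1.0, 0.5, 0.25, 0.1):
            kept = filter_calls(calls, ERVFilterConfig(max_missing_fraction=mx))
            counts.append(count_hom_nonref(kept, "s1", [f"s{j+1}" for j in range(8)]).n_hom_nonref)
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestWrightFisher:
    def test_zero_generations_returns_initial_frequency(self):
        q = wf_frequencies(50, 0.0, 0.5, 100, 0, np.random.default_rng(0))
        assert np.all(q == 0.5)

    def test_neutral_fixation_fraction_near_q0(self):
        # neutral WF: P(fix) = q0; census after ~20N generations
        rng = np.random.default_rng(1)
        q = wf_frequencies(50, 0.0, 0.5, 10_000, 2_000, rng)
        fixed = (q == 1.0).mean()
        se = np.sqrt(0.5 * 0.5 / 10_000)
        assert abs(fixed - 0.5) < 3 * se

    def test_cap_rescaling_and_error(self):
        with pytest.raises(ValueError, match="cap"):
            wf_frequencies(50_000, -0.01, 0.5, 10, 1, np.random.default_rng(0), rescale_capped=False)
        q = wf_frequencies(50_000, -0.01, 0.5, 10, 1, np.random.default_rng(0))
        assert q.shape == (10,)


def test_hom_nonref_declines_with_island_area(default_archipelago):
    """Drift fixes mildly deleterious insertions on small islands; the
    per-individual homozygous-insertion count falls with log area."""
    _, truth, result = default_archipelago
    tb = result.table
    rho, _ = spearmanr(tb["log10_area"], tb["erv_hom_nonref"])
    assert rho < 0
    # pipeline counts over clean loci match the generator's emitted genotypes
    for island, n in truth["erv"]["hom_nonref"].items():
        assert result.table.loc[island, "erv_hom_nonref"] == n
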