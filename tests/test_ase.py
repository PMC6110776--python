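"""Four-category pair classification, coverage, apportionment, FPKM."""

import numpy as np
import pytest

from petalsplit.ase import (
    AlleleCoverage,
    apportion_ambiguous,
    classify_read_pairs,
    coverage_tracks,
    combine_tracks,
    estimate_allele_fraction,
    expression_per_stage,
)
from petalsplit.seqio import SequenceRecord, revcomp
from petalsplit.simdata import ReadPair, SimParams, simulate_rnaseq_pairs


def _pair_from(tx, start, frag=300, rl=100, pid="p"):
    frag_seq = tx[start : start + frag]
    return ReadPair(pid, frag_seq[:rl], revcomp(frag_seq)[:rl], 0)


def test_pair_over_diagnostic_snp_is_allele_specific(allele_pair):
    a, b, _ = allele_pair
    # SNPs sit at multiples of 150 outside [800, 1300]; cover position 150
    p = _pair_from(a.seq, 100)
    cats = classify_read_pairs([p], a, b)
    assert len(cats.cat_i) == 1 and cats.total == 1
    pb = _pair_from(b.seq, 100)
    cats = classify_read_pairs([pb], a, b)
    assert len(cats.cat_ii) == 1


def test_pair_inside_identical_region_is_ambiguous(allele_pair):
    a, b, _ = allele_pair
    p = _pair_from(a.seq, 850, frag=250)       # fully inside [800, 1300]
    cats = classify_read_pairs([p], a, b)
    assert len(cats.cat_iii) == 1


def test_pair_matching_decoy_is_category_iv(allele_pair):
    a, b, decoys = allele_pair
    p = _pair_from(a.seq, 850, frag=250)
    cats = classify_read_pairs([p], a, b, decoys)
    assert len(cats.cat_iv) == 1 and len(cats.cat_iii) == 0


def test_category_partition_conservation(allele_pair):
    a, b, decoys = allele_pair
    pairs = simulate_rnaseq_pairs((a, b), SimParams(
        mixture=0.6, error_rate=0.0, te_len=2000, ltr_len=300),
        seed=8, n_pairs=500)
    cats = classify_read_pairs(pairs, a, b, decoys)
    # at zero error rate every simulated pair matches at least one allele
    assert cats.total == 500
    ids = [c.pair_id for group in
           (cats.cat_i, cats.cat_ii, cats.cat_iii, cats.cat_iv)
           for c in group]
    assert len(ids) == len(set(ids))           # categories are disjoint


def test_categories_verified_against_placement_enumeration(allele_pair):
    """Brute-force oracle: enumerate all concordant placements directly."""
    from petalsplit.align import scan_end_to_end
    a, b, decoys = allele_pair
    pairs = simulate_rnaseq_pairs((a, b), SimParams(
        mixture=0.5, error_rate=0.01, te_len=2000, ltr_len=300),
        seed=9, n_pairs=60)
    cats = classify_read_pairs(pairs, a, b, decoys)
    got = {}
    for label, group in (("i", cats.cat_i), ("ii", cats.cat_ii),
                         ("iii", cats.cat_iii), ("iv", cats.cat_iv)):
        for c in group:
            got[c.pair_id] = label

    def best(pair, ref):
        hits1 = scan_end_to_end(pair.r1, ref.seq, 2)
        hits2 = scan_end_to_end(pair.r2, ref.seq, 2)
        scores = [h1.mismatches + h2.mismatches
                  for h1 in hits1 for h2 in hits2
                  if h1.strand != h2.strand
                  and (h1 if h1.strand == "+" else h2).offset
                  <= (h2 if h1.strand == "+" else h1).offset]
        return min(scores) if scores else None

    for pair in pairs:
        sa, sb = best(pair, a), best(pair, b)
        sd = min((s for s in (best(pair, d) for d in decoys)
                  if s is not None), default=None)
        if sa is None and sb is None:
            expect = None
        else:
            ab = min(s for s in (sa, sb) if s is not None)
            if sd is not None and sd <= ab:
                expect = "iv"
            elif sb is None or (sa is not None and sa < sb):
                expect = "i"
            elif sa is None or sb < sa:
                expect = "ii"
            else:
                expect = "iii"
        assert got.get(pair.id) == expect


# ---------------------------------------------------------------------------
# coverage
# ---------------------------------------------------------------------------

def test_pair_coverage_excludes_fragment_gap(allele_pair):
    a, b, _ = allele_pair
    p = _pair_from(a.seq, 0, frag=250, rl=100)
    cats = classify_read_pairs([p], a, b)
    cov = coverage_tracks(cats, 2000, 2000, library_size=1, scale=1.0)
    track = cov.cov_i + cov.cov_ii + cov.ambiguous
    assert track[:100].sum() == 100            # mate 1: positions 1-100
    assert track[100:150].sum() == 0           # inner gap uncovered
    assert track[150:250].sum() == 100         # mate 2: positions 151-250
    assert track[250:].sum() == 0


def test_track_equals_brute_force_tally(allele_pair):
    a, b, decoys = allele_pair
    pairs = simulate_rnaseq_pairs((a, b), SimParams(
        mixture=0.7, error_rate=0.0, te_len=2000, ltr_len=300),
        seed=10, n_pairs=300)
    cats = classify_read_pairs(pairs, a, b, decoys)
    cov = coverage_tracks(cats, 2000, 2000, library_size=300, scale=300.0)
    manual = np.zeros(2000)
    for group in (cats.cat_i, cats.cat_ii, cats.cat_iii, cats.cat_iv):
        for c in group:
            for lo, hi in c.cov:
                manual[lo - 1 : hi] += 1.0
    total = cov.cov_i + cov.cov_ii + cov.ambiguous
    assert np.allclose(total, manual)


def test_library_scaling_invariance(allele_pair):
    a, b, _ = allele_pair
    pairs = simulate_rnaseq_pairs((a, b), SimParams(
        mixture=0.5, error_rate=0.0, te_len=2000, ltr_len=300),
        seed=11, n_pairs=100)
    cats = classify_read_pairs(pairs, a, b)
    base = coverage_tracks(cats, 2000, 2000, library_size=100)
    # duplicating the library (same pairs twice, doubled size) changes nothing
    doubled_cats = classify_read_pairs(list(pairs) + list(pairs), a, b)
    doubled = coverage_tracks(doubled_cats, 2000, 2000, library_size=200)
    assert np.allclose(base.cov_i + base.cov_ii + base.ambiguous,
                       doubled.cov_i + doubled.cov_ii + doubled.ambiguous)


# ---------------------------------------------------------------------------
# apportionment
# ---------------------------------------------------------------------------

def test_symmetric_coverage_splits_ambiguous_evenly():
    n = 500
    cov = AlleleCoverage(np.ones(n), np.ones(n), np.full(n, 2.0), window=241)
    a, b = apportion_ambiguous(cov)
    assert np.allclose(a, 2.0) and np.allclose(b, 2.0)


def test_all_ambiguous_to_a_when_b_absent():
    n = 500
    cov = AlleleCoverage(np.ones(n), np.zeros(n), np.ones(n), window=241)
    a, b = apportion_ambiguous(cov)
    assert np.allclose(a, 2.0) and np.allclose(b, 0.0)


def test_zero_windows_split_half_half():
    n = 100
    cov = AlleleCoverage(np.zeros(n), np.zeros(n), np.ones(n), window=41)
    a, b = apportion_ambiguous(cov)
    assert np.allclose(a, 0.5) and np.allclose(b, 0.5)


def test_even_window_rejected():
    cov = AlleleCoverage(np.ones(10), np.ones(10), np.ones(10), window=240)
    with pytest.raises(ValueError):
        apportion_ambiguous(cov)


def test_apportionment_conserves_coverage(allele_pair):
    a, b, decoys = allele_pair
    pairs = simulate_rnaseq_pairs((a, b), SimParams(
        mixture=0.3, error_rate=0.005, te_len=2000, ltr_len=300),
        seed=12, n_pairs=1_000)
    frac, cov = estimate_allele_fraction(pairs, a, b, decoys)
    err = np.abs((cov.assigned_a + cov.assigned_b)
                 - (cov.cov_i + cov.cov_ii + cov.ambiguous)).max()
    assert err <= 1e-9


def test_mixture_recovered_within_tolerance(allele_pair):
    a, b, decoys = allele_pair
    pairs = simulate_rnaseq_pairs((a, b), SimParams(
        mixture=0.7, error_rate=0.005, te_len=2000, ltr_len=300),
        seed=13, n_pairs=3_000)
    frac, _ = estimate_allele_fraction(pairs, a, b, decoys)
    assert abs(frac - 0.7) <= 0.05


def test_zero_divergence_alleles_split_half(allele_pair):
    a, _, _ = allele_pair
    twin = SequenceRecord("alleleB", a.seq)
    pairs = simulate_rnaseq_pairs((a, twin), SimParams(
        mixture=0.9, error_rate=0.0, te_len=2000, ltr_len=300),
        seed=14, n_pairs=500)
    cats = classify_read_pairs(pairs, a, twin)
    assert len(cats.cat_i) == 0 and len(cats.cat_ii) == 0
    frac, _ = estimate_allele_fraction(pairs, a, twin)
    assert frac == pytest.approx(0.5)


# ---------------------------------------------------------------------------
# expression table
# ---------------------------------------------------------------------------

def test_fpkm_formula():
    df = expression_per_stage({"s1": (1_000.0, 0.0)}, 2_000, 2_000,
                              {"s1": 1_000_000})
    assert df.loc[0, "fpkm_a"] == pytest.approx(500.0)
    assert df.loc[0, "fpkm_b"] == 0.0


def test_stage_profile_recovered(allele_pair):
    a, b, decoys = allele_pair
    profile = {"s1": 2.0, "s2": 1.0, "s3": 0.5}
    frags, libs = {}, {}
    for i, (stage, level) in enumerate(profile.items()):
        n = int(1_000 * level)
        pairs = simulate_rnaseq_pairs((a, b), SimParams(
            mixture=0.5, error_rate=0.005, te_len=2000, ltr_len=300),
            seed=20 + i, n_pairs=n)
        cats = classify_read_pairs(pairs, a, b, decoys)
        frac, cov = estimate_allele_fraction(pairs, a, b, decoys)
        frags[stage] = (cats.total * frac, cats.total * (1 - frac))
        libs[stage] = 1_000_000
    df = expression_per_stage(frags, 2_000, 2_000, libs).set_index("stage")
    fa = df["fpkm_a"]
    assert fa["s1"] > fa["s2"] > fa["s3"]
    assert fa["s1"] / fa["s2"] == pytest.approx(2.0, rel=0.1)
    assert fa["s2"] / fa["s3"] == pytest.approx(2.0, rel=0.1)
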