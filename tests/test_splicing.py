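"""Acceptor prediction, chimeric transcript assembly, miR172 site scanning."""

import numpy as np
import pytest

from petalsplit.seqio import GenomicInterval, SequenceRecord, revcomp
from petalsplit.simdata import (
    MIR172,
    MIR172_TARGET,
    SimParams,
    simulate_locus,
)
from petalsplit.splicing import (
    AcceptorConfig,
    build_transcript_pair,
    compare_mir_status,
    predict_new_acceptor,
    scan_mir_target,
)


# ---------------------------------------------------------------------------
# acceptor prediction
# ---------------------------------------------------------------------------

def test_planted_acceptor_found_at_truth_position(locus):
    got = predict_new_acceptor(locus.ins_haplotype.seq, locus.te.ltr5)
    assert got == locus.acceptor_pos


def test_ag_without_polypyrimidine_tract_rejected():
    # AG preceded by only 2 pyrimidines in the 12-base window
    seq = "G" * 20 + "AAAAAAAAAACT" + "AG" + "G" * 20
    ltr = GenomicInterval("x", 1, len(seq))
    assert predict_new_acceptor(seq, ltr) is None


def test_qualifying_ag_found():
    seq = "G" * 20 + "TTTCCTTTCCTT" + "AG" + "G" * 20
    ltr = GenomicInterval("x", 1, len(seq))
    assert predict_new_acceptor(seq, ltr) == 20 + 12 + 2


def test_shuffled_ltr_negative_controls_match_motif_frequency():
    """Acceptors in shuffled LTRs appear no more often than a brute-force
    motif scan of the same sequences says they should."""
    rng = np.random.default_rng(0)
    found, brute = 0, 0
    for _ in range(20):
        seq = "".join(rng.choice(list("ACGT"), 300))
        ltr = GenomicInterval("x", 1, 300)
        hit = predict_new_acceptor(seq, ltr)
        if hit is not None:
            found += 1
        # brute-force motif scan oracle
        any_motif = any(
            seq[g - 2] == "A" and seq[g - 1] == "G"
            and sum(1 for c in seq[g - 14 : g - 2] if c in "CT") >= 6
            for g in range(14, 301)
        )
        brute += bool(any_motif)
        assert (hit is not None) == any_motif
    assert found == brute


# ---------------------------------------------------------------------------
# transcript pair
# ---------------------------------------------------------------------------

def test_standard_fixture_truncation(locus):
    tp = build_transcript_pair(locus)
    assert tp.wt_protein_len == 460
    assert tp.mut_protein_len == 342       # 302 exonic + 40 chimeric codons
    assert tp.premature_stop
    assert tp.lost_exons == (9, 10)


def test_mutant_protein_matches_manual_translation(locus):
    """Independent oracle: translate the mutant mRNA codon by codon."""
    from Bio.Seq import Seq
    tp = build_transcript_pair(locus)
    mrna = tp.mut_mrna.seq
    start = 60                             # annotated start at mRNA pos 61
    assert mrna[start : start + 3] == "ATG"
    prot = []
    for i in range(start, len(mrna) - 2, 3):
        aa = str(Seq(mrna[i : i + 3]).translate())
        if aa == "*":
            break
        prot.append(aa)
    assert len(prot) == tp.mut_protein_len


def test_mut_shares_exons_1_to_8(locus):
    tp = build_transcript_pair(locus)
    assert tp.mut_exons[:8] == locus.gene_model_ins.exons[:8]
    wt_prefix = "".join(
        e.extract(locus.wt_haplotype.seq) for e in locus.gene_model_wt.exons[:8])
    assert tp.mut_mrna.seq.startswith(wt_prefix)


def test_premature_stop_implies_shorter_protein(locus):
    tp = build_transcript_pair(locus)
    assert tp.premature_stop == (tp.mut_protein_len < tp.wt_protein_len)


def test_insertion_downstream_of_stop_is_neutral(locus):
    """Planting the stop codon upstream of the insertion (in exon 7) makes
    the truncation silent: identical proteins, no premature stop."""
    import dataclasses
    gm = locus.gene_model_wt
    # mRNA position of codon 250 of the CDS: inside exon 7
    m_pos = 60 + 3 * 249 + 1                       # 1-based, = 808
    cum = 0
    for e in gm.exons:
        if cum + e.length >= m_pos:
            g_pos = e.start + (m_pos - cum - 1)    # genomic, same on both haps
            break
        cum += e.length

    def plant_stop(seq):
        return seq[: g_pos - 1] + "TAA" + seq[g_pos + 2 :]

    fx = dataclasses.replace(
        locus,
        wt_haplotype=SequenceRecord("wt_hap", plant_stop(locus.wt_haplotype.seq)),
        ins_haplotype=SequenceRecord("ins_hap", plant_stop(locus.ins_haplotype.seq)),
    )
    tp = build_transcript_pair(fx)
    assert tp.wt_protein_len == tp.mut_protein_len == 249
    assert not tp.premature_stop


# ---------------------------------------------------------------------------
# miR target scanning
# ---------------------------------------------------------------------------

def test_perfect_site_scores_zero():
    rng = np.random.default_rng(1)
    mrna = "".join(rng.choice(list("ACGT"), 200)) + MIR172_TARGET + \
        "".join(rng.choice(list("ACGT"), 200))
    sites = scan_mir_target(mrna, MIR172)
    assert sites and sites[0].score == 0.0 and sites[0].position == 201
    assert set(sites[0].pairing) == {"|"}


def test_single_wobble_at_position_15_scores_half():
    site = list(MIR172_TARGET)
    # miRNA position 15 pairs with site index L-15 (0-based)
    L = len(MIR172)
    idx = L - 15
    mir15 = MIR172[14]
    # replace the complementary base with a wobble partner
    site[idx] = "T" if mir15 == "G" else "G"
    assert mir15 in "GT", "position 15 must allow a wobble"
    sites = scan_mir_target("".join(site), MIR172, cutoff=3.0)
    assert sites and sites[0].score == pytest.approx(0.5)


def test_seed_region_penalties_doubled():
    site = list(MIR172_TARGET)
    L = len(MIR172)
    # mismatch opposite miRNA position 5 (seed): penalty 2.0
    idx = L - 5
    site[idx] = {"A": "C", "C": "A", "G": "A", "T": "G"}[site[idx]]
    sites = scan_mir_target("".join(site), MIR172, cutoff=3.0)
    assert sites and sites[0].score == pytest.approx(2.0)


@pytest.mark.parametrize("seed", range(10))
def test_scan_agrees_with_exhaustive_penalty_oracle(seed):
    rng = np.random.default_rng(seed)
    mrna = "".join(rng.choice(list("ACGT"), 400))
    if rng.random() < 0.5:   # plant a degraded site in half the runs
        pos = int(rng.integers(0, 380))
        site = list(MIR172_TARGET)
        site[int(rng.integers(0, 21))] = "ACGT"[int(rng.integers(0, 4))]
        mrna = mrna[:pos] + "".join(site) + mrna[pos + 21 :]
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    L = len(MIR172)
    expected = []
    for s in range(len(mrna) - L + 1):
        total = 0.0
        for i in range(1, L + 1):
            m, t = MIR172[i - 1], mrna[s + L - i]
            if comp[m] == t:
                pen = 0.0
            elif (m == "G" and t == "T") or (m == "T" and t == "G"):
                pen = 0.5
            else:
                pen = 1.0
            if 2 <= i <= 13:
                pen *= 2
            total += pen
        if total <= 3.0:
            expected.append((s + 1, total))
    got = sorted((x.position, x.score) for x in scan_mir_target(mrna, MIR172))
    assert got == sorted(expected)


def test_mir_status_lost_on_truncation(locus):
    tp = build_transcript_pair(locus)
    status = compare_mir_status(tp, locus.mir_seq)
    assert status == {"wt_has_site": True, "mut_has_site": False}


def test_site_in_early_exon_survives_truncation(locus):
    """A site upstream of the truncation point is retained by both."""
    tp = build_transcript_pair(locus)
    early = tp.wt_mrna.seq[:500] + MIR172_TARGET + tp.wt_mrna.seq[500:]
    early_mut = tp.mut_mrna.seq[:500] + MIR172_TARGET + tp.mut_mrna.seq[500:]
    import dataclasses
    tp2 = dataclasses.replace(
        tp,
        wt_mrna=SequenceRecord("wt", early),
        mut_mrna=SequenceRecord("mut", early_mut),
    )
    status = compare_mir_status(tp2, locus.mir_seq)
    assert status["wt_has_site"] and status["mut_has_site"]


def test_no_site_anywhere():
    rng = np.random.default_rng(3)
    mrna = "".join(rng.choice(list("ACGT"), 300))
    # random sequence essentially never reaches penalty <= 3
    assert scan_mir_target(mrna, MIR172) == []
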