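"""Internal alignment kernels.

Two matchers are shared by the pipeline stages:

* an exact, substitution-only end-to-end matcher (Hamming scan) with an
  optional pigeonhole-seeded index for repeated queries against one
  target — this is the read-placement contract used for junction
  genotyping and allele-specific read classification (up to ``max_mm``
  mismatches over the whole read, no indels);
* an ungapped seed-and-extend local matcher used for marker mapping and
  the LTR family census.  Because every simulated mutation is a
  substitution, true matches lie on a single diagonal, which the matcher
  exploits: exact seed words are grouped per (strand, diagonal), chained,
  and extended with an X-drop rule.

Bases outside {A,C,G,T} (e.g. N) mismatch everything, including N.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .seqio import revcomp

__all__ = ["Placement", "hamming", "scan_end_to_end", "EndToEndIndex",
           "LocalMatch", "SeedExtendMatcher"]

_ACGT = frozenset(b"ACGT")


def _as_bytes(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _ambig_mask(arr: np.ndarray) -> np.ndarray:
    """True where the base is not a plain A/C/G/T."""
    mask = np.ones(arr.shape, dtype=bool)
    for b in b"ACGT":
        mask &= arr != b
    return mask


@dataclass(frozen=True)
class Placement:
    """One end-to-end placement of a read on a target.

    ``offset`` is the 0-based start of the read on the forward target;
    the read covers target positions ``offset+1 .. offset+len(read)``
    (1-based inclusive) regardless of strand.
    """

    offset: int
    strand: str
    mismatches: int


def hamming(a: str, b: str) -> int:
    """Mismatch count between equal-length strings; non-ACGT mismatches all."""
    if len(a) != len(b):
        raise ValueError("hamming requires equal lengths")
    xa, xb = _as_bytes(a), _as_bytes(b)
    return int(np.count_nonzero((xa != xb) | _ambig_mask(xa) | _ambig_mask(xb)))


def _scan_one_strand(read_arr: np.ndarray, tgt_arr: np.ndarray,
                     tgt_ambig: np.ndarray, max_mm: int) -> list[tuple[int, int]]:
    n, r = tgt_arr.size, read_arr.size
    if r > n:
        return []
    windows = np.lib.stride_tricks.sliding_window_view(tgt_arr, r)
    amb_win = np.lib.stride_tricks.sliding_window_view(tgt_ambig, r)
    read_amb = _ambig_mask(read_arr)
    mm = np.count_nonzero((windows != read_arr) | amb_win | read_amb, axis=1)
    return [(int(o), int(m)) for o, m in zip(np.nonzero(mm <= max_mm)[0], mm[mm <= max_mm])]


def scan_end_to_end(read: str, target: str, max_mm: int = 2) -> list[Placement]:
    """All placements of ``read`` on both strands of ``target`` with <= max_mm
    mismatches (exhaustive Hamming scan; substitution-only)."""
    if len(read) > len(target):
        return []
    tgt = _as_bytes(target)
    tgt_amb = _ambig_mask(tgt)
    out = [Placement(o, "+", m)
           for o, m in _scan_one_strand(_as_bytes(read), tgt, tgt_amb, max_mm)]
    out += [Placement(o, "-", m)
            for o, m in _scan_one_strand(_as_bytes(revcomp(read)), tgt, tgt_amb, max_mm)]
    return sorted(out, key=lambda p: (p.offset, p.strand))


class EndToEndIndex:
    """Pigeonhole-seeded index over one target for repeated read queries.

    The read is split into ``max_mm + 1`` contiguous segments; any
    placement with at most ``max_mm`` mismatches must contain at least one
    exact segment, so exact segment hits enumerate every candidate offset,
    each of which is then verified by Hamming count.  Results are identical
    to :func:`scan_end_to_end`.
    """

    def __init__(self, target: str, read_len: int, max_mm: int = 2) -> None:
        if read_len < max_mm + 1:
            raise ValueError("read_len must exceed max_mm")
        self.target = target
        self.read_len = read_len
        self.max_mm = max_mm
        self._tgt = _as_bytes(target)
        self._tgt_amb = _ambig_mask(self._tgt)
        bounds = np.linspace(0, read_len, max_mm + 2, dtype=int)
        self._segments = list(zip(bounds[:-1], bounds[1:]))
        self._index: dict[str, list[int]] = {}
        for seg_start, seg_end in self._segments:
            w = seg_end - seg_start
            for pos in range(len(target) - w + 1):
                word = target[pos : pos + w]
                self._index.setdefault(word, []).append(pos)

    def _candidates(self, read: str) -> set[int]:
        cands: set[int] = set()
        for seg_start, seg_end in self._segments:
            for pos in self._index.get(read[seg_start:seg_end], ()):
                off = pos - seg_start
                if 0 <= off <= len(self.target) - len(read):
                    cands.add(off)
        return cands

    def _verify(self, read_arr: np.ndarray, read_amb: np.ndarray,
                offsets: Iterable[int]) -> list[tuple[int, int]]:
        out = []
        r = read_arr.size
        for off in offsets:
            window = self._tgt[off : off + r]
            mm = int(np.count_nonzero(
                (window != read_arr) | self._tgt_amb[off : off + r] | read_amb))
            if mm <= self.max_mm:
                out.append((off, mm))
        return out

    def placements(self, read: str) -> list[Placement]:
        if len(read) != self.read_len:
            raise ValueError(
                f"index built for {self.read_len} bp reads, got {len(read)} bp")
        out = []
        fwd = _as_bytes(read)
        out += [Placement(o, "+", m)
                for o, m in self._verify(fwd, _ambig_mask(fwd), self._candidates(read))]
        rc = revcomp(read)
        rc_arr = _as_bytes(rc)
        out += [Placement(o, "-", m)
                for o, m in self._verify(rc_arr, _ambig_mask(rc_arr), self._candidates(rc))]
        return sorted(out, key=lambda p: (p.offset, p.strand))

    def best_score(self, read: str) -> int | None:
        """Minimum mismatch count over all placements, or None."""
        hits = self.placements(read)
        return min(p.mismatches for p in hits) if hits else None


# ---------------------------------------------------------------------------
# Ungapped seed-and-extend local matching
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LocalMatch:
    """An ungapped local match of a query on a genome contig.

    Genome and query coordinates are 1-based inclusive; ``q_start`` always
    refers to the forward query.  On the '-' strand the reverse complement
    of the query matches the forward genome at ``g_start..g_end``.
    """

    contig: str
    g_start: int
    g_end: int
    q_start: int
    q_end: int
    strand: str
    length: int
    identity: float


# extension scoring: reward a match, penalize a mismatch heavily so the
# extension stops near the true boundary of a diverged copy
_MATCH_SCORE = 1
_MISMATCH_SCORE = -3
_XDROP = 15


def _extend(genome: np.ndarray, query: np.ndarray,
            g0: int, g1: int, q0: int, q1: int) -> tuple[int, int, int, int]:
    """Extend [g0,g1) x [q0,q1) outward on one diagonal with X-drop."""
    # left
    best_gain, best_steps = 0, 0
    score, steps = 0, 0
    while g0 - steps - 1 >= 0 and q0 - steps - 1 >= 0:
        steps += 1
        score += _MATCH_SCORE if genome[g0 - steps] == query[q0 - steps] else _MISMATCH_SCORE
        if score > best_gain:
            best_gain, best_steps = score, steps
        if best_gain - score > _XDROP:
            break
    g0 -= best_steps
    q0 -= best_steps
    # right
    best_gain, best_steps = 0, 0
    score, steps = 0, 0
    while g1 + steps < genome.size and q1 + steps < query.size:
        score += _MATCH_SCORE if genome[g1 + steps] == query[q1 + steps] else _MISMATCH_SCORE
        steps += 1
        if score > best_gain:
            best_gain, best_steps = score, steps
        if best_gain - score > _XDROP:
            break
    g1 += best_steps
    q1 += best_steps
    return g0, g1, q0, q1


class SeedExtendMatcher:
    """Exact-word seeded, ungapped local matcher over a set of contigs.

    Seeds of length ``seed_k`` are indexed for every contig; a query is
    searched by collecting seed hits, grouping them per (contig, strand,
    diagonal), chaining hits whose gaps do not exceed ``max_seed_gap`` and
    extending each chain with an X-drop rule.  Gaps are out of model:
    markers and TE-family copies diverge by substitutions.
    """

    def __init__(self, contigs: Sequence, seed_k: int = 12,
                 max_seed_gap: int = 150) -> None:
        self.seed_k = seed_k
        self.max_seed_gap = max_seed_gap
        self._seqs: dict[str, str] = {
            (c.id if hasattr(c, "id") else f"contig{i}"):
            (c.seq if hasattr(c, "seq") else str(c))
            for i, c in enumerate(contigs)
        }
        if not self._seqs:
            raise ValueError("empty genome: no contigs to index")
        self._arrays = {name: _as_bytes(s) for name, s in self._seqs.items()}
        self._index: dict[str, dict[str, list[int]]] = {}
        for name, seq in self._seqs.items():
            idx: dict[str, list[int]] = {}
            for pos in range(len(seq) - seed_k + 1):
                word = seq[pos : pos + seed_k]
                if set(word) <= {"A", "C", "G", "T"}:
                    idx.setdefault(word, []).append(pos)
            self._index[name] = idx

    def _search_oriented(self, query: str, strand: str, query_len: int,
                         min_len: int, min_identity: float) -> list[LocalMatch]:
        k = self.seed_k
        q_arr = _as_bytes(query)
        matches: list[LocalMatch] = []
        for name, idx in self._index.items():
            g_arr = self._arrays[name]
            # seed hits grouped by diagonal (genome pos - query pos)
            by_diag: dict[int, list[tuple[int, int]]] = {}
            for qpos in range(len(query) - k + 1):
                for gpos in idx.get(query[qpos : qpos + k], ()):
                    by_diag.setdefault(gpos - qpos, []).append((qpos, gpos))
            for diag, hits in by_diag.items():
                hits.sort()
                # chain seeds separated by at most max_seed_gap
                chains: list[list[tuple[int, int]]] = [[hits[0]]]
                for h in hits[1:]:
                    if h[0] - chains[-1][-1][0] <= self.max_seed_gap:
                        chains[-1].append(h)
                    else:
                        chains.append([h])
                for chain in chains:
                    q0, g0 = chain[0]
                    q1, g1 = chain[-1][0] + k, chain[-1][1] + k
                    g0, g1, q0, q1 = _extend(g_arr, q_arr, g0, g1, q0, q1)
                    length = g1 - g0
                    if length < min_len:
                        continue
                    ident = float(
                        np.count_nonzero(g_arr[g0:g1] == q_arr[q0:q1])) / length
                    if ident < min_identity:
                        continue
                    if strand == "+":
                        qs, qe = q0 + 1, q1
                    else:  # map back to forward-query coordinates
                        qs, qe = query_len - q1 + 1, query_len - q0
                    matches.append(LocalMatch(name, g0 + 1, g1, qs, qe,
                                              strand, length, ident))
        return matches

    @staticmethod
    def _dedup(matches: list[LocalMatch]) -> list[LocalMatch]:
        """Drop matches nested inside a longer match on the same contig/strand."""
        kept: list[LocalMatch] = []
        for m in sorted(matches, key=lambda m: (-m.length, m.contig, m.g_start)):
            if any(k.contig == m.contig and k.strand == m.strand
                   and k.g_start <= m.g_start and m.g_end <= k.g_end
                   for k in kept):
                continue
            kept.append(m)
        kept.sort(key=lambda m: (m.contig, m.g_start, m.g_end, m.strand))
        return kept

    def search(self, query: str, min_len: int,
               min_identity: float = 0.8) -> list[LocalMatch]:
        """All local matches of ``query`` (both strands) passing the filters."""
        query = query.upper()
        out = self._search_oriented(query, "+", len(query), min_len, min_identity)
        out += self._search_oriented(revcomp(query), "-", len(query),
                                     min_len, min_identity)
        return self._dedup(out)
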