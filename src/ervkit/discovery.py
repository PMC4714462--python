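"""Proviral locus discovery: scan a genome with an ERV consensus.

The scan is classic seed-and-extend homology search, sized for planted-truth
recovery on desk-scale genomes (a few Mb) rather than whole-genome repeat
annotation:

1. a 2-bit k-mer index of the genome (both strands served by scanning the
   consensus and its reverse complement),
2. ungapped X-drop extension of diagonal-merged seeds into HSPs (indels are
   handled at the chaining stage, not inside an HSP),
3. optimal colinear chaining of HSPs by dynamic programming,
4. locus calling from chains covering enough of the consensus, with per-ORF
   nucleotide identity (global alignment; gap columns count in the
   denominator) and LTR-pair detection by self-alignment of the locus ends.

Default scoring: match +1, mismatch −2, gap open −5, gap extend −2, k = 12,
X-drop 20 — sensible for targets around 85–90 % identity; all configurable.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from Bio import Align

from .util import revcomp, slice1

_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _LUT[ord(_b)] = _i
    _LUT[ord(_b.lower())] = _i


@dataclasses.dataclass
class ConsensusModel:
    """An ERV reference: sequence plus named ORF intervals (1-based inclusive)."""

    name: str
    sequence: str
    orfs: dict[str, tuple[int, int]]
    ltr: tuple[int, int] | None = None

    def __post_init__(self):
        L = len(self.sequence)
        for orf, (s, e) in self.orfs.items():
            if not 1 <= s <= e <= L:
                raise ValueError(f"ORF {orf} interval ({s}, {e}) outside [1, {L}]")
        if self.ltr is not None and not 1 <= self.ltr[0] <= self.ltr[1] <= L:
            raise ValueError(f"LTR interval {self.ltr} outside [1, {L}]")


@dataclasses.dataclass
class ScanParams:
    k: int = 12
    match: int = 1
    mismatch: int = -2
    gap_open: int = -5
    gap_extend: int = -2
    xdrop: int = 20
    min_score: int = 25
    max_gap: int = 500
    min_coverage: float = 0.5
    min_ltr_identity: float = 0.8
    ltr_window: int = 800
    min_ltr_len: int = 100
    mask_low_complexity: bool = False


@dataclasses.dataclass
class Hsp:
    """An ungapped high-scoring pair in forward-consensus / forward-genome coords."""

    query: tuple[int, int]
    target: tuple[int, int]
    target_name: str
    strand: str
    score: int
    identity: float


@dataclasses.dataclass
class ProviralLocus:
    chromosome: str
    interval: tuple[int, int]
    strand: str
    score: int
    supporting_hsps: list[Hsp]
    per_orf_identity: dict[str, float | None] = dataclasses.field(default_factory=dict)
    ltr_pair: tuple[tuple[int, int], tuple[int, int], float] | None = None


# ---------------------------------------------------------------------------
# k-mer index


class KmerIndex:
    """Sorted-code exact k-mer index over the forward strand of each sequence.

    Reverse-strand occurrences of a query k-mer are found by looking up its
    reverse complement, so nothing is stored twice.
    """

    def __init__(self, genome: dict[str, str], k: int, mask_low_complexity: bool = False):
        if not 4 <= k <= 32:
            raise ValueError(f"k must be in [4, 32], got {k}")
        self.k = k
        self._seqs: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        self.total_indexed = 0
        for name, seq in genome.items():
            if len(seq) < k:
                warnings.warn(f"sequence {name!r} shorter than k={k}; not indexed")
                continue
            codes, positions = self._build(seq, k, mask_low_complexity)
            self._seqs[name] = (codes, positions)
            self.total_indexed += len(seq) - k + 1

    @staticmethod
    def _build(seq: str, k: int, mask: bool):
        vals = _LUT[np.frombuffer(seq.encode(), dtype=np.uint8)]
        n = len(seq)
        nwin = n - k + 1
        codes = np.zeros(nwin, dtype=np.uint64)
        for i in range(k):
            codes = (codes << np.uint64(2)) | vals[i : i + nwin].astype(np.uint64)
        # windows containing a non-ACGT base are invalid
        bad = np.cumsum(np.concatenate(([0], (vals == 255).astype(np.int64))))
        valid = (bad[k:] - bad[:-k]) == 0
        if mask:
            # drop homopolymer windows (minimal low-complexity filter)
            same = np.concatenate(([0], np.cumsum((vals[1:] == vals[:-1]).astype(np.int64))))
            valid &= (same[k - 1 :] - same[: -(k - 1)]) != (k - 1)
        positions = np.flatnonzero(valid).astype(np.int64)
        codes = codes[positions]
        order = np.argsort(codes, kind="stable")
        return codes[order], positions[order]

    @staticmethod
    def encode(kmer: str) -> int | None:
        vals = _LUT[np.frombuffer(kmer.encode(), dtype=np.uint8)]
        if (vals == 255).any():
            return None
        code = 0
        for v in vals:
            code = (code << 2) | int(v)
        return code

    def lookup_code(self, name: str, code: int) -> np.ndarray:
        """0-based forward positions of an encoded k-mer in one sequence."""
        if name not in self._seqs:
            return np.empty(0, dtype=np.int64)
        codes, positions = self._seqs[name]
        lo = np.searchsorted(codes, np.uint64(code), side="left")
        hi = np.searchsorted(codes, np.uint64(code), side="right")
        return positions[lo:hi]

    def lookup(self, kmer: str) -> list[tuple[str, int, str]]:
        """All (sequence, 1-based position, strand) occurrences of a k-mer.

        A '-' hit at position p means the reverse complement of the k-mer
        occurs on the forward strand at p.
        """
        if len(kmer) != self.k:
            raise ValueError(f"kmer length {len(kmer)} != k={self.k}")
        out = []
        for strand, query in (("+", kmer), ("-", revcomp(kmer))):
            code = self.encode(query)
            if code is None:
                continue
            for name in self._seqs:
                for p in self.lookup_code(name, code):
                    out.append((name, int(p) + 1, strand))
        return out

    def query_positions(self, name: str, query_codes: np.ndarray, valid: np.ndarray):
        """Vectorized lookup of many query k-mers against one sequence.

        Returns (query_offsets, target_positions), both 0-based.
        """
        if name not in self._seqs:
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
        codes, positions = self._seqs[name]
        lo = np.searchsorted(codes, query_codes, side="left")
        hi = np.searchsorted(codes, query_codes, side="right")
        counts = np.where(valid, hi - lo, 0)
        qoff = np.repeat(np.arange(len(query_codes)), counts)
        idx = np.concatenate([np.arange(l, h) for l, h, c in zip(lo, hi, counts) if c]) if counts.sum() else np.empty(0, dtype=np.int64)
        return qoff, positions[idx] if counts.sum() else np.empty(0, dtype=np.int64)


def index_kmers(genome: dict[str, str], k: int, mask_low_complexity: bool = False) -> KmerIndex:
    return KmerIndex(genome, k, mask_low_complexity)


# ---------------------------------------------------------------------------
# seed and extend


def _query_codes(seq: str, k: int):
    vals = _LUT[np.frombuffer(seq.encode(), dtype=np.uint8)]
    n = len(seq)
    if n < k:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool)
    nwin = n - k + 1
    codes = np.zeros(nwin, dtype=np.uint64)
    for i in range(k):
        codes = (codes << np.uint64(2)) | vals[i : i + nwin].astype(np.uint64)
    bad = np.cumsum(np.concatenate(([0], (vals == 255).astype(np.int64))))
    valid = (bad[k:] - bad[:-k]) == 0
    return codes, valid


def _extend_xdrop(qseq: str, tseq: str, qs: int, qe: int, ts: int, params: ScanParams):
    """Ungapped X-drop extension of a seed region [qs, qe) vs target from ts.

    All coordinates 0-based half-open; returns (qs, qe, ts, te, score, matches).
    """
    m, mm, X = params.match, params.mismatch, params.xdrop
    # score the seed region itself (may contain mismatches after merging)
    score = 0
    matches = 0
    for i in range(qe - qs):
        if qseq[qs + i] == tseq[ts + i]:
            score += m
            matches += 1
        else:
            score += mm
    # right extension
    best, run = score, score
    best_i = qe - qs
    i = qe - qs
    limit = min(len(qseq) - qs, len(tseq) - ts)
    while i < limit:
        run += m if qseq[qs + i] == tseq[ts + i] else mm
        i += 1
        if run > best:
            best, best_i = run, i
        elif best - run > X:
            break
    right = best_i
    score = best
    # left extension
    run = score
    best = score
    best_j = 0
    j = 0
    limit = min(qs, ts)
    while j < limit:
        j += 1
        run += m if qseq[qs - j] == tseq[ts - j] else mm
        if run > best:
            best, best_j = run, j
        elif best - run > X:
            break
    left = best_j
    nqs, nqe = qs - left, qs + right
    nts = ts - left
    matches = sum(1 for i in range(nqe - nqs) if qseq[nqs + i] == tseq[nts + i])
    return nqs, nqe, nts, nts + (nqe - nqs), best, matches


def seed_and_extend(
    consensus: ConsensusModel,
    index: KmerIndex,
    genome: dict[str, str],
    params: ScanParams | None = None,
) -> list[Hsp]:
    """Find HSPs of the consensus against the indexed genome, both strands."""
    params = params or ScanParams()
    k = index.k
    Lc = len(consensus.sequence)
    hsps: list[Hsp] = []
    for strand in "+-":
        qseq = consensus.sequence if strand == "+" else revcomp(consensus.sequence)
        codes, valid = _query_codes(qseq, k)
        for name, tseq in genome.items():
            qoff, tpos = index.query_positions(name, codes, valid)
            if len(qoff) == 0:
                continue
            diag = tpos - qoff
            order = np.lexsort((qoff, diag))
            qoff, tpos, diag = qoff[order], tpos[order], diag[order]
            seen: set[tuple[int, int]] = set()
            # merge seeds on the same diagonal into segments, then extend
            i = 0
            n = len(qoff)
            while i < n:
                j = i
                while (
                    j + 1 < n
                    and diag[j + 1] == diag[i]
                    and qoff[j + 1] - qoff[j] <= k
                ):
                    j += 1
                qs, qe = int(qoff[i]), int(qoff[j]) + k
                ts = int(tpos[i])
                nqs, nqe, nts, nte, score, matches = _extend_xdrop(
                    qseq, tseq, qs, qe, ts, params
                )
                i = j + 1
                if score < params.min_score:
                    continue
                key = (nqs, nts)
                if key in seen:
                    continue
                seen.add(key)
                if strand == "+":
                    q_iv = (nqs + 1, nqe)
                else:
                    q_iv = (Lc - nqe + 1, Lc - nqs)
                hsps.append(
                    Hsp(
                        query=q_iv,
                        target=(nts + 1, nte),
                        target_name=name,
                        strand=strand,
                        score=score,
                        identity=matches / (nqe - nqs),
                    )
                )
    return hsps


# ---------------------------------------------------------------------------
# chaining


def chain_hsps(hsps: list[Hsp], max_gap: int = 500) -> list[list[Hsp]]:
    """Optimal colinear chains of HSPs (per target sequence and strand).

    Chain score is the sum of member scores; selection is exact for colinear
    subsets by dynamic programming over HSPs sorted by query start.  Both the
    query gap and the target gap between consecutive members must be
    <= max_gap.  Chains are returned best-score first.
    """
    groups: dict[tuple[str, str], list[Hsp]] = {}
    for h in hsps:
        groups.setdefault((h.target_name, h.strand), []).append(h)
    chains: list[tuple[int, list[Hsp]]] = []
    for (name, strand), group in groups.items():
        group.sort(key=lambda h: (h.query[0], h.target[0]))
        n = len(group)
        best = [h.score for h in group]
        prev = [-1] * n
        for i in range(n):
            hi = group[i]
            for j in range(i):
                hj = group[j]
                if hj.query[1] >= hi.query[0]:
                    continue
                qgap = hi.query[0] - hj.query[1] - 1
                if qgap > max_gap:
                    continue
                if strand == "+":
                    if hj.target[1] >= hi.target[0]:
                        continue
                    tgap = hi.target[0] - hj.target[1] - 1
                else:
                    if hi.target[1] >= hj.target[0]:
                        continue
                    tgap = hj.target[0] - hi.target[1] - 1
                if tgap > max_gap:
                    continue
                cand = best[j] + hi.score
                if cand > best[i]:
                    best[i] = cand
                    prev[i] = j
        used = [False] * n
        for i in sorted(range(n), key=lambda x: -best[x]):
            if used[i]:
                continue
            chain = []
            j = i
            clean = True
            while j != -1:
                if used[j]:
                    clean = False
                    break
                chain.append(j)
                j = prev[j]
            if not clean:
                continue
            for j in chain:
                used[j] = True
            members = [group[j] for j in reversed(chain)]
            chains.append((sum(h.score for h in members), members))
    chains.sort(key=lambda c: -c[0])
    return [members for _, members in chains]


# ---------------------------------------------------------------------------
# locus calling


def _query_coverage(chain: list[Hsp], consensus_len: int) -> float:
    ivs = sorted(h.query for h in chain)
    covered = 0
    cur_s, cur_e = ivs[0]
    for s, e in ivs[1:]:
        if s <= cur_e + 1:
            cur_e = max(cur_e, e)
        else:
            covered += cur_e - cur_s + 1
            cur_s, cur_e = s, e
    covered += cur_e - cur_s + 1
    return covered / consensus_len


def call_loci(
    chains: list[list[Hsp]], consensus: ConsensusModel, min_coverage: float = 0.5
) -> list[ProviralLocus]:
    """One locus per retained chain; same-strand overlapping loci are merged.

    Opposite-strand overlaps are kept separate (nested insertions are real).
    Loci are sorted by score, best first.
    """
    Lc = len(consensus.sequence)
    loci: list[ProviralLocus] = []
    for chain in chains:
        if _query_coverage(chain, Lc) < min_coverage:
            continue
        ts = min(h.target[0] for h in chain)
        te = max(h.target[1] for h in chain)
        loci.append(
            ProviralLocus(
                chromosome=chain[0].target_name,
                interval=(ts, te),
                strand=chain[0].strand,
                score=sum(h.score for h in chain),
                supporting_hsps=chain,
            )
        )
    merged: list[ProviralLocus] = []
    for locus in sorted(loci, key=lambda l: (l.chromosome, l.strand, l.interval)):
        if (
            merged
            and merged[-1].chromosome == locus.chromosome
            and merged[-1].strand == locus.strand
            and merged[-1].interval[1] >= locus.interval[0]
        ):
            prev = merged[-1]
            prev.interval = (prev.interval[0], max(prev.interval[1], locus.interval[1]))
            prev.score += locus.score
            prev.supporting_hsps.extend(locus.supporting_hsps)
        else:
            merged.append(locus)
    merged.sort(key=lambda l: -l.score)
    return merged


# ---------------------------------------------------------------------------
# per-ORF identity


def _make_aligner(params: ScanParams, local: bool) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local" if local else "global"
    aligner.match_score = params.match
    aligner.mismatch_score = params.mismatch
    aligner.open_gap_score = params.gap_open + params.gap_extend
    aligner.extend_gap_score = params.gap_extend
    return aligner


def alignment_identity(alignment) -> tuple[float, int]:
    """(identity, columns) over all alignment columns; gaps count in the denominator."""
    a, b = alignment[0], alignment[1]
    matches = sum(1 for x, y in zip(a, b) if x == y and x != "-")
    return matches / len(a), len(a)


def orf_identity_from_sequences(
    consensus_orf: str, locus_region: str, params: ScanParams | None = None
) -> float:
    """Percent identity of a consensus ORF to its projected locus region.

    Global alignment with end gaps in the locus region free (the projection
    may over-extract a few flanking bases); identity = matched columns over
    all columns spanned by the consensus ORF, gap columns included; reported
    to 0.1 %.
    """
    params = params or ScanParams()
    aligner = _make_aligner(params, local=False)
    aligner.end_deletion_score = 0.0  # extra locus flanks align as free end gaps
    aln = aligner.align(locus_region.upper(), consensus_orf.upper())[0]
    t, q = str(aln[0]), str(aln[1])
    # strip columns where the consensus row has leading/trailing end gaps
    start = len(q) - len(q.lstrip("-"))
    end = len(q) - (len(q) - len(q.rstrip("-")))
    t, q = t[start:end], q[start:end]
    matches = sum(1 for x, y in zip(t, q) if x == y and x != "-")
    return round(100.0 * matches / len(q), 1)


def locus_local_sequence(locus: ProviralLocus, genome: dict[str, str]) -> str:
    """The locus sequence oriented so the consensus maps forward onto it."""
    sub = slice1(genome[locus.chromosome], locus.interval)
    return revcomp(sub) if locus.strand == "-" else sub


def _local_anchors(locus: ProviralLocus) -> list[tuple[int, int]]:
    """(consensus position, locus-local position) pairs from HSP endpoints."""
    s, e = locus.interval
    anchors = []
    for h in locus.supporting_hsps:
        if h.strand == "+":
            l_iv = (h.target[0] - s + 1, h.target[1] - s + 1)
        else:
            l_iv = (e - h.target[1] + 1, e - h.target[0] + 1)
        anchors.append((h.query[0], l_iv[0]))
        anchors.append((h.query[1], l_iv[1]))
    anchors.sort()
    return anchors


def _project(anchors: list[tuple[int, int]], q: int, local_len: int) -> int:
    """Map a consensus position through the anchor list (linear between anchors)."""
    if q <= anchors[0][0]:
        l = anchors[0][1] - (anchors[0][0] - q)
    elif q >= anchors[-1][0]:
        l = anchors[-1][1] + (q - anchors[-1][0])
    else:
        for (q1, l1), (q2, l2) in zip(anchors, anchors[1:]):
            if q1 <= q <= q2:
                frac = 0 if q2 == q1 else (q - q1) / (q2 - q1)
                l = round(l1 + frac * (l2 - l1))
                break
    return min(max(int(l), 1), local_len)


def compute_orf_identity(
    locus: ProviralLocus,
    consensus: ConsensusModel,
    orf_name: str,
    genome: dict[str, str],
    params: ScanParams | None = None,
    min_orf_coverage: float = 0.5,
) -> float | None:
    """Percent nucleotide identity of one consensus ORF at a called locus.

    Returns None ("not assessable") when the chain covers less than
    ``min_orf_coverage`` of the ORF.
    """
    params = params or ScanParams()
    if orf_name not in consensus.orfs:
        raise KeyError(f"consensus has no ORF {orf_name!r}")
    os_, oe = consensus.orfs[orf_name]
    olen = oe - os_ + 1
    covered = 0
    for h in locus.supporting_hsps:
        lo = max(os_, h.query[0])
        hi = min(oe, h.query[1])
        if hi >= lo:
            covered += hi - lo + 1
    if covered / olen < min_orf_coverage:
        return None
    local = locus_local_sequence(locus, genome)
    anchors = _local_anchors(locus)
    pad = 5
    ls = max(1, _project(anchors, os_, len(local)) - pad)
    le = min(len(local), _project(anchors, oe, len(local)) + pad)
    region = local[ls - 1 : le]
    return orf_identity_from_sequences(slice1(consensus.sequence, (os_, oe)), region, params)


# ---------------------------------------------------------------------------
# LTR pair detection


def detect_ltr_pair(
    locus: ProviralLocus,
    genome: dict[str, str],
    params: ScanParams | None = None,
) -> tuple[tuple[int, int], tuple[int, int], float] | None:
    """Best pair of similar direct repeats at the two ends of a locus.

    Self-aligns the two terminal windows (local alignment); reports genome
    intervals and identity, or None if the repeat is too short or diverged.
    """
    params = params or ScanParams()
    local = locus_local_sequence(locus, genome)
    W = min(params.ltr_window, len(local) // 2)
    if W < params.min_ltr_len:
        return None
    left, right = local[:W], local[-W:]
    aligner = _make_aligner(params, local=True)
    alns = aligner.align(left, right)
    if len(alns) == 0:
        return None
    aln = alns[0]
    identity, columns = alignment_identity(aln)
    if columns < params.min_ltr_len or identity < params.min_ltr_identity:
        return None
    tblocks, qblocks = aln.aligned
    l_iv_local = (int(tblocks[0][0]) + 1, int(tblocks[-1][1]))
    r_off = len(local) - W
    r_iv_local = (int(qblocks[0][0]) + 1 + r_off, int(qblocks[-1][1]) + r_off)
    s, e = locus.interval
    if locus.strand == "+":
        iv5 = (s + l_iv_local[0] - 1, s + l_iv_local[1] - 1)
        iv3 = (s + r_iv_local[0] - 1, s + r_iv_local[1] - 1)
    else:
        iv5 = (e - l_iv_local[1] + 1, e - l_iv_local[0] + 1)
        iv3 = (e - r_iv_local[1] + 1, e - r_iv_local[0] + 1)
    return iv5, iv3, round(identity, 4)


# ---------------------------------------------------------------------------
# top level


def scan_genome(
    genome: dict[str, str],
    consensus: ConsensusModel,
    params: ScanParams | None = None,
) -> list[ProviralLocus]:
    """Full scan: index, seed/extend, chain, call loci, annotate identity and LTRs."""
    params = params or ScanParams()
    index = KmerIndex(genome, params.k, params.mask_low_complexity)
    hsps = seed_and_extend(consensus, index, genome, params)
    chains = chain_hsps(hsps, params.max_gap)
    loci = call_loci(chains, consensus, params.min_coverage)
    for locus in loci:
        for orf in consensus.orfs:
            locus.per_orf_identity[orf] = compute_orf_identity(
                locus, consensus, orf, genome, params
            )
        locus.ltr_pair = detect_ltr_pair(locus, genome, params)
    return loci
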