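"""ORF coding-potential classification and spliced-transcript reconstruction.

A called locus is compared ORF-by-ORF against the consensus by global
affine-gap alignment; the classifier then asks the question that matters for
an endogenous retrovirus: *could this reading frame still code for a
full-length protein?*  Statuses:

``intact``
    no net frame disruption, start codon present, translation reaches the
    expected stop with no internal stop.
``frameshift``
    at least one indel whose length is not a multiple of 3 disrupts the net
    frame (compensating indel pairs are reported as defects but do not force
    this status — the translated product is checked directly).
``premature_stop``
    an in-frame stop before 95 % of the consensus ORF length.
``truncated``
    start codon missing or the ORF is clipped at the locus edge.
``not_assessable``
    less than half of the ORF is covered by the locus alignment.

Splice reconstruction maps a captured mRNA back onto its provirus, recovers
exon blocks by anchor chaining, and places each junction so the intron is
GT…AG when the alignment allows it (non-canonical junctions are flagged, not
discarded).
"""

from __future__ import annotations

import dataclasses

from Bio.Seq import Seq

from .discovery import ConsensusModel, ScanParams, _make_aligner
from .util import slice1

_STOPS = ("TAA", "TAG", "TGA")


# ---------------------------------------------------------------------------
# codon alignment


@dataclasses.dataclass
class CodonAlignment:
    """Column-wise global alignment of a consensus ORF to a locus region."""

    orf_name: str
    consensus_interval: tuple[int, int]
    columns: list[tuple[str, str]]  # (consensus base or '-', locus base or '-')
    frame_offsets: list[int]  # cumulative (insertions - deletions) mod 3 per column

    def consensus_row(self) -> str:
        return "".join(c for c, _ in self.columns)

    def locus_row(self) -> str:
        return "".join(l for _, l in self.columns)

    def ungapped_consensus(self) -> str:
        return self.consensus_row().replace("-", "")

    def ungapped_locus(self) -> str:
        return self.locus_row().replace("-", "")


def align_orf(
    consensus: ConsensusModel,
    orf_name: str,
    locus_region: str,
    params: ScanParams | None = None,
) -> CodonAlignment:
    """Globally align one consensus ORF against the locus region covering it.

    ``locus_region`` should be the projected region from locus discovery (the
    locus subsequence corresponding to the ORF, in consensus orientation).
    Frame offsets are cumulative (insertions − deletions) mod 3, where an
    insertion is a locus base absent from the consensus.
    """
    params = params or ScanParams()
    if orf_name not in consensus.orfs:
        raise KeyError(f"consensus has no ORF {orf_name!r}")
    iv = consensus.orfs[orf_name]
    orf_seq = slice1(consensus.sequence, iv)
    aligner = _make_aligner(params, local=False)
    aligner.end_deletion_score = 0.0  # projection may over-extract flanks
    aln = aligner.align(locus_region.upper(), orf_seq.upper())[0]
    locus_row, cons_row = str(aln[0]), str(aln[1])
    # trim columns outside the consensus ORF (end gaps in the consensus row)
    start = len(cons_row) - len(cons_row.lstrip("-"))
    stop = len(cons_row.rstrip("-"))
    columns = []
    offsets = []
    net = 0
    for c, l in zip(cons_row[start:stop], locus_row[start:stop]):
        if c == "-":
            net += 1
        elif l == "-":
            net -= 1
        columns.append((c, l))
        offsets.append(net % 3)
    return CodonAlignment(
        orf_name=orf_name, consensus_interval=iv, columns=columns, frame_offsets=offsets
    )


# ---------------------------------------------------------------------------
# classification


@dataclasses.dataclass
class OrfDefect:
    kind: str  # 'frameshift_indel', 'inframe_indel', 'premature_stop', 'missing_start'
    position: int  # 1-based position in the locus region (start of the defect)
    detail: str


@dataclasses.dataclass
class OrfReport:
    orf_name: str
    status: str  # intact | frameshift | premature_stop | truncated | not_assessable
    defects: list[OrfDefect]
    protein: str | None  # predicted protein, only for intact ORFs


def _indel_runs(alignment: CodonAlignment):
    """Yield (which_row_gapped, start_column, length) for each gap run."""
    runs = []
    prev = None
    for i, (c, l) in enumerate(alignment.columns):
        kind = "ins" if c == "-" else ("del" if l == "-" else None)
        if kind is None:
            prev = None
            continue
        if prev is not None and prev[0] == kind and prev[2] + prev[1] == i:
            runs[-1] = (kind, prev[1], prev[2] + 1)
            prev = (kind, prev[1], prev[2] + 1)
        else:
            runs.append((kind, i, 1))
            prev = (kind, i, 1)
    return runs


def classify_orf(alignment: CodonAlignment, premature_frac: float = 0.95) -> OrfReport:
    """Classify an aligned ORF by its coding potential.

    The decision is made on the *product*: the locus sequence is translated in
    the consensus frame from its start codon, and defects (indels, stops) are
    reported at locus coordinates within the aligned region.
    """
    cols = alignment.columns
    cons_len = sum(1 for c, _ in cols if c != "-")
    locus_seq = alignment.ungapped_locus()
    defects: list[OrfDefect] = []

    # locus coordinate per column (1-based within the aligned locus region)
    locus_pos = []
    p = 0
    for _, l in cols:
        if l != "-":
            p += 1
        locus_pos.append(p)

    net_frame = 0
    for kind, start_col, length in _indel_runs(alignment):
        net_frame += length if kind == "ins" else -length
        dkind = "frameshift_indel" if length % 3 else "inframe_indel"
        defects.append(
            OrfDefect(
                kind=dkind,
                position=max(locus_pos[start_col], 1),
                detail=f"{length}-nt {'insertion' if kind == 'ins' else 'deletion'}",
            )
        )
    frame_disrupted = any(d.kind == "frameshift_indel" for d in defects) and net_frame % 3 != 0
    any_fs_indel = any(d.kind == "frameshift_indel" for d in defects)

    has_start = locus_seq[:3] == "ATG"
    if not has_start:
        defects.append(OrfDefect(kind="missing_start", position=1, detail="no ATG at ORF start"))

    # direct product check: translate the locus region in the consensus frame
    stop_at = None  # 1-based locus position of the first premature stop
    n_codons = len(locus_seq) // 3
    for ci in range(n_codons):
        codon = locus_seq[3 * ci : 3 * ci + 3]
        if codon in _STOPS:
            end_pos = 3 * ci + 3
            if end_pos < premature_frac * cons_len:
                stop_at = 3 * ci + 1
            break
    if stop_at is not None:
        frame_note = " (out of frame)" if any_fs_indel else ""
        defects.append(
            OrfDefect(kind="premature_stop", position=stop_at, detail=f"in-frame stop{frame_note}")
        )

    if any_fs_indel and frame_disrupted:
        status = "frameshift"
    elif stop_at is not None:
        status = "premature_stop"
    elif not has_start:
        status = "truncated"
    else:
        # full-length product check: translation must reach a terminal stop
        protein = str(Seq(locus_seq[: 3 * n_codons]).translate())
        if "*" not in protein:
            status = "truncated"  # no stop at all: clipped at the locus edge
            defects.append(
                OrfDefect(kind="missing_stop", position=len(locus_seq), detail="no stop codon")
            )
        else:
            status = "intact"
            return OrfReport(
                orf_name=alignment.orf_name,
                status=status,
                defects=defects,
                protein=protein[: protein.index("*")],
            )
    return OrfReport(orf_name=alignment.orf_name, status=status, defects=defects, protein=None)


# ---------------------------------------------------------------------------
# splice-junction reconstruction


@dataclasses.dataclass
class SpliceParams:
    min_intron: int = 50
    min_identity: float = 0.9
    anchor_k: int = 16
    max_junction_shift: int = 30


@dataclasses.dataclass
class TranscriptModel:
    transcript_name: str
    exons: list[tuple[int, int]]  # provirus intervals, 1-based inclusive
    junctions: list[tuple[str, str]]  # (donor dinucleotide, acceptor dinucleotide)
    canonical: list[bool]  # per intron: donor/acceptor == GT/AG
    cds: tuple[int, int] | None  # CDS interval on the *transcript*
    identity: float  # transcript-to-provirus identity over aligned blocks


class OriginError(ValueError):
    """The transcript does not originate from this locus."""


def _anchor_blocks(transcript: str, provirus: str, k: int):
    """Maximal colinear same-diagonal anchor blocks (t_start, p_start, length), 0-based."""
    index: dict[str, list[int]] = {}
    for i in range(len(provirus) - k + 1):
        index.setdefault(provirus[i : i + k], []).append(i)
    hits = []
    for t in range(len(transcript) - k + 1):
        for p in index.get(transcript[t : t + k], ()):
            hits.append((p - t, t))
    hits.sort()
    blocks = []
    for diag, t in hits:
        if blocks and blocks[-1][0] == diag and t <= blocks[-1][1] + blocks[-1][2]:
            b = blocks[-1]
            blocks[-1] = (diag, b[1], t + k - b[1])
        else:
            blocks.append((diag, t, k))
    # keep the best colinear chain of blocks (DP on covered length); blocks
    # may overlap slightly (junction-straddling anchors) — overlap is trimmed
    # from the gain so the score tracks transcript coverage
    blocks = [(t, t + diag, ln) for diag, t, ln in blocks]
    blocks.sort()
    n = len(blocks)
    best = [b[2] for b in blocks]
    prev = [-1] * n
    for i in range(n):
        ti, pi, li = blocks[i]
        for j in range(i):
            tj, pj, lj = blocks[j]
            if tj >= ti or pj >= pi:
                continue
            overlap = max(tj + lj - ti, pj + lj - pi, 0)
            if overlap >= li:
                continue
            cand = best[j] + li - overlap
            if cand > best[i]:
                best[i] = cand
                prev[i] = j
    if not blocks:
        return []
    i = max(range(n), key=lambda x: best[x])
    chain = []
    while i != -1:
        chain.append(blocks[i])
        i = prev[i]
    return chain[::-1]


def find_splice_junctions(
    transcript: str,
    provirus: str,
    params: SpliceParams | None = None,
    name: str = "transcript",
) -> TranscriptModel:
    """Reconstruct the exon structure of a transcript on its provirus.

    Anchors exact matches, merges blocks separated by less than ``min_intron``
    on the provirus (those are mismatch patches inside an exon), and treats
    larger provirus gaps as introns.  Each junction is slid within its
    alignment-ambiguous range to make the intron start GT and end AG; if no
    shift achieves that, the junction keeps its anchored position and is
    flagged non-canonical.
    """
    params = params or SpliceParams()
    transcript = transcript.upper()
    provirus = provirus.upper()
    chain = _anchor_blocks(transcript, provirus, params.anchor_k)
    if not chain:
        raise OriginError(f"{name}: transcript does not originate from this locus")
    # anchored blocks are exact matches; identity = anchored transcript
    # coverage (union, blocks may overlap at junctions)
    covered = 0
    cur_end = -1
    for t, _, ln in chain:
        s, e = t, t + ln - 1
        if s > cur_end:
            covered += e - s + 1
        elif e > cur_end:
            covered += e - cur_end
        cur_end = max(cur_end, e)
    identity = covered / max(len(transcript), 1)
    if identity < params.min_identity:
        raise OriginError(
            f"{name}: transcript does not originate from this locus "
            f"(anchored identity {identity:.2f} < {params.min_identity})"
        )

    # merge chain blocks separated by < min_intron on the provirus into exons
    exons0: list[tuple[int, int, int, int]] = []  # (t_start, t_end, p_start, p_end) 0-based incl.
    for t, p, ln in chain:
        if exons0 and p - (exons0[-1][3] + 1) < params.min_intron:
            ts, te, ps, pe = exons0[-1]
            exons0[-1] = (ts, t + ln - 1, ps, p + ln - 1)
        else:
            exons0.append((t, t + ln - 1, p, p + ln - 1))

    # extend the first/last exon to the transcript ends along their diagonal
    ts, te, ps, pe = exons0[0]
    shift = min(ts, ps)
    exons0[0] = (ts - shift, te, ps - shift, pe)
    ts, te, ps, pe = exons0[-1]
    tail = min(len(transcript) - 1 - te, len(provirus) - 1 - pe)
    exons0[-1] = (ts, te + tail, ps, pe + tail)

    # place each junction; the breakpoint b (last transcript index of the
    # upstream exon) may slide within the alignment-ambiguous range, and the
    # position making the intron GT...AG is preferred
    junctions: list[tuple[str, str]] = []
    canonical: list[bool] = []
    final: list[tuple[int, int, int, int]] = [exons0[0]]
    for nxt in exons0[1:]:
        ts1, te1, ps1, pe1 = final[-1]
        ts2, te2, ps2, pe2 = nxt
        hi = te1
        while (
            hi - te1 < params.max_junction_shift
            and hi + 1 <= te2 - 1
            and pe1 + (hi + 1 - te1) < len(provirus)
            and transcript[hi + 1] == provirus[pe1 + (hi + 1 - te1)]
        ):
            hi += 1
        lo = ts2 - 1
        while (
            ts2 - 1 - (lo - 1) <= params.max_junction_shift
            and lo - 1 >= ts1
            and ps2 - (ts2 - lo) >= 0
            and transcript[lo] == provirus[ps2 - (ts2 - lo)]
        ):
            lo -= 1
        chosen = None
        for b in sorted(range(lo, hi + 1), key=lambda x: abs(x - te1)):
            d = pe1 + (b - te1) + 1  # first intron base, 0-based
            a = ps2 - (ts2 - b - 1) - 1  # last intron base, 0-based
            if a - d + 1 < params.min_intron:
                continue
            if provirus[d : d + 2] == "GT" and provirus[a - 1 : a + 1] == "AG":
                chosen = (b, d, a, True)
                break
        if chosen is None:
            b = te1
            d = pe1 + 1
            a = ps2 - (ts2 - b - 1) - 1
            chosen = (b, d, a, False)
        b, d, a, canon = chosen
        final[-1] = (ts1, b, ps1, pe1 + (b - te1))
        final.append((b + 1, te2, ps2 - (ts2 - b - 1), pe2))
        junctions.append((provirus[d : d + 2], provirus[a - 1 : a + 1]))
        canonical.append(canon)

    exon_ivs = [(ps + 1, pe + 1) for _, _, ps, pe in final]
    cds = find_cds(transcript)
    return TranscriptModel(
        transcript_name=name,
        exons=exon_ivs,
        junctions=junctions,
        canonical=canonical,
        cds=cds,
        identity=round(identity, 4),
    )


def find_cds(transcript: str) -> tuple[int, int] | None:
    """Longest ATG-initiated ORF on the transcript; ties broken toward 5'.

    The interval includes the stop codon, 1-based inclusive.
    """
    best = None
    t = transcript.upper()
    for frame in range(3):
        i = frame
        while i + 3 <= len(t):
            if t[i : i + 3] == "ATG":
                j = i
                while j + 3 <= len(t):
                    if t[j : j + 3] in _STOPS:
                        length = j + 3 - i
                        if best is None or length > best[1] - best[0] + 1 or (
                            length == best[1] - best[0] + 1 and i + 1 < best[0]
                        ):
                            best = (i + 1, j + 3)
                        break
                    j += 3
                # restart search after this ATG to allow overlapping ORFs
            i += 3
    return best


def translate_spliced_cds(model: TranscriptModel, transcript: str) -> str:
    """Standard-code translation of the model's CDS; terminal stop removed."""
    if model.cds is None:
        raise ValueError(f"{model.transcript_name}: no CDS on the spliced transcript")
    s, e = model.cds
    if (e - s + 1) % 3:
        raise ValueError(f"{model.transcript_name}: CDS ({s}, {e}) is not a multiple of 3")
    protein = str(Seq(transcript[s - 1 : e].upper()).translate())
    return protein[:-1] if protein.endswith("*") else protein
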