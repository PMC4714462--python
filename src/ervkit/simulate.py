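"""Synthetic data with planted ground truth.

Everything downstream of this module (locus scanning, ORF classification,
splice reconstruction, phylogenetics, plate quantification) is tested against
data generated here, where the truth — insertion coordinates, mutation logs,
exon blocks, tree topologies, assay effect sizes — is known exactly.

The generative model is deliberately plain:

* Host background is i.i.d. DNA with configurable GC content (no repeat
  landscape — enough for planted-truth recovery).
* An ancestral provirus has the canonical LTR–gag–pro–pol–env–LTR layout
  with identical LTRs, a splice donor in the 5' leader and a splice acceptor
  just upstream of env.
* Proviral decay is modelled as per-site substitutions plus geometric-length
  indels, with optional *forced* defects (a 1-nt deletion for a frameshift,
  an in-frame stop substitution for a premature stop).  Every event is logged
  so the degraded sequence can be replayed byte-for-byte from the ancestor.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd

from .phylo import Node, parse_newick
from .util import interval_len, random_dna, revcomp, slice1

_STOPS = ("TAA", "TAG", "TGA")
_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
]


# ---------------------------------------------------------------------------
# ancestral provirus


@dataclasses.dataclass
class AncestralProvirus:
    """A clean provirus with known organization (all coordinates 1-based inclusive)."""

    name: str
    sequence: str
    ltr5: tuple[int, int]
    ltr3: tuple[int, int]
    orfs: dict[str, tuple[int, int]]
    splice_donor: int  # first base of the intron (the G of GT)
    splice_acceptor: int  # last base of the intron (the G of AG)

    def validate(self) -> None:
        seq = self.sequence
        if slice1(seq, self.ltr5) != slice1(seq, self.ltr3):
            raise ValueError("LTRs are not identical")
        for name, iv in self.orfs.items():
            sub = slice1(seq, iv)
            if len(sub) % 3:
                raise ValueError(f"ORF {name} length {len(sub)} not a multiple of 3")
            if not sub.startswith("ATG"):
                raise ValueError(f"ORF {name} does not start with ATG")
            codons = [sub[i : i + 3] for i in range(0, len(sub), 3)]
            if codons[-1] not in _STOPS:
                raise ValueError(f"ORF {name} does not end with a stop codon")
            if any(c in _STOPS for c in codons[:-1]):
                raise ValueError(f"ORF {name} has an internal in-frame stop")
        if not self.splice_donor < self.splice_acceptor:
            raise ValueError("splice donor must precede acceptor")
        if "env" in self.orfs and self.splice_acceptor >= self.orfs["env"][0]:
            raise ValueError("splice acceptor must precede env start")
        d, a = self.splice_donor, self.splice_acceptor
        if seq[d - 1 : d + 1] != "GT" or seq[a - 2 : a] != "AG":
            raise ValueError("splice junction context is not GT...AG")


@dataclasses.dataclass
class ProvirusConfig:
    """Lengths (nt) and composition of a generated provirus."""

    ltr_len: int = 450
    leader_len: int = 120
    spacer_len: int = 60
    utr_len: int = 80
    orf_lens: dict[str, int] = dataclasses.field(
        default_factory=lambda: {"gag": 600, "pro": 300, "pol": 900, "env": 600}
    )
    gc: float = 0.5


def make_ancestral_provirus(
    config: ProvirusConfig | None = None, seed: int = 0, name: str = "provirus"
) -> AncestralProvirus:
    """Generate a provirus satisfying every :class:`AncestralProvirus` invariant.

    Layout: LTR5 – leader (with splice donor) – gag – pro – pol – acceptor
    spacer – env – UTR – LTR3.  Deterministic for a fixed seed.
    """
    cfg = config or ProvirusConfig()
    rng = np.random.default_rng(seed)
    for orf, L in cfg.orf_lens.items():
        if L < 30 or L % 3:
            raise ValueError(f"ORF {orf} length must be >= 30 and a multiple of 3, got {L}")
    if cfg.leader_len < 12 or cfg.spacer_len < 12 or cfg.utr_len < 4:
        raise ValueError("leader/spacer/UTR too short: ORFs would overlap the LTRs")

    if cfg.ltr_len < 20:
        raise ValueError("LTR must be at least 20 nt")
    # the LTR tail carries stops in all three frames so that ORFs on a spliced
    # transcript cannot extend upstream into the R/U5 leader
    ltr = random_dna(cfg.ltr_len - 11, rng, cfg.gc) + "TAACTAACTAA"
    parts: list[str] = [ltr]
    pos = cfg.ltr_len
    orfs: dict[str, tuple[int, int]] = {}

    leader = list(random_dna(cfg.leader_len, rng, cfg.gc))
    leader[0:8] = "CCTCCTCC"  # fixed ATG-free context upstream of the donor
    donor = pos + 9  # inside the leader, past the 5' LTR
    leader[8:10] = "GT"
    parts.append("".join(leader))
    pos += cfg.leader_len

    order = [o for o in ("gag", "pro", "pol", "env") if o in cfg.orf_lens]
    order += [o for o in cfg.orf_lens if o not in order]
    for i, orf in enumerate(order):
        if orf == "env":
            spacer = list(random_dna(cfg.spacer_len, rng, cfg.gc))
            spacer[-6:-4] = "AG"  # splice acceptor, a few bases before env ATG
            spacer[-4:] = "CACC"  # fixed ATG-free context between acceptor and env
            acceptor = pos + cfg.spacer_len - 4
            parts.append("".join(spacer))
            pos += cfg.spacer_len
        elif i > 0:
            parts.append(random_dna(cfg.spacer_len, rng, cfg.gc))
            pos += cfg.spacer_len
        L = cfg.orf_lens[orf]
        n_mid = L // 3 - 2
        body = (
            "ATG"
            + "".join(_CODONS[k] for k in rng.choice(len(_CODONS), size=n_mid))
            + _STOPS[rng.integers(3)]
        )
        orfs[orf] = (pos + 1, pos + L)
        parts.append(body)
        pos += L
    parts.append(random_dna(cfg.utr_len, rng, cfg.gc))
    pos += cfg.utr_len
    parts.append(ltr)
    ltr3 = (pos + 1, pos + cfg.ltr_len)
    pos += cfg.ltr_len

    pv = AncestralProvirus(
        name=name,
        sequence="".join(parts),
        ltr5=(1, cfg.ltr_len),
        ltr3=ltr3,
        orfs=orfs,
        splice_donor=donor,
        splice_acceptor=acceptor,
    )
    pv.validate()
    return pv


# ---------------------------------------------------------------------------
# degradation


@dataclasses.dataclass
class DegradationSpec:
    """Stochastic decay parameters plus guaranteed (forced) ORF defects."""

    substitution_rate: float = 0.0
    indel_rate: float = 0.0
    indel_geom_p: float = 0.5
    indel_max: int = 10
    forced_defects: list[tuple[str, str, int]] = dataclasses.field(default_factory=list)
    seed: int = 0

    def validate(self, provirus: AncestralProvirus) -> None:
        for r in (self.substitution_rate, self.indel_rate):
            if not 0 <= r <= 1:
                raise ValueError(f"rate {r} outside [0, 1]")
        for orf, kind, pos in self.forced_defects:
            if orf not in provirus.orfs:
                raise ValueError(f"forced defect names unknown ORF {orf!r}")
            if kind not in ("frameshift", "premature_stop"):
                raise ValueError(f"unknown defect kind {kind!r}")
            s, e = provirus.orfs[orf]
            if not s <= pos <= e:
                raise ValueError(f"forced {kind} position {pos} outside ORF {orf} ({s}-{e})")


# A mutation log entry is ("sub", pos, new_base) | ("del", pos, length) |
# ("ins", pos, inserted_seq); positions are ancestor coordinates, deletions
# remove pos..pos+length-1, insertions insert after pos.
MutationLog = list[tuple]


def apply_mutation_log(ancestor: str, log: MutationLog) -> str:
    """Replay a mutation log on the ancestor; the defining semantics of the log."""
    subs: dict[int, str] = {}
    dels: dict[int, int] = {}
    ins: dict[int, str] = {}
    for entry in log:
        kind, pos = entry[0], entry[1]
        if kind == "sub":
            subs[pos] = entry[2]
        elif kind == "del":
            dels[pos] = entry[2]
        elif kind == "ins":
            ins[pos] = entry[2]
        else:
            raise ValueError(f"unknown log entry kind {kind!r}")
    out: list[str] = []
    if 0 in ins:
        out.append(ins[0])
    skip_until = 0
    for p in range(1, len(ancestor) + 1):
        if p in dels:
            skip_until = max(skip_until, p + dels[p] - 1)
        if p <= skip_until:
            continue
        out.append(subs.get(p, ancestor[p - 1]))
        if p in ins:
            out.append(ins[p])
    return "".join(out)


def degrade(provirus: AncestralProvirus, spec: DegradationSpec) -> tuple[str, MutationLog]:
    """Apply stochastic decay and forced defects; returns (sequence, mutation log).

    Forced frameshifts are 1-nt deletions (the smallest defect the classifier
    must detect); forced premature stops substitute the containing in-frame
    codon to TAA.  Replaying the log on the ancestor reproduces the output
    exactly, and random events never overlap a forced defect.
    """
    spec.validate(provirus)
    rng = np.random.default_rng(spec.seed)
    seq = provirus.sequence
    L = len(seq)
    log: MutationLog = []
    protected: set[int] = set()

    for orf, kind, pos in spec.forced_defects:
        s, _ = provirus.orfs[orf]
        if kind == "frameshift":
            log.append(("del", pos, 1))
            protected.add(pos)
        else:  # premature_stop
            cs = s + 3 * ((pos - s) // 3)  # start of the codon containing pos
            for i, base in enumerate("TAA"):
                if seq[cs - 1 + i] != base:
                    log.append(("sub", cs + i, base))
                protected.add(cs + i)

    if spec.substitution_rate > 0:
        hit = np.flatnonzero(rng.random(L) < spec.substitution_rate) + 1
        for p in hit:
            p = int(p)
            if p in protected:
                continue
            others = [b for b in "ACGT" if b != seq[p - 1]]
            log.append(("sub", p, others[rng.integers(3)]))
    if spec.indel_rate > 0:
        hit = np.flatnonzero(rng.random(L) < spec.indel_rate) + 1
        occupied = set(protected)
        for p in hit:
            p = int(p)
            size = min(int(rng.geometric(spec.indel_geom_p)), spec.indel_max)
            if rng.random() < 0.5:
                span = set(range(p, p + size))
                if span & occupied or p + size - 1 > L:
                    continue
                log.append(("del", p, size))
                occupied |= span
            else:
                if p in occupied:
                    continue
                log.append(("ins", p, random_dna(size, rng)))
                occupied.add(p)

    log.sort(key=lambda e: (e[1], e[0]))
    return apply_mutation_log(seq, log), log


def map_ancestor_position(log: MutationLog, pos: int) -> int | None:
    """Map an ancestor coordinate to the degraded sequence (None if deleted)."""
    offset = 0
    for kind, p, payload in sorted(log, key=lambda e: e[1]):
        if kind == "sub":
            continue
        if kind == "ins":
            if p < pos:
                offset += len(payload)
        elif kind == "del":
            if p + payload - 1 < pos:
                offset -= payload
            elif p <= pos:
                return None
    return pos + offset


@dataclasses.dataclass
class DegradedProvirus:
    """A decayed provirus with its organization lifted through the mutation log."""

    name: str
    sequence: str
    orfs: dict[str, tuple[int | None, int | None]]
    splice_donor: int | None
    splice_acceptor: int | None
    log: MutationLog
    ancestor: AncestralProvirus
    junction_edits: list[tuple[int, str]] = dataclasses.field(default_factory=list)


def degrade_provirus(provirus: AncestralProvirus, spec: DegradationSpec) -> DegradedProvirus:
    """Degrade and lift coordinates; splice-site context is restored to GT/AG
    if decay destroyed it, with each repaired base recorded as an edit."""
    seq, log = degrade(provirus, spec)
    orfs = {
        name: (map_ancestor_position(log, iv[0]), map_ancestor_position(log, iv[1]))
        for name, iv in provirus.orfs.items()
    }
    donor = map_ancestor_position(log, provirus.splice_donor)
    acceptor = map_ancestor_position(log, provirus.splice_acceptor)
    edits: list[tuple[int, str]] = []
    chars = list(seq)
    if donor is not None and donor + 1 <= len(chars):
        for off, base in enumerate("GT"):
            if chars[donor - 1 + off] != base:
                chars[donor - 1 + off] = base
                edits.append((donor + off, base))
    if acceptor is not None and acceptor >= 2:
        for off, base in enumerate("AG"):
            if chars[acceptor - 2 + off] != base:
                chars[acceptor - 2 + off] = base
                edits.append((acceptor - 1 + off, base))
    return DegradedProvirus(
        name=provirus.name,
        sequence="".join(chars),
        orfs=orfs,
        splice_donor=donor,
        splice_acceptor=acceptor,
        log=log,
        ancestor=provirus,
        junction_edits=edits,
    )


# ---------------------------------------------------------------------------
# planting into a host genome


@dataclasses.dataclass
class LocusTruth:
    name: str
    chromosome: str
    interval: tuple[int, int]
    strand: str
    sequence: str  # the inserted provirus in its forward (provirus) orientation
    mutation_log: MutationLog | None = None
    orf_statuses: dict[str, str] | None = None
    exon_truth: list[tuple[int, int]] | None = None


@dataclasses.dataclass
class GroundTruth:
    loci: list[LocusTruth]

    def validate_against(self, genome: dict[str, str]) -> None:
        """Truth coherence: extracting each interval recovers the stored sequence."""
        for t in self.loci:
            sub = slice1(genome[t.chromosome], t.interval)
            if t.strand == "-":
                sub = revcomp(sub)
            if sub != t.sequence:
                raise AssertionError(f"locus {t.name} does not match the emitted genome")


def plant(
    host_length: int,
    proviruses: list[str],
    positions: list[tuple[str, int]] | list[int],
    strands: list[str],
    seed: int = 0,
    chromosomes: list[str] | None = None,
    gc: float = 0.5,
    names: list[str] | None = None,
) -> tuple[dict[str, str], GroundTruth]:
    """Insert provirus sequences into i.i.d. background chromosomes.

    ``positions`` are background coordinates (insertion after position-1, so
    the provirus starts at that coordinate before shifting); final-genome
    coordinates in the returned :class:`GroundTruth` account for upstream
    insertions.  Positions may be bare integers (single chromosome) or
    (chromosome, position) pairs.
    """
    if not len(proviruses) == len(positions) == len(strands):
        raise ValueError("proviruses, positions and strands must be parallel lists")
    chromosomes = chromosomes or ["chr1"]
    rng = np.random.default_rng(seed)
    genome = {c: random_dna(host_length, rng, gc) for c in chromosomes}
    names = names or [f"locus_{i+1}" for i in range(len(proviruses))]

    per_chrom: dict[str, list[tuple[int, int]]] = {c: [] for c in chromosomes}
    for i, posspec in enumerate(positions):
        chrom, pos = (chromosomes[0], posspec) if isinstance(posspec, int) else posspec
        if chrom not in genome:
            raise ValueError(f"unknown chromosome {chrom!r}")
        if not 1 <= pos <= host_length + 1:
            raise ValueError(f"position {pos} outside chromosome {chrom!r}")
        per_chrom[chrom].append((pos, i))
    for chrom, items in per_chrom.items():
        seen: dict[int, int] = {}
        for pos, i in items:
            if pos in seen:
                raise ValueError(
                    f"overlapping insertions on {chrom}: #{seen[pos]} and #{i} both at {pos}"
                )
            seen[pos] = i

    loci: list[LocusTruth] = []
    for chrom, items in per_chrom.items():
        items.sort()
        offset = 0
        pieces: list[str] = []
        prev = 0
        background = genome[chrom]
        for pos, i in items:
            inserted = proviruses[i] if strands[i] == "+" else revcomp(proviruses[i])
            pieces.append(background[prev : pos - 1])
            start = pos + offset
            pieces.append(inserted)
            loci.append(
                LocusTruth(
                    name=names[i],
                    chromosome=chrom,
                    interval=(start, start + len(inserted) - 1),
                    strand=strands[i],
                    sequence=proviruses[i],
                )
            )
            offset += len(inserted)
            prev = pos - 1
        pieces.append(background[prev:])
        genome[chrom] = "".join(pieces)

    truth = GroundTruth(loci=sorted(loci, key=lambda t: (t.chromosome, t.interval)))
    truth.validate_against(genome)
    return genome, truth


# ---------------------------------------------------------------------------
# transcripts


def simulate_transcripts(
    provirus: AncestralProvirus | DegradedProvirus, spliced: bool = True
) -> tuple[str, list[tuple[int, int]]]:
    """Transcript sequence plus exon truth (1-based provirus intervals).

    Spliced: exon1 = [1, donor-1], exon2 = [acceptor+1, L] (the intron spans
    gag/pro/pol, as for a subgenomic env mRNA).  Unspliced: the contiguous
    provirus interval.
    """
    seq = provirus.sequence
    L = len(seq)
    if not spliced:
        return seq, [(1, L)]
    d, a = provirus.splice_donor, provirus.splice_acceptor
    if d is None or a is None:
        raise ValueError("provirus lost its splice donor/acceptor; cannot splice")
    exons = [(1, d - 1), (a + 1, L)]
    return "".join(slice1(seq, iv) for iv in exons), exons


# ---------------------------------------------------------------------------
# sequence evolution along a tree


_JC_BASES = "ACGT"


def evolve_on_tree(
    root_sequence: str,
    tree: Node | str,
    model: str = "JC69",
    seed: int = 0,
) -> dict[str, str]:
    """Evolve a sequence down a tree under JC69; returns {leaf name: sequence}.

    Branch lengths are expected substitutions per site; per site the
    probability of observing a different base after a branch of length t is
    (3/4)(1 - exp(-4t/3)), the JC69 transition probability.
    """
    if model.upper() != "JC69":
        raise ValueError(f"unsupported evolution model {model!r}")
    node = parse_newick(tree) if isinstance(tree, str) else tree
    for n in node.walk():
        if n.length < 0:
            raise ValueError("branch lengths must be >= 0")
    rng = np.random.default_rng(seed)
    out: dict[str, str] = {}

    def descend(n: Node, seq: np.ndarray):
        if n.length > 0:
            p = 0.75 * (1.0 - math.exp(-4.0 * n.length / 3.0))
            hit = rng.random(seq.size) < p
            if hit.any():
                seq = seq.copy()
                # conditional on change: uniform over the three other bases
                seq[hit] = (seq[hit] + rng.integers(1, 4, size=int(hit.sum()))) % 4
        if n.is_leaf():
            if n.name in out:
                raise ValueError(f"duplicate leaf name {n.name!r}")
            out[n.name] = "".join(_JC_BASES[b] for b in seq)
        for c in n.children:
            descend(c, seq)

    enc = np.frombuffer(root_sequence.encode(), dtype=np.uint8)
    lut = np.zeros(256, dtype=np.int64)
    for i, b in enumerate(_JC_BASES):
        lut[ord(b)] = i
    descend(node, lut[enc])
    return out


# ---------------------------------------------------------------------------
# immunoassay plates


@dataclasses.dataclass
class PlateDesign:
    """Design of a simulated ELISPOT/ELISA plate.

    ``true_effects`` maps stimulus label → true signal above background, in
    counts (ELISPOT) or absorbance units (ELISA); the background ("no stim")
    wells are always included.
    """

    true_effects: dict[str, float]
    replicates: int = 2
    true_background: float = 5.0
    noise_sd: float = 2.0
    cells_per_well: int = 200_000
    assay: str = "elispot"
    seed: int = 0


@dataclasses.dataclass
class SimulatedPlate:
    wells: list[tuple[str, str, int, float]]  # (well id, stimulus, replicate, value)
    cells_per_well: int
    true_background: float
    true_effects: dict[str, float]
    seed: int

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.wells, columns=["well", "stimulus", "replicate", "value"])

    def values_for(self, stimulus: str) -> list[float]:
        return [v for _, s, _, v in self.wells if s == stimulus]


def simulate_plate(design: PlateDesign) -> SimulatedPlate:
    """Draw well values as background + effect + Gaussian noise.

    ELISPOT values are rounded to whole spots and floored at zero (counts);
    ELISA absorbances are left continuous (floored at zero).  Deterministic
    per seed; with ``noise_sd == 0`` replicate wells are exactly equal.
    """
    if design.replicates < 1:
        raise ValueError("each stimulus needs at least one replicate")
    if any(e < 0 for e in design.true_effects.values()):
        raise ValueError("true effects must be non-negative")
    rng = np.random.default_rng(design.seed)
    wells = []
    stimuli = {"no stim": 0.0, **design.true_effects}
    widx = 0
    for label, effect in stimuli.items():
        for rep in range(1, design.replicates + 1):
            widx += 1
            value = design.true_background + effect
            if design.noise_sd > 0:
                value += rng.normal(0.0, design.noise_sd)
            value = max(value, 0.0)
            if design.assay == "elispot":
                value = float(round(value))
            wells.append((f"W{widx:03d}", label, rep, value))
    return SimulatedPlate(
        wells=wells,
        cells_per_well=design.cells_per_well,
        true_background=design.true_background,
        true_effects=dict(design.true_effects),
        seed=design.seed,
    )
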