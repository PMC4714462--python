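"""Canonical retroviral Env structural features and hydropathy profiles.

A functional retroviral envelope protein carries, N- to C-terminus: a signal
leader peptide, the surface subunit (SU), a furin-type R-X-(K/R)-R cleavage
motif, and the transmembrane subunit (TM) containing the fusion peptide, an
immunosuppressive (ISU) domain and a membrane anchor.  The detectors here are
hydropathy-based heuristics (not trained predictors): the leader, fusion
peptide and anchor are hydrophobic stretches in characteristic positions, and
the composite annotator picks the cleavage motif that yields a consistent
layout.

Defaults follow standard practice: Kyte–Doolittle scale, window 9 for plots,
window 19 and threshold 1.6 for membrane-anchor detection.
"""

from __future__ import annotations

import dataclasses
import re

import numpy as np

# Kyte-Doolittle hydropathy values
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

SCALES = {"kd": KYTE_DOOLITTLE}


@dataclasses.dataclass
class HydropathyProfile:
    """Sliding-window mean hydropathy; ``values[i]`` is position i+1 (NaN at
    ends narrower than half a window)."""

    scale_name: str
    window: int
    values: np.ndarray

    def __len__(self):
        return len(self.values)


def _residue_values(protein: str, scale: dict[str, float], on_unknown: str) -> np.ndarray:
    vals = np.empty(len(protein))
    for i, aa in enumerate(protein.upper()):
        if aa in scale:
            vals[i] = scale[aa]
        elif on_unknown == "error":
            raise ValueError(f"unknown residue {aa!r} at position {i + 1}")
        else:
            vals[i] = 0.0
    return vals


def hydropathy_profile(
    protein: str,
    scale: str | dict[str, float] = "kd",
    window: int = 9,
    on_unknown: str = "error",
) -> HydropathyProfile:
    """Sliding-window mean hydropathy (window must be odd, <= protein length).

    Positions whose window would run off either end are NaN.  ``on_unknown``
    is 'error' or 'zero' (score unknown residues 0 with a warning-free pass).
    """
    scale_name = scale if isinstance(scale, str) else "custom"
    table = SCALES[scale] if isinstance(scale, str) else scale
    if window % 2 == 0 or window < 1:
        raise ValueError(f"window must be odd and positive, got {window}")
    if window > len(protein):
        raise ValueError(f"window {window} exceeds protein length {len(protein)}")
    vals = _residue_values(protein, table, on_unknown)
    half = window // 2
    out = np.full(len(protein), np.nan)
    means = np.convolve(vals, np.ones(window) / window, mode="valid")
    out[half : len(protein) - half] = means
    return HydropathyProfile(scale_name=scale_name, window=window, values=out)


# ---------------------------------------------------------------------------
# individual detectors


_CLEAVAGE_RE = re.compile(r"(?=(R.[KR]R))")


def find_cleavage_motif(protein: str) -> list[tuple[tuple[int, int], int]]:
    """All (possibly overlapping) R-X-(K/R)-R furin-type motifs.

    Returns [(motif interval, cleavage position)]; cleavage is after the
    final R of the motif (the cleavage position *is* the motif end).
    """
    out = []
    for m in _CLEAVAGE_RE.finditer(protein.upper()):
        start = m.start() + 1
        out.append(((start, start + 3), start + 3))
    return out


@dataclasses.dataclass
class LeaderParams:
    min_core: int = 7      # consecutive hydrophobic residues forming the h-core
    min_h: float = 1.5     # per-residue hydropathy threshold for the core
    n_term: int = 45       # search window from the N-terminus
    c_region: int = 5      # polar C-region residues appended after the core


def detect_leader(
    protein: str, profile: HydropathyProfile | None = None, params: LeaderParams | None = None
) -> tuple[int, int] | None:
    """Signal-leader heuristic: first N-terminal hydrophobic core + C-region.

    Returns positions 1..c, or None when no core of ``min_core`` consecutive
    residues with hydropathy >= ``min_h`` lies within the first ``n_term``
    residues.  (``profile`` is accepted for API symmetry; the core rule works
    on per-residue values.)
    """
    params = params or LeaderParams()
    vals = _residue_values(protein, KYTE_DOOLITTLE, "zero")
    limit = min(params.n_term, len(protein))
    run = 0
    for i in range(limit):
        run = run + 1 if vals[i] >= params.min_h else 0
        if run >= params.min_core:
            # extend to the end of the hydrophobic run
            j = i
            while j + 1 < limit and vals[j + 1] >= params.min_h:
                j += 1
            end = min(j + 1 + params.c_region, len(protein))
            return (1, end)
    return None


@dataclasses.dataclass
class FusionParams:
    min_len: int = 12      # minimum fusion-peptide length
    min_h: float = 1.0     # minimum mean hydropathy of the peptide
    fusion_offset: int = 12  # max residues between cleavage and fusion start


def detect_fusion_domain(
    protein: str,
    cleavage_pos: int,
    profile: HydropathyProfile | None = None,
    params: FusionParams | None = None,
) -> tuple[int, int] | None:
    """First hydrophobic window of >= min_len residues starting within
    ``fusion_offset`` residues after the cleavage position; extended to the
    right while the running mean stays above threshold."""
    params = params or FusionParams()
    if cleavage_pos >= len(protein):
        return None
    vals = _residue_values(protein, KYTE_DOOLITTLE, "zero")
    for start in range(cleavage_pos + 1, min(cleavage_pos + 1 + params.fusion_offset, len(protein) + 1)):
        end = start + params.min_len - 1
        if end > len(protein):
            break
        if vals[start - 1 : end].mean() >= params.min_h:
            while end + 1 <= len(protein) and vals[start - 1 : end + 1].mean() >= params.min_h:
                end += 1
            return (start, end)
    return None


def match_isu(
    protein: str, isu_consensus: str, min_identity: float = 0.8
) -> tuple[tuple[int, int], float] | None:
    """Best ungapped window matching the ISU consensus (ties -> leftmost).

    The consensus is a configuration input: the immunosuppressive domain is a
    conserved TM segment but its exact sequence varies by retroviral family.
    """
    w = len(isu_consensus)
    if w == 0 or w > len(protein):
        return None
    target = protein.upper()
    cons = isu_consensus.upper()
    best = None
    for start in range(len(target) - w + 1):
        ident = sum(1 for a, b in zip(target[start : start + w], cons) if a == b) / w
        if best is None or ident > best[1]:
            best = (start, ident)
    if best is None or best[1] < min_identity:
        return None
    return ((best[0] + 1, best[0] + w), round(best[1], 4))


@dataclasses.dataclass
class AnchorParams:
    tm_window: int = 19
    tm_threshold: float = 1.6


def detect_tm_anchor(
    protein: str,
    profile: HydropathyProfile | None = None,
    params: AnchorParams | None = None,
    search_start: int = 1,
) -> tuple[int, int] | None:
    """Maximal-scoring window of length ``tm_window`` with mean hydropathy >=
    ``tm_threshold`` in the C-terminal half; ties break toward the C-terminus.

    ``search_start`` restricts the window to begin at or after that position
    (used by the composite annotator to keep the anchor downstream of the
    fusion/ISU features).
    """
    params = params or AnchorParams()
    if len(protein) < params.tm_window:
        return None
    if profile is None or profile.window != params.tm_window:
        profile = hydropathy_profile(protein, "kd", params.tm_window, on_unknown="zero")
    half = params.tm_window // 2
    centers = np.arange(len(protein)) + 1
    ok = (~np.isnan(profile.values)) & (profile.values >= params.tm_threshold)
    ok &= centers > len(protein) / 2
    ok &= centers - half >= search_start
    if not ok.any():
        return None
    vals = np.where(ok, profile.values, -np.inf)
    best = int(np.flatnonzero(vals == vals.max())[-1])  # C-terminal-most tie
    return (best + 1 - half, best + 1 + half)


# ---------------------------------------------------------------------------
# composite annotation


@dataclasses.dataclass
class EnvParams:
    leader: LeaderParams = dataclasses.field(default_factory=LeaderParams)
    fusion: FusionParams = dataclasses.field(default_factory=FusionParams)
    anchor: AnchorParams = dataclasses.field(default_factory=AnchorParams)
    plot_window: int = 9
    isu_consensus: str | None = None
    isu_min_identity: float = 0.7


@dataclasses.dataclass
class EnvAnnotation:
    """Positioned Env features; absent features are None.

    Invariants (checked by :meth:`validate`): leader starts at 1; SU ends at
    the cleavage position; TM starts right after it; the fusion domain lies
    within TM near the cleavage site; the anchor lies within TM; every
    interval is within [1, length].
    """

    protein_length: int
    leader: tuple[int, int] | None
    cleavage_motif: tuple[int, int] | None
    cleavage_pos: int | None
    su: tuple[int, int] | None
    tm: tuple[int, int] | None
    fusion_domain: tuple[int, int] | None
    isu_domain: tuple[tuple[int, int], float] | None
    cysteines: list[int]
    tm_anchor: tuple[int, int] | None

    def validate(self, fusion_offset: int = 12) -> None:
        L = self.protein_length

        def _in_bounds(iv, what):
            if iv is not None and not (1 <= iv[0] <= iv[1] <= L):
                raise AssertionError(f"{what} {iv} outside [1, {L}]")

        _in_bounds(self.leader, "leader")
        _in_bounds(self.cleavage_motif, "cleavage motif")
        _in_bounds(self.su, "SU")
        _in_bounds(self.tm, "TM")
        _in_bounds(self.fusion_domain, "fusion domain")
        _in_bounds(self.tm_anchor, "TM anchor")
        if self.isu_domain is not None:
            _in_bounds(self.isu_domain[0], "ISU domain")
        if self.leader is not None and self.leader[0] != 1:
            raise AssertionError("leader must start at position 1")
        if self.cleavage_pos is not None:
            if self.su is not None and self.su[1] != self.cleavage_pos:
                raise AssertionError("SU must end at the cleavage position")
            if self.tm is not None and self.tm[0] != self.cleavage_pos + 1:
                raise AssertionError("TM must start after the cleavage position")
        if self.fusion_domain is not None and self.tm is not None:
            if not (self.tm[0] <= self.fusion_domain[0] <= self.fusion_domain[1] <= self.tm[1]):
                raise AssertionError("fusion domain must lie within TM")
            if self.fusion_domain[0] - self.tm[0] > fusion_offset:
                raise AssertionError("fusion domain must begin near the cleavage site")
        if self.tm_anchor is not None and self.tm is not None:
            if not (self.tm[0] <= self.tm_anchor[0] <= self.tm_anchor[1] <= self.tm[1]):
                raise AssertionError("TM anchor must lie within TM")
        for p in self.cysteines:
            if not 1 <= p <= L:
                raise AssertionError(f"cysteine position {p} outside [1, {L}]")


def annotate_env(protein: str, params: EnvParams | None = None) -> EnvAnnotation:
    """Compose the detectors into a full (possibly partial) Env annotation.

    Among multiple cleavage motifs, the one whose downstream fusion window is
    most hydrophobic wins; features that cannot be placed are None, and the
    returned annotation always satisfies the ordering invariants.
    """
    params = params or EnvParams()
    protein = protein.upper()
    L = len(protein)
    leader = detect_leader(protein, params=params.leader)
    vals = _residue_values(protein, KYTE_DOOLITTLE, "zero")

    best = None  # (fusion mean hydropathy, cleavage motif, cleavage pos, fusion iv)
    for motif_iv, cpos in find_cleavage_motif(protein):
        if leader is not None and cpos <= leader[1]:
            continue
        fusion = detect_fusion_domain(protein, cpos, params=params.fusion)
        if fusion is None:
            continue
        mean_h = float(vals[fusion[0] - 1 : fusion[1]].mean())
        if best is None or mean_h > best[0]:
            best = (mean_h, motif_iv, cpos, fusion)

    if best is not None:
        _, motif_iv, cpos, fusion = best
    else:
        hits = [h for h in find_cleavage_motif(protein) if leader is None or h[1] > leader[1]]
        motif_iv, cpos = hits[0] if hits else (None, None)
        fusion = None

    su = tm = None
    if cpos is not None:
        su_start = leader[1] + 1 if leader is not None and leader[1] + 1 <= cpos else 1
        if su_start <= cpos:
            su = (su_start, cpos)
        if cpos + 1 <= L:
            tm = (cpos + 1, L)

    isu = None
    if params.isu_consensus and tm is not None:
        search_from = fusion[1] + 1 if fusion is not None else tm[0]
        sub = protein[search_from - 1 : tm[1]]
        hit = match_isu(sub, params.isu_consensus, params.isu_min_identity)
        if hit is not None:
            (s, e), ident = hit
            isu = ((s + search_from - 1, e + search_from - 1), ident)

    anchor = None
    if tm is not None and tm[1] - tm[0] + 1 >= params.anchor.tm_window:
        after = isu[0][1] if isu is not None else (fusion[1] if fusion is not None else tm[0] - 1)
        anchor = detect_tm_anchor(
            protein, params=params.anchor, search_start=max(tm[0], after + 1)
        )

    ann = EnvAnnotation(
        protein_length=L,
        leader=leader,
        cleavage_motif=motif_iv,
        cleavage_pos=cpos,
        su=su,
        tm=tm,
        fusion_domain=fusion,
        isu_domain=isu,
        cysteines=[i + 1 for i, aa in enumerate(protein) if aa == "C"],
        tm_anchor=anchor,
    )
    ann.validate(fusion_offset=params.fusion.fusion_offset)
    return ann


@dataclasses.dataclass
class ImmunoEpitope:
    """A named epitope on a protein, 1-based inclusive (e.g. Env 526-540, a 15-mer)."""

    name: str
    start: int
    end: int
    sequence: str

    def __post_init__(self):
        if self.end - self.start + 1 != len(self.sequence):
            raise ValueError(
                f"epitope {self.name}: span {self.start}-{self.end} "
                f"({self.end - self.start + 1} residues) != sequence length {len(self.sequence)}"
            )
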