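"""Peptide-level immunology analytics.

Three small toolboxes used to interpret antigen-specific immune data:

* overlapping peptide libraries (default 15-mers overlapping by 11, the
  standard design for T-cell epitope mapping, with the last peptide anchored
  at the protein's C-terminus),
* ungapped sliding-window identity scans of an epitope against another
  protein (the cross-reactivity question: could a response against epitope X
  be explained by similarity to protein Y?),
* ELISPOT / ELISA quantification: replicate averaging, background
  subtraction, spot-forming cells per million, and a configurable positivity
  rule.
"""

from __future__ import annotations

import dataclasses
import math
import statistics
import warnings

from .envfeatures import ImmunoEpitope

__all__ = [
    "ImmunoEpitope",
    "PeptideLibrary",
    "make_peptide_library",
    "WindowIdentityResult",
    "window_identity",
    "ResponseCall",
    "elispot_quantify",
    "elisa_quantify",
    "PositivityRule",
    "call_positive",
]


# ---------------------------------------------------------------------------
# peptide libraries


@dataclasses.dataclass
class PeptideLibrary:
    protein_name: str
    peptide_length: int
    overlap: int
    peptides: list[tuple[int, int, int, str]]  # (index, start, end, sequence)

    @property
    def step(self) -> int:
        return self.peptide_length - self.overlap

    def covers_fully(self, protein_length: int) -> bool:
        covered = 0
        for _, s, e, _ in sorted(self.peptides, key=lambda p: p[1]):
            if s <= covered + 1:
                covered = max(covered, e)
        return covered >= protein_length


def make_peptide_library(
    protein: str, name: str = "protein", length: int = 15, overlap: int = 11
) -> PeptideLibrary:
    """Overlapping peptides spanning the whole protein.

    Starts run 1, 1+step, ... with step = length − overlap; if the final
    regular window would overrun, one last peptide ending exactly at the
    C-terminus is appended.  Peptide count = ceil((L − length)/step) + 1.
    A protein shorter than ``length`` yields itself as a single peptide,
    with a warning.
    """
    if not length > overlap >= 0:
        raise ValueError(f"need length > overlap >= 0, got {length}, {overlap}")
    L = len(protein)
    if L < length:
        warnings.warn(f"{name}: protein ({L} aa) shorter than peptide length {length}")
        return PeptideLibrary(name, length, overlap, [(1, 1, L, protein)])
    step = length - overlap
    starts = list(range(1, L - length + 2, step))
    if starts[-1] != L - length + 1:
        starts.append(L - length + 1)  # C-terminal anchored final peptide
    peptides = [
        (i + 1, s, s + length - 1, protein[s - 1 : s + length - 1])
        for i, s in enumerate(starts)
    ]
    assert len(peptides) == math.ceil((L - length) / step) + 1
    return PeptideLibrary(name, length, overlap, peptides)


# ---------------------------------------------------------------------------
# cross-reactivity identity scan


@dataclasses.dataclass
class WindowIdentityResult:
    epitope: ImmunoEpitope
    target_name: str
    identities: list[tuple[int, float]]  # (window start on target, fraction)
    max_identity: float
    argmax_start: int

    @property
    def max_identity_percent(self) -> int:
        """Max identity as a display percentage, rounded half-up."""
        return int(math.floor(self.max_identity * 100 + 0.5))


def window_identity(
    epitope: ImmunoEpitope, target: str, target_name: str = "target"
) -> WindowIdentityResult:
    """Ungapped identity of the epitope at every window of the target.

    Identity at a start = exact positional matches / epitope length; the
    first window achieving the maximum is the argmax.
    """
    pep = epitope.sequence.upper()
    tgt = target.upper()
    w = len(pep)
    if len(tgt) < w:
        raise ValueError(
            f"target {target_name!r} ({len(tgt)} aa) shorter than epitope {epitope.name} ({w} aa)"
        )
    identities = []
    best, best_start = -1.0, 1
    for start in range(1, len(tgt) - w + 2):
        ident = sum(1 for a, b in zip(pep, tgt[start - 1 : start + w - 1]) if a == b) / w
        identities.append((start, ident))
        if ident > best:
            best, best_start = ident, start
    return WindowIdentityResult(
        epitope=epitope,
        target_name=target_name,
        identities=identities,
        max_identity=best,
        argmax_start=best_start,
    )


# ---------------------------------------------------------------------------
# immunoassay quantification


@dataclasses.dataclass
class ResponseCall:
    stimulus: str
    replicate_values: list[float]
    background_values: list[float]
    corrected: float              # mean(stim) - mean(background); assay-specific flooring
    sfc_per_million: float | None  # ELISPOT only
    sd: float | None               # replicate SD when >= 3 replicates
    positive: bool | None = None
    rule: dict | None = None


def elispot_quantify(
    stim_wells: list[float],
    background_wells: list[float],
    cells_per_well: int,
    stimulus: str = "stimulus",
    summed: bool = False,
) -> ResponseCall:
    """Background-subtracted ELISPOT response, floored at zero.

    corrected = mean(stim) − mean(background) spots per well; SFC per million
    = corrected × 1e6 / cells_per_well.  With ``summed`` the
    background-subtracted replicates are summed instead of averaged (the
    duplicate-well reporting convention for summed responses).
    """
    if cells_per_well <= 0:
        raise ValueError(f"cells_per_well must be positive, got {cells_per_well}")
    if not stim_wells or not background_wells:
        raise ValueError("need at least one stimulus and one background well")
    bg = statistics.fmean(background_wells)
    if summed:
        corrected = max(sum(v - bg for v in stim_wells), 0.0)
    else:
        corrected = max(statistics.fmean(stim_wells) - bg, 0.0)
    sd = statistics.stdev(stim_wells) if len(stim_wells) >= 3 else None
    return ResponseCall(
        stimulus=stimulus,
        replicate_values=list(stim_wells),
        background_values=list(background_wells),
        corrected=corrected,
        sfc_per_million=corrected * 1e6 / cells_per_well,
        sd=sd,
    )


def elisa_quantify(
    duplicate_wells: list[float],
    background_wells: list[float],
    stimulus: str = "peptide",
) -> ResponseCall:
    """Duplicate-averaged, background-subtracted ELISA absorbance.

    Negative corrected values are retained (plotting parity for peptide
    arrays).  A single well instead of a duplicate is accepted with a warning.
    """
    if not duplicate_wells or not background_wells:
        raise ValueError("need at least one sample and one background well")
    if len(duplicate_wells) < 2:
        warnings.warn(f"{stimulus}: single well where a duplicate was expected")
    corrected = statistics.fmean(duplicate_wells) - statistics.fmean(background_wells)
    sd = statistics.stdev(duplicate_wells) if len(duplicate_wells) >= 3 else None
    return ResponseCall(
        stimulus=stimulus,
        replicate_values=list(duplicate_wells),
        background_values=list(background_wells),
        corrected=corrected,
        sfc_per_million=None,
        sd=sd,
    )


@dataclasses.dataclass
class PositivityRule:
    """Default positivity: a response is positive when the corrected value
    reaches ``min_corrected`` AND the stimulus mean is at least ``fold`` times
    the background mean.  Entirely configurable; recorded on the call."""

    min_corrected: float = 10.0
    fold: float = 2.0


def call_positive(response: ResponseCall, rule: PositivityRule | None = None) -> bool:
    rule = rule or PositivityRule()
    stim_mean = statistics.fmean(response.replicate_values)
    bg_mean = statistics.fmean(response.background_values)
    positive = response.corrected >= rule.min_corrected and stim_mean >= rule.fold * max(
        bg_mean, 1e-12
    )
    response.positive = positive
    response.rule = dataclasses.asdict(rule)
    return positive
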