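"""Heptad-repeat register calling for the PadC sensor–effector linker.

The coiled-coil linker between the PHY domain and the GGDEF effector follows
the classical heptad pattern a-b-c-d-e-f-g with hydrophobics at positions a
and d.  Because the effector-proximal end of the linker is structurally
pinned by the DXLT wide turn, register phases here are counted back from the
DXLT end of the linker rather than from its N-terminus: under phase ``p`` a
linker index ``i`` (0-based, 0 adjacent to the PHY anchor, ``L-1`` adjacent
to the D of DXLT) occupies heptad slot ``(i - L - p) mod 7`` with slot 0 = a
and slot 3 = d.  This makes phases directly comparable between linkers whose
lengths differ by multiples of seven.

Two overlapping registers can typically be defined; by convention the
top-scoring phase is labelled "inhibiting" (the register resolved in the
dark-state crystal structure) and the runner-up "stimulating".  Linkers four
residues shorter than the 28-residue reference are modelled as locally
overwound: a 10-residue stretch spanning three helical turns, treated as a
single frame shift of +4 (mod 7, equivalent to a 3-residue phase
retardation) for all positions upstream of a breakpoint.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

#: coiled-coil stabilising residues: hydrophobics plus Asn.  Ala is included
#: as a (weak) hydrophobic; override via the ``stabilisers`` arguments.
DEFAULT_STABILISERS = frozenset("AVLIMFWYN")

A_SLOT, D_SLOT = 0, 3
N_PHASES = 7

REG_SWITCH = "switch_capable"
REG_OVERWOUND = "overwound_switch"
REG_IMPAIRED = "impaired_cc"
REG_UNKNOWN = "unknown"


@dataclass(frozen=True)
class RegisterAssignment:
    sequence_id: str
    phase_scores: tuple  # 7 floats in [0, 1]
    inhibiting_phase: int
    stimulating_phase: int
    overwind_breakpoint: Optional[int]
    regulatory_class: str


def heptad_slot(i: int, linker_length: int, phase: int) -> int:
    """Heptad slot (0=a … 6=g) of linker index ``i`` under ``phase``, DXLT-framed."""
    return (i - linker_length - phase) % N_PHASES


def score_register(linker_seq: str, phase: int,
                   stabilisers: Iterable[str] = DEFAULT_STABILISERS) -> float:
    """Fraction of a/d slots under ``phase`` occupied by stabilising residues."""
    L = len(linker_seq)
    if L < 7:
        raise ValueError(f"linker too short for register scoring ({L} < 7)")
    stab = frozenset(stabilisers)
    slots = 0
    occupied = 0
    for i, res in enumerate(linker_seq):
        if heptad_slot(i, L, phase) in (A_SLOT, D_SLOT):
            slots += 1
            if res in stab:
                occupied += 1
    return occupied / slots


def _overwound_scores(linker_seq: str, breakpoint: int,
                      stab: frozenset) -> list[float]:
    """Per-phase a/d occupancy with positions before ``breakpoint`` shifted +4."""
    L = len(linker_seq)
    scores = []
    for p in range(N_PHASES):
        slots = occupied = 0
        for i, res in enumerate(linker_seq):
            eff = p + 4 if i < breakpoint else p  # upstream part in retarded frame
            if heptad_slot(i, L, eff) in (A_SLOT, D_SLOT):
                slots += 1
                if res in stab:
                    occupied += 1
        scores.append(occupied / slots if slots else 0.0)
    return scores


def overwind_adjust(linker_seq: str,
                    stabilisers: Iterable[str] = DEFAULT_STABILISERS
                    ) -> tuple[int, tuple]:
    """Best breakpoint for the overwinding model of −4 linkers.

    Every breakpoint position ``b`` (the 10-residue overwound stretch must fit
    between ``b`` and the DXLT end, so ``0 ≤ b ≤ L − 10``) is scored with the
    upstream part of the linker phase-shifted by +4; the breakpoint maximising
    the best per-phase stabiliser fraction is returned together with the
    adjusted phase scores.  Ties go to the smallest breakpoint.
    """
    L = len(linker_seq)
    if L < 10:
        raise ValueError(f"linker too short for the overwinding model ({L} < 10)")
    stab = frozenset(stabilisers)
    best_b, best_scores, best_top = 0, None, -1.0
    for b in range(0, L - 10 + 1):
        scores = _overwound_scores(linker_seq, b, stab)
        top = max(scores)
        if top > best_top:
            best_b, best_scores, best_top = b, scores, top
    return best_b, tuple(best_scores)


def predict_regulatory_class(relative_length: int) -> str:
    """Regulatory phenotype expected from the relative linker length.

    Lengths divisible by seven preserve both registers (light-switchable);
    −4 is rescued by local overwinding; +2 breaks the heptad periodicity and
    impairs the coiled coil; anything else is unclassified.
    """
    if relative_length % 7 == 0:
        return REG_SWITCH
    if relative_length == -4:
        return REG_OVERWOUND
    if relative_length == 2:
        return REG_IMPAIRED
    return REG_UNKNOWN


def _rank_phases(scores: Sequence[float]) -> tuple[int, int]:
    order = sorted(range(N_PHASES), key=lambda p: (-scores[p], p))
    return order[0], order[1]


def call_registers(linker_seq: str, relative_length: int,
                   sequence_id: str = "",
                   stabilisers: Iterable[str] = DEFAULT_STABILISERS
                   ) -> RegisterAssignment:
    """Score all seven phases and call the inhibiting/stimulating registers.

    For ``relative_length == -4`` the overwinding path is taken first and the
    adjusted scores are ranked.  The top phase is labelled inhibiting and the
    runner-up stimulating (convention, not a structure prediction); ties are
    broken toward the lower phase index, so the two calls are always distinct.
    """
    stab = frozenset(stabilisers)
    breakpoint: Optional[int] = None
    if relative_length == -4:
        breakpoint, scores = overwind_adjust(linker_seq, stab)
    else:
        scores = tuple(score_register(linker_seq, p, stab) for p in range(N_PHASES))
    inhibiting, stimulating = _rank_phases(scores)
    return RegisterAssignment(
        sequence_id=sequence_id,
        phase_scores=tuple(scores),
        inhibiting_phase=inhibiting,
        stimulating_phase=stimulating,
        overwind_breakpoint=breakpoint,
        regulatory_class=predict_regulatory_class(relative_length),
    )
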