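"""Linker-length statistics for sensor–effector fusion proteins.

The central statistic is the length of the coiled-coil linker between the
photosensory module and the GGDEF effector: the number of residues strictly
between a conserved hydrophobic anchor residue in the terminal PHY helix
(residue 495 of the prototypical homolog) and the D of the DXLT motif that
opens the effector domain (both endpoints excluded).  Lengths are reported
absolute and relative to the 28-residue reference linker, and binned into
the naturally occurring families: multiples of seven (``div7``), −4
(``minus4``), +2 (``plus2``) and everything else (``other``).

The anchor is located by alignment transfer: given an MSA containing a named
reference sequence and the reference's 1-based anchor position, the query
residue occupying the same alignment column is the query anchor.  A query
gapped at that column is reported as unalignable, never silently dropped.
Internally all coordinates are 0-based; reports print 1-based residue
numbers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .motifs import FamilyCall, MotifSet, CLASS_PADC_EAL, default_motif_set

REFERENCE_LINKER_LENGTH = 28

FAMILY_DIV7 = "div7"
FAMILY_MINUS4 = "minus4"
FAMILY_PLUS2 = "plus2"
FAMILY_OTHER = "other"


class AnchorNotAlignable(ValueError):
    """The query has a gap in the reference anchor column."""


class EffectorStartNotFound(ValueError):
    """No DXLT motif downstream of the anchor."""


@dataclass(frozen=True)
class LinkerAnnotation:
    sequence_id: str
    anchor_index: int      # 0-based, unaligned coordinates
    dxlt_index: int        # 0-based index of the D of DXLT
    absolute_length: int
    relative_length: int
    linker_family: str
    eal_linker_length: Optional[int] = None


@dataclass(frozen=True)
class AnchorSpec:
    """Reference sequence id and its 1-based anchor residue number."""

    reference_sequence_id: str
    reference_anchor_position: int  # 1-based residue number in the reference

    def __post_init__(self):
        if self.reference_anchor_position < 1:
            raise ValueError("reference anchor position is 1-based and must be >= 1")


GAP_CHARS = frozenset("-.")


def _is_gap(c: str) -> bool:
    return c in GAP_CHARS


def anchor_column(reference_row: str, anchor_position_1based: int) -> int:
    """Alignment column (0-based) of the reference's Nth residue."""
    n = 0
    for col, c in enumerate(reference_row):
        if not _is_gap(c):
            n += 1
            if n == anchor_position_1based:
                return col
    raise ValueError(
        f"reference row has only {n} residues, anchor position "
        f"{anchor_position_1based} not reachable")


def locate_phy_anchor(query_row: str, reference_row: str,
                      spec: AnchorSpec, query_id: str = "") -> int:
    """Unaligned 0-based index of the query residue in the anchor column."""
    col = anchor_column(reference_row, spec.reference_anchor_position)
    if col >= len(query_row) or _is_gap(query_row[col]):
        raise AnchorNotAlignable(
            f"sequence {query_id or '<query>'}: gap at the reference anchor column {col}")
    return sum(1 for c in query_row[:col] if not _is_gap(c))


def bin_linker_family(relative_length: int) -> str:
    """Linker-family bin; mathematical modulo, so −7, 0, +14 are all div7."""
    if relative_length % 7 == 0:
        return FAMILY_DIV7
    if relative_length == -4:
        return FAMILY_MINUS4
    if relative_length == 2:
        return FAMILY_PLUS2
    return FAMILY_OTHER


def compute_linker(seq: str, anchor_index: int,
                   motifs: Optional[MotifSet] = None,
                   sequence_id: str = "",
                   reference_length: int = REFERENCE_LINKER_LENGTH) -> LinkerAnnotation:
    """Linker annotation from the anchor and the first DXLT downstream of it.

    The absolute length counts residues strictly between the anchor residue
    and the D of DXLT (both excluded).
    """
    motifs = motifs or default_motif_set()
    m = motifs.pattern("DXLT").search(seq, anchor_index + 1)
    if m is None:
        raise EffectorStartNotFound(
            f"sequence {sequence_id or '<seq>'}: no DXLT motif downstream of "
            f"anchor index {anchor_index} (effector start not found)")
    absolute = m.start() - anchor_index - 1
    relative = absolute - reference_length
    return LinkerAnnotation(
        sequence_id=sequence_id,
        anchor_index=anchor_index,
        dxlt_index=m.start(),
        absolute_length=absolute,
        relative_length=relative,
        linker_family=bin_linker_family(relative),
    )


def extract_linker_sequence(seq: str, annotation: LinkerAnnotation) -> str:
    """Residues strictly between anchor and DXLT, N- to C-terminal."""
    return seq[annotation.anchor_index + 1:annotation.dxlt_index]


def eal_linker_length(seq: str, call: FamilyCall,
                      motifs: Optional[MotifSet] = None) -> int:
    """Residues strictly between the end of the GGDEF motif and the EAL motif.

    Only defined for PadC-EALs; uses the same exclusive-endpoint convention
    as the sensor–effector linker.
    """
    if call.class_call != CLASS_PADC_EAL:
        raise ValueError(f"EAL-linker length undefined for class {call.class_call!r}")
    ggdef = next(h for h in call.hits if h.motif_name == "GGDEF")
    eal_hits = [h for h in call.hits
                if h.motif_name in ("EAL", "EAF_DEGENERATE") and h.start >= ggdef.end]
    if not eal_hits:
        raise ValueError("no EAL/EAF hit downstream of GGDEF")
    eal = min(eal_hits, key=lambda h: h.start)
    return eal.start - ggdef.end
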