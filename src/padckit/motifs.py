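"""Essential-motif screening and family classification for PadC-like proteins.

Phytochrome-activated diguanylate cyclases (PadCs) are recognised by a small
set of essential sequence motifs that must occur in domain order along the
protein: a chromophore-binding cysteine near the N-terminus, the DIP motif of
the GAF binding pocket, the PRXSF motif of the PHY tongue, the DXLT wide-turn
motif opening the effector domain and the catalytic GG(D/E)EF signature of
diguanylate cyclases.  PadC-EALs carry, downstream of the GGDEF domain, an
additional EAL phosphodiesterase domain recognised by its E[aliphatic]L
active-site motif (degenerate EAF in catalytically dead homologs) and the
DDFGTG loop required for catalysis.

The classifier in this module is purely sequence based: regular-expression
motif hits chained in domain order.  It performs no profile/HMM search and no
structural validation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: motifs that must all be present, in this order, for a PadC verdict
REQUIRED_ORDER = ("NTS_CYS", "DIP", "PRXSF", "DXLT", "GGDEF")


@dataclass(frozen=True)
class MotifSet:
    """Named residue patterns plus the N-terminal search window for the cysteine.

    Wildcard positions (the X of DXLT/PRXSF) match any residue including the
    ambiguity letter X; positions naming specific residues never match X.
    """

    nts_window: int = 30
    exl_hydrophobics: str = "AILV"
    patterns: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.patterns:
            h = self.exl_hydrophobics
            object.__setattr__(self, "patterns", {
                "NTS_CYS": re.compile("C"),
                "DIP": re.compile("DIP"),
                "PRXSF": re.compile("PR.SF"),
                "DXLT": re.compile("D.LT"),
                "GGDEF": re.compile("GG[DE]EF"),
                "EAL": re.compile(f"E[{h}]L"),
                "EAF_DEGENERATE": re.compile(f"E[{h}]F"),
                "DDFGTG": re.compile("DDFGTG"),
            })

    def pattern(self, name: str) -> re.Pattern:
        return self.patterns[name]


def default_motif_set(nts_window: int = 30, exl_hydrophobics: str = "AILV") -> MotifSet:
    return MotifSet(nts_window=nts_window, exl_hydrophobics=exl_hydrophobics)


@dataclass(frozen=True)
class MotifHit:
    motif_name: str
    start: int  # 0-based
    end: int  # 0-based exclusive
    matched_text: str


CLASS_PADC = "PadC"
CLASS_PADC_EAL = "PadC-EAL"
CLASS_NON_MEMBER = "non-member"


@dataclass(frozen=True)
class FamilyCall:
    class_call: str
    hits: tuple
    pde_active: Optional[bool]  # None ⇔ not applicable (no EAL domain)
    missing_motifs: tuple


def _finditer(seq: str, pat: re.Pattern):
    # non-overlapping leftmost matches, re semantics
    return pat.finditer(seq)


def scan_motifs(seq: str, motifs: Optional[MotifSet] = None) -> list[MotifHit]:
    """All non-overlapping leftmost occurrences of every motif, ordered by start.

    The N-terminal cysteine is only searched within the first
    ``motifs.nts_window`` residues.
    """
    if not seq:
        raise ValueError("empty sequence")
    motifs = motifs or default_motif_set()
    hits: list[MotifHit] = []
    for name, pat in motifs.patterns.items():
        region = seq[: motifs.nts_window] if name == "NTS_CYS" else seq
        for m in _finditer(region, pat):
            hits.append(MotifHit(name, m.start(), m.end(), m.group()))
    hits.sort(key=lambda h: (h.start, h.motif_name))
    return hits


def _first_match_after(seq: str, pat: re.Pattern, pos: int) -> Optional[re.Match]:
    return pat.search(seq, pos)


def classify_family(seq: str, motifs: Optional[MotifSet] = None) -> FamilyCall:
    """Classify a sequence as PadC, PadC-EAL or non-member.

    The required motifs are chained in domain order: the leftmost hit of each
    motif that lies downstream of the previous link is used, so chance matches
    upstream of their proper domain cannot break the chain.  EAL-domain
    evidence (EAL, degenerate EAF, or DDFGTG) downstream of the GGDEF hit
    upgrades the verdict to PadC-EAL; ``pde_active`` is False when only the
    degenerate EAF form is found or the DDFGTG loop is absent.
    """
    if not seq:
        raise ValueError("empty sequence")
    motifs = motifs or default_motif_set()
    chain: dict[str, MotifHit] = {}
    missing: list[str] = []
    pos = 0
    for name in REQUIRED_ORDER:
        if name == "NTS_CYS":
            m = motifs.pattern(name).search(seq[: motifs.nts_window])
        else:
            m = _first_match_after(seq, motifs.pattern(name), pos)
        if m is None:
            missing.append(name)
        else:
            chain[name] = MotifHit(name, m.start(), m.end(), m.group())
            pos = m.end()
    if missing:
        return FamilyCall(CLASS_NON_MEMBER, tuple(chain.values()), None, tuple(missing))

    downstream = chain["GGDEF"].end
    hits = list(chain.values())
    eal = _first_match_after(seq, motifs.pattern("EAL"), downstream)
    eaf = _first_match_after(seq, motifs.pattern("EAF_DEGENERATE"), downstream)
    ddfgtg = _first_match_after(seq, motifs.pattern("DDFGTG"), downstream)
    if eal is None and eaf is None and ddfgtg is None:
        return FamilyCall(CLASS_PADC, tuple(hits), None, ())

    for name, m in (("EAL", eal), ("EAF_DEGENERATE", eaf), ("DDFGTG", ddfgtg)):
        if m is not None:
            hits.append(MotifHit(name, m.start(), m.end(), m.group()))
    pde_active = eal is not None and ddfgtg is not None
    hits.sort(key=lambda h: (h.start, h.motif_name))
    return FamilyCall(CLASS_PADC_EAL, tuple(hits), pde_active, ())
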