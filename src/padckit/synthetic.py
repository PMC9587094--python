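"""Synthetic PadC-like protein families with planted ground truth.

Generates multi-domain protein sequences that carry the essential PadC
motifs (N-terminal Cys, DIP, PRXSF, DXLT, GG[DE]EF and, for PadC-EALs,
E[aliphatic]L and DDFGTG) in the natural domain order
NTS–PAS/GAF–PHY–linker–GGDEF(–EAL-linker–EAL), with a coiled-coil linker of
configurable length relative to the 28-residue reference.  Every emitted
record comes with a ground-truth row (class, linker coordinates and lengths,
planted register phases), so motif screening, linker metrics, register
calling, similarity networks and phylogenies can all be tested for parameter
recovery without any external data.

Divergence model: within a family, each member substitutes mutable template
positions independently at a fixed per-site probability (uniform over the 19
alternative residues); between families, all mutable positions are redrawn
from scratch on a shared motif scaffold, which makes families far closer
within than between — the property the tree and network recovery tests rely
on.  Motif positions, the PHY anchor and (by default) the whole linker are
immutable: the linker is the most length- and sequence-constrained element
of these proteins, and freezing it keeps the planted register phases exact.
There is no indel evolution outside the linker, so the true alignment is a
fixed column layout with gap blocks for linker-length differences and for
the EAL region of EAL-less homologs.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .motifs import AMINO_ACIDS

REFERENCE_LINKER_LENGTH = 28  # absolute linker length of the reference homolog

#: canonical coiled-coil composition for the linker block
LINKER_HYDROPHOBICS = "LIVM"
#: polar residues for non-a/d linker positions; excludes D (would risk a
#: spurious DXLT match inside the linker), and A/N (register stabilisers)
LINKER_POLAR = "STQEKRG"

_N_PHASES = 7

# default block lengths (residues); the natural domain order is fixed,
# lengths are order-of-magnitude realistic and configurable
DEFAULT_BLOCK_LENGTHS = {
    "nts": 30,
    "pas_gaf": 320,
    "phy": 150,
    "eal_linker": 25,
    "ggdef": 160,
    "eal": 250,
}

# patterns that must not arise by chance in mutable template regions
_SCRUB_PATTERNS = ("DIP", "PR.SF", "D.LT", "GG[DE]EF", "E[AILV]L", "E[AILV]F", "DDFGTG")


@dataclass(frozen=True)
class FamilySpec:
    """One synthetic family: linker length, domain complement and divergence."""

    family_id: str
    relative_linker_length: int
    has_eal: bool = False
    pde_active: bool = False
    n_members: int = 1
    within_divergence: float = 0.15
    taxonomy_class: str = ""

    def __post_init__(self):
        if self.absolute_linker_length < 0:
            raise ValueError(
                f"family {self.family_id!r}: relative linker length "
                f"{self.relative_linker_length} gives a negative absolute length "
                f"({REFERENCE_LINKER_LENGTH} + {self.relative_linker_length} < 0)")
        if self.pde_active and not self.has_eal:
            raise ValueError(f"family {self.family_id!r}: pde_active requires has_eal")
        if self.n_members < 1:
            raise ValueError(f"family {self.family_id!r}: n_members must be >= 1")
        if not (0.0 <= self.within_divergence < 1.0):
            raise ValueError(f"family {self.family_id!r}: within_divergence must be in [0, 1)")

    @property
    def absolute_linker_length(self) -> int:
        return REFERENCE_LINKER_LENGTH + self.relative_linker_length


@dataclass
class ScaffoldTemplate:
    """Family template: block strings, motif offsets and the immutable mask."""

    spec: FamilySpec
    blocks: dict            # block name -> residue string, in domain order
    block_order: tuple
    motif_offsets: dict     # motif name -> absolute 0-based offset
    immutable_mask: np.ndarray  # bool per residue of the concatenation
    anchor_index: int       # 0-based index of the PHY anchor residue
    dxlt_index: int         # 0-based index of the D of DXLT
    inhibiting_phase: int   # planted top register phase (DXLT-framed)
    stimulating_phase: int  # planted runner-up phase
    overwind_breakpoint: Optional[int]  # linker index, −4 families only

    @property
    def sequence(self) -> str:
        return "".join(self.blocks[b] for b in self.block_order)


def _draw(rng: np.random.Generator, alphabet: str, n: int) -> str:
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), size=n))


def _linker_hydrophobic_positions(L: int, rel: int) -> tuple[set, int]:
    """Planted a/d hydrophobic indices and the designed frame breakpoint.

    The C-terminal part of the linker is laid in the DXLT-anchored frame of
    phase 0 (a-positions at indices ≡ L mod 7).  Families whose relative
    length is not a multiple of seven carry an N-terminal part in a shifted
    frame: the ancestral frame displaced by ``rel mod 7``, with the frame
    switch at index 10 for −4 linkers (the overwound stretch) and at the
    linker midpoint otherwise.
    """
    if rel % 7 == 0:
        b = 0
    elif rel == -4:
        b = 10
    else:
        b = L // 2
    shift = rel % 7
    positions = set()
    for i in range(L):
        slot = (i - L + shift) % 7 if i < b else (i - L) % 7
        if slot in (0, 3):
            positions.add(i)
    return positions, b


def _occupancy_scores(L: int, hydro: set, breakpoint: int) -> list[float]:
    """Per-phase a/d occupancy of the planted hydrophobics; positions before
    ``breakpoint`` are slotted in the +4-shifted (overwound) frame."""
    scores = []
    for p in range(_N_PHASES):
        slots = occ = 0
        for i in range(L):
            eff = p + 4 if i < breakpoint else p
            if (i - L - eff) % _N_PHASES in (0, 3):
                slots += 1
                if i in hydro:
                    occ += 1
        scores.append(occ / slots if slots else 0.0)
    return scores


def _planted_phases(L: int, rel: int, hydro: set) -> tuple[int, int, int]:
    """Generator-side register truth: (inhibiting, stimulating, breakpoint).

    For −4 linkers the recoverable breakpoint is the canonical representative
    of the designed frame switch: the smallest breakpoint maximising the best
    per-phase occupancy (breakpoints between two heptad slots are scoring-
    equivalent, so the physical switch position is only identifiable up to
    that interval).  Other families use the plain DXLT frame (breakpoint 0).
    """
    if rel == -4:
        best_b, best_scores, best_top = 0, None, -1.0
        for b in range(0, L - 10 + 1):
            scores = _occupancy_scores(L, hydro, b)
            if max(scores) > best_top:
                best_b, best_scores, best_top = b, scores, max(scores)
        scores, breakpoint = best_scores, best_b
    else:
        scores, breakpoint = _occupancy_scores(L, hydro, 0), 0
    order = sorted(range(_N_PHASES), key=lambda p: (-scores[p], p))
    return order[0], order[1], breakpoint


def _scrub(seq_arr: np.ndarray, mask: np.ndarray, rng: np.random.Generator) -> None:
    """Redraw mutable residues wherever a chance motif match arises.

    Guarantees that an undiverged template contains no motif occurrences
    beyond the planted ones (point mutations applied later can still create
    chance matches; the classifier's order chain tolerates those).
    """
    import re
    union = re.compile("|".join(_SCRUB_PATTERNS))
    for _ in range(100):
        seq = "".join(seq_arr)
        dirty = False
        for m in union.finditer(seq):
            span = np.arange(m.start(), m.end())
            mutable = span[~mask[span]]
            if mutable.size == 0:
                continue  # fully planted occurrence
            dirty = True
            for i in mutable:
                seq_arr[i] = AMINO_ACIDS[rng.integers(0, len(AMINO_ACIDS))]
        if not dirty:
            return
    raise RuntimeError("motif scrubbing did not converge")


def build_template(spec: FamilySpec, rng_seed: int,
                   block_lengths: Optional[dict] = None) -> ScaffoldTemplate:
    """Draw a family scaffold with all essential motifs planted in order."""
    bl = dict(DEFAULT_BLOCK_LENGTHS)
    if block_lengths:
        bl.update(block_lengths)
    rng = np.random.default_rng(rng_seed)
    L = spec.absolute_linker_length

    nts = list(_draw(rng, AMINO_ACIDS, bl["nts"]))
    nts[16] = "C"  # chromophore-binding cysteine (C17 in 1-based numbering)
    pas_gaf = list(_draw(rng, AMINO_ACIDS, bl["pas_gaf"]))
    pas_gaf[150:153] = "DIP"
    phy = list(_draw(rng, AMINO_ACIDS, bl["phy"]))
    phy[60:65] = "PRLSF"
    phy[-1] = "I"  # terminal PHY-helix hydrophobic anchor

    hydro, breakpoint = _linker_hydrophobic_positions(L, spec.relative_linker_length)
    linker = [
        LINKER_HYDROPHOBICS[rng.integers(0, len(LINKER_HYDROPHOBICS))]
        if i in hydro else LINKER_POLAR[rng.integers(0, len(LINKER_POLAR))]
        for i in range(L)
    ]

    ggdef = list(_draw(rng, AMINO_ACIDS, bl["ggdef"]))
    ggdef[0:4] = "D" + AMINO_ACIDS[rng.integers(0, len(AMINO_ACIDS))] + "LT"
    ggdef[-5:] = "GGDEF"

    block_order = ["nts", "pas_gaf", "phy", "linker", "ggdef"]
    blocks = {"nts": nts, "pas_gaf": pas_gaf, "phy": phy, "linker": linker,
              "ggdef": ggdef}
    if spec.has_eal:
        eal_linker = list(_draw(rng, AMINO_ACIDS, bl["eal_linker"]))
        eal = list(_draw(rng, AMINO_ACIDS, bl["eal"]))
        exl = "AILV"[rng.integers(0, 4)]
        eal[0:3] = "E" + exl + ("L" if spec.pde_active else "F")
        eal[100:106] = "DDFGTG" if spec.pde_active else "DGFDTG"  # scrambled loop
        blocks["eal_linker"] = eal_linker
        blocks["eal"] = eal
        block_order += ["eal_linker", "eal"]

    # absolute offsets
    offs, pos = {}, 0
    for name in block_order:
        offs[name] = pos
        pos += len(blocks[name])
    total = pos
    anchor_index = offs["phy"] + bl["phy"] - 1
    dxlt_index = offs["ggdef"]

    motif_offsets = {
        "NTS_CYS": 16,
        "DIP": offs["pas_gaf"] + 150,
        "PRXSF": offs["phy"] + 60,
        "DXLT": dxlt_index,
        "GGDEF": offs["ggdef"] + bl["ggdef"] - 5,
    }
    mask = np.zeros(total, dtype=bool)
    mask[16] = True
    mask[motif_offsets["DIP"]:motif_offsets["DIP"] + 3] = True
    mask[motif_offsets["PRXSF"]:motif_offsets["PRXSF"] + 5] = True
    mask[anchor_index] = True
    mask[offs["linker"]:offs["linker"] + L] = True  # linker frozen by default
    mask[dxlt_index:dxlt_index + 4] = True
    mask[motif_offsets["GGDEF"]:motif_offsets["GGDEF"] + 5] = True
    if spec.has_eal:
        motif_offsets["EAL"] = offs["eal"]
        motif_offsets["DDFGTG"] = offs["eal"] + 100
        mask[offs["eal"]:offs["eal"] + 3] = True
        mask[offs["eal"] + 100:offs["eal"] + 106] = True

    seq_arr = np.array(list("".join("".join(b) for b in
                                    ("".join(blocks[n]) for n in block_order))))
    _scrub(seq_arr, mask, rng)
    # write scrubbed residues back into the blocks
    flat = "".join(seq_arr)
    for name in block_order:
        blocks[name] = flat[offs[name]:offs[name] + len(blocks[name])]

    inhib, stim, canon_b = _planted_phases(L, spec.relative_linker_length, hydro)
    return ScaffoldTemplate(
        spec=spec, blocks=blocks, block_order=tuple(block_order),
        motif_offsets=motif_offsets, immutable_mask=mask,
        anchor_index=anchor_index, dxlt_index=dxlt_index,
        inhibiting_phase=inhib, stimulating_phase=stim,
        overwind_breakpoint=canon_b if spec.relative_linker_length == -4 else None,
    )


def mutate_sequence(template: ScaffoldTemplate, rate: float,
                    rng_seed: Optional[int] = None,
                    rng: Optional[np.random.Generator] = None) -> str:
    """Point-substitute mutable positions at probability ``rate`` per site.

    Substitutions draw uniformly from the 19 alternative residues; masked
    (motif, anchor, linker) positions are never touched.  Deterministic for a
    fixed seed.
    """
    if not (0.0 <= rate < 1.0):
        raise ValueError("rate must be in [0, 1)")
    if rng is None:
        rng = np.random.default_rng(rng_seed)
    seq = np.array(list(template.sequence))
    mutable = ~template.immutable_mask
    hit = mutable & (rng.random(seq.size) < rate)
    idx = np.flatnonzero(hit)
    for i in idx:
        choices = AMINO_ACIDS.replace(seq[i], "")
        seq[i] = choices[rng.integers(0, len(choices))]
    return "".join(seq)


@dataclass
class SimulatedDataset:
    """Unaligned sequences, the true alignment and the ground-truth table."""

    sequences: dict          # id -> unaligned residue string (insertion order)
    alignment: dict          # id -> aligned row (shared column layout)
    truth: pd.DataFrame
    reference_id: str
    reference_anchor_1based: int
    templates: dict          # family_id -> ScaffoldTemplate

    def write_fasta(self, path) -> None:
        _write_fasta(path, self.sequences)

    def write_alignment(self, path) -> None:
        _write_fasta(path, self.alignment)

    def write_truth(self, path) -> None:
        self.truth.to_csv(path, sep="\t", index=False)


def _write_fasta(path, seqs: dict) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")


def generate_dataset(specs: Sequence[FamilySpec], global_seed: int,
                     block_lengths: Optional[dict] = None) -> SimulatedDataset:
    """Simulate all families and assemble FASTA, true MSA and truth table.

    Reproducible bit-for-bit for fixed ``(specs, global_seed)``: each family
    and each member draws from its own spawned random substream.
    """
    ids = [s.family_id for s in specs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate family_ids")
    bl = dict(DEFAULT_BLOCK_LENGTHS)
    if block_lengths:
        bl.update(block_lengths)
    any_eal = any(s.has_eal for s in specs)
    max_L = max(s.absolute_linker_length for s in specs)

    ss = np.random.SeedSequence(global_seed)
    family_streams = ss.spawn(len(specs))

    sequences: dict[str, str] = {}
    rows: dict[str, str] = {}
    templates: dict[str, ScaffoldTemplate] = {}
    records = []
    for spec, stream in zip(specs, family_streams):
        tpl_stream, *member_streams = stream.spawn(spec.n_members + 1)
        template = build_template(
            spec, rng_seed=int(tpl_stream.generate_state(1)[0] % (2 ** 31)),
            block_lengths=bl)
        templates[spec.family_id] = template
        L = spec.absolute_linker_length
        for k, mstream in enumerate(member_streams):
            sid = f"{spec.family_id}_{k:02d}"
            if sid in sequences:
                raise ValueError(f"duplicate sequence id {sid}")
            seq = mutate_sequence(template, spec.within_divergence,
                                  rng=np.random.default_rng(mstream))
            sequences[sid] = seq
            rows[sid] = _aligned_row(seq, template, spec, bl, max_L, any_eal)
            records.append({
                "sequence_id": sid,
                "family": spec.family_id,
                "class": "PadC-EAL" if spec.has_eal else "PadC",
                "rel_linker_len": spec.relative_linker_length,
                "abs_linker_len": L,
                "anchor_idx": template.anchor_index,
                "dxlt_idx": template.dxlt_index,
                "pde_active": spec.pde_active if spec.has_eal else "",
                "inhibiting_phase": template.inhibiting_phase,
                "stimulating_phase": template.stimulating_phase,
                "overwind_breakpoint": (template.overwind_breakpoint
                                        if template.overwind_breakpoint is not None else ""),
                "taxonomy_class": spec.taxonomy_class,
            })
    truth = pd.DataFrame(records)
    ref_id = truth["sequence_id"].iloc[0]
    ref_anchor_1b = int(truth["anchor_idx"].iloc[0]) + 1
    return SimulatedDataset(sequences=sequences, alignment=rows, truth=truth,
                            reference_id=ref_id,
                            reference_anchor_1based=ref_anchor_1b,
                            templates=templates)


def _aligned_row(seq: str, template: ScaffoldTemplate, spec: FamilySpec,
                 bl: dict, max_L: int, any_eal: bool) -> str:
    """Lay the sequence into the shared column frame.

    Linker columns are right-aligned against the DXLT turn (the structurally
    conserved end), padded with gaps toward the PHY side; EAL-less homologs
    get a gap block across the EAL-linker and EAL columns.
    """
    L = spec.absolute_linker_length
    pre = bl["nts"] + bl["pas_gaf"] + bl["phy"]
    parts = [seq[:pre], "-" * (max_L - L), seq[pre:pre + L], seq[pre + L:pre + L + bl["ggdef"]]]
    tail = seq[pre + L + bl["ggdef"]:]
    if spec.has_eal:
        parts.append(tail)
    elif any_eal:
        parts.append("-" * (bl["eal_linker"] + bl["eal"]))
    return "".join(parts)


# ---------------------------------------------------------------------------
# configuration

_DEMO_TAXONOMY = {
    -7: "Gammaproteobacteria", -4: "Actinobacteria", 0: "Gammaproteobacteria",
    2: "Gammaproteobacteria", 7: "Gammaproteobacteria", 14: "Alphaproteobacteria",
}


def default_demo_specs(n_members: int = 10,
                       within_divergence: float = 0.15) -> list[FamilySpec]:
    """Six families mirroring the naturally observed linker-length classes.

    Relative lengths {−7, −4, 0, +2, +7, +14}; the −7 family is a PadC-EAL
    with a degenerate (EAF) phosphodiesterase motif, all others are plain
    PadCs.  The 0 family stands in for the 28-residue reference homolog and
    the +7 family for the prototypical light-switchable homolog.
    """
    out = []
    for rel in (-7, -4, 0, 2, 7, 14):
        out.append(FamilySpec(
            family_id=f"fam{'m' if rel < 0 else 'p'}{abs(rel)}",
            relative_linker_length=rel,
            has_eal=(rel == -7),
            pde_active=False,
            n_members=n_members,
            within_divergence=within_divergence,
            taxonomy_class=_DEMO_TAXONOMY[rel],
        ))
    return out


def load_family_config(path) -> tuple[list[FamilySpec], int]:
    """Read a YAML family configuration: list of families plus a seed."""
    cfg = yaml.safe_load(Path(path).read_text())
    specs = [FamilySpec(**fam) for fam in cfg["families"]]
    return specs, int(cfg.get("seed", 0))


def dump_family_config(specs: Sequence[FamilySpec], seed: int, path) -> None:
    cfg = {"seed": seed, "families": [
        {"family_id": s.family_id,
         "relative_linker_length": s.relative_linker_length,
         "has_eal": s.has_eal, "pde_active": s.pde_active,
         "n_members": s.n_members, "within_divergence": s.within_divergence,
         "taxonomy_class": s.taxonomy_class}
        for s in specs]}
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=False))


def eal_loss_scenario(global_seed: int, n_members: int = 4,
                      within_divergence: float = 0.15) -> SimulatedDataset:
    """Scenario emulating PadC(−4) emergence through loss of the EAL domain.

    Three families — PadCs with a −4 linker, PadC-EALs with a −4 linker and a
    reference-length PadC control — plus one chimeric lone PadC-EAL(−4)
    whose photosensory module shares ancestry with the PadC(−4) family while
    its EAL module shares ancestry with the PadC-EAL(−4) family.  A tree
    built from the full alignment should place the chimera inside the
    PadC(−4) clade with maximal support, mirroring the signature expected
    when PadCs(−4) arose from PadC-EALs(−4) by domain loss.
    """
    wd = within_divergence
    specs = [
        FamilySpec("padc_m4", -4, n_members=n_members, within_divergence=wd,
                   taxonomy_class="Actinobacteria"),
        FamilySpec("padc_eal_m4", -4, has_eal=True, pde_active=True,
                   n_members=n_members, within_divergence=wd,
                   taxonomy_class="Actinobacteria"),
        FamilySpec("padc_p0", 0, n_members=n_members, within_divergence=wd,
                   taxonomy_class="Gammaproteobacteria"),
    ]
    ds = generate_dataset(specs, global_seed)
    stream = np.random.SeedSequence(global_seed).spawn(len(specs) + 1)[-1]
    rng = np.random.default_rng(stream)
    tpl_sensor = ds.templates["padc_m4"]
    tpl_eal = ds.templates["padc_eal_m4"]
    bl = DEFAULT_BLOCK_LENGTHS
    sensor_seq = mutate_sequence(tpl_sensor, wd, rng=rng)
    eal_suffix = mutate_sequence(tpl_eal, wd, rng=rng)[-(bl["eal_linker"] + bl["eal"]):]
    kx_seq = sensor_seq + eal_suffix
    sid = "kx_eal_m4_00"
    max_L = max(s.absolute_linker_length for s in specs)
    pre = bl["nts"] + bl["pas_gaf"] + bl["phy"]
    L = tpl_sensor.spec.absolute_linker_length
    ds.sequences[sid] = kx_seq
    ds.alignment[sid] = kx_seq[:pre] + "-" * (max_L - L) + kx_seq[pre:]
    row = {
        "sequence_id": sid, "family": "kx_eal_m4", "class": "PadC-EAL",
        "rel_linker_len": -4, "abs_linker_len": L,
        "anchor_idx": tpl_sensor.anchor_index, "dxlt_idx": tpl_sensor.dxlt_index,
        "pde_active": True, "inhibiting_phase": tpl_sensor.inhibiting_phase,
        "stimulating_phase": tpl_sensor.stimulating_phase,
        "overwind_breakpoint": tpl_sensor.overwind_breakpoint,
        "taxonomy_class": "Actinobacteria",
    }
    ds.truth = pd.concat([ds.truth, pd.DataFrame([row])], ignore_index=True)
    return ds
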