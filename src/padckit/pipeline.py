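"""End-to-end orchestration: FASTA → classification → linker metrics →
register calls → similarity network → jackknife consensus tree → summary
tables.

Every input sequence appears exactly once in the annotation table; per-
sequence failures (gap at the anchor column, missing DXLT) become explicit
status rows rather than silent drops, so prevalence denominators are always
explicit.  Outputs are deterministic for a fixed configuration and seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import linker as linker_mod
from . import phylo, seqio, ssn as ssn_mod
from .motifs import CLASS_PADC, CLASS_PADC_EAL, classify_family, default_motif_set
from .registers import DEFAULT_STABILISERS, call_registers

STATUS_OK = "ok"


@dataclass
class PipelineConfig:
    """Inputs, thresholds and seeds for a full run."""

    fasta: str
    msa: str
    reference_id: str
    reference_anchor: int            # 1-based residue number in the reference
    outdir: str = "padckit_out"
    msa_format: str = "fasta"        # or "phylip-relaxed"
    threshold_bits: float = ssn_mod.DEFAULT_THRESHOLD_BITS
    n_replicates: int = 1000
    seed: int = 0
    nts_window: int = 30
    stabilisers: str = "".join(sorted(DEFAULT_STABILISERS))
    reference_linker_length: int = 28
    outgroup: Optional[str] = None
    taxonomy: dict = field(default_factory=dict)  # sequence_id -> class label

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        cfg = yaml.safe_load(Path(path).read_text())
        return cls(**cfg)

    def validate(self) -> None:
        for name in ("fasta", "msa", "reference_id"):
            if not getattr(self, name):
                raise ValueError(f"configuration error: {name!r} must be set")
        if self.reference_anchor < 1:
            raise ValueError("configuration error: reference_anchor is 1-based "
                             "and must be >= 1")


@dataclass
class PipelineResult:
    annotations: pd.DataFrame
    prevalence: pd.DataFrame
    graph: object
    components: dict
    pair_scores: list
    consensus: object       # phylo.ConsensusResult
    output_dir: Optional[Path]


def annotate_sequences(sequences: dict, alignment: dict,
                       anchor: linker_mod.AnchorSpec,
                       nts_window: int = 30,
                       stabilisers=DEFAULT_STABILISERS,
                       reference_linker_length: int = 28,
                       taxonomy: Optional[dict] = None) -> pd.DataFrame:
    """Per-sequence annotation table (classification, linker, registers).

    One row per input sequence; the ``status`` column is ``ok`` or an error
    description for sequences whose anchor or effector start could not be
    located.
    """
    motifs = default_motif_set(nts_window=nts_window)
    if anchor.reference_sequence_id not in alignment:
        raise ValueError(f"reference {anchor.reference_sequence_id!r} not in MSA")
    ref_row = alignment[anchor.reference_sequence_id]
    taxonomy = taxonomy or {}
    rows = []
    for sid, seq in sequences.items():
        row = {"sequence_id": sid, "status": STATUS_OK, "class": "",
               "pde_active": "", "anchor_1based": "", "dxlt_1based": "",
               "abs_linker_len": "", "rel_linker_len": "", "linker_family": "",
               "eal_linker_len": "", "phase_scores": "", "inhibiting_phase": "",
               "stimulating_phase": "", "overwind_breakpoint": "",
               "regulatory_class": "",
               "taxonomy_class": taxonomy.get(sid, "")}
        call = classify_family(seq, motifs)
        row["class"] = call.class_call
        row["pde_active"] = "" if call.pde_active is None else call.pde_active
        try:
            if sid not in alignment:
                raise linker_mod.AnchorNotAlignable(
                    f"sequence {sid}: not present in the MSA")
            a_idx = linker_mod.locate_phy_anchor(alignment[sid], ref_row,
                                                 anchor, query_id=sid)
            ann = linker_mod.compute_linker(
                seq, a_idx, motifs, sequence_id=sid,
                reference_length=reference_linker_length)
            if call.class_call == CLASS_PADC_EAL:
                row["eal_linker_len"] = linker_mod.eal_linker_length(seq, call, motifs)
            reg = call_registers(linker_mod.extract_linker_sequence(seq, ann),
                                 ann.relative_length, sequence_id=sid,
                                 stabilisers=stabilisers)
            row.update({
                "anchor_1based": ann.anchor_index + 1,
                "dxlt_1based": ann.dxlt_index + 1,
                "abs_linker_len": ann.absolute_length,
                "rel_linker_len": ann.relative_length,
                "linker_family": ann.linker_family,
                "phase_scores": ",".join(f"{s:.4f}" for s in reg.phase_scores),
                "inhibiting_phase": reg.inhibiting_phase,
                "stimulating_phase": reg.stimulating_phase,
                "overwind_breakpoint": ("" if reg.overwind_breakpoint is None
                                        else reg.overwind_breakpoint),
                "regulatory_class": reg.regulatory_class,
            })
        except (linker_mod.AnchorNotAlignable,
                linker_mod.EffectorStartNotFound, ValueError) as exc:
            row["status"] = str(exc)
        rows.append(row)
    return pd.DataFrame(rows)


def prevalence_table(annotations: pd.DataFrame) -> pd.DataFrame:
    """Relative-linker-length prevalence split by class, plus a combined split.

    Fractions sum to one within each split; only rows with a measured linker
    enter the denominators.
    """
    ok = annotations[(annotations["status"] == STATUS_OK)
                     & (annotations["rel_linker_len"] != "")]
    rows = []
    groups = [(c, ok[ok["class"] == c]) for c in (CLASS_PADC, CLASS_PADC_EAL)]
    groups.append(("combined", ok))
    for cls, sub in groups:
        if sub.empty:
            continue
        counts = sub["rel_linker_len"].astype(int).value_counts().sort_index()
        total = int(counts.sum())
        for rel, cnt in counts.items():
            rows.append({"class": cls, "relative_length": int(rel),
                         "count": int(cnt), "fraction": cnt / total})
    return pd.DataFrame(rows)


def div7_fraction(prevalence: pd.DataFrame, cls: str = CLASS_PADC) -> float:
    """Fraction of a class whose relative linker length is ≡ 0 (mod 7)."""
    sub = prevalence[prevalence["class"] == cls]
    if sub.empty:
        raise ValueError(f"no prevalence rows for class {cls!r}")
    mask = (sub["relative_length"] % 7) == 0
    return float(sub.loc[mask, "fraction"].sum())


def linker_family_fraction(prevalence: pd.DataFrame, family: str,
                           cls: str = CLASS_PADC) -> float:
    """Fraction of a class falling in one linker family bin."""
    sub = prevalence[prevalence["class"] == cls]
    if sub.empty:
        raise ValueError(f"no prevalence rows for class {cls!r}")
    fams = sub["relative_length"].map(linker_mod.bin_linker_family)
    return float(sub.loc[(fams == family).values, "fraction"].sum())


def run_pipeline(config: PipelineConfig, write: bool = True) -> PipelineResult:
    """Run all stages and (optionally) write the output bundle to disk."""
    config.validate()
    sequences = seqio.read_fasta(config.fasta)
    alignment = seqio.read_alignment(config.msa, config.msa_format)
    anchor = linker_mod.AnchorSpec(config.reference_id, config.reference_anchor)

    annotations = annotate_sequences(
        sequences, alignment, anchor, nts_window=config.nts_window,
        stabilisers=frozenset(config.stabilisers),
        reference_linker_length=config.reference_linker_length,
        taxonomy=config.taxonomy)
    prevalence = prevalence_table(annotations)

    pair_scores = ssn_mod.all_vs_all(sequences)
    node_attrs = {
        r["sequence_id"]: {
            "linker_family": str(r["linker_family"]),
            "relative_length": (int(r["rel_linker_len"])
                                if r["rel_linker_len"] != "" else -999),
            "class_call": str(r["class"]),
            "taxonomy_class": str(r["taxonomy_class"]),
        } for _, r in annotations.iterrows()}
    graph = ssn_mod.build_ssn(pair_scores, node_attrs,
                              threshold=config.threshold_bits)
    comp = ssn_mod.components(graph)

    cons = phylo.jackknife_consensus(
        alignment, phylo.JackknifeConfig(n_replicates=config.n_replicates,
                                         seed=config.seed))
    tree = cons.tree
    if config.outgroup:
        tree = phylo.root_tree(tree, config.outgroup)

    outdir = None
    if write:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        annotations.to_csv(outdir / "annotations.tsv", sep="\t", index=False)
        prevalence.to_csv(outdir / "prevalence.tsv", sep="\t", index=False)
        ssn_mod.write_edge_tsv(pair_scores, outdir / "ssn_edges.tsv")
        ssn_mod.write_graphml(graph, outdir / "ssn.graphml")
        tree.write(path=str(outdir / "consensus.nwk"), schema="newick",
                   suppress_rooting=True, unquoted_underscores=True)
        log = dataclasses.asdict(config)
        log["n_sequences"] = len(sequences)
        log["n_components"] = len(set(comp.values()))
        (outdir / "run_log.json").write_text(json.dumps(log, indent=2, default=str))
    return PipelineResult(annotations=annotations, prevalence=prevalence,
                          graph=graph, components=comp,
                          pair_scores=pair_scores, consensus=cons,
                          output_dir=outdir)
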