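"""Classification of C4-/CAM-specific gene copies.

Combines two lines of evidence, mirroring how photosynthesis-recruited PEPC
copies are identified in CO2-concentrating-mechanism (CCM) studies:

* diel/stress expression phasing -- C4-like copies are day-phased under
  control conditions and downregulated under stress, CAM-like copies are
  strongly induced at night under stress (drought and/or heat);
* diagnostic residues read at reference-numbered alignment positions
  (maize PEPC numbering): serine at position 780 marks a
  photosynthesis-functional enzyme while the ancestral non-photosynthetic
  form carries alanine; positions 890 (inhibitor affinity: R tight-binding
  vs M/G low-affinity) and 519 (malate sensitivity) are recorded as
  supporting evidence only.

A copy is called C4-specific (resp. CAM-specific) when it is
residue-functional AND C4-like (resp. CAM-like) in expression.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome_io import ExpressionMatrix

__all__ = [
    "DielClass",
    "ResidueDiagnostics",
    "DEFAULT_POSITIONS",
    "MAIZE_PEPC_REFERENCE",
    "filter_expressed",
    "phase_genes",
    "map_reference_positions",
    "diagnose_residues",
    "classify_ccm",
]

#: Maize PEPC reference protein whose numbering anchors the diagnostics.
MAIZE_PEPC_REFERENCE = "Zm00001d046170"

DEFAULT_POSITIONS = (519, 780, 890)

STRESS_CONDITIONS = ("D", "H", "DH")

FUNCTIONAL = "functional-C4/CAM-type"
NON_PHOTOSYNTHETIC = "non-photosynthetic-type"
AMBIGUOUS = "ambiguous"


@dataclass
class DielClass:
    """Expression-phasing label for one gene with the fold changes used."""

    gene_id: str
    label: str  # "C4-like" | "CAM-like" | "none"
    evidence: dict[str, float] = field(default_factory=dict)


@dataclass
class ResidueDiagnostics:
    """Residues at reference-numbered positions and the per-gene call."""

    reference_id: str
    positions: list[int]
    residues: dict[str, dict[int, str]]  # gene -> position -> aa or '-'
    calls: dict[str, str]  # gene -> FUNCTIONAL | NON_PHOTOSYNTHETIC | AMBIGUOUS


def filter_expressed(
    expr: ExpressionMatrix, tpm_min: float = 1.0, min_reps: int = 2
) -> set[str]:
    """Genes with TPM > tpm_min in >= min_reps replicates of some condition.

    This is the standard expressed-gene filter (TPM > 1 in at least 2
    biological replicates from at least one condition).
    """
    keep: set[str] = set()
    groups = sorted({(s.condition, s.time) for s in expr.samples})
    ok = np.zeros(len(expr.gene_ids), dtype=bool)
    for cond, time in groups:
        cols = expr.columns(cond, time)
        ok |= (cols > tpm_min).sum(axis=1) >= min_reps
    for i, g in enumerate(expr.gene_ids):
        if ok[i]:
            keep.add(g)
    return keep


def phase_genes(
    expr: ExpressionMatrix,
    day_fold: float = 4.0,
    stress_fold: float = 4.0,
    cam_induction_fold: float = 10.0,
    min_tpm: float = 1.0,
    pseudocount: float = 0.1,
) -> dict[str, DielClass]:
    """Assign C4-like / CAM-like / none diel classes from group-mean TPMs.

    C4-like: day-phased under control (CK day >= day_fold x CK night), with
    CK day >= min_tpm, and downregulated by at least stress_fold under some
    stress condition during the day. CAM-like: night expression under some
    stress condition >= cam_induction_fold x CK night, >= day_fold x that
    stress's day mean, and >= min_tpm. The pseudocount stabilises ratios of
    small means. When both rules fire, the CAM call wins (stress-night
    induction is the discriminating CAM signature).
    """
    conds = expr.conditions()
    if "CK" not in conds:
        raise ValueError("expression matrix lacks the CK (control) condition")
    stresses = [c for c in STRESS_CONDITIONS if c in conds]
    if not stresses:
        raise ValueError("expression matrix lacks any stress condition (D/H/DH)")

    ck_day = expr.group_mean("CK", "day")
    ck_night = expr.group_mean("CK", "night")
    stress_day = {c: expr.group_mean(c, "day") for c in stresses}
    stress_night = {c: expr.group_mean(c, "night") for c in stresses}

    out: dict[str, DielClass] = {}
    for i, gene in enumerate(expr.gene_ids):
        evidence: dict[str, float] = {}
        day_ratio = ck_day[i] / (ck_night[i] + pseudocount)
        evidence["CK_day/CK_night"] = float(day_ratio)
        c4 = False
        if day_ratio >= day_fold and ck_day[i] >= min_tpm:
            for c in stresses:
                downreg = ck_day[i] / (stress_day[c][i] + pseudocount)
                evidence[f"CK_day/{c}_day"] = float(downreg)
                if downreg >= stress_fold:
                    c4 = True
        cam = False
        for c in stresses:
            induction = stress_night[c][i] / (ck_night[i] + pseudocount)
            night_vs_day = stress_night[c][i] / (stress_day[c][i] + pseudocount)
            evidence[f"{c}_night/CK_night"] = float(induction)
            evidence[f"{c}_night/{c}_day"] = float(night_vs_day)
            if (
                induction >= cam_induction_fold
                and night_vs_day >= day_fold
                and stress_night[c][i] >= min_tpm
            ):
                cam = True
        label = "CAM-like" if cam else ("C4-like" if c4 else "none")
        out[gene] = DielClass(gene_id=gene, label=label, evidence=evidence)
    return out


def map_reference_positions(
    family_alignment: dict[str, str], reference_id: str
) -> dict[int, int]:
    """Map 1-based ungapped reference positions to 0-based alignment columns."""
    if reference_id not in family_alignment:
        raise KeyError(f"reference {reference_id} absent from alignment")
    mapping: dict[int, int] = {}
    pos = 0
    for col, aa in enumerate(family_alignment[reference_id]):
        if aa != "-":
            pos += 1
            mapping[pos] = col
    return mapping


def diagnose_residues(
    family_alignment: dict[str, str],
    reference_id: str,
    positions: tuple[int, ...] = DEFAULT_POSITIONS,
) -> ResidueDiagnostics:
    """Record residues at reference-numbered positions and call each gene.

    The call is driven by position 780 alone: S -> functional C4/CAM type,
    A -> non-photosynthetic type, anything else (including a gap) ->
    ambiguous. Other positions are annotation only, since the S780 rule is
    known to admit exceptions.
    """
    mapping = map_reference_positions(family_alignment, reference_id)
    for p in positions:
        if p not in mapping:
            raise KeyError(
                f"position {p} is beyond the ungapped reference length "
                f"({max(mapping)})"
            )
    aln_len = len(family_alignment[reference_id])
    residues: dict[str, dict[int, str]] = {}
    calls: dict[str, str] = {}
    for gene, row in family_alignment.items():
        if len(row) != aln_len:
            raise ValueError(f"aligned row {gene} has inconsistent length")
        res = {p: row[mapping[p]] for p in sorted(positions)}
        residues[gene] = res
        site780 = res.get(780, "-")
        if site780 == "S":
            calls[gene] = FUNCTIONAL
        elif site780 == "A":
            calls[gene] = NON_PHOTOSYNTHETIC
        else:
            calls[gene] = AMBIGUOUS
    return ResidueDiagnostics(
        reference_id=reference_id,
        positions=sorted(positions),
        residues=residues,
        calls=calls,
    )


def classify_ccm(
    diag: ResidueDiagnostics, phases: dict[str, DielClass]
) -> dict[str, str]:
    """Final per-gene call: C4-specific, CAM-specific, or other.

    C4-specific requires a functional residue call AND C4-like phasing;
    CAM-specific requires a functional call AND CAM-like phasing. The
    reference row itself is skipped.
    """
    out: dict[str, str] = {}
    for gene, residue_call in diag.calls.items():
        if gene == diag.reference_id:
            continue
        phase = phases.get(gene)
        if phase is None:
            raise KeyError(f"no diel class for {gene}")
        if residue_call == FUNCTIONAL and phase.label == "C4-like":
            out[gene] = "C4-specific"
        elif residue_call == FUNCTIONAL and phase.label == "CAM-like":
            out[gene] = "CAM-specific"
        else:
            out[gene] = "other"
    return out
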