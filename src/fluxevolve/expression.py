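"""Mapping transcript expression and differential expression onto reactions.

Transcript-level TPM tables (one per fermentation timepoint) and differential
expression tables (log2 fold change + q-value per timepoint comparison) are
lifted to the reaction level through each reaction's association tree:
isoenzymes (OR) sum, complex subunits (AND) take the minimum.  Reactions whose
reaction-level expression falls below a TPM cutoff are switched off (both flux
bounds zeroed).  Reaction-level differential-expression calls drive the
eligibility of reactions for the evolutionary algorithm's mutation operator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Mapping

import pandas as pd

from .gpr import Association, evaluate_association
from .model import MetabolicModel

__all__ = [
    "ExpressionProfile",
    "DifferentialExpression",
    "ReactionDifferential",
    "reaction_expression",
    "apply_expression_switch",
    "reaction_differential",
    "eligible_reactions",
    "read_expression_tsv",
    "read_de_tsv",
]

TPM_CUTOFF = 1.0          # strict '<': reactions at exactly the cutoff stay on
Q_THRESHOLD = 0.01
LOG2FC_THRESHOLD = 0.7    # reaction-level significance call
FOLD_THRESHOLD = 2.0      # eligibility for the mutation operator
PSEUDOCOUNT = 0.5         # TPM added to both sides of the reaction-level ratio


@dataclass
class ExpressionProfile:
    """TPM per transcript at one timepoint."""

    timepoint: str
    tpm: dict[str, float]

    def __post_init__(self) -> None:
        bad = {t: v for t, v in self.tpm.items() if v < 0}
        if bad:
            raise ValueError(f"negative TPM values: {bad}")


@dataclass
class DifferentialExpression:
    """Transcript-level log2FC and q-value for one ordered timepoint comparison."""

    comparison: tuple[str, str]
    records: dict[str, tuple[float, float]]  # transcript -> (log2fc, q)

    def __post_init__(self) -> None:
        if self.comparison[0] == self.comparison[1]:
            raise ValueError("comparison endpoints must differ")
        for t, (_, q) in self.records.items():
            if not 0.0 <= q <= 1.0:
                raise ValueError(f"q-value out of [0,1] for {t}: {q}")


@dataclass
class ReactionDifferential:
    """Reaction-level differential-expression call for one comparison."""

    log2fc: float
    significant: bool
    reason: str = ""

    @property
    def fold_change(self) -> float:
        return 2.0 ** abs(self.log2fc)


def reaction_expression(
    association: Association | None, profile: ExpressionProfile
) -> float | None:
    """Reaction-level TPM, or None for reactions without an association."""
    if association is None:
        return None
    return evaluate_association(association, profile.tpm)


def apply_expression_switch(
    model: MetabolicModel, profile: ExpressionProfile, cutoff: float = TPM_CUTOFF
) -> MetabolicModel:
    """Zero the bounds of reactions expressed below ``cutoff`` (strict ``<``).

    Reactions without an association are untouched.  Idempotent.
    """
    new = model.copy()
    for rxn in new.reactions.values():
        level = reaction_expression(rxn.association, profile)
        if level is not None and level < cutoff:
            rxn.lower_bound = 0.0
            rxn.upper_bound = 0.0
    return new


def reaction_differential(
    association: Association | None,
    de: DifferentialExpression,
    profile_early: ExpressionProfile,
    profile_late: ExpressionProfile,
    pseudocount: float = PSEUDOCOUNT,
    log2fc_threshold: float = LOG2FC_THRESHOLD,
    q_threshold: float = Q_THRESHOLD,
) -> ReactionDifferential:
    """Lift differential expression to the reaction level.

    The reaction-level log2FC is the log-ratio of reaction-level TPM at the
    later vs earlier timepoint (pseudocount on both sides).  The call is
    significant iff |log2FC| exceeds the threshold *and* at least one
    associated transcript has q below the q-threshold (transcript q-values are
    combined by minimum).
    """
    if association is None:
        return ReactionDifferential(0.0, False, "no association")
    early = reaction_expression(association, profile_early)
    late = reaction_expression(association, profile_late)
    if early == 0.0 and late == 0.0:
        return ReactionDifferential(0.0, False, "zero expression at both timepoints")
    log2fc = math.log2((late + pseudocount) / (early + pseudocount))
    qs = [de.records[t][1] for t in association.transcripts() if t in de.records]
    min_q = min(qs) if qs else 1.0
    significant = abs(log2fc) > log2fc_threshold and min_q < q_threshold
    reason = "" if significant else "below threshold"
    return ReactionDifferential(log2fc, significant, reason)


Direction = Literal["constrain", "force"]


def eligible_reactions(
    model: MetabolicModel,
    de_first: DifferentialExpression,
    de_second: DifferentialExpression,
    profiles: Mapping[str, ExpressionProfile],
    fold_threshold: float = FOLD_THRESHOLD,
    q_threshold: float = Q_THRESHOLD,
    mode: Literal["union", "intersection"] = "union",
    pseudocount: float = PSEUDOCOUNT,
) -> dict[str, Direction]:
    """Reactions eligible for flux-bound mutation, with intervention kind.

    A differential-expression *event* for a reaction in one comparison is a
    fold change >= ``fold_threshold`` with transcript-level support
    (min q < ``q_threshold``).  Down-regulation maps to "constrain" and
    up-regulation to "force".  With ``mode='union'`` (default) an event in
    either comparison suffices; ``mode='intersection'`` requires an event in
    both.  Conflicting directions across comparisons are resolved in favour of
    the larger |log2FC|; an exact tie makes the reaction ineligible.
    """
    log2_threshold = math.log2(fold_threshold)
    out: dict[str, Direction] = {}
    for rxn in model.reactions.values():
        if rxn.association is None:
            continue
        events: list[float] = []  # signed log2fc of qualifying events
        for de in (de_first, de_second):
            early = profiles[de.comparison[0]]
            late = profiles[de.comparison[1]]
            call = reaction_differential(
                rxn.association,
                de,
                early,
                late,
                pseudocount=pseudocount,
                log2fc_threshold=0.0,  # the inclusive fold test is applied below
                q_threshold=q_threshold,
            )
            if call.significant and abs(call.log2fc) >= log2_threshold:
                events.append(call.log2fc)
        if mode == "intersection" and len(events) < 2:
            continue
        if not events:
            continue
        if len(events) == 2 and events[0] * events[1] < 0:
            if abs(events[0]) == abs(events[1]):
                continue  # tie -> ineligible
            winner = max(events, key=abs)
        else:
            winner = max(events, key=abs)
        out[rxn.id] = "constrain" if winner < 0 else "force"
    return out


# ---------------------------------------------------------------------------
# Tabular I/O

def read_expression_tsv(path) -> dict[str, ExpressionProfile]:
    """Read TPM tables: long (``transcript_id  tpm``, one timepoint) or wide
    (``transcript_id  tpm_T1  tpm_T2 ...``)."""
    df = pd.read_csv(path, sep="\t")
    if "transcript_id" not in df.columns:
        raise ValueError("expression TSV needs a transcript_id column")
    tpm_cols = [c for c in df.columns if c.startswith("tpm")]
    if not tpm_cols:
        raise ValueError("expression TSV needs tpm or tpm_<timepoint> columns")
    profiles: dict[str, ExpressionProfile] = {}
    for col in tpm_cols:
        label = col[4:] if col.startswith("tpm_") else col
        profiles[label] = ExpressionProfile(
            label, dict(zip(df["transcript_id"], df[col].astype(float)))
        )
    return profiles


def write_expression_tsv(profiles: Mapping[str, ExpressionProfile], path) -> None:
    transcripts = sorted({t for p in profiles.values() for t in p.tpm})
    data = {"transcript_id": transcripts}
    for label, profile in profiles.items():
        data[f"tpm_{label}"] = [profile.tpm.get(t, 0.0) for t in transcripts]
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)


def read_de_tsv(path) -> dict[str, DifferentialExpression]:
    """Read ``transcript_id  comparison  log2FC  q_value`` with comparison
    tokens like ``T1-T2``; returns one table per comparison."""
    df = pd.read_csv(path, sep="\t")
    needed = {"transcript_id", "comparison", "log2FC", "q_value"}
    if not needed <= set(df.columns):
        raise ValueError(f"DE TSV needs columns {sorted(needed)}")
    out: dict[str, DifferentialExpression] = {}
    for token, group in df.groupby("comparison"):
        a, _, b = str(token).partition("-")
        records = {
            row.transcript_id: (float(row.log2FC), float(row.q_value))
            for row in group.itertuples(index=False)
        }
        out[str(token)] = DifferentialExpression((a, b), records)
    return out


def write_de_tsv(tables: Mapping[str, DifferentialExpression], path) -> None:
    rows = []
    for token, de in tables.items():
        for transcript, (lfc, q) in de.records.items():
            rows.append(
                {"transcript_id": transcript, "comparison": token, "log2FC": lfc, "q_value": q}
            )
    pd.DataFrame(rows, columns=["transcript_id", "comparison", "log2FC", "q_value"]).to_csv(
        path, sep="\t", index=False
    )
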