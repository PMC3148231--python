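"""Consensus miRNA→target voting and inverse-expression pairing.

A (miRNA, gene) prediction is accepted when it appears in at least
``min_votes`` of the k prediction databases (default 3 of 5 — the databases
are static tables supplied by the user, never queried live).  Accepted pairs
are then evaluated against the measured mRNA fold changes per condition:

* **inverse** — the miRNA and mRNA change in strictly opposite directions
  (the canonical repression pattern, e.g. miR-144 up with IRS1 down);
* **concordant** — both change in the same direction and both pass the
  magnitude cut (the putative RNA-activator pattern, e.g. miR-30d down with
  INS down);
* **null** — anything else, including flat profiles and missing records.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

from .diffexp import FilterConfig, FoldChangeRecord
from .io_formats import ConfigurationError, PredictionSet
from .signature import SignatureEntry

__all__ = [
    "TargetVote",
    "PairEvaluation",
    "consensus_targets",
    "evaluate_pairs",
    "INSULIN_SIGNALING_PANEL",
]

#: editable reporting panel of insulin-signaling genes; used only to subset
#: report output, never to change any computation
INSULIN_SIGNALING_PANEL = (
    "INSR",
    "GLUT4",
    "SLC2A4",
    "IRS1",
    "CBL",
    "FOXO1",
    "PTPN1",
    "INS",
    "INS1",
    "INS2",
    "AKT2",
)


@dataclass(frozen=True)
class TargetVote:
    mirna_id: str
    gene_id: str
    votes: int
    databases: frozenset
    accepted: bool


@dataclass(frozen=True)
class PairEvaluation:
    mirna_id: str
    gene_id: str
    condition: str
    mirna_signed_fc: float
    mrna_signed_fc: float
    relationship: str  # inverse | concordant | null


def consensus_targets(predictions: PredictionSet, min_votes: int = 3) -> list[TargetVote]:
    """One vote record per distinct (miRNA, gene) pair across all databases.

    Invariant to database ordering and to duplicated pairs within a database
    (pairs are deduplicated per database on load).
    """
    if min_votes > predictions.k:
        raise ConfigurationError(
            f"min_votes={min_votes} exceeds the number of databases k={predictions.k}"
        )
    out = []
    for (mirna, gene), dbs in sorted(predictions.votes().items()):
        out.append(
            TargetVote(
                mirna_id=mirna,
                gene_id=gene,
                votes=len(dbs),
                databases=frozenset(dbs),
                accepted=len(dbs) >= min_votes,
            )
        )
    return out


def _direction(signed_fc: float) -> str:
    if signed_fc > 1:
        return "up"
    if signed_fc < -1:
        return "down"
    return "none"  # |signed_fc| == 1: no change


def evaluate_pairs(
    signature: Sequence[SignatureEntry],
    mrna_records_by_label: Mapping[str, Sequence[FoldChangeRecord]],
    votes: Sequence[TargetVote],
    config: FilterConfig | None = None,
) -> list[PairEvaluation]:
    """Label each accepted (signature miRNA, gene) pair per condition.

    One evaluation is emitted per accepted pair per condition; pairs whose
    gene has no mRNA record in a condition are labeled ``null`` with a
    warning.  Signature miRNAs use the per-condition human fold change from
    their entry.
    """
    config = config or FilterConfig()
    by_mirna = {e.mirna_id: e for e in signature}
    accepted = [v for v in votes if v.accepted and v.mirna_id in by_mirna]
    mrna = {
        label: {r.feature_id: r for r in records}
        for label, records in mrna_records_by_label.items()
    }
    out = []
    for vote in accepted:
        entry = by_mirna[vote.mirna_id]
        for condition in mrna_records_by_label:
            mirna_fc = entry.human_fc.get(condition)
            gene_rec = mrna[condition].get(vote.gene_id)
            if mirna_fc is None or gene_rec is None:
                if gene_rec is None:
                    warnings.warn(
                        f"no mRNA record for {vote.gene_id!r} in condition {condition!r}; "
                        "pair labeled null"
                    )
                out.append(
                    PairEvaluation(vote.mirna_id, vote.gene_id, condition,
                                   mirna_fc if mirna_fc is not None else float("nan"),
                                   gene_rec.signed_fc if gene_rec is not None else float("nan"),
                                   "null")
                )
                continue
            mrna_fc = gene_rec.signed_fc
            d_mi, d_m = _direction(mirna_fc), _direction(mrna_fc)
            if d_mi != "none" and d_m != "none" and d_mi != d_m:
                rel = "inverse"
            elif (
                d_mi != "none"
                and d_mi == d_m
                and abs(mirna_fc) >= config.min_abs_fc
                and abs(mrna_fc) >= config.min_abs_fc
            ):
                rel = "concordant"
            else:
                rel = "null"
            out.append(PairEvaluation(vote.mirna_id, vote.gene_id, condition, mirna_fc, mrna_fc, rel))
    return out
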