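"""Multi-source and cross-species signature selection.

A candidate signature miRNA must pass the significance, magnitude and
replication filters in **every** source of the multi-source study with a
consistent direction of change (``cross_source_signature``), and its rat
direction must agree with the human T2D blood direction, with the human T2D
record significant (``cross_species_signature``).  IFG fold changes are
recorded on each entry but deliberately not used for concordance: discordant
IFG behaviour (e.g. miR-30d, miR-182 moving the other way in pre-diabetes)
is biology worth reporting, not an exclusion criterion.

``venn_counts`` provides the exact region counts of the source-wise
significant sets (the k-set Venn diagram of the study).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

from .diffexp import FilterConfig, FoldChangeRecord
from .io_formats import ConfigurationError

__all__ = [
    "VennCounts",
    "SignatureEntry",
    "venn_counts",
    "cross_source_signature",
    "cross_species_signature",
    "DEFAULT_ALIASES",
]

#: user-extensible probe alias table; reconciles naming between array
#: generations (miR-320 and miR-320a are the same mature sequence here)
DEFAULT_ALIASES: dict[str, str] = {"miR-320": "miR-320a"}


@dataclass
class VennCounts:
    """Exact element counts for every non-empty membership region of k sets."""

    set_names: tuple[str, ...]
    regions: dict[frozenset, int]
    union_size: int

    def count(self, *names: str) -> int:
        """Elements belonging to exactly the given sets (and no others)."""
        return self.regions.get(frozenset(names), 0)

    def in_all(self) -> int:
        return self.count(*self.set_names)


@dataclass
class SignatureEntry:
    mirna_id: str
    rat_fc: dict[str, float]  # source -> signed fold change
    human_fc: dict[str, float] = field(default_factory=dict)  # case label -> signed fc
    direction: str = "none"  # rat consensus direction
    concordant: bool = False


def venn_counts(sets: Mapping[str, set] | Sequence[tuple[str, set]]) -> VennCounts:
    """Region counts by membership pattern for 2–6 named sets.

    The regions are disjoint and sum to the union size by construction.
    """
    items = list(sets.items()) if isinstance(sets, Mapping) else list(sets)
    names = [n for n, _ in items]
    if len(names) != len(set(names)):
        raise ConfigurationError("duplicate set names in Venn input")
    if not 2 <= len(names) <= 6:
        raise ConfigurationError(f"venn_counts supports 2..6 sets, got {len(names)}")
    by_name = {n: set(s) for n, s in items}
    union = set().union(*by_name.values())
    regions: dict[frozenset, int] = {}
    for element in union:
        pattern = frozenset(n for n in names if element in by_name[n])
        regions[pattern] = regions.get(pattern, 0) + 1
    return VennCounts(tuple(names), regions, len(union))


def cross_source_signature(
    records_by_source: Mapping[str, Sequence[FoldChangeRecord]],
    required_sources: Sequence[str] | None = None,
    config: FilterConfig | None = None,
) -> list[SignatureEntry]:
    """miRNAs passing all three filters in every source with one direction.

    ``records_by_source`` maps source name → that source's contrast records.
    When ``required_sources`` is given (default: the keys present), all of
    them must be present or a :class:`ConfigurationError` lists the missing
    ones.  Filter flags are re-derived from ``config`` when supplied,
    otherwise the flags already on the records are used.
    """
    sources = list(records_by_source.keys())
    if required_sources is not None:
        missing = [s for s in required_sources if s not in records_by_source]
        if missing:
            raise ConfigurationError(f"missing source(s): {missing}")
        sources = list(required_sources)

    def passes(r: FoldChangeRecord) -> bool:
        if config is None:
            return r.passes_all
        return (
            r.p_value < config.p_max
            and abs(r.signed_fc) >= config.min_abs_fc
            and r.replication_fraction >= config.min_replication
        )

    per_source: dict[str, dict[str, FoldChangeRecord]] = {
        s: {r.feature_id: r for r in records_by_source[s]} for s in sources
    }
    candidates = set.intersection(
        *({f for f, r in per_source[s].items() if passes(r)} for s in sources)
    )
    entries = []
    for mirna in sorted(candidates):
        fcs = {s: per_source[s][mirna].signed_fc for s in sources}
        signs = {fc > 0 for fc in fcs.values()}
        if len(signs) != 1:
            continue  # direction flips between sources
        direction = "up" if signs.pop() else "down"
        entries.append(SignatureEntry(mirna_id=mirna, rat_fc=fcs, direction=direction))
    return entries


def cross_species_signature(
    rat_entries: Sequence[SignatureEntry],
    human_records_by_label: Mapping[str, Sequence[FoldChangeRecord]],
    aliases: Mapping[str, str] | None = None,
    p_max: float = 0.05,
    concordance_label: str = "T2D",
) -> list[SignatureEntry]:
    """Flag rat-signature miRNAs concordant with the human T2D blood change.

    An entry is concordant iff a human record exists for the miRNA under the
    concordance label (after alias resolution), that record is significant
    (p < ``p_max``), and its direction matches the rat direction.  Fold
    changes for every human case label (e.g. IFG) are attached for reporting
    regardless of concordance.
    """
    if not rat_entries:
        warnings.warn("empty rat signature; nothing to compare across species")
        return []
    aliases = dict(DEFAULT_ALIASES if aliases is None else aliases)

    def canon(name: str) -> str:
        return aliases.get(name, name)

    human: dict[str, dict[str, FoldChangeRecord]] = {}
    for label, records in human_records_by_label.items():
        table: dict[str, FoldChangeRecord] = {}
        for r in records:
            key = canon(r.feature_id)
            if key in table:
                raise ConfigurationError(
                    f"alias table maps two human records onto {key!r} in {label!r}"
                )
            table[key] = r
        human[label] = table

    out = []
    for entry in rat_entries:
        key = canon(entry.mirna_id)
        human_fc = {
            label: table[key].signed_fc for label, table in human.items() if key in table
        }
        rec = human.get(concordance_label, {}).get(key)
        concordant = (
            rec is not None
            and rec.p_value < p_max
            and rec.direction == entry.direction
        )
        out.append(
            SignatureEntry(
                mirna_id=key,
                rat_fc=dict(entry.rat_fc),
                human_fc=human_fc,
                direction=entry.direction,
                concordant=bool(concordant),
            )
        )
    return out
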