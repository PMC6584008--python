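"""Multi-locus combination of per-locus identifications.

Plants are barcoded with 2-locus (rbcL + matK) or 4-locus
(rbcL + matK + trnH-psbA + ITS2) sets, and fungal ITS is searched as
subunit 1, subunit 2, or the combined spacer. This module scores a
specimen from its per-locus classifications.

The default combination rule intersects the top-set species identities
across loci: a species survives only if every informative locus supports
it, so adding loci can only shrink the candidate set — never manufacture a
species no locus returned. ``union`` and ``best_locus`` (fewest tied
identities, ties broken by a configurable locus priority) are provided as
alternatives.
"""

from __future__ import annotations

from dataclasses import dataclass

from .adjudication import Classification
from .errors import DataError, InvalidInputError
from .taxonomy import Lineage, SynonymTable, rank_depth, resolve_synonym

STRATEGIES = ("intersection", "union", "best_locus")

#: Tie-break order for best_locus (first = preferred).
DEFAULT_LOCUS_PRIORITY = ("rbcL", "matK", "trnH-psbA", "ITS2")


@dataclass
class SpecimenClassification:
    """Specimen-level outcome after combining loci."""

    specimen_id: str
    loci: frozenset[str]
    strategy: str
    status: str
    source_db: str = ""
    run_id: str = ""
    deepest_correct_rank: str | None = None
    ambiguity_categories: frozenset[str] = frozenset()
    candidates: frozenset[str] = frozenset()
    truth_species: str = ""

    @property
    def is_correct(self) -> bool:
        return self.status in ("reliable_correct", "ambiguous_correct")


def _categorize_candidate(key: str, truth: Lineage) -> str:
    genus = truth.genus.casefold()
    if key.startswith("uncultured"):
        return "uncultured"
    if key.endswith(" sp.") or " " not in key:
        return "undetermined_species"
    return "congeneric" if key.split(" ")[0] == genus else "heterogeneric"


def _combined_status(
    candidates: set[str], truth: Lineage, synonyms: SynonymTable | None
) -> tuple[str, frozenset[str]]:
    truth_key = resolve_synonym(truth.species, synonyms).casefold()
    if candidates == {truth_key}:
        return "reliable_correct", frozenset()
    if truth_key in candidates:
        cats = frozenset(
            _categorize_candidate(k, truth) for k in candidates if k != truth_key
        )
        return "ambiguous_correct", cats
    return "misidentified", frozenset()


def combine_loci(
    per_locus: list[Classification],
    truth: Lineage,
    synonyms: SynonymTable | None = None,
    strategy: str = "intersection",
    locus_priority: tuple[str, ...] = DEFAULT_LOCUS_PRIORITY,
) -> SpecimenClassification:
    """Combine one specimen's per-locus classifications into a single call.

    Loci that returned no match are dropped before combining (a failed locus
    should not veto the specimen). If every locus is no_match this raises
    :class:`DataError`; the batch wrapper :func:`combine_all` converts that
    into a no_match specimen row with a warning.
    """
    if not per_locus:
        raise InvalidInputError("combine_loci needs at least one classification")
    if strategy not in STRATEGIES:
        raise InvalidInputError(f"unknown strategy {strategy!r}; expected one of {STRATEGIES}")
    specimen_ids = {c.query_id for c in per_locus}
    if len(specimen_ids) != 1:
        raise InvalidInputError(f"classifications span several specimens: {sorted(specimen_ids)}")
    specimen_id = per_locus[0].query_id
    if not truth.species:
        raise InvalidInputError(f"truth lineage for specimen {specimen_id!r} lacks a species")

    informative = [c for c in per_locus if c.status != "no_match"]
    all_loci = frozenset(c.locus for c in per_locus)
    if not informative:
        raise DataError(f"specimen {specimen_id!r}: every locus returned no match")

    if strategy == "best_locus":
        prio = {loc: i for i, loc in enumerate(locus_priority)}
        chosen = min(
            informative,
            key=lambda c: (len(c.candidates), prio.get(c.locus, len(prio)), c.locus),
        )
        candidates = set(chosen.candidates)
    elif strategy == "union":
        candidates = set().union(*(c.candidates for c in informative))
    else:
        candidates = set(informative[0].candidates)
        for c in informative[1:]:
            candidates &= c.candidates

    status, categories = _combined_status(candidates, truth, synonyms)
    source_dbs = {c.source_db for c in per_locus}
    run_ids = {c.run_id for c in per_locus}

    if status == "misidentified":
        # deepest rank every informative locus still supports
        depths = []
        for c in informative:
            if c.is_correct:
                depths.append(rank_depth("species"))
            elif c.deepest_correct_rank is not None:
                depths.append(rank_depth(c.deepest_correct_rank))
            else:
                depths.append(-1)
        floor = min(depths)
        from .taxonomy import RANKS

        deepest = RANKS[floor] if floor >= 0 else None
    else:
        deepest = "species"

    return SpecimenClassification(
        specimen_id=specimen_id, loci=all_loci, strategy=strategy, status=status,
        source_db=source_dbs.pop() if len(source_dbs) == 1 else "mixed",
        run_id=run_ids.pop() if len(run_ids) == 1 else "mixed",
        deepest_correct_rank=deepest, ambiguity_categories=categories,
        candidates=frozenset(candidates), truth_species=truth.species,
    )


def combine_all(
    classifications: list[Classification],
    truth_table,
    synonyms: SynonymTable | None = None,
    strategy: str = "intersection",
    locus_priority: tuple[str, ...] = DEFAULT_LOCUS_PRIORITY,
) -> tuple[list[SpecimenClassification], list[str]]:
    """Combine loci per specimen, separately within each (source_db, run).

    Loci are only ever combined within one database and parameter set — a
    specimen searched against both databases gets one combined row per
    database. Specimens whose loci are all no_match yield a no_match row
    (with a warning entry in the returned list) instead of aborting the
    batch.
    """
    by_key: dict[tuple[str, str, str], list[Classification]] = {}
    for c in classifications:
        by_key.setdefault((c.query_id, c.source_db, c.run_id), []).append(c)
    out: list[SpecimenClassification] = []
    warnings: list[str] = []
    for (specimen_id, source_db, run_id) in sorted(by_key):
        group = by_key[(specimen_id, source_db, run_id)]
        truth = truth_table.lookup(specimen_id, group[0].locus)
        if truth is None:
            warnings.append(f"specimen {specimen_id!r}: no truth entry; skipped")
            continue
        try:
            out.append(combine_loci(group, truth, synonyms, strategy, locus_priority))
        except DataError:
            warnings.append(f"specimen {specimen_id!r} ({source_db}/{run_id}): "
                            "all loci no_match")
            out.append(
                SpecimenClassification(
                    specimen_id=specimen_id,
                    loci=frozenset(c.locus for c in group),
                    strategy=strategy, status="no_match",
                    source_db=source_db, run_id=run_id,
                    truth_species=truth.species,
                )
            )
    return out, warnings


SPECIMEN_COLUMNS = (
    "specimen_id", "loci", "source_db", "run_id", "strategy", "status",
    "deepest_correct_rank", "categories", "candidates", "truth_species",
)


def write_specimen_classifications(rows: list[SpecimenClassification], path) -> None:
    """Write specimen-level classifications to TSV (loci joined with '+')."""
    with open(path, "w") as fh:
        fh.write("\t".join(SPECIMEN_COLUMNS) + "\n")
        for s in rows:
            fh.write("\t".join([
                s.specimen_id, "+".join(sorted(s.loci)), s.source_db, s.run_id,
                s.strategy, s.status, s.deepest_correct_rank or "",
                ",".join(sorted(s.ambiguity_categories)),
                "|".join(sorted(s.candidates)), s.truth_species,
            ]) + "\n")


@dataclass
class ItsComparison:
    """Side-by-side statuses for ITS1 / ITS2 / combined-ITS searches."""

    specimen_id: str
    statuses: dict[str, str]
    concordant: bool
    headline_status: str


def its_modes(by_mode: dict[str, Classification]) -> ItsComparison:
    """Compare ITS subunit searches against the combined-spacer search.

    ``by_mode`` maps mode name ("ITS1", "ITS2", "ITS") to that mode's
    classification; missing modes are simply absent from the comparison.
    The combined spacer, when present, is the headline result.
    """
    if not by_mode:
        raise InvalidInputError("its_modes needs at least one mode")
    specimen_ids = {c.query_id for c in by_mode.values()}
    if len(specimen_ids) != 1:
        raise InvalidInputError("its_modes classifications span several specimens")
    statuses = {mode: c.status for mode, c in by_mode.items()}
    headline = statuses.get("ITS") or next(iter(statuses.values()))
    return ItsComparison(
        specimen_id=next(iter(specimen_ids)),
        statuses=statuses,
        concordant=len(set(statuses.values())) == 1,
        headline_status=headline,
    )
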