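"""Top-match ties and per-query identification calls.

The adjudication rule mirrors how practitioners read a database search:
the *top-match set* is every record sharing the best match statistics
(lowest e-value, then highest bit score, then highest percent identity for
GenBank-style output; highest similarity for BOLD-style output), with
printed-equal values treated as ties. A query is then:

* ``reliable_correct`` — every tied top record names the expected species;
* ``ambiguous_correct`` — the expected species is in the top set alongside
  at least one other identity (congener, different genus, undetermined, or
  uncultured record);
* ``misidentified`` — no top record names the expected species; the deepest
  rank at which the assignment still agrees with the truth is rolled up;
* ``no_match`` — the search returned nothing.

A low-confidence flag marks queries whose top similarity falls below a
threshold (default 96%), the regime where restricted reference subsets
tend to return no match at all.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import DataError, InvalidInputError
from .hit_io import HitRecord, HitTable
from .taxonomy import (
    Lineage,
    LineageIndex,
    SynonymTable,
    deepest_correct_rank,
    parse_taxon_name,
    rank_depth,
    resolve_synonym,
)

DEFAULT_CONFIDENCE_THRESHOLD = 96.0  # percent similarity
FULL_LENGTH_CUTOFF = 640  # bp; full-length animal barcode
MID_LENGTH_CUTOFF = 430   # bp; below this a barcode is mid-length

STATUSES = ("reliable_correct", "ambiguous_correct", "misidentified", "no_match")
AMBIGUITY_CATEGORIES = ("congeneric", "heterogeneric", "undetermined_species", "uncultured")


@dataclass(frozen=True)
class TiePolicy:
    """When do two records share the top match statistics?

    GenBank records are ordered by (e-value ascending, bit score descending,
    percent identity descending) and must tie on all three; BOLD records are
    ordered by similarity alone. Statistics printed to two decimals compare
    equal within ``stat_abs_tol``; e-values within a relative tolerance
    (0 == 0 exactly).
    """

    evalue_rel_tol: float = 1e-9
    stat_abs_tol: float = 0.005

    def __post_init__(self) -> None:
        if self.evalue_rel_tol < 0 or self.stat_abs_tol < 0:
            raise InvalidInputError("tie tolerances must be nonnegative")

    def exact_key(self, record: HitRecord) -> tuple:
        """Strict sort key (smaller is better) used to locate the best record."""
        if record.source_db == "bold":
            if not record.has_bold_stats:
                raise DataError(
                    f"record {record.subject_id!r} for query {record.query_id!r} "
                    "lacks the BOLD similarity statistic"
                )
            return (-record.similarity,)
        if not record.has_genbank_stats:
            raise DataError(
                f"record {record.subject_id!r} for query {record.query_id!r} "
                "lacks GenBank statistics (e-value, bit score, percent identity)"
            )
        return (record.evalue, -record.bitscore, -record.percent_identity)

    def _evalue_eq(self, a: float, b: float) -> bool:
        if a == b:  # covers 0 == 0 exactly
            return True
        return abs(a - b) <= self.evalue_rel_tol * max(abs(a), abs(b))

    def _stat_eq(self, a: float, b: float) -> bool:
        return abs(a - b) <= self.stat_abs_tol

    def ties(self, a: HitRecord, b: HitRecord) -> bool:
        """True iff *a* and *b* share the top match statistics."""
        if a.source_db == "bold":
            return self._stat_eq(a.similarity, b.similarity)
        return (
            self._evalue_eq(a.evalue, b.evalue)
            and self._stat_eq(a.bitscore, b.bitscore)
            and self._stat_eq(a.percent_identity, b.percent_identity)
        )


DEFAULT_TIE_POLICY = TiePolicy()


@dataclass
class TopMatchSet:
    """Records sharing the best match statistics for one query."""

    query_id: str
    members: list[HitRecord]
    best_key: tuple | None
    source_db: str = "genbank"

    @property
    def tie_count(self) -> int:
        return len(self.members)

    @property
    def is_empty(self) -> bool:
        return not self.members


def top_match_set(table: HitTable, policy: TiePolicy = DEFAULT_TIE_POLICY) -> TopMatchSet:
    """All records tied with the lexicographic best under the tie policy.

    The best record is located with the strict key (input-order independent);
    membership then admits every record whose statistics tie the best within
    the policy tolerances. An empty table yields an empty set (no match).
    """
    if not table.records:
        return TopMatchSet(table.query_id, [], None, table.source_db)
    keys = [policy.exact_key(r) for r in table.records]
    best_i = min(range(len(keys)), key=keys.__getitem__)
    best = table.records[best_i]
    members = [r for r in table.records if policy.ties(r, best)]
    return TopMatchSet(table.query_id, members, keys[best_i], table.source_db)


@dataclass
class Classification:
    """Per-query identification outcome."""

    query_id: str
    locus: str
    source_db: str
    run_id: str
    status: str
    deepest_correct_rank: str | None = None
    ambiguity_categories: frozenset[str] = frozenset()
    top_similarity: float | None = None
    low_confidence: bool = False
    tie_count: int = 0
    candidates: frozenset[str] = frozenset()  # identity keys of the top set
    truth_species: str = ""

    @property
    def is_correct(self) -> bool:
        return self.status in ("reliable_correct", "ambiguous_correct")


def flag_confidence(similarity: float, threshold: float = DEFAULT_CONFIDENCE_THRESHOLD) -> bool:
    """True (low confidence) iff similarity is strictly below the threshold."""
    return similarity < threshold


def _member_lineage(record: HitRecord, parsed, lineage_index: LineageIndex | None) -> Lineage:
    if record.lineage is not None:
        return record.lineage
    if lineage_index is not None:
        return lineage_index.expand(parsed)
    return Lineage(genus=parsed.genus, species=parsed.canonical_binomial)


def classify_query(
    top: TopMatchSet,
    truth: Lineage,
    synonyms: SynonymTable | None = None,
    confidence_threshold: float = DEFAULT_CONFIDENCE_THRESHOLD,
    *,
    locus: str = "",
    run_id: str = "",
    lineage_index: LineageIndex | None = None,
) -> Classification:
    """Classify one query from its top-match set and the expected lineage."""
    if not truth.species:
        raise InvalidInputError(f"truth lineage for query {top.query_id!r} lacks a species")

    if top.is_empty:
        return Classification(
            query_id=top.query_id, locus=locus, source_db=top.source_db,
            run_id=run_id, status="no_match", truth_species=truth.species,
        )

    truth_key = resolve_synonym(truth.species, synonyms).casefold()
    truth_genus = truth.genus.casefold()

    sims = [r.best_similarity_stat for r in top.members if r.best_similarity_stat is not None]
    top_similarity = max(sims) if sims else None

    correct_members: list[HitRecord] = []
    other_categories: set[str] = set()
    candidates: set[str] = set()
    member_info = []
    for rec in top.members:
        parsed = parse_taxon_name(rec.subject_label)
        canonical = parsed.canonical_binomial
        is_correct = bool(canonical) and (
            resolve_synonym(canonical, synonyms).casefold() == truth_key
        )
        member_info.append((rec, parsed, is_correct))
        candidates.add(
            truth_key if is_correct else parsed.identity_key
        )
        if is_correct:
            correct_members.append(rec)
        elif parsed.is_uncultured:
            other_categories.add("uncultured")
        elif parsed.is_undetermined:
            other_categories.add("undetermined_species")
        elif parsed.genus and parsed.genus.casefold() == truth_genus:
            other_categories.add("congeneric")
        else:
            other_categories.add("heterogeneric")

    if correct_members and len(correct_members) == len(top.members):
        status, deepest, categories = "reliable_correct", "species", frozenset()
    elif correct_members:
        status, deepest, categories = "ambiguous_correct", "species", frozenset(other_categories)
    else:
        status, categories = "misidentified", frozenset()
        deepest = None
        for rec, parsed, _ in member_info:
            r = deepest_correct_rank(truth, _member_lineage(rec, parsed, lineage_index), synonyms)
            if r is not None and (deepest is None or rank_depth(r) > rank_depth(deepest)):
                deepest = r

    low = top_similarity is not None and flag_confidence(top_similarity, confidence_threshold)
    return Classification(
        query_id=top.query_id, locus=locus, source_db=top.source_db, run_id=run_id,
        status=status, deepest_correct_rank=deepest, ambiguity_categories=categories,
        top_similarity=top_similarity, low_confidence=low, tie_count=top.tie_count,
        candidates=frozenset(candidates), truth_species=truth.species,
    )


def adjudicate_tables(
    tables: list[HitTable],
    truth,
    synonyms: SynonymTable | None = None,
    policy: TiePolicy = DEFAULT_TIE_POLICY,
    confidence_threshold: float = DEFAULT_CONFIDENCE_THRESHOLD,
    lineage_index: LineageIndex | None = None,
) -> tuple[list[Classification], list[str]]:
    """Adjudicate every hit table against a :class:`~.hit_io.TruthTable`.

    Returns the classifications plus the query ids skipped because the truth
    table has no entry for them.
    """
    if lineage_index is None:
        lineage_index = LineageIndex(truth.lineages())
    out: list[Classification] = []
    skipped: list[str] = []
    for table in tables:
        lin = truth.lookup(table.query_id, table.locus)
        if lin is None or not lin.species:
            skipped.append(table.query_id)
            continue
        top = top_match_set(table, policy)
        out.append(
            classify_query(
                top, lin, synonyms, confidence_threshold,
                locus=table.locus, run_id=table.run_id, lineage_index=lineage_index,
            )
        )
    return out, skipped


@dataclass
class LengthStratum:
    """Misidentification bookkeeping for one query-length stratum."""

    query_ids: list[str] = field(default_factory=list)
    n_misidentified: int = 0

    @property
    def n(self) -> int:
        return len(self.query_ids)

    @property
    def misidentification_rate(self) -> float | None:
        """Percent misidentified, or None for an empty stratum."""
        return 100.0 * self.n_misidentified / self.n if self.query_ids else None


CLASSIFICATION_COLUMNS = (
    "query_id", "locus", "source_db", "run_id", "status", "deepest_correct_rank",
    "categories", "top_similarity", "low_confidence", "tie_count", "candidates",
    "truth_species",
)


def write_classifications(classifications: list[Classification], path) -> None:
    """Write per-query classifications to the canonical TSV."""
    with open(path, "w") as fh:
        fh.write("\t".join(CLASSIFICATION_COLUMNS) + "\n")
        for c in classifications:
            fh.write("\t".join([
                c.query_id, c.locus, c.source_db, c.run_id, c.status,
                c.deepest_correct_rank or "",
                ",".join(sorted(c.ambiguity_categories)),
                repr(c.top_similarity) if c.top_similarity is not None else "",
                "1" if c.low_confidence else "0",
                str(c.tie_count),
                "|".join(sorted(c.candidates)),
                c.truth_species,
            ]) + "\n")


def read_classifications(path) -> list[Classification]:
    """Read a classification TSV written by :func:`write_classifications`."""
    out: list[Classification] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != CLASSIFICATION_COLUMNS:
            raise DataError(f"{path}: unexpected classification header {header}")
        for line in fh:
            cols = line.rstrip("\n").split("\t")
            out.append(Classification(
                query_id=cols[0], locus=cols[1], source_db=cols[2], run_id=cols[3],
                status=cols[4], deepest_correct_rank=cols[5] or None,
                ambiguity_categories=frozenset(cols[6].split(",")) - {""},
                top_similarity=float(cols[7]) if cols[7] else None,
                low_confidence=cols[8] == "1", tie_count=int(cols[9]),
                candidates=frozenset(cols[10].split("|")) - {""},
                truth_species=cols[11],
            ))
    return out


def stratify_by_length(
    classifications: list[Classification],
    lengths: dict[str, int],
    full_cutoff: int = FULL_LENGTH_CUTOFF,
    mid_cutoff: int = MID_LENGTH_CUTOFF,
) -> dict[str, LengthStratum]:
    """Split queries into full-length (≥ *full_cutoff* bp) and mid-length strata.

    Queries between the two cutoffs count as mid-length. Each stratum reports
    its misidentification rate (percent of queries with status
    ``misidentified``).
    """
    missing = [c.query_id for c in classifications if c.query_id not in lengths]
    if missing:
        raise DataError(f"no query length for: {', '.join(sorted(missing))}")
    strata = {"full": LengthStratum(), "mid": LengthStratum()}
    for c in classifications:
        stratum = strata["full" if lengths[c.query_id] >= full_cutoff else "mid"]
        stratum.query_ids.append(c.query_id)
        if c.status == "misidentified":
            stratum.n_misidentified += 1
    return strata
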