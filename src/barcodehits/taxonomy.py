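"""Taxon-label parsing, synonym resolution, and rank-wise lineage comparison.

Reference databases label records inconsistently: undetermined species
("Amanita sp."), environmental/uncultured records, open-nomenclature
qualifiers (cf./aff./nr.) and subspecific trinomials all occur alongside
clean binomials. This module normalizes raw labels into :class:`ParsedTaxon`,
represents expert truth as a five-rank :class:`Lineage`
(class > order > family > genus > species), and answers the question the
whole pipeline turns on: at which rank does an assigned name agree with the
vouchered specimen's identity?

Comparisons are case-insensitive and whitespace-normalized. Known synonyms
(user-supplied, two-column CSV) are resolved at species rank only before an
equality test, so a record filed under a junior synonym still counts as the
correct species.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

from .errors import ConfigError, InvalidInputError

#: Rank names, shallow to deep. Order is load-bearing for roll-ups.
RANKS: tuple[str, ...] = ("class", "order", "family", "genus", "species")

_RANK_DEPTH = {r: i for i, r in enumerate(RANKS)}

#: Epithet tokens that mark a record as not determined to species.
PLACEHOLDER_EPITHETS = frozenset(
    {"sp", "sp.", "spp", "spp.", "ssp", "ssp.", "indet", "indet.", "gen", "gen."}
)

#: Open-nomenclature qualifiers between genus and epithet.
QUALIFIER_TOKENS = frozenset({"cf", "cf.", "aff", "aff.", "nr", "nr."})

#: Leading tokens marking environmental/uncultured records.
UNCULTURED_MARKERS = frozenset({"uncultured", "environmental", "unidentified"})

# Words that follow "uncultured ..." but are not genus names.
_GENERIC_WORDS = frozenset(
    {
        "fungus", "fungal", "fungi", "bacterium", "bacteria", "organism",
        "eukaryote", "clone", "soil", "root", "sample", "isolate", "species",
    }
)


def _norm_ws(s: str) -> str:
    return " ".join(s.split())


@dataclass(frozen=True)
class ParsedTaxon:
    """A normalized reading of one database taxon label."""

    raw_label: str
    genus: str = ""
    species_epithet: str = ""
    is_undetermined: bool = False
    is_uncultured: bool = False
    is_qualified: bool = False

    @property
    def canonical_binomial(self) -> str:
        """``"Genus epithet"`` when determined to species, else ``""``."""
        if self.genus and self.species_epithet and not self.is_undetermined:
            return f"{self.genus} {self.species_epithet}"
        return ""

    @property
    def identity_key(self) -> str:
        """Casefolded identity string used for tie-set algebra.

        A determined record keys on its binomial, an undetermined one on
        ``"genus sp."``, an uncultured one on ``"uncultured [genus]"`` — so
        two loci whose top sets both contain *Amanita* sp. intersect on it.
        """
        if self.canonical_binomial:
            return self.canonical_binomial.casefold()
        if self.is_uncultured:
            return f"uncultured {self.genus}".strip().casefold()
        if self.genus:
            return f"{self.genus} sp.".casefold()
        return self.raw_label.casefold()


def parse_taxon_name(raw_label: str) -> ParsedTaxon:
    """Parse a raw database taxon label into its normalized components.

    Token rules: a leading uncultured/environmental marker flags the record
    as uncultured (and undetermined); an epithet that is a placeholder
    (``sp.``, ``spp.`` ...) or contains digits flags it undetermined;
    cf./aff./nr. between genus and epithet set the qualified flag.
    Subspecific parts beyond the binomial are dropped. Genus is capitalized
    and the epithet lowercased.

    Raises
    ------
    InvalidInputError
        If the label is empty or whitespace-only.
    """
    label = _norm_ws(raw_label)
    if not label:
        raise InvalidInputError("taxon label is empty or whitespace-only")

    tokens = label.split()
    is_uncultured = False
    while tokens and tokens[0].casefold() in UNCULTURED_MARKERS:
        is_uncultured = True
        tokens = tokens[1:]

    genus = ""
    epithet = ""
    is_qualified = False
    is_undetermined = False

    if tokens:
        cand = tokens[0]
        if cand.isalpha() and cand.casefold() not in _GENERIC_WORDS:
            genus = cand.capitalize()
            rest = tokens[1:]
            if rest and rest[0].casefold() in QUALIFIER_TOKENS:
                is_qualified = True
                rest = rest[1:]
            if rest:
                ep = rest[0].casefold()
                if ep in PLACEHOLDER_EPITHETS or any(c.isdigit() for c in ep):
                    is_undetermined = True
                else:
                    epithet = ep
        # else: code-like or generic first token — no usable genus

    if is_uncultured or not epithet:
        is_undetermined = True
    if is_undetermined:
        epithet = ""

    return ParsedTaxon(
        raw_label=raw_label,
        genus=genus,
        species_epithet=epithet,
        is_undetermined=is_undetermined,
        is_uncultured=is_uncultured,
        is_qualified=is_qualified,
    )


@dataclass(frozen=True)
class Lineage:
    """A five-rank lineage; an empty field means unknown at that rank."""

    class_: str = ""
    order: str = ""
    family: str = ""
    genus: str = ""
    species: str = ""

    def __post_init__(self) -> None:
        if self.species:
            if not self.genus:
                raise InvalidInputError(
                    f"species {self.species!r} set without a genus"
                )
            if not self.species.casefold().startswith(self.genus.casefold()):
                raise InvalidInputError(
                    f"species {self.species!r} does not begin with genus {self.genus!r}"
                )

    def at(self, rank: str) -> str:
        if rank not in _RANK_DEPTH:
            raise InvalidInputError(f"unknown rank {rank!r}; expected one of {RANKS}")
        return getattr(self, "class_" if rank == "class" else rank)


def rank_depth(rank: str) -> int:
    """0 for class ... 4 for species; raises on unknown rank names."""
    if rank not in _RANK_DEPTH:
        raise InvalidInputError(f"unknown rank {rank!r}; expected one of {RANKS}")
    return _RANK_DEPTH[rank]


@dataclass
class SynonymTable:
    """Alias binomial → canonical binomial map, case-insensitive, cycle-free."""

    mapping: dict[str, str] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        norm: dict[str, str] = {}
        for alias, canonical in self.mapping.items():
            norm[_norm_ws(alias).casefold()] = _norm_ws(canonical)
        self.mapping = norm
        for alias, canonical in self.mapping.items():
            target = self.mapping.get(canonical.casefold())
            if target is not None and target.casefold() != canonical.casefold():
                raise ConfigError(
                    f"synonym table is not idempotent: {alias!r} -> {canonical!r} "
                    f"-> {target!r}"
                )

    def resolve(self, name: str) -> str:
        """Map an alias to its canonical binomial; unknown names pass through."""
        return self.mapping.get(_norm_ws(name).casefold(), name)

    def __len__(self) -> int:
        return len(self.mapping)

    @classmethod
    def from_csv(cls, path) -> "SynonymTable":
        """Load a two-column CSV ``alias,canonical`` (header required)."""
        mapping: dict[str, str] = {}
        provenance: dict[str, str] = {}
        with open(path, newline="") as fh:
            reader = csv.reader(fh)
            header = next(reader, None)
            if header is None or len(header) < 2:
                raise ConfigError(f"{path}: synonym CSV needs an 'alias,canonical' header")
            for row in reader:
                if not row or not row[0].strip():
                    continue
                if len(row) < 2:
                    raise ConfigError(f"{path}: synonym row {row!r} lacks a canonical name")
                mapping[row[0]] = row[1]
                if len(row) > 2:
                    provenance[_norm_ws(row[0]).casefold()] = row[2]
        return cls(mapping=mapping, provenance=provenance)


def resolve_synonym(name: str, table: SynonymTable | None) -> str:
    """Resolve a canonical binomial through the synonym table (identity if absent)."""
    if table is None:
        return name
    return table.resolve(name)


def same_taxon_at_rank(
    a: Lineage,
    b: Lineage,
    rank: str,
    synonyms: SynonymTable | None = None,
) -> bool:
    """True iff both lineages are known and equal at *rank*.

    Unknown (empty) at either side is never a match. Species-rank equality
    resolves both sides through the synonym table first.
    """
    va, vb = a.at(rank), b.at(rank)
    if not va or not vb:
        return False
    if rank == "species":
        va = resolve_synonym(va, synonyms)
        vb = resolve_synonym(vb, synonyms)
    return _norm_ws(va).casefold() == _norm_ws(vb).casefold()


def deepest_correct_rank(
    truth: Lineage,
    assigned: Lineage,
    synonyms: SynonymTable | None = None,
) -> str | None:
    """Deepest rank at which the assigned lineage agrees with the truth.

    Returns ``None`` when no rank matches (including the all-unknown case).
    """
    for rank in reversed(RANKS):
        if same_taxon_at_rank(truth, assigned, rank, synonyms):
            return rank
    return None


class LineageIndex:
    """Genus → higher-rank backbone, built from the truth table.

    Search outputs often carry only a binomial label; this index fills in
    family/order/class for genera the study knows about, so roll-ups above
    genus are still possible for misidentified queries.
    """

    def __init__(self, lineages: list[Lineage] | None = None):
        self._by_genus: dict[str, Lineage] = {}
        for lin in lineages or []:
            self.add(lin)

    def add(self, lineage: Lineage) -> None:
        if lineage.genus:
            key = lineage.genus.casefold()
            self._by_genus.setdefault(
                key,
                Lineage(
                    class_=lineage.class_,
                    order=lineage.order,
                    family=lineage.family,
                    genus=lineage.genus,
                ),
            )

    def expand(self, parsed: ParsedTaxon) -> Lineage:
        """Best-effort lineage for a parsed label (empty ranks where unknown)."""
        backbone = self._by_genus.get(parsed.genus.casefold()) if parsed.genus else None
        species = parsed.canonical_binomial
        if backbone is not None:
            return Lineage(
                class_=backbone.class_,
                order=backbone.order,
                family=backbone.family,
                genus=backbone.genus,
                species=species,
            )
        return Lineage(genus=parsed.genus, species=species)
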