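"""Synthetic truth tables, reference databases and hit tables.

The generator emulates the error structure of public barcode repositories:
records whose label is a congener of the true source (misidentified
submissions), records determined only to genus ("Genus sp."), environmental
"uncultured" records, and species missing from the database entirely.
Match statistics follow a similarity-versus-taxonomic-distance model: a
query's percent identity against a record is drawn from a normal
distribution whose mean decreases with the taxonomic distance between the
query's species and the record's true source (conspecific > congeneric >
confamilial > ordinal > background), truncated to [50, 100].

GenBank-dialect statistics are derived from the drawn identity with a
Karlin–Altschul-shaped convention: a raw score from match/mismatch
reward/penalty (+1/−2), a bit score ``(λ·s − ln K)/ln 2`` with generator
constants λ=1.28, K=0.46, and an e-value ``N·L·2^(−bit)``. These formulas
are a generator convention chosen for realism, not a claim about search
engine internals — the pipeline never aligns sequences.

Everything is deterministic under the config seed; a fixture bundle written
twice with the same config is byte-identical.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .errors import ConfigError, DataError
from .hit_io import BOLD_DEFAULT_COLUMNS, HitRecord, HitTable
from .taxonomy import Lineage, SynonymTable

DISTANCES = ("conspecific", "congeneric", "confamilial", "ordinal", "background")

#: Default similarity model: mean/sd percent identity by taxonomic distance.
DEFAULT_SIMILARITY_MODEL: dict[str, tuple[float, float]] = {
    "conspecific": (99.6, 0.3),
    "congeneric": (96.5, 1.2),
    "confamilial": (92.0, 2.0),
    "ordinal": (88.0, 2.5),
    "background": (82.0, 3.0),
}

_LAMBDA, _K = 1.28, 0.46
_REWARD, _PENALTY = 1, -2


@dataclass
class SimConfig:
    """Simulation scenario parameters.

    The defaults mirror a modest barcode study: a taxonomy of a few hundred
    species, a handful of database records per species, low but nonzero
    label-error rates, ~30% mid-length queries (shorter amplicons from
    degraded material), and a tie rate that makes roughly a fifth of correct
    matches ambiguous.
    """

    seed: int = 0
    n_classes: int = 2
    n_orders_per_class: int = 3
    n_families_per_order: int = 3
    n_genera_per_family: int = 4
    n_species_per_genus: int = 4
    records_per_species: int = 5
    mislabel_rate: float = 0.05
    undetermined_rate: float = 0.10
    uncultured_rate: float = 0.05
    missing_species_rate: float = 0.0
    similarity_model: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_SIMILARITY_MODEL)
    )
    tie_rate: float = 0.3
    n_queries: int = 94
    max_hits: int = 10
    db_size_for_evalue: float = 1e7
    loci: tuple[str, ...] = ("COI",)
    runs: tuple[str, ...] = ("default",)
    synonym_rate: float = 0.0
    # query-length model: full-length vs mid-length amplicons
    mid_fraction: float = 0.3
    full_length_mean: float = 614.0
    full_length_sd: float = 34.0
    mid_length_mean: float = 340.0
    mid_length_sd: float = 65.0

    def __post_init__(self) -> None:
        rates = {
            "mislabel_rate": self.mislabel_rate,
            "undetermined_rate": self.undetermined_rate,
            "uncultured_rate": self.uncultured_rate,
            "missing_species_rate": self.missing_species_rate,
            "tie_rate": self.tie_rate,
            "synonym_rate": self.synonym_rate,
            "mid_fraction": self.mid_fraction,
        }
        for name, r in rates.items():
            if not (0.0 <= r <= 1.0):
                raise ConfigError(f"{name}={r} outside [0, 1]")
        if self.mislabel_rate + self.undetermined_rate + self.uncultured_rate > 1.0:
            raise ConfigError("record error rates sum above 1; no probability mass left "
                              "for correctly labeled records")
        means = [self.similarity_model[d][0] for d in DISTANCES]
        if not all(a > b for a, b in zip(means, means[1:])):
            raise ConfigError("similarity means must strictly decrease with taxonomic distance")
        if any(self.similarity_model[d][1] < 0 for d in DISTANCES):
            raise ConfigError("similarity sds must be nonnegative")

    @property
    def n_species(self) -> int:
        return (self.n_classes * self.n_orders_per_class * self.n_families_per_order
                * self.n_genera_per_family * self.n_species_per_genus)


def _alpha(n: int, width: int = 3) -> str:
    """Deterministic lowercase-letter encoding of an index ('aaa', 'aab', ...)."""
    s = []
    for _ in range(width):
        s.append(chr(ord("a") + n % 26))
        n //= 26
    return "".join(reversed(s))


@dataclass
class SimTaxonomy:
    """Synthetic taxonomic backbone with flat per-species rank indices."""

    config: SimConfig
    species_names: list[str]
    lineages: list[Lineage]
    sp_genus: np.ndarray
    sp_family: np.ndarray
    sp_order: np.ndarray
    sp_class: np.ndarray

    @classmethod
    def build(cls, config: SimConfig) -> "SimTaxonomy":
        names, lineages = [], []
        g_idx, f_idx, o_idx = [], [], []
        c_idx = []
        sp = 0
        genus_no = 0
        family_no = 0
        order_no = 0
        for c in range(config.n_classes):
            class_name = f"Class{_alpha(c, 2)}"
            for _o in range(config.n_orders_per_class):
                order_name = f"Ord{_alpha(order_no, 3)}"
                for _f in range(config.n_families_per_order):
                    family_name = f"Fam{_alpha(family_no, 3)}"
                    for _g in range(config.n_genera_per_family):
                        genus_name = f"Gen{_alpha(genus_no, 4)}".capitalize()
                        for s in range(config.n_species_per_genus):
                            epithet = _alpha(sp, 4) + "ensis"
                            binomial = f"{genus_name} {epithet}"
                            names.append(binomial)
                            lineages.append(
                                Lineage(class_=class_name, order=order_name,
                                        family=family_name, genus=genus_name,
                                        species=binomial)
                            )
                            g_idx.append(genus_no)
                            f_idx.append(family_no)
                            o_idx.append(order_no)
                            c_idx.append(c)
                            sp += 1
                        genus_no += 1
                    family_no += 1
                order_no += 1
        return cls(
            config=config, species_names=names, lineages=lineages,
            sp_genus=np.array(g_idx), sp_family=np.array(f_idx),
            sp_order=np.array(o_idx), sp_class=np.array(c_idx),
        )


@dataclass
class SimRecord:
    """One reference-database record with its ground truth."""

    record_id: str
    true_species: int           # index into the taxonomy
    label: str                  # reported taxon label (possibly wrong)
    labeled_species: int | None  # index of the labelled species, if determined
    error_type: str             # correct | mislabel | undetermined | uncultured


@dataclass
class SimDatabase:
    """A simulated reference database plus flat arrays for fast scoring."""

    taxonomy: SimTaxonomy
    records: list[SimRecord]
    rec_species: np.ndarray
    present_species: np.ndarray  # bool mask over species

    def __len__(self) -> int:
        return len(self.records)


def simulate_reference_db(
    config: SimConfig,
    rng: np.random.Generator | None = None,
    taxonomy: SimTaxonomy | None = None,
    synonyms: SynonymTable | None = None,
    alias_of: dict[int, str] | None = None,
) -> SimDatabase:
    """Generate the reference database part of the simulation truth.

    Each present species gets ``records_per_species`` records; each record is
    independently mislabeled as a congener, left undetermined ("Genus sp."),
    or marked uncultured, per the configured rates. A species is dropped
    entirely (absent from the database) with ``missing_species_rate``.
    ``alias_of`` maps species index → alias binomial; correctly labeled
    records of such species use the alias half the time, exercising synonym
    resolution downstream.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    tax = taxonomy if taxonomy is not None else SimTaxonomy.build(config)
    n_sp = config.n_species
    present = rng.random(n_sp) >= config.missing_species_rate
    records: list[SimRecord] = []
    rec_species: list[int] = []
    t_mis = config.mislabel_rate
    t_und = t_mis + config.undetermined_rate
    t_unc = t_und + config.uncultured_rate
    clone_no = 0
    for sp in range(n_sp):
        if not present[sp]:
            continue
        genus = tax.sp_genus[sp]
        sisters = np.flatnonzero(tax.sp_genus == genus)
        sisters = sisters[sisters != sp]
        if sisters.size == 0:
            fam = tax.sp_family[sp]
            sisters = np.flatnonzero((tax.sp_family == fam) & (tax.sp_genus != genus))
        for k in range(config.records_per_species):
            u = rng.random()
            rid = f"REC{sp:05d}_{k}"
            if u < t_mis and sisters.size:
                swap = int(sisters[rng.integers(sisters.size)])
                records.append(SimRecord(rid, sp, tax.species_names[swap], swap, "mislabel"))
            elif u < t_und:
                records.append(
                    SimRecord(rid, sp, f"{tax.lineages[sp].genus} sp.", None, "undetermined")
                )
            elif u < t_unc:
                clone_no += 1
                records.append(
                    SimRecord(rid, sp, f"uncultured organism clone C{_alpha(clone_no, 4)}",
                              None, "uncultured")
                )
            else:
                label = tax.species_names[sp]
                if alias_of and sp in alias_of and rng.random() < 0.5:
                    label = alias_of[sp]
                records.append(SimRecord(rid, sp, label, sp, "correct"))
            rec_species.append(sp)
    return SimDatabase(
        taxonomy=tax, records=records,
        rec_species=np.array(rec_species, dtype=int),
        present_species=present,
    )


def _distance_index(tax: SimTaxonomy, query_sp: int, rec_species: np.ndarray) -> np.ndarray:
    """0=conspecific ... 4=background for each record vs the query species."""
    d = np.full(rec_species.shape, 4, dtype=int)
    d[tax.sp_order[rec_species] == tax.sp_order[query_sp]] = 3
    d[tax.sp_family[rec_species] == tax.sp_family[query_sp]] = 2
    d[tax.sp_genus[rec_species] == tax.sp_genus[query_sp]] = 1
    d[rec_species == query_sp] = 0
    return d


def _genbank_stats(pident: np.ndarray, length: int, db_size: float):
    nmatch = np.rint(length * pident / 100.0)
    s = nmatch * _REWARD + (length - nmatch) * _PENALTY
    bit = (_LAMBDA * s - math.log(_K)) / math.log(2.0)
    with np.errstate(under="ignore"):
        evalue = db_size * length * np.exp2(-np.clip(bit, -500, None))
    return bit, evalue


def bitscore_for(pident: float, length: int) -> float:
    """Generator bit score at a given percent identity and query length."""
    bit, _ = _genbank_stats(np.array([pident]), length, 1.0)
    return float(bit[0])


def simulate_hit_table(
    query_sp: int,
    query_length: int,
    db: SimDatabase,
    config: SimConfig,
    rng: np.random.Generator,
    dialect: str = "genbank",
    *,
    query_id: str = "Q1",
    locus: str = "",
    run_id: str = "",
) -> HitTable:
    """Score the database against one query and keep the top hits.

    Percent identity per record is drawn from the distance model (truncated
    to [50, 100]) and rounded to two decimals, matching how search engines
    print statistics. With probability ``tie_rate`` the runner-up's
    statistics are copied from the best hit, manufacturing a printed tie.
    An empty database (query species missing, no background) yields an empty
    table — a valid no-match fixture.
    """
    tax = db.taxonomy
    if len(db) == 0:
        return HitTable(query_id=query_id, locus=locus, source_db=dialect, run_id=run_id,
                        query_length=query_length)
    dist = _distance_index(tax, query_sp, db.rec_species)
    means = np.array([config.similarity_model[d][0] for d in DISTANCES])[dist]
    sds = np.array([config.similarity_model[d][1] for d in DISTANCES])[dist]
    pident = np.clip(rng.normal(means, sds), 50.0, 100.0)
    pident = np.round(pident, 2)

    if dialect == "genbank":
        bit, _ = _genbank_stats(pident, query_length, config.db_size_for_evalue)
        # statistics as printed: bit to one decimal, e-value derived from it so
        # printed-equal bit scores carry exactly equal e-values
        bit = np.round(bit, 1)
        with np.errstate(under="ignore"):
            evalue = config.db_size_for_evalue * query_length * np.exp2(-np.clip(bit, -500, None))
        order = np.lexsort((-pident, -bit, evalue))
    else:
        order = np.argsort(-pident, kind="stable")
    top = order[: config.max_hits]

    records: list[HitRecord] = []
    for i in top:
        rec = db.records[i]
        lineage = None
        if dialect == "bold":
            if rec.labeled_species is not None:
                lineage = tax.lineages[rec.labeled_species]
            elif rec.error_type == "undetermined":
                src = tax.lineages[rec.true_species]
                lineage = Lineage(class_=src.class_, order=src.order,
                                  family=src.family, genus=src.genus)
            else:
                lineage = Lineage()
        kwargs: dict = {}
        if dialect == "genbank":
            kwargs = dict(
                percent_identity=float(pident[i]),
                align_length=query_length,
                evalue=float(evalue[i]),
                bitscore=float(bit[i]),
            )
        else:
            kwargs = dict(similarity=float(pident[i]))
        records.append(
            HitRecord(query_id=query_id, subject_id=rec.record_id,
                      subject_label=rec.label, source_db=dialect, run_id=run_id,
                      lineage=lineage, **kwargs)
        )

    if len(records) >= 2 and rng.random() < config.tie_rate:
        best, runner = records[0], records[1]
        records[1] = HitRecord(
            query_id=runner.query_id, subject_id=runner.subject_id,
            subject_label=runner.subject_label, source_db=runner.source_db,
            run_id=runner.run_id, percent_identity=best.percent_identity,
            align_length=runner.align_length, evalue=best.evalue,
            bitscore=best.bitscore, similarity=best.similarity,
            lineage=runner.lineage,
        )

    return HitTable(query_id=query_id, locus=locus, source_db=dialect, run_id=run_id,
                    records=records, query_length=query_length)


@dataclass
class SimQuery:
    specimen_id: str
    locus: str
    species: int
    length: int


def simulate_queries(
    config: SimConfig,
    tax: SimTaxonomy,
    rng: np.random.Generator,
    present: np.ndarray | None = None,
    distinct_species: bool = False,
) -> list[SimQuery]:
    """Draw query specimens (species + per-locus amplicon lengths)."""
    pool = np.flatnonzero(present) if present is not None else np.arange(config.n_species)
    if pool.size == 0:
        raise DataError("no species available for queries")
    replace = not distinct_species or config.n_queries > pool.size
    species = rng.choice(pool, size=config.n_queries, replace=replace)
    queries: list[SimQuery] = []
    for i, sp in enumerate(species):
        sid = f"SP{i:04d}"
        for locus in config.loci:
            if rng.random() < config.mid_fraction:
                length = rng.normal(config.mid_length_mean, config.mid_length_sd)
            else:
                length = rng.normal(config.full_length_mean, config.full_length_sd)
            queries.append(SimQuery(sid, locus, int(sp), max(100, int(round(length)))))
    return queries


def _spawn(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng([seed, *key])


def simulate_study(config: SimConfig, distinct_species: bool = False,
                   queries_from_all_species: bool = False):
    """Generate taxonomy, per-locus databases, queries and hit tables in memory.

    Returns ``(taxonomy, dbs, queries, tables, alias_of)`` where ``dbs`` maps
    locus → :class:`SimDatabase` and ``tables`` is a list of
    :class:`~.hit_io.HitTable` covering every (query, locus, dialect, run).
    """
    tax = SimTaxonomy.build(config)
    alias_of: dict[int, str] = {}
    if config.synonym_rate > 0:
        rng_syn = _spawn(config.seed, 99)
        for sp, name in enumerate(tax.species_names):
            if rng_syn.random() < config.synonym_rate:
                genus, epithet = name.split(" ", 1)
                alias_of[sp] = f"{genus} {epithet}oides"
    dbs: dict[str, SimDatabase] = {}
    for li, locus in enumerate(config.loci):
        dbs[locus] = simulate_reference_db(
            config, _spawn(config.seed, 1, li), tax, alias_of=alias_of
        )
    rng_q = _spawn(config.seed, 2)
    # default: query only species the databases cover (vouchered taxa known
    # to have reference records); opt out to probe missing-species behaviour
    present = None
    if not queries_from_all_species:
        any_present = np.ones(config.n_species, dtype=bool)
        for db in dbs.values():
            any_present &= db.present_species
        present = any_present if any_present.any() else None
    queries = simulate_queries(config, tax, rng_q, present=present,
                               distinct_species=distinct_species)
    tables: list[HitTable] = []
    for li, locus in enumerate(config.loci):
        db = dbs[locus]
        for ri, run in enumerate(config.runs):
            rng_g = _spawn(config.seed, 3, li, ri)
            for q in queries:
                if q.locus != locus:
                    continue
                tables.append(
                    simulate_hit_table(q.species, q.length, db, config, rng_g,
                                       "genbank", query_id=q.specimen_id,
                                       locus=locus, run_id=run)
                )
        rng_b = _spawn(config.seed, 4, li)
        for q in queries:
            if q.locus != locus:
                continue
            tables.append(
                simulate_hit_table(q.species, q.length, db, config, rng_b, "bold",
                                   query_id=q.specimen_id, locus=locus, run_id="ids_all")
            )
    return tax, dbs, queries, tables, alias_of


def restrict_bold_subset(tables: list[HitTable], threshold: float = 96.0,
                         run_id: str = "ids_subset") -> list[HitTable]:
    """Derive a restricted BOLD sequence-subset run from an "all records" run.

    Queries whose top similarity falls below *threshold* return no match in
    the restricted subset — the behaviour observed when searching full/
    public/species-only record subsets instead of all records.
    """
    out = []
    for t in tables:
        best = max((r.similarity for r in t.records if r.similarity is not None),
                   default=None)
        records = [] if (best is None or best < threshold) else [
            HitRecord(query_id=r.query_id, subject_id=r.subject_id,
                      subject_label=r.subject_label, source_db=r.source_db,
                      run_id=run_id, similarity=r.similarity, lineage=r.lineage)
            for r in t.records
        ]
        out.append(HitTable(query_id=t.query_id, locus=t.locus, source_db=t.source_db,
                            run_id=run_id, records=records, query_length=t.query_length))
    return out


_FASTA_ALPHABET = np.array(list("ACGT"))


def generate_study_fixture(config: SimConfig, out_dir, overwrite: bool = False) -> dict:
    """Write a complete on-disk fixture bundle.

    Layout::

        <out_dir>/queries.fasta          random sequences at the drawn lengths
        <out_dir>/genbank/<locus>__<run>.tsv   BLAST outfmt-6 (13 columns)
        <out_dir>/bold/<locus>.csv       BOLD-dialect CSV with rank columns
        <out_dir>/truth.tsv              specimen expected lineages
        <out_dir>/synonyms.csv           alias,canonical pairs (may be empty)
        <out_dir>/config.yaml            the exact config used

    Refuses to write into an existing non-empty directory unless *overwrite*.
    """
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not overwrite:
        raise DataError(f"{out} exists and is not empty (pass overwrite=True)")
    out.mkdir(parents=True, exist_ok=True)
    (out / "genbank").mkdir(exist_ok=True)
    (out / "bold").mkdir(exist_ok=True)

    tax, dbs, queries, tables, alias_of = simulate_study(config)

    rng_seq = _spawn(config.seed, 5)
    with open(out / "queries.fasta", "w") as fh:
        for q in queries:
            seq = "".join(rng_seq.choice(_FASTA_ALPHABET, size=q.length))
            fh.write(f">{q.specimen_id}_{q.locus}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")

    with open(out / "truth.tsv", "w") as fh:
        fh.write("specimen_id\tlocus\tclass\torder\tfamily\tgenus\tspecies\n")
        for q in queries:
            lin = tax.lineages[q.species]
            fh.write("\t".join([q.specimen_id, q.locus, lin.class_, lin.order,
                                lin.family, lin.genus, lin.species]) + "\n")

    with open(out / "synonyms.csv", "w") as fh:
        fh.write("alias,canonical\n")
        for sp in sorted(alias_of):
            fh.write(f"{alias_of[sp]},{tax.species_names[sp]}\n")

    by_file: dict[tuple, list[HitTable]] = {}
    for t in tables:
        key = (t.source_db, t.locus, t.run_id)
        by_file.setdefault(key, []).append(t)

    paths: dict[str, Path] = {
        "queries": out / "queries.fasta", "truth": out / "truth.tsv",
        "synonyms": out / "synonyms.csv", "config": out / "config.yaml",
    }
    for (source_db, locus, run_id), group in sorted(by_file.items()):
        if source_db == "genbank":
            p = out / "genbank" / f"{locus}__{run_id}.tsv"
            with open(p, "w") as fh:
                for t in group:
                    for r in t.records:
                        fh.write("\t".join([
                            t.query_id, r.subject_id, f"{r.percent_identity:.2f}",
                            str(r.align_length), "0", "0", "1", str(r.align_length),
                            "1", str(r.align_length),
                            f"{r.evalue:.3g}" if r.evalue else "0.0",
                            f"{r.bitscore:.1f}", r.subject_label,
                        ]) + "\n")
        else:
            p = out / "bold" / f"{locus}__{run_id}.csv"
            cols = BOLD_DEFAULT_COLUMNS
            with open(p, "w") as fh:
                fh.write(",".join([cols["query_id"], cols["subject_id"], cols["class"],
                                   cols["order"], cols["family"], cols["genus"],
                                   cols["species"], cols["similarity"]]) + "\n")
                for t in group:
                    for r in t.records:
                        lin = r.lineage or Lineage()
                        genus = lin.genus
                        species_ep = ""
                        if lin.species and " " in lin.species:
                            species_ep = lin.species.split(" ", 1)[1]
                        if not genus:
                            # uncultured record: label only
                            genus, species_ep = "", ""
                        fh.write(",".join([
                            t.query_id, r.subject_id, lin.class_, lin.order,
                            lin.family, genus, species_ep, f"{r.similarity:.2f}",
                        ]) + "\n")
        paths[f"{source_db}:{locus}:{run_id}"] = p

    cfg_dict = asdict(config)
    cfg_dict["loci"] = list(config.loci)
    cfg_dict["runs"] = list(config.runs)
    cfg_dict["similarity_model"] = {k: list(v) for k, v in config.similarity_model.items()}
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg_dict, fh, sort_keys=True)
    return paths


def misidentification_oracle(
    config: SimConfig, n_replicates: int = 10_000, seed: int = 12345
) -> float:
    """Independent Monte-Carlo estimate of the species misidentification rate.

    Direct simulation of one query at a time: draw the label-error types and
    percent identities of every database record class (conspecific records
    plus congeneric, confamilial, ordinal and background competitors) and
    declare a misidentification when no correctly-labelled record comes
    within printed-tie distance (0.005 after rounding to two decimals) of
    the best hit. This bypasses the hit-table, tie-policy and classification
    code entirely and serves as the oracle those stages are checked against.
    """
    rng = np.random.default_rng(seed)
    cfg = config
    rps = cfg.records_per_species
    s_g = cfg.n_species_per_genus
    n_con = rps
    n_cog = (s_g - 1) * rps
    n_fam = (cfg.n_genera_per_family - 1) * s_g * rps
    n_ord = (cfg.n_families_per_order - 1) * cfg.n_genera_per_family * s_g * rps
    n_bg = cfg.n_species * rps - (n_con + n_cog + n_fam + n_ord)
    counts = [n_con, n_cog, n_fam, n_ord, max(n_bg, 0)]
    means = [cfg.similarity_model[d][0] for d in DISTANCES]
    sds = [cfg.similarity_model[d][1] for d in DISTANCES]

    misid = 0
    for _ in range(n_replicates):
        scores = []
        correct_mask = []
        for ci, (n, m, s) in enumerate(zip(counts, means, sds)):
            if n == 0:
                continue
            p = np.round(np.clip(rng.normal(m, s, size=n), 50.0, 100.0), 2)
            scores.append(p)
            if ci == 0:
                # conspecific record is correctly labelled unless errored
                u = rng.random(n)
                ok = u >= (cfg.mislabel_rate + cfg.undetermined_rate + cfg.uncultured_rate)
                correct_mask.append(ok)
            elif ci == 1 and s_g > 1:
                # a mislabeled congener picks the query species 1/(s_g-1) of the time
                u = rng.random(n)
                ok = (u < cfg.mislabel_rate) & (rng.random(n) < 1.0 / (s_g - 1))
                correct_mask.append(ok)
            else:
                correct_mask.append(np.zeros(n, dtype=bool))
        scores = np.concatenate(scores)
        correct = np.concatenate(correct_mask)
        best = scores.max()
        if not correct.any() or scores[correct].max() < best - 0.005:
            misid += 1
    return misid / n_replicates
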