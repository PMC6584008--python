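"""Simulator contracts: determinism, error-rate calibration, recovery."""

import hashlib
from collections import Counter
from pathlib import Path

import numpy as np
import pytest

from barcodehits.adjudication import adjudicate_tables
from barcodehits.errors import ConfigError, DataError
from barcodehits.hit_io import TruthTable, read_blast_tabular, read_bold_results, read_query_fasta
from barcodehits.summarize import accuracy_table
from barcodehits.synthetic_data import (
    SimConfig,
    SimTaxonomy,
    bitscore_for,
    generate_study_fixture,
    restrict_bold_subset,
    simulate_hit_table,
    simulate_reference_db,
    simulate_study,
)

SMALL = dict(n_classes=1, n_orders_per_class=2, n_families_per_order=2,
             n_genera_per_family=3, n_species_per_genus=3)

#: near-noiseless similarity model for degenerate-noise scenarios
SHARP = {"conspecific": (99.5, 0.01), "congeneric": (96.0, 0.01),
         "confamilial": (92.0, 0.01), "ordinal": (88.0, 0.01),
         "background": (82.0, 0.01)}


def adjudicated(cfg, tables_filter=None):
    tax, dbs, queries, tables, _ = simulate_study(cfg)

    class _Truth:
        def lookup(self, sid, locus=""):
            for q in queries:
                if q.specimen_id == sid:
                    return tax.lineages[q.species]
            return None

        def lineages(self):
            return tax.lineages

    if tables_filter:
        tables = [t for t in tables if tables_filter(t)]
    cls, skipped = adjudicate_tables(tables, _Truth())
    assert not skipped
    return cls


class TestConfigValidation:
    def test_rates_bounded(self):
        with pytest.raises(ConfigError):
            SimConfig(mislabel_rate=1.5)

    def test_error_mass_cannot_exceed_one(self):
        with pytest.raises(ConfigError):
            SimConfig(mislabel_rate=0.5, undetermined_rate=0.4, uncultured_rate=0.2)

    def test_similarity_means_must_decrease(self):
        bad = dict(SHARP)
        bad["congeneric"] = (99.9, 0.01)
        with pytest.raises(ConfigError):
            SimConfig(similarity_model=bad)


class TestReferenceDb:
    def test_no_errors_when_rates_zero(self):
        cfg = SimConfig(seed=5, mislabel_rate=0, undetermined_rate=0,
                        uncultured_rate=0, **SMALL)
        db = simulate_reference_db(cfg)
        assert all(r.error_type == "correct" for r in db.records)
        assert all(r.label == db.taxonomy.species_names[r.true_species]
                   for r in db.records)

    def test_error_fractions_within_binomial_bounds(self):
        rates = dict(mislabel=0.2, undetermined=0.1, uncultured=0.05)
        cfg = SimConfig(seed=7, records_per_species=36,
                        mislabel_rate=rates["mislabel"],
                        undetermined_rate=rates["undetermined"],
                        uncultured_rate=rates["uncultured"],
                        n_classes=2, n_orders_per_class=3, n_families_per_order=3,
                        n_genera_per_family=4, n_species_per_genus=4)
        db = simulate_reference_db(cfg)
        n = len(db)
        assert n >= 10_000
        counts = Counter(r.error_type for r in db.records)
        for kind, p in [("mislabel", 0.2), ("undetermined", 0.1), ("uncultured", 0.05)]:
            sd = (p * (1 - p) / n) ** 0.5
            assert abs(counts[kind] / n - p) < 3 * sd, kind

    def test_same_seed_identical_database(self):
        cfg = SimConfig(seed=9, **SMALL)
        a = simulate_reference_db(cfg)
        b = simulate_reference_db(cfg)
        assert [(r.record_id, r.label, r.error_type) for r in a.records] == \
               [(r.record_id, r.label, r.error_type) for r in b.records]

    def test_missing_species_dropped_entirely(self):
        cfg = SimConfig(seed=3, missing_species_rate=0.5, **SMALL)
        db = simulate_reference_db(cfg)
        present = set(db.rec_species.tolist())
        absent = set(range(cfg.n_species)) - present
        assert absent  # some species really are missing
        assert np.flatnonzero(~db.present_species).tolist() == sorted(absent)


class TestHitTables:
    def test_degenerate_noise_top_hit_is_conspecific(self, rng):
        cfg = SimConfig(seed=1, similarity_model=SHARP, tie_rate=0,
                        mislabel_rate=0, undetermined_rate=0, uncultured_rate=0,
                        **SMALL)
        db = simulate_reference_db(cfg)
        for sp in range(0, cfg.n_species, 7):
            t = simulate_hit_table(sp, 600, db, cfg, rng)
            top = t.records[0]
            assert db.records[[r.record_id for r in db.records].index(top.subject_id)].true_species == sp

    def test_forced_tie_with_congeneric_runner_up_makes_ambiguous(self):
        cfg = SimConfig(seed=21, records_per_species=1, tie_rate=1.0,
                        mislabel_rate=0, undetermined_rate=0, uncultured_rate=0,
                        similarity_model=SHARP, n_queries=30, **SMALL)
        cls = adjudicated(cfg)
        assert cls and all(c.status == "ambiguous_correct" for c in cls)
        assert all("congeneric" in c.ambiguity_categories for c in cls)

    def test_bitscore_strictly_increases_with_identity(self):
        bits = [bitscore_for(p, 600) for p in range(50, 101)]
        assert all(b2 > b1 for b1, b2 in zip(bits, bits[1:]))

    def test_empty_database_yields_no_match_table(self, rng):
        cfg = SimConfig(seed=2, missing_species_rate=1.0, **SMALL)
        db = simulate_reference_db(cfg)
        assert len(db) == 0
        t = simulate_hit_table(0, 600, db, cfg, rng)
        assert len(t.records) == 0

    def test_max_hits_respected(self, rng):
        cfg = SimConfig(seed=2, max_hits=7, **SMALL)
        db = simulate_reference_db(cfg)
        t = simulate_hit_table(0, 600, db, cfg, rng)
        assert len(t.records) == 7


class TestParameterRecovery:
    def test_clean_database_gives_perfect_species_accuracy(self):
        cfg = SimConfig(seed=31, mislabel_rate=0, undetermined_rate=0,
                        uncultured_rate=0, tie_rate=0, missing_species_rate=0,
                        similarity_model=SHARP, n_queries=60, **SMALL)
        cls = adjudicated(cfg)
        table = accuracy_table(cls, group_keys=("source_db",))
        species = table[table["rank"] == "species"]
        assert (species["percent_correct"] == 100.0).all()

    def test_undetermined_only_database(self):
        cfg = SimConfig(seed=32, mislabel_rate=0, undetermined_rate=1.0,
                        uncultured_rate=0, tie_rate=0, similarity_model=SHARP,
                        n_queries=40, **SMALL)
        cls = adjudicated(cfg)
        table = accuracy_table(cls, group_keys=("source_db",))
        species = table[table["rank"] == "species"]
        genus = table[table["rank"] == "genus"]
        assert (species["percent_correct"] == 0.0).all()
        assert (genus["percent_correct"] == 100.0).all()


class TestFixtureBundle:
    def test_bundle_round_trips_through_readers(self, tmp_path):
        cfg = SimConfig(seed=41, n_queries=10, loci=("rbcL", "matK"),
                        synonym_rate=0.2, **SMALL)
        generate_study_fixture(cfg, tmp_path / "fx")
        lengths = read_query_fasta(tmp_path / "fx" / "queries.fasta")
        assert len(lengths) == 20  # one entry per specimen x locus
        truth = TruthTable.from_tsv(tmp_path / "fx" / "truth.tsv")
        tables = []
        for p in sorted((tmp_path / "fx" / "genbank").glob("*.tsv")):
            locus = p.stem.split("__")[0]
            tables += read_blast_tabular(p, locus=locus)
        for p in sorted((tmp_path / "fx" / "bold").glob("*.csv")):
            locus = p.stem.split("__")[0]
            tables += read_bold_results(p, locus=locus)
        cls, skipped = adjudicate_tables(tables, truth)
        assert not skipped
        assert len(cls) == 40  # 10 specimens x 2 loci x 2 databases

    def test_byte_identical_under_same_seed(self, tmp_path):
        cfg = SimConfig(seed=42, n_queries=6, **SMALL)
        generate_study_fixture(cfg, tmp_path / "a")
        generate_study_fixture(cfg, tmp_path / "b")
        for pa in sorted((tmp_path / "a").rglob("*")):
            if pa.is_file():
                pb = tmp_path / "b" / pa.relative_to(tmp_path / "a")
                assert hashlib.sha256(pa.read_bytes()).hexdigest() == \
                       hashlib.sha256(pb.read_bytes()).hexdigest(), pa.name

    def test_refuses_non_empty_dir_without_overwrite(self, tmp_path):
        cfg = SimConfig(seed=43, n_queries=2, **SMALL)
        out = tmp_path / "fx"
        generate_study_fixture(cfg, out)
        with pytest.raises(DataError):
            generate_study_fixture(cfg, out)
        generate_study_fixture(cfg, out, overwrite=True)  # explicit opt-in

    def test_zero_queries_is_a_valid_empty_bundle(self, tmp_path):
        cfg = SimConfig(seed=44, n_queries=0, **SMALL)
        generate_study_fixture(cfg, tmp_path / "fx")
        truth = (tmp_path / "fx" / "truth.tsv").read_text().splitlines()
        assert len(truth) == 1  # header only

    def test_synonym_aliases_resolve_to_correct(self, tmp_path):
        from barcodehits.taxonomy import SynonymTable
        cfg = SimConfig(seed=45, n_queries=40, synonym_rate=0.5,
                        mislabel_rate=0, undetermined_rate=0, uncultured_rate=0,
                        tie_rate=0, similarity_model=SHARP, **SMALL)
        generate_study_fixture(cfg, tmp_path / "fx")
        syn = SynonymTable.from_csv(tmp_path / "fx" / "synonyms.csv")
        assert len(syn) > 0
        truth = TruthTable.from_tsv(tmp_path / "fx" / "truth.tsv")
        tables = []
        for p in sorted((tmp_path / "fx" / "genbank").glob("*.tsv")):
            tables += read_blast_tabular(p, locus=p.stem.split("__")[0])
        cls, _ = adjudicate_tables(tables, truth, synonyms=syn)
        # alias labels count as the correct species once resolved
        assert all(c.status == "reliable_correct" for c in cls)


def test_restricted_bold_subset_no_matches_low_similarity(rng):
    cfg = SimConfig(seed=51, n_queries=30, missing_species_rate=0.3, **SMALL)
    tax, dbs, queries, tables, _ = simulate_study(cfg)
    bold = [t for t in tables if t.source_db == "bold"]
    subset = restrict_bold_subset(bold, threshold=96.0)
    for before, after in zip(bold, subset):
        best = max((r.similarity for r in before.records), default=None)
        if best is None or best < 96.0:
            assert len(after.records) == 0
        else:
            assert len(after.records) == len(before.records)
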