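"""Shared builders for synthetic hit records and classifications."""

import numpy as np
import pytest

from barcodehits.adjudication import Classification
from barcodehits.hit_io import HitRecord, HitTable
from barcodehits.taxonomy import Lineage


def make_record(label, query_id="Q1", source_db="genbank", subject_id=None,
                pident=99.0, evalue=1e-50, bitscore=1000.0, similarity=None,
                lineage=None, run_id=""):
    if source_db == "bold" and similarity is None:
        similarity = pident
    return HitRecord(
        query_id=query_id, subject_id=subject_id or f"S-{label}",
        subject_label=label, source_db=source_db, run_id=run_id,
        percent_identity=pident if source_db == "genbank" else None,
        evalue=evalue if source_db == "genbank" else None,
        bitscore=bitscore if source_db == "genbank" else None,
        similarity=similarity if source_db == "bold" else None,
        lineage=lineage,
    )


def make_table(records, query_id="Q1", source_db="genbank", locus="COI", run_id=""):
    return HitTable(query_id=query_id, locus=locus, source_db=source_db,
                    run_id=run_id, records=records)


def make_classification(query_id="Q1", status="reliable_correct", locus="COI",
                        source_db="genbank", run_id="", deepest=None,
                        categories=(), similarity=None, candidates=(),
                        truth_species="Aus bus"):
    if deepest is None and status in ("reliable_correct", "ambiguous_correct"):
        deepest = "species"
    return Classification(
        query_id=query_id, locus=locus, source_db=source_db, run_id=run_id,
        status=status, deepest_correct_rank=deepest,
        ambiguity_categories=frozenset(categories), top_similarity=similarity,
        candidates=frozenset(candidates), truth_species=truth_species,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def aus_lineage():
    return Lineage(class_="Insecta", order="Diptera", family="Ausidae",
                   genus="Aus", species="Aus bus")


def random_hit_table(rng, source_db="genbank", max_hits=50, query_id="Q1"):
    """A random table whose statistics are drawn from small discrete pools,
    so printed-equal ties occur often."""
    n = int(rng.integers(1, max_hits + 1))
    evalues = rng.choice([0.0, 1e-60, 1e-50, 1.0000000001e-50, 1e-40, 1e-10], size=n)
    bits = rng.choice([1130.0, 1130.004, 1100.0, 900.0, 500.5], size=n)
    pidents = rng.choice([100.0, 99.84, 99.84, 98.5, 96.0, 90.0], size=n)
    sims = rng.choice([100.0, 99.1, 99.1, 97.0, 95.9, 60.0], size=n)
    records = []
    for i in range(n):
        records.append(
            HitRecord(
                query_id=query_id, subject_id=f"S{i}", subject_label=f"Gen{i} sp{i}",
                source_db=source_db,
                percent_identity=float(pidents[i]) if source_db == "genbank" else None,
                evalue=float(evalues[i]) if source_db == "genbank" else None,
                bitscore=float(bits[i]) if source_db == "genbank" else None,
                similarity=float(sims[i]) if source_db == "bold" else None,
            )
        )
    return make_table(records, source_db=source_db, query_id=query_id)
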