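import numpy as np
import pytest

from bescope import AlleleRow, AlleleTable, RunConfig, TargetSite

# ABE site: protospacer As at 5, 6, 7 (window) and 14, 18 (outside)
PROTO = "CTGCAAACGTCGTACGTACG"
CONTEXT = "GGGGGGGGGG" + PROTO + "AGG" + "TTTTTTT"


@pytest.fixture
def abe_site() -> TargetSite:
    return TargetSite(
        site_id="s1", editor="ABE", context40=CONTEXT,
        chrom="chr1", start=5000, strand="+",
    )


@pytest.fixture
def abe_cfg() -> RunConfig:
    return RunConfig(editor="ABE")


def make_table(rows, reference=CONTEXT, site_id="s1", replicate_id="r1"):
    return AlleleTable(
        site_id=site_id, replicate_id=replicate_id, reference=reference,
        rows=[AlleleRow(**r) if isinstance(r, dict) else r for r in rows],
    )


def edited(reference: str, edits: dict[int, str]) -> str:
    """Apply {0-based reference index: base} substitutions ('-' deletes)."""
    seq = list(reference)
    for i, b in edits.items():
        seq[i] = b
    return "".join(seq)


def edit_at_position(reference: str, positions, base="G", offset=10) -> str:
    """Substitute at 1-based protospacer positions."""
    return edited(reference, {offset + p - 1: base for p in np.atleast_1d(positions)})


@pytest.fixture
def random_tables(abe_site, abe_cfg):
    """Small random allele tables for oracle-equivalence checks."""
    rng = np.random.default_rng(42)
    tables = []
    for _ in range(5):
        rows = []
        for _ in range(rng.integers(2, 10)):
            seq = list(CONTEXT)
            # random substitutions
            for _ in range(rng.integers(0, 4)):
                i = int(rng.integers(0, 40))
                seq[i] = "ACGT"[rng.integers(0, 4)]
            # occasional deletion
            if rng.random() < 0.3:
                seq[int(rng.integers(10, 30))] = "-"
            insertions = ()
            if rng.random() < 0.2:
                insertions = ((int(rng.integers(10, 30)), "A"),)
            rows.append(
                AlleleRow(
                    aligned="".join(seq),
                    n_reads=int(rng.integers(1, 500)),
                    insertions=insertions,
                    n_deleted="".join(seq).count("-"),
                    n_inserted=len(insertions),
                )
            )
        tables.append(make_table(rows))
    return tables
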