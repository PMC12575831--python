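import pathlib

import pandas as pd
import pytest

from psidelta import core_io, psi_calling
from psidelta.synthetic_data import make_fixture


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory) -> pathlib.Path:
    """One complete synthetic fixture shared by integration tests."""
    d = tmp_path_factory.mktemp("fixture")
    make_fixture(d, seed=11)
    return d


@pytest.fixture(scope="session")
def fixture_truth(fixture_dir) -> pd.DataFrame:
    df = pd.read_csv(fixture_dir / "truth_psi.tsv", sep="\t")
    df["decoy_class"] = df["decoy_class"].fillna("")
    return df


@pytest.fixture(scope="session")
def ctrl_called(fixture_dir, fixture_truth):
    """Sites called on the fixture's control condition, fully annotated."""
    counts = pd.concat(
        [
            core_io.read_pileup_counts(p)
            for p in sorted(fixture_dir.glob("pileup_ctrl_*.tsv"))
        ],
        ignore_index=True,
    )
    libs = psi_calling.LibrarySet(
        "ctrl",
        tuple(f"ctrl_bs_{i}" for i in (1, 2, 3)),
        tuple(f"ctrl_in_{i}" for i in (1, 2, 3)),
    )
    seqs = core_io.SequenceStore.from_fasta(fixture_dir / "genome.fa")
    models = core_io.read_gene_models(fixture_dir / "genes.gtf")
    sites = psi_calling.call_sites(counts, libs, seqs=seqs, gene_models=models)
    return psi_calling.annotate_sites(sites, seqs=seqs, models=models)


def make_counts(rows) -> pd.DataFrame:
    """Build a SiteCounts frame from (chrom, pos0, ref, depth, del, lib) tuples."""
    return pd.DataFrame(
        rows, columns=["chrom", "pos0", "ref_base", "depth", "del_count", "library_id"]
    )
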