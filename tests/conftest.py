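from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from mockbias.mock_design import CommunityProfile
from mockbias.profile_io import AbundanceTable

REPO_ROOT = Path(__file__).resolve().parent.parent

#: Local assembly store for the genome-level checks. Populated by
#: ``scripts/fetch_assemblies.py`` (requires network); the genome-level
#: acceptance tests fail with a pointer to that script when it is empty.
ASSEMBLY_DIR = REPO_ROOT / "data" / "assemblies"


@pytest.fixture
def two_strain_profile() -> CommunityProfile:
    return CommunityProfile(["a", "b"], [0.25, 0.75])


@pytest.fixture
def five_strain_profile() -> CommunityProfile:
    return CommunityProfile(
        ["s1", "s2", "s3", "s4", "s5"], [0.1, 0.2, 0.3, 0.25, 0.15]
    )


@pytest.fixture
def small_table() -> AbundanceTable:
    df = pd.DataFrame(
        [[9000, 1000], [500, 1500]],
        index=["samp1", "samp2"],
        columns=["taxA", "taxB"],
        dtype=np.int64,
    )
    return AbundanceTable(df)


def assembly_path(accession: str, suffix: str) -> Path:
    """Path of a locally stored assembly file (.fna or .gff)."""
    return ASSEMBLY_DIR / f"{accession}.{suffix}"


def require_assembly(accession: str, suffix: str) -> Path:
    path = assembly_path(accession, suffix)
    if not path.exists():
        pytest.fail(
            f"assembly file {path} is absent. Genome-level checks need the "
            "public assemblies downloaded once with "
            "`python scripts/fetch_assemblies.py` (network required); this "
            "environment has no route to the assembly archive.",
            pytrace=False,
        )
    return path
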