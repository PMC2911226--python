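import warnings
from pathlib import Path

import numpy as np
import pytest

from cycloscan import synthdata
from cycloscan.energy import EnergyModel
from cycloscan.peptide import build_peptide

DATA_DIR = Path(__file__).resolve().parent.parent / "data" / "structures"

#: varied sequence so alignments place gaps unambiguously
CHAIN160 = ("ACDEFGHIKLMNPQRSTVWY" * 8)


def structure_file(accession: str) -> Path:
    """Path to a locally provided deposited structure, or skip."""
    for ext in (".pdb", ".cif"):
        p = DATA_DIR / f"{accession.lower()}{ext}"
        if p.exists():
            return p
    pytest.skip(
        f"accession-gated: {accession} not available offline "
        f"(place {accession.lower()}.pdb under data/structures/)"
    )


@pytest.fixture(scope="session")
def model():
    return EnergyModel()


@pytest.fixture(scope="session")
def aromatic_scene():
    cfg = synthdata.SCENARIOS["aromatic-S2"]
    receptor, truth = synthdata.make_toy_receptor(cfg)
    site_map = synthdata.toy_active_site_map(receptor)
    template = synthdata.make_template_complex(cfg)
    return {
        "config": cfg, "receptor": receptor, "truth": truth,
        "map": site_map, "template": template,
    }


@pytest.fixture(scope="session")
def occluded_scene():
    cfg = synthdata.SCENARIOS["occluded"]
    receptor, truth = synthdata.make_toy_receptor(cfg)
    site_map = synthdata.toy_active_site_map(receptor)
    template = synthdata.make_template_complex(cfg)
    return {
        "config": cfg, "receptor": receptor, "truth": truth,
        "map": site_map, "template": template,
    }


@pytest.fixture(scope="session")
def chain160():
    """A 160-residue extended chain with a non-repetitive sequence."""
    return build_peptide(CHAIN160).structure


@pytest.fixture(autouse=True)
def _silence_placement_warnings():
    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message="initial P2/P3 placement clashes"
        )
        yield


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
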