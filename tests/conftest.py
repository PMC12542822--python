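import numpy as np
import pytest

from phoskit import Design, PsmRecord, SimConfig, generate_phospho_dataset


@pytest.fixture(scope="session")
def design6() -> Design:
    return Design.two_group(3)


@pytest.fixture(scope="session")
def small_dataset():
    """A small simulated 6-plex phospho dataset shared across tests."""
    return generate_phospho_dataset(SimConfig(seed=11, n_proteins=60))


def make_psm(
    psm_id="1",
    seq="AASAK",
    mod=None,
    group="P1",
    pep=0.001,
    intensities=None,
    sites=None,
    decoy=False,
    contaminant=False,
) -> PsmRecord:
    return PsmRecord(
        psm_id=psm_id,
        peptide_sequence=seq,
        modified_sequence=mod if mod is not None else f"_{seq}(ph)_",
        protein_group_id=group,
        pep=pep,
        reporter_intensities=np.asarray(
            intensities if intensities is not None else [100.0] * 6, dtype=float
        ),
        site_probabilities=sites if sites is not None else {},
        is_decoy=decoy,
        is_contaminant=contaminant,
    )
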