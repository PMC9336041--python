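import warnings

import numpy as np
import pandas as pd
import pytest

from tmistrat.simulate import (
    PlantedCutoff,
    PlantedGene,
    PlantedUShape,
    SimConfig,
    make_fixture_suite,
    simulate_cohort,
    tiny_cohort,
)


@pytest.fixture(scope="session")
def fixtures():
    """The standard named simulated cohorts (regenerated once per session)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return make_fixture_suite()


@pytest.fixture()
def tiny():
    return tiny_cohort()


@pytest.fixture(scope="session")
def null_cohort(fixtures):
    return fixtures["null"]


@pytest.fixture(scope="session")
def single_cutoff_cohort(fixtures):
    return fixtures["single_cutoff"]


@pytest.fixture(scope="session")
def u_shape_cohort(fixtures):
    return fixtures["u_shape"]


@pytest.fixture(scope="session")
def gene_cohort(fixtures):
    return fixtures["unfavourable_gene"]


def simulate(seed, **kwargs):
    """Convenience: simulate quietly with keyword overrides."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return simulate_cohort(SimConfig(seed=seed, **kwargs))


@pytest.fixture()
def clinical_tsv(tmp_path):
    """A small hand-written clinical TSV exercising the reader vocabulary."""
    text = (
        "patient_id\tarm\tcohort\tsex\tsmoking\thistology\tdriver_gene\t"
        "metastasis_sites\tos_months\tos_event\tpfs_months\tpfs_event\tbest_response\n"
        "P1\tdocetaxel\tdiscovery\tFEMALE\tsmoker\tLUSC\tnegative\t1\t10.5\t1\t4.2\t1\tPR\n"
        "P2\tDocetaxel\tdiscovery\tmale\tnon_smoker\tnon_LUSC\tpositive\t3\t8.0\t0\t3.0\t1\tSD\n"
        "P3\tatezolizumab\tdiscovery\tmale\tex-smoker\tlusc\tnegative\t5\t20.0\t1\t6.0\t0\tPD\n"
    )
    path = tmp_path / "clinical.tsv"
    path.write_text(text)
    return path


@pytest.fixture()
def mutations_tsv(tmp_path):
    text = (
        "patient_id\tgene\teffect\n"
        "P1\tTP53\tmissense\n"
        "P1\tKRAS\tsynonymous\n"
        "P2\tEGFR\tsplice\n"
        "P2\tTP53\tnonsense\n"
        "P9\tBRAF\tmissense\n"  # orphan: no clinical row
    )
    path = tmp_path / "mutations.tsv"
    path.write_text(text)
    return path


@pytest.fixture()
def maf_tsv(tmp_path):
    text = (
        "Tumor_Sample_Barcode\tHugo_Symbol\tVariant_Classification\n"
        "P1\tTP53\tMissense_Mutation\n"
        "P1\tKRAS\tSilent\n"
        "P2\tEGFR\tSplice_Site\n"
        "P2\tSTK11\tNonsense_Mutation\n"
        "P2\tKEAP1\tIn_Frame_Del\n"
    )
    path = tmp_path / "mutations.maf"
    path.write_text(text)
    return path
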