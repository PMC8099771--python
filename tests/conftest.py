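"""Shared fixtures: synthetic pedigrees and small simulated cohorts."""

from __future__ import annotations

import numpy as np
import pytest

from pedmut.records import Pedigree, Trio
from pedmut.simulate import SimulationConfig, simulate_dataset


def build_study_pedigree() -> Pedigree:
    """Synthetic 19-trio pedigree emulating the study design.

    Two families (one with 2 reproductive males and 4 females, one with 1
    male and 7 females), two second-generation trios, paternal ages within
    10.0-14.5 years and maternal ages within 3.5-15.7 years.
    """
    sex = {}
    trios = []

    def add(father, mother, child, age_p, age_m, family, child_sex):
        for ind, s in ((father, "M"), (mother, "F"), (child, child_sex)):
            sex.setdefault(ind, s)
        trios.append(Trio(father, mother, child, age_p, age_m, family=family))

    # family A: 2 reproductive males, 4 reproductive females, 2 extended trios
    add("FA1", "MA1", "A1", 10.0, 3.5, "A", "F")
    add("FA1", "MA2", "A2", 10.5, 4.6, "A", "F")
    add("FA1", "MA3", "A3", 11.0, 5.5, "A", "M")
    add("FA2", "MA3", "A4", 11.5, 6.4, "A", "M")
    add("FA2", "MA4", "A5", 12.0, 7.3, "A", "F")
    add("FA1", "MA1", "A6", 12.5, 8.2, "A", "M")
    add("FA2", "A1", "G1", 13.0, 9.1, "A", "F")  # second generation
    add("FA2", "A2", "G2", 13.5, 10.0, "A", "M")  # second generation
    # family B: 1 reproductive male, 7 reproductive females
    add("FB1", "MB1", "B1", 14.0, 10.9, "B", "M")
    add("FB1", "MB2", "B2", 14.5, 11.8, "B", "F")
    add("FB1", "MB3", "B3", 12.4, 12.7, "B", "M")
    add("FB1", "MB4", "B4", 12.0, 13.6, "B", "F")
    add("FB1", "MB5", "B5", 13.2, 14.5, "B", "M")
    add("FB1", "MB6", "B6", 11.8, 15.7, "B", "F")
    add("FB1", "MB7", "B7", 12.6, 6.0, "B", "M")
    add("FB1", "MB1", "B8", 13.8, 7.0, "B", "F")
    add("FB1", "MB2", "B9", 14.2, 8.0, "B", "M")
    add("FB1", "MB3", "B10", 12.9, 9.0, "B", "F")
    add("FB1", "MB4", "B11", 11.3, 11.0, "B", "M")
    return Pedigree(sex=sex, trios=trios)


@pytest.fixture(scope="session")
def study_pedigree() -> Pedigree:
    return build_study_pedigree()


@pytest.fixture(scope="session")
def halfsib_pedigree() -> Pedigree:
    """Four trios giving both paternal and maternal half-sibling pairs."""
    sex = {"F1": "M", "F2": "M", "M1": "F", "M2": "F",
           "C1": "M", "C2": "F", "C3": "M", "C4": "F"}
    trios = [
        Trio("F1", "M1", "C1", 12.0, 8.0),
        Trio("F1", "M2", "C2", 13.0, 9.0),
        Trio("F2", "M1", "C3", 11.0, 7.0),
        Trio("F2", "M2", "C4", 12.5, 8.5),
    ]
    return Pedigree(sex=sex, trios=trios)


@pytest.fixture(scope="session")
def small_cohort(halfsib_pedigree):
    """A 60 kb four-trio cohort with all event types planted."""
    config = SimulationConfig(
        genome_length=60_000,
        seed=42,
        error_mv_rate=2e-4,  # enough spurious violations to exercise filters
        mosaic_sharing_rate=0.2,
    )
    return simulate_dataset(config, halfsib_pedigree)
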