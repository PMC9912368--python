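import numpy as np
import pandas as pd
import pytest

from phenotyper import codelist, synthetic


@pytest.fixture(scope="session")
def fixture_dictionaries():
    return synthetic.fixture_dictionaries()


@pytest.fixture(scope="session")
def master_dict(fixture_dictionaries):
    return codelist.build_master_dictionary(fixture_dictionaries)


@pytest.fixture(scope="session")
def dm_codelist():
    cl = codelist.Codelist(outcome_id="DM")
    for system, code, role in synthetic.FIXTURE_CODELISTS["DM"]:
        cl.add(codelist.ClinicalCode(system, code, ""), codelist.Role(role))
    return cl


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_events(rows):
    """Helper: build an event table from (pid, source, system, code, date, valid[, role])."""
    frame = pd.DataFrame(
        [r[:6] for r in rows],
        columns=["participant_id", "source", "system", "code", "event_date", "valid"],
    )
    frame["event_date"] = pd.to_datetime(frame["event_date"])
    frame["invalid_reason"] = ""
    if rows and len(rows[0]) > 6:
        frame["role"] = [r[6] for r in rows]
    return frame
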