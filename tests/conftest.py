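import sys
from pathlib import Path

import pytest
from hypothesis import settings

sys.path.insert(0, str(Path(__file__).parent))

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture
def toy_tnt() -> str:
    return (
        "xread\n"
        "'toy matrix'\n"
        "3 4\n"
        "A 000\n"
        "B 011\n"
        "C 101\n"
        "D 110\n"
        ";\n"
        "proc /;\n"
    )


@pytest.fixture
def vasuki_like_specimen():
    """A mid-trunk vertebra at the large end of the madtsoiid size range."""
    from paleosnake.morphometrics import VertebraSpecimen

    return VertebraSpecimen(
        specimen_id="MTV-max",
        lengths_mm={"cL": 62.7, "prW": 111.4, "coW": 12.0, "coH": 10.0},
        flags={"chisel_process_present": True},
    )
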