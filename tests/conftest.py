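import pytest

from crctnm.corpus import ClinicalReport
from crctnm.context import default_trigger_rules
from crctnm.crc import default_crc_lexicons


@pytest.fixture
def make_report():
    def _make(text, report_id="r1", report_type="pathology"):
        return ClinicalReport(report_id=report_id, report_type=report_type,
                              text=text)

    return _make


@pytest.fixture(scope="session")
def trigger_rules():
    return default_trigger_rules()


@pytest.fixture(scope="session")
def crc_lexicons():
    return default_crc_lexicons()
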