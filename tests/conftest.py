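import numpy as np
import pytest

from cxrnlp.corpus import Report
from cxrnlp.lexicon import default_lexicon


@pytest.fixture(scope="session")
def lexicon():
    return default_lexicon()


def make_report(i, *, encounter=None, text="Lungs are clear.", age=24, disposition="discharged", acquired="2010-06-01T10:00:00"):
    return Report(
        report_id=f"r{i:05d}",
        encounter_id=encounter or f"e{i:05d}",
        acquired_at=acquired,
        age_months=age,
        disposition=disposition,
        text=text,
    )


@pytest.fixture
def random_reports():
    """Factory for lightweight random corpora (no text generation)."""

    def _make(n, seed=0, admitted_rate=0.4):
        rng = np.random.default_rng(seed)
        return [
            make_report(
                i,
                age=int(rng.integers(3, 217)),
                disposition="admitted" if rng.random() < admitted_rate else "discharged",
                acquired=f"2010-0{1 + int(rng.integers(9))}-01T0{int(rng.integers(10))}:00:00",
            )
            for i in range(n)
        ]

    return _make
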