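import numpy as np
import pytest
from hypothesis import settings

from sdrwatch import synthetic

settings.register_profile("default", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_study():
    """A small planted-signal study shared across tests (read-only)."""
    cfg = synthetic.SimConfig(
        n_study_drugs=2,
        n_background_drugs=18,
        n_events=20,
        start_month="2010-01",
        end_month="2011-12",
        baseline_rate=0.12,
        seed=5,
    )
    cfg = synthetic.plant_signals(
        cfg, n_signals=6, relative_rate=8.0, onset_month="2010-07", forum_lead_months=-3
    )
    stream, truth = synthetic.generate_streams(cfg)
    terminology = synthetic.build_terminology(cfg.pt_codes)
    lexicon, form_types = synthetic.build_lexicon(cfg.drug_ids)
    occurrences = synthetic.stream_to_occurrences(stream, terminology)
    return {
        "config": cfg,
        "stream": stream,
        "truth": truth,
        "terminology": terminology,
        "lexicon": lexicon,
        "form_types": form_types,
        "occurrences": occurrences,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
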