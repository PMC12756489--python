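import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import srflex

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def toy_lexicon():
    return srflex.packaged_lexicon()


@pytest.fixture(scope="session")
def mini_lexicon():
    """Two-category compiled lexicon used by hand-traceable matcher tests."""
    import io

    src = io.StringIO(
        "category_id\tlabel\tphrase\n"
        "hopelessness\tHopelessness\tno hope\n"
        "hopelessness\tHopelessness\thopeless\n"
        "loneliness\tLoneliness\tall alone\n"
        "loneliness\tLoneliness\talone\n"
    )
    return srflex.compile_lexicon(srflex.load_lexicon(src))


@pytest.fixture(scope="session")
def small_corpus(toy_lexicon):
    """400 rendered synthetic sessions plus ground truth (seeded)."""
    config = srflex.default_config(toy_lexicon, n_sessions=400, seed=11)
    return srflex.generate_corpus(config, toy_lexicon)


def make_session(hs_texts, counselor_texts=(), session_id="s1", **meta):
    """Interleave help-seeker and counselor messages into a session."""
    msgs = []
    counselor_texts = list(counselor_texts)
    for i, t in enumerate(hs_texts):
        msgs.append(srflex.Message("help_seeker", t))
        if i < len(counselor_texts):
            msgs.append(srflex.Message("counselor", counselor_texts[i]))
    return srflex.ChatSession(session_id, msgs, **meta)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
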