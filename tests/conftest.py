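import pytest

from catgait.features import default_registry
from catgait.footfalls import Footfall, Paw, Run
from catgait.synthetic import GaitTemplate, generate_run


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture()
def template():
    return GaitTemplate()


@pytest.fixture()
def perfect_run(template):
    """Noise-free, perfectly patterned generator run (AB stepping)."""
    return generate_run(template, run_id="perfect")


def make_run(placements, run_id="r", frame_rate=100.0):
    """Build a run from (paw, t_contact, t_release, t_max, x, y) tuples."""
    records = [
        Footfall(paw=Paw(p), t_contact=tc, t_release=tr, t_max_contact=tm, x=x, y=y)
        for p, tc, tr, tm, x, y in placements
    ]
    return Run(run_id=run_id, records=records, frame_rate=frame_rate)


def simple_paw_run(paw, contacts, run_id="r"):
    """Single-paw run from (t_contact, t_release) pairs at fixed geometry."""
    return make_run(
        [(paw, tc, tr, tc, 0.0, 0.0) for tc, tr in contacts], run_id=run_id
    )
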