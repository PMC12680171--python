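import numpy as np
import pytest

import assemblyreaders as ar


@pytest.fixture(scope="session")
def planted_session():
    """One 10-min two-structure session with three planted assemblies and a
    collective, an independent and a coincidence reader per assembly."""
    cfg = ar.default_config(
        seed=401, duration_s=600.0, n_assemblies=3,
        reader_modes=("collective", "independent", "coincidence"),
    )
    spikes, epochs, truth = ar.generate_session(cfg)
    return {"config": cfg, "spikes": spikes, "epochs": epochs, "truth": truth}


@pytest.fixture(scope="session")
def detected(planted_session):
    """Detection results on the planted session, with models matched to the
    planted member sets."""
    spikes = planted_session["spikes"]
    epochs = planted_session["epochs"]
    truth = planted_session["truth"]
    A = spikes.subset(spikes.units_in("A"))
    models = ar.detect(A, epochs, seed=401)
    by_planted = {}
    for pi, members in enumerate(truth.members):
        for m in models:
            if set(int(u) for u in m.members) == set(members):
                by_planted[pi] = m
    return {"models": models, "by_planted": by_planted}


@pytest.fixture(scope="session")
def first_assembly(planted_session, detected):
    """The detected model matching planted assembly 0, with its activation
    events and the planted readers for it."""
    assert 0 in detected["by_planted"], "planted assembly 0 not recovered"
    model = detected["by_planted"][0]
    spikes = planted_session["spikes"]
    events = ar.activation_events(spikes, model, planted_session["epochs"])
    truth = planted_session["truth"]
    readers = {
        r["mode"]: r["unit"] for r in truth.readers if r["assembly"] == 0
    }
    return {"model": model, "events": events, "readers": readers}


def poisson_train(rate_hz: float, duration_s: float, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    return np.sort(rng.uniform(0.0, duration_s, rng.poisson(rate_hz * duration_s)))
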