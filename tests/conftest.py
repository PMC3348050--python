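import logging

import pytest

import cocktailnet as ck


@pytest.fixture(scope="session")
def toy_bundle(tmp_path_factory):
    """The hand-computed worked toy bundle, written once per session."""
    outdir = tmp_path_factory.mktemp("toy_bundle")
    return ck.worked_toy_bundle(outdir)


@pytest.fixture(scope="session")
def toy_data(toy_bundle):
    """Ingested toy bundle: network, drugs, combinations, pathways."""
    net = ck.read_genetic_interactions(toy_bundle.interactions)
    drugs = ck.read_drugs(toy_bundle.targets, toy_bundle.atc)
    combos = ck.read_combinations(toy_bundle.combinations)
    kept = ck.filter_combinations(combos, drugs)
    pathways = ck.read_pathways(toy_bundle.pathways)
    return {
        "net": net,
        "drugs": drugs,
        "combos_all": combos,
        "combos": kept,
        "pathways": pathways,
        "manifest": toy_bundle.manifest,
    }


@pytest.fixture(autouse=True)
def _capture_logs(caplog):
    caplog.set_level(logging.INFO)
    return caplog
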