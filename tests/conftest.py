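from dataclasses import dataclass

import pytest

import ppiref
from ppiref.annotation import load_expression, presence_calls
from ppiref.scoring import load_reliability_table


@dataclass
class FixtureCtx:
    """A generated input set loaded through every reader."""

    manifest: dict
    idmap: ppiref.IdMap
    bundles: dict
    report: object
    scored: list
    net: ppiref.PPINetwork
    calls: object
    truth: dict | None = None


def _load(manifest, truth=None, roles=None):
    files = manifest["files"]
    idmap = ppiref.IdMap.from_tsv(files["idmap"])
    table = ppiref.load_interolog_table(files["interologs"])
    bundles, report = ppiref.ingest(files["mitab"], idmap, table)
    config = ppiref.ScoreConfig(
        reliability=load_reliability_table(files["reliability"])
    )
    scored = ppiref.rescore(bundles, config)
    net = ppiref.build_network(scored, idmap=idmap, roles=roles)
    calls = presence_calls(load_expression(files["expression"]))
    return FixtureCtx(manifest, idmap, bundles, report, scored, net, calls, truth)


@pytest.fixture(scope="session")
def hippo(tmp_path_factory) -> FixtureCtx:
    outdir = tmp_path_factory.mktemp("hippo")
    manifest = ppiref.hippo_fixture(outdir)
    roles = ppiref.RegulatoryRoles.from_tsv(
        manifest["files"]["receptors"], manifest["files"]["tfs"]
    )
    return _load(manifest, roles=roles)


@pytest.fixture(scope="session")
def corpus(tmp_path_factory) -> FixtureCtx:
    import json
    from pathlib import Path

    outdir = tmp_path_factory.mktemp("corpus")
    spec = ppiref.FixtureSpec(seed=7)
    manifest = ppiref.generate_corpus(spec, outdir)
    truth = json.loads(Path(manifest["files"]["truth"]).read_text())
    return _load(manifest, truth=truth)
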