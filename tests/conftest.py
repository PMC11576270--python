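"""Shared fixtures: synthetic databases at the scales the checks need.

Session-scoped databases are generated once and reused; each bundles the
emitted files, the ground-truth ledger, the typed records and the
deduplicated (case, PT) pair universe.
"""

from __future__ import annotations

from types import SimpleNamespace

import pytest
from hypothesis import HealthCheck, settings

from faerspv import cohort, pipeline
from faerspv.synthetic import GeneratorConfig, generate_database

settings.register_profile(
    "suite", derandomize=True, deadline=None, max_examples=200,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")

FOCAL_NAMES = ("TIRZEPATIDE", "MOUNJARO", "ZEPBOUND")


def build_db(out_dir, config: GeneratorConfig) -> SimpleNamespace:
    """Generate a database and load it back through the package readers."""
    gt = generate_database(config, out_dir)
    demo, drugs, reacs, malformed = pipeline.load_database(out_dir)
    dedup = cohort.deduplicate(demo)
    pt_soc = cohort.load_pt_soc_map(out_dir / "pt_soc_map.txt")
    pairs = cohort.build_case_pt_pairs(
        demo, drugs, reacs, dedup.kept_primaryids, FOCAL_NAMES,
        pt_soc_map=pt_soc, focal_only=False)
    return SimpleNamespace(dir=out_dir, config=config, gt=gt, demo=demo,
                           drugs=drugs, reacs=reacs, dedup=dedup,
                           pt_soc=pt_soc, pairs=pairs, malformed=malformed)


@pytest.fixture(scope="session")
def small_db(tmp_path_factory):
    """Default study conditions at modest scale for structural checks."""
    cfg = GeneratorConfig(n_reports=3000, seed=11)
    return build_db(tmp_path_factory.mktemp("small_db"), cfg)


@pytest.fixture(scope="session")
def mid_db(tmp_path_factory):
    """Default study conditions at n=10,000 for marginal-calibration checks."""
    cfg = GeneratorConfig(n_reports=10_000, seed=13)
    return build_db(tmp_path_factory.mktemp("mid_db"), cfg)


@pytest.fixture(scope="session")
def planted_db(tmp_path_factory):
    """n=50,000 with a single planted reporting-rate ratio of 5 on
    (focal drug, NAUSEA)."""
    cfg = GeneratorConfig(n_reports=50_000, seed=42,
                          planted_rr={("TIRZEPATIDE", "NAUSEA"): 5.0})
    return build_db(tmp_path_factory.mktemp("planted_db"), cfg)


@pytest.fixture(scope="session")
def null_db(tmp_path_factory):
    """n=50,000 with no planted signals: drug and event independent."""
    cfg = GeneratorConfig(n_reports=50_000, seed=77, planted_rr={})
    return build_db(tmp_path_factory.mktemp("null_db"), cfg)


@pytest.fixture(scope="session")
def sexrr_db(tmp_path_factory):
    """n=50,000 with a female-only reporting-rate multiplier of 8 on
    (focal drug, INJECTION SITE RASH) and nothing else planted."""
    cfg = GeneratorConfig(
        n_reports=50_000, seed=99, planted_rr={},
        sex_specific_rr={("TIRZEPATIDE", "INJECTION SITE RASH", "F"): 8.0})
    return build_db(tmp_path_factory.mktemp("sexrr_db"), cfg)
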