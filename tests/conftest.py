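import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def demo_study():
    """One synthetic demo study shared across the session."""
    from netpharm.synthetic import gen_study

    return gen_study(7)


@pytest.fixture(scope="session")
def demo_run(demo_study, tmp_path_factory):
    """A persisted demo study plus a completed pipeline run."""
    import yaml

    from netpharm.pipeline import PipelineConfig, run
    from netpharm.synthetic import write_study

    base = tmp_path_factory.mktemp("study")
    out = tmp_path_factory.mktemp("run")
    manifest = write_study(demo_study, base)
    cfg = PipelineConfig.model_validate(
        {
            "seed": 7,
            "drug_sources": manifest["drug_sources"],
            "disease_sources": manifest["disease_sources"],
            "association_network": manifest["association_network"],
            "ppi_network": manifest["ppi_network"],
            "libraries": manifest["libraries"],
            "tf_library": manifest["tf_library"],
        }
    )
    (base / "config.yaml").write_text(yaml.safe_dump(cfg.model_dump(), sort_keys=True))
    report = run(cfg, base, out)
    return {"study": demo_study, "cfg": cfg, "base": base, "out": out, "report": report}
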