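import logging

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

logging.getLogger("transelect").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_panel(tmp_path_factory):
    """A compact 4-species synthetic panel, generated once and written out."""
    from transelect.synthetic_data import PanelConfig, generate_panel

    config = PanelConfig(seed=7, n_species=4, n_heg=25, n_rest=120,
                         gc_targets=(45.0, 50.0, 55.0, 60.0))
    out = tmp_path_factory.mktemp("panel")
    records, manifest = generate_panel(config, out_dir=out)
    return {"config": config, "records": records, "manifest": manifest,
            "dir": out}


@pytest.fixture(scope="session")
def parsed_species(small_panel):
    """The rank-1 genome of the small panel, parsed and classified."""
    from transelect.genome_io import classify_expression, parse_genbank

    genome = parse_genbank(small_panel["dir"] / "species_R1.gb", rank_gt=1)
    classify_expression(genome.cds)
    return genome
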