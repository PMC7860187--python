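import pytest

from umiamp.panel import toy_panel
from umiamp.pipeline import quantify_library
from umiamp.readproc import PanelAligner
from umiamp.simulate import SimulationConfig, amplify_and_sequence, simulate_molecules


@pytest.fixture(scope="session")
def panel():
    return toy_panel()


@pytest.fixture(scope="session")
def aligner(panel):
    return PanelAligner(panel)


@pytest.fixture(scope="session")
def mut_library(panel, aligner, tmp_path_factory):
    """A small simulated library with a planted 20% molecular AF, quantified."""
    td = tmp_path_factory.mktemp("mutlib")
    cfg = SimulationConfig(
        panel=panel,
        seed=424242,
        n_molecules_per_gene={g: 250 for g in panel.gene_names},
        planted_af={panel.hotspots[0].label: 0.20},
        library_size=1500,
        seq_error_rate=0.001,
    )
    gt = simulate_molecules(cfg)
    r1, r2 = td / "R1.fastq.gz", td / "R2.fastq.gz"
    amplify_and_sequence(cfg, gt, r1, r2, td / "prov.tsv")
    res = quantify_library(r1, r2, panel, seed=cfg.seed, library_id="mutlib", aligner=aligner)
    return {"result": res, "truth": gt, "cfg": cfg, "r1": r1, "r2": r2}
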