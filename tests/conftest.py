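import pytest

from endomir import SimConfig, endosperm_truth_set, simulate_experiment
from endomir.preprocess import preprocess_fastq


@pytest.fixture(scope="session")
def clean_experiment(tmp_path_factory):
    """Zero-background simulated experiment: 8 hairpins, 2 tandem, 20k reads."""
    outdir = tmp_path_factory.mktemp("clean_sim")
    truths = endosperm_truth_set(n_hairpins=8, n_tandem=2, seed=42)
    cfg = SimConfig(total_reads=20_000, background_fraction=0.0, seed=42)
    res = simulate_experiment(truths, cfg, outdir)
    tags, totals = preprocess_fastq(res.fastq_paths, cfg.adapter_seq)
    return {"truths": truths, "cfg": cfg, "res": res,
            "tags": tags, "totals": totals}


@pytest.fixture(scope="session")
def noisy_experiment(tmp_path_factory):
    """Background-dominated experiment (auto-filled background fraction)."""
    outdir = tmp_path_factory.mktemp("noisy_sim")
    truths = endosperm_truth_set(n_hairpins=8, n_tandem=2, seed=7)
    cfg = SimConfig(total_reads=20_000, seed=7)
    res = simulate_experiment(truths, cfg, outdir)
    tags, totals = preprocess_fastq(res.fastq_paths, cfg.adapter_seq)
    return {"truths": truths, "cfg": cfg, "res": res,
            "tags": tags, "totals": totals}
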