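import numpy as np
import pytest

from hybridia.acquire import AcqConfig, run_acquisition
from hybridia.mzml_io import read_mzml, split_hybrid, write_mzml
from hybridia.pipeline import quantify_targets, run_pierce_benchmark
from hybridia.synth import make_panel_run
from hybridia.targets import FragmentIon, PeptideSpec, TargetEntry


@pytest.fixture(scope="session")
def hybrid_cfg():
    return AcqConfig(mode="hybrid")


@pytest.fixture(scope="session")
def small_panel():
    """A short 3-target hybrid run, acquired once and shared."""
    run, incl = make_panel_run(3, gradient_length=8.0, endo_range=(0.5, 5.0), seed=11)
    cfg = AcqConfig(mode="hybrid")
    scans = run_acquisition(run, incl, cfg, seed=11)
    return run, incl, cfg, scans


@pytest.fixture(scope="session")
def pierce_result(tmp_path_factory):
    """The full dilution-series benchmark (seed 1), run once per session."""
    return run_pierce_benchmark(seed=1, workdir=tmp_path_factory.mktemp("pierce"))


@pytest.fixture(scope="session")
def panel20_results(tmp_path_factory):
    """Clean 20-target panel (seed 7), acquired + quantified once per session."""
    run, incl = make_panel_run(20, endo_range=(0.1, 10.0), seed=7)
    cfg = AcqConfig(mode="hybrid")
    scans = run_acquisition(run, incl, cfg, seed=7)
    path = write_mzml(scans, tmp_path_factory.mktemp("panel") / "panel.mzML")
    _, msx_path, _ = split_hybrid(path)
    results = quantify_targets(read_mzml(msx_path), incl, cfg)
    return run, incl, results


def make_entry(is_mz=500.0, endo_mz=496.0, rt_center=10.0, rt_halfwidth=2.0,
               n_frags=6, label="K8", charge=2, seq="TESTPEPK"):
    frags = tuple(
        FragmentIon("y", i + 1, 1, 300.0 + 100.0 * i, i + 1) for i in range(n_frags)
    )
    pep = PeptideSpec(sequence=seq, charge=charge, label=label,
                      precursor_mz=is_mz, fragments=frags)
    return TargetEntry(is_peptide=pep, endo_mz=endo_mz, rt_center=rt_center,
                       rt_halfwidth=rt_halfwidth)
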