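import pytest
from hypothesis import settings

from isaflux import CycleSchedule, paper_preset

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture
def schedule() -> CycleSchedule:
    """Two 14-day cycles of 10% waste/feed in a 0.25 L reactor."""
    return CycleSchedule(feed_times=(0.0, 14.0), waste_fraction=0.10, reactor_volume=0.25)


@pytest.fixture
def preset_noiseless():
    return paper_preset(noise_cv=0.0, seed=0)


@pytest.fixture
def chem_csv(tmp_path):
    """Small tidy chemistry file: one alpha-ISA decay series plus acetate."""
    path = tmp_path / "chem.csv"
    lines = ["time_d,analyte,concentration,unit,replicate"]
    for t, c in [(0, 8.0), (2, 4.0), (4, 2.0), (6, 1.0)]:
        lines.append(f"{t},alpha_ISA,{c},mM,r1")
    for t, c in [(0, 1.0), (2, 1.5), (4, 2.0), (6, 2.5)]:
        lines.append(f"{t},acetate,{c},mM,r1")
    path.write_text("\n".join(lines) + "\n")
    return path
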