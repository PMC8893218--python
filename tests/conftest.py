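import numpy as np
import pytest

from metamem import AnalysisConfig, EffectSizeRecord, StudyDataset
from metamem.simulate import SimulationSpec, simulate_dataset


def make_gv_dataset(y, v, clusters=None, name="toy", moderators=None):
    """Dataset of precomputed (g, v) records, one per effect."""
    y = np.asarray(y, float)
    v = np.asarray(v, float)
    clusters = clusters if clusters is not None else [f"r{i}" for i in range(y.size)]
    recs = []
    for i, (gi, vi, cl) in enumerate(zip(y, v, clusters)):
        mods = {} if moderators is None else dict(moderators[i])
        recs.append(EffectSizeRecord(report_id=str(cl), effect_id=f"e{i}",
                                     design="between", g=float(gi), v=float(vi),
                                     moderators=mods))
    return StudyDataset(recs, name)


@pytest.fixture
def cfg():
    return AnalysisConfig()


@pytest.fixture
def toy_summary_dataset():
    """Three summary-stat records across two reports (both designs)."""
    recs = [
        EffectSizeRecord("repA", "repA.1", "between",
                         m1=10.0, sd1=4.0, n1=20, m2=8.0, sd2=4.0, n2=20,
                         moderators={"recovery_sleep": "yes"}),
        EffectSizeRecord("repA", "repA.2", "between",
                         m1=5.0, sd1=2.0, n1=10, m2=5.0, sd2=2.0, n2=30),
        EffectSizeRecord("repB", "repB.1", "within",
                         m1=1.0, sd1=1.2, n1=20, m2=0.5, sd2=0.8, r_within=0.5,
                         moderators={"recovery_sleep": "no"}),
    ]
    return StudyDataset(recs, "toy-summary")


@pytest.fixture(scope="session")
def paper_scale_dataset():
    """One simulated literature at the after-learning study scale."""
    return simulate_dataset(SimulationSpec(seed=42))


@pytest.fixture(scope="session")
def small_sim_dataset():
    """Smaller clustered literature for oracle comparisons."""
    return simulate_dataset(SimulationSpec(n_reports=12, effects_per_report=(1, 3),
                                           seed=7))
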