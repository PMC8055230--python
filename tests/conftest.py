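import numpy as np
import pytest

from clonodyn.datamodel import MutationTable, SampleInfo
from clonodyn.inference import VIConfig, fit, model_by_name
from clonodyn.simulate import SimConfig, simulate_dataset


def make_table(alt, total, purities, times_raw, cn_total=None, multiplicity=None):
    """Assemble a small MutationTable directly from arrays."""
    alt = np.asarray(alt, dtype=np.int64)
    total = np.asarray(total, dtype=np.int64)
    N, M = alt.shape
    t = np.asarray(times_raw, dtype=float)
    unit = (t - t[0]) / (t[-1] - t[0]) if M > 1 else np.zeros(1)
    samples = [
        SampleInfo(sample_id=f"s{j + 1}", time_raw=float(t[j]),
                   time_unit=float(unit[j]), purity=float(purities[j]))
        for j in range(M)
    ]
    cn = np.full((N, M), 2, dtype=np.int64) if cn_total is None else np.asarray(cn_total)
    mult = (np.ones((N, M), dtype=np.int64) if multiplicity is None
            else np.asarray(multiplicity))
    return MutationTable([f"m{i + 1}" for i in range(N)], samples, alt, total, cn, mult)


@pytest.fixture(scope="session")
def clean_two_cluster():
    """Deeply sequenced, well-separated two-cluster dataset plus its truth."""
    cfg = SimConfig(n_samples=4, n_mutations=60, n_clusters=2, depth_mean=1000,
                    min_separation=0.3, purity_range=(0.9, 1.0), seed=11)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def gp0_fit(clean_two_cluster):
    """A converged GP0-Mat32 fit of the clean two-cluster dataset."""
    table, _ = clean_two_cluster
    spec = model_by_name("GP0-Mat32", truncation=8)
    return fit(table, spec, VIConfig(seed=5, max_iters=1500))
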