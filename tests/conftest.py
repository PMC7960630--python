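import numpy as np
import pytest

import kinetax as kx


@pytest.fixture(scope="session")
def fig3_params():
    """Fixed-linear-gradient benchmark parameter set."""
    return kx.ModelParamsND(
        N=0.0, H=0.0, K_S=1.0, K_chi=0.53, delta0=50.0,
        eta=2.0, omega=0.2, n_hill=5.0, zeta=0.0,
    )


@pytest.fixture(scope="session")
def transient_runs():
    """The four transient-source variants, as B_S time series."""
    spec = kx.make_transient_source()
    out = {}
    for label, _ in spec.iter_runs():
        if label == "base":
            continue
        traj = kx.run_variant(spec, label)
        out[label] = {
            "times": traj.times,
            "B_S": np.array([s.B.max() for s in traj.states]),
            "traj": traj,
        }
    return spec, out


@pytest.fixture(scope="session")
def agar_runs():
    """Chemokinetic population vs the two constant-speed controls."""
    spec = kx.make_agar_plate()
    out = {label: kx.run_variant(spec, None if label == "base" else label)
           for label in ("base", "const_speed_base", "const_speed_high")}
    return spec, out
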