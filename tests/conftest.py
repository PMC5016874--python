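import numpy as np
import pytest

from mprkit.core import AcquisitionParams
from mprkit import synthetic as sy


@pytest.fixture
def acq() -> AcquisitionParams:
    return AcquisitionParams(n_frames=60)


@pytest.fixture
def aif_model() -> sy.GammaVariateAIF:
    return sy.GammaVariateAIF()


@pytest.fixture
def aif_curve(acq, aif_model):
    return sy.gamma_variate_aif(aif_model, acq.frame_times)


def make_noiseless_curves(mbf: float, acq: AcquisitionParams,
                          aif_model: sy.GammaVariateAIF):
    """AIF + tissue ΔR1 curves recovered through the signal chain at zero noise."""
    from mprkit import perfusion as pf
    aif = sy.gamma_variate_aif(aif_model, acq.frame_times)
    tf = sy.tissue_curve_from_fermi(aif, sy.fermi_for_mbf(mbf))
    sb = sy.concentration_to_signal(aif, acq, 1.55, role="blood")
    st = sy.concentration_to_signal(tf, acq, 1.45, role="tissue")
    return pf.series_to_delta_r1(sb), pf.series_to_delta_r1(st)
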