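"""Shared fixtures: published parameter sets and small simulation designs."""

import pytest

import germthresh as gt

# Fitted constants for P. tomentosa seed lots, as published for each model
# family (control-seed thermal response; storage response at each
# temperature; combined one- and two-phased aging thermal time).

TT_PUBLISHED = gt.TTParams(theta_T50=253.7, T_b=3.9, sigma_lnTheta=0.79)

MTT_PUBLISHED = gt.MTTParams(
    low=gt.MTTLowParams(theta_Tm=383.9, T_m50=4.4, sigma_Tm=3.79),
    high=gt.TTParams(theta_T50=149.1, T_b=9.5, sigma_lnTheta=0.56),
    T_split=12.5,
)

MLT_PUBLISHED = {
    5: gt.MLTParams(p_max50=17.45, sigma_pmax=23.54, theta_A=4384.03),
    10: gt.MLTParams(p_max50=26.55, sigma_pmax=19.30, theta_A=1940.62),
    15: gt.MLTParams(p_max50=32.88, sigma_pmax=19.30, theta_A=966.18),
    20: gt.MLTParams(p_max50=30.54, sigma_pmax=22.43, theta_A=454.34),
    25: gt.MLTParams(p_max50=31.32, sigma_pmax=14.44, theta_A=262.05),
    30: gt.MLTParams(p_max50=27.86, sigma_pmax=14.72, theta_A=181.06),
}

THETA_A_BY_TEMP = {T: p.theta_A for T, p in MLT_PUBLISHED.items()}

ATT_ONE_PHASE = gt.ATTParams(p_max50=25.53, sigma_pmax=21.58,
                             theta_AT=6261.0, T_b=3.99)

ATT_TWO_PHASE_LOW = gt.ATTParams(
    p_max50=30.79, sigma_pmax=22.5, theta_AT=18114.0, T_b=1.49,
    low_range_extension=gt.LowRangeExtension(k=1.41, T_i=12.06, p_maxi50=30.79),
)

ATT_TWO_PHASE_HIGH = gt.ATTParams(p_max50=30.79, sigma_pmax=18.05,
                                  theta_AT=4158.0, T_b=10.26)


@pytest.fixture
def tt_params():
    return TT_PUBLISHED


@pytest.fixture
def mtt_params():
    return MTT_PUBLISHED


@pytest.fixture
def mlt_params_by_temp():
    return MLT_PUBLISHED


@pytest.fixture
def att_one_phase():
    return ATT_ONE_PHASE


@pytest.fixture
def att_two_phase():
    return ATT_TWO_PHASE_LOW, ATT_TWO_PHASE_HIGH


@pytest.fixture
def control_design():
    """Control seeds only (no storage), 2-hourly scoring for speed."""
    return gt.SimulationDesign(storage_days=(0.0,), recording_interval=2.0)


@pytest.fixture
def full_design():
    """The full 6 temperatures x 8 storage durations layout, 2-hourly."""
    return gt.SimulationDesign(recording_interval=2.0)
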