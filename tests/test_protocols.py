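"""Protocol definitions: validation, lossless serialization, AP-clamp
parsing, synthetic waveforms, and self-consistency of the clamp machinery."""

import numpy as np
import pytest

from gpmyo import analysis, cell, protocols


def test_roundtrip_serialization_all_variants():
    specs = [
        protocols.pacing(1000.0, 3),
        protocols.voltage_step_family(),
        protocols.s1s2_restitution(),
        protocols.frequency_staircase(),
        protocols.workload_transition(2.0),
        protocols.ap_clamp_from_text(
            "time_ms,voltage_mV\n0,-85\n1,20\n300,-85\n"),
    ]
    for spec in specs:
        back = protocols.ProtocolSpec.from_yaml(spec.to_yaml())
        assert back == spec


def test_validation_errors():
    with pytest.raises(ValueError):
        protocols.ProtocolSpec(variant="nope")
    with pytest.raises(ValueError):
        protocols.voltage_step_family(tests=[])
    with pytest.raises(ValueError):
        protocols.voltage_step_family(tests=[120.0])
    with pytest.raises(ValueError):
        protocols.s1s2_restitution(di_list=[100.0, 50.0])
    with pytest.raises(ValueError):
        protocols.workload_transition(-1.0)


def test_staircase_records_seven_steps():
    spec = protocols.frequency_staircase()
    assert len(spec.bcls) == 7
    assert spec.bcls == protocols.STAIRCASE_BCLS


@pytest.mark.parametrize("text,line", [
    ("bad_header\n0,-85\n", 1),
    ("time_ms,voltage_mV\n0,-85\n1\n", 3),
    ("time_ms,voltage_mV\n0,-85\n0,-80\n", 3),
    ("time_ms,voltage_mV\n0,abc\n", 2),
])
def test_ap_clamp_parse_errors_carry_line_numbers(text, line):
    with pytest.raises(ValueError) as err:
        protocols.ap_clamp_from_text(text)
    assert f"line {line}" in str(err.value) or line == 1


def test_synthetic_waveforms_have_expected_morphology():
    t, v = protocols.synthetic_ap_waveform("guinea-pig", apd=200.0)
    assert v.max() > 40.0
    k = np.argmax(v)
    # monotone plateau decay, no notch
    assert np.all(np.diff(v[k:np.argmin(np.abs(t - 200.0))]) <= 1e-9)
    t, v = protocols.synthetic_ap_waveform("canine", apd=250.0)
    k = np.argmax(v)
    seg = v[k:np.argmin(np.abs(t - 60.0))]
    assert seg.min() < 10.0 and v[np.argmin(np.abs(t - 59.0))] > seg.min()
    csv = protocols.waveform_to_csv(t, v)
    spec = protocols.ap_clamp_from_text(csv)
    assert len(spec.clamp_t) == len(t)


def test_ap_clamp_at_rest_keeps_cell_quiescent(p, y1hz):
    t = np.arange(0.0, 501.0, 10.0)
    v = np.full_like(t, y1hz[cell.IV])
    spec = protocols.ap_clamp_from_text(protocols.waveform_to_csv(t, v))
    res = protocols.run_protocol(spec, p, y1hz)
    # waveform text is written at 6 significant digits
    assert np.abs(res.v - y1hz[cell.IV]).max() < 1e-3
    assert res.ca_i.max() < 2.0 * res.ca_i[0]


def test_ap_clamp_with_own_ap_reproduces_transient(p, y1hz, beat_1hz):
    """Clamping with the model's own 1 Hz AP reproduces the free-running
    Ca2+ transient within interpolation error."""
    free = beat_1hz
    spec = protocols.ap_clamp_from_text(
        protocols.waveform_to_csv(free.t, free.v))
    res = protocols.run_protocol(spec, p, free.y[0])
    assert res.ca_i.max() == pytest.approx(free.ca_i.max(), rel=0.02)


def test_uniporter_overlay_validation():
    spec = protocols.pacing(1000.0, 1)
    spec.vmuni_scale = 1.5
    from gpmyo.params import load_reference
    with pytest.raises(ValueError):
        protocols.run_protocol(spec, load_reference())
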