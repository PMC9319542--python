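"""Configs, unit conversion, case studies, sweeps, fixtures, CLI."""

import json
import math

import numpy as np
import pytest
import yaml
from click.testing import CliRunner

from nanoplume.cli import main as cli_main
from nanoplume.deposition import deposited_fraction
from nanoplume.scenarios import (
    Scenario,
    case_study,
    enm_sweep,
    generate_fixtures,
    generic_sweep,
    mini_sweep,
    parse_config,
    run_scenario,
    run_sweep,
    serialize_config,
    sweep_summary,
)

CFG = {
    "name": "demo",
    "source": {"emission": "0.51 g/h", "height": "7.8 m"},
    "particle": {"diameter": "260 nm", "density": "940 kg/m3"},
    "atmosphere": {
        "wind": "2.5 m/s",
        "temperature": "288.15 K",
        "hpbl": "1 km",
        "scheme": "davidson",
        "stability": "d",
    },
    "domain": {"x_max": "500 km"},
    "soil": {"years": 100, "pnec": "1000 ug/kg"},
}


def test_unit_parsing_matches_field_style_inputs():
    s = parse_config(CFG)
    assert s.source.E == pytest.approx(0.51 / 3600.0)  # g/h -> g/s
    assert s.source.H == 7.8
    assert s.particle.dp == 260.0 and s.particle.rho == 940.0
    assert s.hpbl == 1000.0 and s.x_max == 500_000.0
    s2 = parse_config({**CFG, "source": {"emission": "20 mg/min", "height": "3 m"}})
    assert s2.source.E == pytest.approx(0.33e-3, rel=0.02)


def test_config_round_trip_idempotent():
    s = parse_config(CFG)
    cfg1 = serialize_config(s)
    s2 = parse_config(cfg1)
    cfg2 = serialize_config(s2)
    assert cfg1 == cfg2
    assert yaml.safe_load(yaml.safe_dump(cfg1)) == cfg1


def test_exactly_one_particle_mode_enforced():
    with pytest.raises(ValueError):
        parse_config({**CFG, "velocities": {"vset": "0.01 cm/s", "vdep": "0.1 cm/s"}})
    bad = dict(CFG)
    bad.pop("particle")
    with pytest.raises(ValueError):
        parse_config(bad)


def test_case_study_configurations():
    k = case_study("koivisto")
    assert k.source.E == pytest.approx(3.5e-6) and k.source.H == 3.0
    assert k.particle.dp == 280.0 and k.particle.rho == 2100.0
    f = case_study("fonseca", "activity")
    assert f.source.E == pytest.approx(0.14e-3) and f.source.H == 7.8
    assert f.U == 2.5 and f.T == 288.15 and f.hpbl == 1000.0 and f.scheme == "davidson"
    assert f.stability == tuple("abcdef")
    with pytest.raises(ValueError):
        case_study("nope")


def test_sweep_counts_match_study_design():
    assert generic_sweep().n_combinations == 486
    assert enm_sweep().n_combinations == 1296
    assert mini_sweep().n_combinations == 3


def test_mini_sweep_runs_and_is_order_independent():
    spec = mini_sweep()
    df = run_sweep(spec)
    assert len(df) == 3
    # order independence: rows sorted by inputs are identical however produced
    scens = list(spec.expand())
    from nanoplume.scenarios import _run_single

    rows = [_run_single(s) for s in reversed(scens)]
    import pandas as pd

    df2 = pd.DataFrame(rows)
    a = df.sort_values("stability").reset_index(drop=True)
    b = df2.sort_values("stability").reset_index(drop=True)
    pd.testing.assert_frame_equal(a, b)
    summ = sweep_summary(df)
    assert {"parameter", "x50_median_m"} <= set(summ.columns)


def test_report_deterministic(koivisto_run):
    again = run_scenario(case_study("koivisto"))
    assert koivisto_run.report_json() == again.report_json()


def test_report_contents_koivisto(koivisto_run):
    r = koivisto_run.report
    assert set(r["per_class"]) == set("abcdef")
    assert r["worst_case"]["cmax_ug_m3"] > 0
    assert r["per_class"]["d"]["x50_m"] == "beyond_domain"
    assert "weighted" in r and "soil" in r
    json.loads(koivisto_run.report_json())  # serializable


def test_fixture_set(tmp_path):
    fx = generate_fixtures(seed=7, outdir=tmp_path)
    assert fx["seed"] == 7
    k = fx["koivisto"]
    assert k.source.E == pytest.approx(3.5e-6) and k.particle.dp == 280.0
    assert fx["fonseca"].source.H == 7.8
    assert fx["mini_sweep"].n_combinations == 3
    assert (tmp_path / "wellmixed.yaml").exists()
    reloaded = parse_config(yaml.safe_load((tmp_path / "koivisto.yaml").read_text()))
    assert reloaded.source.E == pytest.approx(3.5e-6)


def test_wellmixed_fixture_matches_closed_form():
    """The constant-vdep fixture in the fully mixed regime follows the
    analytic depletion law (1-fdep(x2))/(1-fdep(x1)) = exp(-vdep dx /(U hpbl))
    to better than 0.5%."""
    fx = generate_fixtures()
    sc = fx["wellmixed"]
    prof = run_scenario(sc).profiles["a"]
    x1, x2 = 5e3, 5e4
    got = (1 - deposited_fraction(prof, x2)) / (1 - deposited_fraction(prof, x1))
    want = math.exp(-sc.fixed.vdep * (x2 - x1) / (sc.U * sc.hpbl))
    assert got == pytest.approx(want, rel=5e-3)


def test_cli_run_and_x50(tmp_path):
    cfg = dict(CFG)
    cfg["atmosphere"] = {**CFG["atmosphere"], "stability": "d"}
    path = tmp_path / "demo.yaml"
    path.write_text(yaml.safe_dump(cfg))
    runner = CliRunner()
    out = tmp_path / "report.json"
    res = runner.invoke(cli_main, ["run", str(path), "-o", str(out)])
    assert res.exit_code == 0, res.output
    report = json.loads(out.read_text())
    assert report["per_class"]["d"]["cmax_ug_m3"] > 0
    res2 = runner.invoke(cli_main, ["x50", str(path)])
    assert res2.exit_code == 0 and "class d" in res2.output


def test_cli_case_study_and_fixtures(tmp_path):
    runner = CliRunner()
    res = runner.invoke(cli_main, ["fixtures", str(tmp_path / "fx"), "--seed", "3"])
    assert res.exit_code == 0
    assert (tmp_path / "fx" / "fonseca.yaml").exists()
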