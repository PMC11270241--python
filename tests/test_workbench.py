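"""Pipeline plumbing: file-format round trips, CLI stages and idempotence."""

import numpy as np
import pandas as pd
import pytest
import yaml
from click.testing import CliRunner

from nanobracket import cli, events, io, synth
from nanobracket.events import RawTrace


@pytest.fixture
def runner():
    return CliRunner()


class TestEventTSV:
    def test_round_trip_is_lossless(self, tmp_path, rng):
        truth = synth.TruthSpec("let-7b", 9000, 16.0, 30.0, 5.0, 8.0)
        table = synth.simulate_experiment(truth, seed=3)[1].events
        p = tmp_path / "events.tsv"
        io.write_event_tsv(table, p)
        back = io.read_event_tsv(p)
        assert back[["channel", "start_tps", "duration_tps"]].equals(
            table[["channel", "start_tps", "duration_tps"]]
        )
        # ratios carry the documented 4-decimal precision
        assert np.allclose(back["min_ratio"], table["min_ratio"], atol=5e-5)

    def test_missing_column_is_named(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("channel\tstart_tps\n1\t2\n")
        with pytest.raises(io.SchemaError, match="duration_tps"):
            io.read_event_tsv(p)


class TestTraceContainer:
    def test_round_trip_preserves_samples_and_metadata(self, tmp_path, rng):
        traces = [
            RawTrace(channel_id=ch, samples=220.0 + rng.normal(0, 4, 500))
            for ch in (1, 2, 3)
        ]
        p = tmp_path / "run.h5"
        io.write_trace_container(p, traces, seed=7, duration_min=45.0)
        back, attrs = io.read_trace_container(p)
        assert attrs["seed"] == 7
        assert attrs["duration_min"] == 45.0
        assert attrs["voltage_mV"] == -180.0
        assert attrs["sampling_rate_per_ms"] == 3.0
        assert len(back) == 3
        np.testing.assert_allclose(back[0].samples, traces[0].samples, rtol=1e-6)


class TestManifest:
    def _doc(self):
        return {
            "test_id": "T1",
            "sample": {"id": "H1", "condition": "healthy", "rna_conc": 18.8},
            "experiments": [
                {
                    "mirna_id": "let-7b", "rna_vol": 9.5, "probe_vol": 6.0,
                    "probe_conc": 30.0, "call": "SILENCING",
                }
            ],
            "seed": 1,
        }

    def test_round_trip(self, tmp_path):
        p = tmp_path / "manifest.yaml"
        io.write_manifest(self._doc(), p)
        assert io.read_manifest(p) == self._doc()

    def test_missing_field_is_named(self, tmp_path):
        doc = self._doc()
        del doc["experiments"][0]["rna_vol"]
        p = tmp_path / "manifest.yaml"
        io.write_manifest(doc, p)
        with pytest.raises(io.SchemaError, match="rna_vol"):
            io.read_manifest(p)


class TestCliPipeline:
    def test_simulate_detect_call_stages_compose(self, runner, tmp_path):
        container = tmp_path / "run.h5"
        res = runner.invoke(
            cli.main, ["simulate", "--seed", "5", "--out", str(container)]
        )
        assert res.exit_code == 0, res.output
        assert container.exists()
        sidecar = yaml.safe_load((tmp_path / "run.h5.truth.yaml").read_text())
        assert sidecar["seed"] == 5
        assert sidecar["planted_events"] > 0

        ev = tmp_path / "events.tsv"
        res = runner.invoke(cli.main, ["detect", str(container), "--out", str(ev)])
        assert res.exit_code == 0, res.output
        table = io.read_event_tsv(ev)
        # most planted events survive the filter (decoys are rejected)
        assert len(table) > 0.6 * sidecar["planted_events"]

        report = tmp_path / "calls.tsv"
        res = runner.invoke(
            cli.main,
            ["call", str(ev), str(ev), str(ev), "--out", str(report)],
        )
        assert res.exit_code == 0, res.output
        rep = io.read_call_report(report)
        assert rep.loc[0, "call"] in ("DETECTION", "SILENCING", "INCONCLUSIVE")

    def test_seeded_simulation_is_idempotent(self, runner, tmp_path):
        outs = []
        for name in ("a.h5", "b.h5"):
            path = tmp_path / name
            res = runner.invoke(
                cli.main, ["simulate", "--seed", "11", "--out", str(path)]
            )
            assert res.exit_code == 0, res.output
            ev = tmp_path / f"{name}.tsv"
            res = runner.invoke(cli.main, ["detect", str(path), "--out", str(ev)])
            assert res.exit_code == 0, res.output
            outs.append(ev.read_bytes())
        assert outs[0] == outs[1]

    def test_empty_event_file_calls_inconclusive(self, runner, tmp_path):
        ev = tmp_path / "empty.tsv"
        io.write_event_tsv(
            pd.DataFrame(columns=events.EVENT_COLUMNS).astype(
                {"channel": int, "start_tps": int, "duration_tps": int,
                 "min_ratio": float, "max_ratio": float}
            ),
            ev,
        )
        report = tmp_path / "calls.tsv"
        res = runner.invoke(
            cli.main, ["call", str(ev), str(ev), str(ev), "--out", str(report)]
        )
        assert res.exit_code == 0, res.output
        assert "INCONCLUSIVE" in res.output

    def test_unknown_simulate_config_field_is_usage_error(self, runner, tmp_path):
        cfg = tmp_path / "cfg.yaml"
        cfg.write_text("bogus_field: 3\n")
        res = runner.invoke(
            cli.main,
            ["simulate", "--config", str(cfg), "--out", str(tmp_path / "x.h5")],
        )
        assert res.exit_code != 0
        assert "bogus_field" in res.output


class TestCliQuantifyValidate:
    def test_quantify_published_sample(self, runner, tmp_path):
        doc = {
            "test_id": "H1-let7b",
            "sample": {"id": "H1", "condition": "healthy", "rna_conc": 18.8},
            "experiments": [
                {"mirna_id": "let-7b", "rna_vol": 9.5, "probe_vol": 6.0,
                 "probe_conc": 30.0, "call": "SILENCING"},
                {"mirna_id": "let-7b", "rna_vol": 6.3, "probe_vol": 6.0,
                 "probe_conc": 30.0, "call": "DETECTION"},
            ],
            "seed": 0,
        }
        mp = tmp_path / "manifest.yaml"
        io.write_manifest(doc, mp)
        out = tmp_path / "results.csv"
        res = runner.invoke(
            cli.main, ["quantify", "--manifest", str(mp), "--out", str(out)]
        )
        assert res.exit_code == 0, res.output
        df = io.read_results_csv(out)
        row = df.iloc[0]
        assert row["miRNA"] == "let-7b"
        assert row["HL"] == pytest.approx(1.00)
        assert row["half_range"] == pytest.approx(0.20)

    def test_validate_on_cohort_table(self, runner, tmp_path):
        from nanobracket.datasets import cohort_hl

        table = tmp_path / "hl.csv"
        cohort_hl().to_csv(table, index=False)
        prefix = tmp_path / "report"
        res = runner.invoke(
            cli.main, ["validate", "--results", str(table), "--out", str(prefix)]
        )
        assert res.exit_code == 0, res.output
        text = (tmp_path / "report.txt").read_text()
        assert "sensitivity=1.000" in text
        assert "specificity=1.000" in text
        summary = pd.read_csv(tmp_path / "report.csv")
        cancer_row = summary[summary.group == "cancer-biomarkers"].iloc[0]
        assert cancer_row["mean"] == pytest.approx(1.83)
        assert cancer_row["rsd"] == pytest.approx(0.09)

    def test_plan_test_prints_volumes(self, runner):
        res = runner.invoke(
            cli.main,
            ["plan-test", "--mirna", "let-7b", "--rna-conc", "16.0"],
        )
        assert res.exit_code == 0, res.output
        assert "P/y=" in res.output
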