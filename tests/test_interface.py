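import numpy as np
import pandas as pd
import pytest

from nkdeconv import RunConfig
from nkdeconv import io as nkio
from nkdeconv.pipeline import condition_grid_from_config, run_pipeline


def _reduced_config(tmp_path, seed=81):
    return RunConfig(
        seed=seed,
        outdir=str(tmp_path / "out"),
        runs_per_condition=4,
        max_conditions=1,
    )


class TestExpressionIO:
    def test_round_trip(self, tmp_path):
        df = pd.DataFrame(
            [[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]],
            index=pd.Index(["g1", "g2", "g3"], name="gene"),
            columns=["s1", "s2"],
        )
        path = tmp_path / "expr.tsv"
        nkio.write_expression_matrix(df, path)
        back = nkio.read_expression_matrix(path)
        assert back.shape == (3, 2)
        assert np.allclose(back.to_numpy(), df.to_numpy())

    def test_duplicate_genes_summed(self, tmp_path):
        path = tmp_path / "dup.tsv"
        path.write_text("gene\ts1\ng1\t1\ng1\t2\ng2\t5\n")
        back = nkio.read_expression_matrix(path)
        assert back.loc["g1", "s1"] == 3
        assert back.shape == (2, 1)

    def test_missing_header_rejected(self, tmp_path):
        path = tmp_path / "nohead.tsv"
        path.write_text("g1\t1\t2\ng2\t3\t4\n")
        with pytest.raises(ValueError, match="header"):
            nkio.read_expression_matrix(path)

    def test_non_numeric_cell_located(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("gene\ts1\ts2\ng1\t1\t2\ng2\tx\t4\n")
        with pytest.raises(ValueError, match="g2"):
            nkio.read_expression_matrix(path)


class TestClinicalIO:
    def test_valid_table_aligns_with_expression(self, tmp_path):
        clin = tmp_path / "clin.tsv"
        clin.write_text(
            "sample_id\tpfs_days\tevent\ns1\t100\t1\ns2\t250\t0\ns3\t400\t1\ns4\t90\t1\n"
        )
        table = nkio.read_clinical_table(clin)
        expr = pd.DataFrame(
            np.ones((2, 3)), index=["g1", "g2"], columns=["s1", "s3", "s9"]
        )
        times, events, aligned, unmatched = nkio.align_clinical(expr, table)
        assert times.tolist() == [100.0, 400.0]
        assert events.tolist() == [1, 1]
        assert unmatched == ["s9"]

    def test_invalid_event_rejected(self, tmp_path):
        clin = tmp_path / "clin.tsv"
        clin.write_text("sample_id\tpfs_days\tevent\ns1\t100\t2\n")
        with pytest.raises(ValueError, match="event"):
            nkio.read_clinical_table(clin)

    def test_negative_time_rejected(self, tmp_path):
        clin = tmp_path / "clin.tsv"
        clin.write_text("sample_id\tpfs_days\tevent\ns1\t-5\t1\n")
        with pytest.raises(ValueError):
            nkio.read_clinical_table(clin)

    def test_grade_vocabulary_enforced(self, tmp_path):
        clin = tmp_path / "clin.tsv"
        clin.write_text("sample_id\tpfs_days\tevent\tgrade\ns1\t100\t1\tmedium\n")
        with pytest.raises(ValueError, match="grade"):
            nkio.read_clinical_table(clin)


def test_compendium_round_trip(tmp_path, compendium):
    nkio.write_compendium(compendium, tmp_path / "comp")
    back = nkio.read_compendium(tmp_path / "comp")
    assert np.array_equal(back.counts, compendium.counts)
    assert back.sample_ids == compendium.sample_ids
    assert back.cell_types == compendium.cell_types
    assert back.taxonomy.leaves == compendium.taxonomy.leaves


def test_survival_pool_round_trip(tmp_path, survival_pool):
    path = tmp_path / "pool.tsv"
    nkio.write_survival_pool(survival_pool, path)
    back = nkio.read_survival_pool(path)
    assert np.allclose(back.times, survival_pool.times)


class TestConfig:
    def test_yaml_round_trip_is_lossless(self, tmp_path):
        cfg = RunConfig(seed=7, alpha=0.1, slope_levels=[-1.0, 0.0, 1.0])
        path = tmp_path / "cfg.yaml"
        cfg.to_yaml(path)
        assert RunConfig.from_yaml(path) == cfg

    def test_unknown_keys_rejected(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text("seed: 1\nbogus_knob: 3\n")
        with pytest.raises(ValueError, match="bogus_knob"):
            RunConfig.from_yaml(path)

    def test_default_grid_matches_defaults(self):
        grid = condition_grid_from_config(RunConfig())
        assert len(grid) == 81

    def test_child_seeds_are_stable_and_distinct(self):
        cfg = RunConfig(seed=5)
        assert cfg.child_seed(1) == RunConfig(seed=5).child_seed(1)
        assert cfg.child_seed(1) != cfg.child_seed(2)
        assert 0 <= cfg.child_seed(1) < 2**31


class TestPipeline:
    def test_reduced_run_produces_artifacts(self, tmp_path):
        cfg = _reduced_config(tmp_path)
        bundle = run_pipeline(cfg, write=True)
        out = tmp_path / "out"
        assert (out / "signature.tsv").exists()
        assert (out / "benchmark_auc.tsv").exists()
        assert (out / "run.yaml").exists()
        assert len(bundle.signature.cell_types) == 24
        assert len(bundle.benchmark) == 1
        assert len(bundle.benchmark[0].run_records) == 4

    def test_rerun_same_config_is_byte_identical(self, tmp_path):
        cfg_a = _reduced_config(tmp_path / "a")
        cfg_b = _reduced_config(tmp_path / "b")
        run_pipeline(cfg_a, write=True)
        run_pipeline(cfg_b, write=True)
        for name in ("signature.tsv", "benchmark_auc.tsv"):
            assert (tmp_path / "a" / "out" / name).read_text() == (
                tmp_path / "b" / "out" / name
            ).read_text()

    def test_alpha_is_plumbed_through(self, tmp_path):
        strict = _reduced_config(tmp_path / "s")
        lax = _reduced_config(tmp_path / "l")
        lax.alpha = 0.999
        res_strict = run_pipeline(strict, write=False).benchmark[0]
        res_lax = run_pipeline(lax, write=False).benchmark[0]
        assert [r.p_value for r in res_strict.run_records] == pytest.approx(
            [r.p_value for r in res_lax.run_records]
        )
        assert sum(r.significant for r in res_lax.run_records) >= sum(
            r.significant for r in res_strict.run_records
        )


class TestCLI:
    def test_signature_construction_via_cli(self, tmp_path):
        from click.testing import CliRunner

        from nkdeconv.cli import main

        runner = CliRunner()
        comp_dir = tmp_path / "comp"
        steps = [
            ["simulate-reference", "--out", str(comp_dir), "--seed", "3"],
            ["fit-model", "--compendium", str(comp_dir), "--out", str(tmp_path / "post.tsv")],
            [
                "select-markers",
                "--posteriors", str(tmp_path / "post.tsv"),
                "--taxonomy", str(comp_dir / "taxonomy.tsv"),
                "--out", str(tmp_path / "markers.tsv"),
            ],
            [
                "build-signature",
                "--posteriors", str(tmp_path / "post.tsv"),
                "--markers", str(tmp_path / "markers.tsv"),
                "--taxonomy", str(comp_dir / "taxonomy.tsv"),
                "--out", str(tmp_path / "sig.tsv"),
            ],
        ]
        for args in steps:
            result = runner.invoke(main, args, catch_exceptions=False)
            assert result.exit_code == 0, result.output
        sig = pd.read_csv(tmp_path / "sig.tsv", sep="\t", index_col=0)
        assert sig.shape[1] == 24

    def test_deconvolve_and_survival_commands(self, tmp_path, signature):
        from click.testing import CliRunner

        from nkdeconv.cli import main

        runner = CliRunner()
        sig_path = tmp_path / "sig.tsv"
        signature.to_tsv(sig_path)
        rng = np.random.default_rng(82)
        n = 24
        cols = rng.integers(0, len(signature.cell_types), n)
        expr = pd.DataFrame(
            signature.values[:, cols] * rng.lognormal(0, 0.05, (len(signature.genes), n)),
            index=pd.Index(signature.genes, name="gene"),
            columns=[f"s{i}" for i in range(n)],
        )
        expr_path = tmp_path / "expr.tsv"
        nkio.write_expression_matrix(expr, expr_path)
        props_path = tmp_path / "props.tsv"
        result = runner.invoke(
            main,
            ["deconvolve", "--signature", str(sig_path), "--expression", str(expr_path),
             "--backend", "nnls", "--out", str(props_path)],
            catch_exceptions=False,
        )
        assert result.exit_code == 0, result.output
        clin_path = tmp_path / "clin.tsv"
        clin = pd.DataFrame(
            {
                "sample_id": expr.columns,
                "pfs_days": rng.exponential(500, n) + 1,
                "event": rng.integers(0, 2, n),
            }
        )
        clin.to_csv(clin_path, sep="\t", index=False)
        result = runner.invoke(
            main,
            ["survival", "--props", str(props_path), "--clinical", str(clin_path),
             "--cell-type", "nk_il2", "--out", str(tmp_path / "km.tsv")],
            catch_exceptions=False,
        )
        assert result.exit_code == 0, result.output
        assert (tmp_path / "km.tsv").exists()
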