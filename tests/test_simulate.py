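"""Synthetic-data generators: determinism, ground-truth geometry,
calibrated energies and round-trips through the package's readers."""

import numpy as np
import pandas as pd
import pytest

from intersav.energetics import read_ddg_table
from intersav.regions import assign_regions
from intersav.simulate import (
    ConfigError, SimulationConfig, ddg_table_for_complex, make_toy_complex,
    savs_for_complex, simulate_counts, simulate_ddg, simulate_savs,
    to_pdb_text,
)
from intersav.structure import read_structure
from intersav.variants import read_sav_table


class TestToyComplex:
    def test_same_seed_byte_identical_pdb(self):
        a = to_pdb_text(make_toy_complex(SimulationConfig(seed=5))[0])
        b = to_pdb_text(make_toy_complex(SimulationConfig(seed=5))[0])
        assert a == b

    def test_different_seed_differs(self):
        a = to_pdb_text(make_toy_complex(SimulationConfig(seed=5))[0])
        b = to_pdb_text(make_toy_complex(SimulationConfig(seed=6))[0])
        assert a != b

    def test_pdb_round_trip(self, tmp_path):
        cx, _ = make_toy_complex(SimulationConfig(seed=5))
        path = tmp_path / "toy.pdb"
        path.write_text(to_pdb_text(cx))
        back = read_structure(path)
        assert len(back.residues) == len(cx.residues)
        assert back.sequence("A") == cx.sequence("A")
        orig = np.array([a.coords for r in cx.residues for a in r.atoms])
        rt = np.array([a.coords for r in back.residues for a in r.atoms])
        assert np.allclose(orig, rt, atol=1e-3)  # PDB prints 3 decimals

    def test_clashing_geometry_rejected(self):
        with pytest.raises(ConfigError):
            make_toy_complex(SimulationConfig(seed=0, gap=1.5))

    def test_excessive_jitter_rejected(self):
        with pytest.raises(ConfigError):
            make_toy_complex(SimulationConfig(seed=0, jitter=0.8))


class TestSimulateSavs:
    def test_deterministic_per_seed(self):
        a = simulate_savs(SimulationConfig(seed=9))
        b = simulate_savs(SimulationConfig(seed=9))
        pd.testing.assert_frame_equal(a, b)

    def test_zero_rate_region_empty(self):
        cfg = SimulationConfig(seed=1)
        cfg.disease_rates["core"] = 0.0
        savs = simulate_savs(cfg)
        disease = savs[savs.category == "disease"]
        assert (disease.region != "core").all()

    def test_round_trip_through_reader(self, tmp_path):
        cfg = SimulationConfig(
            seed=3, region_sizes={"core": 400, "rim": 400,
                                  "buried": 400, "surface": 400})
        savs = simulate_savs(cfg)
        path = tmp_path / "savs.tsv"
        savs.to_csv(path, sep="\t", index=False)
        recs = read_sav_table(path, "plain_tsv")
        assert len(recs) == len(savs)
        assert all(r.wt_aa != r.mut_aa for r in recs)

    def test_null_rates_give_or_near_one(self):
        # equal per-region rates: mean core-vs-rim log-OR over
        # replicates is within 3 standard errors of zero
        sizes = {"core": 13486, "rim": 23478}
        rates = {"core": 0.01, "rim": 0.01}
        rng = np.random.default_rng(42)
        logs = []
        for _ in range(100):
            counts = simulate_counts(sizes, rates, rng)
            x_c = counts["core"] / sizes["core"]
            x_r = counts["rim"] / sizes["rim"]
            logs.append(np.log((x_c / (1 - x_c)) / (x_r / (1 - x_r))))
        mean_se = np.std(logs, ddof=1) / np.sqrt(len(logs))
        assert abs(np.mean(logs)) < 3 * mean_se + 1e-9


class TestSimulateDdg:
    def test_infeasible_targets_rejected(self):
        with pytest.raises(ConfigError):
            SimulationConfig(ddg_exceedance={"core": (0.2, 0.4)})

    def test_unknown_region_rejected(self):
        with pytest.raises(ConfigError):
            simulate_ddg(["surface"], SimulationConfig(seed=0))

    def test_exceedance_calibration(self):
        cfg = SimulationConfig(seed=8)
        n = 100_000
        core = simulate_ddg(["core"] * n, cfg)["ddg_wt"].to_numpy()
        rim = simulate_ddg(["rim"] * n, cfg)["ddg_wt"].to_numpy()
        assert (core >= 1).mean() == pytest.approx(0.425, abs=0.005)
        assert (core >= 2).mean() == pytest.approx(0.203, abs=0.005)
        assert (rim >= 1).mean() == pytest.approx(0.232, abs=0.005)
        assert (rim >= 2).mean() == pytest.approx(0.089, abs=0.005)

    def test_mut_positively_correlated_with_wt(self):
        cfg = SimulationConfig(seed=2)
        df = simulate_ddg(["core"] * 20_000, cfg)
        assert np.corrcoef(df["ddg_wt"], df["ddg_mut"])[0, 1] > 0.3

    def test_table_round_trip_through_reader(self, tmp_path):
        cx, _ = make_toy_complex(SimulationConfig(seed=11))
        ann = assign_regions(cx, {"A"}, {"B"})
        region_by_key = {k: a.region for k, a in ann.items()}
        table = ddg_table_for_complex(cx, region_by_key, SimulationConfig(seed=11))
        path = tmp_path / "ddg.tsv"
        table.to_csv(path, sep="\t", index=False)
        recs = read_ddg_table(path)
        assert len(recs) == len(table)
        assert all(r.wt_tier is not None for r in recs.values())


def test_savs_for_complex_wild_types_match_structure():
    cx, _ = make_toy_complex(SimulationConfig(seed=11))
    savs = savs_for_complex(cx, SimulationConfig(seed=11))
    by_key = {(r.chain_id, r.seq_number): r.aa_type for r in cx.residues}
    from intersav.variants import parse_protein_change
    for _, row in savs.iterrows():
        wt, pos, mut = parse_protein_change(row["change"])
        chain = row["accession"].split("_")[1]
        assert by_key[(chain, pos)] == wt
        assert wt != mut


def test_chisq_type_one_error_near_nominal():
    """Under proportional (null) variant placement, the four-region
    observed-vs-expected chi-square rejects at ~5%."""
    from intersav.stats import chisq_obs_vs_expected
    sizes = {"buried": 72467, "core": 13486, "rim": 23478, "surface": 141704}
    rate = 0.013
    rates = {r: rate for r in sizes}
    rng = np.random.default_rng(7)
    n_rep = 400
    rejections = 0
    size_arr = np.array(list(sizes.values()), dtype=float)
    for _ in range(n_rep):
        counts = simulate_counts(sizes, rates, rng)
        obs = np.array([counts[r] for r in sizes], dtype=float)
        expected = obs.sum() * size_arr / size_arr.sum()
        _, p = chisq_obs_vs_expected(obs, expected)
        rejections += p < 0.05
    se = np.sqrt(0.05 * 0.95 / n_rep)
    assert abs(rejections / n_rep - 0.05) < 3 * se
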