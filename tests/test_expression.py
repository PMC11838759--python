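import numpy as np
import pandas as pd
import pytest
from scipy.stats import pearsonr

from skingwas.errors import DegenerateInputError, DomainError
from skingwas.expression import (benjamini_hochberg, group_fold_change,
                                 module_score, per_donor_log2fc,
                                 stimulation_contrast)
from skingwas.simulate import simulate_stimulation_matrix


def matrix(values, genes=None, cols=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    cols = cols or [f"c{j}" for j in range(values.shape[1])]
    return pd.DataFrame(values, index=genes, columns=cols)


class TestModuleScore:
    def test_identical_expression_scores_zero(self):
        m = matrix(np.full((60, 8), 3.7))
        s = module_score(m, ["g0", "g1", "g2"], rng=0)
        assert np.abs(s.to_numpy()).max() <= 1e-9

    def test_planted_shift_recovered(self, rng):
        m = matrix(rng.lognormal(0, 0.4, size=(300, 40)))
        module = [f"g{i}" for i in range(10)]
        shifted_cols = m.columns[:20]
        m.loc[module, shifted_cols] += 2.0
        s = module_score(m, module, rng=1)
        assert s[shifted_cols].mean() == pytest.approx(2.0, abs=0.4)
        assert abs(s[m.columns[20:]].mean()) < 0.4

    def test_degenerate_sizes_run(self, rng):
        m = matrix(rng.lognormal(0, 0.3, size=(30, 4)))
        s = module_score(m, ["g5"], n_bins=2, n_ctrl=100, rng=0)
        assert len(s) == 4 and np.isfinite(s).all()

    def test_missing_module_is_error(self, rng):
        m = matrix(rng.lognormal(0, 0.3, size=(10, 3)))
        with pytest.raises(DegenerateInputError):
            module_score(m, ["absent"], rng=0)

    def test_negative_values_rejected(self):
        m = matrix([[1.0, -0.5], [0.2, 0.3]])
        with pytest.raises(DomainError):
            module_score(m, ["g0"], rng=0)

    def test_invariance_under_column_and_row_permutation(self, rng):
        m = matrix(rng.lognormal(0, 0.4, size=(80, 12)))
        module = ["g3", "g40", "g77"]
        s = module_score(m, module, rng=7)
        cols = list(m.columns)
        rng.shuffle(cols)
        s_col = module_score(m[cols], module, rng=7)
        assert np.allclose(s[cols].to_numpy(), s_col.to_numpy())
        rows = list(m.index)
        rng.shuffle(rows)
        s_row = module_score(m.loc[rows], module, rng=7)
        assert np.allclose(s.to_numpy(), s_row.to_numpy())


class TestGroupFoldChange:
    def _labelled(self, a_vals, b_vals):
        vals = np.concatenate([a_vals, b_vals])[None, :]
        m = matrix(vals, genes=["IL1A"])
        labels = pd.Series(["lesional"] * len(a_vals)
                           + ["nonlesional"] * len(b_vals), index=m.columns)
        return m, labels

    def test_identical_groups(self, rng):
        v = rng.lognormal(0, 0.3, 30)
        m, labels = self._labelled(v, v)
        fc, p = group_fold_change(m, labels, "IL1A", "lesional", "nonlesional")
        assert fc == pytest.approx(1.0)
        assert p > 0.99

    def test_doubled_group(self, rng):
        b = rng.lognormal(2, 0.2, 200)
        m, labels = self._labelled(2 * b, b)
        fc, p = group_fold_change(m, labels, "IL1A", "lesional", "nonlesional")
        assert 1.5 < fc < 2.0  # pseudocount attenuates the ratio below 2
        assert p < 1e-6

    def test_absent_gene(self, rng):
        m, labels = self._labelled(rng.random(5), rng.random(5))
        with pytest.raises(DegenerateInputError):
            group_fold_change(m, labels, "KRT1", "lesional", "nonlesional")


class TestBenjaminiHochberg:
    def test_matches_brute_force_step_up(self, rng):
        def brute(p):
            p = np.asarray(p)
            n = len(p)
            order = np.argsort(p)
            adj = np.empty(n)
            prev = 1.0
            for rank in range(n, 0, -1):
                i = order[rank - 1]
                prev = min(prev, p[i] * n / rank)
                adj[i] = prev
            return adj
        for _ in range(25):
            n = int(rng.integers(1, 51))
            p = rng.random(n)
            assert np.allclose(benjamini_hochberg(p), brute(p), atol=1e-12)


class TestStimulationContrast:
    def test_planted_proportionality_gives_high_r(self):
        planted = {f"SG{i:04d}": (1.5 + 0.45 * i, 1.5 + 0.15 * i)
                   for i in range(15)}
        table = simulate_stimulation_matrix(120, 4, planted, rng=3,
                                            noise_sigma=0.05)
        res = stimulation_contrast(table)
        assert res.n_induced >= 10
        assert res.pearson_r > 0.7

    def test_null_diff_keeps_r_moderate(self):
        hits = 0
        n_seeds = 40
        for seed in range(n_seeds):
            planted = {f"SG{i:04d}": (2.5, 2.5) for i in range(15)}
            table = simulate_stimulation_matrix(40, 4, planted, rng=1000 + seed)
            res = stimulation_contrast(table)
            if res.n_induced >= 3 and abs(res.pearson_r) < 0.5:
                hits += 1
        assert hits >= 0.9 * n_seeds

    def test_fc_boundary_is_strict(self):
        # a gene with geometric-mean fold change exactly 1.5 is not induced
        rows = []
        for donor in ("A00", "A01", "B00", "B01"):
            group = donor[0]
            rows.append(("g_border", donor, group, "unstimulated", 100.0))
            # (stim + 1)/(unstim + 1) = 1.5 exactly
            rows.append(("g_border", donor, group, "stimulated", 150.5))
            rows.append(("g_in", donor, group, "unstimulated", 100.0))
            rows.append(("g_in", donor, group, "stimulated", 200.0))
        table = pd.DataFrame(rows, columns=["gene", "donor", "group",
                                            "condition", "count"])
        with pytest.warns(UserWarning):
            res = stimulation_contrast(table)
        tab = res.table.set_index("gene")
        assert tab.loc["g_border", "fc"] == pytest.approx(1.5)
        assert not tab.loc["g_border", "induced"]
        assert tab.loc["g_in", "induced"]

    def test_small_induced_set_is_undefined(self):
        table = simulate_stimulation_matrix(20, 3, None, rng=5)
        with pytest.warns(UserWarning):
            res = stimulation_contrast(table)
        assert np.isnan(res.pearson_r)

    def test_pearson_matches_closed_form(self):
        planted = {f"SG{i:04d}": (1.8 + 0.3 * i, 1.6 + 0.1 * i)
                   for i in range(12)}
        table = simulate_stimulation_matrix(60, 4, planted, rng=9,
                                            noise_sigma=0.05)
        res = stimulation_contrast(table)
        induced = res.table[res.table["induced"]]
        x, y = induced["avg"].to_numpy(), induced["diff"].to_numpy()
        r_closed = (np.cov(x, y, bias=True)[0, 1]
                    / (x.std() * y.std()))
        assert res.pearson_r == pytest.approx(r_closed, abs=1e-12)

    def test_single_donor_group_rejected(self):
        table = simulate_stimulation_matrix(10, 1, None, rng=2)
        with pytest.raises(DegenerateInputError):
            stimulation_contrast(table)

    def test_unpaired_rows_rejected(self):
        table = simulate_stimulation_matrix(5, 2, None, rng=2)
        broken = table[~((table["gene"] == "SG0000")
                         & (table["condition"] == "stimulated"))]
        with pytest.raises(DegenerateInputError):
            stimulation_contrast(broken)


def test_per_donor_log2fc_pseudocount():
    rows = [("g", "A00", "A", "unstimulated", 3.0),
            ("g", "A00", "A", "stimulated", 7.0)]
    table = pd.DataFrame(rows, columns=["gene", "donor", "group",
                                        "condition", "count"])
    out = per_donor_log2fc(table, pseudocount=1.0)
    assert out.loc[0, "log2fc"] == pytest.approx(1.0)  # log2(8/4)
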