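import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from diffindex import (
    common_genes,
    fit_developing_line,
    gen_timecourse,
    select_significant,
    weight_significance,
)
from diffindex.gene_stats import CUTOFF_PRESETS, collapse_to_genes


def brute_force_bh(p: np.ndarray) -> np.ndarray:
    """Step-up definition: q_(i) = min_{j >= i} p_(j) * m / j, clipped at 1."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(m)
    for rank, idx in enumerate(order, start=1):
        js = np.arange(rank, m + 1)
        q_sorted[rank - 1] = min(1.0, np.min(p[order][rank - 1:] * m / js))
    out = np.empty(m)
    out[order] = q_sorted
    return out


@pytest.fixture(scope="module")
def fitted():
    tc, planted = gen_timecourse(n_genes=500, n_signal=30, seed=5)
    return fit_developing_line(tc), planted


class TestWeightSignificance:
    def test_zero_weight_in_symmetric_table_gets_p_one(self):
        line = _line_with_weights([-2.0, -1.0, 0.0, 1.0, 2.0])
        tab = weight_significance(line)
        mid = tab.iloc[2]
        assert mid["z"] == 0.0
        assert mid["p"] == pytest.approx(1.0)

    def test_table_columns_and_direction(self, fitted):
        line, _ = fitted
        tab = weight_significance(line)
        assert list(tab.columns) == ["weight", "z", "p", "fdr", "direction"]
        assert (tab.loc[tab["weight"] > 0, "direction"] == "up").all()
        w = tab["weight"].to_numpy()
        assert np.allclose(tab["z"], (w - w.mean()) / w.std(ddof=1))
        # fdr monotone in p order
        srt = tab.sort_values("p")
        assert np.all(np.diff(srt["fdr"].to_numpy()) >= -1e-12)

    def test_planted_probes_dominate_small_p_ranks(self, fitted):
        line, planted = fitted
        tab = weight_significance(line)
        top = set(tab.nsmallest(len(planted), "p").index)
        assert len(top & set(planted)) >= 0.9 * len(planted)

    def test_requires_oriented_line_and_variance(self, fitted):
        line, _ = fitted
        unoriented = line.restrict(line.probe_ids)
        unoriented.oriented = False
        with pytest.raises(ValueError, match="orient"):
            weight_significance(unoriented)
        flat = _line_with_weights([1.0, 1.0, 1.0, 1.0])
        with pytest.raises(ValueError, match="variance"):
            weight_significance(flat)

    def test_permutation_null_agrees_on_strong_signal(self):
        tc, planted = gen_timecourse(n_genes=120, n_signal=10,
                                     drift_scale=2.0, noise_sd=0.1, seed=7)
        line = fit_developing_line(tc)
        tab = weight_significance(line, null="permutation",
                                  n_permutations=60, seed=3)
        top = set(tab.nsmallest(10, "p").index)
        assert len(top & set(planted)) >= 8


class TestBH:
    def test_worked_example(self):
        line = _line_with_weights([0.1, 0.2, 0.3, 0.4])
        tab = weight_significance(line)
        tab["p"] = [0.01, 0.02, 0.03, 0.5]
        expect = brute_force_bh(np.array([0.01, 0.02, 0.03, 0.5]))
        assert np.allclose(expect, [0.04, 0.04, 0.04, 0.5])
        from statsmodels.stats.multitest import multipletests
        assert np.allclose(multipletests(tab["p"], method="fdr_bh")[1],
                           expect)

    @given(st.lists(st.floats(min_value=1e-8, max_value=1.0), min_size=1,
                    max_size=40))
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_statsmodels_bh_matches_step_up_oracle(self, ps):
        from statsmodels.stats.multitest import multipletests
        p = np.array(ps)
        assert np.allclose(multipletests(p, method="fdr_bh")[1],
                           brute_force_bh(p), atol=1e-12)


class TestSelection:
    def test_empty_and_all_null_tables(self):
        empty = pd.DataFrame(columns=["weight", "z", "p", "fdr", "direction"])
        assert select_significant(empty) == ([], [])
        line = _line_with_weights([-1.0, 0.0, 1.0, 0.5])
        tab = weight_significance(line)
        tab["p"] = 1.0
        tab["fdr"] = 1.0
        assert select_significant(tab) == ([], [])

    def test_worked_bh_selection(self):
        tab = pd.DataFrame({
            "weight": [1.0, -1.0, 2.0, 0.5],
            "z": [1, -1, 2, 0.5],
            "p": [0.01, 0.02, 0.03, 0.5],
            "fdr": [0.04, 0.04, 0.04, 0.5],
            "direction": ["up", "down", "up", "up"],
        }, index=["P1", "P2", "P3", "P4"])
        up, down = select_significant(tab, p_cut=0.05, fdr_cut=0.1)
        assert up == ["P1", "P3"] and down == ["P2"]

    def test_monotone_in_cuts(self):
        rng = np.random.default_rng(8)
        tc, _ = gen_timecourse(n_genes=400, n_signal=40, seed=8)
        tab = weight_significance(fit_developing_line(tc))
        tight = set().union(*select_significant(tab, 0.001, 0.05))
        loose = set().union(*select_significant(tab, 0.01, 0.1))
        assert tight <= loose

    def test_published_presets(self):
        assert CUTOFF_PRESETS["results2011"] == {"p_cut": 0.01,
                                                 "fdr_cut": 0.1}
        assert CUTOFF_PRESETS["methods2011"] == {"p_cut": 0.001,
                                                 "fdr_cut": 0.1}


class TestCommonGenes:
    def test_intersections(self):
        a = (["P1", "P2"], ["P5"])
        b = (["P2", "P3"], ["P5", "P6"])
        assert common_genes(a, b) == (["P2"], ["P5"])
        assert common_genes(a, a) == (sorted(a[0]), sorted(a[1]))
        assert common_genes(a, ([], [])) == ([], [])


class TestCollapse:
    def test_keeps_max_abs_z_probe_per_symbol(self):
        tab = pd.DataFrame({
            "weight": [1.0, 3.0, -2.0],
            "z": [1.0, 3.0, -2.0],
            "p": [0.3, 0.01, 0.05],
            "fdr": [0.3, 0.02, 0.06],
            "direction": ["up", "up", "down"],
        }, index=pd.Index(["P1", "P2", "P3"], name="probe_id"))
        mapping = pd.Series({"P1": "GATA4", "P2": "GATA4", "P3": "SOX2"})
        out = collapse_to_genes(tab, mapping)
        assert list(out.index) == ["GATA4", "SOX2"]
        assert out.loc["GATA4", "z"] == 3.0


def _line_with_weights(weights):
    from diffindex.devline import DevelopingLineResults

    w = pd.Series(np.asarray(weights, dtype=float),
                  index=[f"P{i}" for i in range(len(weights))])
    return DevelopingLineResults(
        weights=w, lambdas=np.array([1.0]), cosine_constant=1.0,
        segment_norms=np.array([1.0]), residual=0.0, oriented=True)
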