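"""Coexpression table and the three-criterion network assembly."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from florinet.io_formats import CountMatrix
from florinet.trn_build import TRNConfig, assemble_trn, compute_coexpression, deg_union


def _cm_from_rows(rows: dict[str, list[int]], conditions: str) -> CountMatrix:
    df = pd.DataFrame.from_dict(rows, orient="index", dtype=np.int64)
    df.columns = [f"s{i}" for i in range(df.shape[1])]
    return CountMatrix(df, pd.Series(list(conditions), index=df.columns))


def _with_housekeeping(rows: dict[str, list[int]]) -> dict[str, list[int]]:
    """Pad with constant genes so every size factor is exactly 1 and the
    normalization step cannot perturb ranks."""
    n = len(next(iter(rows.values())))
    out = dict(rows)
    for i in range(3 * len(rows) + 1):
        out[f"hk{i}"] = [10] * n
    return out


class TestSpearman:
    def test_identity_and_reversal(self):
        cm = _cm_from_rows(
            _with_housekeeping(
                {"tf": [1, 2, 3, 4, 5], "same": [10, 20, 30, 40, 50], "rev": [50, 40, 30, 20, 10]}
            ),
            "CCFFF",
        )
        rho = compute_coexpression(cm, ["tf"])
        assert rho.at["tf", "same"] == pytest.approx(1.0)
        assert rho.at["tf", "rev"] == pytest.approx(-1.0)
        assert np.isnan(rho.at["tf", "tf"])

    def test_textbook_value(self):
        # ranks (1,2,3,4,5) vs (2,1,4,3,5): sum d^2 = 4 -> rho = 1 - 24/120 = 0.8
        cm = _cm_from_rows(
            _with_housekeeping({"x": [1, 2, 3, 4, 5], "y": [2, 1, 4, 3, 5]}), "CCFFF"
        )
        rho = compute_coexpression(cm, ["x"])
        assert rho.at["x", "y"] == pytest.approx(0.8)

    def test_constant_vector_is_nan_not_zero(self):
        cm = _cm_from_rows(_with_housekeeping({"tf": [1, 2, 3, 4], "flat": [7, 7, 7, 7]}), "CCFF")
        rho = compute_coexpression(cm, ["tf"])
        assert np.isnan(rho.at["tf", "flat"])

    def test_matches_scipy_including_ties(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 12, size=(60, 9))  # small ints force ties
        counts[0] = 1  # keep a positive reference gene for normalization
        rows = {f"g{i}": list(counts[i]) for i in range(60)}
        cm = _cm_from_rows(rows, "CCCIIIFFF")
        from florinet.expression_de import normalize_counts

        _, norm = normalize_counts(cm)
        rho = compute_coexpression(cm, ["g1", "g2", "g3"])
        for tf in ("g1", "g2", "g3"):
            for g in (f"g{j}" for j in range(4, 30)):
                expected = stats.spearmanr(norm.loc[tf], norm.loc[g]).statistic
                got = rho.at[tf, g]
                if np.isnan(expected):
                    assert np.isnan(got)
                else:
                    assert got == pytest.approx(expected, abs=1e-12)

    def test_too_few_samples_rejected(self):
        cm = _cm_from_rows({"tf": [1, 2]}, "CF")
        with pytest.raises(ValueError, match=">= 3 samples"):
            compute_coexpression(cm, ["tf"])


def _hits(pairs):
    return pd.DataFrame(
        [
            {"gene": g, "motif": m, "offset": 1, "strand": "+", "score_bits": 10.0, "p_value": 1e-6}
            for m, g in pairs
        ]
    )


class TestAssembly:
    def test_empty_hits_empty_network(self):
        rho = pd.DataFrame(np.zeros((1, 2)), index=["TF1"], columns=["TF1", "g1"])
        trn = assemble_trn(pd.DataFrame(columns=["gene", "motif"]), rho, set(), {"TF1": "M1"}, set())
        assert len(trn.edges) == 0 and trn.nodes == set()

    def test_criteria_gate_each_edge(self):
        """Hand-applied criteria: motif + rho + DEG/floral must all hold."""
        rho = pd.DataFrame(
            [[np.nan, 0.93, -0.92, 0.95, 0.5]],
            index=["TF1"],
            columns=["TF1", "g1", "g2", "g3", "g4"],
        )
        rho.loc["TF2"] = [0.2, 0.1, 0.1, 0.95, 0.1]
        hits = _hits([("M1", "g1"), ("M1", "g2"), ("M1", "g4")])  # TF2->g3 has NO hit
        trn = assemble_trn(
            hits,
            rho,
            deg_genes={"g1", "TF1"},
            tf_map={"TF1": "M1", "TF2": "M2"},
            floral_set={"TF1"},
            comparison="C-F",
        )
        assert {(r.tf, r.target, r.sign) for r in trn.edges.itertuples()} == {
            ("TF1", "g1", "+"),
            ("TF1", "g2", "-"),  # kept via |rho| in absolute mode, floral TF1
        }

    def test_high_rho_without_deg_or_floral_excluded(self):
        rho = pd.DataFrame([[0.95]], index=["TF1"], columns=["g1"])
        trn = assemble_trn(_hits([("M1", "g1")]), rho, set(), {"TF1": "M1"}, set())
        assert len(trn.edges) == 0

    def test_signed_mode_drops_negative_edges(self):
        rho = pd.DataFrame([[0.93, -0.93]], index=["TF1"], columns=["g1", "g2"])
        trn = assemble_trn(
            _hits([("M1", "g1"), ("M1", "g2")]),
            rho,
            {"g1", "g2"},
            {"TF1": "M1"},
            {"g1", "g2"},
            TRNConfig(rho_mode="signed"),
        )
        assert {(r.tf, r.target) for r in trn.edges.itertuples()} == {("TF1", "g1")}

    def test_monotone_in_every_filter(self, dataset, hits, de_tables):
        degs = deg_union(de_tables)
        floral = dataset.gene_sets["floral"]
        rho = compute_coexpression(
            dataset.counts, list(dataset.tf_map), dataset.counts.samples_of("C", "F")
        )

        def n_edges(rho_thr, degs_, floral_):
            cfg = TRNConfig(rho_threshold=rho_thr)
            return len(
                assemble_trn(hits, rho, degs_, dataset.tf_map, floral_, cfg).edges
            )

        base = n_edges(0.9, degs, floral)
        assert n_edges(0.95, degs, floral) <= base
        smaller_deg = set(sorted(degs)[: len(degs) // 2])
        assert n_edges(0.9, smaller_deg, floral) <= base
        smaller_floral = set(sorted(floral)[: len(floral) // 2])
        assert n_edges(0.9, degs, smaller_floral) <= base

    def test_edge_order_is_deterministic(self, trns):
        df = trns["C-F"].edges
        keys = list(zip(df["tf"], df["target"]))
        assert keys == sorted(keys)
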