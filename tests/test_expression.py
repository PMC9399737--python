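"""TPM stratification, significance filters, Tukey boxplot statistics."""
import math

import numpy as np
import pandas as pd
import pytest

from chromprofiler.coverage import CoverageTrack
from chromprofiler.expression import (
    boxplot_summary,
    filter_significant,
    gene_body_signal,
    read_rmats_table,
    splice_event_gene_sets,
    stratify_by_expression,
)

from conftest import make_gene


def expr_df(rows):
    return pd.DataFrame(rows, columns=["gene_id", "biotype", "tpm"])


class TestStratify:
    @pytest.mark.parametrize(
        "biotype,tpm,stratum",
        [
            ("protein_coding", 2.0, "low"),    # boundary inclusive
            ("protein_coding", 3.0, None),     # gap between cutoffs
            ("protein_coding", 4.0, "high"),
            ("protein_coding", 0.0, None),     # unexpressed: neither
            ("protein_coding", 0.001, "low"),
            ("lncRNA", 0.1, "low"),
            ("lncRNA", 0.3, None),
            ("lncRNA", 0.5, "high"),
        ],
    )
    def test_published_cutoff_boundaries(self, biotype, tpm, stratum):
        df = expr_df([{"gene_id": "g", "biotype": biotype, "tpm": tpm}])
        strata = stratify_by_expression(df, biotype)
        for name in ("low", "high"):
            assert ("g" in strata[name]) == (stratum == name)

    def test_strata_are_disjoint(self):
        rng = np.random.default_rng(8)
        df = expr_df(
            [{"gene_id": f"g{i}", "biotype": "protein_coding",
              "tpm": float(t)} for i, t in enumerate(rng.lognormal(0.5, 2, 200))]
        )
        strata = stratify_by_expression(df, "protein_coding")
        assert strata["low"] & strata["high"] == set()

    def test_other_biotype_rows_ignored(self):
        df = expr_df([
            {"gene_id": "c", "biotype": "protein_coding", "tpm": 1.0},
            {"gene_id": "l", "biotype": "lncRNA", "tpm": 0.05},
        ])
        assert stratify_by_expression(df, "protein_coding")["low"] == {"c"}
        assert stratify_by_expression(df, "lncRNA")["low"] == {"l"}

    def test_unknown_biotype_errors(self):
        with pytest.raises(ValueError, match="biotype"):
            stratify_by_expression(expr_df([]), "rRNA")


class TestGeneBodySignal:
    def test_uniform_track(self):
        genes = [make_gene("a", "chr1", 100, 800), make_gene("b", "chr1", 2000, 2700)]
        sig = gene_body_signal(CoverageTrack.uniform({"chr1": 10000}, 3.0), genes)
        assert sig["a"] == 3.0 and sig["b"] == 3.0

    def test_track_confined_to_one_gene(self):
        genes = [make_gene("a", "chr1", 100, 800), make_gene("b", "chr1", 2000, 2700)]
        track = CoverageTrack.from_intervals({"chr1": 10000},
                                             [("chr1", 100, 800, 2.0)])
        sig = gene_body_signal(track, genes)
        assert sig["a"] == 2.0 and sig["b"] == 0.0

    def test_expression_coupled_track_orders_strata(self, synth_ann):
        """With amplitude coupled to TPM, the high stratum's gene-body signal
        exceeds the low stratum's."""
        from chromprofiler.synth import SignalSpec, generate_coverage, generate_expression

        ann, _ = synth_ann
        expr, _ = generate_expression(ann, seed=5)
        tpm = dict(zip(expr["gene_id"], expr["tpm"]))
        cov = generate_coverage(
            ann, SignalSpec(rho=1.0, gamma=0.0, expr_coupling=0.7, noise="none"),
            tpm=tpm)
        sig = gene_body_signal(cov.track, ann.genes)
        strata = stratify_by_expression(expr, "protein_coding")
        low = sig.reindex(sorted(strata["low"])).mean()
        high = sig.reindex(sorted(strata["high"])).mean()
        assert high > low


def quantile_oracle(values, q):
    """Brute-force linear-interpolation quantile on sorted order statistics."""
    xs = sorted(values)
    h = (len(xs) - 1) * q
    lo, hi = math.floor(h), math.ceil(h)
    return xs[lo] + (h - lo) * (xs[hi] - xs[lo])


class TestBoxplot:
    def test_one_to_hundred(self):
        box = boxplot_summary(np.arange(1.0, 101.0))
        assert box.median == 50.5
        assert box.q1 == 25.75
        assert box.q3 == 75.25
        assert box.whisker_low == 1.0 and box.whisker_high == 100.0
        assert box.outliers == ()

    def test_constant_vector(self):
        box = boxplot_summary([4.2] * 9)
        assert (box.median, box.q1, box.q3, box.whisker_low, box.whisker_high) \
            == (4.2, 4.2, 4.2, 4.2, 4.2)
        assert box.outliers == ()

    def test_single_extreme_flagged_outlier(self):
        """{0,0,0,100}: IQR = 25, upper fence = 25 + 37.5; 100 is outside."""
        box = boxplot_summary([0.0, 0.0, 0.0, 100.0])
        assert box.outliers == (100.0,)
        assert box.whisker_high == 0.0  # most extreme point inside the fence

    def test_whiskers_are_data_points_within_fences(self):
        x = np.array([1.0, 2, 3, 4, 5, 6, 7, 8, 9, 50])
        box = boxplot_summary(x)
        iqr = box.q3 - box.q1
        assert box.whisker_high == max(v for v in x if v <= box.q3 + 1.5 * iqr)
        assert box.whisker_low == min(v for v in x if v >= box.q1 - 1.5 * iqr)

    def test_agrees_with_brute_force_oracle_on_seeded_vectors(self):
        """100 random vectors: quartiles match an independent order-statistic
        interpolation to 1e-9."""
        rng = np.random.default_rng(123)
        for _ in range(100):
            n = int(rng.integers(1, 400))
            x = rng.normal(0, 10, n)
            box = boxplot_summary(x)
            assert box.q1 == pytest.approx(quantile_oracle(x, 0.25), abs=1e-9)
            assert box.median == pytest.approx(quantile_oracle(x, 0.50), abs=1e-9)
            assert box.q3 == pytest.approx(quantile_oracle(x, 0.75), abs=1e-9)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            boxplot_summary([])


def de_df(rows):
    return pd.DataFrame(rows, columns=["gene_id", "log2fc", "fdr"])


class TestFilterSignificant:
    def test_fc_and_fdr_boundaries_inclusive(self):
        """FC >= 2 means |log2fc| >= 1; FDR <= 0.05; both inclusive."""
        df = de_df([
            {"gene_id": "kept_up", "log2fc": 1.0, "fdr": 0.04},
            {"gene_id": "kept_boundary", "log2fc": -1.0, "fdr": 0.05},
            {"gene_id": "weak_fc", "log2fc": 0.99, "fdr": 0.001},
            {"gene_id": "weak_fdr", "log2fc": 3.0, "fdr": 0.051},
        ])
        out = filter_significant(df)
        assert list(out["gene_id"]) == ["kept_up", "kept_boundary"]
        assert list(out["direction"]) == ["up", "down"]

    def test_ten_row_toy_table_keeps_four(self):
        rows = [
            ("g0", 1.5, 0.01, True), ("g1", -2.0, 0.04, True),
            ("g2", 1.0, 0.05, True), ("g3", 2.5, 0.02, True),
            ("g4", 0.5, 0.001, False), ("g5", -0.9, 0.01, False),
            ("g6", 3.0, 0.06, False), ("g7", -4.0, 0.2, False),
            ("g8", 0.0, 0.0, False), ("g9", 0.3, 0.5, False),
        ]
        df = de_df([{"gene_id": g, "log2fc": f, "fdr": q} for g, f, q, _ in rows])
        out = filter_significant(df)
        assert sorted(out["gene_id"]) == sorted(g for g, _, _, keep in rows if keep)
        assert len(out) == 4

    def test_as_events_use_fdr_only(self):
        df = pd.DataFrame({
            "gene_id": ["a", "b"],
            "delta_psi": [0.01, -0.4],
            "fdr": [0.03, 0.2],
        })
        out = filter_significant(df, min_fc=2.0)
        # tiny delta_psi kept (no FC rule for splicing), high FDR dropped
        assert list(out["gene_id"]) == ["a"]
        assert list(out["direction"]) == ["up"]

    def test_subset_and_idempotent(self):
        rng = np.random.default_rng(31)
        df = de_df([
            {"gene_id": f"g{i}", "log2fc": float(f), "fdr": float(q)}
            for i, (f, q) in enumerate(zip(rng.normal(0, 2, 50),
                                           rng.uniform(0, 1, 50)))
        ])
        once = filter_significant(df)
        assert set(once["gene_id"]) <= set(df["gene_id"])
        twice = filter_significant(once)
        pd.testing.assert_frame_equal(
            once.reset_index(drop=True), twice.reset_index(drop=True))

    def test_missing_columns_error(self):
        with pytest.raises(ValueError, match="fdr"):
            filter_significant(pd.DataFrame({"gene_id": ["a"]}))
        with pytest.raises(ValueError, match="log2fc"):
            filter_significant(pd.DataFrame({"gene_id": ["a"], "fdr": [0.01]}))


class TestSpliceGeneSets:
    def _events(self, rows):
        df = pd.DataFrame(rows, columns=["gene_id", "event_type", "delta_psi", "fdr"])
        return filter_significant(df)

    def test_single_positive_event_up_only(self):
        sets = splice_event_gene_sets(self._events(
            [{"gene_id": "g", "event_type": "RI", "delta_psi": 0.3, "fdr": 0.01}]))
        assert sets == {"Up": {"g"}, "Down": set()}

    def test_gene_with_both_directions_in_both_sets(self):
        sets = splice_event_gene_sets(self._events([
            {"gene_id": "g", "event_type": "SE", "delta_psi": 0.3, "fdr": 0.01},
            {"gene_id": "g", "event_type": "RI", "delta_psi": -0.2, "fdr": 0.02},
        ]))
        assert sets["Up"] == {"g"} and sets["Down"] == {"g"}

    def test_empty_events_empty_sets(self):
        sets = splice_event_gene_sets(self._events([]))
        assert sets == {"Up": set(), "Down": set()}


class TestRmatsIO:
    def test_round_trip_via_generator_tables(self, tmp_path, synth_ann):
        from chromprofiler.synth import generate_events, write_rmats_tables

        ann, _ = synth_ann
        events, truth = generate_events(ann, seed=9, n_up=6, n_down=4)
        write_rmats_tables(events, tmp_path)
        frames = [
            read_rmats_table(tmp_path / f"{et}.MATS.JC.txt", et)
            for et in ("SE", "A5SS", "A3SS", "MXE", "RI")
        ]
        back = pd.concat(frames, ignore_index=True)
        sig = filter_significant(back)
        assert len(sig) == truth["n_significant"] == 10
        sets = splice_event_gene_sets(sig)
        assert sorted(sets["Up"]) == truth["up_genes"]
        assert sorted(sets["Down"]) == truth["down_genes"]

    def test_unknown_event_type_rejected(self, tmp_path):
        p = tmp_path / "x.txt"
        p.write_text("GeneID\tIncLevelDifference\tFDR\n")
        with pytest.raises(ValueError, match="event type"):
            read_rmats_table(p, "XX")
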