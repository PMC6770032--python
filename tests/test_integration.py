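"""Anti-correlation edge construction, its oracle equivalence, and exports."""

from datetime import date, timedelta

import numpy as np
import pandas as pd
import pytest

from agecorr.correlation import spearman_p_exact, spearman_rho
from agecorr.integration import (
    EXPORT_FORMATS,
    IntegrationConfig,
    IntegrationNetwork,
    export_network,
    integrate,
    read_graphml,
)
from agecorr.io import ExpressionMatrix, SampleRecord, TargetTable


def _samples(n, tissue="tumor", start=0):
    diag = date(2019, 1, 1)
    return [
        SampleRecord.create(
            f"S{start + i}", diag - timedelta(days=800 + 117 * i), diag, tissue
        )
        for i in range(n)
    ]


def _matrix(rows, ids, sample_ids, kind):
    return ExpressionMatrix(
        pd.DataFrame(np.asarray(rows, dtype=float), index=ids, columns=sample_ids),
        kind,
    )


@pytest.fixture
def toy():
    samples = _samples(6)
    sids = [s.sample_id for s in samples]
    mirna = _matrix([[1, 2, 3, 4, 5, 6]], ["m1"], sids, "mirna")
    gene = _matrix(
        [[6, 5, 4, 3, 2, 1], [1.5, 2.5, 3, 4.2, 5, 6.1], [3, 1, 4, 1.5, 5, 2]],
        ["gA", "gB", "gC"],
        sids,
        "gene",
    )
    targets = TargetTable.from_pairs([("m1", "gA"), ("m1", "gB"), ("m1", "gC")])
    return mirna, gene, targets, samples


class TestEdgeRetention:
    def test_perfect_anticorrelation_retained(self, toy):
        mirna, gene, targets, samples = toy
        net = integrate(mirna, gene, ["m1"], targets, samples)
        edge = net.edges.set_index("gene").loc["gA"]
        assert edge["rho"] == pytest.approx(-1.0)
        assert edge["p"] < 0.05

    def test_positively_tracking_gene_never_edge(self, toy):
        mirna, gene, targets, samples = toy
        net = integrate(
            mirna, gene, ["m1"], targets, samples, IntegrationConfig(alpha=0.999)
        )
        assert "gB" not in net.gene_nodes  # rho > 0 fails the sign filter

    def test_candidate_without_targets_reported_not_fatal(self, toy):
        mirna_df = pd.concat(
            [toy[0].data, pd.DataFrame([[2, 1, 4, 3, 6, 5]], index=["m2"],
                                       columns=toy[0].data.columns)]
        )
        mirna = ExpressionMatrix(mirna_df, "mirna")
        net = integrate(mirna, toy[1], ["m1", "m2"], toy[2], toy[3])
        assert net.candidates_without_targets == {"m2"}

    def test_unknown_candidate_rejected(self, toy):
        mirna, gene, targets, samples = toy
        with pytest.raises(ValueError, match="mX"):
            integrate(mirna, gene, ["mX"], targets, samples)

    def test_empty_network_warns_but_valid(self, toy):
        mirna, gene, _, samples = toy
        targets = TargetTable.from_pairs([("m1", "gB")])  # positive tracker only
        with pytest.warns(UserWarning, match="empty network"):
            net = integrate(mirna, gene, ["m1"], targets, samples)
        assert net.n_edges == 0

    def test_tumor_scope_excludes_normal_samples(self, toy):
        mirna, gene, targets, samples = toy
        # add normal samples carrying a contradictory signal
        extra = _samples(4, tissue="normal", start=10)
        sids = [s.sample_id for s in extra]
        mirna2 = ExpressionMatrix(
            pd.concat([mirna.data, pd.DataFrame([[1, 2, 3, 4]], index=["m1"],
                                                columns=sids)], axis=1),
            "mirna",
        )
        gene2 = ExpressionMatrix(
            pd.concat([gene.data, pd.DataFrame([[1, 2, 3, 4], [0, 0, 1, 1], [1, 1, 0, 0]],
                                               index=["gA", "gB", "gC"],
                                               columns=sids)], axis=1),
            "gene",
        )
        net_t = integrate(mirna2, gene2, ["m1"], targets, samples + extra,
                          IntegrationConfig(scope="tumor"))
        assert net_t.n_samples == 6
        net_all = integrate(mirna2, gene2, ["m1"], targets, samples + extra,
                            IntegrationConfig(scope="all"))
        assert net_all.n_samples == 10


class TestOracleEquivalence:
    def test_edge_set_equals_brute_force_double_loop(self, rng):
        """Randomized small instances: edges == the naive candidate x target loop."""
        for trial in range(30):
            n = int(rng.integers(5, 9))
            samples = _samples(n)
            sids = [s.sample_id for s in samples]
            n_mirna, n_gene = int(rng.integers(2, 5)), int(rng.integers(3, 8))
            mids = [f"m{i}" for i in range(n_mirna)]
            gids = [f"g{i}" for i in range(n_gene)]
            mirna = _matrix(rng.normal(size=(n_mirna, n)), mids, sids, "mirna")
            gene = _matrix(rng.normal(size=(n_gene, n)), gids, sids, "gene")
            pairs = [
                (m, g) for m in mids for g in gids if rng.random() < 0.5
            ] or [(mids[0], gids[0])]
            targets = TargetTable.from_pairs(pairs)
            alpha = float(rng.uniform(0.05, 0.6))
            cfg = IntegrationConfig(alpha=alpha)
            with np.errstate(all="ignore"):
                import warnings as w

                with w.catch_warnings():
                    w.simplefilter("ignore")
                    net = integrate(mirna, gene, mids, targets, samples, cfg)

                    expected = set()
                    for m, g in pairs:
                        rho = spearman_rho(
                            mirna.data.loc[m, sids], gene.data.loc[g, sids]
                        )
                        p, _ = spearman_p_exact(rho, n)
                        if rho < 0 and p < alpha:
                            expected.add((m, g))
            assert net.edge_set() == expected, f"trial {trial}"

    def test_alpha_monotone_thinning(self, reduced_cohort):
        """Raising alpha never removes edges; lowering never adds them."""
        candidates = sorted(reduced_cohort.truth.ids("mirna", scope="tumor_only"))
        targets = reduced_cohort.targets.restrict(reduced_cohort.gene.feature_ids)
        args = (reduced_cohort.mirna, reduced_cohort.gene, candidates, targets,
                reduced_cohort.samples)
        e_tight = integrate(*args, IntegrationConfig(alpha=0.01)).edge_set()
        e_mid = integrate(*args, IntegrationConfig(alpha=0.05)).edge_set()
        e_loose = integrate(*args, IntegrationConfig(alpha=0.2)).edge_set()
        assert e_tight <= e_mid <= e_loose

    def test_restricting_targets_never_adds_edges(self, reduced_cohort):
        candidates = sorted(reduced_cohort.truth.ids("mirna", scope="tumor_only"))
        targets = reduced_cohort.targets.restrict(reduced_cohort.gene.feature_ids)
        full = integrate(reduced_cohort.mirna, reduced_cohort.gene, candidates,
                         targets, reduced_cohort.samples).edge_set()
        half_universe = sorted(reduced_cohort.gene.feature_ids)[::2]
        import warnings as w

        with w.catch_warnings():
            w.simplefilter("ignore")
            sub = integrate(reduced_cohort.mirna, reduced_cohort.gene, candidates,
                            targets.restrict(half_universe),
                            reduced_cohort.samples).edge_set()
        assert sub <= full

    def test_planted_repression_recovered(self, reduced_cohort):
        """Most planted (candidate miRNA -> target) pairs survive as edges."""
        candidates = sorted(reduced_cohort.truth.ids("mirna", scope="tumor_only"))
        targets = reduced_cohort.targets.restrict(reduced_cohort.gene.feature_ids)
        net = integrate(reduced_cohort.mirna, reduced_cohort.gene, candidates,
                        targets, reduced_cohort.samples)
        planted = reduced_cohort.truth.repression_pairs
        recovered = net.edge_set() & planted
        assert len(recovered) / len(planted) >= 0.8


class TestExports:
    def _net(self, toy):
        mirna, gene, targets, samples = toy
        return integrate(mirna, gene, ["m1"], targets, samples,
                         IntegrationConfig(alpha=0.2))

    def test_sif_line_count_matches_edges(self, toy, tmp_path):
        net = self._net(toy)
        paths = export_network(net, tmp_path / "net.sif", "sif")
        lines = paths[0].read_text().splitlines()
        assert len(lines) == net.n_edges
        assert all(len(l.split("\t")) == 3 for l in lines)
        attrs = pd.read_csv(paths[1], sep="\t")
        assert len(attrs) == net.n_edges

    def test_graphml_round_trip_preserves_structure(self, toy, tmp_path):
        net = self._net(toy)
        export_network(net, tmp_path / "net.graphml", "graphml")
        back = read_graphml(tmp_path / "net.graphml")
        assert back.edge_set() == net.edge_set()
        merged = net.edges.merge(back.edges, on=["mirna", "gene"])
        assert np.allclose(merged["rho_x"], merged["rho_y"])

    def test_empty_network_graphml_valid(self, tmp_path):
        empty = IntegrationNetwork(
            edges=pd.DataFrame(columns=["mirna", "gene", "rho", "p", "n",
                                        "method", "ties"])
        )
        export_network(empty, tmp_path / "empty.graphml", "graphml")
        back = read_graphml(tmp_path / "empty.graphml")
        assert back.n_edges == 0

    def test_unknown_format_lists_supported(self, toy, tmp_path):
        with pytest.raises(ValueError, match=", ".join(EXPORT_FORMATS)):
            export_network(self._net(toy), tmp_path / "x", "gexf")

    def test_bipartite_and_weight_convention(self, toy, tmp_path):
        net = self._net(toy)
        g = net.to_graph()
        for u, v, data in g.edges(data=True):
            kinds = {g.nodes[u]["kind"], g.nodes[v]["kind"]}
            assert kinds == {"mirna", "gene"}
            assert data["rho"] < 0
            assert data["width"] == pytest.approx(abs(data["rho"]))
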