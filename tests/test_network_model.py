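import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from termnet.errors import DomainError, ParseError, ValidationError
from termnet.network_model import (
    Activity,
    Compound,
    CompoundClass,
    CrossFeedingNetwork,
    MetabolicActivity,
    abundance_transport_correlation,
    confidence_score,
    load_network,
    metabolite_usage,
    transport_profile,
)
from termnet.segmentation import AbundanceTable

from conftest import make_network


def write_tables(tmp_path, activity_rows, compound_rows):
    act = tmp_path / "activities.tsv"
    act.write_text(
        "species\tcompound\tactivity\tn_publications\tkegg_flag\n"
        + "".join(f"{r}\n" for r in activity_rows)
    )
    comp = tmp_path / "compounds.tsv"
    comp.write_text(
        "compound\tclass\tdegradation_products\n" + "".join(f"{r}\n" for r in compound_rows)
    )
    return act, comp


class TestLoadNetwork:
    def test_toy_tables(self, tmp_path):
        act, comp = write_tables(
            tmp_path,
            [
                "A\tglucose\timport\t3\t1",
                "A\tacetate\texport\t1\t0",
                "B\tcellulose\tdegrades\t2\t1",
            ],
            [
                "glucose\tsmall_metabolite\t",
                "acetate\tsmall_metabolite\t",
                "cellulose\tmacromolecule\tglucose",
            ],
        )
        net = load_network(act, comp)
        assert net.n_species == 2
        assert net.n_compounds == 3
        assert net.effective_exports("B") == {"glucose"}
        assert net.n_transport_events == 2
        assert net.n_degradation_events == 1

    def test_empty_activity_table(self, tmp_path):
        act, comp = write_tables(tmp_path, [], ["glucose\tsmall_metabolite\t"])
        net = load_network(act, comp)
        assert net.n_species == 0

    def test_unknown_activity_keyword_names_row(self, tmp_path):
        act, comp = write_tables(
            tmp_path, ["A\tglucose\tconsumes\t1\t0"], ["glucose\tsmall_metabolite\t"]
        )
        with pytest.raises(ParseError, match="row 2"):
            load_network(act, comp)

    def test_degrades_without_products_rejected(self, tmp_path):
        act, comp = write_tables(
            tmp_path, ["B\tcellulose\tdegrades\t1\t0"], ["cellulose\tmacromolecule\t"]
        )
        with pytest.raises(ValidationError, match="no degradation products"):
            load_network(act, comp)

    def test_conflicting_duplicates_rejected(self, tmp_path):
        act, comp = write_tables(
            tmp_path,
            ["A\tglucose\timport\t3\t1", "A\tglucose\timport\t5\t0"],
            ["glucose\tsmall_metabolite\t"],
        )
        with pytest.raises(ValidationError, match="glucose"):
            load_network(act, comp)

    def test_identical_strain_rows_merge_idempotently(self, tmp_path):
        act, comp = write_tables(
            tmp_path,
            ["A\tglucose\timport\t3\t1", "A\tGlucose\timport\t3\t1"],
            ["glucose\tsmall_metabolite\t"],
        )
        net = load_network(act, comp)
        assert len(net.activities) == 1

    def test_load_write_load_fixed_point(self, tmp_path, small_community):
        """Reloading the serialized network reproduces the same activity sets."""
        small_community.write(tmp_path / "sim")
        net1 = load_network(tmp_path / "sim/activities.tsv", tmp_path / "sim/compounds.tsv")
        for s in sorted(small_community.network.species):
            assert net1.imports(s) == small_community.network.imports(s)
            assert net1.effective_exports(s) == small_community.network.effective_exports(s)


class TestConfidenceScore:
    @pytest.mark.parametrize(
        "n,n_max,k,expected",
        [(10, 10, 1, 100.0), (0, 10, 0, 0.0), (7, 10, 0, 49.0)],
    )
    def test_analytic_values(self, n, n_max, k, expected):
        assert confidence_score(n, n_max, k) == pytest.approx(expected)

    @pytest.mark.parametrize("n,n_max,k", [(11, 10, 0), (1, 0, 0), (-1, 10, 0)])
    def test_domain_errors(self, n, n_max, k):
        with pytest.raises(DomainError):
            confidence_score(n, n_max, k)

    @given(
        n=st.integers(0, 50),
        n_max=st.integers(1, 50),
        k=st.integers(0, 1),
    )
    @settings(max_examples=200, deadline=None)
    def test_bounds_and_monotonicity(self, n, n_max, k):
        if n > n_max:
            n = n_max
        c = confidence_score(n, n_max, k)
        assert 0.0 <= c <= 100.0
        if n + 1 <= n_max:
            assert confidence_score(n + 1, n_max, k) >= c
        assert confidence_score(n, n_max, 1) >= confidence_score(n, n_max, 0)


class TestTransportProfile:
    def test_toy_counts(self, toy_net):
        prof = transport_profile(toy_net).per_species
        assert tuple(prof.loc["a"]) == (1, 1)
        assert tuple(prof.loc["b"]) == (0, 1)

    def test_degradation_products_count_as_exports(self):
        net = make_network(
            [("D", "cellulose", Activity.DEGRADES)],
            products={"cellulose": ["glucose", "cellobiose"]},
        )
        prof = transport_profile(net).per_species
        assert tuple(prof.loc["d"]) == (0, 2)

    def test_both_counts_once_for_each_role(self):
        net = make_network([("A", "glucose", Activity.BOTH)])
        prof = transport_profile(net).per_species
        assert tuple(prof.loc["a"]) == (1, 1)

    def test_transport_conservation(self, small_community):
        """Degradation inflates exports, never deflates: total counted
        transports are at least the number of activity rows."""
        net = small_community.network
        prof = transport_profile(net).per_species
        assert prof.to_numpy().sum() >= net.n_transport_events


class TestMetaboliteUsage:
    def test_consumer_fraction(self):
        net = make_network(
            [
                ("A", "glucose", Activity.IMPORT),
                ("B", "glucose", Activity.IMPORT),
                ("C", "xylose", Activity.IMPORT),
                ("D", "acetate", Activity.EXPORT),
            ]
        )
        usage = metabolite_usage(net)
        assert usage.loc["glucose", "consumer_pct"] == pytest.approx(50.0)
        assert usage.loc["acetate", "producer_pct"] == pytest.approx(25.0)

    def test_untouched_compound_is_zero(self):
        net = make_network(
            [("A", "glucose", Activity.IMPORT)], compounds={"orphan"}
        )
        usage = metabolite_usage(net)
        assert usage.loc["orphan", "consumer_pct"] == 0.0
        assert usage.loc["orphan", "producer_pct"] == 0.0

    def test_empty_restriction_rejected(self, toy_net):
        with pytest.raises(DomainError):
            metabolite_usage(toy_net, restrict_to=[])

    def test_permutation_invariance(self, small_community):
        net = small_community.network
        species = sorted(net.species)
        u1 = metabolite_usage(net, restrict_to=species)
        u2 = metabolite_usage(net, restrict_to=list(reversed(species)))
        pd.testing.assert_frame_equal(u1, u2)


class TestAbundanceTransportCorrelation:
    def test_collinear_gives_r2_one(self):
        acts = []
        for i, s in enumerate(["A", "B", "C", "D"]):
            for j in range(i + 1):
                acts.append((s, f"met{j}", Activity.IMPORT))
        net = make_network(acts)
        # abundance proportional to transport count
        data = pd.DataFrame(
            {"C": [1.0, 2.0, 3.0, 4.0], "M": [1.0, 2.0, 3.0, 4.0], "P1": [1.0, 2.0, 3.0, 4.0]},
            index=["A", "B", "C", "D"],
        )
        r2 = abundance_transport_correlation(net, AbundanceTable(data))
        assert r2 == pytest.approx(1.0)

    def test_independent_draws_give_r2_near_zero(self):
        rng = np.random.default_rng(42)
        n = 500
        acts = []
        for i in range(n):
            k = int(rng.integers(1, 20))
            for j in range(k):
                acts.append((f"s{i}", f"met{j}", Activity.IMPORT))
        net = make_network(acts)
        data = pd.DataFrame(
            rng.lognormal(0, 1, size=(n, 3)),
            index=[f"s{i}" for i in range(n)],
            columns=["C", "M", "P1"],
        )
        r2 = abundance_transport_correlation(net, AbundanceTable(data))
        assert r2 < 0.05

    def test_too_few_shared_species_rejected(self, toy_net):
        data = pd.DataFrame({"C": [1.0], "M": [1.0], "P1": [2.0]}, index=["A"])
        with pytest.raises(DomainError):
            abundance_transport_correlation(toy_net, AbundanceTable(data))


class TestExports:
    def test_sif_and_graphml(self, toy_net, tmp_path):
        toy_net.to_sif(tmp_path / "net.sif")
        toy_net.to_graphml(tmp_path / "net.graphml")
        lines = (tmp_path / "net.sif").read_text().strip().split("\n")
        assert "a\timports\tglucose" in lines
        assert "b\tdegrades\tcellulose" in lines
        g = toy_net.to_graph()
        assert g.edges["a", "glucose"]["activity"] == "import"
        assert 0 <= g.edges["a", "glucose"]["confidence"] <= 100
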