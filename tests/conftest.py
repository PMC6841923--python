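import numpy as np
import pandas as pd
import pytest

from termnet.network_model import (
    Activity,
    Compound,
    CompoundClass,
    CrossFeedingNetwork,
    MetabolicActivity,
)
from termnet.segmentation import AbundanceTable
from termnet.synthetic_data import CommunitySpec, generate_community


def make_network(activities, compounds=None, products=None):
    """Terse builder: activities as (species, compound, activity[, n, K]) tuples;
    ``products`` maps macromolecule -> iterable of product names."""
    products = products or {}
    acts = [MetabolicActivity(*a) for a in activities]
    names = {a.compound for a in acts} | set(products) | {
        p for prods in products.values() for p in prods
    }
    if compounds is not None:
        names |= set(compounds)
    comps = []
    for n in sorted(names):
        if n in products:
            comps.append(
                Compound(n, CompoundClass.MACROMOLECULE, frozenset(products[n]))
            )
        else:
            comps.append(Compound(n, CompoundClass.SMALL_METABOLITE))
    return CrossFeedingNetwork(comps, acts)


@pytest.fixture
def toy_net():
    """Two species: A imports glucose / exports acetate, B degrades cellulose."""
    return make_network(
        [
            ("A", "glucose", Activity.IMPORT),
            ("A", "acetate", Activity.EXPORT),
            ("B", "cellulose", Activity.DEGRADES),
        ],
        products={"cellulose": ["glucose"]},
    )


@pytest.fixture
def trio_net():
    """One cellulose degrader feeding two fermenters that compete for glucose."""
    return make_network(
        [
            ("deg", "cellulose", Activity.DEGRADES),
            ("deg", "met_x", Activity.IMPORT),
            ("f1", "glucose", Activity.IMPORT),
            ("f1", "acetate", Activity.EXPORT),
            ("f2", "glucose", Activity.IMPORT),
            ("f2", "ethanol", Activity.EXPORT),
        ],
        products={"cellulose": ["glucose"]},
    )


@pytest.fixture
def trio_abundance():
    data = pd.DataFrame(
        {
            "C": [1.0, 1.0, 1.0],
            "M": [1.0, 1.0, 1.0],
            "P1": [1.0, 1.0, 1.0],
        },
        index=["deg", "f1", "f2"],
    )
    return AbundanceTable(data)


@pytest.fixture(scope="session")
def small_community():
    """Default-structure synthetic community at test scale (one fixed seed)."""
    spec = CommunitySpec(
        n_species=40, n_metabolites=140, n_macromolecules=4, seed=11
    )
    return generate_community(spec)


def hub_spec(seed):
    """Community whose single degrader is a planted hub feeding most species."""
    return CommunitySpec(
        n_species=30,
        n_metabolites=120,
        n_macromolecules=4,
        degrader_fraction=0.034,
        fermenter_fraction=0.6,
        specialist_fraction=0.1,
        n_hubs=1,
        seed=seed,
    )
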