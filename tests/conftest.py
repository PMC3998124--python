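import numpy as np
import pytest

from metaregulon import (
    SiteCollection,
    build_scoring_model,
    generate_metagenome,
    recovery_fixture_config,
)

CONSENSUS = "GAACGTTC"

#: Mixed-column collection used for all brute-force-derived expectations.
SIX_SITES = [
    "GAACGTTC",
    "GTACGTTC",
    "GAACGTAC",
    "CAACGTTC",
    "GAACGATC",
    "TAACGTTG",
]

#: Frozen values from an independent per-column-counting oracle
#: (direct application of f = (n + a)/(N + 4a), w = 2 + log2 f, and
#: per-site summation; pseudocount 0.25, population SD).
SIX_SITE_ORACLE = {
    "pseudocount": 0.25,
    "mean": 11.16069059118013,
    "sd_pop": 1.1131489628991855,
    "sd_sample": 1.2193935936867304,
    "threshold": 9.490967146831352,
    "rsequence": 8.126467369767632,
    "probe_scores": {
        "GAACGTTC": 13.12946172522872,
        "CTACGATG": 5.152758995191551,
        "TTTTTTTT": -9.03034834112859,
    },
    "max_score": 13.12946172522872,
}


@pytest.fixture(scope="session")
def consensus_model():
    """4 identical sites, pseudocount 0: 2 bits at the consensus base."""
    return build_scoring_model(
        SiteCollection.from_sequences([CONSENSUS] * 4), pseudocount=0.0
    )


@pytest.fixture(scope="session")
def uniform_model():
    """Every position holds one of each base: f = 0.25 everywhere."""
    return build_scoring_model(
        SiteCollection.from_sequences(
            ["AAAAAAAA", "CCCCCCCC", "GGGGGGGG", "TTTTTTTT"]
        ),
        pseudocount=0.0,
    )


@pytest.fixture(scope="session")
def six_site_model():
    return build_scoring_model(
        SiteCollection.from_sequences(SIX_SITES), pseudocount=0.25
    )


@pytest.fixture(scope="session")
def recovery_metagenome():
    """The standard parameter-recovery dataset (~2 Mb, 5 regulon COGs x
    15 planted sites, 50 background COGs), fixed seed."""
    return generate_metagenome(recovery_fixture_config(seed=1))


def random_contig_seq(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=p)])
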